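"""Model contracts: shapes, determinism, probability outputs, parameter
arithmetic, and gradient correctness of the underlying engine."""

import numpy as np
import pytest

from seedlingrgbd.autograd import (Tensor, conv2d_3x3, layer_norm, maxpool2x2,
                                   softmax, softmax_cross_entropy)
from seedlingrgbd.models import (CnnBlockSpec, ModelSpec, TransformerSpec,
                                 build_model)
from seedlingrgbd.nn import GRU


# -- autograd engine --------------------------------------------------------

def _gradcheck(f, *arrays, eps=1e-6, tol=1e-5):
    """Central finite differences against the engine's backward pass."""
    ts = [Tensor(a.copy(), requires_grad=True) for a in arrays]
    f(*ts).backward()
    for j, a in enumerate(arrays):
        num = np.zeros_like(a)
        it = np.nditer(a, flags=["multi_index"])
        for _ in it:
            i = it.multi_index

            def ev(val):
                args = [Tensor(x.copy()) for x in arrays]
                args[j].data[i] = val
                return f(*args).data

            num[i] = (ev(a[i] + eps) - ev(a[i] - eps)) / (2 * eps)
        assert np.abs(num - ts[j].grad).max() < tol, f"argument {j}"


def test_conv_pool_crossentropy_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((2, 3, 6, 6))
    w = rng.standard_normal((4, 3, 3, 3)) * 0.3
    b = rng.standard_normal(4) * 0.1
    proj = Tensor(rng.standard_normal((4 * 3 * 3, 4)) * 0.1)
    y = np.array([1, 3])
    _gradcheck(
        lambda x, w, b: softmax_cross_entropy(
            maxpool2x2(conv2d_3x3(x, w, b).relu()).reshape(2, -1) @ proj, y),
        x, w, b)


def test_layernorm_and_softmax_gradients_match_finite_differences():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((3, 4, 5))
    g, b = np.ones(5), np.zeros(5)
    _gradcheck(lambda x, g, b: layer_norm(x, g, b).tanh().mean(), x, g, b)
    _gradcheck(lambda x: (softmax(x, axis=-1) * Tensor(np.arange(5.0))).mean(),
               x)


def test_gru_gradients_match_finite_differences():
    rng = np.random.default_rng(2)
    gru = GRU(3, 4, rng)
    xs = [rng.standard_normal((2, 3)) for _ in range(3)]

    def f(*steps):
        return gru([s for s in steps]).mean()

    _gradcheck(f, *xs, tol=1e-5)


# -- model construction -----------------------------------------------------

ALL_SPECS = [(b, f) for b in ("cnn", "td_cnn_gru", "transformer")
             for f in ("none_rgb", "image", "feature")]


@pytest.mark.parametrize("backbone,fusion", ALL_SPECS)
def test_probabilities_sum_to_one_for_every_variant(backbone, fusion):
    spec = ModelSpec(backbone=backbone, fusion=fusion)
    clf = build_model(spec, seed=0)
    rng = np.random.default_rng(0)
    shape = ((3, 66, 66, 4) if spec.sequence_length == 1
             else (3, spec.sequence_length, 66, 66, 4))
    p = clf.predict_proba(rng.random(shape))
    assert p.shape == (3, 4)
    assert (p >= 0).all()
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_first_conv_differs_only_in_input_channels():
    """Image fusion consumes 4 channels where the RGB baseline consumes 3;
    everything after the first convolution has identical shapes."""
    m4 = build_model(ModelSpec(backbone="cnn", fusion="image"), seed=0)
    m3 = build_model(ModelSpec(backbone="cnn", fusion="none_rgb"), seed=0)
    w4 = [c.w.data.shape for c in m4.streams[0].convs]
    w3 = [c.w.data.shape for c in m3.streams[0].convs]
    assert w4[0] == (w3[0][0], 4, 3, 3)
    assert w3[0][1] == 3
    assert w4[1:] == w3[1:]


def test_same_seed_builds_identical_models():
    rng = np.random.default_rng(9)
    batch = rng.random((2, 66, 66, 4))
    a = build_model(ModelSpec(backbone="cnn", fusion="image"), seed=5)
    b = build_model(ModelSpec(backbone="cnn", fusion="image"), seed=5)
    assert np.array_equal(a.predict_proba(batch), b.predict_proba(batch))
    c = build_model(ModelSpec(backbone="cnn", fusion="image"), seed=6)
    assert not np.array_equal(a.predict_proba(batch), c.predict_proba(batch))


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="backbone"):
        ModelSpec(backbone="vgg16")
    with pytest.raises(ValueError, match="fusion"):
        ModelSpec(fusion="decision")
    with pytest.raises(ValueError, match="single frames"):
        ModelSpec(backbone="cnn", sequence_length=4)


def test_shape_mismatch_error_names_expected_shape():
    clf = build_model(ModelSpec(backbone="cnn", fusion="image"), seed=0)
    with pytest.raises(ValueError, match=r"\(N, 66, 66, 4\)"):
        clf.predict_proba(np.zeros((2, 66, 66, 3)))
    tclf = build_model(ModelSpec(backbone="td_cnn_gru", fusion="image"), seed=0)
    with pytest.raises(ValueError, match="4, 66, 66, 4"):
        tclf.predict_proba(np.zeros((2, 66, 66, 4)))


@pytest.mark.parametrize("fusion,channels", [("none_rgb", (3,)),
                                             ("image", (4,)),
                                             ("feature", (3, 1))])
def test_parameter_count_matches_closed_form(fusion, channels):
    spec = ModelSpec(backbone="cnn", fusion=fusion)
    assert build_model(spec, 0).param_count() == spec.cnn.param_count(channels)


def test_untrained_models_are_unbiased_across_seeds():
    """Mean class probability over many fresh initialisations is ~uniform."""
    rng = np.random.default_rng(0)
    batch = rng.random((4, 66, 66, 4))
    probs = [build_model(ModelSpec(backbone="cnn", fusion="image"), seed=s)
             .predict_proba(batch).mean(axis=0) for s in range(20)]
    mean = np.mean(probs, axis=0)
    assert np.abs(mean - 0.25).max() < 0.05


def test_inference_is_deterministic_and_batch_invariant():
    clf = build_model(ModelSpec(backbone="cnn", fusion="image"), seed=0)
    rng = np.random.default_rng(4)
    x = rng.random((1, 66, 66, 4))
    single = clf.predict_proba(x)
    dup = clf.predict_proba(np.concatenate([x, x]))
    assert np.allclose(single[0], dup[0], atol=1e-12)
    assert np.allclose(dup[0], dup[1], atol=1e-12)
    assert np.array_equal(clf.predict_proba(x), clf.predict_proba(x))


def test_checkpoint_round_trip(tmp_path):
    clf = build_model(ModelSpec(backbone="cnn", fusion="feature"), seed=3)
    rng = np.random.default_rng(0)
    x = rng.random((2, 66, 66, 4))
    before = clf.predict_proba(x)
    path = tmp_path / "ckpt.npz"
    clf.save(path)
    loaded = type(clf).load(path)
    assert loaded.spec == clf.spec
    assert np.array_equal(loaded.predict_proba(x), before)


def test_presets_expose_study_scale_and_desk_scale():
    paper = CnnBlockSpec()
    assert paper.filters == (64, 128, 256, 256)
    assert paper.dense_units == 512 and paper.dropout == 0.5
    assert TransformerSpec.paper().n_layers == 32
    assert TransformerSpec.paper().batch_size == 64
    desk = CnnBlockSpec.desk()
    assert len(desk.filters) == len(paper.filters)
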