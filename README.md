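# seedlingrgbd

RGB-Depth fusion for monitoring the earliest stages of seedling growth
from top-view time-lapse imagery.

Plant scientists track when a seedling emerges from the soil, when its
cotyledons open and when the first true leaf appears: the timing of these
transitions drives emergence phenotyping and seed-lot quality assessment.
Low-cost RGB-D cameras mounted above pots capture a registered colour and
metric-depth image pair every 15 minutes.  Colour is only available while
the growth-chamber lights are on; the active-IR depth channel records
day and night.  This package implements, end to end:

- **Growth-stage classification** of 66×66 pot crops into the four ordered
  stages `SOIL < FA < OC < FL` (soil, first appearance of the cotyledon,
  opening of the cotyledons, first leaf), with six classifier variants —
  {CNN, TD-CNN-GRU, transformer} × {image fusion, feature fusion} — plus
  RGB-only baselines.  *Image fusion* stacks RGB and depth into a
  4-channel input; *feature fusion* extracts deep features per modality
  and merges them before the classification head.
- **Night-time switch detection** from depth alone: the cotyledons opening
  raise the canopy abruptly by ~10 mm, so the spatial-mean camera distance
  drops.  The detector reports the first night frame from which the mean
  depth stays (for 4 consecutive frames = 1 h) closer to the next stage's
  depth level than to the previous one.
- **A synthetic RGB-D seedling simulator** that emulates the structure of
  such a dataset — 616 frames per sequence (424 day + 192 night), six bean
  varieties with heterogeneous cotyledon size/shape/colour, abrupt depth
  step at cotyledon opening, gradual RGB change in every stage, sensor
  dropouts in depth, no RGB at night — so the full pipeline is testable
  without any data download.

The classifiers are trained with a compact NumPy neural-network engine
bundled in the package (reverse-mode autograd, 3×3 convolutions, GRU,
multi-head attention); everything is CPU-only, deterministic under a seed,
and desk-scale presets keep experiments in the minutes range.

## Worked example

Simulate a small dataset, train an image-fusion CNN against the RGB-only
baseline, and localise a night-time switch:

```python
import seedlingrgbd as sg
from seedlingrgbd.experiment import TrainConfig, run_comparison
from seedlingrgbd.night import extract_night_episode, detect_night_switch

# sequences with the cotyledon opening visible only in depth
params = sg.SceneParams(oc_rgb_contrast=0.0, frames_day=128, frames_night=32,
                        day_block=128, soil_frames_mean=30,
                        fa_frames_mean=35, oc_frames_mean=35)
seqs = {split: [sg.generate_sequence(params, s + i, variety=v, pot_id=f"{v}_{split}")
                for i, v in enumerate(["Caprice", "Deezer"])]
        for s, split in ((1000, "train"), (1002, "validation"), (1004, "test"))}

cfg = TrainConfig(epochs=12, batch_size=32, repetitions=1, seeds=[0],
                  patience=5, window_stride=2)
results, table = run_comparison(["cnn"], ["none_rgb", "image"], seqs, cfg)
print(table.to_string(index=False))
```

```
backbone   fusion  train_mean  train_std  validation_mean  validation_std  test_mean  test_std
     cnn none_rgb      0.8984        0.0           0.9219             0.0     0.8516       0.0
     cnn    image      1.0000        0.0           1.0000             0.0     1.0000       0.0
```

The RGB-only model cannot separate a fully grown cotyledon bud (late FA)
from an opened one (OC) — the information is in the depth channel — so it
tops out near 0.85 while the 4-channel model is perfect on this synthetic
set; its confusions sit exclusively on developmentally adjacent stages.

```python
episode = sg.generate_switch_episode(sg.SceneParams(), seed=5,
                                     transition="FA:OC", night_offset=10)
inputs, truth = extract_night_episode(episode, "FA:OC")
trace = detect_night_switch(inputs)
print(trace.idx, truth, trace.pt)   # -> 10 10 74
```

`trace.idx` is the detected offset inside the night, `trace.pt` the same
event indexed into the concatenation of the preceding day and the night
(`Pt = len(Sa) + Idx`, here 64 + 10).

The same workflows are available from the shell:

```bash
seedlingrgbd simulate --preset table1 --out dataset --seed 1
seedlingrgbd train --spec cnn:image --data dataset --seed 0
seedlingrgbd compare --data dataset --backbones cnn --reps 10
seedlingrgbd detect-night --sequence dataset/train/Flavert/... --transition FA:OC
seedlingrgbd validate-night --data dataset --tolerance 4 --out report.json
```

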