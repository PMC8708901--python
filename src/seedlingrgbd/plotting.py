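"""Small plotting helpers (matplotlib is an optional dependency)."""

from __future__ import annotations

import numpy as np

from .experiment import ConfusionMatrix
from .night import NightEventTrace
from .records import GrowthStage

__all__ = ["plot_confusion_matrix", "plot_night_trace"]


def _require_axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_confusion_matrix(cm: ConfusionMatrix, ax=None, normalize: bool = True):
    """Heatmap of the 4x4 stage confusion matrix with count annotations."""
    ax = _require_axes(ax)
    counts = cm.counts.astype(float)
    shown = counts / counts.sum(axis=1, keepdims=True).clip(min=1) if normalize \
        else counts
    ax.imshow(shown, cmap="Blues", vmin=0)
    labels = [s.name for s in GrowthStage]
    ax.set_xticks(range(4), labels)
    ax.set_yticks(range(4), labels)
    ax.set_xlabel("predicted stage")
    ax.set_ylabel("true stage")
    for i in range(4):
        for j in range(4):
            ax.text(j, i, f"{cm.counts[i, j]}", ha="center", va="center",
                    color="black" if shown[i, j] < 0.5 * shown.max() else "white")
    return ax


def plot_night_trace(trace: NightEventTrace, ax=None):
    """Spatial-mean depth through the night with the stage levels and the
    detected switch frame."""
    ax = _require_axes(ax)
    k = np.arange(len(trace.dn_bar))
    ax.plot(k, trace.dn_bar, marker=".", label="night mean depth")
    ax.axhline(trace.mda, ls="--", color="tab:green", label="stage-A level")
    ax.axhline(trace.mdb, ls="--", color="tab:orange", label="stage-B level")
    if trace.detected:
        ax.axvline(trace.idx, color="tab:red", label=f"detected (Idx={trace.idx})")
    ax.set_xlabel("night frame")
    ax.set_ylabel("mean camera distance (mm)")
    ax.legend(fontsize=8)
    return ax
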