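"""Gradient saliency maps per time point, with heatmap/overlay rendering.

The map at time point k is the absolute gradient of the series-level IA
probability (the final step's, optionally its pre-sigmoid logit) with
respect to the voxels of patch k, clipped to [0, 0.01] for display.  Because
the temporal attention is causal and decays with elapsed time, early scans
of a fast-growing series receive little gradient mass once late scans carry
the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from .model import ViSTANetwork
from .preprocess import FollowUpSeries

DEFAULT_CLIP = 0.01


@dataclass
class SaliencyMap:
    """Clipped absolute-gradient grid for one time point of a series."""

    values: np.ndarray           # in [0, clip_max], shape of the patch
    timepoint: int
    clip_max: float = DEFAULT_CLIP
    raw: np.ndarray | None = None   # unclipped |gradient|, for re-scaling


def saliency_map(network: ViSTANetwork, series: FollowUpSeries, timepoint: int,
                 clip_max: float = DEFAULT_CLIP,
                 target: str = "probability") -> SaliencyMap:
    """Backpropagated saliency of the final-step prediction w.r.t. patch k."""
    if not 0 <= timepoint < len(series):
        raise IndexError(f"timepoint {timepoint} out of range for series of "
                         f"length {len(series)}")
    network.eval()
    patches = Tensor(np.asarray(series.patches, dtype=network.dtype),
                     requires_grad=True)
    logits = network.forward(patches, series.times)
    out = logits[-1]
    if target == "probability":
        out = out.sigmoid()
    elif target != "logit":
        raise ValueError(f"unknown saliency target {target!r}")
    out.backward()
    raw = np.abs(patches.grad[timepoint])
    return SaliencyMap(values=np.clip(raw, 0.0, clip_max),
                       timepoint=timepoint, clip_max=clip_max, raw=raw)


def saliency_series(network, series, clip_max=DEFAULT_CLIP,
                    target="probability") -> list[SaliencyMap]:
    """Saliency map at every time point (one backward pass per point)."""
    return [saliency_map(network, series, k, clip_max, target)
            for k in range(len(series))]


def _axial_slice(grid: np.ndarray, index: int | None) -> np.ndarray:
    if index is None:
        index = grid.shape[0] // 2
    return grid[index]


def overlay(patch: np.ndarray, smap: SaliencyMap, axis: int = 0,
            index: int | None = None, out_path: str | Path | None = None,
            ax=None):
    """Render CT slice, heatmap and overlay for one time point.

    The colour scale is fixed to [0, clip_max] so maps are comparable across
    the time points of a series.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    patch = np.moveaxis(patch, axis, 0)
    values = np.moveaxis(smap.values, axis, 0)
    if patch.shape != values.shape:
        raise ValueError("patch and saliency map shapes differ")
    ct = _axial_slice(patch, index)
    heat = _axial_slice(values, index)
    fig, axes = plt.subplots(3, 1, figsize=(2.2, 6.6))
    _draw_column(axes, ct, heat, smap.clip_max)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=100)
        plt.close(fig)
        return None
    return fig


def _draw_column(axes, ct, heat, clip_max):
    axes[0].imshow(ct, cmap="gray", vmin=0.0, vmax=1.0)
    axes[1].imshow(heat, cmap="jet", vmin=0.0, vmax=clip_max)
    axes[2].imshow(ct, cmap="gray", vmin=0.0, vmax=1.0)
    axes[2].imshow(heat, cmap="jet", vmin=0.0, vmax=clip_max, alpha=0.5)
    for ax in axes:
        ax.set_xticks([])
        ax.set_yticks([])


def series_montage(network: ViSTANetwork, series: FollowUpSeries,
                   out_path: str | Path, clip_max: float = DEFAULT_CLIP,
                   axis: int = 0, index: int | None = None):
    """Three-row montage (CT / heatmap / overlay), one column per time point."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    maps = saliency_series(network, series, clip_max)
    n = len(series)
    fig, axes = plt.subplots(3, n, figsize=(2.0 * n, 6.0), squeeze=False)
    for k in range(n):
        patch = np.moveaxis(series.patches[k], axis, 0)
        values = np.moveaxis(maps[k].values, axis, 0)
        ct = _axial_slice(patch, index)
        heat = _axial_slice(values, index)
        _draw_column(axes[:, k], ct, heat, clip_max)
        axes[0, k].set_title(f"day {int(series.times[k])}", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return maps
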