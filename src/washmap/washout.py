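"""Signed wash-out percentage maps and per-voxel three-class labels.

The map compares the normalized early (~5 min) and late (~25 min)
post-contrast signals voxel by voxel:

    percent(v) = 100 * (early(v) - late(v)) / early(v)   where early(v) > 0

Positive values mean the signal dropped between the acquisitions (rapid
contrast wash-out, glioblastoma-like kinetics); negative values mean it
rose (late enhancement, metastasis-like kinetics). The denominator is
the early signal by convention — the percentage is the fraction of the
early signal that cleared. A symmetric dead-band ``epsilon`` absorbs
residual noise and normalization error; voxels inside it, and voxels
with non-positive early signal (air, background), are NEUTRAL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Any

import numpy as np

from .volume import Volume3D

__all__ = ["Label", "WashoutMap", "compute_map", "render_overlay", "save_montage"]


class Label(IntEnum):
    NEUTRAL = 0
    WASHOUT = 1
    LATE_ENHANCEMENT = 2


@dataclass
class WashoutMap:
    percent: Volume3D
    labels: Volume3D  # uint8 grid of Label values
    epsilon: float
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def washout_mask(self) -> np.ndarray:
        return self.labels.values == Label.WASHOUT

    @property
    def late_mask(self) -> np.ndarray:
        return self.labels.values == Label.LATE_ENHANCEMENT

    def save(self, percent_path: str | Path, labels_path: str | Path) -> None:
        self.percent.save(percent_path)
        import nibabel as nib
        nib.save(
            nib.Nifti1Image(self.labels.values.astype(np.uint8), self.labels.affine),
            str(labels_path),
        )


def compute_map(
    early_n: Volume3D,
    late_n: Volume3D,
    epsilon: float = 5.0,
    difference_only: bool = False,
    provenance: dict[str, Any] | None = None,
) -> WashoutMap:
    """Build the wash-out map from co-registered, normalized volumes.

    ``difference_only=True`` stores the plain difference (early - late)
    instead of the percentage; labels still use the dead-band rule on the
    stored values.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if not early_n.same_grid_as(late_n):
        raise ValueError("early and late volumes must share grid and affine")

    e = np.asarray(early_n.values, dtype=float)
    l = np.asarray(late_n.values, dtype=float)
    valid = e > 0
    if difference_only:
        values = np.where(valid, e - l, 0.0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(valid, 100.0 * (e - l) / np.where(valid, e, 1.0), 0.0)

    labels = np.zeros(e.shape, dtype=np.uint8)
    labels[valid & (values > epsilon)] = Label.WASHOUT
    labels[valid & (values < -epsilon)] = Label.LATE_ENHANCEMENT

    return WashoutMap(
        percent=Volume3D(values, early_n.affine, {"kind": "percent" if not difference_only else "difference"}),
        labels=Volume3D(labels, early_n.affine, {"kind": "labels"}),
        epsilon=float(epsilon),
        provenance=provenance or {},
    )


def render_overlay(
    wmap: WashoutMap,
    background: Volume3D,
    saturation_percent: float = 50.0,
    alpha: float = 0.6,
) -> np.ndarray:
    """Red/green overlay on the grayscale background, shape ``(*grid, 3)``.

    Red encodes wash-out (positive percent), green late enhancement
    (negative percent); both channels saturate at ``saturation_percent``
    so the color scale is symmetric. Neutral voxels stay grayscale.
    """
    if not wmap.percent.same_grid_as(background):
        raise ValueError("overlay background must share the map grid")
    if saturation_percent <= 0:
        raise ValueError("saturation_percent must be > 0")

    bg = np.asarray(background.values, dtype=float)
    lo, hi = np.min(bg), np.max(bg)
    gray = (bg - lo) / (hi - lo) if hi > lo else np.zeros_like(bg)

    p = np.asarray(wmap.percent.values, dtype=float)
    red = np.clip(p / saturation_percent, 0.0, 1.0)
    green = np.clip(-p / saturation_percent, 0.0, 1.0)
    strength = np.maximum(red, green)

    rgb = np.repeat(gray[..., np.newaxis], 3, axis=-1)
    blend = alpha * strength
    rgb[..., 0] = (1 - blend) * gray + blend * (red / np.maximum(strength, 1e-30))
    rgb[..., 1] = (1 - blend) * gray + blend * (green / np.maximum(strength, 1e-30))
    rgb[..., 2] = (1 - blend) * gray
    return np.clip(rgb, 0.0, 1.0)


def save_montage(
    rgb: np.ndarray,
    path: str | Path,
    axis: int = 2,
    n_slices: int = 9,
) -> None:
    """Write a QC montage PNG of evenly spaced slices along ``axis``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = rgb.shape[axis]
    picks = np.linspace(0, n - 1, min(n_slices, n)).round().astype(int)
    cols = int(np.ceil(np.sqrt(len(picks))))
    rows = int(np.ceil(len(picks) / cols))
    fig, axes = plt.subplots(rows, cols, figsize=(3 * cols, 3 * rows))
    for ax, idx in zip(np.atleast_1d(axes).ravel(), picks):
        sl = np.take(rgb, idx, axis=axis)
        ax.imshow(np.transpose(sl, (1, 0, 2)), origin="lower")
        ax.set_title(f"slice {idx}", fontsize=8)
    for ax in np.atleast_1d(axes).ravel():
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
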