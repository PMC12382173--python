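"""Lesion segmentation, compartment volumetry, and per-lesion ratios.

Mirrors a semi-automatic clinical workflow: lesions are traced slice by
slice with a level-trace analog (2-D connected components within an
intensity band, stacked across contiguous slices), compartment volumes
are voxel counts times voxel volume, and three per-lesion scalars are
derived:

* wash-out ratio = V(wash-out) / (V(wash-out) + V(late enhancement)),
* rCBV ratio = mean of three single-slice tumor ROI means over the
  contralateral ROI mean,
* ADC ratio = tumor ROI mean over contralateral ROI mean.

Size filters reproduce the study's lesion-inclusion rules: a minimum
bounding-box extent of 3 mm per axis (micrometastases are excluded —
they are often visible only on the late acquisition and have wash-out
ratios near zero, which would bias group means), and a sensitivity
filter dropping enhancing volumes below 1 cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .volume import Volume3D
from .washout import Label, WashoutMap

__all__ = [
    "LesionMeasurement",
    "trace_lesion",
    "compartment_volumes",
    "washout_ratio",
    "size_filters",
    "rcbv_ratio",
    "adc_ratio",
    "bounding_extents_mm",
    "largest_area_slices",
]

MIN_EXTENT_MM = 3.0
MIN_VOLUME_MM3 = 1000.0


@dataclass
class LesionMeasurement:
    """One row of the per-lesion measurement table."""

    lesion_id: str
    group: str = "unknown"
    v_washout_mm3: float = 0.0
    v_late_mm3: float = 0.0
    v_enhancing_mm3: float = 0.0
    washout_ratio: float = float("nan")
    rcbv_ratio: float = float("nan")
    adc_ratio: float = float("nan")
    bbox_extents_mm: tuple[float, float, float] | None = None
    flags: set[str] = field(default_factory=set)

    def as_row(self) -> dict:
        return {
            "lesion_id": self.lesion_id,
            "group": self.group,
            "v_washout_mm3": self.v_washout_mm3,
            "v_late_mm3": self.v_late_mm3,
            "v_enhancing_mm3": self.v_enhancing_mm3,
            "washout_ratio": self.washout_ratio,
            "rcbv_ratio": self.rcbv_ratio,
            "adc_ratio": self.adc_ratio,
            "flags": ";".join(sorted(self.flags)),
        }


def trace_lesion(
    volume: Volume3D,
    seed_voxel: Sequence[int],
    band: tuple[float, float],
    axis: int = 2,
    fill_holes: bool = False,
) -> np.ndarray:
    """Level-trace analog: slice-wise connected region growing from a seed.

    Starting at the seed's slice, take the 2-D connected component (8-
    connectivity) of voxels whose intensity lies within ``band`` and
    which contains the seed; then walk outward slice by slice, keeping
    the in-band components that touch the previous slice's trace, until
    a slice contributes nothing. Deterministic given its inputs.

    ``fill_holes`` closes 2-D holes in each slice's trace, as a human
    rater's closed contour would.
    """
    lo, hi = band
    if lo > hi:
        raise ValueError("band lower bound exceeds upper bound")
    seed = tuple(int(s) for s in seed_voxel)
    if len(seed) != 3 or any(not 0 <= seed[a] < volume.shape[a] for a in range(3)):
        raise ValueError(f"seed voxel {seed} outside grid {volume.shape}")
    seed_value = float(volume.values[seed])
    if not lo <= seed_value <= hi:
        raise ValueError(f"seed intensity {seed_value} outside band [{lo}, {hi}]")

    in_band = (volume.values >= lo) & (volume.values <= hi)
    mask = np.zeros(volume.shape, dtype=bool)

    def slice_of(arr: np.ndarray, k: int) -> np.ndarray:
        return np.take(arr, k, axis=axis)

    def put_slice(k: int, sl: np.ndarray) -> None:
        idx: list = [slice(None)] * 3
        idx[axis] = k
        mask[tuple(idx)] = sl

    k0 = seed[axis]
    seed_2d = tuple(s for a, s in enumerate(seed) if a != axis)
    lab0 = skmeasure.label(slice_of(in_band, k0), connectivity=2)
    if lab0[seed_2d] == 0:
        raise ValueError("seed not inside an in-band region")
    current = lab0 == lab0[seed_2d]
    if fill_holes:
        current = ndimage.binary_fill_holes(current)
    put_slice(k0, current)

    for direction in (1, -1):
        prev = current
        k = k0 + direction
        while 0 <= k < volume.shape[axis]:
            lab = skmeasure.label(slice_of(in_band, k), connectivity=2)
            touching = np.unique(lab[prev & (lab > 0)])
            if touching.size == 0:
                break
            sl = np.isin(lab, touching)
            if fill_holes:
                sl = ndimage.binary_fill_holes(sl)
            put_slice(k, sl)
            prev = sl
            k += direction

    if not mask.any():
        raise ValueError("trace produced an empty mask")
    return mask


def compartment_volumes(
    lesion_mask: np.ndarray,
    wmap: WashoutMap,
    voxel_volume_mm3: float | None = None,
) -> tuple[float, float, float]:
    """(V_washout, V_late, V_enhancing) in mm^3 within the lesion mask."""
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if lesion_mask.shape != wmap.labels.shape:
        raise ValueError("lesion mask and map grids differ")
    if not lesion_mask.any():
        raise ValueError("empty lesion mask")
    vv = float(voxel_volume_mm3 if voxel_volume_mm3 is not None else wmap.labels.voxel_volume_mm3)
    labels = wmap.labels.values
    v_wash = float(np.count_nonzero(lesion_mask & (labels == Label.WASHOUT))) * vv
    v_late = float(np.count_nonzero(lesion_mask & (labels == Label.LATE_ENHANCEMENT))) * vv
    v_enh = float(np.count_nonzero(lesion_mask & (labels != Label.NEUTRAL))) * vv
    return v_wash, v_late, v_enh


def washout_ratio(v_washout_mm3: float, v_late_mm3: float) -> float:
    """V(wash-out) / (V(wash-out) + V(late enhancement)); NaN when both are zero.

    Callers should flag the NaN case (``ratio_undefined``) rather than
    propagate it silently.
    """
    if v_washout_mm3 < 0 or v_late_mm3 < 0:
        raise ValueError("volumes must be non-negative")
    denom = v_washout_mm3 + v_late_mm3
    if denom == 0:
        return float("nan")
    return v_washout_mm3 / denom


def bounding_extents_mm(mask: np.ndarray, spacing_mm: Sequence[float]) -> tuple[float, float, float]:
    """Per-axis bounding-box extent of a mask, in mm (voxel-count x spacing)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no bounding box")
    extents = []
    for ax in range(3):
        proj = np.any(mask, axis=tuple(a for a in range(3) if a != ax))
        idx = np.nonzero(proj)[0]
        extents.append(float((idx[-1] - idx[0] + 1) * spacing_mm[ax]))
    return tuple(extents)  # type: ignore[return-value]


def size_filters(
    measurements: Sequence[LesionMeasurement],
    min_extent_mm: float = MIN_EXTENT_MM,
    min_volume_mm3: float = MIN_VOLUME_MM3,
) -> list[LesionMeasurement]:
    """Flag lesions against the study's size rules; drop below-minimum lesions.

    ``below_min_size``: some bounding-box extent is smaller than 3 mm
    (boundary-inclusive — exactly 3 mm is retained). These lesions are
    removed from the returned primary list. ``below_1cm3``: enhancing
    volume under 1000 mm^3; retained in the primary analysis, excluded
    only by the sensitivity analysis (filter on the flag downstream).
    """
    out: list[LesionMeasurement] = []
    for m in measurements:
        flags = set(m.flags)
        if m.bbox_extents_mm is not None and any(e < min_extent_mm for e in m.bbox_extents_mm):
            flags.add("below_min_size")
        if m.v_enhancing_mm3 < min_volume_mm3:
            flags.add("below_1cm3")
        if np.isnan(m.washout_ratio):
            flags.add("ratio_undefined")
        m = replace(m, flags=flags)
        if "below_min_size" not in flags:
            out.append(m)
    return out


def _roi_mean(vol: Volume3D, roi: np.ndarray, name: str) -> float:
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != vol.shape:
        raise ValueError(f"{name} ROI grid mismatch")
    if not roi.any():
        raise ValueError(f"{name} ROI is empty")
    return float(vol.values[roi].mean())


def rcbv_ratio(
    rcbv_map: Volume3D,
    tumor_rois: Sequence[np.ndarray],
    contralateral_roi: np.ndarray,
    slice_axis: int = 2,
) -> float:
    """Mean of three single-slice tumor ROI means over the contralateral mean.

    The three ROIs must each live on a single, distinct slice.
    """
    if len(tumor_rois) != 3:
        raise ValueError("exactly 3 tumor ROIs are required")
    slices = []
    means = []
    for i, roi in enumerate(tumor_rois):
        roi = np.asarray(roi, dtype=bool)
        ks = np.unique(np.nonzero(roi)[slice_axis])
        if ks.size == 0:
            raise ValueError(f"tumor ROI {i} is empty")
        if ks.size > 1:
            raise ValueError(f"tumor ROI {i} spans multiple slices along axis {slice_axis}")
        slices.append(int(ks[0]))
        means.append(_roi_mean(rcbv_map, roi, f"tumor {i}"))
    if len(set(slices)) != 3:
        raise ValueError("tumor ROIs must be on three distinct slices")
    contra = _roi_mean(rcbv_map, contralateral_roi, "contralateral")
    if contra <= 0:
        raise ValueError("contralateral rCBV mean must be positive")
    return float(np.mean(means) / contra)


def adc_ratio(
    adc_map: Volume3D,
    tumor_roi: np.ndarray,
    contralateral_roi: np.ndarray,
) -> float:
    """Tumor ROI mean ADC over the healthy contralateral ROI mean."""
    tumor = _roi_mean(adc_map, tumor_roi, "tumor")
    contra = _roi_mean(adc_map, contralateral_roi, "contralateral")
    if contra <= 0:
        raise ValueError("contralateral ADC mean must be positive")
    return float(tumor / contra)


def largest_area_slices(mask: np.ndarray, n: int = 3, axis: int = 2) -> list[np.ndarray]:
    """Single-slice ROIs at the ``n`` slices where the mask area is largest.

    Automates ROI placement on phantoms; clinical use supplies drawn ROIs.
    """
    mask = np.asarray(mask, dtype=bool)
    areas = mask.sum(axis=tuple(a for a in range(3) if a != axis))
    order = np.argsort(areas)[::-1]
    picks = [k for k in order if areas[k] > 0][:n]
    if len(picks) < n:
        raise ValueError(f"mask spans only {len(picks)} nonempty slices; {n} required")
    rois = []
    for k in picks:
        roi = np.zeros_like(mask)
        idx: list = [slice(None)] * 3
        idx[axis] = k
        sl = np.take(mask, k, axis=axis)
        roi[tuple(idx)] = sl
        rois.append(roi)
    return rois
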