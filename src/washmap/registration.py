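"""Rigid co-registration and intensity normalization of the two acquisitions.

The late acquisition is mapped onto the early grid with a 6-DOF rigid
transform (same subject, same session: translation + rotation only),
optimized multi-resolution against normalized cross-correlation by
default (mutual information is available for cross-field-strength
pairs). Intensities are then matched by a robust gain/offset fitted on
normal-appearing brain so that non-enhancing tissue differences center
on zero and the subtraction map is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml
from scipy import ndimage

from .volume import RigidTransform, Volume3D

__all__ = [
    "RegistrationError",
    "RegistrationConfig",
    "RegistrationResult",
    "NormalizationReport",
    "register_rigid",
    "resample_volume",
    "normalize_pair",
    "save_transform",
    "load_transform",
]


class RegistrationError(RuntimeError):
    """Raised when registration preconditions fail (e.g. disjoint fields of view)."""


@dataclass(frozen=True)
class RegistrationConfig:
    metric: str = "ncc"  # "ncc" (normalized cross-correlation) or "mi" (Mattes MI)
    shrink_factors: tuple[int, ...] = (4, 2)
    smoothing_sigmas_mm: tuple[float, ...] = (4.0, 2.0)
    learning_rate: float = 1.0
    min_step: float = 1e-5
    iterations: int = 400
    sampling_fraction: float = 1.0  # dense by default; MI uses random sampling
    convergence_ncc: float = 0.2  # minimum acceptable |correlation| at the optimum
    refine_masked: bool = True  # second pass excluding high-change voxels
    change_sigma_factor: float = 4.0  # |difference| > factor * robust sigma marks change

    def __post_init__(self) -> None:
        if self.metric not in ("ncc", "mi"):
            raise ValueError("metric must be 'ncc' or 'mi'")
        if len(self.shrink_factors) != len(self.smoothing_sigmas_mm):
            raise ValueError("shrink_factors and smoothing_sigmas_mm must align")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    resampled: Volume3D
    metric_trace: list[float]
    final_metric: float
    converged: bool


def _world_bounds(vol: Volume3D) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(vol.shape)
    corners = np.array([[i, j, k] for i in (0, n[0] - 1) for j in (0, n[1] - 1) for k in (0, n[2] - 1)], dtype=float)
    world = corners @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    return world.min(axis=0), world.max(axis=0)


def _check_overlap(fixed: Volume3D, moving: Volume3D) -> None:
    lo_f, hi_f = _world_bounds(fixed)
    lo_m, hi_m = _world_bounds(moving)
    if np.any(hi_f < lo_m) or np.any(hi_m < lo_f):
        raise RegistrationError("fixed and moving volumes do not overlap in world space")


def _run_registration(
    f_img: sitk.Image,
    m_img: sitk.Image,
    config: RegistrationConfig,
    initial: sitk.Euler3DTransform,
    fixed_mask: sitk.Image | None,
    trace: list[float],
) -> sitk.Euler3DTransform:
    reg = sitk.ImageRegistrationMethod()
    if config.metric == "ncc":
        reg.SetMetricAsCorrelation()
    else:
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=48)
    if config.sampling_fraction < 1.0 or config.metric == "mi":
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(min(config.sampling_fraction, 0.5), seed=12345)
    if fixed_mask is not None:
        reg.SetMetricFixedMask(fixed_mask)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=config.learning_rate,
        minStep=config.min_step,
        numberOfIterations=config.iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(initial, inPlace=True)
    reg.SetShrinkFactorsPerLevel(list(config.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(config.smoothing_sigmas_mm))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.AddCommand(sitk.sitkIterationEvent, lambda: trace.append(float(reg.GetMetricValue())))
    out = reg.Execute(f_img, m_img)
    # record the achieved metric for the caller
    trace.append(float(reg.GetMetricValue()))
    return sitk.Euler3DTransform(out)


def register_rigid(
    fixed: Volume3D,
    moving: Volume3D,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Returns the transform (such that ``resampled(x) = moving(T(x))``), the
    moving volume resampled onto the fixed grid with cubic B-spline
    interpolation (linear interpolation blurs the high-contrast lesion
    edge asymmetrically and biases the subtraction there), and the
    optimizer's metric trace.

    The two acquisitions genuinely differ inside enhancing tissue, which
    biases a plain intensity metric: the optimizer trades true alignment
    for overlaying the changed region. A second pass therefore re-runs
    the optimization with the high-change voxels (|difference| beyond
    ``change_sigma_factor`` robust sigmas after the first pass, dilated)
    excluded from the metric, refining on stable anatomy only. A result
    whose final correlation is poor is flagged ``converged=False`` rather
    than silently returned.
    """
    config = config or RegistrationConfig()
    if any(n < 16 for n in fixed.shape) or any(n < 16 for n in moving.shape):
        raise RegistrationError("registration requires at least 16^3 voxels")
    _check_overlap(fixed, moving)

    f_img = fixed.to_sitk()
    m_img = moving.to_sitk()

    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    trace: list[float] = []
    euler = _run_registration(f_img, m_img, config, sitk.Euler3DTransform(initial), None, trace)

    if config.refine_masked:
        resampled1 = sitk.Resample(m_img, f_img, euler, sitk.sitkLinear, 0.0, sitk.sitkFloat64)
        f_arr = sitk.GetArrayFromImage(f_img)
        r_arr = sitk.GetArrayFromImage(resampled1)
        diff = np.abs(r_arr - f_arr)
        body = f_arr > 0.1 * np.percentile(f_arr, 99)
        if body.any():
            sigma = 1.4826 * np.median(np.abs(diff[body] - np.median(diff[body])))
            med = np.median(f_arr[body])
            mad = 1.4826 * np.median(np.abs(f_arr[body] - med))
        else:
            sigma, med, mad = 0.0, 0.0, 0.0
        # only *bright* high-difference voxels are enhancement-driven change;
        # dim high-difference voxels are residual edge misalignment and must
        # stay in the metric, or translation loses its anchors
        bright = np.maximum(f_arr, r_arr) > med + 3.0 * mad
        change = (diff > max(config.change_sigma_factor * sigma, 1e-12)) & bright
        change = ndimage.binary_dilation(change, iterations=1)
        if 0 < change.sum() < 0.5 * change.size:
            mask_img = sitk.GetImageFromArray((~change).astype(np.uint8))
            mask_img.CopyInformation(f_img)
            # local refinement: the first pass already found the basin, the
            # mask removes the change-driven bias; mild smoothing keeps the
            # metric gradient above the voxel-noise floor
            refine_cfg = replace(
                config, shrink_factors=(2, 1), smoothing_sigmas_mm=(2.0, 1.0),
                learning_rate=0.5, iterations=300,
            )
            euler = _run_registration(f_img, m_img, refine_cfg, euler, mask_img, trace)

    transform = RigidTransform.from_sitk(euler)

    final_metric = trace[-1] if trace else 0.0
    # the Correlation metric is the negative squared correlation; MI is negative MI
    if config.metric == "ncc":
        converged = final_metric <= -(config.convergence_ncc**2)
    else:
        converged = final_metric < 0.0

    resampled_img = sitk.Resample(m_img, f_img, euler, sitk.sitkBSpline, 0.0, sitk.sitkFloat64)
    resampled = Volume3D.from_sitk(resampled_img, **{**moving.meta, "registered_to": fixed.meta.get("subject")})
    return RegistrationResult(
        transform=transform,
        resampled=resampled,
        metric_trace=trace,
        final_metric=final_metric,
        converged=converged,
    )


def resample_volume(
    moving: Volume3D,
    reference: Volume3D,
    transform: RigidTransform,
    nearest: bool = False,
) -> Volume3D:
    """Pull ``moving`` through ``transform`` onto the reference grid.

    Cubic B-spline interpolation for images, nearest-neighbour for masks.
    """
    interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkBSpline
    img = sitk.Resample(moving.to_sitk(), reference.to_sitk(), transform.to_sitk(), interp, 0.0, sitk.sitkFloat64)
    return Volume3D.from_sitk(img, **moving.meta)


# ---------------------------------------------------------------------------
# intensity normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationReport:
    gain: float
    offset: float
    reference_scale: float
    n_reference: int
    median_abs_diff_before: float
    median_abs_diff_after: float


def _huber_line_fit(x: np.ndarray, y: np.ndarray, iters: int = 12, k: float = 1.345) -> tuple[float, float]:
    """Deterministic IRLS Huber fit of y ~ gain * x + offset."""
    w = np.ones_like(x)
    gain, offset = 1.0, 0.0
    for _ in range(iters):
        sw = w.sum()
        mx = (w * x).sum() / sw
        my = (w * y).sum() / sw
        cov = (w * (x - mx) * (y - my)).sum()
        var = (w * (x - mx) ** 2).sum()
        if var <= 0:
            break
        gain = cov / var
        offset = my - gain * mx
        r = y - (gain * x + offset)
        mad = np.median(np.abs(r - np.median(r)))
        scale = max(1.4826 * mad, 1e-12)
        w = np.minimum(1.0, k * scale / np.maximum(np.abs(r), 1e-30))
    return float(gain), float(offset)


def normalize_pair(
    fixed: Volume3D,
    registered: Volume3D,
    brain_mask: np.ndarray,
    lesion_mask: np.ndarray | None = None,
    exclude_top_fraction: float = 0.02,
    min_reference_voxels: int = 1000,
) -> tuple[Volume3D, Volume3D, NormalizationReport]:
    """Match the registered late volume's intensities to the early volume.

    The reference set is the brain mask minus any provided lesion mask and
    minus the brightest ``exclude_top_fraction`` of voxels of either
    volume (strong enhancers must not be fitted away). The gain of the
    late -> early line is fitted by a Huber regression on *band-passed*
    copies of the two volumes — a light Gaussian smooth suppresses voxel
    noise (which would otherwise attenuate the slope) and subtracting a
    heavy smooth removes slow intensity drifts such as coil bias, which a
    global line cannot represent and must not contaminate. Band-passing
    commutes with any true affine intensity relation, so an exact
    ``registered = a * fixed + b`` is recovered exactly. The offset is
    then set so the median paired difference over the reference set is
    zero. Both volumes are finally divided by the fixed volume's median
    reference intensity, so normal-appearing brain sits near 1.
    """
    if not fixed.same_grid_as(registered):
        raise ValueError("volumes must share one grid")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != fixed.shape:
        raise ValueError("brain mask shape mismatch")

    ref = brain_mask.copy()
    if lesion_mask is not None:
        ref &= ~np.asarray(lesion_mask, dtype=bool)
    if ref.sum() >= min_reference_voxels and exclude_top_fraction > 0:
        q = 100.0 * (1.0 - exclude_top_fraction)
        hi_f = np.percentile(fixed.values[ref], q)
        hi_m = np.percentile(registered.values[ref], q)
        ref &= (fixed.values <= hi_f) & (registered.values <= hi_m)
    n_ref = int(ref.sum())
    if n_ref < min_reference_voxels:
        raise ValueError(
            f"normalization reference set has {n_ref} voxels (< {min_reference_voxels}); unreliable"
        )

    def band_pass(values: np.ndarray) -> np.ndarray:
        lo = ndimage.gaussian_filter(values, sigma=1.0)
        return lo - ndimage.gaussian_filter(values, sigma=8.0)

    x_bp = band_pass(registered.values.astype(float))[ref]
    y_bp = band_pass(fixed.values.astype(float))[ref]
    x = registered.values[ref].astype(float)
    y = fixed.values[ref].astype(float)
    before = float(np.median(np.abs(y - x)))

    if np.var(x_bp) < 1e-30:
        gain = 1.0
    else:
        gain, _ = _huber_line_fit(x_bp, y_bp)
    offset = float(np.median(y - gain * x))

    scale = float(np.median(y))
    if scale <= 0:
        raise ValueError("fixed volume has non-positive reference median; cannot scale")

    fixed_n = Volume3D(fixed.values / scale, fixed.affine, dict(fixed.meta))
    late_n = Volume3D((gain * registered.values + offset) / scale, registered.affine, dict(registered.meta))
    after = float(np.median(np.abs(fixed_n.values[ref] - late_n.values[ref]))) * scale

    report = NormalizationReport(
        gain=gain,
        offset=offset,
        reference_scale=scale,
        n_reference=n_ref,
        median_abs_diff_before=before,
        median_abs_diff_after=after,
    )
    return fixed_n, late_n, report


# ---------------------------------------------------------------------------
# transform serialization
# ---------------------------------------------------------------------------

def save_transform(transform: RigidTransform, path: str | Path) -> None:
    """Write the 4x4 matrix (text) and a YAML parameter sidecar."""
    path = Path(path)
    mat = np.eye(4)
    mat[:3, :3] = transform.rotation_matrix
    c = np.asarray(transform.center_mm)
    mat[:3, 3] = np.asarray(transform.translation_mm) + c - transform.rotation_matrix @ c
    np.savetxt(path, mat, fmt="%.10f")
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(yaml.safe_dump({
        "rotation_deg": list(transform.rotation_deg),
        "translation_mm": list(transform.translation_mm),
        "center_mm": list(transform.center_mm),
    }))


def load_transform(path: str | Path) -> RigidTransform:
    sidecar = Path(path).with_suffix(Path(path).suffix + ".yaml")
    doc = yaml.safe_load(sidecar.read_text())
    return RigidTransform(
        rotation_deg=tuple(doc["rotation_deg"]),
        translation_mm=tuple(doc["translation_mm"]),
        center_mm=tuple(doc["center_mm"]),
    )
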