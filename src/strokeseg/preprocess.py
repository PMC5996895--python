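"""Tree input maps: slice-wise DWI normalization and mirror correction.

The segmenter consumes four per-voxel features: the slice-normalized DWI,
the ADC (kept on its absolute scale), and mirror-corrected versions of the
two.  Mirror correction subtracts, voxel for voxel, the most "critical"
value (highest for DWI, lowest for ADC) found in a small neighborhood of
the smoothed contralateral mirror image, so that bilaterally symmetric
structures and artifacts cancel while unilateral anomalies stand out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import SimpleITK as sitk

from .volumes import PatientCase, Volume

__all__ = [
    "FEATURE_NAMES",
    "PreprocessConfig",
    "MirrorTransform",
    "hemisphere_masks",
    "infer_contralateral_side",
    "normalize_dwi",
    "estimate_mirror_transform",
    "apply_mirror",
    "critical_filter",
    "mirror_correct",
    "preprocess_case",
    "build_feature_table",
]

#: Column order of the tree's feature matrix.
FEATURE_NAMES = ("dwi_norm", "adc", "mc_dwi", "mc_adc")


@dataclass
class PreprocessConfig:
    """Knobs of the feature pipeline.

    smooth_sigma_mm
        Isotropic Gaussian width applied to the mirrored image before the
        critical-intensity filter.  Default 2 mm.
    critical_radius_vox
        Half-width of the cubic neighborhood of the critical-intensity
        filter ((2r+1)^3 voxels).  Default 1.
    contralateral
        ``"left"``, ``"right"`` or ``"auto"`` — which hemisphere supplies
        the per-slice normalization mean.  Auto picks the side with the
        smaller hyperintense burden.
    """

    smooth_sigma_mm: float = 2.0
    critical_radius_vox: int = 1
    contralateral: str = "auto"
    normalize_slicewise: bool = True

    def __post_init__(self) -> None:
        if self.smooth_sigma_mm < 0:
            raise ValueError("smooth_sigma_mm must be >= 0")
        if self.critical_radius_vox < 0 or int(self.critical_radius_vox) != self.critical_radius_vox:
            raise ValueError("critical_radius_vox must be a non-negative integer")
        if self.contralateral not in ("left", "right", "auto"):
            raise ValueError("contralateral must be 'left', 'right' or 'auto'")


@dataclass
class MirrorTransform:
    """Flip about the grid midplane composed with a rigid correction.

    ``rotation`` (rad) and ``translation`` (mm) are Euler rigid parameters
    about ``center`` (mm, physical) acting on the flipped image; when all
    are zero the transform is the exact grid flip (no interpolation) and
    applying it twice is the identity.
    """

    flip_axis: int = 0
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def is_pure_flip(self) -> bool:
        return all(v == 0.0 for v in self.rotation) and all(
            v == 0.0 for v in self.translation
        )

    def to_dict(self) -> dict:
        return {
            "flip_axis": self.flip_axis,
            "rotation": list(self.rotation),
            "translation": list(self.translation),
            "center": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MirrorTransform":
        return cls(
            flip_axis=int(d["flip_axis"]),
            rotation=tuple(d["rotation"]),
            translation=tuple(d["translation"]),
            center=tuple(d["center"]),
        )


def hemisphere_masks(shape: tuple[int, int, int], axis: int = 0):
    """Boolean (left, right) hemisphere index masks along ``axis``.

    With an odd extent the central plane belongs to neither hemisphere.
    """
    n = shape[axis]
    idx = np.arange(n)
    left_1d = idx < n // 2
    right_1d = idx >= (n + 1) // 2
    shp = [1, 1, 1]
    shp[axis] = n
    left = np.broadcast_to(left_1d.reshape(shp), shape)
    right = np.broadcast_to(right_1d.reshape(shp), shape)
    return left, right


def infer_contralateral_side(
    dwi: Volume, brain_mask: Volume, percentile: float = 98.0
) -> tuple[str, bool]:
    """Guess which hemisphere is lesion-free.

    After a provisional whole-brain slice-wise normalization, the side with
    the smaller count of voxels above the given percentile of the in-brain
    intensity distribution is taken as contralateral.  Returns the side and
    an ambiguity flag (counts within 10% of each other).
    """
    brain = brain_mask.data.astype(bool)
    prov = _slicewise_divide(dwi.data, brain, brain)
    vals = prov[brain]
    q = np.percentile(vals, percentile)
    hot = (prov > q) & brain
    left, right = hemisphere_masks(dwi.shape)
    n_left = int((hot & left).sum())
    n_right = int((hot & right).sum())
    side = "left" if n_left <= n_right else "right"
    ambiguous = abs(n_left - n_right) < 0.1 * max(n_left, n_right, 1)
    if ambiguous:
        warnings.warn(
            "contralateral-side choice is ambiguous "
            f"(left={n_left}, right={n_right} hyperintense voxels)",
            stacklevel=2,
        )
    return side, ambiguous


def _slicewise_divide(data: np.ndarray, region: np.ndarray, brain: np.ndarray) -> np.ndarray:
    """Divide each axial (z) slice by the mean of ``data`` over ``region``.

    Falls back to the whole-brain slice mean when the region is empty or
    non-positive; slices with no brain voxels (or all-zero intensities) map
    to zero.  Output is zero outside ``brain``.
    """
    out = np.zeros_like(data, dtype=np.float64)
    for k in range(data.shape[2]):
        sl = data[:, :, k]
        b = brain[:, :, k]
        if not b.any():
            continue
        r = region[:, :, k]
        m = sl[r].mean() if r.any() else 0.0
        if m <= 0:
            m = sl[b].mean()
        if m <= 0:
            if np.all(sl[b] == 0):
                continue
            raise ValueError(
                f"slice {k}: non-positive normalization mean with nonzero intensities"
            )
        out[:, :, k] = np.where(b, sl / m, 0.0)
    return out


def normalize_dwi(
    dwi: Volume, brain_mask: Volume, contralateral: str = "auto"
) -> Volume:
    """Slice-wise standardization of the DWI image.

    Every axial slice is divided by the mean DWI intensity over the
    contralateral-hemisphere brain voxels of that slice; voxels outside the
    brain mask are set to zero.
    """
    brain = brain_mask.data.astype(bool)
    side = contralateral
    if side == "auto":
        side, _ = infer_contralateral_side(dwi, brain_mask)
    left, right = hemisphere_masks(dwi.shape)
    region = (left if side == "left" else right) & brain
    return dwi.with_data(_slicewise_divide(dwi.data, region, brain))


# --- mirror transform -------------------------------------------------------


def _to_sitk(data: np.ndarray, spacing: np.ndarray) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0)


def estimate_mirror_transform(
    b0: Volume,
    brain_mask: Volume | None = None,
    *,
    max_iterations: int = 200,
    snap_tol_mm: float = 0.05,
    snap_tol_rad: float = 1e-4,
) -> MirrorTransform:
    """Estimate the hemisphere-to-hemisphere mirror transform from b0.

    The b0 image is registered (rigid 6-DOF, mean-squared intensity metric,
    linear interpolation, dense sampling — deterministic) to its own flip
    about the grid midplane of axis 0.  A failed or divergent registration
    falls back to the pure midplane flip with a warning.  Near-identity
    results are snapped to the exact flip so that perfectly symmetric
    inputs incur no interpolation.
    """
    data = b0.data.astype(np.float64)
    flipped = np.flip(data, axis=0)
    if np.ptp(data) == 0:
        warnings.warn("constant b0; falling back to pure midplane flip", stacklevel=2)
        return MirrorTransform()
    fixed = _to_sitk(data, b0.spacing)
    moving = _to_sitk(flipped, b0.spacing)
    try:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetMetricSamplingStrategy(reg.NONE)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0,
            minStep=1e-4,
            numberOfIterations=int(max_iterations),
            relaxationFactor=0.5,
            gradientMagnitudeTolerance=1e-8,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        init = sitk.CenteredTransformInitializer(
            fixed,
            moving,
            sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY,
        )
        reg.SetInitialTransform(init, inPlace=False)
        if brain_mask is not None:
            reg.SetMetricFixedMask(
                _to_sitk(brain_mask.data.astype(np.uint8), b0.spacing)
            )
        result = reg.Execute(fixed, moving).Downcast()
        if isinstance(result, sitk.CompositeTransform):
            result = result.GetNthTransform(0).Downcast()
        euler = sitk.Euler3DTransform(result)
        params = np.asarray(euler.GetParameters(), dtype=float)  # (ax,ay,az,tx,ty,tz)
        center = tuple(float(c) for c in euler.GetFixedParameters()[:3])
        if not np.all(np.isfinite(params)):
            raise RuntimeError("non-finite registration parameters")
    except Exception as exc:  # registration failure -> pure flip
        warnings.warn(
            f"mirror registration failed ({exc}); falling back to pure midplane flip",
            stacklevel=2,
        )
        return MirrorTransform()
    rot = params[:3]
    trans = params[3:]
    if np.max(np.abs(rot)) < snap_tol_rad and np.max(np.abs(trans)) < snap_tol_mm:
        return MirrorTransform()
    # sitk parameter order is (x, y, z) in physical space; our physical axes
    # coincide with array axes (spacing-scaled), so no reordering is needed.
    return MirrorTransform(
        flip_axis=0,
        rotation=tuple(float(v) for v in rot),
        translation=tuple(float(v) for v in trans),
        center=center,
    )


def apply_mirror(vol: Volume, t: MirrorTransform) -> Volume:
    """Map one hemisphere onto the other: flip about the grid midplane, then
    resample with the rigid correction (linear interpolation)."""
    flipped = np.flip(vol.data, axis=t.flip_axis)
    if t.is_pure_flip:
        return vol.with_data(flipped.copy())
    img = _to_sitk(flipped.astype(np.float64), vol.spacing)
    euler = sitk.Euler3DTransform()
    euler.SetCenter(t.center)
    euler.SetRotation(*t.rotation)
    euler.SetTranslation(t.translation)
    ref = _to_sitk(vol.data.astype(np.float64), vol.spacing)
    out = sitk.Resample(img, ref, euler, sitk.sitkLinear, 0.0)
    return vol.with_data(_from_sitk(out))


def critical_filter(vol: Volume, mode: str, radius_vox: int) -> Volume:
    """Assign each voxel the most critical value in its neighborhood.

    ``mode="max"`` takes the maximum (DWI convention), ``mode="min"`` the
    minimum (ADC convention) over the cubic (2r+1)^3 neighborhood; radius 0
    is the identity.
    """
    r = int(radius_vox)
    if r < 0:
        raise ValueError("radius_vox must be >= 0")
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    if r == 0:
        return vol.with_data(vol.data.copy())
    f = ndi.maximum_filter if mode == "max" else ndi.minimum_filter
    return vol.with_data(f(vol.data, size=2 * r + 1, mode="nearest"))


def mirror_correct(
    vol: Volume, t: MirrorTransform, cfg: PreprocessConfig, mode: str
) -> Volume:
    """Subtract the critical-filtered, smoothed mirror image.

    out = v - critical_filter(smooth(mirror(v)), mode, r).  For DWI
    (mode="max") unilateral hyperintensity maps to positive values, for ADC
    (mode="min") unilateral hypointensity maps to negative values, while
    symmetric structure cancels.
    """
    mirrored = apply_mirror(vol, t)
    m = mirrored.data
    if cfg.smooth_sigma_mm > 0:
        sigma_vox = cfg.smooth_sigma_mm / vol.spacing
        m = ndi.gaussian_filter(m, sigma=sigma_vox)
    crit = critical_filter(vol.with_data(m), mode, cfg.critical_radius_vox)
    return vol.with_data(vol.data - crit.data)


# --- feature assembly --------------------------------------------------------


def preprocess_case(
    case: PatientCase, cfg: PreprocessConfig | None = None
) -> dict[str, Volume]:
    """Compute the four feature maps for one case.

    Returns a dict keyed by :data:`FEATURE_NAMES`.  Only the patient's own
    volumes enter any statistic, so features may be cached and reused across
    cross-validation folds without leakage.
    """
    cfg = cfg or PreprocessConfig()
    dwi_norm = normalize_dwi(case.dwi, case.brain_mask, cfg.contralateral)
    t = estimate_mirror_transform(case.b0, case.brain_mask)
    mc_dwi = mirror_correct(dwi_norm, t, cfg, mode="max")
    mc_adc = mirror_correct(case.adc, t, cfg, mode="min")
    return {
        "dwi_norm": dwi_norm,
        "adc": case.adc,
        "mc_dwi": mc_dwi,
        "mc_adc": mc_adc,
    }


def build_feature_table(
    cases: list[PatientCase],
    cfg: PreprocessConfig | None = None,
    *,
    require_labels: bool = True,
    features: dict[str, dict[str, Volume]] | None = None,
) -> pd.DataFrame:
    """One row per brain-mask voxel across the cohort.

    Columns: ``patient_id``, voxel indices ``i j k``, the four features and
    (when expert masks are present) the binary ``label``.  ``features`` may
    supply precomputed per-case maps from :func:`preprocess_case`.
    """
    cfg = cfg or PreprocessConfig()
    frames = []
    for case in cases:
        if require_labels and case.expert_mask is None:
            raise ValueError(f"case {case.patient_id} has no expert mask")
        maps = (features or {}).get(case.patient_id) or preprocess_case(case, cfg)
        brain = case.brain_mask.data.astype(bool)
        ii, jj, kk = np.nonzero(brain)
        cols = {
            "patient_id": np.repeat(case.patient_id, ii.size),
            "i": ii.astype(np.int32),
            "j": jj.astype(np.int32),
            "k": kk.astype(np.int32),
        }
        for name in FEATURE_NAMES:
            cols[name] = maps[name].data[brain]
        if case.expert_mask is not None:
            cols["label"] = case.expert_mask.data.astype(np.uint8)[brain]
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)
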