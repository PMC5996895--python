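"""Synthetic diffusion-stroke cohorts.

Each case is a scaled-down, bilaterally quasi-symmetric "head": an
ellipsoidal brain in which DWI is bright and ADC is reduced inside one
unilateral lesion.  The generator reproduces the statistical structure the
segmenter relies on and the nuisances it must defeat:

* per-slice intensity drift (removed by slice-wise DWI normalization),
* bilaterally mirrored artifact pairs whose DWI/ADC contrasts overlap the
  lesion's contrast ranges (defeating pure intensity bands, cancelled by
  mirror correction),
* a small whole-head rigid offset (anatomical asymmetry, recovered by the
  mirror registration),
* additive Gaussian noise per channel,
* graded lesion contrast (strong core, fainter rim).

Everything is a deterministic function of (seed, case index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .volumes import PatientCase, Volume, save_case, write_manifest

__all__ = ["SyntheticConfig", "generate_case", "generate_cohort", "write_cohort"]


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    Contrasts are multiplicative factors at the lesion core relative to
    normal tissue; each case draws uniformly from the given ranges.  The
    rim of a lesion retains ``rim_contrast_frac`` of the core's contrast
    deviation from 1.  ``artifact_rate`` mirrored artifact pairs are placed
    per volume with contrasts drawn from their own (overlapping) ranges.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 20)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_semiaxes_mm: tuple[float, float, float] = (26.0, 28.0, 16.0)
    n_patients: int = 12
    lesion_volume_ml_range: tuple[float, float] = (2.0, 8.0)
    lesion_dwi_contrast_range: tuple[float, float] = (1.5, 2.5)
    lesion_adc_contrast_range: tuple[float, float] = (0.4, 0.7)
    rim_contrast_frac: float = 0.7
    noise_sd_frac: float = 0.05
    asymmetry_sd_mm: float = 0.5
    artifact_rate: int = 3
    artifact_radius_mm_range: tuple[float, float] = (4.0, 9.0)
    artifact_dwi_contrast_range: tuple[float, float] = (1.4, 2.2)
    artifact_adc_contrast_range: tuple[float, float] = (0.4, 0.75)
    dwi_tissue_mean: float = 100.0
    adc_tissue_mean: float = 0.8e-3
    slice_drift_amplitude: float = 0.1
    texture_sd_dwi: float = 0.15
    texture_sd_adc: float = 0.15
    texture_sd_b0: float = 0.10
    texture_n_waves: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lesion_dwi_contrast_range",
            "lesion_adc_contrast_range",
            "artifact_dwi_contrast_range",
            "artifact_adc_contrast_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")


def _affine(cfg: SyntheticConfig) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(cfg.spacing_mm)
    # world origin at the grid center
    aff[:3, 3] = -(np.asarray(cfg.grid_shape) - 1) / 2.0 * np.asarray(cfg.spacing_mm)
    return aff


def _head_coords(cfg: SyntheticConfig, rng: np.random.Generator):
    """Physical coordinates (mm) of voxel centers in head space.

    The head is offset from the grid by a small random rigid transform
    (translation sd and rotation of ~0.5 deg per mm of asymmetry), so the
    anatomical midplane does not coincide with the grid midplane.
    """
    shape = cfg.grid_shape
    sp = np.asarray(cfg.spacing_mm)
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, sp)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    t = rng.normal(0.0, cfg.asymmetry_sd_mm, size=3) if cfg.asymmetry_sd_mm > 0 else np.zeros(3)
    theta = (
        rng.normal(0.0, cfg.asymmetry_sd_mm * np.pi / 360.0)
        if cfg.asymmetry_sd_mm > 0
        else 0.0
    )
    c, s = np.cos(theta), np.sin(theta)
    # inverse rigid: rotate about z then translate back
    x = gx - t[0]
    y = gy - t[1]
    z = gz - t[2]
    xr = c * x + s * y
    yr = -s * x + c * y
    return xr, yr, z


def _ellipsoid(x, y, z, center, semiaxes) -> np.ndarray:
    return (
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    )


def _symmetric_texture(
    x, y, z, rng: np.random.Generator, brain: np.ndarray, sd: float, n_waves: int
) -> np.ndarray:
    """Smooth multiplicative tissue-heterogeneity field, bilaterally
    symmetric about the anatomical midplane.

    A random cosine series even in the left-right coordinate (cos has no
    phase in x), normalized to the requested standard deviation over the
    brain.  Mimics gray/white-matter structure: it defeats plain intensity
    thresholds but cancels under mirror correction.
    """
    if sd <= 0 or n_waves <= 0:
        return np.ones_like(x)
    field = np.zeros_like(x)
    for _ in range(n_waves):
        wx, wy, wz = rng.uniform(0.05, 0.5, size=3)  # rad/mm
        py, pz = rng.uniform(0, 2 * np.pi, size=2)
        a = rng.normal()
        field += a * np.cos(wx * x) * np.cos(wy * y + py) * np.cos(wz * z + pz)
    s = field[brain].std()
    if s > 0:
        field = field * (sd / s)
    return np.clip(1.0 + field, 0.3, None)


def _draw_lesion(cfg: SyntheticConfig, rng: np.random.Generator, brain_sa):
    """Target volume, semiaxes and center of the lesion ellipsoid (head mm)."""
    vol_ml = rng.uniform(*cfg.lesion_volume_ml_range)
    target_mm3 = vol_ml * 1000.0
    ratios = rng.uniform(0.7, 1.3, size=3)
    ratios /= np.prod(ratios) ** (1.0 / 3.0)
    r0 = (3.0 * target_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    sa = r0 * ratios
    # keep the left-right extent small enough to stay in one hemisphere
    cap = np.array([0.42 * brain_sa[0], 0.62 * brain_sa[1], 0.62 * brain_sa[2]])
    scale = np.minimum(1.0, cap / sa)
    sa = sa * scale
    deficit = 1.0 / np.prod(scale)  # volume lost to capping
    free = scale == 1.0
    if deficit > 1.0 and free.any():
        sa[free] *= deficit ** (1.0 / free.sum())
        sa = np.minimum(sa, cap)
    side = -1.0 if rng.random() < 0.5 else 1.0
    margin = 2.0
    lo_x = sa[0] + margin
    hi_x = max(lo_x, 0.80 * brain_sa[0] - sa[0])
    if lo_x > 0.95 * brain_sa[0]:
        return None  # cannot fit in one hemisphere
    cx = side * rng.uniform(lo_x, hi_x)
    cy = rng.uniform(-1, 1) * max(0.0, 0.70 * brain_sa[1] - sa[1])
    cz = rng.uniform(-1, 1) * max(0.0, 0.70 * brain_sa[2] - sa[2])
    return target_mm3, sa, np.array([cx, cy, cz])


def _draw_artifacts(cfg, rng, lesion_center, lesion_sa, brain_sa):
    """Mirrored artifact pairs kept clear of the lesion and its mirror."""
    out = []
    clearance = float(np.max(lesion_sa)) + 4.0
    for _ in range(cfg.artifact_rate):
        for _try in range(20):
            radius = rng.uniform(*cfg.artifact_radius_mm_range)
            lo_x = radius + 1.0
            hi_x = 0.75 * brain_sa[0] - radius
            if hi_x <= lo_x:
                continue
            cx = (1.0 if rng.random() < 0.5 else -1.0) * rng.uniform(lo_x, hi_x)
            cy = rng.uniform(-1, 1) * max(0.0, 0.65 * brain_sa[1] - radius)
            cz = rng.uniform(-1, 1) * max(0.0, 0.65 * brain_sa[2] - radius)
            center = np.array([cx, cy, cz])
            mirror_lesion = lesion_center * np.array([-1.0, 1.0, 1.0])
            ok = True
            for lc in (lesion_center, mirror_lesion):
                for ac in (center, center * np.array([-1.0, 1.0, 1.0])):
                    if np.linalg.norm(ac - lc) < radius + clearance:
                        ok = False
            if ok:
                out.append(
                    {
                        "center": center,
                        "radius": radius,
                        "dwi": rng.uniform(*cfg.artifact_dwi_contrast_range),
                        "adc": rng.uniform(*cfg.artifact_adc_contrast_range),
                    }
                )
                break
    return out


def generate_case(cfg: SyntheticConfig, index: int) -> PatientCase:
    """One synthetic patient, fully determined by (cfg.seed, index)."""
    rng = np.random.default_rng([int(cfg.seed), int(index)])
    brain_sa = np.asarray(cfg.brain_semiaxes_mm, dtype=float)
    x, y, z = _head_coords(cfg, rng)
    brain = _ellipsoid(x, y, z, (0, 0, 0), brain_sa) <= 1.0
    if not brain.any():
        raise ValueError("brain ellipsoid does not intersect the grid")
    voxvol = float(np.prod(cfg.spacing_mm))

    lesion_mask = None
    for _attempt in range(25):
        drawn = _draw_lesion(cfg, rng, brain_sa)
        if drawn is None:
            continue
        target_mm3, les_sa, les_c = drawn
        rho2 = _ellipsoid(x, y, z, les_c, les_sa)
        cand = (rho2 <= 1.0) & brain
        if cand.sum() * voxvol >= 0.7 * target_mm3 and cand.any():
            lesion_mask = cand
            lesion_rho2 = rho2
            break
    if lesion_mask is None:
        raise ValueError(
            "requested lesion volume is infeasible for this grid/brain geometry"
        )

    artifacts = _draw_artifacts(cfg, rng, les_c, les_sa, brain_sa)

    dwi_f = np.ones_like(x)
    adc_f = np.ones_like(x)
    for a in artifacts:
        for sgn in (1.0, -1.0):
            c = a["center"] * np.array([sgn, 1.0, 1.0])
            sphere = _ellipsoid(x, y, z, c, (a["radius"],) * 3) <= 1.0
            dwi_f[sphere] = a["dwi"]
            adc_f[sphere] = a["adc"]

    # graded lesion: full contrast at the core, rim keeps rim_contrast_frac
    frac = 1.0 - (1.0 - cfg.rim_contrast_frac) * np.clip(lesion_rho2, 0.0, 1.0)
    c_dwi = rng.uniform(*cfg.lesion_dwi_contrast_range)
    c_adc = rng.uniform(*cfg.lesion_adc_contrast_range)
    dwi_f[lesion_mask] = 1.0 + (c_dwi - 1.0) * frac[lesion_mask]
    adc_f[lesion_mask] = 1.0 + (c_adc - 1.0) * frac[lesion_mask]

    drift = gaussian_filter1d(rng.standard_normal(cfg.grid_shape[2]), sigma=2.0)
    mod = np.clip(1.0 + cfg.slice_drift_amplitude * drift, 0.5, 1.5)[None, None, :]

    tex_dwi = _symmetric_texture(x, y, z, rng, brain, cfg.texture_sd_dwi, cfg.texture_n_waves)
    tex_adc = _symmetric_texture(x, y, z, rng, brain, cfg.texture_sd_adc, cfg.texture_n_waves)
    tex_b0 = _symmetric_texture(x, y, z, rng, brain, cfg.texture_sd_b0, cfg.texture_n_waves)

    dwi = np.where(brain, cfg.dwi_tissue_mean * mod * tex_dwi * dwi_f, 0.0)
    adc = np.where(brain, cfg.adc_tissue_mean * tex_adc * adc_f, 0.0)
    b0 = np.where(brain, cfg.dwi_tissue_mean * mod * tex_b0, 0.0)

    if cfg.noise_sd_frac > 0:
        dwi = dwi + rng.normal(0, cfg.noise_sd_frac * cfg.dwi_tissue_mean, dwi.shape)
        adc = adc + rng.normal(0, cfg.noise_sd_frac * cfg.adc_tissue_mean, adc.shape)
        b0 = b0 + rng.normal(0, cfg.noise_sd_frac * cfg.dwi_tissue_mean, b0.shape)

    aff = _affine(cfg)
    return PatientCase(
        patient_id=f"case{index:03d}",
        dwi=Volume(dwi, aff),
        adc=Volume(adc, aff),
        b0=Volume(b0, aff),
        brain_mask=Volume(brain.astype(np.uint8), aff),
        expert_mask=Volume(lesion_mask.astype(np.uint8), aff),
    )


def generate_cohort(cfg: SyntheticConfig) -> list[PatientCase]:
    """n independent cases drawn from the configured condition."""
    return [generate_case(cfg, i) for i in range(cfg.n_patients)]


def write_cohort(cases: list[PatientCase], out_dir) -> Path:
    """Write a cohort as NIfTI files plus a manifest CSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [save_case(case, out_dir) for case in cases]
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
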