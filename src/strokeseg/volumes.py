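"""Core volume containers and NIfTI I/O.

All images are held as 3-D scalar grids in a canonical (RAS) axis order so
that array axis 0 is the patient left-right axis.  Masks are 0/1 uint8,
probability maps float32, everything else float64.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import ball

__all__ = [
    "Volume",
    "PatientCase",
    "load_volume",
    "save_volume",
    "load_case",
    "save_case",
    "load_cohort",
    "compute_brain_mask",
]


@dataclass
class Volume:
    """A 3-D scalar grid with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar grid.  Axis 0 is the left-right axis after canonical
        reorientation on load.
    affine : ndarray, shape (4, 4)
        Voxel-to-world map (mm).  Must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume on the same grid with different data."""
        return Volume(np.asarray(data), self.affine.copy())

    def same_grid(self, other: "Volume", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class PatientCase:
    """One patient's co-registered diffusion volumes and masks."""

    patient_id: str
    dwi: Volume
    adc: Volume
    b0: Volume
    brain_mask: Volume
    expert_mask: Volume | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vols = {"adc": self.adc, "b0": self.b0, "brain_mask": self.brain_mask}
        if self.expert_mask is not None:
            vols["expert_mask"] = self.expert_mask
        for name, v in vols.items():
            if v.shape != self.dwi.shape:
                raise ValueError(
                    f"{name} shape {v.shape} does not match dwi shape {self.dwi.shape}"
                )
            if not np.allclose(v.affine, self.dwi.affine, atol=1e-3):
                raise ValueError(f"{name} affine does not match dwi affine")
        brain = self.brain_mask.data.astype(bool)
        if not brain.any():
            raise ValueError("brain_mask is empty")
        if self.expert_mask is not None:
            expert = self.expert_mask.data.astype(bool)
            if np.any(expert & ~brain):
                raise ValueError("expert_mask is not a subset of brain_mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dwi.shape


def load_volume(path: str | os.PathLike) -> Volume:
    """Load a NIfTI file reoriented to canonical (RAS) axis order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.dataobj, dtype=np.float64)
    return Volume(data, np.asarray(img.affine, dtype=float))


def save_volume(vol: Volume, path: str | os.PathLike, dtype=None) -> None:
    """Write a Volume as NIfTI-1.

    Masks should be passed with ``dtype=np.uint8``, probability maps with
    ``dtype=np.float32``; the default keeps float64.
    """
    data = vol.data if dtype is None else np.asarray(vol.data, dtype=dtype)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


_CHANNELS = ("dwi", "adc", "b0")


def load_case(
    patient_id: str,
    dwi_path: str | os.PathLike,
    adc_path: str | os.PathLike,
    b0_path: str | os.PathLike,
    expert_path: str | os.PathLike | None = None,
    brain_path: str | os.PathLike | None = None,
) -> PatientCase:
    """Load one patient's channels, deriving the brain mask from b0 if absent.

    All channels must already live on one grid; a shape or affine mismatch
    raises ``ValueError``.
    """
    dwi = load_volume(dwi_path)
    adc = load_volume(adc_path)
    b0 = load_volume(b0_path)
    for name, v in (("adc", adc), ("b0", b0)):
        if v.shape != dwi.shape:
            raise ValueError(
                f"{name} shape {v.shape} does not match dwi shape {dwi.shape}"
            )
    if brain_path is not None:
        brain = load_volume(brain_path)
        brain = brain.with_data((brain.data > 0.5).astype(np.uint8))
    else:
        brain = compute_brain_mask(b0)
    expert = None
    if expert_path is not None:
        expert = load_volume(expert_path)
        e = (expert.data > 0.5) & brain.data.astype(bool)
        expert = expert.with_data(e.astype(np.uint8))
    return PatientCase(patient_id, dwi, adc, b0, brain, expert)


def save_case(case: PatientCase, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a case's volumes; returns a manifest row of written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    row = {"patient_id": case.patient_id}
    for name, vol, dtype in (
        ("dwi", case.dwi, None),
        ("adc", case.adc, None),
        ("b0", case.b0, None),
        ("brain", case.brain_mask, np.uint8),
        ("expert", case.expert_mask, np.uint8),
    ):
        if vol is None:
            continue
        path = out_dir / f"{case.patient_id}_{name}.nii.gz"
        save_volume(vol, path, dtype=dtype)
        row[f"{name}_path"] = str(path)
    return row


def load_cohort(manifest_path: str | os.PathLike) -> list[PatientCase]:
    """Load all cases listed in a cohort manifest CSV.

    The manifest has one row per patient with columns ``patient_id``,
    ``dwi_path``, ``adc_path``, ``b0_path`` and optionally ``expert_path``
    and ``brain_path``.  Relative paths resolve against the manifest's
    directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent

    def _resolve(p):
        if p is None or (isinstance(p, float) and np.isnan(p)):
            return None
        p = Path(p)
        return p if p.is_absolute() else base / p

    cases = []
    for _, row in df.iterrows():
        cases.append(
            load_case(
                str(row["patient_id"]),
                _resolve(row["dwi_path"]),
                _resolve(row["adc_path"]),
                _resolve(row["b0_path"]),
                expert_path=_resolve(row.get("expert_path")),
                brain_path=_resolve(row.get("brain_path")),
            )
        )
    return cases


def compute_brain_mask(b0: Volume, closing_radius_vox: int = 2) -> Volume:
    """Derive a brain mask from the b0 image.

    Otsu thresholding of the b0 intensities, retain the largest connected
    foreground component, and close with a ball of ``closing_radius_vox``
    voxels.  Invariant to positive affine rescaling of the intensities.
    """
    data = b0.data
    if np.ptp(data) == 0:
        raise ValueError("b0 image is constant; no brain/background threshold exists")
    thr = threshold_otsu(data)
    fg = data > thr
    labels, n = ndi.label(fg)
    if n == 0:
        raise ValueError("no foreground voxels above Otsu threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    r = int(closing_radius_vox)
    if r > 0:
        pad = r + 1
        padded = np.pad(mask, pad)
        padded = ndi.binary_closing(padded, structure=ball(r))
        mask = padded[pad:-pad, pad:-pad, pad:-pad]
    return b0.with_data(mask.astype(np.uint8))


def write_manifest(rows: list[dict], path: str | os.PathLike) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_json(path: str | os.PathLike):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
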