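"""Volume/mask containers, NIfTI round-trip, geometry checks and ROI quantization.

A patient is represented by two co-registered 3D MR volumes (contrast-enhanced
T1-weighted and T2-weighted) plus one binary tumor mask on the same voxel
grid.  The mask delineates the whole-tumor region of interest (ROI) used for
all intensity and texture features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumePair",
    "TumorMask",
    "GeometryError",
    "EmptyMaskError",
    "load_patient",
    "save_patient",
    "quantize_roi",
]

MIN_ROI_VOXELS = 27  # smallest ROI on which 3D texture matrices are meaningful


class GeometryError(ValueError):
    """Image/mask grids do not agree (shape or spacing)."""


class EmptyMaskError(ValueError):
    """Mask contains no foreground voxels."""


@dataclass
class VolumePair:
    """Two co-registered 3D intensity volumes for one patient.

    Parameters
    ----------
    cet1w, t2w : ndarray, 3D
        Contrast-enhanced T1-weighted and T2-weighted intensities on the
        same voxel grid.
    spacing : tuple of 3 floats
        Voxel spacing in mm per axis.
    patient_id : str
    """

    cet1w: np.ndarray
    t2w: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.cet1w = np.asarray(self.cet1w, dtype=np.float64)
        self.t2w = np.asarray(self.t2w, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.cet1w.ndim != 3 or self.t2w.ndim != 3:
            raise GeometryError("volumes must be 3D")
        if self.cet1w.shape != self.t2w.shape:
            raise GeometryError(
                f"modalities differ in shape: CET1-w {self.cet1w.shape} vs T2-w {self.t2w.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive values, got {self.spacing}")
        if not (np.isfinite(self.cet1w).all() and np.isfinite(self.t2w).all()):
            raise ValueError("volumes contain non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cet1w.shape


class TumorMask:
    """Binary whole-tumor mask on the image grid.

    The mask must contain at least ``MIN_ROI_VOXELS`` foreground voxels.  A
    mask that splits into several connected components after binary closing
    triggers a warning (a delineated tumor is expected to be one lesion).
    """

    def __init__(self, voxels: np.ndarray, spacing) -> None:
        arr = np.asarray(voxels)
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask is not binary; values found: {uniq[:10]}")
        self.voxels = arr.astype(bool)
        self.spacing = tuple(float(s) for s in spacing)
        if self.voxels.ndim != 3:
            raise GeometryError("mask must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        n = int(self.voxels.sum())
        if n == 0:
            raise EmptyMaskError("mask has no foreground voxels")
        if n < MIN_ROI_VOXELS:
            raise EmptyMaskError(
                f"mask has only {n} foreground voxels; need >= {MIN_ROI_VOXELS} for 3D texture"
            )
        closed = ndimage.binary_closing(self.voxels)
        _, n_comp = ndimage.label(closed | self.voxels)
        if n_comp > 1:
            warnings.warn(
                f"tumor mask has {n_comp} connected components after closing",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_compatible(self, pair: VolumePair) -> None:
        if self.voxels.shape != pair.shape:
            raise GeometryError(
                f"mask shape {self.voxels.shape} does not match image shape {pair.shape}"
            )
        if not np.allclose(self.spacing, pair.spacing):
            raise GeometryError(
                f"mask spacing {self.spacing} does not match image spacing {pair.spacing}"
            )


def _nifti_affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_patient(pair: VolumePair, mask: TumorMask, directory, patient_id: str | None = None) -> dict:
    """Write CET1-w/T2-w volumes and the mask as .nii.gz; return the paths."""
    pid = patient_id or pair.patient_id or "patient"
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _nifti_affine(pair.spacing)
    paths = {
        "cet1w": directory / f"{pid}_CET1w.nii.gz",
        "t2w": directory / f"{pid}_T2w.nii.gz",
        "mask": directory / f"{pid}_mask.nii.gz",
    }
    nib.save(nib.Nifti1Image(pair.cet1w, aff), paths["cet1w"])
    nib.save(nib.Nifti1Image(pair.t2w, aff), paths["t2w"])
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), aff), paths["mask"])
    return {k: str(v) for k, v in paths.items()}


def load_patient(paths: dict, patient_id: str = "") -> tuple[VolumePair, TumorMask]:
    """Load a patient from NIfTI files and validate geometry.

    Parameters
    ----------
    paths : dict with keys ``cet1w``, ``t2w``, ``mask``
        Paths to the NIfTI files.

    Raises
    ------
    GeometryError
        If image/mask shapes or spacings disagree; the message names both
        geometries.
    EmptyMaskError
        If the mask has no (or too few) foreground voxels.
    ValueError
        If the mask contains values other than 0/1.
    """
    imgs = {}
    for key in ("cet1w", "t2w", "mask"):
        p = Path(paths[key])
        if not p.exists():
            raise FileNotFoundError(f"{key} file not found: {p}")
        imgs[key] = nib.load(str(p))

    def _spacing(img) -> tuple:
        return tuple(float(z) for z in img.header.get_zooms()[:3])

    pair = VolumePair(
        cet1w=np.asarray(imgs["cet1w"].dataobj, dtype=np.float64),
        t2w=np.asarray(imgs["t2w"].dataobj, dtype=np.float64),
        spacing=_spacing(imgs["cet1w"]),
        patient_id=patient_id,
    )
    mask = TumorMask(np.asarray(imgs["mask"].dataobj), _spacing(imgs["mask"]))
    mask.check_compatible(pair)
    return pair, mask


def quantize_roi(volume: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Quantize in-mask intensities to integer levels 1..n_bins.

    Equal-width bins between the in-mask minimum and maximum.  A constant ROI
    maps to all-1s.  Out-of-mask voxels are set to 0 (background flag).

    The mapping is monotone: v1 <= v2 implies level(v1) <= level(v2).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot quantize an empty ROI")
    vals = volume[mask]
    lo, hi = vals.min(), vals.max()
    out = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        out[mask] = 1
        return out
    levels = np.floor((vals - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    np.clip(levels, 1, n_bins, out=levels)
    out[mask] = levels
    return out
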