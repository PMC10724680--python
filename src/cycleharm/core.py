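"""Shared domain containers: volumes, tissue segmentations, NIfTI round-trip.

A :class:`Volume` is a 3D scalar intensity grid together with its voxel
spacing, an aligned binary brain mask and a passthrough affine.  All
operations in this package assume the volume is already skull-stripped,
bias-corrected and linearly registered (those steps are external); the
background outside the brain mask is expected to be exactly zero.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "TissueSegmentation",
    "DegenerateInputError",
    "load_volume",
    "save_volume",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally unusable (empty mask, all-zero map)."""


@dataclasses.dataclass
class Volume:
    """3D intensity grid + spacing + binary brain mask + affine."""

    data: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        if self.mask.shape != self.data.shape:
            raise ValueError("mask and grid dimensions differ")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def brain_values(self) -> np.ndarray:
        """Intensities of voxels inside the brain mask (1D)."""
        if not self.mask.any():
            raise DegenerateInputError("brain mask is empty")
        return self.data[self.mask]

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(np.asarray(data, dtype=np.float64), self.mask.copy(),
                      self.spacing, self.affine.copy())


@dataclasses.dataclass
class TissueSegmentation:
    """Partial-volume maps for GM, WM and CSF, aligned to a volume.

    Values are in [0, 1]; inside the brain mask the three maps sum to 1,
    outside they are 0.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        self.gm = np.asarray(self.gm, dtype=np.float64)
        self.wm = np.asarray(self.wm, dtype=np.float64)
        self.csf = np.asarray(self.csf, dtype=np.float64)
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise ValueError("partial-volume maps have mismatched shapes")

    def map_for(self, tissue: str) -> np.ndarray:
        try:
            return {"gm": self.gm, "wm": self.wm, "csf": self.csf}[tissue.lower()]
        except KeyError:
            raise ValueError(f"unknown tissue {tissue!r}; expected gm/wm/csf") from None

    def total(self) -> np.ndarray:
        return self.gm + self.wm + self.csf

    def hard_mask(self, tissue: str, threshold: float = 0.5) -> np.ndarray:
        return self.map_for(tissue) >= threshold


def save_volume(vol: Volume, path: str | Path, mask_path: str | Path | None = None) -> None:
    """Write a volume (and optionally its mask) as NIfTI-1."""
    affine = vol.affine.copy()
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    if mask_path is not None:
        mimg = nib.Nifti1Image(vol.mask.astype(np.uint8), affine)
        mimg.header.set_zooms(vol.spacing)
        nib.save(mimg, str(mask_path))


def load_volume(path: str | Path, mask_path: str | Path | None = None,
                mask_threshold: float = 0.0) -> Volume:
    """Read a NIfTI volume; the mask comes from ``mask_path`` or from data > 0."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0.5
    else:
        mask = data > mask_threshold
    return Volume(data, mask, spacing, np.asarray(img.affine))
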