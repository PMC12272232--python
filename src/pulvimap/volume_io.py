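"""Volumetric image and motion-table I/O, and the shared grid-geometry contract.

All images in a pulvino-cortical analysis — runs, masks, slab labelings,
statistic maps — must live on one voxel grid.  This module owns that
contract: :class:`VolumeGeometry` describes the grid (dims, voxel size and
the 4x4 affine mapping 0-based voxel indices to RAS+ world mm), and
:func:`check_same_grid` is the single gatekeeper every downstream operation
uses to reject mismatched inputs.

Voxel indices are 0-based everywhere; all anatomical-axis logic downstream
(slab binning, sulcus parameterization) operates on world-mm coordinates
obtained through the affine, never on array indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("pulvimap")

__all__ = [
    "VolumeGeometry",
    "Image4D",
    "RunData",
    "ROIMask",
    "check_same_grid",
    "load_image4d",
    "save_image4d",
    "load_mask",
    "save_mask",
    "load_motion",
    "save_motion",
    "voxel_centers_mm",
]

#: Per-element tolerance (mm) for affine agreement between grids.
AFFINE_ATOL_MM = 1e-4


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid geometry: dims, voxel size and voxel->world (RAS+ mm) affine."""

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray  # 4x4

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        col_norms = np.linalg.norm(aff[:3, :3], axis=0)
        if not np.allclose(col_norms, self.voxel_size_mm, atol=1e-6):
            raise ValueError(
                f"voxel_size_mm {self.voxel_size_mm} does not match affine "
                f"column norms {tuple(col_norms)}"
            )
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "affine", aff)

    @classmethod
    def from_affine(cls, dims, affine) -> "VolumeGeometry":
        aff = np.asarray(affine, dtype=float)
        vox = tuple(float(v) for v in np.linalg.norm(aff[:3, :3], axis=0))
        return cls(dims=tuple(int(d) for d in dims), voxel_size_mm=vox, affine=aff)


def check_same_grid(a: VolumeGeometry, b: VolumeGeometry) -> bool:
    """True iff dims are equal and affines agree within 1e-4 mm per element."""
    return a.dims == b.dims and bool(
        np.allclose(a.affine, b.affine, atol=AFFINE_ATOL_MM, rtol=0.0)
    )


def require_same_grid(a: VolumeGeometry, b: VolumeGeometry, what: str = "input") -> None:
    if not check_same_grid(a, b):
        raise ValueError(f"grid mismatch for {what}: {a.dims}/{a.affine[:3, 3]} "
                         f"vs {b.dims}/{b.affine[:3, 3]}")


@dataclass
class Image4D:
    """A 4D volumetric time series (X, Y, Z, T) with grid geometry and TR."""

    geometry: VolumeGeometry
    data: np.ndarray  # dims + (T,)
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Image4D data must be 4D, got ndim={self.data.ndim}")
        if self.data.shape[:3] != self.geometry.dims:
            raise ValueError(
                f"data shape {self.data.shape[:3]} does not match geometry dims "
                f"{self.geometry.dims}"
            )
        if self.n_volumes < 2:
            raise ValueError("Image4D requires at least 2 volumes")
        if self.tr_s <= 0:
            raise ValueError(f"TR must be positive, got {self.tr_s}")
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            where = tuple(int(x) for x in bad[0])
            raise ValueError(f"non-finite value at voxel index {where}")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])


@dataclass
class RunData:
    """One resting-state run: its 4D image plus the 6-column motion table."""

    image: Image4D
    motion: np.ndarray  # T x 6: three translations (mm), three rotations (rad)
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=np.float64)
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError(
                f"motion table must be T x 6, got shape {self.motion.shape}"
            )
        if self.motion.shape[0] != self.image.n_volumes:
            raise ValueError(
                f"motion rows ({self.motion.shape[0]}) != image volumes "
                f"({self.image.n_volumes})"
            )
        if not np.all(np.isfinite(self.motion)):
            raise ValueError("non-finite value in motion table")


@dataclass
class ROIMask:
    """A binary region-of-interest mask on a voxel grid."""

    geometry: VolumeGeometry
    voxels: np.ndarray  # boolean, shape == dims
    name: str = "roi"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.geometry.dims:
            raise ValueError(
                f"mask shape {self.voxels.shape} != geometry dims {self.geometry.dims}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def indices(self) -> np.ndarray:
        """N x 3 array of 0-based voxel indices of the mask, in C order."""
        return np.argwhere(self.voxels)

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise ValueError(f"mask '{self.name}' is empty")


def voxel_centers_mm(geometry: VolumeGeometry, ijk: np.ndarray) -> np.ndarray:
    """World-mm (RAS+) coordinates of voxel centers for N x 3 index array."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    hom = np.c_[ijk, np.ones(len(ijk))]
    return (geometry.affine @ hom.T).T[:, :3]


# ---------------------------------------------------------------------------
# NIfTI-1 and motion-table I/O
# ---------------------------------------------------------------------------

def load_image4d(path, tr_s: float | None = None) -> Image4D:
    """Load a 4D NIfTI-1 file.

    TR is taken from the header's 4th zoom unless overridden by ``tr_s``
    (the override is logged).  Non-finite voxels and 3D-only files are
    errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path} is {img.ndim}D; a 4D time series is required")
    geometry = VolumeGeometry.from_affine(img.shape[:3], img.affine)
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_s is not None:
        if tr_s <= 0:
            raise ValueError(f"TR override must be positive, got {tr_s}")
        if header_tr > 0 and not np.isclose(header_tr, tr_s):
            logger.info("TR override %.4gs replaces header TR %.4gs for %s",
                        tr_s, header_tr, path.name)
        tr = tr_s
    else:
        tr = header_tr
    if tr <= 0:
        raise ValueError(f"{path}: TR {tr} is not positive (no valid header TR "
                         "and no override)")
    data = np.asarray(img.dataobj, dtype=np.float64)
    return Image4D(geometry=geometry, data=data, tr_s=tr)


def save_image4d(image: Image4D, path) -> None:
    """Write an Image4D as NIfTI-1 with TR stored in the header zooms."""
    hdr = nib.Nifti1Header()
    hdr.set_xyzt_units("mm", "sec")
    out = nib.Nifti1Image(image.data, image.geometry.affine, hdr)
    out.set_data_dtype(np.float64)
    zooms = list(out.header.get_zooms())
    zooms[3] = image.tr_s
    out.header.set_zooms(zooms)
    nib.save(out, str(path))


def load_mask(path, name: str | None = None) -> ROIMask:
    """Load a binary {0,1} NIfTI-1 mask; any other value is an error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"mask {path} must be 3D, got {img.ndim}D")
    data = np.asarray(img.dataobj, dtype=np.float64)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError(f"mask {path} has non-binary values {vals[:5]}")
    geometry = VolumeGeometry.from_affine(img.shape, img.affine)
    return ROIMask(geometry=geometry, voxels=data > 0.5,
                   name=name or path.name.split(".")[0])


def save_mask(mask: ROIMask, path) -> None:
    out = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.geometry.affine)
    nib.save(out, str(path))


def load_motion(path, n_volumes: int | None = None) -> np.ndarray:
    """Load a whitespace-delimited motion table (T rows x exactly 6 columns)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    table = np.loadtxt(str(path), ndmin=2)
    if table.shape[1] != 6:
        raise ValueError(
            f"motion file {path} has {table.shape[1]} columns; exactly 6 "
            "(3 translations mm + 3 rotations rad) are required"
        )
    if n_volumes is not None and table.shape[0] != n_volumes:
        raise ValueError(
            f"motion file {path} has {table.shape[0]} rows for {n_volumes} volumes"
        )
    return table


def save_motion(motion: np.ndarray, path) -> None:
    np.savetxt(str(path), np.asarray(motion), fmt="%.10g")
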