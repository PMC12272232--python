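"""Fixed-thickness slab subdivision of a seed mask along an anatomical axis.

The seed nucleus (here the pulvinar of one hemisphere) is cut into 2-mm-thick
slabs along one of three anatomical axes; each slab is later used as one
connectivity seed.  Axis conventions (labels increase along the stated
direction, in world mm through the affine):

* ``AP`` — posterior to anterior (+y in RAS+),
* ``VD`` — ventral to dorsal (+z),
* ``LM`` — lateral to medial, hemisphere-aware: +x for a left-hemisphere
  mask, -x for a right-hemisphere mask, so that a mask and its mirror get
  identical labels at mirrored voxels.

Binning is half-open, ``[c_min + k*t, c_min + (k+1)*t)``, anchored at the
mask's own minimum coordinate; boundary voxels are decided by their center
coordinate.  Empty bins (possible for masks that are not connected along the
axis) are compacted away so labels are always contiguous ``0..n_slabs-1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import ROIMask, VolumeGeometry, voxel_centers_mm

__all__ = ["AXES", "SlabLabeling", "axis_coordinate", "slice_mask",
           "slab_position", "infer_hemisphere"]

AXES = ("LM", "AP", "VD")


def infer_hemisphere(mask: ROIMask) -> str:
    """'L' if the mask's mean world x is negative (RAS+), else 'R'."""
    xs = voxel_centers_mm(mask.geometry, mask.indices())[:, 0]
    return "L" if float(np.mean(xs)) < 0 else "R"


def axis_coordinate(geometry: VolumeGeometry, ijk: np.ndarray, axis: str,
                    hemisphere: str | None = None) -> np.ndarray:
    """World-mm coordinate of each voxel along an anatomical axis.

    For ``LM`` a hemisphere must be given ('L' or 'R'); the coordinate is
    signed so that it increases lateral -> medial in either hemisphere.
    """
    xyz = voxel_centers_mm(geometry, ijk)
    if axis == "AP":
        return xyz[:, 1]
    if axis == "VD":
        return xyz[:, 2]
    if axis == "LM":
        if hemisphere not in ("L", "R"):
            raise ValueError("LM axis requires hemisphere 'L' or 'R'")
        return xyz[:, 0] if hemisphere == "L" else -xyz[:, 0]
    raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")


@dataclass
class SlabLabeling:
    """Per-voxel slab labels over a seed mask, one anatomical axis.

    ``labels[i]`` is the slab index (0-based, contiguous) of mask voxel
    ``indices[i]``; ``slab_center_mm`` holds each slab's bin-midpoint world
    coordinate along the axis and is strictly increasing with label.
    """

    axis: str
    thickness_mm: float
    geometry: VolumeGeometry
    indices: np.ndarray       # N x 3 voxel indices of the mask (C order)
    labels: np.ndarray        # N integer slab labels
    slab_center_mm: np.ndarray
    hemisphere: str | None = None

    @property
    def n_slabs(self) -> int:
        return len(self.slab_center_mm)

    def slab_voxels(self, label: int) -> np.ndarray:
        """Voxel indices (M x 3) belonging to one slab."""
        if not 0 <= label < self.n_slabs:
            raise ValueError(f"slab label {label} out of range [0, {self.n_slabs})")
        return self.indices[self.labels == label]

    def to_volume(self) -> np.ndarray:
        """Integer volume: 0 outside the mask, k+1 for slab k."""
        vol = np.zeros(self.geometry.dims, dtype=np.int16)
        vol[tuple(self.indices.T)] = self.labels + 1
        return vol

    def centers_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "slab": np.arange(self.n_slabs),
            "center_mm": self.slab_center_mm,
            "position": [slab_position(self, k) for k in range(self.n_slabs)],
            "n_voxels": np.bincount(self.labels, minlength=self.n_slabs),
        })


def slice_mask(mask: ROIMask, axis: str, thickness_mm: float,
               hemisphere: str | None = None) -> SlabLabeling:
    """Partition a seed mask into slabs of fixed thickness along an axis.

    Each voxel gets label ``floor((c - c_min) / thickness_mm)`` from its
    center coordinate ``c`` along the axis; empty bins are compacted so the
    returned labels are contiguous.  A mask thinner than one slab yields a
    single slab.
    """
    mask.require_nonempty()
    if thickness_mm <= 0:
        raise ValueError(f"thickness_mm must be positive, got {thickness_mm}")
    if axis == "LM" and hemisphere is None:
        hemisphere = infer_hemisphere(mask)
    ijk = mask.indices()
    c = axis_coordinate(mask.geometry, ijk, axis, hemisphere)
    c_min = float(c.min())
    raw = np.floor((c - c_min) / thickness_mm).astype(np.int64)
    occupied = np.unique(raw)  # sorted
    remap = {int(b): k for k, b in enumerate(occupied)}
    labels = np.array([remap[int(b)] for b in raw], dtype=np.int64)
    centers = c_min + (occupied + 0.5) * thickness_mm
    return SlabLabeling(axis=axis, thickness_mm=float(thickness_mm),
                        geometry=mask.geometry, indices=ijk, labels=labels,
                        slab_center_mm=centers.astype(float),
                        hemisphere=hemisphere)


def slab_position(labeling: SlabLabeling, label: int) -> float:
    """Normalized slab position in [0, 1] along the axis (0.5 if one slab)."""
    if not 0 <= label < labeling.n_slabs:
        raise ValueError(f"slab label {label} out of range [0, {labeling.n_slabs})")
    if labeling.n_slabs == 1:
        return 0.5
    lo = labeling.slab_center_mm[0]
    hi = labeling.slab_center_mm[-1]
    return float((labeling.slab_center_mm[label] - lo) / (hi - lo))
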