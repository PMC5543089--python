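"""Volume-of-interest construction: spheres, gray-matter filtering, size equating.

Masks live on an explicit grid (shape + index-to-mm affine).  Sphere
membership uses the voxel-center criterion; gray-matter retention is strict
(> threshold); size equating raises the probability threshold until the
surviving count fits the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Grid",
    "VoiMask",
    "sphere_mask",
    "gray_matter_filter",
    "equate_size",
    "combine_masks",
]


@dataclass(frozen=True)
class Grid:
    """Voxel grid geometry: array shape and index-to-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """mm coordinates of voxel centers for an (N, 3) index array."""
        ijk = np.asarray(indices, dtype=float)
        hom = np.column_stack([ijk, np.ones(len(ijk))])
        return (self.affine @ hom.T).T[:, :3]

    def mm_to_index(self, mm: Sequence[float]) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        return (inv @ np.append(np.asarray(mm, dtype=float), 1.0))[:3]

    def all_indices(self) -> np.ndarray:
        return np.indices(self.shape).reshape(3, -1).T

    def compatible(self, other: "Grid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class VoiMask:
    """Voxel index set with grid geometry and construction provenance."""

    grid: Grid
    indices: np.ndarray
    name: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("indices must be an (N, 3) array")
        if idx.shape[0] == 0:
            raise ValueError(f"mask {self.name!r} is empty")
        if np.unique(idx, axis=0).shape[0] != idx.shape[0]:
            raise ValueError("duplicate voxel indices")
        lo_bad = np.any(idx < 0)
        hi_bad = np.any(idx >= np.asarray(self.grid.shape))
        if lo_bad or hi_bad:
            raise ValueError("voxel indices outside grid bounds")
        # canonical lexicographic order makes masks comparable
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        self.indices = idx[order]

    @property
    def size(self) -> int:
        return self.indices.shape[0]

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid.shape, dtype=bool)
        vol[tuple(self.indices.T)] = True
        return vol


def sphere_mask(
    center_mm: Sequence[float],
    radius: float,
    grid: Grid,
    name: str = "sphere",
) -> VoiMask:
    """Voxels whose center lies within ``radius`` mm of ``center_mm``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    center_idx = grid.mm_to_index(center_mm)
    if np.any(center_idx < -0.5) or np.any(center_idx > np.asarray(grid.shape) - 0.5):
        raise ValueError(f"sphere center {list(center_mm)} lies outside the grid")
    idx = grid.all_indices()
    centers = grid.voxel_centers(idx)
    dist = np.linalg.norm(centers - np.asarray(center_mm, dtype=float), axis=1)
    keep = idx[dist <= radius + 1e-9]
    if keep.shape[0] == 0:
        raise ValueError("sphere contains no voxel center")
    return VoiMask(
        grid,
        keep,
        name,
        {"kind": "sphere", "center_mm": list(map(float, center_mm)), "radius_mm": float(radius)},
    )


def gray_matter_filter(
    mask: VoiMask,
    gm_map: np.ndarray,
    threshold: float = 0.5,
) -> VoiMask:
    """Retain only voxels with gray-matter probability strictly above threshold."""
    gm = np.asarray(gm_map, dtype=float)
    if gm.shape != mask.grid.shape:
        raise ValueError(
            f"gray-matter map shape {gm.shape} does not match grid {mask.grid.shape}"
        )
    keep = mask.indices[gm[tuple(mask.indices.T)] > threshold]
    if keep.shape[0] == 0:
        raise ValueError(
            f"mask {mask.name!r} has no voxel above gray-matter threshold {threshold}"
        )
    prov = dict(mask.provenance)
    prov["gray_matter_threshold"] = float(threshold)
    return VoiMask(mask.grid, keep, mask.name, prov)


def equate_size(
    prob_map: np.ndarray,
    target_size: int,
    grid: Grid,
    gm_mask: np.ndarray | None = None,
    name: str = "equated",
) -> tuple[float, VoiMask]:
    """Smallest probability threshold whose surviving voxel count <= target.

    Survival means map value strictly above the threshold, within the optional
    gray-matter mask.  Candidate thresholds are the map's distinct values plus
    a sentinel just below the minimum, so the full map is attainable.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    prob = np.asarray(prob_map, dtype=float)
    if prob.shape != grid.shape:
        raise ValueError("probability map shape does not match grid")
    gm = np.ones(grid.shape, dtype=bool) if gm_mask is None else np.asarray(gm_mask, dtype=bool)
    vals = np.sort(prob[gm].ravel())
    if vals.size == 0:
        raise ValueError("gray-matter mask is empty")
    if target_size > vals.size:
        raise ValueError(
            f"target {target_size} unachievable; at most {vals.size} voxels available"
        )
    candidates = np.concatenate([[np.nextafter(vals[0], -np.inf)], np.unique(vals)])
    # count of strictly-greater values is monotone non-increasing in threshold
    counts = vals.size - np.searchsorted(vals, candidates, side="right")
    ok = np.flatnonzero(counts <= target_size)
    threshold = float(candidates[ok[0]])
    keep_vol = (prob > threshold) & gm
    idx = np.argwhere(keep_vol)
    if idx.shape[0] == 0:
        raise ValueError(
            f"target {target_size} leaves an empty mask; "
            f"achievable sizes are 1..{int(counts[0])}"
        )
    mask = VoiMask(
        grid,
        idx,
        name,
        {"kind": "thresholded_probability_map", "threshold": threshold,
         "target_size": int(target_size), "size": int(idx.shape[0])},
    )
    return threshold, mask


def combine_masks(masks: Sequence[VoiMask], name: str = "combined") -> VoiMask:
    """Set union of masks on a common grid; provenance lists the components."""
    if not masks:
        raise ValueError("no masks to combine")
    grid = masks[0].grid
    for m in masks[1:]:
        if not grid.compatible(m.grid):
            raise ValueError(
                f"grid mismatch between masks {masks[0].name!r} and {m.name!r}"
            )
    stacked = np.vstack([m.indices for m in masks])
    union = np.unique(stacked, axis=0)
    return VoiMask(
        grid,
        union,
        name,
        {"kind": "union", "components": [m.name for m in masks]},
    )
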