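"""Voxelized depth below the molecular surface, and the burial predicate.

The solvent-excluded volume is approximated in three stages on a regular
grid (default 0.5 Angstrom voxels):

1. probe-center space: voxels whose center lies outside every sphere of
   radius (vdW_i + probe) around atom i, restricted to the connected
   component that touches the grid boundary. Interior cavities unreachable
   by the probe are thereby treated as molecular volume.
2. solvent region: probe-center space dilated by the probe radius.
3. depth: Euclidean distance transform of the complement (the molecular
   volume) to the nearest solvent voxel.

An atom is *buried* when the voxel containing its heavy-atom position is
at least ``burial_threshold`` (default 4.5 Angstroms, sensible range
3.5-5.5) below the surface. Because the grid is computed on the
poly-Leucine conversion of the structure, burial is independent of
sequence and rotamer choice and can be precomputed once before packing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .chemistry import PolarClass
from .errors import ParameterError, StructureError
from .structure import Pose

__all__ = ["BurialGrid", "compute_burial_grid", "depth_at", "is_buried",
           "list_buried_polar_atoms"]

logger = logging.getLogger(__name__)

DEFAULT_VOXEL = 0.5
DEFAULT_PROBE = 2.3
DEFAULT_THRESHOLD = 4.5


@dataclass
class BurialGrid:
    """Per-voxel depth field; depth 0 marks solvent."""

    origin: np.ndarray
    voxel_size: float
    dims: tuple
    depth: np.ndarray
    probe_radius: float = DEFAULT_PROBE
    burial_threshold: float = DEFAULT_THRESHOLD

    def voxel_index(self, point) -> tuple | None:
        """Index of the voxel whose center is nearest to ``point``, or
        None when the point falls outside the grid."""
        idx = np.rint((np.asarray(point, float) - self.origin)
                      / self.voxel_size).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.dims)):
            return None
        return tuple(idx)


def compute_burial_grid(polyleu_pose: Pose,
                        voxel_size: float = DEFAULT_VOXEL,
                        probe_radius: float = DEFAULT_PROBE,
                        burial_threshold: float = DEFAULT_THRESHOLD,
                        ) -> BurialGrid:
    """Compute the depth-below-surface field for a (poly-Leu) pose."""
    if voxel_size <= 0:
        raise ParameterError(f"voxel_size must be positive, got {voxel_size}")
    if probe_radius < 0:
        raise ParameterError(f"probe_radius must be >= 0, got {probe_radius}")
    atoms = [a for a in polyleu_pose.all_atoms()]
    if not atoms:
        raise StructureError("empty pose: no atoms to voxelize")
    if any(a.polar_class is not PolarClass.NONE and not a.is_backbone
           for a in atoms):
        logger.warning("pose has polar sidechain atoms; burial is meant to "
                       "be computed on the poly-Leucine conversion")

    centers = np.array([a.position for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms])
    margin = probe_radius + radii.max() + 3.0 * voxel_size
    origin = centers.min(axis=0) - margin
    span = centers.max(axis=0) + margin - origin
    dims = tuple(int(np.ceil(s / voxel_size)) + 1 for s in span)

    # Stage 1: voxels within (vdW + probe) of any atom center.
    occupied = np.zeros(dims, dtype=bool)
    reach = radii + probe_radius
    lo_idx = np.floor((centers - reach[:, None] - origin)
                      / voxel_size).astype(int)
    hi_idx = np.ceil((centers + reach[:, None] - origin)
                     / voxel_size).astype(int)
    np.clip(lo_idx, 0, np.array(dims) - 1, out=lo_idx)
    np.clip(hi_idx, 0, np.array(dims) - 1, out=hi_idx)
    for center, r, lo, hi in zip(centers, reach, lo_idx, hi_idx):
        grids = np.ogrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        d2 = sum((g * voxel_size + origin[k] - center[k]) ** 2
                 for k, g in enumerate(grids))
        occupied[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= (
            d2 <= r * r)

    probe_space = ~occupied
    # Keep only probe-center space connected to the boundary (bulk solvent).
    labels, n_labels = ndimage.label(probe_space)
    if n_labels > 0:
        boundary_labels = set()
        for axis in range(3):
            for sl in (0, -1):
                face = np.take(labels, sl, axis=axis)
                boundary_labels.update(np.unique(face[face > 0]).tolist())
        exterior = np.isin(labels, sorted(boundary_labels))
    else:
        exterior = probe_space

    # Stage 2: dilate probe-center space by the probe radius.
    if exterior.any():
        dist_to_probe_center = ndimage.distance_transform_edt(
            ~exterior, sampling=voxel_size)
        solvent = dist_to_probe_center <= probe_radius
    else:
        solvent = np.zeros(dims, dtype=bool)

    # Stage 3: depth = distance to nearest solvent voxel.
    if solvent.any():
        depth = ndimage.distance_transform_edt(~solvent, sampling=voxel_size)
    else:
        depth = np.full(dims, np.inf)
    return BurialGrid(origin=origin, voxel_size=voxel_size, dims=dims,
                      depth=depth, probe_radius=probe_radius,
                      burial_threshold=burial_threshold)


def depth_at(grid: BurialGrid, point) -> float:
    """Depth of the voxel containing ``point``; 0 outside the grid."""
    idx = grid.voxel_index(point)
    if idx is None:
        return 0.0
    return float(grid.depth[idx])


def is_buried(grid: BurialGrid, point) -> bool:
    """True when the point's voxel is at least the burial threshold deep
    (inclusive comparison)."""
    return depth_at(grid, point) >= grid.burial_threshold


def list_buried_polar_atoms(grid: BurialGrid, candidates):
    """Filter atoms to those whose heavy-atom position is buried,
    preserving order."""
    return [a for a in candidates if is_buried(grid, a.position)]
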