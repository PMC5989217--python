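"""Voxel-grid containers and geometry helpers.

All analysis happens in 0-based voxel space; the NIfTI affine is carried
through for provenance but never used for computation (inputs are assumed
co-registered to a common grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError

VALUE_KINDS = ("spearman_r", "fisher_z", "group_t", "svr_r", "other")


@dataclass
class StatMap:
    """A per-voxel scalar map defined on the in-mask voxels of a grid.

    ``values`` is a 1-D array aligned with ``np.flatnonzero(mask)`` in C
    order; NaN marks voxels where the statistic is undefined (e.g. a
    searchlight below the minimum sphere size).
    """

    grid_shape: tuple[int, int, int]
    mask: np.ndarray
    values: np.ndarray
    value_kind: str = "other"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask.shape != tuple(self.grid_shape):
            raise ShapeError(
                f"mask shape {self.mask.shape} != grid_shape {tuple(self.grid_shape)}"
            )
        if self.values.shape != (int(self.mask.sum()),):
            raise ShapeError(
                f"values length {self.values.shape} != in-mask voxel count {int(self.mask.sum())}"
            )
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.values).sum())

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        """Scatter values into a dense 3-D volume; out-of-mask voxels get ``fill``."""
        vol = np.full(self.grid_shape, fill, dtype=float)
        vol[self.mask] = np.where(np.isfinite(self.values), self.values, fill)
        return vol

    @classmethod
    def from_volume(cls, vol: np.ndarray, mask: np.ndarray, value_kind: str = "other",
                    affine: np.ndarray | None = None) -> "StatMap":
        mask = np.asarray(mask, dtype=bool)
        if vol.shape != mask.shape:
            raise ShapeError(f"volume shape {vol.shape} != mask shape {mask.shape}")
        kwargs = {} if affine is None else {"affine": affine}
        return cls(tuple(vol.shape), mask, np.asarray(vol, float)[mask], value_kind, **kwargs)


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer offsets (k, 3) with squared Euclidean norm <= radius**2.

    At radius 3 (a 7-voxel-diameter searchlight) this lattice ball contains
    123 voxels.
    """
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def ellipsoid_mask(grid_shape: tuple[int, int, int],
                   semiaxes: tuple[float, float, float]) -> np.ndarray:
    """Boolean ellipsoidal 'brain' mask centred on the grid."""
    grid_shape = tuple(int(s) for s in grid_shape)
    center = (np.asarray(grid_shape) - 1) / 2.0
    idx = np.indices(grid_shape).astype(float)
    d2 = sum(((idx[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def ball_region(grid_shape: tuple[int, int, int], center: tuple[float, float, float],
                n_voxels: int, within: np.ndarray | None = None) -> np.ndarray:
    """Indices (n, 3) of the ``n_voxels`` in-mask voxels nearest to ``center``.

    Used to plant compact signal regions; ties in distance are broken by
    C-order voxel index so the region is deterministic.
    """
    idx = np.argwhere(within) if within is not None else np.argwhere(np.ones(grid_shape, bool))
    d2 = ((idx - np.asarray(center, float)) ** 2).sum(axis=1)
    order = np.lexsort((np.arange(len(idx)), d2))
    if n_voxels > len(idx):
        raise ShapeError(f"requested {n_voxels} voxels but only {len(idx)} available")
    return idx[order[:n_voxels]]


def coords_to_flat(coords: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    return np.ravel_multi_index(tuple(np.asarray(coords).T), grid_shape)
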