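"""Polyrigid deformation fields: structure weights and log-Euclidean fusion.

A polyrigid field fuses K rigid transforms ``T_1..T_K`` (one per rigid
structure) into a dense, smooth, locally-rigid warp.  At every point the
transform is the exponential of a convex combination of the structure twists:

    Phi(x) = exp( sum_k w_k(x) log T_k / sum_k w_k(x) ) @ [x; 1]

The weights derive from Euclidean distance maps ``d_k`` to each structure and
come in two flavours:

* ``mass`` (default, hyperparameter-free): ``w_k = m_k / (1 + d_k^2)`` with
  ``m_k`` the normalized structure volume ("mass" under constant density).
  Heavy structures keep influence further into the surrounding tissue.
* ``reciprocal``: ``w_k = 1 / (1 + eps * d_k^2)`` with a decay hyperparameter
  ``eps <= 1``, the classical reciprocal-distance weighting.

Weights are precomputed once on the moving volume's lattice and held fixed
during optimization; only the K twists evolve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from . import se3
from .volume import Grid, Labelmap, Volume, sample_trilinear

__all__ = [
    "StructureSet",
    "WeightField",
    "PolyrigidField",
    "compute_masses",
    "compute_distance_maps",
    "build_structure_set",
    "build_weights",
    "build_field",
]


@dataclass
class StructureSet:
    """Masks, normalized masses, and distance maps for K rigid structures."""

    ids: np.ndarray  # (K,) structure ids
    masks: np.ndarray  # (K,) + grid.shape, bool
    masses: np.ndarray  # (K,), non-negative, sums to 1
    distance_maps: np.ndarray  # (K,) + grid.shape, mm, 0 on the structure
    grid: Grid


@dataclass
class WeightField:
    """Normalized per-voxel structure weights W (rows sum to 1)."""

    weights: np.ndarray  # grid.shape + (K,)
    mode: str
    grid: Grid
    ids: np.ndarray
    epsilon: Optional[float] = None

    @property
    def n_structures(self) -> int:
        return self.weights.shape[-1]

    @property
    def table(self) -> np.ndarray:
        """Flat M x K view of the weights (voxels in C order)."""
        return self.weights.reshape(-1, self.n_structures)


def compute_masses(lm: Labelmap, ids=None) -> np.ndarray:
    """Normalized structure masses: voxel count x voxel volume, summing to 1.

    Assumes constant density across structures, so mass is proportional to
    physical volume.
    """
    ids = lm.structure_ids() if ids is None else np.asarray(ids)
    voxel_volume = float(abs(np.linalg.det(lm.affine[:3, :3])))
    masses = np.empty(len(ids), dtype=float)
    for i, sid in enumerate(ids):
        count = int((lm.labels == sid).sum())
        if count == 0:
            raise ValueError(f"structure {sid} is empty")
        masses[i] = count * voxel_volume
    return masses / masses.sum()


def compute_distance_maps(lm: Labelmap, ids=None) -> np.ndarray:
    """Per-structure Euclidean distance transforms in physical units (mm)."""
    ids = lm.structure_ids() if ids is None else np.asarray(ids)
    spacing = lm.spacing
    maps = np.empty((len(ids),) + lm.labels.shape, dtype=float)
    for i, sid in enumerate(ids):
        mask = lm.labels == sid
        if not mask.any():
            raise ValueError(f"structure {sid} is empty")
        maps[i] = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return maps


def build_structure_set(lm: Labelmap, ids=None) -> StructureSet:
    ids = lm.structure_ids() if ids is None else np.asarray(ids, dtype=int)
    if len(ids) == 0:
        raise ValueError("at least one structure is required")
    masks = np.stack([lm.labels == sid for sid in ids])
    return StructureSet(
        ids=ids,
        masks=masks,
        masses=compute_masses(lm, ids),
        distance_maps=compute_distance_maps(lm, ids),
        grid=lm.grid,
    )


def build_weights(ss: StructureSet, mode: str = "mass", epsilon: Optional[float] = None) -> WeightField:
    """Construct the normalized weight field from a structure set.

    ``mass`` mode is hyperparameter-free (passing ``epsilon`` is an error);
    ``reciprocal`` mode requires ``epsilon <= 1``.
    """
    d2 = ss.distance_maps**2
    if mode == "mass":
        if epsilon is not None:
            raise ValueError("mass mode is hyperparameter-free: epsilon must not be supplied")
        w = ss.masses[:, None, None, None] / (1.0 + d2)
    elif mode == "reciprocal":
        if epsilon is None:
            raise ValueError("reciprocal mode requires epsilon")
        if not 0 < epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")
        w = 1.0 / (1.0 + epsilon * d2)
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    w = np.moveaxis(w, 0, -1)  # grid.shape + (K,)
    w = w / w.sum(axis=-1, keepdims=True)
    return WeightField(weights=w, mode=mode, grid=ss.grid, ids=ss.ids, epsilon=epsilon)


@dataclass
class PolyrigidField:
    """Dense locally-rigid deformation from K twists fused by a weight field.

    ``Phi`` maps output-lattice world coordinates into the input volume's
    world coordinates (resampling convention), so warping is ``V o Phi``.
    """

    weight_field: WeightField
    twists: np.ndarray  # (K, 6)

    def __post_init__(self):
        self.twists = np.asarray(self.twists, dtype=float)
        if self.twists.shape != (self.weight_field.n_structures, 6):
            raise ValueError(
                f"twists must be ({self.weight_field.n_structures}, 6), got {self.twists.shape}"
            )

    @property
    def grid(self) -> Grid:
        return self.weight_field.grid

    def voxel_twists(self) -> np.ndarray:
        """Fused per-voxel twists eta(x) = W(x) @ T_hat, shape grid + (6,)."""
        eta = self.weight_field.table @ self.twists
        return eta.reshape(self.grid.shape + (6,))

    def mapped_coords(self, grid: Grid | None = None) -> np.ndarray:
        """Phi evaluated at all voxel centers, shape grid.shape + (3,)."""
        if grid is not None and not grid.same_lattice(self.grid):
            raise ValueError("polyrigid field lattice differs from the requested grid")
        eta = self.voxel_twists().reshape(-1, 6)
        T = se3.batch_exp(eta)
        x = self.grid.voxel_centers().reshape(-1, 3)
        y = np.einsum("nij,nj->ni", T[:, :3, :3], x) + T[:, :3, 3]
        return y.reshape(self.grid.shape + (3,))

    def displacement(self) -> np.ndarray:
        """Dense displacement field Phi(x) - x in mm, shape grid + (3,)."""
        return self.mapped_coords() - self.grid.voxel_centers()

    def at_points(self, points: np.ndarray) -> np.ndarray:
        """Continuous extension of Phi at arbitrary world points.

        The normalized weights are interpolated trilinearly (a convex
        combination of rows each summing to 1 still sums to 1); beyond the
        lattice the weights fade to 0 and the field tends to the identity.
        """
        points = np.asarray(points, dtype=float)
        W = self.weight_field.weights
        K = W.shape[-1]
        wk = np.stack(
            [
                sample_trilinear(
                    Volume(W[..., k], self.grid.affine), points
                )
                for k in range(K)
            ],
            axis=-1,
        )
        eta = wk @ self.twists
        T = se3.exp_se3(eta)
        return np.einsum("...ij,...j->...i", T[..., :3, :3], points) + T[..., :3, 3]

    def to_nifti(self, path) -> None:
        """Export the dense displacement field (mm, output-to-input) as NIfTI."""
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.displacement().astype(np.float32), self.grid.affine), str(path))


def build_field(weight_field: WeightField, twists: np.ndarray) -> PolyrigidField:
    """Fuse a K x 6 twist table with a weight field into a polyrigid deformation."""
    twists = np.asarray(twists, dtype=float)
    if twists.ndim != 2 or twists.shape != (weight_field.n_structures, 6):
        raise ValueError(
            f"expected a ({weight_field.n_structures}, 6) twist table, got {twists.shape}"
        )
    return PolyrigidField(weight_field, twists)
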