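"""Volume-to-surface sampling by trilinear interpolation.

Microstructure profiles are obtained by probing an intensity volume (a
T1w/T2w ratio image, or a phantom) at the matched vertices of the
equivolumetric depth surfaces.  Sampling uses trilinear interpolation —
the weighted average of the eight voxels surrounding each point — under
the usual neuroimaging convention that voxel centres sit at integer
0-based voxel coordinates and the NIfTI affine maps voxel indices to
world millimetres.

Points falling outside the valid interpolation domain (closer than one
voxel layer to the array edge, on the outside) are flagged invalid and
never extrapolated; silently substituted values would corrupt the moment
estimates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .equivolume import DepthSurfaceStack
from .errors import ContractError

__all__ = ["Volume", "DepthProfileSet", "trilinear_sample", "sample_profiles"]


@dataclass
class Volume:
    """3D intensity array plus voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ContractError("volume data must be 3D")
        if self.affine.shape != (4, 4):
            raise ContractError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-300:
            raise ContractError("affine is singular")


@dataclass
class DepthProfileSet:
    """Per-vertex intensity profiles across depths.

    ``intensities`` has shape (n_vertices, n_depths) ordered pial to
    white; ``mask`` flags vertices whose samples were all valid.
    """

    intensities: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensities.shape[0] != self.mask.shape[0]:
            raise ContractError("mask length must equal number of vertices")

    @property
    def n_depths(self) -> int:
        return self.intensities.shape[1]


def world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map world-mm points to continuous 0-based voxel coordinates."""
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def trilinear_sample(volume: Volume, points: np.ndarray):
    """Sample a volume at world-mm points.

    Returns
    -------
    values : (K,) array
        Trilinear interpolates; NaN where invalid.
    valid : (K,) bool array
        False for points outside the interpolation domain
        ``[0, n_i - 1]`` along any axis.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.shape[1] != 3:
        raise ContractError("points must be (K, 3)")
    if not np.all(np.isfinite(points)):
        raise ContractError("points must be finite")
    vox = world_to_voxel(volume.affine, points)
    shape = np.asarray(volume.data.shape)
    valid = np.all((vox >= 0.0) & (vox <= shape - 1), axis=1)
    values = np.full(len(points), np.nan)
    if valid.any():
        values[valid] = ndimage.map_coordinates(
            volume.data, vox[valid].T, order=1, mode="nearest", prefilter=False
        )
    return values, valid


def sample_profiles(volume: Volume, stack: DepthSurfaceStack) -> DepthProfileSet:
    """Sample a volume at every depth surface vertex.

    Row ``v``, column ``d`` holds the trilinear sample at vertex ``v`` of
    depth surface ``d`` (pial to white).  A vertex is masked out if any
    of its depth samples is invalid.
    """
    coords = stack.vertex_coordinates()  # (D, N, 3)
    n_depths, n_vertices, _ = coords.shape
    values, valid = trilinear_sample(volume, coords.reshape(-1, 3))
    intensities = values.reshape(n_depths, n_vertices).T
    mask = valid.reshape(n_depths, n_vertices).all(axis=0)
    return DepthProfileSet(intensities=intensities, mask=mask)
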