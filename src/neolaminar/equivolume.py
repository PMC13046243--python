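"""Equivolumetric intracortical surface construction.

The cortical ribbon is bounded by a pial and a white-matter triangle mesh
with one-to-one vertex correspondence.  Intermediate depth surfaces are
placed along each pial-white vertex segment so that each inter-surface
shell encloses an equal fraction of the local cortical *volume* rather
than an equal Euclidean distance.  This compensates for cortical folding:
in gyral crowns the outer surface is larger than the inner one and layers
are compressed towards the white matter, in sulcal fundi the opposite
holds.

Local curvature enters through the ratio of the pial and white vertex
areas.  Modelling the column above a vertex as a frustum whose
cross-sectional area varies linearly from the white area ``A_in`` to the
pial area ``A_out``, the cumulative volume up to distance fraction
``rho`` is

    V(rho) = A_in * rho + (A_out - A_in) * rho**2 / 2,

and solving ``V(rho) = alpha * V(1)`` for ``rho`` gives the closed form
implemented in :func:`equivolume_fraction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, GeometryError, TopologyError

__all__ = [
    "SurfaceMesh",
    "CorticalRibbon",
    "DepthSurfaceStack",
    "vertex_areas",
    "triangle_areas",
    "equivolume_fraction",
    "depth_fractions",
    "build_depth_surfaces",
]


@dataclass
class SurfaceMesh:
    """Triangle mesh in world millimetres.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates.
    triangles : (M, 3) int array
        0-based vertex indices of each triangle.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ContractError("vertices must be an (N, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ContractError("triangles must be an (M, 3) array")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ContractError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)


@dataclass
class CorticalRibbon:
    """Matched pial/white mesh pair; correspondence is by vertex index."""

    pial: SurfaceMesh
    white: SurfaceMesh

    def __post_init__(self):
        if self.pial.n_vertices != self.white.n_vertices:
            raise ContractError(
                f"pial/white vertex count mismatch "
                f"({self.pial.n_vertices} vs {self.white.n_vertices})"
            )
        if not np.array_equal(self.pial.triangles, self.white.triangles):
            raise ContractError("pial and white meshes must share the triangle list")

    @property
    def n_vertices(self) -> int:
        return self.pial.n_vertices


@dataclass
class DepthSurfaceStack:
    """Ordered intracortical surfaces, index 0 = pial, index -1 = white.

    ``alpha`` holds the volume fraction measured from the pial side
    (0 at the pial surface, 1 at the white surface), strictly increasing.
    """

    surfaces: list  # of SurfaceMesh, shared topology
    alpha: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if len(self.surfaces) != len(self.alpha):
            raise ContractError("one alpha per surface required")
        if np.any(np.diff(self.alpha) <= 0):
            raise ContractError("alpha must be strictly increasing (pial -> white)")

    @property
    def n_depths(self) -> int:
        return len(self.surfaces)

    @property
    def n_vertices(self) -> int:
        return self.surfaces[0].n_vertices

    def vertex_coordinates(self) -> np.ndarray:
        """Stacked coordinates, shape (n_depths, n_vertices, 3)."""
        return np.stack([s.vertices for s in self.surfaces])


def triangle_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Area of each triangle in mm^2."""
    v = mesh.vertices
    t = mesh.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Barycentric (one-third) vertex areas.

    Each triangle contributes a third of its area to each of its corners,
    so the vertex areas sum exactly to the total surface area.

    Raises
    ------
    TopologyError
        If some vertex has no incident triangle.
    """
    tri_area = triangle_areas(mesh)
    areas = np.zeros(mesh.n_vertices)
    np.add.at(areas, mesh.triangles.ravel(), np.repeat(tri_area / 3.0, 3))
    if np.any(areas == 0):
        idx = int(np.flatnonzero(areas == 0)[0])
        raise TopologyError(f"vertex {idx} has no incident triangle")
    return areas


_EQUAL_AREA_RTOL = 1e-9


def equivolume_fraction(alpha, area_in, area_out):
    """Distance fraction enclosing volume fraction ``alpha``.

    Parameters
    ----------
    alpha : float or array
        Volume fraction in [0, 1], measured from the surface with area
        ``area_in``.
    area_in, area_out : float or array, > 0
        Vertex areas of the start and end surfaces.

    Returns
    -------
    rho : float or array
        Fractional Euclidean distance from the ``area_in`` surface toward
        the ``area_out`` surface.  When the two areas coincide the column
        is a prism and ``rho == alpha``.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    a_in = np.asarray(area_in, dtype=np.float64)
    a_out = np.asarray(area_out, dtype=np.float64)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")
    if np.any(a_in <= 0) or np.any(a_out <= 0):
        raise ValueError("vertex areas must be positive")

    alpha, a_in, a_out = np.broadcast_arrays(alpha, a_in, a_out)
    diff = a_out - a_in
    # near-equal areas: the closed form cancels catastrophically, use the
    # prism limit rho = alpha
    flat = np.abs(diff) < _EQUAL_AREA_RTOL * np.maximum(a_in, a_out)
    safe_diff = np.where(flat, 1.0, diff)
    rho = (-a_in + np.sqrt(alpha * a_out**2 + (1.0 - alpha) * a_in**2)) / safe_diff
    rho = np.where(flat, alpha, rho)
    rho = np.clip(rho, 0.0, 1.0)
    if rho.ndim == 0:
        return float(rho)
    return rho


def depth_fractions(n_depths: int = 12, boundary: bool = True) -> np.ndarray:
    """Pial-side volume fractions of the depth grid.

    With ``boundary=True`` (default) the grid spans [0, 1] inclusive, so
    the first and last surfaces coincide with the pial and white
    boundaries.  With ``boundary=False`` an interior grid
    ``(d - 0.5) / n`` is used, avoiding boundary partial-volume.
    """
    if n_depths < 2:
        raise ValueError("n_depths must be >= 2")
    if boundary:
        return np.linspace(0.0, 1.0, n_depths)
    return (np.arange(n_depths) + 0.5) / n_depths


def build_depth_surfaces(
    ribbon: CorticalRibbon, n_depths: int = 12, boundary: bool = True
) -> DepthSurfaceStack:
    """Construct the equivolumetric depth-surface stack of a ribbon.

    Each depth surface places vertex ``v`` at
    ``white_v + rho * (pial_v - white_v)`` where ``rho`` is the
    equivolumetric distance fraction computed from the white-side vertex
    area (``A_in``) and the pial-side vertex area (``A_out``).  Surfaces
    are ordered pial (index 0) to white (index -1).
    """
    a_white = vertex_areas(ribbon.white)
    a_pial = vertex_areas(ribbon.pial)
    thickness = np.linalg.norm(ribbon.pial.vertices - ribbon.white.vertices, axis=1)
    if np.any(thickness <= 0):
        raise GeometryError("pial and white vertices coincide somewhere")

    alpha_pial = depth_fractions(n_depths, boundary=boundary)
    surfaces = []
    for a_p in alpha_pial:
        # volume fraction measured from the white side
        rho = equivolume_fraction(1.0 - a_p, a_white, a_pial)
        pts = ribbon.white.vertices + rho[:, None] * (
            ribbon.pial.vertices - ribbon.white.vertices
        )
        surfaces.append(SurfaceMesh(pts, ribbon.pial.triangles))
    return DepthSurfaceStack(surfaces=surfaces, alpha=alpha_pial)
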