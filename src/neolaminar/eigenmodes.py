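"""Geometric eigenmodes of a cortical mesh.

The Laplace-Beltrami operator (LBO) treats the cortical surface as a
Riemannian 2-manifold; its eigenfunctions — the *geometric eigenmodes*
— form spatial patterns ordered from coarse to fine spatial frequency.
The first mode is constant over the surface; modes 2-4 of a roughly
ellipsoidal cortex capture the anterior-posterior, superior-inferior and
medial-lateral axes, which is why downstream analyses correlate effect
maps with modes 2-4.

Discretization is linear (P1) finite elements on the triangle mesh:

* stiffness ``K``: the cotangent Laplacian, ``K[i,j] = -(cot a + cot
  b)/2`` over the one or two angles opposite edge (i, j), diagonal set so
  rows sum to zero;
* mass ``M``: the consistent FEM mass matrix, each triangle of area
  ``A`` contributing ``A/6`` to its corner diagonals and ``A/12`` to
  each corner pair, so all entries sum to the total surface area.

Eigenpairs solve the generalized problem ``K v = lambda M v``; on a
sphere of radius R the spectrum follows the closed-form degeneracy law
``lambda = l (l + 1) / R**2`` with multiplicity ``2 l + 1``, which
serves as the accuracy oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import eigsh

from .equivolume import SurfaceMesh
from .errors import ContractError, GeometryError, NumericalError
from .moments import Parcellation

__all__ = [
    "EigenmodeBasis",
    "build_fem_matrices",
    "compute_eigenmodes",
    "upsample_parcel_map",
]


@dataclass
class EigenmodeBasis:
    """Mass-orthonormal LBO eigenpairs.

    ``eigenvalues`` ascend; ``modes[:, i]`` is the per-vertex loading of
    mode ``i + 1`` (1-based mode numbering, mode 1 constant).
    """

    eigenvalues: np.ndarray
    modes: np.ndarray
    mass_matrix_ref: str = ""

    def mode(self, number: int) -> np.ndarray:
        """Loadings of a 1-based mode number (mode 1 = constant)."""
        if not 1 <= number <= self.modes.shape[1]:
            raise ContractError(f"mode {number} not computed")
        return self.modes[:, number - 1]


_DEGENERATE_COT = 1e12


def build_fem_matrices(mesh: SurfaceMesh):
    """Assemble the P1 FEM (stiffness, mass) pair of a triangle mesh.

    Returns two symmetric CSR matrices.  Raises GeometryError on a
    degenerate (zero-area) triangle, naming it.
    """
    v = mesh.vertices
    tris = mesh.triangles
    n = mesh.n_vertices

    ii, jj, kk = tris[:, 0], tris[:, 1], tris[:, 2]
    e0 = v[kk] - v[jj]  # edge opposite vertex i
    e1 = v[ii] - v[kk]
    e2 = v[jj] - v[ii]
    double_area = np.linalg.norm(np.cross(e1, e2), axis=1)
    if np.any(double_area <= 0) or not np.all(np.isfinite(double_area)):
        bad = int(np.flatnonzero(~(double_area > 0))[0])
        raise GeometryError(f"degenerate triangle {bad} (zero area)")

    # cot of the angle at each corner: dot of adjacent edges / (2 * area)
    cot_i = np.einsum("ij,ij->i", -e1, e2) / double_area
    cot_j = np.einsum("ij,ij->i", -e2, e0) / double_area
    cot_k = np.einsum("ij,ij->i", -e0, e1) / double_area
    for name, c in (("i", cot_i), ("j", cot_j), ("k", cot_k)):
        if np.any(np.abs(c) > _DEGENERATE_COT):
            bad = int(np.flatnonzero(np.abs(c) > _DEGENERATE_COT)[0])
            raise GeometryError(f"near-degenerate triangle {bad} (cot overflow)")

    # off-diagonal stiffness: edge (j,k) gets -cot(angle at i)/2, etc.
    rows = np.concatenate([jj, kk, kk, ii, ii, jj])
    cols = np.concatenate([kk, jj, ii, kk, jj, ii])
    w = np.concatenate([cot_i, cot_i, cot_j, cot_j, cot_k, cot_k]) * -0.5
    K = sparse.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    K = K - sparse.diags(np.asarray(K.sum(axis=1)).ravel())

    area = double_area / 2.0
    m_off = np.tile(area / 12.0, 6)
    m_diag_rows = np.concatenate([ii, jj, kk])
    m_diag = np.tile(area / 6.0, 3)
    M = (
        sparse.coo_matrix((m_off, (rows, cols)), shape=(n, n))
        + sparse.coo_matrix((m_diag, (m_diag_rows, m_diag_rows)), shape=(n, n))
    ).tocsr()
    return K, M


def lump_mass(M: sparse.spmatrix) -> sparse.spmatrix:
    """Row-sum (lumped) diagonal approximation of the mass matrix."""
    return sparse.diags(np.asarray(M.sum(axis=1)).ravel())


def _fix_signs(modes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the entry of largest magnitude is
    positive; ties broken by lowest vertex index."""
    out = modes.copy()
    for i in range(out.shape[1]):
        col = out[:, i]
        idx = int(np.argmax(np.abs(col)))  # argmax returns the first maximum
        if col[idx] < 0:
            out[:, i] = -col
    return out


def compute_eigenmodes(
    mesh: SurfaceMesh, k: int, lumped: bool = False
) -> EigenmodeBasis:
    """Smallest-k eigenpairs of the surface LBO, mass-orthonormal.

    Solved in shift-invert mode around a small negative shift (the
    operator is positive semi-definite with a single zero eigenvalue on
    a connected closed surface).
    """
    if k < 1:
        raise ContractError("k must be >= 1")
    if k >= mesh.n_vertices:
        raise ContractError("k must be much smaller than the vertex count")
    K, M = build_fem_matrices(mesh)
    if lumped:
        M = lump_mass(M)
    # fixed, generic start vector: ARPACK otherwise randomizes the basis of
    # degenerate eigenspaces (e.g. the sphere's l-multiplets) between runs
    v0 = np.linspace(1.0, 2.0, mesh.n_vertices)
    try:
        vals, vecs = eigsh(K, k=k, M=M, sigma=-0.01, which="LM", v0=v0)
    except Exception as exc:  # pragma: no cover - solver failure path
        raise NumericalError(f"eigenmode solver failed: {exc}") from exc
    order = np.argsort(vals)
    vals = np.maximum(vals[order], 0.0)
    vals[0] = 0.0 if vals[0] < 1e-8 else vals[0]
    vecs = vecs[:, order]
    # enforce exact mass-orthonormality (eigsh already returns M-orthonormal
    # vectors; renormalize to guard against round-off)
    norms = np.sqrt(np.einsum("ij,ij->j", vecs, M @ vecs))
    vecs = vecs / norms
    vecs = _fix_signs(vecs)
    return EigenmodeBasis(
        eigenvalues=vals, modes=vecs,
        mass_matrix_ref="lumped" if lumped else "consistent",
    )


def upsample_parcel_map(effects: pd.DataFrame, parcellation: Parcellation,
                        column: str = "t") -> np.ndarray:
    """Broadcast a parcel-level statistic to vertices.

    Each vertex receives its parcel's value from ``effects[column]``
    (indexed by parcel id); vertices of excluded or absent parcels get
    NaN.
    """
    labels = parcellation.labels
    out = np.full(len(labels), np.nan)
    values = effects[column]
    for pid in effects.index:
        out[labels == pid] = values.loc[pid]
    for pid in parcellation.excluded_ids:
        out[labels == pid] = np.nan
    return out
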