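"""Linear (P1) tetrahedral finite-element kernels.

Vectorized assembly of the standard operators on an unstructured tet mesh:
stiffness with per-element coefficient, lumped mass with per-element
coefficient, lumped boundary (Robin) mass on labeled facets, distribution of
per-element volumetric sources to nodes, and barycentric point evaluation.

All quantities are SI; coordinates in meters.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = [
    "tet_volumes",
    "shape_gradients",
    "stiffness_matrix",
    "lumped_mass",
    "facet_areas",
    "robin_lumped",
    "element_source_to_nodes",
    "element_means",
    "PointLocator",
    "apply_dirichlet",
]


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of all tets (positive for correctly oriented elements)."""
    p = nodes[tets]                      # (M,4,3)
    J = p[:, 1:] - p[:, :1]              # (M,3,3)
    return np.linalg.det(J) / 6.0


def shape_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Gradients of the four P1 basis functions per tet.

    Returns ``(grads, vols)`` with ``grads`` of shape (M,4,3).
    """
    p = nodes[tets]
    J = p[:, 1:] - p[:, :1]
    vols = np.linalg.det(J) / 6.0
    # with edge-row Jacobian J[i] = p_{i+1}-p_0: grad(lambda_i) = rows of
    # J^{-T} for i=1..3; lambda_0 = 1 - sum
    g123 = np.transpose(np.linalg.inv(J), (0, 2, 1))
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vols


def stiffness_matrix(nodes, tets, coeff) -> sp.csr_matrix:
    """Assemble ``K[i,j] = sum_e coeff_e * vol_e * grad(phi_i).grad(phi_j)``."""
    grads, vols = shape_gradients(nodes, tets)
    coeff = np.broadcast_to(np.asarray(coeff, dtype=float), vols.shape)
    ke = np.einsum("eid,ejd->eij", grads, grads) * (coeff * vols)[:, None, None]
    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    n = nodes.shape[0]
    return sp.coo_matrix((ke.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()


def lumped_mass(nodes, tets, coeff, vols=None) -> np.ndarray:
    """Diagonal (row-sum lumped) mass vector with per-element coefficient."""
    if vols is None:
        vols = tet_volumes(nodes, tets)
    coeff = np.broadcast_to(np.asarray(coeff, dtype=float), vols.shape)
    contrib = (coeff * vols / 4.0)
    m = np.zeros(nodes.shape[0])
    np.add.at(m, tets.reshape(-1), np.repeat(contrib, 4))
    return m


def facet_areas(nodes, tris) -> np.ndarray:
    p = nodes[tris]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def robin_lumped(nodes, tris, h: float) -> np.ndarray:
    """Lumped boundary-mass vector ``h * area/3`` per facet node."""
    areas = facet_areas(nodes, tris)
    m = np.zeros(nodes.shape[0])
    np.add.at(m, tris.reshape(-1), np.repeat(h * areas / 3.0, 3))
    return m


def element_source_to_nodes(nodes, tets, q_elem, vols=None) -> np.ndarray:
    """Nodal load vector of a piecewise-constant volumetric source (W/m^3)."""
    if vols is None:
        vols = tet_volumes(nodes, tets)
    contrib = np.asarray(q_elem, dtype=float) * vols / 4.0
    f = np.zeros(nodes.shape[0])
    np.add.at(f, tets.reshape(-1), np.repeat(contrib, 4))
    return f


def element_means(tets, nodal: np.ndarray) -> np.ndarray:
    """Per-element mean of a nodal field."""
    return nodal[tets].mean(axis=1)


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, fixed: np.ndarray,
                    values: np.ndarray):
    """Reduce ``A x = b`` by the Dirichlet rows ``fixed`` with given values.

    Returns ``(A_ff, b_f, free)`` where ``free`` indexes the retained rows.
    """
    n = A.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[fixed] = True
    free = np.nonzero(~mask)[0]
    x = np.zeros(n)
    x[fixed] = values
    b_f = b[free] - A[free][:, fixed] @ x[fixed]
    A_ff = A[free][:, free].tocsc()
    return A_ff, b_f, free


class PointLocator:
    """Locate arbitrary points in a tet mesh and interpolate nodal fields.

    Builds a centroid KD-tree once; each query tests barycentric coordinates
    of nearby tets.  Interpolation weights are cached per point set so that
    repeated probing during a transient run costs one matrix-vector product.
    """

    def __init__(self, nodes: np.ndarray, tets: np.ndarray):
        self.nodes = nodes
        self.tets = tets
        p = nodes[tets]
        self._J = p[:, 1:] - p[:, :1]
        self._Jinv = np.linalg.inv(self._J)
        self._p0 = p[:, 0]
        self._tree = cKDTree(nodes)
        # node -> incident tets (CSR layout); candidate search via vertex
        # adjacency stays robust on strongly graded meshes where centroid
        # proximity is misleading
        order = np.argsort(tets.reshape(-1), kind="stable")
        self._inc_tets = order // 4
        counts = np.bincount(tets.reshape(-1), minlength=len(nodes))
        self._inc_ptr = np.concatenate([[0], np.cumsum(counts)])

    def _bary(self, e: int, pt: np.ndarray) -> np.ndarray:
        lam = self._Jinv[e].T @ (pt - self._p0[e])
        return np.concatenate([[1.0 - lam.sum()], lam])

    def locate(self, points: np.ndarray, tol: float = 1e-9):
        """Return ``(tet_index, bary)`` for each point; raises if outside."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        npts = points.shape[0]
        elems = np.full(npts, -1, dtype=np.int64)
        bary = np.zeros((npts, 4))
        remaining = np.arange(npts)
        for k in (2, 16, 128):
            if remaining.size == 0:
                break
            k_eff = min(k, len(self.nodes))
            _, near = self._tree.query(points[remaining], k=k_eff)
            near = np.atleast_2d(near)
            still = []
            for idx, nds in zip(remaining, near):
                cand = np.unique(np.concatenate(
                    [self._inc_tets[self._inc_ptr[n]:self._inc_ptr[n + 1]]
                     for n in nds]))
                found = False
                for e in cand:
                    lam = self._bary(e, points[idx])
                    if np.all(lam >= -tol):
                        elems[idx] = e
                        bary[idx] = lam
                        found = True
                        break
                if not found:
                    still.append(idx)
            remaining = np.asarray(still, dtype=np.int64)
        # exhaustive fallback for stragglers (points on coarse-cell interiors
        # whose vertices are not among their nearest mesh nodes)
        for idx in remaining:
            d = points[idx] - self._p0
            lam123 = np.einsum("eji,ej->ei", self._Jinv, d)
            lam = np.concatenate([1.0 - lam123.sum(axis=1, keepdims=True),
                                  lam123], axis=1)
            e = int(np.argmax(lam.min(axis=1)))
            if lam[e].min() < -1e-6:
                raise ValueError(f"point outside the mesh: {points[idx]}")
            elems[idx] = e
            bary[idx] = lam[e]
        return elems, np.clip(bary, 0.0, 1.0)

    def interpolation_weights(self, points: np.ndarray) -> sp.csr_matrix:
        """Sparse operator W with ``W @ nodal_field = field at points``."""
        elems, bary = self.locate(points)
        rows = np.repeat(np.arange(len(elems)), 4)
        cols = self.tets[elems].reshape(-1)
        return sp.coo_matrix(
            (bary.reshape(-1), (rows, cols)),
            shape=(len(elems), self.nodes.shape[0])).tocsr()

    def interpolate(self, points: np.ndarray, nodal: np.ndarray) -> np.ndarray:
        return self.interpolation_weights(points) @ nodal
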