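"""Quasi-static electric solve with constant-power source scaling.

At 480 kHz the RF current in tissue is governed, to quasi-static accuracy,
by the conduction Laplace problem ``div(sigma grad V) = 0`` with the active
tip held at the applied potential and the dispersive ground pad modeled as
V = 0 on the grounded outer boundaries.  The Joule heat density is
``Qp = sigma |grad V|^2``.

Because the problem is linear in V at frozen sigma(T), constant-power
delivery is exact: solve once at unit tip potential, then scale V by
``sqrt(P_target / P_unit)``.  The tip-to-ground impedance ``Z =
V_applied^2 / P_delivered`` is invariant under that scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from . import fem
from .geometry import Mesh

__all__ = ["ElectricSolution", "solve_unit_potential", "scale_to_power",
           "impedance", "solve_mesh_unit_potential"]


class SolverError(RuntimeError):
    pass


@dataclass
class ElectricSolution:
    """Potential field and derived power/impedance quantities."""

    V: np.ndarray            # nodal potential, V
    E_mag: np.ndarray        # element field magnitude, V/m
    Qp: np.ndarray           # element Joule heat density, W/m^3
    P_delivered: float       # total Joule power, W
    Z: float                 # tip-to-ground impedance, Ohm
    V_applied: float         # tip potential, V


def solve_unit_potential(nodes: np.ndarray, tets: np.ndarray,
                         sigma_elem: np.ndarray,
                         source_nodes: np.ndarray,
                         ground_nodes: np.ndarray,
                         active_mask: np.ndarray | None = None,
                         ) -> ElectricSolution:
    """Solve the conduction problem with V = 1 on ``source_nodes`` and
    V = 0 on ``ground_nodes``.

    ``active_mask`` selects the elements assembled and counted in the power
    integral (conductor-interior elements are excluded by the caller).
    """
    if active_mask is None:
        active_mask = np.ones(len(tets), dtype=bool)
    sig = np.asarray(sigma_elem, dtype=float)
    if np.any(sig[active_mask] <= 0):
        raise ValueError("sigma must be strictly positive on active elements")
    K = fem.stiffness_matrix(nodes, tets[active_mask], sig[active_mask])

    fixed = np.concatenate([np.asarray(source_nodes), np.asarray(ground_nodes)])
    if len(np.intersect1d(source_nodes, ground_nodes)):
        raise ValueError("source and ground node sets overlap")
    vals = np.concatenate([np.ones(len(source_nodes)), np.zeros(len(ground_nodes))])
    A, b, free = fem.apply_dirichlet(K, np.zeros(nodes.shape[0]), fixed, vals)

    V = np.zeros(nodes.shape[0])
    V[fixed] = vals
    if free.size:
        try:
            V[free] = spla.splu(A).solve(b)
        except RuntimeError as exc:  # pragma: no cover - singular system
            raise SolverError(f"electric solve failed: {exc}") from exc
    res = np.linalg.norm(A @ V[free] - b) if free.size else 0.0
    nrm = max(np.linalg.norm(b), 1e-300)
    if free.size and res / nrm > 1e-8:
        raise SolverError(f"electric solve residual too large: {res / nrm:.2e}")

    grads, vols = fem.shape_gradients(nodes, tets)
    gradV = np.einsum("eid,ei->ed", grads, V[tets])
    E_mag = np.linalg.norm(gradV, axis=1)
    Qp = sig * E_mag ** 2
    Qp[~active_mask] = 0.0
    P = float(np.sum(Qp * vols))
    if P <= 0:
        raise SolverError("non-positive delivered power (disconnected path?)")
    return ElectricSolution(V=V, E_mag=E_mag, Qp=Qp, P_delivered=P,
                            Z=1.0 / P, V_applied=1.0)


def solve_mesh_unit_potential(mesh: Mesh, sigma_elem: np.ndarray,
                              ) -> ElectricSolution:
    """Unit-potential solve on a phantom mesh.

    Tip-region nodes are the equipotential source (the copper conductor is
    effectively equipotential; modeling its interior as a Dirichlet block
    avoids an ill-conditioned 5.99e7 S/m contrast).  Grounded-boundary nodes
    are V = 0; the skin surface and the shaft wall are naturally insulated.
    """
    tip_nodes = np.unique(mesh.tets[mesh.region_mask("tip")])
    ground = mesh.boundary_nodes("outer_ground")
    ground = np.setdiff1d(ground, tip_nodes)
    active = ~mesh.region_mask("tip")
    return solve_unit_potential(mesh.nodes, mesh.tets, sigma_elem,
                                tip_nodes, ground, active)


def scale_to_power(sol: ElectricSolution, P_target: float) -> ElectricSolution:
    """Rescale a solution to deliver exactly ``P_target`` watts."""
    if P_target <= 0:
        raise ValueError("target power must be positive")
    s = P_target / sol.P_delivered
    return ElectricSolution(V=sol.V * np.sqrt(s), E_mag=sol.E_mag * np.sqrt(s),
                            Qp=sol.Qp * s, P_delivered=P_target, Z=sol.Z,
                            V_applied=sol.V_applied * np.sqrt(s))


def impedance(sol: ElectricSolution) -> float:
    """Tip-to-ground impedance ``V_applied^2 / P_delivered`` (Ohm)."""
    if sol.P_delivered <= 0:
        raise ValueError("impedance undefined at zero power")
    return sol.V_applied ** 2 / sol.P_delivered
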