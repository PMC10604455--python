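"""Transient Pennes bioheat solver (backward Euler, P1 elements).

The temperature field obeys

    rho c_p dT/dt - div(k grad T) = Qp + rho_b c_b omega_b (T_b - T) + Q_met

with Dirichlet T = 37 degC on the grounded outer boundaries and a Robin
(convective) condition ``-n.q = h (T_ext - T)`` on the skin surface
(h = 10 W/m^2/K, T_ext = 25 degC).  The perfusion sink uses the
damage-decayed perfusion field; all material coefficients are piecewise
constant per element and lagged one step, so each implicit step is a single
symmetric positive-definite solve.

Mass and perfusion/Robin terms are lumped (row-sum), which keeps the step
matrix an M-matrix and the scheme unconditionally stable and monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .geometry import Mesh

__all__ = ["BoundaryConditions", "ThermalState", "ThermalSystem",
           "probe_temperature"]

T_BODY = 37.0


@dataclass(frozen=True)
class BoundaryConditions:
    """Thermal boundary data: body-temperature Dirichlet on the outer
    boundary, convective exchange with room air on the skin surface."""

    dirichlet_T: float = 37.0   # degC
    h: float = 10.0             # W/m^2/K
    T_ext: float = 25.0         # degC

    def __post_init__(self):
        if self.h < 0:
            raise ValueError("convective coefficient h must be >= 0")


@dataclass
class ThermalState:
    T: np.ndarray   # nodal temperature, degC
    t: float = 0.0  # elapsed time, s


@dataclass
class ThermalSystem:
    """Reusable assembly context for one mesh + boundary configuration.

    Per step the caller supplies the lagged coefficient fields; the system
    assembles ``(M/dt + K + P_lumped + R_lumped) T = M/dt T_old + loads``
    and solves the Dirichlet-reduced SPD system with a sparse direct solve
    for small meshes and preconditioned CG (warm-started from the previous
    temperature) for larger ones.
    """

    mesh: Mesh
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)
    dirichlet_nodes: np.ndarray | None = None
    robin_tris: np.ndarray | None = None
    _direct_limit: int = 20000

    def __post_init__(self):
        m = self.mesh
        if self.dirichlet_nodes is None:
            ground = m.boundary_nodes("outer_ground")
            skin = m.boundary_nodes("skin_surface")
            self.dirichlet_nodes = np.setdiff1d(ground, skin)
        if self.robin_tris is None:
            from .geometry import BOUNDARY_LABELS
            lab = m.boundary_label == BOUNDARY_LABELS.index("skin_surface")
            self.robin_tris = m.boundary_tris[lab]
        self._vols = m.volumes
        self._robin_m = fem.robin_lumped(m.nodes, self.robin_tris, self.bc.h)
        n = m.nodes.shape[0]
        mask = np.zeros(n, dtype=bool)
        mask[self.dirichlet_nodes] = True
        self._free = np.nonzero(~mask)[0]
        self._fixed_mask = mask
        self._factor_cache: dict | None = None

    def initial_state(self, T0: float = T_BODY) -> ThermalState:
        return ThermalState(T=np.full(self.mesh.nodes.shape[0], float(T0)))

    def step(self, state: ThermalState, dt: float, *,
             k_elem: np.ndarray, rhoc_elem: np.ndarray,
             perf_sink_elem: np.ndarray, q_elem: np.ndarray,
             T_blood: float = T_BODY,
             extra_nodal_load: np.ndarray | None = None,
             coeff_retol: float = 0.0) -> ThermalState:
        """Advance one implicit step.

        ``perf_sink_elem`` is ``rho_b c_b omega_b`` per element (W/m^3/K);
        ``q_elem`` is the total volumetric source ``Qp + Q_met`` (W/m^3);
        ``extra_nodal_load`` adds an arbitrary nodal load (W), used by
        manufactured-solution verification.

        ``coeff_retol > 0`` reuses the factorized step matrix while the
        coefficient fields (k, perfusion sink, dt) have drifted less than
        that relative tolerance since the last factorization — the same
        property-lag idea used for the electric solve; 0 refactors every
        step.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        m = self.mesh
        nodes, tets = m.nodes, m.tets
        k_elem = np.broadcast_to(np.asarray(k_elem, dtype=float),
                                 (len(tets),))
        perf_sink_elem = np.broadcast_to(
            np.asarray(perf_sink_elem, dtype=float), (len(tets),))
        M = fem.lumped_mass(nodes, tets, np.asarray(rhoc_elem) / dt, self._vols)
        P = fem.lumped_mass(nodes, tets, perf_sink_elem, self._vols)
        b = M * state.T + fem.element_source_to_nodes(nodes, tets, q_elem,
                                                      self._vols)
        b += P * T_blood + self._robin_m * self.bc.T_ext
        if extra_nodal_load is not None:
            b = b + extra_nodal_load

        T = state.T.copy()
        if self.dirichlet_nodes.size:
            T[self.dirichlet_nodes] = self.bc.dirichlet_T
        free = self._free
        if free.size:
            solve = self._get_solver(dt, k_elem, perf_sink_elem, M, P,
                                     coeff_retol, T)
            x0 = T[free]
            bc_vals = np.full(self.dirichlet_nodes.size, self.bc.dirichlet_T)
            T[free] = solve(b, bc_vals, x0)
        if not np.all(np.isfinite(T)):
            raise RuntimeError("non-finite temperature after thermal step")
        return ThermalState(T=T, t=state.t + dt)

    def _get_solver(self, dt, k_elem, perf_elem, M, P, retol, T):
        cache = self._factor_cache
        reuse = (retol > 0 and cache is not None and cache["dt"] == dt
                 and _drift(k_elem, cache["k"]) <= retol
                 and _drift(perf_elem, cache["perf"]) <= retol)
        if not reuse:
            m = self.mesh
            K = fem.stiffness_matrix(m.nodes, m.tets, k_elem)
            A = K + sp.diags(M + P + self._robin_m)
            free, fixed = self._free, self.dirichlet_nodes
            A_csr = A.tocsr()
            A_ff = A_csr[free][:, free].tocsc()
            A_fd = A_csr[free][:, fixed].tocsr()
            direct = free.size <= self._direct_limit
            cache = {
                "dt": dt, "k": k_elem.copy(), "perf": perf_elem.copy(),
                "A_ff": A_ff, "A_fd": A_fd,
                "lu": spla.splu(A_ff) if direct else None,
                "jacobi": None if direct else sp.diags(1.0 / A_ff.diagonal()),
            }
            self._factor_cache = cache

        def solve(b, bc_vals, x0):
            b_f = b[self._free] - cache["A_fd"] @ bc_vals
            if cache["lu"] is not None:
                return cache["lu"].solve(b_f)
            sol, info = spla.cg(cache["A_ff"], b_f, x0=x0,
                                M=cache["jacobi"], rtol=1e-10, atol=0.0,
                                maxiter=2000)
            if info != 0:
                sol = spla.splu(cache["A_ff"]).solve(b_f)
            return sol

        return solve


def _drift(new: np.ndarray, ref: np.ndarray) -> float:
    scale = max(float(np.max(np.abs(ref))), 1e-300)
    return float(np.max(np.abs(new - ref))) / scale


def probe_temperature(mesh: Mesh, state: ThermalState,
                      points: np.ndarray,
                      locator: fem.PointLocator | None = None) -> np.ndarray:
    """P1 interpolation of the temperature at arbitrary points (degC)."""
    loc = locator or fem.PointLocator(mesh.nodes, mesh.tets)
    return loc.interpolate(np.atleast_2d(points), state.T)
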