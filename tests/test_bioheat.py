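"""Pennes solver oracles: equilibrium, scalar-ODE limits, Robin slab."""

import numpy as np
import pytest

from thyrorfa import geometry as geo
from thyrorfa.bioheat import (BoundaryConditions, ThermalSystem,
                              probe_temperature)
from thyrorfa.geometry import Mesh, structured_box_mesh

from conftest import make_cube_mesh

RHO_C = 1050.0 * 3609.0                      # thyroid rho * c_p
SINK = 1050.0 * 0.098 * 3617.0               # rho_b * omega_b * c_b


def _boundary_tris(nodes, tets, predicate):
    """Exterior facets whose three nodes satisfy ``predicate``."""
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    flat = tets[:, local].reshape(-1, 3)
    keys = np.sort(flat, axis=1)
    uniq, inv, counts = np.unique(keys, axis=0, return_inverse=True,
                                  return_counts=True)
    ext = flat[counts[inv] == 1]
    keep = np.all(predicate(nodes[ext]), axis=1)
    return ext[keep]


def _labeled_cube(n=4, L=0.01, robin_at_x0=False):
    """Cube with Dirichlet on x = L (and optionally Robin on x = 0)."""
    xs = np.linspace(0.0, L, n)
    nodes, tets = structured_box_mesh(xs, xs, xs)
    ground = _boundary_tris(nodes, tets, lambda p: p[:, :, 0] > L - 1e-12)
    skin = _boundary_tris(nodes, tets, lambda p: p[:, :, 0] < 1e-12)
    if robin_at_x0:
        tris = np.concatenate([skin, ground])
        labels = np.concatenate([
            np.zeros(len(skin), dtype=int),
            np.full(len(ground), 1, dtype=int)])
    else:
        tris, labels = ground, np.full(len(ground), 1, dtype=int)
    return Mesh(nodes=nodes, tets=tets,
                region=np.full(len(tets), geo.REGIONS.index("thyroid")),
                boundary_tris=tris, boundary_label=labels)


class TestScalarLimits:
    def test_equilibrium_is_exact(self):
        mesh = _labeled_cube()
        sys_ = ThermalSystem(mesh)
        st = sys_.initial_state(37.0)
        for _ in range(5):
            st = sys_.step(st, 1.0, k_elem=0.52, rhoc_elem=RHO_C,
                           perf_sink_elem=0.0, q_elem=0.0)
        np.testing.assert_allclose(st.T, 37.0, atol=1e-10)

    @pytest.mark.parametrize("dt", [1.0, 0.5])
    def test_perfusion_relaxation_matches_exponential(self, dt):
        """Insulated, perfusion only: T = 37 + 10 exp(-t/tau) with
        tau = rho c_p / (rho_b omega_b c_b) ~ 10.2 s for thyroid."""
        mesh = make_cube_mesh()
        sys_ = ThermalSystem(mesh, BoundaryConditions(h=0.0),
                             dirichlet_nodes=np.array([], dtype=int),
                             robin_tris=np.zeros((0, 3), dtype=int))
        tau = RHO_C / SINK
        assert tau == pytest.approx(10.2, abs=0.1)
        st = sys_.initial_state(47.0)
        t_end = 20.0
        for _ in range(int(round(t_end / dt))):
            st = sys_.step(st, dt, k_elem=0.52, rhoc_elem=RHO_C,
                           perf_sink_elem=SINK, q_elem=0.0)
        exact = 37.0 + 10.0 * np.exp(-t_end / tau)
        err = abs(float(st.T.mean()) - exact)
        assert err < 0.25 * dt   # O(dt) accuracy

    def test_halving_dt_halves_relaxation_error(self):
        mesh = make_cube_mesh()
        errs = []
        for dt in (1.0, 0.5):
            sys_ = ThermalSystem(mesh, BoundaryConditions(h=0.0),
                                 dirichlet_nodes=np.array([], dtype=int),
                                 robin_tris=np.zeros((0, 3), dtype=int))
            st = sys_.initial_state(47.0)
            for _ in range(int(round(20.0 / dt))):
                st = sys_.step(st, dt, k_elem=0.52, rhoc_elem=RHO_C,
                               perf_sink_elem=SINK, q_elem=0.0)
            errs.append(abs(float(st.T.mean())
                            - (37.0 + 10.0 * np.exp(-20.0 / 10.1815))))
        assert errs[0] / errs[1] == pytest.approx(2.0, abs=0.3)

    def test_constant_source_linear_ramp(self):
        """Insulated, non-perfused, uniform Q: exact ramp Q/(rho c_p) per
        unit time (backward Euler is exact for constant sources)."""
        mesh = make_cube_mesh()
        sys_ = ThermalSystem(mesh, BoundaryConditions(h=0.0),
                             dirichlet_nodes=np.array([], dtype=int),
                             robin_tris=np.zeros((0, 3), dtype=int))
        Q = 5e5
        st = sys_.initial_state(37.0)
        for _ in range(10):
            st = sys_.step(st, 1.0, k_elem=0.52, rhoc_elem=RHO_C,
                           perf_sink_elem=0.0, q_elem=Q)
        np.testing.assert_allclose(st.T, 37.0 + 10 * Q / RHO_C, rtol=1e-9)

    def test_rejects_nonpositive_dt(self):
        mesh = make_cube_mesh()
        sys_ = ThermalSystem(mesh, BoundaryConditions(h=0.0),
                             dirichlet_nodes=np.array([], dtype=int),
                             robin_tris=np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            sys_.step(sys_.initial_state(), 0.0, k_elem=1.0, rhoc_elem=1.0,
                      perf_sink_elem=0.0, q_elem=0.0)


class TestBoundaries:
    def test_robin_slab_steady_profile(self):
        """Steady 1D slab: Robin (h=10, T_ext=25) at x=0, Dirichlet 37 at
        x=L, no sources -> linear profile with flux-matched surface
        temperature T0 = (k/L * 37 + h * 25) / (k/L + h)."""
        L, k, n = 0.01, 0.52, 9
        mesh = _labeled_cube(n=n, L=L, robin_at_x0=True)
        bc = BoundaryConditions(h=10.0, T_ext=25.0)
        sys_ = ThermalSystem(mesh, bc)
        st = sys_.initial_state(37.0)
        st = sys_.step(st, 1e15, k_elem=k, rhoc_elem=RHO_C,
                       perf_sink_elem=0.0, q_elem=0.0)
        T0 = (k / L * 37.0 + bc.h * bc.T_ext) / (k / L + bc.h)
        x = mesh.nodes[:, 0]
        exact = T0 + (37.0 - T0) * x / L
        np.testing.assert_allclose(st.T, exact, rtol=1e-3)

    def test_h_zero_means_insulated(self):
        mesh = _labeled_cube(robin_at_x0=True)
        sys_ = ThermalSystem(mesh, BoundaryConditions(h=0.0, T_ext=25.0))
        st = sys_.initial_state(37.0)
        st = sys_.step(st, 1e15, k_elem=0.52, rhoc_elem=RHO_C,
                       perf_sink_elem=0.0, q_elem=0.0)
        np.testing.assert_allclose(st.T, 37.0, atol=1e-8)

    def test_matched_external_temperature_gives_zero_flux(self):
        mesh = _labeled_cube(robin_at_x0=True)
        sys_ = ThermalSystem(mesh, BoundaryConditions(h=10.0, T_ext=37.0))
        st = sys_.initial_state(37.0)
        st = sys_.step(st, 1e15, k_elem=0.52, rhoc_elem=RHO_C,
                       perf_sink_elem=0.0, q_elem=0.0)
        np.testing.assert_allclose(st.T, 37.0, atol=1e-8)

    def test_negative_h_rejected(self):
        with pytest.raises(ValueError):
            BoundaryConditions(h=-1.0)


class TestProbes:
    def test_probe_at_node_and_affine_field(self):
        mesh = make_cube_mesh(n=4)
        sys_ = ThermalSystem(mesh, BoundaryConditions(h=0.0),
                             dirichlet_nodes=np.array([], dtype=int),
                             robin_tris=np.zeros((0, 3), dtype=int))
        st = sys_.initial_state(37.0)
        st.T = 37.0 + 100.0 * mesh.nodes[:, 0]
        got = probe_temperature(mesh, st, mesh.nodes[5])
        assert got[0] == pytest.approx(st.T[5], rel=1e-12)
        pts = np.array([[0.003, 0.004, 0.005], [0.007, 0.002, 0.009]])
        np.testing.assert_allclose(
            probe_temperature(mesh, st, pts), 37.0 + 100.0 * pts[:, 0],
            rtol=1e-10)

    def test_probe_outside_domain_raises(self):
        mesh = make_cube_mesh(n=4)
        sys_ = ThermalSystem(mesh, BoundaryConditions(h=0.0),
                             dirichlet_nodes=np.array([], dtype=int),
                             robin_tris=np.zeros((0, 3), dtype=int))
        st = sys_.initial_state(37.0)
        with pytest.raises(ValueError):
            probe_temperature(mesh, st, np.array([[1.0, 1.0, 1.0]]))
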