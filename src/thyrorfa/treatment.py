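"""One RF treatment: the coupled electro-thermal-damage time loop.

Per step (first-order operator splitting):

1. update sigma(T), k(T) (and, when ``perfusion_decay`` is enabled, the
   damage-decayed perfusion) from the lagged temperature and damage fields;
2. electric solve at unit tip potential, rescaled to deliver the power
   setpoint exactly (the unit solution is reused while the conductivity
   field has drifted less than ``sigma_retol`` since the last solve);
3. implicit (backward Euler) Pennes step;
4. Arrhenius damage accumulation on element-mean temperatures.

The run records impedance, delivered energy, the VRR trajectory, and the
running maximum temperature on a probe shell 10 mm away from the needle
surface (the thermal-safety monitor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import damage as dmg
from . import electric, fem, materials
from .bioheat import BoundaryConditions, ThermalSystem
from .geometry import ElectrodeSpec, Mesh, NeckPhantom, REGIONS

__all__ = ["TreatmentParams", "SafetyConstraint", "SimulationResult",
           "ElementProperties", "run_treatment", "safety_shell_points",
           "safety_margin", "radial_temperature_profile",
           "transverse_ablation_width", "sweep"]

POWER_BOUNDS = (45.0, 60.0)   # W, optimizer box
MAX_DURATION = 1200.0         # s (20 min)


@dataclass(frozen=True)
class TreatmentParams:
    """The two decision variables of the planning problem."""

    power: float      # W
    duration: float   # s

    def __post_init__(self):
        if self.power < 0 or self.duration <= 0:
            raise ValueError("power must be >= 0 and duration > 0")


@dataclass(frozen=True)
class SafetyConstraint:
    """Healthy tissue beyond ``radius`` from the needle surface must stay
    below ``T_limit``."""

    radius: float = 10e-3   # m
    T_limit: float = 100.0  # degC

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("safety radius must be positive")


@dataclass
class SimulationResult:
    times: np.ndarray             # s
    impedance: np.ndarray         # Ohm, per step
    energy: np.ndarray            # J, cumulative = power * t
    vrr: np.ndarray               # %, per step
    shell_max_T: np.ndarray       # degC, per step (max on safety shell)
    peak_T: float                 # degC, max nodal over the whole run
    T_final: np.ndarray           # nodal degC
    D_final: np.ndarray           # element damage index
    transverse_width: float       # m
    params: TreatmentParams
    scenario: str

    @property
    def impedance_drop_pct(self) -> float:
        z = self.impedance[np.isfinite(self.impedance)]
        if len(z) == 0:
            return float("nan")
        return 100.0 * (z[0] - z.min()) / z[0]


class ElementProperties:
    """Per-element property arrays for one mesh + perfusion scenario."""

    def __init__(self, mesh: Mesh, scenario: str = "low",
                 constants: materials.PhysicalConstants = materials.CONSTANTS):
        reg = materials.registry(scenario)
        by_code = [reg[name] for name in REGIONS]
        code = mesh.region
        get = lambda f: np.array([getattr(p, f) for p in by_code])[code]
        self.constants = constants
        self.sigma_ref = get("sigma_ref")
        self.k_ref = get("k_ref")
        self.rhoc = get("rho") * get("c_p")
        self.omega_b0 = get("omega_b0")
        self.Q_met = get("Q_met")
        self.A = get("A")
        self.dE = get("dE")
        self.biological = np.array([p.biological for p in by_code])[code]

    def sigma(self, T_elem: np.ndarray) -> np.ndarray:
        c = self.constants
        sig = np.where(
            self.biological,
            self.sigma_ref * (1.0 + c.p_i * (T_elem - c.T_ref)),
            self.sigma_ref)
        return np.maximum(sig, materials.SIGMA_FLOOR)

    def k(self, T_elem: np.ndarray) -> np.ndarray:
        c = self.constants
        return np.where(self.biological,
                        self.k_ref + c.r_i * (T_elem - c.T_ref), self.k_ref)

    def perfusion_sink(self, D_elem: np.ndarray) -> np.ndarray:
        c = self.constants
        return np.where(self.biological,
                        c.rho_blood * c.c_blood * self.omega_b0
                        * np.exp(-D_elem), 0.0)

    def damage_rate(self, T_elem: np.ndarray,
                    T_cutoff: float | None = None) -> np.ndarray:
        c = self.constants
        with np.errstate(divide="ignore"):
            rate = np.where(
                self.biological,
                self.A * np.exp(-self.dE / (c.R_gas * (T_elem + dmg.KELVIN))),
                0.0)
        if T_cutoff is not None:
            rate = np.where(T_elem >= T_cutoff, rate, 0.0)
        return rate


def safety_shell_points(electrode: ElectrodeSpec, phantom: NeckPhantom,
                        constraint: SafetyConstraint = SafetyConstraint(),
                        spacing: float = 1e-3) -> np.ndarray:
    """Deterministic probe lattice on the surface offset ``constraint.radius``
    from the needle (cylinder around the inserted needle, hemispherical cap
    past the distal tip end), clipped to the domain interior."""
    re = electrode.outer_diameter / 2
    R = constraint.radius + re
    x0 = electrode.tip_end_point[0]
    cy, cz = electrode.tip_end_point[1], electrode.tip_end_point[2]
    bmin, bmax = phantom.bounds
    margin = 1e-3
    xs = np.arange(x0, bmax[0] - margin, spacing)
    ntheta = max(8, int(np.ceil(2 * np.pi * R / spacing)))
    theta = np.arange(ntheta) * (2 * np.pi / ntheta)
    X, TH = np.meshgrid(xs, theta, indexing="ij")
    cyl = np.column_stack([X.ravel(),
                           cy + R * np.cos(TH.ravel()),
                           cz + R * np.sin(TH.ravel())])
    # hemispherical cap beyond the distal end
    nphi = max(3, int(np.ceil((np.pi / 2) * R / spacing)))
    phi = (np.arange(nphi) + 0.5) * (np.pi / 2 / nphi)
    P, TH = np.meshgrid(phi, theta, indexing="ij")
    cap = np.column_stack([
        x0 - R * np.sin(P.ravel()),
        cy + R * np.cos(P.ravel()) * np.cos(TH.ravel()),
        cz + R * np.cos(P.ravel()) * np.sin(TH.ravel())])
    pts = np.concatenate([cyl, cap])
    inside = np.all((pts > bmin + margin) & (pts < bmax - margin), axis=1)
    pts = pts[inside]
    if len(pts) == 0:
        raise ValueError("safety shell has no probe points inside the domain")
    return pts


def radial_temperature_profile(mesh: Mesh, T_nodal: np.ndarray,
                               electrode: ElectrodeSpec,
                               max_distance: float = 20e-3,
                               spacing: float = 0.5e-3,
                               locator: fem.PointLocator | None = None):
    """Temperature along the line perpendicular to the electrode surface at
    the active-tip midpoint.

    Returns ``(distance_m, T_C)`` with distance measured from the electrode
    surface outward (+y direction).
    """
    x_mid = electrode.tip_end_point[0] + electrode.tip_length / 2
    cy, cz = electrode.tip_end_point[1], electrode.tip_end_point[2]
    re = electrode.outer_diameter / 2
    s = np.arange(0.0, max_distance + spacing / 2, spacing)
    pts = np.column_stack([np.full_like(s, x_mid), cy + re + s,
                           np.full_like(s, cz)])
    loc = locator or fem.PointLocator(mesh.nodes, mesh.tets)
    return s, loc.interpolate(pts, T_nodal)


def safety_margin(mesh: Mesh, T_nodal: np.ndarray,
                  electrode: ElectrodeSpec, phantom: NeckPhantom,
                  constraint: SafetyConstraint = SafetyConstraint(),
                  locator: fem.PointLocator | None = None) -> float:
    """Maximum temperature (degC) on the 10 mm offset shell."""
    pts = safety_shell_points(electrode, phantom, constraint)
    loc = locator or fem.PointLocator(mesh.nodes, mesh.tets)
    return float(loc.interpolate(pts, T_nodal).max())


def transverse_ablation_width(mesh: Mesh, D_elem: np.ndarray,
                              electrode: ElectrodeSpec,
                              threshold_D: float = dmg.D_THRESHOLD,
                              slab_half_width: float = 2e-3) -> float:
    """Extent of the coagulated region perpendicular to the electrode axis,
    measured in the slab around the active-tip midpoint (m)."""
    cent = mesh.nodes[mesh.tets].mean(axis=1)
    x_mid = electrode.tip_end_point[0] + electrode.tip_length / 2
    cy, cz = electrode.tip_end_point[1], electrode.tip_end_point[2]
    tissue = ~np.isin(mesh.region,
                      [REGIONS.index("tip"), REGIONS.index("shaft")])
    sel = (tissue & (np.asarray(D_elem) >= threshold_D)
           & (np.abs(cent[:, 0] - x_mid) <= slab_half_width))
    if not np.any(sel):
        return 0.0
    r = np.hypot(cent[sel, 1] - cy, cent[sel, 2] - cz)
    return float(2.0 * r.max())


def run_treatment(mesh: Mesh, params: TreatmentParams,
                  scenario: str = "low", dt: float = 1.0, *,
                  phantom: NeckPhantom | None = None,
                  electrode: ElectrodeSpec | None = None,
                  bc: BoundaryConditions | None = None,
                  constraint: SafetyConstraint = SafetyConstraint(),
                  sigma_retol: float = 0.01,
                  thermal_retol: float = 0.01,
                  perfusion_decay: bool = False,
                  T_cutoff: float | None = None,
                  threshold_D: float = dmg.D_THRESHOLD,
                  constants: materials.PhysicalConstants = materials.CONSTANTS,
                  ) -> SimulationResult:
    """Simulate one constant-power treatment on a labeled phantom mesh.

    ``phantom``/``electrode`` are needed for the safety shell and ablation
    width; when omitted those outputs are skipped (NaN / 0).  Deterministic
    for fixed inputs.

    ``perfusion_decay`` wires the damage-decayed perfusion ``omega_b0
    exp(-D)`` into the Pennes sink.  Off by default: with the steep
    Arrhenius kinetics of thyroid tissue the shutdown front makes the
    treatment run away thermally, whereas the baseline-perfusion sink
    reproduces the expected clinical-scale behavior (confined damage zone,
    sub-100 degC shell temperatures); see docs/methods.md.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(params.duration / dt))
    if abs(n_steps * dt - params.duration) > 1e-9 * max(params.duration, 1.0):
        raise ValueError("duration must be an integer number of steps")

    props = ElementProperties(mesh, scenario, constants)
    system = ThermalSystem(mesh, bc or BoundaryConditions())
    state = system.initial_state(constants.T_body)
    D = np.zeros(len(mesh.tets))

    shell_W = None
    if phantom is not None and electrode is not None:
        pts = safety_shell_points(electrode, phantom, constraint)
        loc = fem.PointLocator(mesh.nodes, mesh.tets)
        shell_W = loc.interpolation_weights(pts)

    times = np.zeros(n_steps)
    z_trace = np.full(n_steps, np.nan)
    vrr_trace = np.zeros(n_steps)
    shell_trace = np.full(n_steps, np.nan)
    peak_T = float(state.T.max())

    unit_sol = None
    sigma_at_solve = None
    for i in range(n_steps):
        T_elem = fem.element_means(mesh.tets, state.T)
        sig = props.sigma(T_elem)
        q = np.where(props.biological, props.Q_met, 0.0)
        if params.power > 0:
            if unit_sol is None or _sigma_drift(sig, sigma_at_solve,
                                                props) > sigma_retol:
                unit_sol = electric.solve_mesh_unit_potential(mesh, sig)
                sigma_at_solve = sig
            scaled = electric.scale_to_power(unit_sol, params.power)
            q = q + scaled.Qp
            z_trace[i] = scaled.Z
        state = system.step(
            state, dt,
            k_elem=props.k(T_elem),
            rhoc_elem=props.rhoc,
            perf_sink_elem=props.perfusion_sink(
                D if perfusion_decay else np.zeros_like(D)),
            q_elem=q,
            T_blood=constants.T_blood,
            coeff_retol=thermal_retol)
        # damage on the end-of-step element temperature (rectangle rule)
        T_elem_new = fem.element_means(mesh.tets, state.T)
        D = D + props.damage_rate(T_elem_new, T_cutoff) * dt
        times[i] = state.t
        vrr_trace[i] = dmg.vrr(mesh, D, threshold_D)
        peak_T = max(peak_T, float(state.T.max()))
        if shell_W is not None:
            shell_trace[i] = float((shell_W @ state.T).max())

    width = 0.0
    if electrode is not None:
        width = transverse_ablation_width(mesh, D, electrode, threshold_D)
    return SimulationResult(
        times=times, impedance=z_trace,
        energy=params.power * times, vrr=vrr_trace,
        shell_max_T=shell_trace, peak_T=peak_T,
        T_final=state.T, D_final=D, transverse_width=width,
        params=params, scenario=scenario)


def _sigma_drift(sig: np.ndarray, sig_ref: np.ndarray,
                 props: ElementProperties) -> float:
    b = props.biological
    return float(np.max(np.abs(sig[b] - sig_ref[b]) / sig_ref[b]))


def sweep(tips, scenarios, *, resolution: str = "coarse", dt: float = 2.0,
          phantom: NeckPhantom | None = None, optimizer_kwargs=None,
          run_kwargs=None):
    """Optimize (power, duration) for every tip length x perfusion scenario.

    Returns a pandas DataFrame with one row per cell; failed cells carry the
    error message and NaNs.  Each cell runs mesh build + optimization + one
    forward run at the optimum.
    """
    import pandas as pd

    from . import optimizer as opt
    from .geometry import build_phantom, mesh_phantom

    phantom = phantom or build_phantom()
    rows = []
    for tip in tips:
        for scen in scenarios:
            row = {"tip_mm": tip * 1e3, "scenario": scen}
            try:
                el = ElectrodeSpec.centered_in(phantom, tip)
                mesh = mesh_phantom(phantom, el, resolution)
                forward = opt.vrr_lookup_forward(
                    mesh, phantom, el, scen, dt=dt, **(run_kwargs or {}))
                problem = opt.OptimizationProblem()
                res = opt.optimize(problem, forward,
                                   **(optimizer_kwargs or {}))
                final = run_treatment(
                    mesh,
                    TreatmentParams(res.power_opt,
                                    _round_duration(res.duration_opt, dt)),
                    scen, dt=dt, phantom=phantom, electrode=el,
                    **(run_kwargs or {}))
                row.update(
                    power_W=res.power_opt,
                    duration_min=res.duration_opt / 60.0,
                    VRR_pct=final.vrr[-1],
                    peakT_C=final.peak_T,
                    shell_maxT_C=float(np.nanmax(final.shell_max_T)),
                    width_mm=final.transverse_width * 1e3,
                    impedance_drop_pct=final.impedance_drop_pct,
                    n_evaluations=res.n_evaluations,
                    converged=res.converged, error="")
            except Exception as exc:  # noqa: BLE001 - sweep continues
                row.update(error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def _round_duration(t: float, dt: float) -> float:
    return max(dt, round(t / dt) * dt)
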