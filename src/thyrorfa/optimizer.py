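"""Bound-constrained derivative-free planning of (power, duration).

Minimizes the squared VRR miss ``f = (VRR - VRR_target)^2`` over the box
45-60 W x (0, 1200] s with the thermal-safety rule (max temperature beyond
10 mm from the needle below 100 degC) as a smooth quadratic exterior
penalty.  The solver is COBYQA (scipy), a quadratic-model trust-region
derivative-free method honoring box bounds — the same algorithm family as
BOBYQA.

Decision variables are scaled to [0,1]^2 (power span 15 W, duration span
1200 s) for trust-region conditioning, and a micro-regularization
``1e-6 * t_scaled`` breaks ties on VRR(t) plateaus toward the shortest
treatment.

The expensive forward model is wrapped by :func:`vrr_lookup_forward`: for a
constant-power treatment the whole VRR(t) trajectory comes from a single
full-horizon run, so duration is read off the stored trace; power is
discretized to a 1 W grid (the setpoint resolution of clinical RF
generators) with linear interpolation between the two bracketing grid
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import ElectrodeSpec, Mesh, NeckPhantom
from .treatment import (MAX_DURATION, POWER_BOUNDS, SafetyConstraint,
                        TreatmentParams, run_treatment)

__all__ = ["OptimizationProblem", "OptimizationResult", "objective",
           "optimize", "vrr_lookup_forward", "LookupForward"]


@dataclass(frozen=True)
class OptimizationProblem:
    vrr_target: float = 65.0                     # %
    power_bounds: tuple = POWER_BOUNDS           # W
    duration_bounds: tuple = (1.0, MAX_DURATION) # s
    safety: SafetyConstraint = field(default_factory=SafetyConstraint)
    penalty_weight: float = 10.0                 # (degC)^-2 (%)^2

    def __post_init__(self):
        if not (0 < self.vrr_target <= 100):
            raise ValueError("VRR target must be in (0, 100]")
        for lo, hi in (self.power_bounds, self.duration_bounds):
            if not lo < hi:
                raise ValueError("bounds must be non-empty")


@dataclass
class OptimizationResult:
    power_opt: float         # W
    duration_opt: float      # s
    vrr_achieved: float      # %
    max_T_outside: float     # degC on the safety shell
    objective: float         # (%)^2
    n_evaluations: int
    converged: bool
    constraint_satisfied: bool


def objective(params: TreatmentParams, forward, problem: OptimizationProblem,
              ) -> float:
    """Penalized squared VRR miss at one candidate setting.

    ``forward(power, duration)`` returns ``(VRR %, max shell T degC)``; a
    forward failure yields a large finite value so the optimizer survives.
    """
    try:
        vrr, max_T = forward(params.power, params.duration)
    except Exception:  # noqa: BLE001 - keep the optimizer alive
        return 1e8
    miss = (vrr - problem.vrr_target) ** 2
    over = max(0.0, max_T - problem.safety.T_limit)
    return float(miss + problem.penalty_weight * over ** 2)


def optimize(problem: OptimizationProblem, forward,
             start: TreatmentParams | None = None, seed: int | None = None,
             maxfev: int = 60, initial_tr_radius: float = 0.25,
             final_tr_radius: float = 1e-3) -> OptimizationResult:
    """Run the trust-region DFO search and return the best feasible point.

    Deterministic; ``seed`` is accepted for interface uniformity (the
    quadratic-model method draws no random numbers).
    """
    (p_lo, p_hi) = problem.power_bounds
    (t_lo, t_hi) = problem.duration_bounds
    span_p, span_t = p_hi - p_lo, t_hi - t_lo

    def unscale(u):
        return p_lo + u[0] * span_p, t_lo + u[1] * span_t

    def fun(u):
        p, t = unscale(u)
        f = objective(TreatmentParams(p, t), forward, problem)
        return f + 1e-6 * u[1]

    if start is not None:
        if not (p_lo <= start.power <= p_hi
                and t_lo <= start.duration <= t_hi):
            raise ValueError("start point outside bounds")
        x0 = [(start.power - p_lo) / span_p, (start.duration - t_lo) / span_t]
    else:
        x0 = [0.5, 0.5]

    res = minimize(fun, x0, method="cobyqa", bounds=[(0, 1), (0, 1)],
                   options={"maxfev": maxfev,
                            "initial_tr_radius": initial_tr_radius,
                            "final_tr_radius": final_tr_radius})
    p_opt, t_opt = unscale(res.x)
    try:
        vrr, max_T = forward(p_opt, t_opt)
    except Exception:  # noqa: BLE001
        vrr, max_T = float("nan"), float("inf")
    return OptimizationResult(
        power_opt=float(p_opt), duration_opt=float(t_opt),
        vrr_achieved=float(vrr), max_T_outside=float(max_T),
        objective=float((vrr - problem.vrr_target) ** 2),
        n_evaluations=int(res.nfev), converged=bool(res.success),
        constraint_satisfied=bool(max_T < problem.safety.T_limit))


class LookupForward:
    """Trajectory-backed forward model ``(power, duration) -> (VRR, maxT)``.

    One full-horizon constant-power run is cached per power-grid point;
    VRR(t) and the running shell-temperature maximum are interpolated in t,
    and linearly blended between the two grid powers bracketing the request.
    """

    def __init__(self, mesh: Mesh, phantom: NeckPhantom,
                 electrode: ElectrodeSpec, scenario: str = "low",
                 dt: float = 2.0, horizon: float = MAX_DURATION,
                 power_grid: float = 1.0, **run_kwargs):
        self.mesh = mesh
        self.phantom = phantom
        self.electrode = electrode
        self.scenario = scenario
        self.dt = dt
        self.horizon = horizon
        self.power_grid = power_grid
        self.run_kwargs = run_kwargs
        self._cache: dict[float, tuple] = {}
        self.n_runs = 0

    def _traj(self, power: float):
        key = round(power, 9)
        if key not in self._cache:
            res = run_treatment(
                self.mesh, TreatmentParams(power, self.horizon),
                self.scenario, dt=self.dt, phantom=self.phantom,
                electrode=self.electrode, **self.run_kwargs)
            t = np.concatenate([[0.0], res.times])
            vrr = np.concatenate([[0.0], res.vrr])
            run_max = np.concatenate([[37.0],
                                      np.fmax.accumulate(res.shell_max_T)])
            self._cache[key] = (t, vrr, run_max)
            self.n_runs += 1
        return self._cache[key]

    def __call__(self, power: float, duration: float):
        if not (0 <= duration <= self.horizon + 1e-9):
            raise ValueError(f"duration {duration} s beyond the "
                             f"{self.horizon} s horizon")
        g = self.power_grid
        p0 = np.floor(power / g) * g
        p1 = p0 + g
        if abs(power - p0) < 1e-12 or g == 0:
            pairs, wts = [p0], [1.0]
        else:
            w = (power - p0) / g
            pairs, wts = [p0, p1], [1.0 - w, w]
        vrr = maxT = 0.0
        for p, w in zip(pairs, wts):
            t, v, m = self._traj(p)
            vrr += w * float(np.interp(duration, t, v))
            maxT += w * float(np.interp(duration, t, m))
        return vrr, maxT


def vrr_lookup_forward(mesh: Mesh, phantom: NeckPhantom,
                       electrode: ElectrodeSpec, scenario: str = "low",
                       dt: float = 2.0, horizon: float = MAX_DURATION,
                       **run_kwargs) -> LookupForward:
    """Build the cached trajectory-backed forward model (see
    :class:`LookupForward`)."""
    return LookupForward(mesh, phantom, electrode, scenario, dt=dt,
                         horizon=horizon, **run_kwargs)
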