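"""Tissue, nodule, electrode and blood physical properties with their
temperature- and damage-dependent constitutive laws.

The registry holds, per anatomical region, the reference physical constants
used by the coupled electro-thermal model: thermal conductivity ``k_ref``
(W/m/K), density ``rho`` (kg/m^3), specific heat ``c_p`` (J/kg/K),
electrical conductivity ``sigma_ref`` (S/m), relative permittivity
``eps_r`` (stored for completeness; the quasi-static conduction solve does
not use it), baseline blood perfusion ``omega_b0`` (1/s), metabolic heat
``Q_met`` (W/m^3), and the Arrhenius injury-kinetics pair ``A`` (1/s) and
``dE`` (J/mol).

Three closed-form constitutive laws couple the fields:

* electrical conductivity rises 1.5 %/degC above body temperature,
  ``sigma(T) = sigma_ref * (1 + p_i (T - T_ref))``;
* thermal conductivity rises linearly,
  ``k(T) = k_ref + r_i (T - T_ref)``;
* blood perfusion shuts down with accumulated thermal damage D,
  ``omega_b(D) = omega_b0 * exp(-D)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TissueProperties",
    "PhysicalConstants",
    "CONSTANTS",
    "lookup",
    "registry",
    "sigma_of_T",
    "k_of_T",
    "perfusion_of_damage",
    "registry_table",
    "load_registry_table",
    "SIGMA_FLOOR",
]

#: lower clamp on extrapolated electrical conductivity (S/m); prevents a
#: nonphysical negative sigma if the affine law is evaluated far below 37 degC
SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class TissueProperties:
    """Physical constants of one region.

    Electrode parts reuse the same record with perfusion, metabolic and
    Arrhenius fields set to zero (no biological response).
    """

    name: str
    k_ref: float          # thermal conductivity at 37 degC, W/m/K
    rho: float            # density, kg/m^3
    c_p: float            # specific heat, J/kg/K
    sigma_ref: float      # electrical conductivity at 37 degC, S/m
    eps_r: float          # relative permittivity (unused by the conduction solve)
    omega_b0: float       # baseline blood perfusion, 1/s
    Q_met: float          # metabolic heat, W/m^3
    A: float              # Arrhenius frequency factor, 1/s
    dE: float             # Arrhenius activation energy, J/mol
    biological: bool = True

    def __post_init__(self) -> None:
        for f in ("k_ref", "rho", "c_p"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{self.name}: {f} must be positive")
        if self.sigma_ref <= 0:
            raise ValueError(f"{self.name}: sigma_ref must be positive")
        if self.omega_b0 < 0 or self.Q_met < 0:
            raise ValueError(f"{self.name}: omega_b0 and Q_met must be >= 0")
        if self.biological and (self.A <= 0 or self.dE <= 0):
            raise ValueError(f"{self.name}: Arrhenius constants must be positive")


@dataclass(frozen=True)
class PhysicalConstants:
    """Model-wide constants (overridable through the run configuration)."""

    R_gas: float = 8.314        # universal gas constant, J/mol/K
    T_body: float = 37.0        # baseline tissue temperature, degC
    T_blood: float = 37.0       # arterial blood temperature, degC
    rho_blood: float = 1050.0   # blood density, kg/m^3
    c_blood: float = 3617.0     # blood specific heat, J/kg/K
    p_i: float = 0.015          # fractional sigma increase per degC
    r_i: float = 0.0013         # thermal-conductivity slope, W/m/K per degC
    T_ref: float = 37.0         # reference temperature of the affine laws, degC


CONSTANTS = PhysicalConstants()

# Reference property table.  Nodule perfusion has two literature scenarios:
# a weakly perfused nodule (0.0096 1/s) and a strongly perfused one (0.021 1/s).
_BASE: dict[str, TissueProperties] = {
    "skin": TissueProperties("skin", 0.37, 1109.0, 3391.0, 4.09e-3, 1.06e3,
                             0.00196, 1829.85, 4.575e72, 4.71e5),
    "fat": TissueProperties("fat", 0.21, 911.0, 2348.0, 4.37e-2, 57.3,
                            5.01e-4, 464.61, 4.43e16, 1.3e5),
    "muscle": TissueProperties("muscle", 0.49, 1090.0, 3421.0, 4.43e-1, 3.77e3,
                               7.08e-4, 1046.0, 2.94e39, 2.596e5),
    "thyroid": TissueProperties("thyroid", 0.52, 1050.0, 3609.0, 5.64e-1, 2.18e3,
                                0.098, 4200.0, 7.39e39, 2.577e5),
    "nodule": TissueProperties("nodule", 0.89, 1050.0, 3770.0, 4.81e-1, 2.18e3,
                               0.0096, 42000.0, 7.39e39, 2.577e5),
    # electrode: copper active tip, insulated polymer shaft
    "tip": TissueProperties("tip", 400.0, 8960.0, 385.0, 5.99e7, 1.0,
                            0.0, 0.0, 0.0, 0.0, biological=False),
    "shaft": TissueProperties("shaft", 0.026, 1150.0, 1700.0, 1e-5, 1.0,
                              0.0, 0.0, 0.0, 0.0, biological=False),
}

_NODULE_PERFUSION = {"low": 0.0096, "high": 0.021}


def lookup(region: str, scenario: str = "low") -> TissueProperties:
    """Return the immutable property record for ``region``.

    ``scenario`` selects the nodule perfusion level (``"low"`` -> 0.0096 1/s,
    ``"high"`` -> 0.021 1/s); it does not affect other regions.
    """
    if region not in _BASE:
        raise KeyError(f"unknown region {region!r}; known: {sorted(_BASE)}")
    if scenario not in _NODULE_PERFUSION:
        raise KeyError(f"unknown perfusion scenario {scenario!r}; use 'low' or 'high'")
    props = _BASE[region]
    if region == "nodule":
        props = replace(props, omega_b0=_NODULE_PERFUSION[scenario])
    return props


def registry(scenario: str = "low") -> dict[str, TissueProperties]:
    """Full region -> properties map for one perfusion scenario."""
    return {name: lookup(name, scenario) for name in _BASE}


def sigma_of_T(props: TissueProperties, T, constants: PhysicalConstants = CONSTANTS):
    """Electrical conductivity at temperature ``T`` (degC).

    Affine in T for biological regions; electrode parts keep their constant
    conductivity.  The result is clamped below at ``SIGMA_FLOOR``.
    """
    T = np.asarray(T, dtype=float)
    if not props.biological:
        return np.broadcast_to(np.float64(props.sigma_ref), T.shape).copy() \
            if T.shape else np.float64(props.sigma_ref)
    sig = props.sigma_ref * (1.0 + constants.p_i * (T - constants.T_ref))
    return np.maximum(sig, SIGMA_FLOOR)


def k_of_T(props: TissueProperties, T, constants: PhysicalConstants = CONSTANTS):
    """Thermal conductivity at temperature ``T`` (degC)."""
    T = np.asarray(T, dtype=float)
    if not props.biological:
        return np.broadcast_to(np.float64(props.k_ref), T.shape).copy() \
            if T.shape else np.float64(props.k_ref)
    return props.k_ref + constants.r_i * (T - constants.T_ref)


def perfusion_of_damage(props: TissueProperties, D):
    """Blood perfusion (1/s) after accumulated Arrhenius damage ``D``."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("damage index D must be non-negative")
    return props.omega_b0 * np.exp(-D)


_TABLE_FIELDS = ("k_ref", "rho", "c_p", "sigma_ref", "eps_r", "omega_b0",
                 "Q_met", "A", "dE", "biological")


def registry_table(scenario: str = "low"):
    """The property registry as a pandas DataFrame (one row per region),
    the human-editable serialization mirroring the reference tables."""
    import pandas as pd

    reg = registry(scenario)
    return pd.DataFrame(
        [{"region": name, **{f: getattr(p, f) for f in _TABLE_FIELDS}}
         for name, p in reg.items()]).set_index("region")


def load_registry_table(path_or_frame, validate: bool = True
                        ) -> dict[str, TissueProperties]:
    """Load a property table (CSV or DataFrame) into a registry.

    ``validate=True`` cross-checks that every region known to the built-in
    defaults is present with the full column set before accepting
    overrides.
    """
    import pandas as pd

    df = (path_or_frame if isinstance(path_or_frame, pd.DataFrame)
          else pd.read_csv(path_or_frame, index_col="region"))
    if validate:
        missing_rows = set(_BASE) - set(df.index)
        missing_cols = set(_TABLE_FIELDS) - set(df.columns)
        if missing_rows or missing_cols:
            raise ValueError(
                f"property table incomplete: missing regions "
                f"{sorted(missing_rows)}, columns {sorted(missing_cols)}")
    out = {}
    for name, row in df.iterrows():
        out[name] = TissueProperties(
            name=name, **{f: (bool(row[f]) if f == "biological"
                              else float(row[f]))
                          for f in _TABLE_FIELDS})
    return out
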