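"""Calcite saturation index, critical calcium and logistic risk mapping.

The saturation index for otoconial calcite is

    Omega = gCa*[Ca2+] * gCO3*[CO3^2-] / Ksp,

with [CO3^2-] = alpha2(pH)*C_T.  Omega > 1 denotes supersaturation
(stable otoconia), Omega < 1 undersaturation (dissolution-prone).
Setting Omega = 1 and solving for calcium gives the critical
concentration

    C_crit(pH) = Ksp / (gCa*gCO3 * alpha2(pH) * C_T),

the free-calcium level that exactly balances precipitation and
dissolution at a given pH.  The relative-risk score is the logistic
transform of the calcium deficit dC = C_crit - [Ca2+]:

    R = 1 / (1 + exp(-dC / sigma_C)),

so R = 0.5 at the Omega = 1 boundary and R -> 1 as calcium falls ever
further below C_crit.  sigma_C (default 80 uM) expresses
inter-individual tolerance to departures from the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .chemistry import (
    DEFAULT_THERMO,
    ActivityCoefficients,
    ThermoParams,
    speciation_fractions,
)

__all__ = [
    "EndolymphState",
    "RiskParams",
    "StabilityResult",
    "ScenarioShift",
    "SCENARIO_PRESETS",
    "DEFAULT_RISK",
    "saturation_index",
    "critical_calcium",
    "calibrate_ct",
    "risk_score",
    "classify_omega",
    "evaluate_state",
    "relative_ccrit_index",
    "apply_scenario",
]


@dataclass(frozen=True)
class EndolymphState:
    """One endolymph condition: pH, free ionized calcium and C_T (mol/L)."""

    ph: float
    ca: float  # mol/L
    ct: float  # mol/L

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"ph {self.ph} outside [0, 14]")
        if self.ca <= 0:
            raise ValueError("ca must be positive")
        if self.ct <= 0:
            raise ValueError("ct must be positive")

    @classmethod
    def from_units(
        cls, ph: float, ca_umol_per_l: float, ct_mmol_per_l: float
    ) -> "EndolymphState":
        """Build a state from the interface units (uM calcium, mM C_T)."""
        return cls(ph=ph, ca=ca_umol_per_l * 1e-6, ct=ct_mmol_per_l * 1e-3)


@dataclass(frozen=True)
class RiskParams:
    """Logistic risk-mapping parameters and the calibration anchor.

    sigma_c : logistic dispersion in umol/L (default 80).
    anchor_ph, anchor_ccrit_umol : the physiological anchor used to
        calibrate C_T so that C_crit(anchor_ph) = anchor_ccrit
        (defaults 7.65 and 265 uM).
    """

    sigma_c: float = 80.0  # umol/L
    anchor_ph: float = 7.65
    anchor_ccrit_umol: float = 265.0

    def __post_init__(self) -> None:
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be positive")
        if self.anchor_ccrit_umol <= 0:
            raise ValueError("anchor_ccrit_umol must be positive")


DEFAULT_RISK = RiskParams()


@dataclass(frozen=True)
class StabilityResult:
    """Derived stability quantities for one endolymph state."""

    omega: float
    c_crit: float  # mol/L
    delta_c_umol: float  # C_crit - Ca, umol/L
    r: float
    i_ccrit_raw: float  # 1/(alpha2*C_T), L/mol
    i_ccrit_norm: float  # raw / raw(anchor_ph)
    label: str  # 'stable', 'dissolution-prone' or 'boundary'

    @property
    def c_crit_umol(self) -> float:
        return self.c_crit * 1e6


@dataclass(frozen=True)
class ScenarioShift:
    """A directional physiological perturbation: additive pH shift and
    multiplicative calcium factor, with the expected sign of the Omega
    change."""

    name: str
    d_ph: float
    ca_factor: float
    expected_omega_sign: int

    def __post_init__(self) -> None:
        if self.ca_factor <= 0:
            raise ValueError("ca_factor must be positive")
        if self.expected_omega_sign not in (-1, 0, 1):
            raise ValueError("expected_omega_sign must be -1, 0 or +1")


# Directional presets.  Magnitudes are illustrative defaults (the
# physiology fixes only the direction): pH +/-0.10, calcium x/1.15.
_UP, _DOWN = 1.15, 1.0 / 1.15
SCENARIO_PRESETS: dict[str, ScenarioShift] = {
    s.name: s
    for s in (
        ScenarioShift("hyperventilation", +0.10, 1.0, +1),
        ScenarioShift("prolonged_vomiting", +0.10, 1.0, +1),
        ScenarioShift("thiazide", +0.10, _UP, +1),
        ScenarioShift("hyperparathyroidism_vitD_excess", 0.0, _UP, +1),
        ScenarioShift("metabolic_acidosis", -0.10, 1.0, -1),
        ScenarioShift("hypoventilation", -0.10, 1.0, -1),
        ScenarioShift("acetazolamide", -0.10, 1.0, -1),
        ScenarioShift("loop_diuretic", 0.0, _DOWN, -1),
        ScenarioShift("hypocalcemia", 0.0, _DOWN, -1),
    )
}


def saturation_index(
    state: EndolymphState,
    params: ThermoParams = DEFAULT_THERMO,
    gammas: ActivityCoefficients | None = None,
) -> float:
    """Calcite saturation index Omega for one endolymph state."""
    gammas = gammas or ActivityCoefficients.unity()
    alpha2 = speciation_fractions(state.ph, params).alpha2
    return gammas.product * state.ca * alpha2 * state.ct / params.ksp


def critical_calcium(
    ph: float | np.ndarray,
    ct: float,
    params: ThermoParams = DEFAULT_THERMO,
    gammas: ActivityCoefficients | None = None,
) -> float | np.ndarray:
    """Free calcium at the Omega = 1 boundary (mol/L); vectorized in pH."""
    if ct <= 0:
        raise ValueError("ct must be positive")
    gammas = gammas or ActivityCoefficients.unity()
    alpha2 = speciation_fractions(ph, params).alpha2
    return params.ksp / (gammas.product * alpha2 * ct)


def calibrate_ct(
    params: ThermoParams = DEFAULT_THERMO,
    gammas: ActivityCoefficients | None = None,
    anchor_ph: float = DEFAULT_RISK.anchor_ph,
    anchor_ccrit: float = DEFAULT_RISK.anchor_ccrit_umol * 1e-6,
) -> float:
    """Total inorganic carbon (mol/L) such that C_crit(anchor_ph) equals
    the anchor calcium concentration (mol/L).

    With the defaults this is the model's physiological calibration,
    C_crit(7.65) = 265 uM, giving C_T of roughly 7.77 mM.
    """
    if anchor_ccrit <= 0:
        raise ValueError("anchor_ccrit must be positive")
    gammas = gammas or ActivityCoefficients.unity()
    alpha2 = speciation_fractions(anchor_ph, params).alpha2
    return params.ksp / (gammas.product * alpha2 * anchor_ccrit)


def risk_score(
    delta_c_umol: float | np.ndarray, sigma_c_umol: float = DEFAULT_RISK.sigma_c
) -> float | np.ndarray:
    """Logistic relative-risk score R = 1/(1 + exp(-dC/sigma_C)).

    ``delta_c_umol`` and ``sigma_c_umol`` share units (umol/L).  R = 0.5
    at dC = 0 (the Omega = 1 boundary), R -> 1 for deep calcium deficit.
    """
    if sigma_c_umol <= 0:
        raise ValueError("sigma_c must be positive")
    out = expit(np.asarray(delta_c_umol, dtype=float) / sigma_c_umol)
    return out if np.ndim(delta_c_umol) else float(out)


def classify_omega(omega: float) -> str:
    """Three-way stability label; Omega exactly 1 is its own class."""
    if omega > 1.0:
        return "stable"
    if omega < 1.0:
        return "dissolution-prone"
    return "boundary"


def evaluate_state(
    state: EndolymphState,
    thermo: ThermoParams = DEFAULT_THERMO,
    risk: RiskParams = DEFAULT_RISK,
    gammas: ActivityCoefficients | None = None,
) -> StabilityResult:
    """Deterministic mapping (pH, Ca, C_T) -> (Omega, C_crit, dC, R).

    All quantities use the same activity-coefficient mode so that the
    boundary identities Omega = Ca/C_crit and R(dC=0) = 0.5 hold exactly.
    """
    gammas = gammas or ActivityCoefficients.unity()
    omega = saturation_index(state, thermo, gammas)
    c_crit = critical_calcium(state.ph, state.ct, thermo, gammas)
    delta_c_umol = (c_crit - state.ca) * 1e6
    raw, norm = relative_ccrit_index(state.ph, state.ct, thermo, risk)
    return StabilityResult(
        omega=omega,
        c_crit=c_crit,
        delta_c_umol=delta_c_umol,
        r=risk_score(delta_c_umol, risk.sigma_c),
        i_ccrit_raw=raw,
        i_ccrit_norm=norm,
        label=classify_omega(omega),
    )


def relative_ccrit_index(
    ph: float,
    ct: float,
    thermo: ThermoParams = DEFAULT_THERMO,
    risk: RiskParams = DEFAULT_RISK,
) -> tuple[float, float]:
    """Relative critical-calcium index, proportional to 1/(alpha2*C_T).

    Returns the raw reciprocal (L/mol) and the variant normalized to 1
    at the anchor pH; the normalized index exceeds 1 under acidosis and
    falls below 1 under alkalosis, tracking relative C_crit shifts
    without requiring Ksp.
    """
    if ct <= 0:
        raise ValueError("ct must be positive")
    raw = 1.0 / (speciation_fractions(ph, thermo).alpha2 * ct)
    raw_anchor = 1.0 / (speciation_fractions(risk.anchor_ph, thermo).alpha2 * ct)
    return raw, raw / raw_anchor


def apply_scenario(
    state: EndolymphState,
    shift: ScenarioShift | str,
    thermo: ThermoParams = DEFAULT_THERMO,
    risk: RiskParams = DEFAULT_RISK,
    gammas: ActivityCoefficients | None = None,
) -> tuple[StabilityResult, StabilityResult, int]:
    """Evaluate a state before and after a directional scenario shift.

    Returns (before, after, sign of the Omega change).  ``shift`` may be
    a preset name from :data:`SCENARIO_PRESETS` or an explicit
    :class:`ScenarioShift`.
    """
    if isinstance(shift, str):
        try:
            shift = SCENARIO_PRESETS[shift]
        except KeyError:
            known = ", ".join(sorted(SCENARIO_PRESETS))
            raise KeyError(f"unknown scenario {shift!r}; presets: {known}") from None
    new_ph = state.ph + shift.d_ph
    shifted = EndolymphState(ph=new_ph, ca=state.ca * shift.ca_factor, ct=state.ct)
    before = evaluate_state(state, thermo, risk, gammas)
    after = evaluate_state(shifted, thermo, risk, gammas)
    d_omega = after.omega - before.omega
    sign = 0 if d_omega == 0 else int(math.copysign(1, d_omega))
    return before, after, sign
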