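"""One-at-a-time robustness sweeps of the Omega = 1 boundary.

Each sweep perturbs a single assumption around the calibrated baseline
— total inorganic carbon, the solubility product, ionic strength
(through Davies activity coefficients), temperature (through anchored
literature relations for pK1, pK2, Ksp), or the logistic dispersion —
and measures how far the critical-calcium boundary C_crit(pH) moves.

Sweeps deliberately do NOT re-run the C_T calibration at each setting:
they quantify the departure of the perturbed boundary from the single
calibrated baseline.  Two of the sweeps have closed-form answers that
double as self-checks: C_crit is proportional to Ksp and to 1/C_T, so
those displacements are pH-independent; and sigma_c never enters the
boundary at all, so its sweep displacement is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chemistry import (
    DEFAULT_THERMO,
    ActivityCoefficients,
    ThermoParams,
    adjust_constants_for_temperature,
)
from .stability import DEFAULT_RISK, RiskParams, calibrate_ct, critical_calcium

__all__ = [
    "SweepSpec",
    "SweepResult",
    "SWEEP_PARAMETERS",
    "run_sweep",
    "boundary_displacement",
    "default_ph_grid",
]

SWEEP_PARAMETERS = ("ct", "ksp", "ionic_strength", "temperature", "sigma_c")


def default_ph_grid() -> np.ndarray:
    """101 evaluation points on pH 7.4-7.9, the simulated endolymph span."""
    return np.linspace(7.4, 7.9, 101)


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: which parameter, which settings, evaluated where.

    ``values`` semantics by parameter: multiplicative factors for ``ct``
    and ``ksp``; ionic strengths in mol/L for ``ionic_strength``
    (evaluated in Davies mode against the minimal-mode baseline); degC
    for ``temperature``; umol/L for ``sigma_c``.
    """

    parameter: str
    values: tuple[float, ...]
    ph_grid: np.ndarray = field(default_factory=default_ph_grid)
    thermo: ThermoParams = DEFAULT_THERMO
    risk: RiskParams = DEFAULT_RISK

    def __post_init__(self) -> None:
        if self.parameter not in SWEEP_PARAMETERS:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"one of {SWEEP_PARAMETERS}"
            )
        if len(self.values) == 0:
            raise ValueError("values must be non-empty")
        grid = np.asarray(self.ph_grid, dtype=float)
        if np.any(grid < 7.0) or np.any(grid > 8.2):
            raise ValueError("ph_grid must lie within [7.0, 8.2]")


@dataclass(frozen=True)
class SweepResult:
    """Boundary curves and displacement summaries for one sweep."""

    parameter: str
    ph_grid: np.ndarray
    baseline_curve: np.ndarray  # C_crit(pH) at the calibrated baseline, mol/L
    curves: pd.DataFrame  # long: parameter, setting, ph, c_crit_umol, rel_change_pct
    displacement: pd.DataFrame  # per setting: mean_pct, max_pct
    topology_flag: bool  # True iff every curve stays strictly decreasing in pH


def boundary_displacement(
    curve_a: np.ndarray, curve_b: np.ndarray, ph_grid: np.ndarray
) -> tuple[float, float]:
    """Mean and max relative boundary change |b - a|/a over a pH grid, %."""
    a = np.asarray(curve_a, float)
    b = np.asarray(curve_b, float)
    grid = np.asarray(ph_grid, float)
    if a.shape != grid.shape or b.shape != grid.shape:
        raise ValueError("curves and ph_grid must share one shape")
    rel = np.abs(b - a) / a * 100.0
    return float(rel.mean()), float(rel.max())


def _curve_for_setting(
    spec: SweepSpec, setting: float, ct_base: float, grid: np.ndarray
) -> np.ndarray:
    thermo = spec.thermo
    unity = ActivityCoefficients.unity()
    if spec.parameter == "ct":
        return np.asarray(critical_calcium(grid, ct_base * setting, thermo, unity))
    if spec.parameter == "ksp":
        perturbed = replace(thermo, ksp=thermo.ksp * setting)
        return np.asarray(critical_calcium(grid, ct_base, perturbed, unity))
    if spec.parameter == "ionic_strength":
        perturbed = replace(thermo, ionic_strength_m=setting)
        gammas = ActivityCoefficients.from_davies(perturbed)
        return np.asarray(critical_calcium(grid, ct_base, perturbed, gammas))
    if spec.parameter == "temperature":
        perturbed = adjust_constants_for_temperature(setting, thermo)
        return np.asarray(critical_calcium(grid, ct_base, perturbed, unity))
    # sigma_c: the logistic dispersion never appears in the boundary
    return np.asarray(critical_calcium(grid, ct_base, thermo, unity))


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Recompute the Omega = 1 boundary for each setting of one parameter.

    The baseline is the minimal-mode boundary with C_T calibrated once at
    the risk anchor; settings perturb around it without recalibration.
    """
    grid = np.asarray(spec.ph_grid, dtype=float)
    ct_base = calibrate_ct(
        spec.thermo,
        ActivityCoefficients.unity(),
        spec.risk.anchor_ph,
        spec.risk.anchor_ccrit_umol * 1e-6,
    )
    baseline = np.asarray(
        critical_calcium(grid, ct_base, spec.thermo, ActivityCoefficients.unity())
    )
    records, disp_records = [], []
    topology = True
    for setting in spec.values:
        curve = _curve_for_setting(spec, setting, ct_base, grid)
        rel_pct = (curve - baseline) / baseline * 100.0
        mean_pct, max_pct = boundary_displacement(baseline, curve, grid)
        topology &= bool(np.all(np.diff(curve) < 0))
        disp_records.append(
            {
                "parameter": spec.parameter,
                "setting": setting,
                "mean_pct": mean_pct,
                "max_pct": max_pct,
            }
        )
        for ph, cc, rc in zip(grid, curve, rel_pct):
            records.append(
                {
                    "parameter": spec.parameter,
                    "setting": setting,
                    "ph": ph,
                    "c_crit_umol": cc * 1e6,
                    "rel_change_pct": rc,
                }
            )
    return SweepResult(
        parameter=spec.parameter,
        ph_grid=grid,
        baseline_curve=baseline,
        curves=pd.DataFrame.from_records(records),
        displacement=pd.DataFrame.from_records(disp_records),
        topology_flag=topology,
    )
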