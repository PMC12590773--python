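"""Blood-derived saturation-index proxy.

Direct sampling of human vestibular endolymph is impractical, so the
model is operationalized with clinically accessible surrogates: serum
ionized calcium plus blood-gas pH/HCO3-/pCO2.  Plugging those into the
same speciation + saturation machinery yields a *proxy* Omega and risk
score whose value is directional only — serum ionized calcium sits in
the mmol/L range, three orders of magnitude above endolymph free
calcium, so the proxy ranks states and tracks within-person trends but
never estimates absolute endolymph chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chemistry import (
    DEFAULT_THERMO,
    ActivityCoefficients,
    ThermoParams,
    ct_from_bicarbonate,
    ct_from_pco2,
)
from .stability import DEFAULT_RISK, EndolymphState, RiskParams, evaluate_state

__all__ = [
    "BloodGasPanel",
    "ProxyResult",
    "RELATIVE_ONLY_CAVEAT",
    "BAND_CUTS",
    "validate_panel",
    "proxy_from_panel",
]

RELATIVE_ONLY_CAVEAT = (
    "relative-risk inference only: blood-derived proxy, not an estimate "
    "of absolute endolymph chemistry"
)

# Risk-band cut points on the proxy R; non-clinical, configurable.
BAND_CUTS: tuple[float, float] = (0.40, 0.68)

_PH_LO, _PH_HI = 6.8, 7.8
_CT_DISAGREE_REL = 0.05


@dataclass(frozen=True)
class BloodGasPanel:
    """Clinical surrogate inputs for the Omega proxy.

    At least one of ``hco3_mmol`` / ``pco2_mmhg`` must be present;
    bicarbonate is preferred for the C_T inference when both are given.
    """

    ph: float
    ica_mmol: float  # serum ionized calcium, mmol/L
    hco3_mmol: float | None = None
    pco2_mmhg: float | None = None
    source: str = "arterial"  # 'arterial' or 'venous'
    temp_corrected: bool = True

    def __post_init__(self) -> None:
        if self.hco3_mmol is None and self.pco2_mmhg is None:
            raise ValueError("panel needs at least one of hco3_mmol / pco2_mmhg")
        if self.ica_mmol <= 0:
            raise ValueError("ica_mmol must be positive")
        if not _PH_LO <= self.ph <= _PH_HI:
            raise ValueError(
                f"panel ph {self.ph} outside accepted clinical range "
                f"[{_PH_LO}, {_PH_HI}]"
            )
        if self.source not in ("arterial", "venous"):
            raise ValueError("source must be 'arterial' or 'venous'")
        if self.hco3_mmol is not None and self.hco3_mmol <= 0:
            raise ValueError("hco3_mmol must be positive")
        if self.pco2_mmhg is not None and self.pco2_mmhg <= 0:
            raise ValueError("pco2_mmhg must be positive")


@dataclass(frozen=True)
class ProxyResult:
    """Blood-derived proxy output; the mandatory caveat is always present."""

    ct: float  # mol/L, inferred from the panel
    omega_proxy: float
    r_proxy: float
    band: str  # 'low', 'intermediate' or 'high'
    caveats: tuple[str, ...] = field(default_factory=tuple)


def validate_panel(
    panel: BloodGasPanel, thermo: ThermoParams = DEFAULT_THERMO
) -> list[str]:
    """Collect non-fatal data-quality caveats for a panel.

    Checks: venous source, missing temperature correction, >5% relative
    disagreement between the bicarbonate and pCO2 routes to C_T, and pH
    outside the normal 7.30-7.50 band (acid-base disturbance).  Never
    raises on a warning.
    """
    caveats: list[str] = []
    if panel.source == "venous":
        caveats.append("venous sample: interpret with caution (arterial preferred)")
    if not panel.temp_corrected:
        caveats.append("blood gas not temperature-corrected to 37 degC")
    if panel.hco3_mmol is not None and panel.pco2_mmhg is not None:
        ct_hco3 = ct_from_bicarbonate(panel.hco3_mmol * 1e-3, panel.ph, thermo)
        ct_pco2 = ct_from_pco2(panel.pco2_mmhg, panel.ph, thermo)
        if abs(ct_pco2 - ct_hco3) / ct_hco3 > _CT_DISAGREE_REL:
            caveats.append(
                f"HCO3- and pCO2 routes disagree on C_T by >5% "
                f"({ct_hco3 * 1e3:.2f} vs {ct_pco2 * 1e3:.2f} mmol/L)"
            )
    if not 7.30 <= panel.ph <= 7.50:
        caveats.append(f"pH {panel.ph} outside 7.30-7.50: acid-base disturbance")
    return caveats


def _band(r: float) -> str:
    lo, hi = BAND_CUTS
    if r < lo:
        return "low"
    if r > hi:
        return "high"
    return "intermediate"


def proxy_from_panel(
    panel: BloodGasPanel,
    thermo: ThermoParams = DEFAULT_THERMO,
    risk: RiskParams = DEFAULT_RISK,
    gammas: ActivityCoefficients | None = None,
) -> ProxyResult:
    """Compute the blood-derived Omega proxy and relative-risk band.

    C_T is inferred from bicarbonate (preferred) or pCO2, then the
    panel's pH and ionized calcium run through the standard
    :func:`~otosat.stability.evaluate_state` pipeline — there is no
    separate chemistry path for clinical inputs.
    """
    if panel.hco3_mmol is not None:
        ct = ct_from_bicarbonate(panel.hco3_mmol * 1e-3, panel.ph, thermo)
    else:
        ct = ct_from_pco2(panel.pco2_mmhg, panel.ph, thermo)
    state = EndolymphState(ph=panel.ph, ca=panel.ica_mmol * 1e-3, ct=ct)
    result = evaluate_state(state, thermo, risk, gammas)
    caveats = (RELATIVE_ONLY_CAVEAT, *validate_panel(panel, thermo))
    return ProxyResult(
        ct=ct,
        omega_proxy=result.omega,
        r_proxy=result.r,
        band=_band(result.r),
        caveats=caveats,
    )
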