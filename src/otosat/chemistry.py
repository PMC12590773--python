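"""Inorganic-carbon speciation and physicochemical constants.

The carbonate system in endolymph (or plasma) is described by the two
carbonic-acid dissociation constants ``K1 = 10**-pK1`` and
``K2 = 10**-pK2``.  At a given pH the total dissolved inorganic carbon
C_T partitions into dissolved CO2, bicarbonate and carbonate according
to the alpha fractions

    alpha0 = h^2 / D,   alpha1 = K1*h / D,   alpha2 = K1*K2 / D,

with ``h = 10**-pH`` and ``D = h^2 + K1*h + K1*K2``.  ``alpha2`` carries
the exponential pH sensitivity that makes calcite solubility so
responsive to acid-base status.

All concentrations in this module are mol/L.  Ionic-strength corrections
use the Davies extension of Debye-Hueckel theory; temperature
corrections use standard calcite/carbonic-acid literature relations
applied as offsets anchored to the 37 degC defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ThermoParams",
    "SpeciationFractions",
    "ActivityCoefficients",
    "DEFAULT_THERMO",
    "hydrogen_activity",
    "speciation_fractions",
    "carbonate_from_ct",
    "ct_from_bicarbonate",
    "ct_from_pco2",
    "davies_gamma",
    "adjust_constants_for_temperature",
]

_T_MIN, _T_MAX = 30.0, 45.0


@dataclass(frozen=True)
class ThermoParams:
    """Physicochemical constants governing the carbonate equilibria.

    Parameters
    ----------
    pk1, pk2 : float
        First and second carbonic-acid dissociation exponents
        (dimensionless); defaults 6.12 and 10.3 at 37 degC.
    ksp : float
        Effective calcite solubility product, mol^2/L^2; default
        4.47e-9 at 37 degC and physiological ionic strength.
    s_co2 : float
        CO2 solubility coefficient in plasma, mmol/L/mmHg; default
        0.0306 at 37 degC.
    temperature_c : float
        Temperature in degC (accepted range 30-45).
    ionic_strength_m : float
        Ionic strength in mol/L; only used in Davies activity mode.
    davies_a : float
        Debye-Hueckel/Davies slope A at the working temperature.
    """

    pk1: float = 6.12
    pk2: float = 10.3
    ksp: float = 4.47e-9
    s_co2: float = 0.0306
    temperature_c: float = 37.0
    ionic_strength_m: float = 0.20
    davies_a: float = 0.52

    def __post_init__(self) -> None:
        if not self.pk1 < self.pk2:
            raise ValueError(f"pk1 ({self.pk1}) must be < pk2 ({self.pk2})")
        if self.ksp <= 0:
            raise ValueError("ksp must be positive")
        if self.s_co2 <= 0:
            raise ValueError("s_co2 must be positive")
        if not _T_MIN <= self.temperature_c <= _T_MAX:
            raise ValueError(
                f"temperature_c={self.temperature_c} outside accepted "
                f"range [{_T_MIN}, {_T_MAX}]"
            )
        if self.ionic_strength_m < 0:
            raise ValueError("ionic_strength_m must be >= 0")

    @property
    def k1(self) -> float:
        return 10.0 ** -self.pk1

    @property
    def k2(self) -> float:
        return 10.0 ** -self.pk2


DEFAULT_THERMO = ThermoParams()


@dataclass(frozen=True)
class SpeciationFractions:
    """Alpha fractions of C_T at one pH (scalars or arrays)."""

    alpha0: float | np.ndarray
    alpha1: float | np.ndarray
    alpha2: float | np.ndarray
    d: float | np.ndarray  # normalization constant, mol^2/L^2
    h: float | np.ndarray  # hydrogen-ion activity, mol/L


@dataclass(frozen=True)
class ActivityCoefficients:
    """Single-ion activity coefficients for Ca2+ and CO3^2-."""

    gamma_ca: float = 1.0
    gamma_co3: float = 1.0

    def __post_init__(self) -> None:
        for g in (self.gamma_ca, self.gamma_co3):
            if not 0.0 < g <= 1.0:
                raise ValueError(f"activity coefficient {g} outside (0, 1]")

    @property
    def product(self) -> float:
        return self.gamma_ca * self.gamma_co3

    @classmethod
    def unity(cls) -> "ActivityCoefficients":
        """The minimal-model convention: activities == concentrations."""
        return cls(1.0, 1.0)

    @classmethod
    def from_davies(cls, params: ThermoParams) -> "ActivityCoefficients":
        g = davies_gamma(params.ionic_strength_m, 2, params)
        return cls(gamma_ca=g, gamma_co3=g)

    @classmethod
    def for_mode(cls, mode: str, params: ThermoParams) -> "ActivityCoefficients":
        if mode == "minimal":
            return cls.unity()
        if mode == "davies":
            return cls.from_davies(params)
        raise ValueError(f"unknown activity mode {mode!r}; use 'minimal' or 'davies'")


def _check_ph(ph: float | np.ndarray) -> np.ndarray | float:
    arr = np.asarray(ph, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 14.0):
        raise ValueError(f"pH must lie in [0, 14], got {ph}")
    return arr if arr.ndim else float(arr)


def hydrogen_activity(ph: float | np.ndarray) -> float | np.ndarray:
    """Hydrogen-ion activity [H+] = 10**-pH in mol/L."""
    ph = _check_ph(ph)
    return 10.0 ** -np.asarray(ph, dtype=float) if np.ndim(ph) else 10.0 ** -ph


def speciation_fractions(
    ph: float | np.ndarray, params: ThermoParams = DEFAULT_THERMO
) -> SpeciationFractions:
    """Partition C_T into CO2(aq), bicarbonate and carbonate fractions."""
    ph = _check_ph(ph)
    h = 10.0 ** -np.asarray(ph, dtype=float)
    k1, k2 = params.k1, params.k2
    d = h * h + k1 * h + k1 * k2
    out = SpeciationFractions(
        alpha0=h * h / d, alpha1=k1 * h / d, alpha2=k1 * k2 / d, d=d, h=h
    )
    if np.ndim(ph) == 0:
        out = SpeciationFractions(
            alpha0=float(out.alpha0),
            alpha1=float(out.alpha1),
            alpha2=float(out.alpha2),
            d=float(out.d),
            h=float(out.h),
        )
    return out


def carbonate_from_ct(
    ct: float | np.ndarray,
    ph: float | np.ndarray,
    params: ThermoParams = DEFAULT_THERMO,
) -> float | np.ndarray:
    """Free carbonate [CO3^2-] = alpha2(pH) * C_T (mol/L)."""
    if np.any(np.asarray(ct) <= 0):
        raise ValueError("ct must be positive")
    return speciation_fractions(ph, params).alpha2 * ct


def ct_from_bicarbonate(
    hco3: float, ph: float, params: ThermoParams = DEFAULT_THERMO
) -> float:
    """Infer C_T from a bicarbonate measurement: C_T = [HCO3-] / alpha1(pH)."""
    if hco3 <= 0:
        raise ValueError("hco3 must be positive")
    return hco3 / speciation_fractions(ph, params).alpha1


def ct_from_pco2(
    pco2: float, ph: float, params: ThermoParams = DEFAULT_THERMO
) -> float:
    """Infer C_T from a pCO2 measurement (mmHg).

    [CO2(aq)] = S_CO2 * pCO2 (mmol/L, converted to mol/L), then
    C_T = [CO2(aq)] / alpha0(pH).
    """
    if pco2 <= 0:
        raise ValueError("pco2 must be positive")
    co2_aq = params.s_co2 * pco2 * 1e-3
    return co2_aq / speciation_fractions(ph, params).alpha0


def davies_gamma(
    ionic_strength: float, z: int, params: ThermoParams = DEFAULT_THERMO
) -> float:
    """Davies single-ion activity coefficient.

    log10 gamma = -A * z^2 * (sqrt(I)/(1 + sqrt(I)) - 0.3 * I)

    Valid up to roughly I ~ 0.5 mol/L; returns 1 at I = 0.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if abs(z) not in (1, 2):
        raise ValueError(f"unsupported ionic charge {z}")
    sqrt_i = np.sqrt(ionic_strength)
    log_gamma = -params.davies_a * z * z * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength)
    return float(10.0 ** log_gamma)


# Literature temperature relations (T in kelvin), used only as *offsets*
# anchored to the 37 degC defaults so the minimal model is unchanged at 37.
def _log_k1_lit(tk: float) -> float:
    return (
        -356.3094
        - 0.06091964 * tk
        + 21834.37 / tk
        + 126.8339 * np.log10(tk)
        - 1684915.0 / tk**2
    )


def _log_k2_lit(tk: float) -> float:
    return (
        -107.8871
        - 0.03252849 * tk
        + 5151.79 / tk
        + 38.92561 * np.log10(tk)
        - 563713.9 / tk**2
    )


def _log_ksp_lit(tk: float) -> float:
    return -171.9065 - 0.077993 * tk + 2839.319 / tk + 71.595 * np.log10(tk)


def _log_kh_lit(tk: float) -> float:
    # Henry's-law constant for CO2; governs the S_CO2 offset.
    return (
        108.3865
        + 0.01985076 * tk
        - 6919.53 / tk
        - 40.45154 * np.log10(tk)
        + 669365.0 / tk**2
    )


def adjust_constants_for_temperature(
    temperature_c: float, base: ThermoParams = DEFAULT_THERMO
) -> ThermoParams:
    """Shift pK1, pK2, Ksp and S_CO2 from ``base.temperature_c`` to a new
    temperature using literature relations applied as offsets.

    The anchor-offset convention means the constants are continuous in T
    and exactly reproduce ``base`` when ``temperature_c`` equals the base
    temperature; re-anchoring back restores ``base`` bit-identically.
    """
    if not _T_MIN <= temperature_c <= _T_MAX:
        raise ValueError(
            f"temperature {temperature_c} outside accepted range [{_T_MIN}, {_T_MAX}]"
        )
    tk = temperature_c + 273.15
    tk0 = base.temperature_c + 273.15
    return replace(
        base,
        pk1=base.pk1 - (_log_k1_lit(tk) - _log_k1_lit(tk0)),
        pk2=base.pk2 - (_log_k2_lit(tk) - _log_k2_lit(tk0)),
        ksp=base.ksp * 10.0 ** (_log_ksp_lit(tk) - _log_ksp_lit(tk0)),
        s_co2=base.s_co2 * 10.0 ** (_log_kh_lit(tk) - _log_kh_lit(tk0)),
        temperature_c=temperature_c,
    )
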