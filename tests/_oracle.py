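"""Independent high-precision oracle for the carbonate equilibria.

Evaluates species concentrations directly from K1, K2, [H+] and C_T in
50-digit arithmetic (mpmath), then normalizes — a brute-force
equilibrium route that never touches the package's closed-form alpha
expressions.
"""

from __future__ import annotations

import mpmath as mp

mp.mp.dps = 50


def alphas_hp(ph, pk1="6.12", pk2="10.3"):
    """(alpha0, alpha1, alpha2) by explicit species construction.

    For an arbitrary C_T, build the un-normalized equilibrium species
    [CO2] = [H+]^2 * c, [HCO3-] = K1 [H+] c, [CO3--] = K1 K2 c and
    normalize by their sum; the fractions are independent of c.
    """
    h = mp.mpf(10) ** -mp.mpf(str(ph))
    k1 = mp.mpf(10) ** -mp.mpf(str(pk1))
    k2 = mp.mpf(10) ** -mp.mpf(str(pk2))
    co2 = h * h
    hco3 = k1 * h
    co3 = k1 * k2
    total = co2 + hco3 + co3
    return co2 / total, hco3 / total, co3 / total


def ccrit_hp(ph, ct, ksp="4.47e-9", pk1="6.12", pk2="10.3"):
    """Critical calcium (mol/L) at unit activity coefficients."""
    a2 = alphas_hp(ph, pk1, pk2)[2]
    return mp.mpf(str(ksp)) / (a2 * mp.mpf(str(ct)))


def calibrated_ct_hp(
    anchor_ph="7.65", anchor_ccrit="265e-6", ksp="4.47e-9", lo="1e-4", hi="1.0"
):
    """C_T solving C_crit(anchor_ph) = anchor_ccrit by bisection.

    Deliberately does NOT invert the formula: bisection against
    ``ccrit_hp`` is the independent check of the closed-form
    calibration.
    """
    target = mp.mpf(str(anchor_ccrit))
    lo, hi = mp.mpf(str(lo)), mp.mpf(str(hi))
    # ccrit is strictly decreasing in ct
    for _ in range(200):
        mid = (lo + hi) / 2
        if ccrit_hp(anchor_ph, mid, ksp) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def logistic_hp(delta_c, sigma_c):
    return 1 / (1 + mp.e ** (-mp.mpf(str(delta_c)) / mp.mpf(str(sigma_c))))
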