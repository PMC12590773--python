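"""Saturation index, critical calcium, calibration, logistic risk and
scenario directions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otosat import (
    SCENARIO_PRESETS,
    ActivityCoefficients,
    EndolymphState,
    RiskParams,
    ThermoParams,
    apply_scenario,
    calibrate_ct,
    classify_omega,
    critical_calcium,
    evaluate_state,
    relative_ccrit_index,
    risk_score,
    saturation_index,
)

from ._oracle import calibrated_ct_hp, ccrit_hp


class TestCriticalCalcium:
    @pytest.mark.parametrize(
        "ph, expected_umol",
        [(7.65, 265.0), (7.50, 378.50231), (7.80, 186.20633)],
    )
    def test_reference_values(self, thermo, unity, ct_cal, ph, expected_umol):
        cc = critical_calcium(ph, ct_cal, thermo, unity)
        assert cc * 1e6 == pytest.approx(expected_umol, rel=1e-6)

    def test_matches_oracle_on_grid(self, thermo, unity, ct_cal):
        for ph in np.linspace(7.0, 8.2, 25):
            assert critical_calcium(ph, ct_cal, thermo, unity) == pytest.approx(
                float(ccrit_hp(ph, ct_cal)), rel=1e-10
            )

    def test_strictly_decreasing_in_ph(self, thermo, unity, ct_cal):
        """Acidification raises the calcium needed to hold Omega = 1."""
        cc = critical_calcium(np.linspace(7.0, 8.2, 200), ct_cal, thermo, unity)
        assert np.all(np.diff(cc) < 0)

    def test_exact_scaling_laws(self, thermo, unity, ct_cal):
        base = critical_calcium(7.6, ct_cal, thermo, unity)
        assert critical_calcium(7.6, ct_cal * 1.1, thermo, unity) == pytest.approx(
            base / 1.1, rel=1e-12
        )
        scaled = ThermoParams(ksp=thermo.ksp * 1.1)
        assert critical_calcium(7.6, ct_cal, scaled, unity) == pytest.approx(
            base * 1.1, rel=1e-12
        )

    def test_domain(self, thermo, unity):
        with pytest.raises(ValueError):
            critical_calcium(7.6, -1e-3, thermo, unity)


class TestCalibration:
    def test_calibrated_ct_value_vs_bisection_oracle(self, ct_cal):
        assert ct_cal == pytest.approx(float(calibrated_ct_hp()), rel=1e-10)
        assert ct_cal * 1e3 == pytest.approx(7.7739, abs=5e-4)

    def test_round_trip(self, thermo, unity, ct_cal):
        assert critical_calcium(7.65, ct_cal, thermo, unity) == pytest.approx(
            265e-6, rel=1e-10
        )

    def test_ksp_proportionality(self, thermo, unity, ct_cal):
        scaled = ThermoParams(ksp=thermo.ksp * 1.1)
        assert calibrate_ct(scaled, unity) == pytest.approx(ct_cal * 1.1, rel=1e-12)

    def test_domain(self, thermo, unity):
        with pytest.raises(ValueError):
            calibrate_ct(thermo, unity, anchor_ccrit=-1.0)


class TestSaturationIndex:
    def test_boundary_identity_random_states(self, thermo, unity, ct_cal):
        """Omega evaluated at Ca = C_crit is exactly 1, over 1000 random
        (pH, C_T) pairs."""
        rng = np.random.default_rng(42)
        phs = rng.uniform(7.0, 8.2, 1000)
        cts = rng.uniform(1e-3, 30e-3, 1000)
        for ph, ct in zip(phs, cts):
            ca = critical_calcium(ph, ct, thermo, unity)
            state = EndolymphState(ph=ph, ca=float(ca), ct=ct)
            assert saturation_index(state, thermo, unity) == pytest.approx(
                1.0, rel=1e-10
            )

    def test_omega_equals_ca_over_ccrit(self, thermo, unity, ct_cal):
        rng = np.random.default_rng(7)
        for _ in range(100):
            ph = rng.uniform(7.0, 8.2)
            ca = rng.uniform(100e-6, 500e-6)
            state = EndolymphState(ph=ph, ca=ca, ct=ct_cal)
            lhs = saturation_index(state, thermo, unity)
            rhs = ca / critical_calcium(ph, ct_cal, thermo, unity)
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_linearity_in_calcium(self, thermo, unity, ct_cal):
        s1 = EndolymphState(ph=7.6, ca=200e-6, ct=ct_cal)
        s2 = EndolymphState(ph=7.6, ca=400e-6, ct=ct_cal)
        assert saturation_index(s2, thermo, unity) == pytest.approx(
            2 * saturation_index(s1, thermo, unity), rel=1e-12
        )

    def test_reference_undersaturated_state(self, thermo, unity, ct_cal):
        state = EndolymphState(ph=7.50, ca=265e-6, ct=ct_cal)
        assert saturation_index(state, thermo, unity) == pytest.approx(
            0.7001278, rel=1e-6
        )


class TestRiskScore:
    @pytest.mark.parametrize(
        "dc, expected, places",
        [(0.0, 0.5, None), (100.0, 0.78, 2), (60.0, 0.68, 2)],
    )
    def test_anchor_values(self, dc, expected, places):
        r = risk_score(dc, 80.0)
        if places is None:
            assert r == expected
        else:
            assert round(r, places) == expected

    @given(dc=st.floats(-500, 500))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_logistic_symmetry(self, dc):
        assert risk_score(dc, 80.0) + risk_score(-dc, 80.0) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_monotone_and_limits(self):
        grid = np.linspace(-2000, 2000, 401)
        r = risk_score(grid, 80.0)
        assert np.all(np.diff(r) > 0)
        assert risk_score(1e6, 80.0) == pytest.approx(1.0)
        assert risk_score(-1e6, 80.0) == pytest.approx(0.0, abs=1e-12)

    def test_sigma_domain(self):
        with pytest.raises(ValueError):
            risk_score(10.0, -1.0)


class TestEvaluateState:
    def test_boundary_state(self, thermo, risk_params, unity, ct_cal):
        res = evaluate_state(
            EndolymphState(ph=7.65, ca=265e-6, ct=ct_cal), thermo, risk_params, unity
        )
        assert res.omega == pytest.approx(1.0, rel=1e-12)
        assert res.delta_c_umol == pytest.approx(0.0, abs=1e-9)
        assert res.r == pytest.approx(0.5, abs=1e-12)
        assert res.label == "boundary"

    def test_undersaturated_reference(self, thermo, risk_params, unity, ct_cal):
        res = evaluate_state(
            EndolymphState(ph=7.50, ca=265e-6, ct=ct_cal), thermo, risk_params, unity
        )
        assert res.delta_c_umol == pytest.approx(113.50231, rel=1e-6)
        assert res.r == pytest.approx(0.8051469, rel=1e-6)
        assert res.label == "dissolution-prone"

    def test_supersaturated_reference(self, thermo, risk_params, unity, ct_cal):
        res = evaluate_state(
            EndolymphState(ph=7.80, ca=300e-6, ct=ct_cal), thermo, risk_params, unity
        )
        assert res.delta_c_umol == pytest.approx(-113.79367, rel=1e-6)
        assert res.r == pytest.approx(0.1942823, rel=1e-6)
        assert res.omega == pytest.approx(1.611116, rel=1e-6)
        assert res.label == "stable"

    def test_sign_coherence(self, thermo, risk_params, unity, ct_cal):
        """r > 1/2 iff delta_c > 0 iff omega < 1 at fixed gammas."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            state = EndolymphState(
                ph=rng.uniform(7.2, 8.0), ca=rng.uniform(100e-6, 500e-6), ct=ct_cal
            )
            res = evaluate_state(state, thermo, risk_params, unity)
            assert (res.r > 0.5) == (res.delta_c_umol > 0) == (res.omega < 1)

    def test_r_monotone_in_omega(self, thermo, risk_params, unity, ct_cal):
        """At fixed pH and C_T, R falls strictly as Omega rises — the
        saturation-to-risk curve."""
        cas = np.linspace(100e-6, 600e-6, 50)
        results = [
            evaluate_state(EndolymphState(7.6, ca, ct_cal), thermo, risk_params, unity)
            for ca in cas
        ]
        omegas = np.array([r.omega for r in results])
        rs = np.array([r.r for r in results])
        assert np.all(np.diff(omegas) > 0)
        assert np.all(np.diff(rs) < 0)


class TestClassify:
    def test_tie_break(self):
        assert classify_omega(1.0) == "boundary"
        assert classify_omega(1.0 + 1e-12) == "stable"
        assert classify_omega(1.0 - 1e-12) == "dissolution-prone"


class TestRelativeIndex:
    def test_normalized_at_anchor(self, thermo, risk_params, ct_cal):
        _, norm = relative_ccrit_index(7.65, ct_cal, thermo, risk_params)
        assert norm == pytest.approx(1.0, rel=1e-12)

    def test_acidosis_alkalosis_ratio(self, thermo, risk_params, ct_cal):
        _, n_acid = relative_ccrit_index(7.50, ct_cal, thermo, risk_params)
        _, n_alk = relative_ccrit_index(7.80, ct_cal, thermo, risk_params)
        assert n_acid > 1 > n_alk
        assert n_acid / n_alk == pytest.approx(2.0327038, rel=1e-6)

    def test_raw_decreasing_in_ph(self, thermo, risk_params, ct_cal):
        raws = [
            relative_ccrit_index(ph, ct_cal, thermo, risk_params)[0]
            for ph in np.linspace(7.0, 8.2, 50)
        ]
        assert np.all(np.diff(raws) < 0)


class TestDaviesMode:
    def test_boundary_above_minimal_and_increasing_in_i(self, thermo, ct_cal):
        """Lower activity coefficients demand more calcium at every pH,
        the more so the higher the ionic strength."""
        phs = np.linspace(7.4, 7.9, 21)
        minimal = np.asarray(
            critical_calcium(phs, ct_cal, thermo, ActivityCoefficients.unity())
        )
        prev = minimal
        for ionic in (0.15, 0.20, 0.30):
            params = ThermoParams(ionic_strength_m=ionic)
            gam = ActivityCoefficients.from_davies(params)
            curve = np.asarray(critical_calcium(phs, ct_cal, params, gam))
            assert np.all(curve > prev)
            prev = curve


class TestScenarios:
    def test_full_preset_table_signs(self, thermo, risk_params, unity, ct_cal):
        """All nine directional presets move Omega in the physiologically
        expected direction from any interior baseline."""
        rng = np.random.default_rng(3)
        baselines = [
            EndolymphState(
                ph=rng.uniform(7.45, 7.85), ca=rng.uniform(210e-6, 340e-6), ct=ct_cal
            )
            for _ in range(5)
        ]
        assert len(SCENARIO_PRESETS) == 9
        for name, preset in SCENARIO_PRESETS.items():
            for state in baselines:
                _, _, sign = apply_scenario(state, name, thermo, risk_params, unity)
                assert sign == preset.expected_omega_sign, name

    def test_identity_shift(self, thermo, risk_params, unity, ct_cal):
        from otosat import ScenarioShift

        state = EndolymphState(ph=7.6, ca=265e-6, ct=ct_cal)
        before, after, sign = apply_scenario(
            state, ScenarioShift("identity", 0.0, 1.0, 0), thermo, risk_params, unity
        )
        assert sign == 0
        assert after.omega == before.omega

    def test_unknown_preset(self, thermo, risk_params, unity, ct_cal):
        state = EndolymphState(ph=7.6, ca=265e-6, ct=ct_cal)
        with pytest.raises(KeyError, match="unknown scenario"):
            apply_scenario(state, "coffee", thermo, risk_params, unity)


class TestStateValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ph": 15.0, "ca": 1e-6, "ct": 1e-3},
            {"ph": 7.4, "ca": 0.0, "ct": 1e-3},
            {"ph": 7.4, "ca": 1e-6, "ct": -1e-3},
        ],
    )
    def test_invalid_states(self, kwargs):
        with pytest.raises(ValueError):
            EndolymphState(**kwargs)

    def test_risk_params_validation(self):
        with pytest.raises(ValueError):
            RiskParams(sigma_c=0.0)
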