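"""Model-core unit and property tests: Hill machinery, ODE right-hand
side, closed-form oracles, and integrator behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from sbrt_pkpd.dosing import build_schedule
from sbrt_pkpd.model import (
    STATE_NAMES,
    PKPDParams,
    combined_effect,
    final_reported_volume,
    hill_effect,
    interaction_index,
    load_params,
    normalized_dose,
    normalized_tumor,
    rhs,
    save_params,
    simulate,
)

from conftest import by_id

# growth-only configuration: therapy machinery effectively disabled so
# the linear two-compartment closed forms apply
GROWTH_ONLY = PKPDParams(emax_rate=1e-12, washout=0.0)


class TestParams:
    @pytest.mark.parametrize(
        "changes",
        [
            {"a": -0.1},
            {"gamma": 0.0},
            {"c50r": 0.0},
            {"c50t": -5.0},
            {"emax_rate": 0.0},
            {"normalization_mode": "weird"},
            {"reported_volume": "x9"},
        ],
    )
    def test_invalid_params_rejected(self, changes):
        with pytest.raises(ValueError):
            PKPDParams(**changes)

    def test_per_lesion_clearance_rule(self, bundled):
        sched = build_schedule(by_id(bundled, "015"))
        assert PKPDParams().resolve_cr(sched) == pytest.approx(3.0 / 17.0)
        assert PKPDParams(cr=0.5).resolve_cr(sched) == 0.5

    def test_yaml_round_trip(self, tmp_path):
        p = PKPDParams(gamma=0.2, washout=0.3, normalization_mode="relative")
        path = tmp_path / "params.yaml"
        save_params(p, path)
        assert load_params(path) == p

    def test_yaml_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "params.yaml"
        path.write_text("nonsense_rate: 1.0\n")
        with pytest.raises(ValueError, match="nonsense_rate"):
            load_params(path)


class TestHillMachinery:
    def test_normalized_dose(self):
        assert normalized_dose(0.0, 20.0) == 0.0
        assert normalized_dose(20.0, 20.0) == 1.0
        assert normalized_dose(34.0, 20.0) == pytest.approx(1.7)
        with pytest.raises(ValueError):
            normalized_dose(-1.0, 20.0)

    def test_normalized_tumor_absolute(self, params):
        assert normalized_tumor(50.0, 0.0, 1000.0, params) == pytest.approx(1.0)
        assert normalized_tumor(30.0, 20.0, 1000.0, params) == pytest.approx(1.0)
        assert normalized_tumor(0.0, 0.0, 1000.0, params) == 0.0

    def test_normalized_tumor_relative(self, params):
        rel = params.with_(normalization_mode="relative")
        # burden equal to its own baseline is 100%, i.e. twice c50t = 50%
        assert normalized_tumor(600.0, 0.0, 600.0, rel) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            normalized_tumor(1.0, 0.0, 0.0, rel)

    def test_interaction_index(self):
        assert interaction_index(1.0, 1.0, 8.0) == 10.0
        assert interaction_index(0.7, 0.0, 8.0) == pytest.approx(0.7)
        assert interaction_index(0.0, 0.0, 8.0) == 0.0

    @pytest.mark.parametrize("gamma", [0.01, 0.043, 0.25, 1.0, 3.0])
    def test_hill_half_effect_at_unit_index(self, gamma):
        assert hill_effect(1.0, gamma) == pytest.approx(0.5, abs=1e-15)

    def test_hill_values(self):
        assert hill_effect(0.0, 0.25) == 0.0
        assert hill_effect(10.0, 0.25) == pytest.approx(0.6401, abs=1e-4)
        with pytest.raises(ValueError):
            hill_effect(-0.1, 0.25)

    @given(
        i=st.floats(1e-6, 1e6),
        factor=st.floats(1.001, 100.0),
        gamma=st.floats(0.01, 2.0),
    )
    def test_hill_strictly_increasing_and_bounded(self, i, factor, gamma):
        lo, hi = hill_effect(i, gamma), hill_effect(i * factor, gamma)
        assert 0.0 < lo < hi < 1.0

    def test_combined_effect(self, params):
        assert combined_effect(0.0, 0.0, params) == 0.0
        # interaction index 1 -> half of the maximal kill rate
        e = combined_effect(1.0, 0.0, params)
        assert e == pytest.approx(params.emax_rate / 2)
        big = combined_effect(1e9, 1e9, params)
        assert e < big < params.emax_rate


class TestRHS:
    def test_zero_state_is_equilibrium(self, bundled, params):
        sched = build_schedule(by_id(bundled, "001"))
        deriv = rhs(50.0, np.zeros(8), params, sched, v0=600.0)
        assert np.all(deriv == 0.0)

    def test_total_volume_balance_without_washout(self, bundled):
        # x1' + x2' = a*x1 identically when washout = 0, any state/dose
        p = PKPDParams(washout=0.0)
        sched = build_schedule(by_id(bundled, "001"))
        state = np.array([700.0, 350.0, 0, 0, 0, 0, 5.0, 3.0])
        for t in (0.0, 0.05, 2.5, 30.0):
            deriv = rhs(t, state, p, sched, v0=700.0)
            assert deriv[0] + deriv[1] == pytest.approx(p.a * state[0], rel=1e-12)

    def test_matches_full_state_integration(self, bundled, params):
        """The fast 4-state integrator agrees with integrating the public
        8-state right-hand side directly."""
        rec = by_id(bundled, "019")
        sched = build_schedule(rec, params.pulse_width)
        cr = params.resolve_cr(sched)
        y = np.zeros(8)
        y[0] = rec.v_pre_cm3 * 1000.0
        t_final = 30.0
        breaks = sched.breakpoints(t_final)
        v0 = rec.v_pre_cm3 * 1000.0
        for t0, t1 in zip(breaks[:-1], breaks[1:]):
            sol = solve_ivp(
                lambda t, s: rhs(t, s, params, sched, v0, cr),
                (t0, t1),
                y,
                rtol=1e-10,
                atol=1e-10,
                max_step=params.pulse_width / 5,
            )
            y = sol.y[:, -1]
        traj = simulate(rec, params, output_grid=np.array([t_final]))
        assert traj.x1[-1] == pytest.approx(y[0], rel=1e-5)
        assert traj.x2[-1] == pytest.approx(y[1], rel=1e-5)


class TestClosedForms:
    def test_exponential_growth_without_therapy(self, bundled):
        """x1(t) = x1(0) e^{(a-n)t} when the kill term is off."""
        rec = by_id(bundled, "001").with_(v_pre_cm3=1.0, followup_days=10.0)
        traj = simulate(rec, GROWTH_ONLY, output_grid=np.array([1.0, 5.0, 10.0]))
        expected = 1000.0 * np.exp(0.593 * traj.times)
        assert traj.x1 == pytest.approx(expected, rel=1e-6)

    def test_necrotic_accumulation_without_therapy(self, bundled):
        """x2(t) = x1(0) n/(a-n) (e^{(a-n)t} - 1) with zero washout."""
        rec = by_id(bundled, "001").with_(v_pre_cm3=1.0, followup_days=1.0)
        traj = simulate(rec, GROWTH_ONLY, output_grid=np.array([1.0]))
        expected = 1000.0 * (0.10 / 0.593) * (math.exp(0.593) - 1.0)
        assert traj.x2[-1] == pytest.approx(expected, rel=1e-6)
        assert traj.x2[-1] == pytest.approx(136.49, abs=0.01)

    def test_drug_level_decays_exponentially_after_bolus(self, bundled, params):
        """After the single pulse, x5 is a pure exponential with rate c_r."""
        rec = by_id(bundled, "019")  # 34 Gy in one fraction, duration 1 day
        cr = 3.0 / 1.0
        grid = np.array([0.5, 1.0, 1.5])
        traj = simulate(rec, params, output_grid=grid)
        ratios = traj.x5[1:] / traj.x5[:-1]
        expected = np.exp(-cr * np.diff(grid))
        assert ratios == pytest.approx(expected, rel=1e-5)


class TestSimulation:
    def test_trajectory_invariants(self, bundled, params):
        traj = simulate(by_id(bundled, "008"), params)
        assert np.all(np.diff(traj.times) > 0)
        assert traj.total_volume == pytest.approx(traj.x1 + traj.x2)
        assert traj.delta_v == pytest.approx(traj.x1)
        frame = traj.to_frame()
        assert list(frame.columns) == [
            "t_days", "x1_mm3", "x2_mm3", "x5", "xe5",
            "total_mm3", "delta_v_mm3", "effect_per_day",
        ]
        assert np.all(frame["effect_per_day"] <= params.emax_rate)

    def test_states_nonnegative(self, bundled, params):
        for pid in ("001", "008", "015", "019"):
            for gamma in (0.043, 0.3, 1.0):
                traj = simulate(by_id(bundled, pid), params.with_(gamma=gamma))
                assert traj.states.min() >= 0.0

    def test_doubled_dose_doubles_effect_site_level(self, bundled, params):
        # the dose compartments are linear, so the effect-site level
        # scales exactly with the emitted dose rate ...
        rec = by_id(bundled, "001")
        doubled = rec.with_(total_dose_gy=2 * rec.total_dose_gy)
        grid = np.linspace(0.0, 20.0, 80)
        x1 = simulate(rec, params, output_grid=grid).xe5
        x2 = simulate(doubled, params, output_grid=grid).xe5
        np.testing.assert_allclose(x2, 2.0 * x1, rtol=1e-6, atol=1e-9)

    def test_effect_monotone_in_dose_and_burden(self, params):
        # ... and the kill rate is monotone in both normalised inputs
        for unt in (0.0, 0.5, 2.0, 50.0):
            effs = [combined_effect(unt, unr, params) for unr in (0.0, 0.5, 1.0, 4.0)]
            assert np.all(np.diff(effs) >= 0)
        for unr in (0.0, 1.0):
            effs = [combined_effect(unt, unr, params) for unt in (0.0, 0.5, 2.0, 50.0)]
            assert np.all(np.diff(effs) >= 0)

    def test_tolerance_refinement_stable(self, bundled, params):
        rec = by_id(bundled, "009")
        coarse = final_reported_volume(rec, params)
        fine = final_reported_volume(rec, params.with_(rtol=1e-10, atol=1e-10))
        assert abs(coarse - fine) / fine < 1e-3

    def test_delivered_dose_reaches_total(self, bundled, params):
        # the forcing seen by the integrator conserves the printed dose
        for pid in ("001", "015", "020"):
            rec = by_id(bundled, pid)
            sched = build_schedule(rec, params.pulse_width)
            assert sched.delivered_dose(rec.followup_days) == pytest.approx(
                rec.total_dose_gy, rel=1e-9
            )

    def test_output_grid_outside_followup_rejected(self, bundled, params):
        with pytest.raises(ValueError, match="grid"):
            simulate(by_id(bundled, "001"), params, output_grid=np.array([1000.0]))
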