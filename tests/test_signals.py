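"""Predicted time courses, HRF convolution and design-matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from savor import (DesignConfig, ModelParams, anticipation_coefficient,
                   anticipation_timecourse, arpe_event_amplitudes,
                   build_design_matrix, canonical_hrf, dct_highpass_basis,
                   discounted_reward_timecourse, ppi_regressor, solve_arpe,
                   standard_rpe, state_prediction_error, stability_bound,
                   urgency_timecourse)
from savor.simulate import TaskConfig, generate_trials, simulate_choices

from conftest import random_admissible_params


@pytest.fixture
def events(boosting_params, rng):
    trials = generate_trials(TaskConfig(n_runs=1), 1, rng)
    return simulate_choices(boosting_params, trials, rng)


class TestWaitingPeriodSignals:
    def test_anticipation_vanishes_at_outcome(self, boosting_params):
        tc = anticipation_timecourse(boosting_params, (0.5, 10.0), "S+",
                                     np.array([10.0]), "+")
        assert tc.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_anticipation_at_cue_onset_unboosted(self):
        p = ModelParams(C=0.0, eta0=0.8, nu_plus=0.1, gamma=0.02)
        tc = anticipation_timecourse(p, (0.5, 20.0), "S+", np.array([0.0]), "+")
        assert tc.values[0] == pytest.approx(
            p.eta0 * anticipation_coefficient(p, 20.0, "+"))

    def test_anticipation_is_integral_of_discounted_urgency(self, rng):
        """The anticipatory utility at t equals the quadrature of the
        discounted urgency over the remaining waiting period, to 1e-8."""
        for _ in range(5):
            p = random_admissible_params(rng)
            q, T = float(rng.uniform(0.1, 0.9)), float(rng.uniform(5, 40))
            for cue in ("S+", "S-", "NI"):
                for valence in ("+", "-"):
                    ts = np.linspace(0.0, T, 7)
                    ant = anticipation_timecourse(p, (q, T), cue, ts, valence)
                    for t, got in zip(ts, ant.values):
                        expected, _ = quad(
                            lambda tp: np.exp(-p.gamma * (tp - t)) *
                            urgency_timecourse(p, (q, T), cue,
                                               np.array([tp]), valence).values[0],
                            t, T, epsabs=1e-12, epsrel=1e-12)
                        assert got == pytest.approx(expected, abs=1e-8)

    def test_urgency_at_outcome_is_boosted_outcome_value(self, boosting_params):
        q, T = 0.3, 12.0
        pair = solve_arpe(boosting_params, (q, T))
        tc = urgency_timecourse(boosting_params, (q, T), "S+",
                                np.array([T]), "+")
        eta = boosting_params.eta0 + boosting_params.C * abs(pair.delta_plus)
        assert tc.values[0] == pytest.approx(boosting_params.R_plus * eta)

    def test_urgency_increases_toward_outcome(self, boosting_params):
        t = np.linspace(0, 19.9, 50)
        tc = urgency_timecourse(boosting_params, (0.5, 20.0), "S+", t, "+")
        assert np.all(np.diff(tc.values) > 0)

    def test_fast_anticipation_rate_concentrates_at_outcome(self):
        p = ModelParams(nu_plus=50.0, eta0=1.0)
        tc = urgency_timecourse(p, (0.5, 20.0), "S+", np.array([10.0]), "+")
        assert tc.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_discounted_reward_signal(self):
        p = ModelParams(gamma=0.1)
        tc = discounted_reward_timecourse(p, (0.5, 20.0), "S+",
                                          np.array([10.0, 20.0]), "+")
        assert tc.values[0] == pytest.approx(np.exp(-1.0))
        assert tc.values[1] == pytest.approx(1.0)
        flat = discounted_reward_timecourse(
            ModelParams(gamma=0.0), (0.5, 20.0), "S+",
            np.linspace(0, 20, 5), "+")
        np.testing.assert_allclose(flat.values, 1.0)

    def test_noninformative_cue_scales_by_probability(self, boosting_params):
        q, T = 0.25, 20.0
        t = np.linspace(0, T, 9)
        ni = discounted_reward_timecourse(boosting_params, (q, T), "NI", t, "+")
        sp = discounted_reward_timecourse(boosting_params, (q, T), "S+", t, "+")
        np.testing.assert_allclose(ni.values, q * sp.values)


class TestEventAmplitudes:
    def test_certain_reward_no_surprise(self, boosting_params):
        amps = arpe_event_amplitudes(boosting_params, (1.0, 10.0))
        assert amps["S+"] == 0.0

    def test_noninformative_cue_carries_no_prediction_error(self, boosting_params):
        assert arpe_event_amplitudes(boosting_params, (0.5, 10.0))["NI"] == 0.0

    def test_amplitudes_match_fixed_point(self, boosting_params):
        from savor import arpe_fixed_point
        amps = arpe_event_amplitudes(boosting_params, (0.25, 20.0))
        pair = arpe_fixed_point(boosting_params, (0.25, 20.0), tol=1e-13)
        assert amps["S+"] == pytest.approx(pair.delta_plus, abs=1e-10)
        assert amps["S-"] == pytest.approx(pair.delta_minus, abs=1e-10)

    @pytest.mark.parametrize("q,cue,expected", [
        (0.95, "S+", 0.05), (0.95, "S-", 0.95),
        (0.5, "S+", 0.5), (0.5, "S-", 0.5),
    ])
    def test_state_prediction_error(self, q, cue, expected):
        assert state_prediction_error((q, 10.0), cue) == pytest.approx(expected)

    def test_standard_rpe_is_arpe_without_anticipation(self, boosting_params):
        stripped = boosting_params.replace(C=0.0, eta0=0.0)
        q, T = 0.25, 20.0
        pair = solve_arpe(stripped, (q, T))
        assert standard_rpe(boosting_params, (q, T), "S+") == \
            pytest.approx(pair.delta_plus)
        assert standard_rpe(boosting_params, (q, T), "S-") == \
            pytest.approx(pair.delta_minus)
        assert standard_rpe(boosting_params, (1.0, 20.0), "S+") == 0.0
        undiscounted = ModelParams(R_minus=0.0, gamma=0.0)
        assert standard_rpe(undiscounted, (0.3, 20.0), "S+") == \
            pytest.approx(0.7 * undiscounted.R_plus)


class TestCanonicalHrf:
    def test_basic_shape(self):
        dt = 0.1
        h = canonical_hrf(dt)
        assert h[0] == pytest.approx(0.0, abs=1e-12)
        assert h.sum() * dt > 0
        peak = np.argmax(h) * dt
        assert 4.0 <= peak <= 6.5

    def test_has_late_undershoot(self):
        h = canonical_hrf(0.1)
        assert h.min() < 0
        assert np.argmin(h) > np.argmax(h)

    def test_shape_matches_reference_canonical_kernel(self):
        """Our double-gamma agrees with nilearn's canonical HRF up to
        normalization."""
        hemo = pytest.importorskip(
            "nilearn.glm.first_level.hemodynamic_models")
        dt = 0.1
        ours = canonical_hrf(dt)
        ref = hemo.spm_hrf(1.0, oversampling=int(1 / dt), time_length=32.0)
        n = min(len(ours), len(ref))
        a, b = ours[:n], ref[:n]
        corr = np.corrcoef(a, b)[0, 1]
        assert corr > 0.999
        assert abs(np.argmax(a) - np.argmax(b)) * dt <= 0.2


class TestDesignMatrix:
    def test_empty_events_give_intercept_only(self, boosting_params):
        empty = pd.DataFrame(columns=["run", "onset_initial", "onset_cue",
                                      "cue", "onset_outcome", "q", "T_s",
                                      "outcome"])
        # run short enough that the high-pass basis is empty
        d = build_design_matrix(empty, boosting_params,
                                DesignConfig(n_scans=15))
        assert d.columns == ["run0_intercept"]

    def test_single_event_column_is_shifted_kernel(self, boosting_params):
        cfg = DesignConfig(tr=1.0, dt=0.1, n_scans=40)
        onset = 4.0
        ev = pd.DataFrame([{"run": 0, "onset_initial": onset,
                            "onset_cue": onset + 3.0, "cue": "S+",
                            "onset_outcome": onset + 13.0, "q": 0.5,
                            "T_s": 10.0, "outcome": 1}])
        d = build_design_matrix(ev, boosting_params, cfg)
        col = d.frame["onset_initial"].to_numpy()
        hrf = canonical_hrf(cfg.dt, cfg.hrf_length)
        scan_t = np.arange(cfg.n_scans) * cfg.tr
        expected = np.zeros_like(scan_t)
        inside = (scan_t >= onset) & (scan_t - onset < cfg.hrf_length)
        idx = np.round((scan_t[inside] - onset) / cfg.dt).astype(int)
        expected[inside] = hrf[idx]
        # microtime discretization is second-order accurate in dt
        np.testing.assert_allclose(col, expected, atol=1e-3)

    def test_convolution_linearity_over_disjoint_events(self, boosting_params,
                                                        events):
        cfg = DesignConfig(n_scans=120)
        part_a = events.iloc[:10]
        part_b = events.iloc[10:]
        d_all = build_design_matrix(events, boosting_params, cfg)
        d_a = build_design_matrix(part_a, boosting_params, cfg)
        d_b = build_design_matrix(part_b, boosting_params, cfg)
        col = "antic_pos"
        # parametric modulators are centered per event set, so compare an
        # uncentered time-varying column
        np.testing.assert_allclose(
            d_all.frame[col],
            d_a.frame.get(col, 0.0) + d_b.frame.get(col, 0.0), atol=1e-8)

    def test_short_delay_trials_modeled_separately(self, boosting_params,
                                                   events):
        d = build_design_matrix(events, boosting_params,
                                DesignConfig(n_scans=120))
        assert "onset_cue_short" in d.columns
        assert "onset_cue" in d.columns

    def test_validation_rejects_negative_onsets(self, boosting_params, events):
        bad = events.copy()
        bad.loc[bad.index[0], "onset_initial"] = -1.0
        with pytest.raises(ValueError):
            build_design_matrix(bad, boosting_params)

    def test_validation_rejects_inconsistent_delay(self, boosting_params,
                                                   events):
        bad = events.copy()
        bad.loc[bad.index[0], "onset_outcome"] += 2.0
        with pytest.raises(ValueError):
            build_design_matrix(bad, boosting_params)

    def test_column_names_unique_and_rows_match_scans(self, boosting_params,
                                                      events):
        cfg = DesignConfig(n_scans=120)
        d = build_design_matrix(events, boosting_params, cfg)
        assert len(set(d.columns)) == len(d.columns)
        assert d.n_scans == 120
        assert np.all(np.isfinite(d.values))

    def test_reproducible_bit_for_bit(self, boosting_params, events):
        cfg = DesignConfig(n_scans=120)
        a = build_design_matrix(events, boosting_params, cfg)
        b = build_design_matrix(events, boosting_params, cfg)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_downsampling_consistency(self, boosting_params, events):
        """Halving the microtime step changes regressors by < 1e-3 rel. RMS."""
        d1 = build_design_matrix(events, boosting_params,
                                 DesignConfig(n_scans=120, dt=0.1))
        d2 = build_design_matrix(events, boosting_params,
                                 DesignConfig(n_scans=120, dt=0.05))
        for col in ("antic_pos", "ev_pos", "urgency_pos", "box_wait"):
            a, b = d1.frame[col].to_numpy(), d2.frame[col].to_numpy()
            rel = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b ** 2))
            assert rel < 1e-3

    def test_optional_control_columns(self, boosting_params, events):
        d = build_design_matrix(
            events, boosting_params,
            DesignConfig(n_scans=120, include_const_ev=True, include_ramp=True,
                         include_spe=True))
        for col in ("pm_const_ev", "ramp_wait", "pm_spe"):
            assert col in d.columns

    def test_highpass_basis_periods(self):
        n, tr = 200, 2.0
        dct = dct_highpass_basis(n, tr, cutoff=128.0)
        assert dct.shape == (n, int(np.floor(2 * n * tr / 128.0)))
        # columns are orthonormal
        np.testing.assert_allclose(dct.T @ dct, np.eye(dct.shape[1]),
                                   atol=1e-10)


class TestPpiRegressor:
    def test_zero_psychological_series_gives_zero(self, rng):
        seed_ts = rng.normal(size=50)
        np.testing.assert_allclose(ppi_regressor(seed_ts, np.zeros(50)), 0.0)

    def test_constant_seed_gives_zero_interaction(self, rng):
        psych = rng.normal(size=50)
        np.testing.assert_allclose(ppi_regressor(np.full(50, 3.0), psych), 0.0)

    def test_matches_hand_computed_product(self, rng):
        seed_ts = rng.normal(size=64)
        psych = rng.normal(size=64)
        got = ppi_regressor(seed_ts, psych, zscore=True)
        s = seed_ts - seed_ts.mean()
        z = (psych - psych.mean()) / (psych - psych.mean()).std()
        np.testing.assert_allclose(got, s * z, atol=1e-12)
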