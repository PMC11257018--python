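"""Oculomotor phenotyping: calibration, blink masking, saccades, RMSE, gain."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pursuitgwas.pursuit import (EyeTrace, apply_blink_mask, apply_calibration,
                                 compute_gain, compute_rmse,
                                 compute_saccade_threshold, correlate_phenotypes,
                                 detect_and_classify_saccades, detect_blinks,
                                 fit_calibration, initial_acceleration_sd,
                                 summarize_session, threshold_from_sds)
from pursuitgwas.pursuit.trace import RawCalibration
from pursuitgwas.sim import SimTraceConfig, TargetSpec, generate_target_waveform, simulate_session


def make_calibration(gain, offset, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    targets = np.repeat([15.0, 10.0, 5.0, 0.0, -5.0, -10.0, -15.0], 1000)
    signal = gain * targets + offset
    if noise_sd:
        signal = signal + rng.normal(0, noise_sd, len(signal))
    return RawCalibration(time_ms=np.arange(len(targets), dtype=float),
                          signal=signal, target_deg=targets, before_trial=0)


def clean_trace(target, eye_positions):
    return EyeTrace(time_ms=target.time_ms, position_deg=eye_positions,
                    valid=np.ones(len(target), dtype=bool),
                    sample_rate_hz=target.sample_rate_hz, calibrated=True)


class TestCalibration:
    @pytest.mark.parametrize("gain,offset", [(2.0, 1.0), (1.0, 0.0), (-1.5, 3.0)])
    def test_exact_affine_recovery(self, gain, offset):
        fit = fit_calibration(make_calibration(gain, offset))
        assert fit.fit_gain == pytest.approx(gain)
        assert fit.fit_offset == pytest.approx(offset)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_gain_recovery_distribution(self):
        """OLS sampling spread over seeded replicates stays inside [1.7, 1.9]."""
        gains = [fit_calibration(make_calibration(1.8, 0.5, noise_sd=0.05, seed=s)).fit_gain
                 for s in range(200)]
        assert all(1.7 < g < 1.9 for g in gains)

    def test_round_trip_restores_distorted_trace(self):
        target = generate_target_waveform(TargetSpec(speed_deg_s=20), seed=0)
        clean = target.position_deg.copy()
        distorted = EyeTrace(time_ms=target.time_ms, position_deg=1.7 * clean + 0.4,
                             valid=np.ones(len(clean), dtype=bool))
        fit = fit_calibration(make_calibration(1.7, 0.4))
        restored = apply_calibration(distorted, fit)
        np.testing.assert_allclose(restored.position_deg, clean, atol=1e-9)

    def test_degenerate_calibrations_rejected(self):
        flat = make_calibration(0.0, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration(flat)
        single = RawCalibration(time_ms=np.arange(1000.0),
                                signal=np.zeros(1000), target_deg=np.zeros(1000),
                                before_trial=0)
        with pytest.raises(ValueError, match="2 distinct"):
            fit_calibration(single)


class TestBlinkDetection:
    def test_clean_trace_has_no_blinks(self):
        target = generate_target_waveform(TargetSpec(), seed=1)
        rng = np.random.default_rng(0)
        tr = clean_trace(target, target.position_deg + rng.normal(0, 0.1, len(target)))
        assert detect_blinks(tr) == []

    def test_injected_blinks_recovered_with_high_overlap(self):
        config = SimTraceConfig(blink_rate_per_s=0.15, catchup_rate_per_s=0,
                                anticipatory_rate_per_s=0, seed=2)
        trials, _, truth = simulate_session([TargetSpec()], config)
        assert truth.blink_intervals
        by_trial = {t.index: t for t in trials}
        for trial_idx, t0, t1 in truth.blink_intervals:
            trial = by_trial[trial_idx]
            fresh = EyeTrace(time_ms=trial.eye.time_ms,
                             position_deg=trial.eye.position_deg,
                             valid=np.ones(len(trial.eye), dtype=bool))
            blinks = detect_blinks(fresh)
            best = 0.0
            for s, e in blinks:
                inter = max(0.0, min(e, t1) - max(s, t0))
                union = max(e, t1) - min(s, t0)
                best = max(best, inter / union)
            assert best >= 0.6

    def test_all_invalid_trace_is_one_unusable_interval(self):
        n = 5000
        tr = EyeTrace(time_ms=np.arange(n, dtype=float),
                      position_deg=np.full(n, -45.0), valid=np.zeros(n, dtype=bool))
        blinks = detect_blinks(tr)
        assert len(blinks) == 1
        assert blinks[0] == (0.0, float(n))
        masked = apply_blink_mask(tr, blinks)
        assert masked.valid_fraction == 0.0


class TestSaccadeThreshold:
    def test_stated_formula_constant_and_median_cases(self):
        assert threshold_from_sds([100.0]) == pytest.approx(600.0)
        assert threshold_from_sds([50.0, 100.0, 150.0]) == pytest.approx(600.0)

    def test_matches_bruteforce_recomputation(self, prepared_session):
        prepared, _ = prepared_session
        traces = [tr for tr, _ in prepared.values()]
        threshold = compute_saccade_threshold(traces)
        sds = [initial_acceleration_sd(tr) for tr in traces]
        sds = [s for s in sds if s is not None]
        assert threshold == pytest.approx(6.0 * float(np.median(sds)))

    def test_no_valid_window_raises(self):
        n = 2000
        tr = EyeTrace(time_ms=np.arange(n, dtype=float), position_deg=np.zeros(n),
                      valid=np.zeros(n, dtype=bool))
        with pytest.raises(ValueError):
            compute_saccade_threshold([tr])

    def test_threshold_stable_across_seeds(self):
        """Coefficient of variation of the threshold over seeded sessions < 20%."""
        thresholds = []
        for seed in range(20):
            config = SimTraceConfig(catchup_rate_per_s=0, anticipatory_rate_per_s=0,
                                    blink_rate_per_s=0, noise_sd_deg=0.1, seed=seed)
            trials, _, _ = simulate_session([TargetSpec(speed_deg_s=20)], config)
            thresholds.append(compute_saccade_threshold([t.eye for t in trials]))
        cv = np.std(thresholds) / np.mean(thresholds)
        assert cv < 0.2


def inject_min_jerk(pos, onset, dur, amp):
    tau = np.arange(1, dur + 1) / dur
    profile = amp * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    out = pos.copy()
    out[onset:onset + dur] += profile
    out[onset + dur:] += amp
    return out


class TestSaccadeClassification:
    """Definition cases on a constructed physiological eye: the smooth
    component follows the target with a 40 ms velocity smoothing (a real eye
    cannot reverse velocity instantaneously), saccades are min-jerk jumps."""

    def setup_method(self):
        # speed 10: motion 500 ms fixation, then 0 -> +15 over 1.5 s, so at
        # t = 1200 ms the target moves rightward at +10 deg/s
        self.target = generate_target_waveform(
            TargetSpec(speed_deg_s=10, initial_fixation_ms=(500, 500)), seed=0)

    def _smooth_eye(self, offset=0.0):
        kernel = np.ones(40) / 40.0
        padded = np.concatenate([np.zeros(39), self.target.position_deg])
        return np.convolve(padded, kernel, mode="valid") + offset

    def _detect(self, eye_pos, mask=None):
        rng = np.random.default_rng(1)
        noisy = eye_pos + rng.normal(0, 0.1, len(eye_pos))
        tr = clean_trace(self.target, noisy)
        if mask is not None:
            tr = EyeTrace(time_ms=tr.time_ms, position_deg=tr.position_deg,
                          valid=mask, sample_rate_hz=tr.sample_rate_hz,
                          calibrated=True)
        threshold = compute_saccade_threshold([tr])
        return detect_and_classify_saccades(tr, self.target, threshold)

    def test_catchup_definition_case(self):
        """3 deg jump toward the target reducing error 3 -> ~0 is a catch-up."""
        eye = inject_min_jerk(self._smooth_eye(offset=-3.0), onset=1200,
                              dur=50, amp=3.0)
        sacs = self._detect(eye)
        assert len(sacs) == 1
        assert sacs[0].klass == "catchup"
        # amplitude is the position change onset -> offset, which includes
        # ~0.8 deg of smooth pursuit drift across the detected window
        assert 2.5 <= sacs[0].amplitude_deg <= 4.2

    def test_anticipatory_definition_case(self):
        """2 deg jump landing 2 deg ahead of the target is anticipatory."""
        eye = inject_min_jerk(self._smooth_eye(), onset=1200, dur=50, amp=2.0)
        sacs = self._detect(eye)
        assert len(sacs) == 1
        assert sacs[0].klass == "anticipatory"

    def test_against_pursuit_direction_is_other(self):
        """A jump opposite to target motion falls in neither named class."""
        eye = inject_min_jerk(self._smooth_eye(), onset=1200, dur=50, amp=-2.0)
        sacs = self._detect(eye)
        assert len(sacs) == 1
        assert sacs[0].klass == "other"

    def test_every_saccade_gets_exactly_one_class(self, prepared_session):
        prepared, _ = prepared_session
        traces = [tr for tr, _ in prepared.values()]
        threshold = compute_saccade_threshold(traces)
        for tr, target in prepared.values():
            for s in detect_and_classify_saccades(tr, target, threshold):
                assert s.klass in ("catchup", "anticipatory", "other")

    def test_blink_overlapping_candidates_discarded(self):
        eye = inject_min_jerk(self._smooth_eye(offset=-3.0), onset=1200,
                              dur=50, amp=3.0)
        # unmasked: the saccade is found; masked mid-event: it is discarded
        assert len(self._detect(eye)) == 1
        mask = np.ones(len(self.target), dtype=bool)
        mask[1210:1230] = False
        assert self._detect(eye, mask=mask) == []


class TestRmseAndGain:
    def setup_method(self):
        self.target = generate_target_waveform(
            TargetSpec(speed_deg_s=20, initial_fixation_ms=(500, 500)), seed=3)

    def test_rmse_identity_and_constant_offset(self):
        tr = clean_trace(self.target, self.target.position_deg.copy())
        assert compute_rmse(tr, self.target) == 0.0
        tr1 = clean_trace(self.target, self.target.position_deg + 1.0)
        assert compute_rmse(tr1, self.target) == pytest.approx(1.0)

    def test_rmse_iid_noise_converges_to_sigma(self):
        rng = np.random.default_rng(4)
        tr = clean_trace(self.target,
                         self.target.position_deg + rng.normal(0, 0.5, len(self.target)))
        assert compute_rmse(tr, self.target) == pytest.approx(0.5, rel=0.02)

    def test_gain_proportional_tracking(self):
        tr = clean_trace(self.target, 0.9 * self.target.position_deg)
        assert compute_gain(tr, self.target, []) == pytest.approx(0.9, abs=0.01)

    def test_gain_frozen_eye_is_zero(self):
        tr = clean_trace(self.target, np.zeros(len(self.target)))
        assert compute_gain(tr, self.target, []) == pytest.approx(0.0, abs=0.01)

    def test_offset_changes_rmse_but_not_gain(self):
        base = clean_trace(self.target, 0.95 * self.target.position_deg)
        shifted = clean_trace(self.target, 0.95 * self.target.position_deg + 2.0)
        assert compute_gain(shifted, self.target, []) == pytest.approx(
            compute_gain(base, self.target, []), abs=1e-9)
        assert compute_rmse(shifted, self.target) > compute_rmse(base, self.target)

    def test_rmse_zero_iff_eye_equals_target(self):
        tr = clean_trace(self.target, self.target.position_deg + 1e-6)
        assert compute_rmse(tr, self.target) > 0.0


class TestSessionSummary:
    def test_null_session_phenotypes(self):
        config = SimTraceConfig(pursuit_gain_true=1.0, catchup_rate_per_s=0,
                                anticipatory_rate_per_s=0, blink_rate_per_s=0,
                                noise_sd_deg=0.1, pursuit_latency_ms=0, seed=5)
        trials, cals, _ = simulate_session(None, config)
        ph = summarize_session(trials, cals)
        assert ph.rmse_deg < 0.3          # noise floor
        assert ph.gain == pytest.approx(1.0, abs=0.05)
        # a 6-sigma relative threshold over ~3e5 samples may fire once or twice
        assert ph.catchup_per_s < 0.01 and ph.anticipatory_per_s < 0.01
        assert ph.n_trials_used == 24

    def test_gain_recovery_with_saccade_removal(self):
        config = SimTraceConfig(pursuit_gain_true=0.85, catchup_rate_per_s=1.0,
                                anticipatory_rate_per_s=0, blink_rate_per_s=0, seed=6)
        trials, cals, _ = simulate_session(None, config)
        ph = summarize_session(trials, cals)
        assert 0.80 <= ph.gain <= 0.90

    def test_session_calibration_undoes_distortion(self):
        config = SimTraceConfig(pursuit_gain_true=1.0, pursuit_latency_ms=0,
                                catchup_rate_per_s=0, anticipatory_rate_per_s=0,
                                blink_rate_per_s=0, noise_sd_deg=0.05,
                                cal_gain=1.8, cal_offset_deg=-0.7, seed=7)
        trials, cals, _ = simulate_session([TargetSpec(speed_deg_s=10)], config)
        ph = summarize_session(trials, cals)
        assert ph.rmse_deg < 0.2
        assert ph.gain == pytest.approx(1.0, abs=0.05)

    def test_rmse_monotone_in_simulated_gain(self):
        def mean_rmse(gain, seeds):
            vals = []
            for s in seeds:
                config = SimTraceConfig(pursuit_gain_true=gain, catchup_rate_per_s=0.5,
                                        anticipatory_rate_per_s=0, blink_rate_per_s=0,
                                        seed=s)
                trials, cals, _ = simulate_session(
                    [TargetSpec(speed_deg_s=20)], config)
                vals.append(summarize_session(trials, cals).rmse_deg)
            return np.mean(vals)

        assert mean_rmse(0.8, range(5)) > mean_rmse(1.0, range(5))

    def test_rate_arithmetic_and_trial_order_invariance(self, standard_session):
        trials, cals, _ = standard_session
        ph = summarize_session(trials, cals)
        reordered = list(reversed(trials))
        ph2 = summarize_session(reordered, cals)
        assert ph2.rmse_deg == pytest.approx(ph.rmse_deg)
        assert ph2.catchup_per_s == pytest.approx(ph.catchup_per_s)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            summarize_session([], [])


class TestPhenotypeCorrelations:
    def test_self_and_reversed_correlations(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        table = pd.DataFrame({"participant_id": range(50),
                              "rmse": x, "gain": -x,
                              "catchup_per_s": x, "anticipatory_per_s": x**3})
        corr, _ = correlate_phenotypes(table)
        assert corr.loc["rmse", "rmse"] == pytest.approx(1.0)
        assert corr.loc["rmse", "gain"] == pytest.approx(-1.0)
        # monotone transform preserves rank correlation
        assert corr.loc["rmse", "anticipatory_per_s"] == pytest.approx(1.0)

    def test_latent_factor_sign_pattern(self):
        """A shared latent skill factor reproduces the expected sign structure:
        RMSE-gain negative, RMSE-anticipatory positive."""
        rng = np.random.default_rng(1)
        skill = rng.normal(size=400)
        table = pd.DataFrame({
            "participant_id": range(400),
            "rmse": -0.8 * skill + rng.normal(0, 0.6, 400),
            "gain": 0.8 * skill + rng.normal(0, 0.6, 400),
            "catchup_per_s": 0.5 * skill + rng.normal(0, 0.8, 400),
            "anticipatory_per_s": -0.6 * skill + rng.normal(0, 0.8, 400),
        })
        corr, _ = correlate_phenotypes(table)
        assert corr.loc["rmse", "gain"] < -0.3
        assert corr.loc["rmse", "anticipatory_per_s"] > 0.2
        assert corr.loc["gain", "anticipatory_per_s"] < -0.2

    def test_retest_reliability_detects_stable_trait(self):
        rng = np.random.default_rng(2)
        trait = rng.normal(size=100)
        def session(noise_seed):
            r = np.random.default_rng(noise_seed)
            return pd.DataFrame({
                "participant_id": range(100),
                "rmse": trait + r.normal(0, 0.4, 100),
                "gain": -trait + r.normal(0, 0.4, 100),
                "catchup_per_s": trait + r.normal(0, 0.4, 100),
                "anticipatory_per_s": trait + r.normal(0, 0.4, 100)})
        _, rel = correlate_phenotypes(session(3), session(4))
        assert (rel > 0.6).all()

    def test_too_few_pairs_rejected(self):
        table = pd.DataFrame({"participant_id": [1, 2], "rmse": [1, 2],
                              "gain": [1, 2], "catchup_per_s": [1, 2],
                              "anticipatory_per_s": [1, 2]})
        with pytest.raises(ValueError):
            correlate_phenotypes(table)
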