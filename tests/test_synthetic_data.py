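"""Simulator: calibration, hypnogram chain, cardiac/motion/thermal forward models."""

import numpy as np
import pytest

from somnostage.io_model import Recording, StageLabel, ValidationError, compute_sleep_metrics
from somnostage.synthetic_data import (
    DEFAULT_MEAN_BOUT_EPOCHS,
    STAGE_ORDER,
    REFERENCE_SLEEP_EFFICIENCY,
    REFERENCE_STAGE_PERCENT,
    SimConfig,
    calibrate_transition_matrix,
    generate_cohort,
    simulate_accelerometer,
    simulate_actigraph,
    simulate_hypnogram,
    simulate_rr_series,
    simulate_temperature,
    synthesize_ecg,
)

from conftest import quiet_config


def stationary(P):
    w, V = np.linalg.eig(P.T)
    pi = np.real(V[:, np.argmin(np.abs(w - 1))])
    return pi / pi.sum()


ALL_STAGES = ("W", "N1", "N2", "SWS", "REM")


def flat_map(value):
    return {s: float(value) for s in ALL_STAGES}


class TestCalibration:
    def test_uniform_targets_give_uniform_stationary(self):
        P = calibrate_transition_matrix(
            {"N1": 25, "N2": 25, "SWS": 25, "REM": 25},
            100.0,
            {"W": 2, "N1": 4, "N2": 4, "SWS": 4, "REM": 4},
            expected_onset_min=0,
        )
        pi = stationary(P)
        assert np.abs(pi[1:] - 0.25).max() < 1e-6
        assert pi[0] == pytest.approx(0.0, abs=1e-9)

    def test_architecture_targets_hit_stationary_ratio(self):
        P = calibrate_transition_matrix(
            REFERENCE_STAGE_PERCENT, REFERENCE_SLEEP_EFFICIENCY, DEFAULT_MEAN_BOUT_EPOCHS
        )
        pi = stationary(P)
        sleep = pi[1:] / pi[1:].sum()
        # targets are renormalized (printed values sum to 99.9)
        total = sum(REFERENCE_STAGE_PERCENT.values())
        assert sleep[1] == pytest.approx(REFERENCE_STAGE_PERCENT["N2"] / total, abs=1e-6)
        assert sleep[2] == pytest.approx(REFERENCE_STAGE_PERCENT["SWS"] / total, abs=1e-6)

    def test_mean_bout_sets_diagonal(self):
        """Geometric bout-length identity: mean bout 10 epochs -> p_stay 0.9."""
        P = calibrate_transition_matrix(
            REFERENCE_STAGE_PERCENT,
            REFERENCE_SLEEP_EFFICIENCY,
            {"W": 2, "N1": 2, "N2": 10, "SWS": 8, "REM": 8},
        )
        assert P[2, 2] == pytest.approx(0.9, abs=1e-12)

    def test_rem_reachable_only_from_n2_by_default(self):
        P = calibrate_transition_matrix(
            REFERENCE_STAGE_PERCENT, REFERENCE_SLEEP_EFFICIENCY, DEFAULT_MEAN_BOUT_EPOCHS
        )
        rem = STAGE_ORDER.index("REM")
        for s in ("W", "N1", "SWS"):
            assert P[STAGE_ORDER.index(s), rem] == 0.0
        assert P[STAGE_ORDER.index("N2"), rem] > 0.0

    def test_infeasible_bout_raises(self):
        with pytest.raises(ValidationError):
            calibrate_transition_matrix(
                REFERENCE_STAGE_PERCENT,
                REFERENCE_SLEEP_EFFICIENCY,
                {"W": 0.5, "N1": 2, "N2": 6, "SWS": 8, "REM": 8},
            )


class TestHypnogram:
    def test_identity_matrix_absorbs_initial_wake(self):
        cfg = SimConfig(
            transition_matrix=np.eye(5), sol_mean_min=None, duration=0.5, seed=1
        )
        hyp = simulate_hypnogram(cfg)
        assert all(s is StageLabel.W for s in hyp.epoch_labels)

    def test_absorbing_n2_dominates_long_nights(self):
        P = np.zeros((5, 5))
        P[:, 2] = 1.0  # every state jumps to N2, N2 absorbs
        cfg = SimConfig(transition_matrix=P, sol_mean_min=None, duration=8.0, seed=2)
        hyp = simulate_hypnogram(cfg)
        frac = np.mean([s is StageLabel.N2 for s in hyp.epoch_labels])
        assert frac > 0.99

    def test_non_stochastic_matrix_rejected(self):
        bad = np.eye(5) * 0.9
        with pytest.raises(ValidationError):
            simulate_hypnogram(SimConfig(transition_matrix=bad, seed=0))

    def test_deterministic_under_seed(self):
        a = simulate_hypnogram(SimConfig(seed=7))
        b = simulate_hypnogram(SimConfig(seed=7))
        assert a.epoch_labels == b.epoch_labels

    def test_stationary_convergence_of_stage_fractions(self):
        """Empirical post-onset stage fractions over many nights approach the
        calibrated stationary distribution (KL divergence < 0.01)."""
        counts = np.zeros(5)
        pi = None
        for s in range(60):
            cfg = SimConfig(seed=4000 + s)
            if pi is None:
                pi = stationary(cfg.transition_matrix)
            hyp = simulate_hypnogram(cfg)
            labels = hyp.as_array()
            onset = next(i for i, l in enumerate(labels) if l != "W")
            for l in labels[onset:]:
                counts[STAGE_ORDER.index(l)] += 1
        emp = counts / counts.sum()
        kl = float(np.sum(np.where(pi > 0, pi * np.log(pi / np.maximum(emp, 1e-12)), 0)))
        assert kl < 0.01


class TestRRSeries:
    def test_noiseless_constant_hr_gives_constant_rr(self):
        cfg = quiet_config(
            stage_hr_mean=flat_map(60.0),
            stage_hr_sd=flat_map(0.0),
            stage_lf_amp=flat_map(0.0),
            stage_hf_amp=flat_map(0.0),
        )
        hyp = simulate_hypnogram(cfg)
        peaks = simulate_rr_series(hyp, cfg)
        rr = np.diff(peaks) * 1000.0
        np.testing.assert_allclose(rr, 1000.0, atol=1e-9)

    def test_stage_hr_sets_mean_rr(self):
        """SWS heart rate 55 bpm -> mean RR over SWS epochs ~ 1090.9 ms."""
        P = np.zeros((5, 5))
        P[:, 3] = 1.0  # everything goes straight to SWS
        cfg = quiet_config(
            transition_matrix=P,
            initial_stage="SWS",
            duration=1.0,
            stage_hr_sd=flat_map(1.0),
            stage_lf_amp=flat_map(0.0),
            stage_hf_amp=flat_map(0.0),
        )
        hyp = simulate_hypnogram(cfg)
        peaks = simulate_rr_series(hyp, cfg)
        rr = np.diff(peaks) * 1000.0
        assert np.mean(rr) == pytest.approx(60000.0 / 55.0, abs=3.0)

    def test_rr_within_physiologic_bounds(self):
        cfg = SimConfig(duration=2.0, ecg_rate=250.0, seed=13)
        hyp = simulate_hypnogram(cfg)
        peaks = simulate_rr_series(hyp, cfg)
        rr = np.diff(peaks) * 1000.0
        assert rr.min() > 300.0 and rr.max() < 2000.0

    def test_determinism(self):
        cfg = SimConfig(duration=0.5, seed=9)
        hyp = simulate_hypnogram(cfg)
        np.testing.assert_array_equal(
            simulate_rr_series(hyp, cfg), simulate_rr_series(hyp, cfg)
        )


class TestECG:
    def test_noiseless_channel_peaks_at_true_r_times(self):
        cfg = quiet_config(duration=1.0 / 30.0, ecg_rate=1000.0)
        hyp = simulate_hypnogram(cfg)
        peaks = simulate_rr_series(hyp, cfg)
        channels, gt = synthesize_ecg(peaks, cfg)
        assert len(gt.r_peak_times) == len(peaks)
        v = channels[1].values
        t = channels[1].timestamps
        for p in peaks[1:-1]:
            sel = (t > p - 0.15) & (t < p + 0.15)
            tmax = t[sel][np.argmax(v[sel])]
            assert abs(tmax - p) <= 0.002

    def test_empty_peaks_give_noise_only_channel(self):
        cfg = quiet_config(duration=1.0 / 60.0, ecg_noise_sd=0.01)
        channels, gt = synthesize_ecg(np.empty(0), cfg)
        assert len(gt.r_peak_times) == 0
        assert np.abs(channels[0].values).max() < 1.0  # no QRS-sized excursions

    def test_zero_artifact_rate_records_no_windows(self):
        cfg = quiet_config(duration=1.0 / 60.0)
        _, gt = synthesize_ecg(np.array([0.5, 1.5]), cfg)
        assert all(len(w) == 0 for w in gt.artifact_windows.values())


class TestAccelerometer:
    def test_no_bursts_leaves_only_noise_floor(self):
        cfg = quiet_config(
            movement_burst_rate=flat_map(0.0), accel_noise_sd=0.001, duration=0.25
        )
        hyp = simulate_hypnogram(cfg)
        nd, _ = simulate_accelerometer(hyp, cfg)
        from somnostage.align import per_second_activity

        _, residuals = per_second_activity(nd)
        assert residuals.max() == 0.0  # below the dead-band everywhere

    def test_wake_movement_exceeds_sws_movement(self):
        P = np.eye(5)
        labels = ["W"] * 30 + ["SWS"] * 30
        from conftest import make_hypnogram

        cfg = quiet_config(accel_noise_sd=0.003, seed=17)
        hyp = make_hypnogram(labels)
        nd, _ = simulate_accelerometer(hyp, cfg)
        from somnostage.preprocess import highpass_filter

        filtered = highpass_filter(nd, cutoff=1.0, order=5)
        var_w = filtered.values[: len(filtered.values) // 2].var()
        var_s = filtered.values[len(filtered.values) // 2 :].var()
        assert var_w > var_s

    def test_determinism(self):
        cfg = quiet_config(duration=0.25, seed=19)
        hyp = simulate_hypnogram(cfg)
        a = simulate_accelerometer(hyp, cfg)[0]
        b = simulate_accelerometer(hyp, cfg)[0]
        np.testing.assert_array_equal(a.values, b.values)


class TestTemperature:
    def test_degenerate_dynamics_are_constant(self):
        cfg = quiet_config(dpg_rise=0.0, temp_proximal_swing=0.0, duration=1.0)
        hyp = simulate_hypnogram(cfg)
        chans = simulate_temperature(hyp, cfg)
        for ch in chans:
            base = (
                cfg.temp_distal_base
                if ch.location in ("hand_nd", "hand_d", "ankle_nd", "ankle_d")
                else cfg.temp_proximal_base
            )
            np.testing.assert_allclose(ch.values, base, atol=1e-9)

    def test_distal_rise_approaches_asymptote(self):
        """With a 20-min time constant, 90 min after onset the distal rise
        exceeds 1 - exp(-90/20) > 0.98 of its 2 degC asymptote."""
        from conftest import make_hypnogram

        hyp = make_hypnogram(["W"] * 10 + ["N2"] * 230)
        cfg = quiet_config(dpg_rise=2.0, temp_tau=20.0, temp_proximal_swing=0.0)
        chans = simulate_temperature(hyp, cfg)
        hand = next(c for c in chans if c.location == "hand_nd")
        onset_t = 10 * 30.0
        at_90 = hand.values[np.searchsorted(hand.timestamps, onset_t + 90 * 60.0)]
        assert at_90 - cfg.temp_distal_base >= 1.9

    def test_dpg_rises_after_sleep_onset(self):
        from conftest import make_hypnogram

        hyp = make_hypnogram(["W"] * 60 + ["N2"] * 120)
        cfg = quiet_config()
        chans = simulate_temperature(hyp, cfg)
        distal = np.mean(
            [c.values for c in chans if c.location.startswith(("hand", "ankle"))], axis=0
        )
        proximal = np.mean(
            [c.values for c in chans if not c.location.startswith(("hand", "ankle"))],
            axis=0,
        )
        dpg = distal - proximal
        t = chans[0].timestamps
        pre = dpg[t < 30 * 60.0].mean()
        post = dpg[(t >= 30 * 60.0) & (t < 90 * 60.0)].mean()
        assert post > pre


class TestActigraph:
    def test_single_burst_lands_in_its_epoch(self):
        from conftest import make_hypnogram
        from somnostage.io_model import ChannelSeries

        rate = 62.5
        n = int(rate * 300)
        t = np.arange(n) / rate
        vals = np.zeros((n, 3))
        vals[:, 2] = 1.0  # gravity
        burst = (t > 7 * 30.0 + 10) & (t < 7 * 30.0 + 11)
        vals[burst, 0] += 0.5 * np.sin(2 * np.pi * 5.0 * t[burst])
        accel = ChannelSeries(t, vals, rate, "wrist_nd", "accel")
        cfg = quiet_config(actigraph_offset=0.0)
        counts, _ = simulate_actigraph(accel, cfg)
        nonzero = np.nonzero(counts.values)[0]
        assert list(nonzero) == [7]

    def test_offset_recorded_in_ground_truth(self):
        cfg = quiet_config(actigraph_offset=37.0, duration=0.25)
        hyp = simulate_hypnogram(cfg)
        nd, _ = simulate_accelerometer(hyp, cfg)
        _, lags = simulate_actigraph(nd, cfg)
        assert lags == {"actigraph": 37.0}


class TestCohort:
    def test_cohort_size_and_distinct_ids(self):
        cfg = SimConfig(duration=0.25, ecg_rate=250.0, seed=23)
        cohort = generate_cohort(cfg, 11)
        assert len(cohort) == 11
        assert len({r.subject_id for r in cohort}) == 11

    def test_cohort_determinism(self, small_cohort):
        cfg = SimConfig(duration=1.0, ecg_rate=250.0, seed=5)
        again = generate_cohort(cfg, 2)
        for a, b in zip(small_cohort, again):
            assert a.subject_id == b.subject_id
            assert a.hypnogram.epoch_labels == b.hypnogram.epoch_labels
            np.testing.assert_array_equal(
                a.ground_truth.r_peak_times, b.ground_truth.r_peak_times
            )
            np.testing.assert_array_equal(
                a.channel("chest_2", "ecg").values, b.channel("chest_2", "ecg").values
            )

    def test_every_recording_passes_domain_validation(self, small_cohort):
        for rec in small_cohort:
            # re-building the Recording re-runs all invariant checks
            Recording(
                subject_id=rec.subject_id,
                channels=rec.channels,
                hypnogram=rec.hypnogram,
                ground_truth=rec.ground_truth,
            )

    def test_single_subject_boundary(self):
        cfg = SimConfig(duration=0.25, ecg_rate=250.0, seed=29)
        cohort = generate_cohort(cfg, 1)
        assert len(cohort) == 1
        with pytest.raises(ValidationError):
            generate_cohort(cfg, 0)
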