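"""Reflex detector: background stats, burst finding, phases, AUC, windows."""

import numpy as np
import pytest

from nwreflex import detect, preprocess, synth
from nwreflex.signal_io import DetectionConfig, EMGEpoch
from conftest import noise_epoch


def flat_epoch(ta=None, so=None, n=3501):
    z = np.zeros(n)
    return EMGEpoch(participant_id="T", trial_index=0, site="FS",
                    energy_mJ=600.0, sampling_rate_Hz=1000.0,
                    t0_offset_ms=-500.0,
                    samples_TA=z if ta is None else ta,
                    samples_SO=z if so is None else so)


def plant_rect(epoch_arr, start_ms, stop_ms, amp):
    i0, i1 = int(start_ms) + 500, int(stop_ms) + 500
    epoch_arr[i0:i1] = amp
    return epoch_arr


class TestBackground:
    def test_constant_value(self, det_cfg):
        ep = flat_epoch(ta=np.full(3501, 3.0))
        bg = detect.estimate_background(ep, "TA", det_cfg)
        assert bg.mu_bg_uV == pytest.approx(3.0)
        assert bg.sigma_bg_uV == pytest.approx(0.0)
        assert bg.window_ms == (-500.0, 0.0)

    def test_folded_normal_sigma(self, det_cfg):
        # rectified N(0, s^2) has SD s*sqrt(1 - 2/pi)
        s = 10.0
        rng = np.random.default_rng(7)
        ta = rng.normal(0, s, 3501)
        bg = detect.estimate_background(flat_epoch(ta=ta), "TA", det_cfg)
        assert bg.sigma_bg_uV == pytest.approx(s * np.sqrt(1 - 2 / np.pi),
                                               rel=0.15)

    def test_artifact_invalidates_trial(self, det_cfg):
        rng = np.random.default_rng(8)
        ta = rng.normal(0, 100.0, 3501)  # sigma_bg >> 30 uV cap
        d = detect.detect_trial(flat_epoch(ta=ta), det_cfg)
        assert not d.valid and d.events == []


class TestDetectBursts:
    def test_all_below_threshold(self, det_cfg):
        ep = flat_epoch()
        bg = detect.BackgroundStats(0.8, 1.0, (-500.0, 0.0))
        assert detect.detect_bursts(np.zeros(3501), ep, bg, det_cfg) == []

    def test_planted_rectangular_burst_onset(self, det_cfg):
        rng = np.random.default_rng(9)
        raw = np.abs(rng.normal(0, 1.0, 3501))
        bg = detect.BackgroundStats(float(raw[:500].mean()),
                                    float(raw[:500].std()), (-500.0, 0.0))
        plant_rect(raw, 200, 300, 10 * bg.sigma_bg_uV)
        ep = flat_epoch()
        bursts = detect.detect_bursts(raw, ep, bg, det_cfg)
        assert len(bursts) == 1
        assert 195 <= bursts[0][0] <= 210

    def test_merge_rule(self, det_cfg):
        x = np.zeros(3501)
        plant_rect(x, 200, 240, 50.0)
        plant_rect(x, 260, 300, 50.0)  # 20 ms gap < 50 ms merge gap
        bg = detect.BackgroundStats(0.0, 1.0, (-500.0, 0.0))
        bursts = detect.detect_bursts(x, flat_epoch(), bg, det_cfg)
        assert len(bursts) == 1
        assert bursts[0][0] == pytest.approx(200, abs=2)
        assert bursts[0][1] == pytest.approx(300, abs=2)

    def test_restricted_to_post_stimulus(self, det_cfg):
        x = np.zeros(3501)
        x[:400] = 50.0  # pre-stimulus activity only
        bg = detect.BackgroundStats(0.0, 1.0, (-500.0, 0.0))
        assert detect.detect_bursts(x, flat_epoch(), bg, det_cfg) == []

    def test_threshold_monotonicity(self):
        # raising the SD multiplier never increases the burst count
        for seed in range(5):
            ep = noise_epoch(seed)
            rect = np.abs(ep.samples_TA)
            rect += synth.simulate_burst(
                300, 150, 12.0, 4, np.random.default_rng(seed))
            counts = []
            for k in (1.0, 1.5, 2.0, 3.0, 5.0):
                cfg = DetectionConfig(threshold_sd_multiplier=k)
                bg = detect.estimate_background(ep, "TA", cfg)
                counts.append(len(detect.detect_bursts(rect, ep, bg, cfg)))
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_translation_consistency(self, det_cfg, pre_cfg):
        onsets = []
        for shift in (0.0, 100.0):
            rng = np.random.default_rng(11)
            ep = noise_epoch(11)
            ep.samples_TA = ep.samples_TA + synth.simulate_burst(
                400 + shift, 200, 100.0, 5, rng)
            filt = preprocess.preprocess_epoch(ep, pre_cfg)
            d = detect.detect_trial(filt, det_cfg)
            ta = [e for e in d.events if e.muscle == "TA"]
            assert ta, f"burst not found at shift {shift}"
            onsets.append(min(e.onset_ms for e in ta))
        assert onsets[1] - onsets[0] == pytest.approx(100.0, abs=2.0)


class TestCountPhases:
    def test_positive_half_wave(self, det_cfg):
        x = np.zeros(3501)
        t = np.arange(100) / 100
        x[700:800] = 20 * np.sin(np.pi * t)
        n = detect.count_phases(x, flat_epoch(), (200.0, 300.0), 10.0, det_cfg)
        assert n == 1

    def test_full_sine_cycle(self, det_cfg):
        x = np.zeros(3501)
        t = np.arange(100) / 100
        x[700:800] = 20 * np.sin(2 * np.pi * t)
        n = detect.count_phases(x, flat_epoch(), (200.0, 300.0), 10.0, det_cfg)
        assert n == 2

    def test_sub_floor_excursions_ignored(self, det_cfg):
        x = np.zeros(3501)
        t = np.arange(100) / 100
        x[700:800] = 2.0 * np.sin(2 * np.pi * t)  # below 0.5 * T = 5
        assert detect.count_phases(x, flat_epoch(), (200.0, 300.0), 10.0,
                                   det_cfg) == 0

    @pytest.mark.parametrize("n_phases", [3, 5])
    def test_generator_contract(self, det_cfg, n_phases):
        rng = np.random.default_rng(13)
        b = synth.simulate_burst(200, 150, 100.0, n_phases, rng)
        n = detect.count_phases(b, flat_epoch(), (200.0, 350.0), 20.0, det_cfg)
        assert n >= n_phases
        assert n >= det_cfg.min_phases


class TestCharacterize:
    def test_rectangular_auc_analytic(self, det_cfg):
        x = np.zeros(3501)
        plant_rect(x, 200, 500, 50.0)  # 50 uV for 0.3 s
        bg = detect.BackgroundStats(0.0, 1.0, (-500.0, 0.0))
        ev = detect.characterize(x, flat_epoch(), (200.0, 500.0), bg)
        assert ev.auc_uVs == pytest.approx(15.0, rel=1e-6)
        assert ev.peak_uV == pytest.approx(50.0)

    def test_auc_equals_riemann_oracle(self, det_cfg):
        rng = np.random.default_rng(14)
        x = np.abs(rng.normal(0, 20, 3501))
        bg = detect.BackgroundStats(5.0, 2.0, (-500.0, 0.0))
        ev = detect.characterize(x, flat_epoch(), (250.0, 800.0), bg)
        # independent brute-force Riemann sum over the same samples
        oracle = sum(max(v - 5.0, 0.0) * 1e-3 for v in x[750:1300])
        assert ev.auc_uVs == pytest.approx(oracle, abs=1e-9)

    def test_simulator_burst_auc_vs_template_integral(self, det_cfg):
        rng = np.random.default_rng(15)
        b = synth.simulate_burst(1200, 300, 200.0, 5, rng)
        rect = np.abs(b)
        bg = detect.BackgroundStats(0.0, 1.0, (-500.0, 0.0))
        ev = detect.characterize(rect, flat_epoch(), (1200.0, 1500.0), bg)
        oracle = np.trapezoid(rect, dx=1e-3)
        assert ev.auc_uVs == pytest.approx(oracle, rel=0.1)


class TestAssignWindow:
    @pytest.mark.parametrize("onset,expected", [
        (187.0, "TW1"), (1460.0, "TW2"), (800.0, "intermediate"),
        (90.0, "TW1"), (599.9, "TW1"), (600.0, "intermediate"),
        (1000.0, "TW2"), (3000.0, "TW2"), (50.0, "none"),
    ])
    def test_boundaries(self, det_cfg, onset, expected):
        assert detect.assign_window(onset, det_cfg) == expected


class TestDetectTrial:
    def test_noise_only_mostly_clean(self, det_cfg, pre_cfg):
        fp = 0
        for seed in range(40):
            ep = preprocess.preprocess_epoch(noise_epoch(100 + seed), pre_cfg)
            d = detect.detect_trial(ep, det_cfg)
            assert d.valid
            fp += bool(d.events)
        assert fp <= 2  # <= 5 % of 40 noise trials

    def test_coactivation_flagged(self, det_cfg, pre_cfg):
        rng = np.random.default_rng(16)
        ep = noise_epoch(16)
        ep.samples_TA = ep.samples_TA + synth.simulate_burst(
            1200, 250, 500.0, 5, rng)
        ep.samples_SO = ep.samples_SO + synth.simulate_burst(
            1220, 250, 500.0, 5, rng)
        d = detect.detect_trial(preprocess.preprocess_epoch(ep, pre_cfg),
                                det_cfg)
        assert "TW2" in d.coactivated_tw

    def test_far_apart_not_coactivated(self, det_cfg, pre_cfg):
        rng = np.random.default_rng(17)
        ep = noise_epoch(17)
        ep.samples_TA = ep.samples_TA + synth.simulate_burst(
            1100, 200, 500.0, 5, rng)
        ep.samples_SO = ep.samples_SO + synth.simulate_burst(
            2500, 200, 500.0, 5, rng)
        d = detect.detect_trial(preprocess.preprocess_epoch(ep, pre_cfg),
                                det_cfg)
        assert "TW2" not in d.coactivated_tw

    def test_events_frame_round_trip_columns(self, small_detections):
        df = detect.detections_to_frame(small_detections)
        assert {"participant_id", "site", "trial_index", "muscle", "onset_ms",
                "window", "auc_uVs", "valid"} <= set(df.columns)
        with_events = df[df.muscle != ""]
        assert (with_events.n_phases >= 3).all()
        assert with_events.onset_ms.between(0, 3000).all()
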