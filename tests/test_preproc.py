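"""Preprocessing stages: exclusion rules, OD, motion handling, filtering,
Beer-Lambert inversion and epoching."""

import numpy as np
import pandas as pd
import pytest

from dyadnirs.beer_lambert import conc_to_od
from dyadnirs.preproc import (
    PreprocConfig,
    bandpass,
    build_epochs,
    detect_motion,
    filter_trials_by_looking,
    heart_rate_check,
    intensity_to_od,
    mask_to_segments,
    meets_min_trials,
    od_to_concentration,
    preprocess,
    prune_channels,
    reject_contaminated_trials,
    wavelet_correct,
)
from dyadnirs.synthetic import (
    MotionConfig,
    NirsSimConfig,
    NoiseConfig,
    roi_montage,
    simulate_nirs,
)
from dyadnirs.types import Montage, NirsRecording


def _recording(intensity, fs=7.8125, n_trials=4, looking=None):
    n_ch = intensity.shape[0]
    chans = np.array(sorted([8, 9, 13, 14, 23, 24, 28, 29]))[:n_ch]
    montage = Montage(
        pd.DataFrame(
            {
                "channel": chans,
                "source": 1,
                "detector": np.arange(n_ch) + 1,
                "distance_mm": 22.5,
                "hemisphere": ["right"] * n_ch,
            }
        )
    )
    onsets = 12.0 + 27.0 * np.arange(n_trials)
    markers = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "condition": ["contingent", "noncontingent"] * (n_trials // 2),
            "baseline_onset_s": onsets - 12.0,
            "onset_s": onsets,
        }
    )
    if looking is None:
        looking = pd.DataFrame(
            {
                "trial": np.arange(n_trials),
                "frac_trial_looking": np.ones(n_trials),
                "frac_brush_looking": np.ones(n_trials),
            }
        )
    return NirsRecording(
        intensity=intensity, fs=fs, montage=montage, markers=markers, looking=looking
    )


class TestLookingFilter:
    def test_strict_trial_threshold_and_lenient_brush_threshold(self):
        looking = pd.DataFrame(
            {
                "trial": [0, 1, 2, 3],
                "frac_trial_looking": [0.49, 1.0, 0.50, 0.51],
                "frac_brush_looking": [1.0, 1.0, 1.0, 0.50],
            }
        )
        rec = _recording(np.full((2, 2, 1200), 0.5), looking=looking)
        mask = filter_trials_by_looking(rec)
        # >50% trial looking is strict; =50% fails. >=50% brush looking passes.
        assert mask.tolist() == [False, True, False, True]

    def test_missing_looking_row_invalidates_with_warning(self):
        looking = pd.DataFrame(
            {"trial": [0, 1, 2], "frac_trial_looking": [1, 1, 1],
             "frac_brush_looking": [1, 1, 1]}
        )
        rec = _recording(np.full((2, 2, 1200), 0.5), looking=looking)
        with pytest.warns(UserWarning):
            mask = filter_trials_by_looking(rec)
        assert mask.tolist() == [True, True, True, False]

    def test_minimum_trials_per_condition(self):
        markers = pd.DataFrame(
            {"trial": range(10),
             "condition": ["contingent"] * 5 + ["noncontingent"] * 5}
        )
        mask = np.array([True] * 5 + [True, True, False, False, False])
        assert not meets_min_trials(mask, markers, 3)
        mask[7] = True
        assert meets_min_trials(mask, markers, 3)


class TestChannelPruning:
    def test_range_and_snr_rules(self):
        rng = np.random.default_rng(0)
        n_t = 1000
        good = 0.5 + 0.01 * rng.standard_normal(n_t)        # kept
        low = np.full(n_t, 0.05)                            # out of range
        noisy = 0.5 + 0.6 * rng.standard_normal(n_t)        # SNR < 0 dB
        intensity = np.stack(
            [np.stack([good, good]), np.stack([low, good]), np.stack([good, noisy])]
        )
        rec = _recording(intensity)
        keep = prune_channels(rec)
        assert keep.tolist() == [True, False, False]

    def test_snr_boundary_value(self):
        # mean 0.5 V, SD 0.6 V -> 20 log10(0.5/0.6) = -1.58 dB -> dropped
        assert 20 * np.log10(0.5 / 0.6) < 0


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        od = intensity_to_od(np.full((1, 2, 100), 0.7))
        assert np.allclose(od, 0.0)

    def test_definition_elementwise(self):
        rng = np.random.default_rng(1)
        intensity = rng.uniform(0.2, 0.9, size=(2, 2, 500))
        od = intensity_to_od(intensity)
        expected = -np.log(intensity / intensity.mean(axis=-1, keepdims=True))
        assert np.allclose(od, expected)

    def test_nonpositive_sample_rejected_with_channel_named(self):
        intensity = np.full((1, 2, 100), 0.5)
        intensity[0, 1, 3] = 0.0
        with pytest.raises(ValueError, match="channel"):
            intensity_to_od(intensity)


class TestMotionDetection:
    def test_large_step_flagged_small_sinusoid_not(self):
        fs = 7.8125
        t = np.arange(0, 120, 1 / fs)
        clean = 0.01 * np.sin(2 * np.pi * 0.3 * t)
        stepped = clean.copy()
        stepped[500:] += 0.45  # 0.45 OD step
        od = np.stack([np.stack([stepped, stepped]), np.stack([clean, clean])])
        mask = detect_motion(od, fs)
        assert mask[0].any()
        assert mask[0][498:504].any()
        assert not mask[1].any()

    def test_injected_spikes_detected(self):
        hits = total = 0
        for seed in (6, 16, 26):
            cfg = NirsSimConfig(seed=seed, n_trials_per_condition=4,
                                motion=MotionConfig(spikes_per_minute=1.0))
            rec = simulate_nirs(cfg, roi_montage())
            od = intensity_to_od(rec.intensity)
            mask = detect_motion(od, rec.fs)
            t = rec.times
            for ci, spikes in enumerate(rec.ground_truth["spikes"]):
                for sp in spikes:
                    if sp["amp_od"] < 0.4:  # below the detection contract
                        continue
                    total += 1
                    hits += mask[ci, (t > sp["t_s"] - 1) & (t < sp["t_s"] + 1)].any()
        assert total > 30
        assert hits / total >= 0.95

    def test_mask_to_segments(self):
        mask = np.array([0, 1, 1, 0, 0, 1, 0], bool)
        assert mask_to_segments(mask) == [(1, 3), (5, 6)]


class TestWaveletCorrection:
    def test_zero_signal_unchanged(self):
        od = np.zeros((1, 2, 512))
        out = wavelet_correct(od, np.ones((1, 512), bool), 7.8125)
        assert np.allclose(out, 0.0)

    def test_clean_channels_pass_through_untouched(self):
        rng = np.random.default_rng(2)
        od = rng.normal(0, 0.001, (2, 2, 512))
        mask = np.zeros((2, 512), bool)
        mask[0, 100] = True
        out = wavelet_correct(od, mask, 7.8125)
        assert np.array_equal(out[1], od[1])
        assert not np.array_equal(out[0], od[0])

    def test_hrf_band_signal_nearly_preserved(self):
        cfg = NirsSimConfig(seed=7, n_trials_per_condition=6,
                            noise=NoiseConfig.zero(), looking_dist=(1, 0))
        rec = simulate_nirs(cfg, roi_montage())
        od = intensity_to_od(rec.intensity)
        out = wavelet_correct(od, np.ones(od.shape[::2], bool), rec.fs)
        rel = np.sqrt(((out - od) ** 2).mean(-1)) / np.sqrt((od**2).mean(-1))
        assert rel.max() < 0.05

    def test_spike_amplitude_reduced_in_flagged_windows(self):
        cfg = NirsSimConfig(seed=8, n_trials_per_condition=4,
                            motion=MotionConfig(spikes_per_minute=1.5))
        rec = simulate_nirs(cfg, roi_montage())
        od = intensity_to_od(rec.intensity)
        mask = detect_motion(od, rec.fs)
        out = wavelet_correct(od, mask, rec.fs)
        t = rec.times
        for ci, spikes in enumerate(rec.ground_truth["spikes"]):
            for sp in spikes:
                t0 = sp["t_s"]
                sel = (t > t0 - 1) & (t < t0 + 1)
                assert np.ptp(out[ci, 0, sel]) < np.ptp(od[ci, 0, sel])


class TestHeartRateCheck:
    def test_cardiac_sinusoid_passes_white_noise_fails(self):
        fs = 7.8125
        rng = np.random.default_rng(3)
        t = np.arange(0, 300, 1 / fs)
        cardiac = 0.01 * np.sin(2 * np.pi * 2.5 * t) + 0.0005 * rng.standard_normal(len(t))
        noise = 0.001 * rng.standard_normal(len(t))
        od = np.stack([np.stack([cardiac, cardiac]), np.stack([noise, noise])])
        passed = heart_rate_check(od, fs)
        assert passed.tolist() == [True, False]

    def test_zero_cardiac_amplitude_fails_everywhere(self):
        noise = NoiseConfig(cardiac_amp_um=0.0)
        cfg = NirsSimConfig(seed=9, n_trials_per_condition=3, noise=noise)
        rec = simulate_nirs(cfg, roi_montage())
        od = intensity_to_od(rec.intensity)
        assert not heart_rate_check(od, rec.fs).any()

    def test_default_simulation_passes(self):
        cfg = NirsSimConfig(seed=10, n_trials_per_condition=3)
        rec = simulate_nirs(cfg, roi_montage())
        od = intensity_to_od(rec.intensity)
        assert heart_rate_check(od, rec.fs).all()


class TestTrialRejection:
    def test_artifact_in_baseline_rejects_trial(self):
        fs = 7.8125
        n_t = int(4 * 27 * fs) + 100
        mask = np.zeros((1, n_t), bool)
        onsets = 12.0 + 27.0 * np.arange(4)
        markers = pd.DataFrame(
            {"trial": range(4), "condition": ["contingent", "noncontingent"] * 2,
             "baseline_onset_s": onsets - 12, "onset_s": onsets}
        )
        mask[0, int((onsets[2] - 5) * fs)] = True  # inside baseline of trial 2
        keep = reject_contaminated_trials(mask, markers, fs)
        assert keep.tolist() == [True, True, False, True]
        cfg = PreprocConfig(reject_span="trial")
        keep2 = reject_contaminated_trials(mask, markers, fs, cfg=cfg)
        assert keep2.all()

    def test_clean_recording_keeps_all_trials(self):
        fs = 7.8125
        onsets = 12.0 + 27.0 * np.arange(2)
        markers = pd.DataFrame(
            {"trial": range(2), "condition": ["contingent", "noncontingent"],
             "baseline_onset_s": onsets - 12, "onset_s": onsets}
        )
        keep = reject_contaminated_trials(np.zeros((1, 600), bool), markers, fs)
        assert keep.all()


class TestBandpass:
    def test_dc_removed_passband_kept_stopband_attenuated(self):
        fs = 7.8125
        t = np.arange(0, 600, 1 / fs)
        for freq, expect_kept in ((0.1, True), (2.5, False)):
            x = np.sin(2 * np.pi * freq * t) + 5.0
            y = bandpass(x[None, None, :], fs)[0, 0]
            mid = slice(len(t) // 4, -len(t) // 4)
            amp = np.ptp(y[mid]) / 2
            if expect_kept:
                assert amp == pytest.approx(1.0, rel=0.05)
            else:
                assert amp < 0.05
            assert abs(y[mid].mean()) < 0.01

    def test_sampling_rate_guard(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((1, 1, 100)), fs=1.5, high=1.0)


class TestBeerLambert:
    def test_zero_od_zero_concentration(self):
        hbo, hbr = od_to_concentration(np.zeros((1, 2, 50)), _recording(np.full((1, 2, 50), 0.5)).montage)
        assert np.allclose(hbo, 0) and np.allclose(hbr, 0)

    def test_inverse_of_forward(self):
        rng = np.random.default_rng(4)
        hbo = rng.normal(0, 0.3, 200)
        hbr = rng.normal(0, 0.1, 200)
        od = conc_to_od(hbo, hbr, 22.5, 5.1)
        rec = _recording(np.full((1, 2, 200), 0.5))
        hbo2, hbr2 = od_to_concentration(od[None], rec.montage)
        assert np.abs(hbo2[0] - hbo).max() < 1e-10
        assert np.abs(hbr2[0] - hbr).max() < 1e-10

    def test_doubling_dpf_halves_concentration(self):
        od = np.ones((1, 2, 10)) * 0.01
        m = _recording(np.full((1, 2, 10), 0.5)).montage
        hbo1, _ = od_to_concentration(od, m, dpf=5.1)
        hbo2, _ = od_to_concentration(od, m, dpf=10.2)
        assert np.allclose(hbo1, 2 * hbo2)


class TestEpochs:
    def test_constant_concentration_gives_zero_epochs(self):
        fs = 7.8125
        n_t = int((2 * 27 + 30) * fs)
        onsets = 12.0 + 27.0 * np.arange(2)
        markers = pd.DataFrame(
            {"trial": range(2), "condition": ["contingent", "noncontingent"],
             "baseline_onset_s": onsets - 12, "onset_s": onsets}
        )
        hbo = np.full((2, n_t), 3.3)
        montage = _recording(np.full((2, 2, 10), 0.5)).montage
        cfg = PreprocConfig(min_trials_per_condition=1)
        eset, _ = build_epochs(hbo, hbo, fs, markers, np.ones(2, bool),
                               np.ones(2, bool), montage, cfg)
        assert eset is not None
        assert np.allclose(eset.condition_average("right", "contingent"), 0.0)

    def test_roi_needs_two_surviving_channels(self):
        cfg = NirsSimConfig(seed=11, n_trials_per_condition=4, looking_dist=(1, 0))
        rec = simulate_nirs(cfg, roi_montage())
        od = intensity_to_od(rec.intensity)
        hbo, hbr = od_to_concentration(od, rec.montage)
        chan_mask = np.ones(8, bool)
        right_idx = [i for i, c in enumerate(rec.montage.channels) if c in (8, 9, 13)]
        chan_mask[right_idx] = False  # only channel 14 survives on the right
        eset, report = build_epochs(
            hbo, hbr, rec.fs, rec.markers, np.ones(8, bool), chan_mask, rec.montage
        )
        assert eset is not None
        assert eset.available_rois() == ["left"]

    def test_amplitude_recovery_low_noise(self):
        cfg = NirsSimConfig(
            seed=12, n_trials_per_condition=5, looking_dist=(1, 0),
            noise=NoiseConfig(cardiac_amp_um=0.05, resp_amp_um=0.02,
                              mayer_amp_um=0.02, drift_amp_um=0.02,
                              white_sd_um=0.01),
            hrf_amplitude={("contingent", "right"): 0.0,
                           ("noncontingent", "right"): 0.5,
                           ("contingent", "left"): 0.0,
                           ("noncontingent", "left"): 0.5},
        )
        rec = simulate_nirs(cfg, roi_montage())
        eset, report = preprocess(rec, PreprocConfig(enable_heart_rate_check=False))
        assert eset is not None
        mean_nc = eset.condition_average("right", "noncontingent").mean()
        mean_c = eset.condition_average("right", "contingent").mean()
        assert mean_nc == pytest.approx(0.5, abs=0.12)
        assert mean_c == pytest.approx(0.0, abs=0.12)


class TestFullPipeline:
    def test_manifest_records_order_and_decisions(self):
        cfg = NirsSimConfig(seed=13, n_trials_per_condition=4)
        rec = simulate_nirs(cfg, roi_montage())
        eset, manifest = preprocess(rec)
        assert manifest["stage_order"][0] == "looking_filter"
        assert manifest["stage_order"][-1] == "roi_epochs"
        assert "parameters" in manifest and manifest["parameters"]["dpf"] == 5.1
        assert set(manifest["valid_trials"]) == {"contingent", "noncontingent"}

    def test_exclusion_decisions_reproducible(self):
        cfg = NirsSimConfig(seed=14, n_trials_per_condition=4,
                            motion=MotionConfig(spikes_per_minute=1.0))
        rec = simulate_nirs(cfg, roi_montage())
        _, m1 = preprocess(rec)
        _, m2 = preprocess(rec)
        assert m1["motion_rejected_trials"] == m2["motion_rejected_trials"]
        assert m1["looking_valid"] == m2["looking_valid"]
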