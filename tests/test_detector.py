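import numpy as np
import pytest
import scipy.signal as sps

from minkepam.detector import (
    BinarizationParams,
    DetectorEvaluation,
    DetectorParams,
    PulseEvent,
    assemble_trains,
    binarize,
    detect_pulses,
    energy_projection,
    evaluate_detector,
    extract_features,
    run_detector,
)
from minkepam.dsp import DspError, Spectrogram, SpectrogramParams, spectrogram
from minkepam.scene import PulseTrainSpec, build_scene, synthesize_noise, synthesize_pulse

FS = 2000.0
SP = SpectrogramParams(512, 0.75, "hann", FS)


def _noise_spec(duration=120.0, level=100.0, seed=0):
    return spectrogram(synthesize_noise(level, (89.1, 355.0), duration, FS, seed=seed), SP)


class TestBinarize:
    def test_constant_spectrogram_gives_empty_mask(self):
        sg = _noise_spec()
        flat = Spectrogram(np.full_like(sg.values, 80.0), sg.times_s, sg.freqs_hz, SP)
        assert not binarize(flat, BinarizationParams()).any()

    def test_burst_forms_connected_on_region(self):
        x = synthesize_noise(95.0, (89.1, 355.0), 60, FS, seed=1)
        burst = synthesize_pulse(110, 50, 0.5, 125, FS)
        i0 = int(30 * FS)
        x[i0 : i0 + burst.size] += burst
        sg = spectrogram(x, SP)
        mask = binarize(sg, BinarizationParams())
        near_burst = (sg.times_s > 29.5) & (sg.times_s < 31.0)
        sub = mask[near_burst]
        assert sub.any()
        f_hit = sg.freqs_hz[np.nonzero(sub.any(axis=0))[0]]
        assert (np.abs(f_hit - 110) < 30).any()
        # per-frame hit density is far higher around the burst than in noise
        noise_density = mask[~near_burst].sum() / max((~near_burst).sum(), 1)
        assert sub.sum() / near_burst.sum() > 5 * noise_density

    def test_noise_mask_density_matches_threshold_tail(self):
        sg = _noise_spec(duration=300.0, seed=2)
        mask = binarize(sg, BinarizationParams(threshold_k=3.0))
        density = mask[:, sg.band_slice(50, 400)].mean()
        # reference tail fraction of the median + 3 MAD rule for dB of an
        # exponential (single-bin Hann periodogram power) by Monte Carlo
        v = 10 * np.log10(np.random.default_rng(0).exponential(size=200000))
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        expected = np.mean(v > med + 3 * mad)
        assert density == pytest.approx(expected, rel=0.5)

    def test_band_outside_spectrogram_rejected(self):
        sg = _noise_spec(duration=60.0)
        with pytest.raises(DspError):
            binarize(sg, BinarizationParams(band=(1200.0, 1500.0)))

    def test_small_region_suppression(self):
        sg = _noise_spec(duration=300.0, seed=3)
        raw = binarize(sg, BinarizationParams(min_region_cells=1))
        cleaned = binarize(sg, BinarizationParams(min_region_cells=4))
        assert cleaned.sum() < 0.2 * raw.sum()


class TestEnergyProjection:
    def test_zero_mask_zero_projection(self):
        sg = _noise_spec(duration=60.0)
        proj = energy_projection(np.zeros_like(sg.values, dtype=bool), sg)
        assert not proj.any()

    def test_single_pulse_peaks_at_pulse_time(self):
        x = synthesize_noise(95.0, (89.1, 355.0), 60, FS, seed=4)
        x[int(30 * FS) : int(30 * FS) + 200] += synthesize_pulse(110, 50, 0.1, 120, FS)
        sg = spectrogram(x, SP)
        mask = binarize(sg, BinarizationParams(min_region_cells=4))
        proj = energy_projection(mask, sg)
        t_peak = sg.times_s[np.argmax(proj)] + 0.5 * SP.fft_size / FS
        assert t_peak == pytest.approx(30.05, abs=2 * SP.time_step_s)

    def test_two_pulses_400ms_apart_are_six_frames_apart(self):
        x = synthesize_noise(95.0, (89.1, 355.0), 30, FS, seed=5)
        p = synthesize_pulse(110, 50, 0.1, 120, FS)
        i0 = int(10 * FS)
        x[i0 : i0 + 200] += p
        x[i0 + 800 : i0 + 1000] += p  # 0.4 s later
        sg = spectrogram(x, SP)
        proj = energy_projection(binarize(sg, BinarizationParams(min_region_cells=4)), sg)
        peaks, _ = sps.find_peaks(proj, prominence=proj.max() / 5)
        assert peaks.size == 2
        assert np.diff(peaks)[0] == pytest.approx(0.4 / SP.time_step_s, abs=1)


class TestDetectPulses:
    def test_flat_projection_empty(self):
        sg = _noise_spec(duration=60.0)
        assert detect_pulses(np.zeros(sg.n_frames), sg) == []

    def test_isolated_spike_is_one_event(self):
        sg = _noise_spec(duration=60.0)
        proj = np.zeros(sg.n_frames)
        proj[100] = 1.0
        events = detect_pulses(proj, sg, min_prominence=0.5)
        assert len(events) == 1
        assert isinstance(events[0], PulseEvent)

    def test_sd3_train_pulses_recovered(self, sd3_scene):
        trains = run_detector(sd3_scene.samples, FS)
        truth = sd3_scene.manifest[0]
        assert len(trains) == 1
        det_times = trains[0].pulse_times
        centers = truth.pulse_times_s + truth.spec.pulse_duration_s / 2
        dt = DetectorParams().spectrogram.time_step_s
        matched = sum(np.min(np.abs(det_times - c)) <= 1.5 * dt for c in centers)
        assert matched / centers.size >= 0.9


class TestAssembleTrains:
    def _pulses(self, times):
        return [PulseEvent(t, 1.0, 100.0) for t in times]

    def test_uniform_gaps_one_train(self):
        trains = assemble_trains(self._pulses(np.arange(20) * 0.5))
        assert len(trains) == 1 and trains[0].n_pulses == 20

    def test_long_gap_splits(self):
        times = np.r_[np.arange(12) * 0.5, 3.0 + 5.5 + np.arange(12) * 0.5]
        trains = assemble_trains(self._pulses(times))
        assert len(trains) == 2

    def test_short_group_dropped(self):
        assert assemble_trains(self._pulses(np.arange(5) * 0.5)) == []


class TestFeatures:
    def _train_features(self, category, n, params, seed=0):
        spec = PulseTrainSpec(category, n, params, peak_freq_hz=110.0,
                              received_level_db=120.0, onset_s=10.0)
        sc = build_scene([spec], (n - 1) * 0.8 + 25, noise_level_db=100.0, seed=seed)
        trains = run_detector(sc.samples, FS)
        assert len(trains) == 1
        return trains[0].features

    def test_constant_train_statistics(self):
        fv = self._train_features("constant", 21, {"ipi_s": 0.5, "jitter_sd": 0.0})
        assert fv.ipi_mean == pytest.approx(0.5, abs=0.01)
        assert fv.ipi_slope == pytest.approx(0.0, abs=0.005)
        assert fv.ipi_min <= fv.ipi_median <= fv.ipi_max
        assert 0 < fv.duty_cycle <= 1
        assert np.isfinite(list(fv.as_dict().values())).all()

    def test_sd3_more_bimodal_than_constant(self):
        spec = PulseTrainSpec("slow_down", 40,
                              {"modes": (0.4, 0.7), "weight_long": 0.4, "jitter_sd": 0.02},
                              subtype="sd3", peak_freq_hz=110.0,
                              received_level_db=120.0, onset_s=10.0)
        sc = build_scene([spec], 60, noise_level_db=100.0, seed=1)
        fv_sd3 = run_detector(sc.samples, FS)[0].features
        fv_uni = self._train_features("constant", 40, {"ipi_s": 0.5, "jitter_sd": 0.02})
        assert fv_sd3.ipi_bimodality > 0.555 > fv_uni.ipi_bimodality

    def test_slow_down_slope_positive(self):
        fv = self._train_features(
            "slow_down", 30, {"ipi_start_s": 0.4, "ipi_end_s": 0.7, "jitter_sd": 0.01}
        )
        assert fv.ipi_slope > 0

    def test_feature_vector_has_18_fields(self):
        fv = self._train_features("constant", 15, {"ipi_s": 0.5, "jitter_sd": 0.0})
        assert len(fv.as_dict()) == 18


class TestEvaluation:
    def test_printed_counts_give_27_percent_fnr(self):
        ev = DetectorEvaluation(tp=2428 - 647, fp=181, fn=647,
                                evaluated_hours=120.0, slices=29847)
        assert round(ev.fnr_percent) == 27

    def test_perfect_detection(self, sd3_scene):
        trains = run_detector(sd3_scene.samples, FS)
        ev = evaluate_detector(trains, sd3_scene.manifest)
        assert (ev.tp, ev.fp, ev.fn) == (1, 0, 0)
        assert ev.fnr == 0.0

    def test_no_detections_is_total_miss(self, sd3_scene):
        ev = evaluate_detector([], sd3_scene.manifest)
        assert ev.fnr == 1.0
        assert ev.tp == 0
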