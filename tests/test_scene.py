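import dataclasses

import numpy as np
import pytest
import scipy.signal as sps

from minkepam.dsp import band_level_db
from minkepam.io import manifest_table, read_selection_table, read_wav, write_selection_table, write_wav
from minkepam.scene import (
    JACKSONVILLE,
    ONSLOW_BAY,
    STELLWAGEN,
    PulseTrainSpec,
    SceneError,
    build_scene,
    place_trains_sequentially,
    realize_ipi_sequence,
    sample_site_trains,
    synthesize_downsweep,
    synthesize_noise,
    synthesize_pulse,
)

FS = 2000.0


def _sd3(n_pulses=86, weight_long=0.2333, jitter=0.02, **kw):
    return PulseTrainSpec(
        category="slow_down",
        subtype="sd3",
        n_pulses=n_pulses,
        ipi_sequence_params={"modes": (0.4, 0.7), "weight_long": weight_long, "jitter_sd": jitter},
        **kw,
    )


class TestIpiSequences:
    def test_sd3_span_matches_mixture_expectation(self):
        # weight 0.2333 puts the mean IPI at 0.47 s -> 85 intervals span ~40 s.
        # Monte-Carlo reference over many seeds:
        spans = [realize_ipi_sequence(_sd3(), s).sum() for s in range(300)]
        assert np.mean(spans) == pytest.approx(0.47 * 85, abs=0.3)

    def test_sd3_histogram_peaks_at_modes(self):
        ipis = np.concatenate(
            [realize_ipi_sequence(_sd3(weight_long=0.4), s) for s in range(50)]
        )
        hist, edges = np.histogram(ipis, bins=np.arange(0.2, 1.0, 0.05))
        centers = (edges[:-1] + edges[1:]) / 2
        peaks, _ = sps.find_peaks(hist, prominence=hist.max() / 4)
        peak_pos = sorted(centers[peaks])
        assert len(peak_pos) == 2
        assert abs(peak_pos[0] - 0.4) <= 0.05
        assert abs(peak_pos[1] - 0.7) <= 0.05

    def test_constant_zero_jitter(self):
        spec = PulseTrainSpec("constant", 3, {"ipi_s": 0.5, "jitter_sd": 0.0})
        assert np.allclose(realize_ipi_sequence(spec, 0), [0.5, 0.5])

    @pytest.mark.parametrize(
        "category,params,sign",
        [
            ("slow_down", {"ipi_start_s": 0.4, "ipi_end_s": 0.7, "jitter_sd": 0.02}, 1),
            ("speed_up", {"ipi_start_s": 0.7, "ipi_end_s": 0.4, "jitter_sd": 0.02}, -1),
        ],
    )
    def test_trend_sign(self, category, params, sign):
        ipis = realize_ipi_sequence(PulseTrainSpec(category, 40, params), 1)
        slope = np.polyfit(np.arange(ipis.size), ipis, 1)[0]
        assert np.sign(slope) == sign

    def test_deterministic_under_seed(self):
        a = realize_ipi_sequence(_sd3(), 9)
        b = realize_ipi_sequence(_sd3(), 9)
        assert np.array_equal(a, b)

    def test_invalid_category_rejected(self):
        with pytest.raises(SceneError):
            PulseTrainSpec("wobble", 10, {})

    def test_ipis_exceed_pulse_duration(self):
        ipis = realize_ipi_sequence(_sd3(jitter=0.3), 2)
        assert (ipis > 0.1).all()


class TestPulseSynthesis:
    def test_rms_calibration(self):
        p = synthesize_pulse(120, 50, 0.1, 120, FS)
        assert p.size == 200
        assert 20 * np.log10(np.sqrt(np.mean(p**2))) == pytest.approx(120, abs=0.1)

    def test_spectral_peak_at_center(self):
        p = synthesize_pulse(100, 50, 0.1, 120, FS)
        f = np.fft.rfftfreq(4096, 1 / FS)
        spec = np.abs(np.fft.rfft(p, 4096))
        assert abs(f[np.argmax(spec)] - 100) <= FS / 4096 + 10.0 / 2

    def test_nyquist_violation_rejected(self):
        with pytest.raises(SceneError):
            synthesize_pulse(1100, 50, 0.1, 120, FS)

    def test_downsweep_frequency_endpoints(self):
        sw = synthesize_downsweep(118.0, 80.0, 0.4, 120.0, FS)
        inst = np.diff(np.unwrap(np.angle(sps.hilbert(sw)))) * FS / (2 * np.pi)
        n = inst.size
        interior = slice(int(0.1 * n), int(0.9 * n))
        coef = np.polyfit(np.arange(n)[interior], inst[interior], 1)
        assert np.polyval(coef, 0) == pytest.approx(118, abs=2)
        assert np.polyval(coef, n) == pytest.approx(80, abs=2)


class TestNoiseSynthesis:
    def test_band_level_round_trip(self):
        x = synthesize_noise(93.1, (89.1, 355.0), 600, FS, seed=0)
        assert band_level_db(x, FS, 89.1, 355.0) == pytest.approx(93.1, abs=0.5)

    def test_silence_flag(self):
        x = synthesize_noise(float("-inf"), (89.1, 355.0), 10, FS, seed=0)
        assert np.array_equal(x, np.zeros(int(10 * FS)))

    def test_seed_contract(self):
        a = synthesize_noise(95.0, (89.1, 355.0), 60, FS, seed=1)
        b = synthesize_noise(95.0, (89.1, 355.0), 60, FS, seed=2)
        assert not np.array_equal(a, b)
        assert band_level_db(a, FS, 89.1, 355.0) == pytest.approx(
            band_level_db(b, FS, 89.1, 355.0), abs=0.5
        )

    def test_spectral_slope_applied(self):
        x = synthesize_noise(95.0, (50.0, 800.0), 120, FS, seed=3, spectral_slope_db_per_octave=-6.0)
        f, psd = sps.welch(x, fs=FS, nperseg=2048)
        sel = (f >= 60) & (f <= 480)
        slope_per_octave = np.polyfit(np.log2(f[sel]), 10 * np.log10(psd[sel]), 1)[0]
        assert slope_per_octave == pytest.approx(-6.0, abs=0.7)


class TestSceneAssembly:
    def test_empty_scene_has_empty_manifest(self):
        sc = build_scene([], 10.0, noise_level_db=95.0, seed=0)
        assert sc.manifest == []
        assert sc.samples.size == int(10 * FS)

    def test_manifest_records_exact_onsets(self):
        spec = _sd3(onset_s=5.0)
        sc = build_scene([spec], 60.0, seed=0)
        pt = sc.manifest[0].pulse_times_s
        assert pt[0] == pytest.approx(5.0, abs=1 / FS)
        assert (np.diff(pt) > 0).all()
        # every onset sits exactly on the sample grid
        assert np.allclose(pt * FS, np.round(pt * FS))

    def test_scene_is_bit_identical_under_seed(self):
        spec = _sd3(onset_s=2.0)
        a = build_scene([spec], 60.0, noise_level_db=95.0, seed=5)
        b = build_scene([spec], 60.0, noise_level_db=95.0, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_train_beyond_duration_rejected(self):
        with pytest.raises(SceneError):
            build_scene([_sd3(onset_s=50.0)], 60.0, seed=0)

    def test_overlapping_trains_flagged(self):
        s1 = _sd3(onset_s=5.0)
        s2 = _sd3(onset_s=10.0)
        sc = build_scene([s1, s2], 70.0, seed=0)
        assert all(tr.overlaps_other for tr in sc.manifest)

    def test_site_preset_group_sizes(self):
        groups = [
            sample_site_trains(p, n, seed=1)
            for p, n in ((STELLWAGEN, 68), (ONSLOW_BAY, 26), (JACKSONVILLE, 35))
        ]
        assert [len(g) for g in groups] == [68, 26, 35]
        for g in groups:
            for s in g:
                assert s.subtype == "sd3" and 55 <= s.peak_freq_hz <= 150

    def test_sequential_placement_fits(self):
        specs = sample_site_trains(STELLWAGEN, 5, seed=2)
        placed, dur = place_trains_sequentially(specs, seed=0)
        sc = build_scene(placed, dur, noise_level_db=100.0, seed=0)
        assert len(sc.manifest) == 5
        assert not any(tr.overlaps_other for tr in sc.manifest)


class TestWavRoundTrip:
    def test_waveform_preserved_within_quantization(self, tmp_path):
        sc = build_scene([_sd3(onset_s=2.0, received_level_db=125.0)], 60.0,
                         noise_level_db=100.0, seed=1)
        path = write_wav(tmp_path / "scene.wav", sc.samples, FS)
        back, fs = read_wav(path)
        assert fs == FS
        full_scale = 10 ** (140.0 / 20.0)
        assert np.max(np.abs(back - sc.samples)) <= full_scale / 32767.0

    def test_selection_table_round_trip(self, tmp_path):
        sc = build_scene([_sd3(onset_s=2.0)], 60.0, seed=1)
        table = manifest_table(sc)
        p = write_selection_table(tmp_path / "sel.txt", table)
        back = read_selection_table(p)
        assert list(back.columns) == list(table.columns)
        assert back["Subtype"].iloc[0] == "sd3"
        assert back["N Pulses"].iloc[0] == 86
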