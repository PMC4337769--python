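import dataclasses

import numpy as np
import pytest

from minkepam.scene import PulseTrainSpec, build_scene, sample_site_trains


@pytest.fixture
def sd3_spec():
    """A canonical sd3 slow-down train: 86 pulses, 0.4/0.7 s IPI modes."""
    return PulseTrainSpec(
        category="slow_down",
        subtype="sd3",
        n_pulses=86,
        ipi_sequence_params={"modes": (0.4, 0.7), "weight_long": 0.25, "jitter_sd": 0.02},
        peak_freq_hz=110.0,
        received_level_db=120.0,
        onset_s=10.0,
    )


@pytest.fixture
def sd3_scene(sd3_spec):
    """The sd3 train embedded in 100 dB ambient noise (SNR 20 dB)."""
    return build_scene([sd3_spec], 70.0, noise_level_db=100.0, seed=3)


def measured_site_sample(preset, n_trains, seed, snr_db_range=(28.0, 42.0)):
    """Generate + measure n trains from a site preset; returns (durations,
    pulse counts, measurements). Shared by measurement tests and acceptance."""
    from minkepam.measure import measure_train

    specs = sample_site_trains(preset, n_trains, seed, snr_db_range=snr_db_range)
    subs = np.random.SeedSequence([seed, 77]).spawn(len(specs))
    durs, counts, meas = [], [], []
    for s, sub in zip(specs, subs):
        s = dataclasses.replace(s, onset_s=6.0)
        span = (s.n_pulses - 1) * 0.75 + 12.0
        sc = build_scene([s], span, noise_level_db=preset.noise_level_db, seed=sub)
        m = measure_train(sc.samples)
        durs.append(m.duration_s)
        counts.append(m.n_pulses)
        meas.append((sc.manifest[0], m))
    return np.array(durs), np.array(counts), meas
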