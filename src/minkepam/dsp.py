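"""Spectrogram, filtering and resampling primitives shared by the pipeline.

All levels are handled on calibrated pressure waveforms in µPa.  Spectrogram
values are one-sided power spectral density in dB re 1 µPa²/Hz.  Frames are
indexed from zero and time-stamped by their *start* sample, so frame ``i``
covers the half-open interval ``[i*hop/fs, i*hop/fs + fft_size/fs)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "SpectrogramParams",
    "Spectrogram",
    "spectrogram",
    "bandpass",
    "decimate_to_2k",
    "band_level_db",
    "DspError",
]

#: floor used when converting zero power to dB
_DB_FLOOR = 1e-30


class DspError(ValueError):
    """Invalid input to a DSP primitive (band, length, rate)."""


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT parameterization.

    Parameters
    ----------
    fft_size : int
        Transform length in samples; must be a power of two.
    overlap_fraction : float
        Fractional overlap between consecutive frames, in ``[0, 1)``.
        The hop is ``round(fft_size * (1 - overlap_fraction))`` samples,
        which makes the conventional 96.9 % overlap at 512 points an exact
        16-sample hop.
    window : str
        Analysis window; only ``"hann"`` is supported.
    sample_rate_hz : float
        Sampling rate of the waveform the params will be applied to.
    """

    fft_size: int = 512
    overlap_fraction: float = 0.75
    window: str = "hann"
    sample_rate_hz: float = 2000.0

    def __post_init__(self) -> None:
        if self.fft_size < 2 or (self.fft_size & (self.fft_size - 1)) != 0:
            raise DspError(f"fft_size must be a power of two, got {self.fft_size}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise DspError("overlap_fraction must be in [0, 1)")
        if self.window != "hann":
            raise DspError(f"unsupported window {self.window!r}")
        if self.hop < 1:
            raise DspError("hop evaluates to < 1 sample")

    @property
    def hop(self) -> int:
        return int(round(self.fft_size * (1.0 - self.overlap_fraction)))

    @property
    def freq_resolution_hz(self) -> float:
        return self.sample_rate_hz / self.fft_size

    @property
    def time_step_s(self) -> float:
        return self.hop / self.sample_rate_hz


@dataclass
class Spectrogram:
    """Time × frequency PSD matrix with its axes.

    ``values[i, j]`` is the PSD (dB re 1 µPa²/Hz) of frame ``i`` at bin
    centre ``freqs_hz[j]``; ``times_s[i]`` is the frame start time.
    """

    values: np.ndarray
    times_s: np.ndarray
    freqs_hz: np.ndarray
    params: SpectrogramParams = field(repr=False)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def power(self) -> np.ndarray:
        """Linear PSD (µPa²/Hz)."""
        return 10.0 ** (self.values / 10.0)

    def band_slice(self, f_low: float, f_high: float) -> slice:
        """Index slice of frequency bins whose centres fall in [f_low, f_high]."""
        if f_low >= f_high:
            raise DspError("band lower edge must be below upper edge")
        if f_low > self.freqs_hz[-1] or f_high < self.freqs_hz[0]:
            raise DspError(
                f"band ({f_low}, {f_high}) Hz outside spectrogram span "
                f"({self.freqs_hz[0]}, {self.freqs_hz[-1]}) Hz"
            )
        idx = np.nonzero((self.freqs_hz >= f_low) & (self.freqs_hz <= f_high))[0]
        return slice(int(idx[0]), int(idx[-1]) + 1)


def spectrogram(waveform: np.ndarray, params: SpectrogramParams) -> Spectrogram:
    """Short-time Fourier power spectral density of a calibrated waveform.

    Frequency resolution is ``fs / fft_size`` and the frame step is
    ``hop / fs``.  The one-sided PSD normalisation preserves total power:
    the frame-mean PSD integrated over frequency approximates the waveform
    mean-square pressure (Parseval consistency within ~1 % for stationary
    input).
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise DspError("waveform must be one-dimensional")
    n, hop = params.fft_size, params.hop
    if x.size < n:
        raise DspError(f"waveform shorter ({x.size}) than fft_size ({n})")
    win = sps.get_window("hann", n, fftbins=True)
    n_frames = 1 + (x.size - n) // hop
    idx = np.arange(n)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * win
    spec = np.fft.rfft(frames, axis=1)
    # one-sided PSD: 2|X|^2 / (fs * sum(w^2)), DC and Nyquist not doubled
    scale = 2.0 / (params.sample_rate_hz * np.sum(win**2))
    psd = (np.abs(spec) ** 2) * scale
    psd[:, 0] *= 0.5
    if n % 2 == 0:
        psd[:, -1] *= 0.5
    values = 10.0 * np.log10(np.maximum(psd, _DB_FLOOR))
    times = hop * np.arange(n_frames) / params.sample_rate_hz
    freqs = np.fft.rfftfreq(n, d=1.0 / params.sample_rate_hz)
    return Spectrogram(values=values, times_s=times, freqs_hz=freqs, params=params)


def bandpass(
    waveform: np.ndarray,
    f_low: float,
    f_high: float,
    sample_rate_hz: float = 2000.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    Forward-backward filtering (``sosfiltfilt``) so pulse timing is not
    skewed by group delay.  An upper edge at or above Nyquist is clamped to
    0.98 × Nyquist with a warning (the conventional 30–800 Hz band is
    Nyquist-limited at a 2 kHz rate).
    """
    nyq = sample_rate_hz / 2.0
    if not 0.0 < f_low < f_high:
        raise DspError(f"invalid band ({f_low}, {f_high}) Hz")
    if f_high >= nyq:
        if f_high > nyq:
            raise DspError(f"upper edge {f_high} Hz above Nyquist {nyq} Hz")
        warnings.warn(
            f"band upper edge {f_high} Hz at Nyquist; clamping to {0.98 * nyq:.1f} Hz",
            stacklevel=2,
        )
        f_high = 0.98 * nyq
    x = np.asarray(waveform, dtype=float)
    if x.size == 0:
        return x.copy()
    sos = sps.butter(order, [f_low, f_high], btype="bandpass", fs=sample_rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x)


def band_level_db(
    waveform: np.ndarray,
    sample_rate_hz: float,
    f_low: float,
    f_high: float,
    nperseg: int = 2048,
) -> float:
    """RMS pressure level (dB re 1 µPa) within a frequency band.

    Welch PSD (Hann window, 50 % segment overlap) integrated over the bins
    whose centres fall in ``[f_low, f_high]``.  This single estimator is
    used both to calibrate synthetic noise and to measure ambient levels,
    so the two round-trip consistently.  Returns ``-inf`` for silence.
    """
    nyq = sample_rate_hz / 2.0
    if not 0.0 <= f_low < f_high <= nyq:
        raise DspError(f"invalid band ({f_low}, {f_high}) Hz at fs {sample_rate_hz}")
    x = np.asarray(waveform, dtype=float)
    if x.size < 2:
        raise DspError("waveform too short for a band level")
    nseg = min(nperseg, x.size)
    freqs, psd = sps.welch(x, fs=sample_rate_hz, window="hann", nperseg=nseg)
    sel = (freqs >= f_low) & (freqs <= f_high)
    ms = float(np.sum(psd[sel]) * (freqs[1] - freqs[0]))
    if ms <= 0.0:
        return float("-inf")
    return 10.0 * np.log10(ms)


def decimate_to_2k(waveform: np.ndarray, native_fs: float, target_fs: float = 2000.0) -> np.ndarray:
    """Anti-aliased resampling of higher-rate recordings down to 2 kHz.

    Rational rate ratios are handled with a polyphase FIR resampler; the
    passband (0–0.9 × Nyquist of the target rate) is preserved within 1 dB.
    """
    if native_fs < target_fs:
        raise DspError(f"native rate {native_fs} Hz below target {target_fs} Hz")
    x = np.asarray(waveform, dtype=float)
    if native_fs == target_fs:
        return x.copy()
    ratio = Fraction(target_fs / native_fs).limit_denominator(10**6)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator)
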