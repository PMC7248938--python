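"""Time-frequency feature extraction.

Raw multichannel signals become the centered, energy-scaled spectral
envelopes x(t) that the correlation stage regresses against the event train:
a complex Morlet wavelet transform over a log-spaced filterbank, absolute
coefficients averaged in sliding windows, then per (channel, band) centering
and division by the session-mean envelope of that band (so features are
relative modulations, invariant to per-channel gain).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from mne.time_frequency import tfr_array_morlet
from scipy.signal import filtfilt, iirnotch

from .synthetic import RawSession

__all__ = [
    "FilterBank",
    "TFFeatures",
    "notch_filter",
    "morlet_filterbank",
    "cwt_amplitude",
    "extract_features",
    "compute_features",
]


class DegenerateInputError(ValueError):
    """A quantity that must have positive variance or energy is constant."""


@dataclass(frozen=True)
class FilterBank:
    """Log-spaced complex Morlet filterbank."""

    center_freqs: np.ndarray  # Hz, strictly increasing, constant ratio
    wavelet_cycles: float     # width of the Morlet wavelet, in cycles

    @property
    def n_bands(self) -> int:
        return self.center_freqs.size


@dataclass(frozen=True)
class TFFeatures:
    """Centered, energy-scaled spectral envelope features.

    ``values`` is frames x channels x bands; each (channel, band) column has
    zero mean and is expressed relative to that column's session-mean
    envelope. ``frame_times`` are window centers in seconds.
    """

    values: np.ndarray
    frame_times: np.ndarray
    window: float  # s
    step: float    # s
    channel_locus: np.ndarray | None = None  # optional channel->locus map

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


def notch_filter(session: RawSession, base_freq: float, n_harmonics: int,
                 q: float = 30.0) -> RawSession:
    """Remove power-line contamination at ``base_freq`` and its harmonics.

    Cascaded zero-phase IIR notches at base_freq * (1 .. n_harmonics+1);
    e.g. base 50 Hz with 4 harmonics notches 50, 100, 150, 200 and 250 Hz.
    """
    freqs = base_freq * np.arange(1, n_harmonics + 2)
    if freqs[-1] >= session.fs / 2:
        raise ValueError(
            f"highest notch {freqs[-1]:g} Hz is at or above Nyquist "
            f"({session.fs / 2:g} Hz)"
        )
    data = session.data
    for f0 in freqs:
        b, a = iirnotch(f0, Q=q, fs=session.fs)
        data = filtfilt(b, a, data, axis=-1)
    return replace(session, data=data)


def morlet_filterbank(f_min: float, f_max: float, n_bands: int,
                      cycles: float = 7.0) -> FilterBank:
    """Filterbank with geometrically spaced center frequencies.

    center_freqs[k] = f_min * (f_max/f_min)^(k/(n_bands-1)); the ratio of
    consecutive bands is constant. n_bands=1 yields the single band f_min.
    """
    if f_min <= 0 or f_max < f_min:
        raise ValueError("need 0 < f_min <= f_max")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if n_bands > 1 and f_max == f_min:
        raise ValueError("f_max must exceed f_min when n_bands > 1")
    return FilterBank(
        center_freqs=np.geomspace(f_min, f_max, n_bands),
        wavelet_cycles=float(cycles),
    )


def cwt_amplitude(session: RawSession, bank: FilterBank) -> np.ndarray:
    """Modulus of the complex Morlet transform, samples x channels x bands.

    The signal is reflection-padded by half the longest wavelet support so
    edge samples are not contaminated by zero-padding transients.
    """
    freqs = bank.center_freqs
    if freqs[-1] >= session.fs / 2:
        raise ValueError("highest band must be below the Nyquist frequency")
    # Gaussian envelope sd is cycles/(2*pi*f); support taken as +-5 sd.
    pad = int(np.ceil(5.0 * bank.wavelet_cycles / (2 * np.pi * freqs[0]) * session.fs))
    if session.n_samples < 2 * pad:
        raise ValueError(
            f"signal ({session.n_samples} samples) is shorter than the "
            f"longest wavelet support ({2 * pad} samples at "
            f"{freqs[0]:g} Hz)"
        )
    padded = np.pad(session.data, ((0, 0), (pad, pad)), mode="reflect")
    power = tfr_array_morlet(
        padded[np.newaxis], sfreq=session.fs, freqs=freqs,
        n_cycles=bank.wavelet_cycles, output="power", verbose="error",
    )[0]
    amp = np.sqrt(power[:, :, pad:-pad])          # channels x bands x samples
    return np.ascontiguousarray(amp.transpose(2, 0, 1))


def extract_features(amplitude: np.ndarray, fs: float, window: float = 0.3,
                     step: float = 0.05,
                     channel_locus: np.ndarray | None = None) -> TFFeatures:
    """Sliding-window envelope averages, centered and energy-scaled.

    Each frame is the mean amplitude in a centered window of ``window``
    seconds, advanced by ``step``; frames whose window would extend beyond
    the recording are dropped. Per (channel, band), the session mean is
    subtracted and the result divided by that same session-mean amplitude,
    making features unitless relative modulations.
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    ws = int(round(window * fs))
    ss = int(round(step * fs))
    if ws < 1:
        raise ValueError("window shorter than one sample")
    n = amplitude.shape[0]
    if n < ws:
        raise ValueError("recording shorter than one window")
    m = (n - ws) // ss + 1

    cs = np.cumsum(amplitude, axis=0, dtype=np.float64)
    cs = np.concatenate([np.zeros((1,) + amplitude.shape[1:]), cs], axis=0)
    starts = np.arange(m) * ss
    frames = (cs[starts + ws] - cs[starts]) / ws   # frames x channels x bands

    mu = frames.mean(axis=0)
    bad = ~(mu > 0)
    if np.any(bad):
        ch, band = np.argwhere(bad)[0]
        raise DegenerateInputError(
            f"zero per-frequency energy scale at channel {ch}, band {band}"
        )
    values = (frames - mu) / mu

    frame_times = (starts + (ws - 1) / 2.0) / fs
    return TFFeatures(
        values=values, frame_times=frame_times,
        window=ws / fs, step=ss / fs, channel_locus=channel_locus,
    )


def compute_features(session: RawSession, bank: FilterBank,
                     window: float = 0.3, step: float = 0.05) -> TFFeatures:
    """Convenience: CWT amplitude followed by windowed feature extraction."""
    amp = cwt_amplitude(session, bank)
    return extract_features(amp, session.fs, window=window, step=step,
                            channel_locus=session.channel_locus)
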