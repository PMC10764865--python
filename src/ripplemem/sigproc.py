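"""Preprocessing and surrogate construction for intracranial EEG.

Implements the standard iEEG conditioning chain — zero-phase FIR notch at the
line frequency and its harmonics, demeaning, zero-phase high-pass,
anti-aliased integer downsampling, white-matter re-referencing — plus
Hann-windowed Welch spectral estimation and spectrally matched Gaussian
surrogate signals used as the chance-level control for ripple detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "PowerSpectrum",
    "preprocess",
    "rereference",
    "estimate_psd",
    "make_surrogate",
]

VALID_REGIONS = ("HPC", "AMY", "WM")


@dataclass
class Recording:
    """Continuous multichannel recording in microvolts.

    ``signal`` is (n_channels, n_samples); ``regions`` assigns each channel
    to hippocampus (HPC), amygdala (AMY), or white matter (WM).
    """

    signal: np.ndarray
    rate: float
    channels: list[str]
    regions: list[str]
    excluded_channels: np.ndarray = field(default=None)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        n_ch = self.signal.shape[0]
        if len(self.channels) != n_ch or len(self.regions) != n_ch:
            raise ValueError("channel/region labels must match signal rows")
        for r in self.regions:
            if r not in VALID_REGIONS:
                raise ValueError(f"unknown region {r!r}; expected one of {VALID_REGIONS}")
        if self.excluded_channels is None:
            self.excluded_channels = np.zeros(n_ch, dtype=bool)
        else:
            self.excluded_channels = np.asarray(self.excluded_channels, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    def region_channels(self, region: str, include_excluded: bool = False) -> list[str]:
        out = []
        for i, (ch, r) in enumerate(zip(self.channels, self.regions)):
            if r == region and (include_excluded or not self.excluded_channels[i]):
                out.append(ch)
        return out

    def trace(self, name: str) -> np.ndarray:
        return self.signal[self.channel_index(name)]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("signal", data=self.signal)
            d.attrs["sampling_rate"] = self.rate
            f.create_dataset("channels", data=np.array(self.channels, dtype="S"))
            f.create_dataset("regions", data=np.array(self.regions, dtype="S"))
            f.create_dataset("excluded_channels", data=self.excluded_channels)

    @classmethod
    def from_hdf5(cls, path) -> "Recording":
        with h5py.File(path, "r") as f:
            return cls(
                signal=f["signal"][()],
                rate=float(f["signal"].attrs["sampling_rate"]),
                channels=[s.decode() for s in f["channels"][()]],
                regions=[s.decode() for s in f["regions"][()]],
                excluded_channels=f["excluded_channels"][()],
            )


@dataclass
class PowerSpectrum:
    """One-sided power spectral density (power per Hz)."""

    frequencies: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.frequencies, self.density]),
                   header="frequency_hz\tdensity", delimiter="\t")


def _notch_taps(rate: float, line_freq: float, bandwidth: float) -> np.ndarray:
    """Linear-phase FIR comb with zero gain in `bandwidth`-wide notches at the
    line frequency and every harmonic below Nyquist."""
    nyq = rate / 2.0
    half = bandwidth / 2.0
    trans = max(0.25, half / 2.0)
    pts = [0.0]
    gains = [1.0]
    k = 1
    while k * line_freq < nyq - half - trans:
        f0 = k * line_freq
        pts += [f0 - half - trans, f0 - half, f0 + half, f0 + half + trans]
        gains += [1.0, 0.0, 0.0, 1.0]
        k += 1
    pts.append(nyq)
    gains.append(1.0)
    # Frequency resolution must resolve the transition band.
    numtaps = int(4 * rate / trans) | 1
    return sps.firwin2(numtaps, pts, gains, fs=rate)


def _fir_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # Symmetric (type-I) taps applied centred => exactly zero phase.
    n = x.shape[1]
    if len(taps) // 2 >= n:  # reflect-padding needs pad < n; trim symmetrically
        k = (len(taps) - (2 * n - 3)) // 2
        taps = taps[k:-k]
    pad = len(taps) // 2
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    y = sps.fftconvolve(xp, taps[None, :], mode="same", axes=1)
    return y[:, pad:-pad]


def preprocess(
    rec: Recording,
    line_freq: float = 60.0,
    hp_cutoff: float = 0.3,
    target_rate: float | None = None,
    notch_bandwidth: float = 2.0,
) -> Recording:
    """Notch line noise + harmonics, demean, high-pass, and downsample.

    All filtering is zero-phase. Downsampling requires an integer decimation
    factor and applies an anti-alias low-pass at 0.8 x the new Nyquist.
    """
    if target_rate is None:
        target_rate = rec.rate
    if target_rate > rec.rate:
        raise ValueError("target_rate must not exceed the original rate")
    if hp_cutoff >= target_rate / 2:
        raise ValueError("high-pass cutoff must be below the target Nyquist")
    ratio = rec.rate / target_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"target_rate {target_rate} is not an integer divisor of the "
            f"recording rate {rec.rate}; resampling requires an integer factor"
        )

    x = rec.signal - rec.signal.mean(axis=1, keepdims=True)

    if line_freq is not None and line_freq < rec.rate / 2:
        x = _fir_zero_phase(x, _notch_taps(rec.rate, line_freq, notch_bandwidth))

    if hp_cutoff is not None and hp_cutoff > 0:
        sos = sps.butter(4, hp_cutoff, btype="highpass", fs=rec.rate, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)

    if factor > 1:
        new_nyq = target_rate / 2.0
        sos = sps.butter(8, 0.8 * new_nyq, btype="lowpass", fs=rec.rate, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)
        x = x[:, ::factor]

    x = x - x.mean(axis=1, keepdims=True)
    return replace(rec, signal=x, rate=float(target_rate))


def rereference(rec: Recording, mapping: dict[str, str]) -> Recording:
    """Subtract the mapped white-matter reference from each channel.

    ``mapping`` sends channel name -> WM channel name. Unmapped channels are
    left untouched.
    """
    out = rec.signal.copy()
    for ch, ref in mapping.items():
        i = rec.channel_index(ch)
        j = rec.channel_index(ref)
        if rec.regions[j] != "WM":
            raise ValueError(f"reference {ref!r} for {ch!r} is not a WM channel")
        if i == j:
            raise ValueError(f"channel {ch!r} cannot reference itself")
        if rec.excluded_channels[j]:
            raise ValueError(f"reference {ref!r} is flagged excluded")
        out[i] = rec.signal[i] - rec.signal[j]
    return replace(rec, signal=out)


def estimate_psd(trace: np.ndarray, rate: float, segment_len: float = 2.0) -> PowerSpectrum:
    """Hann-windowed Welch PSD (one-sided density)."""
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(segment_len * rate))
    if trace.size < nperseg:
        raise ValueError("trace shorter than the requested segment length")
    if np.ptp(trace) == 0:
        warnings.warn("constant trace: returning zero spectrum")
        freqs = np.fft.rfftfreq(nperseg, 1.0 / rate)
        return PowerSpectrum(freqs, np.zeros_like(freqs))
    freqs, dens = sps.welch(trace, fs=rate, window="hann", nperseg=nperseg,
                            detrend="constant")
    return PowerSpectrum(freqs, dens)


def make_surrogate(psd: PowerSpectrum, n_samples: int, rate: float, seed: int) -> np.ndarray:
    """Gaussian surrogate whose PSD matches ``psd``.

    White Gaussian noise is transformed to the frequency domain, scaled by the
    amplitude coefficients sqrt(PSD * rate / 2) (so the surrogate's one-sided
    PSD equals the target), and inverse-transformed.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    nyq = rate / 2.0
    if psd.frequencies[-1] < nyq - 1e-9:
        raise ValueError("target PSD must cover frequencies up to Nyquist")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n_samples)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n_samples, 1.0 / rate)
    amp = np.sqrt(np.clip(np.interp(f, psd.frequencies, psd.density), 0, None) * rate / 2.0)
    return np.fft.irfft(spec * amp, n=n_samples)
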