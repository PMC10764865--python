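"""Hippocampal ripple detection and ripple-rate analyses.

Detection follows the classic band-envelope scheme: analysis epochs are
concatenated, band-pass filtered (80-150 Hz, 4th-order Chebyshev type II,
zero phase), the Hilbert analytic amplitude is blanked +/-75 ms around
concatenation boundaries, z-scored over the concatenated trace, and events
are accepted when the envelope stays above a low threshold (z = 2) for
20-100 ms with a peak above a high threshold (z = 5). A spectrally matched
Gaussian surrogate run through the identical detector provides the
chance-level control used for channel selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .sigproc import PowerSpectrum, estimate_psd, make_surrogate

__all__ = [
    "RippleEvent",
    "ChannelQC",
    "ripple_bandpass_sos",
    "detect_ripples",
    "chance_count",
    "select_channels",
    "time_resolved_rate",
    "coincidence",
    "dual_state_proportion",
    "events_to_table",
]


@dataclass(frozen=True)
class RippleEvent:
    """A detected ripple on one channel; times in seconds on the recording clock."""

    channel: str
    onset: float
    peak: float
    offset: float
    peak_z: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def __post_init__(self):
        if not (self.onset <= self.peak <= self.offset):
            raise ValueError("require onset <= peak <= offset")


@dataclass
class ChannelQC:
    channel: str
    ripple_count: int
    surrogate_count: float
    zscore_across_channels: float = np.nan
    selected: bool = False


def ripple_bandpass_sos(rate: float, band: tuple[float, float],
                        margin: float = 0.25, rs: float = 40.0):
    """4th-order Chebyshev type II band-pass whose passband covers ``band``.

    Type II is specified by its stopband corners, so these are placed a
    relative ``margin`` outside the requested passband; stopband ripple
    ``rs`` dB. Applied forward-backward for zero phase.
    """
    lo = band[0] * (1 - margin)
    hi = min(band[1] * (1 + margin), 0.99 * rate / 2)
    return sps.cheby2(4, rs, (lo, hi), btype="bandpass", fs=rate, output="sos")


def _band_envelope(concat: np.ndarray, rate: float, band: tuple[float, float]) -> np.ndarray:
    sos = ripple_bandpass_sos(rate, band)
    filt = sps.sosfiltfilt(sos, concat)
    nfft = int(2 ** np.ceil(np.log2(max(len(filt), 2))))
    analytic = sps.hilbert(filt, N=nfft)[: len(filt)]
    return np.abs(analytic)


def detect_ripples(
    trace: np.ndarray,
    rate: float,
    trial_epochs: list[tuple[float, float]],
    band: tuple[float, float] = (80.0, 150.0),
    low_z: float = 2.0,
    high_z: float = 5.0,
    dur_range: tuple[float, float] = (0.020, 0.100),
    edge_blank: float = 0.075,
    merge_gap: float = 0.010,
    channel: str = "",
) -> list[RippleEvent]:
    """Detect ripples within the given trial epochs of one channel."""
    trace = np.asarray(trace, dtype=float)
    if rate < 2 * band[1]:
        raise ValueError("sampling rate must be at least twice the band upper edge")
    segments = []
    times = []
    for t0, t1 in trial_epochs:
        i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
        if i0 < 0 or i1 > trace.size or i1 <= i0:
            raise ValueError(f"epoch ({t0}, {t1}) outside the trace")
        segments.append(trace[i0:i1])
        times.append(np.arange(i0, i1) / rate)
    concat = np.concatenate(segments)
    tconcat = np.concatenate(times)

    env = _band_envelope(concat, rate, band)

    # Blank around every concatenation boundary (epoch onsets and offsets).
    nb = int(round(edge_blank * rate))
    pos = 0
    for seg in segments:
        env[pos : pos + nb] = 0.0
        env[max(pos + len(seg) - nb, 0) : pos + len(seg)] = 0.0
        pos += len(seg)

    sd = env.std()
    if sd == 0:
        warnings.warn("zero envelope SD: no events detectable")
        return []
    z = (env - env.mean()) / sd

    above = z > low_z
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]])  # inclusive

    # Merge runs separated by < merge_gap (on the concatenated clock) before
    # duration screening: long enough to bridge brief dips within one burst,
    # short enough not to chain adjacent sidelobes into over-long events.
    gap = int(round(merge_gap * rate))
    merged = []
    cs, ce = run_starts[0], run_ends[0]
    for s, e in zip(run_starts[1:], run_ends[1:]):
        if s - ce < gap and tconcat[s] - tconcat[ce] < merge_gap:
            ce = e
        else:
            merged.append((cs, ce))
            cs, ce = s, e
    merged.append((cs, ce))

    events = []
    for s, e in merged:
        dur = (e - s + 1) / rate
        if not (dur_range[0] <= dur <= dur_range[1]):
            continue
        seg = z[s : e + 1]
        pk = s + int(np.argmax(seg))
        if z[pk] < high_z:
            continue
        events.append(
            RippleEvent(channel=channel, onset=tconcat[s], peak=tconcat[pk],
                        offset=tconcat[e], peak_z=float(z[pk]))
        )
    return events


def chance_count(
    trace: np.ndarray,
    rate: float,
    trial_epochs: list[tuple[float, float]],
    seed: int,
    n_surrogates: int = 1,
    psd: PowerSpectrum | None = None,
    **detect_kwargs,
) -> float:
    """Mean ripple count detected on PSD-matched Gaussian surrogates."""
    trace = np.asarray(trace, dtype=float)
    if psd is None:
        seg = min(2.0, trace.size / rate / 4)
        psd = estimate_psd(trace, rate, segment_len=seg)
    counts = []
    for k in range(n_surrogates):
        surr = make_surrogate(psd, trace.size, rate, seed=seed + k)
        counts.append(len(detect_ripples(surr, rate, trial_epochs, **detect_kwargs)))
    return float(np.mean(counts))


def select_channels(qcs: list[ChannelQC]) -> list[ChannelQC]:
    """Apply the two inclusion criteria and pick the max-count channel.

    A channel qualifies if its ripple count z-scored across channels exceeds
    -2 and its count exceeds the surrogate chance count. If no channel
    qualifies, all stay unselected (the participant is excluded).
    """
    if not qcs:
        raise ValueError("no channels supplied")
    counts = np.array([q.ripple_count for q in qcs], dtype=float)
    sd = counts.std(ddof=0)
    zs = (counts - counts.mean()) / sd if sd > 0 else np.zeros_like(counts)
    best, best_count = None, -1
    for q, z in zip(qcs, zs):
        q.zscore_across_channels = float(z)
        q.selected = False
        if z > -2 and q.ripple_count > q.surrogate_count:
            if q.ripple_count > best_count:
                best, best_count = q, q.ripple_count
    if best is not None:
        best.selected = True
    return qcs


def time_resolved_rate(
    event_times_by_trial: list[np.ndarray],
    window: tuple[float, float],
    bin_width: float = 0.050,
    step: float = 0.010,
    smooth_sigma: float = 0.150,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-bin ripple rate (events/s) averaged across trials.

    ``event_times_by_trial`` holds event times already aligned to the common
    reference (e.g. response time). Returns (bin centers, rate trace).
    Gaussian smoothing with sigma ``smooth_sigma`` seconds (0 disables).
    """
    if step > bin_width:
        warnings.warn("step exceeds bin width: sliding bins leave gaps")
    t0, t1 = window
    centers = np.arange(t0 + bin_width / 2, t1 - bin_width / 2 + 1e-12, step)
    per_trial = np.zeros((len(event_times_by_trial), centers.size))
    for i, ev in enumerate(event_times_by_trial):
        ev = np.asarray(ev, dtype=float)
        for j, c in enumerate(centers):
            per_trial[i, j] = np.sum(
                (ev >= c - bin_width / 2) & (ev < c + bin_width / 2)
            ) / bin_width
    if smooth_sigma > 0:
        per_trial = gaussian_filter1d(per_trial, smooth_sigma / step, axis=1,
                                      mode="nearest")
    return centers, per_trial.mean(axis=0)


def coincidence(
    hpc_events: list[RippleEvent],
    amy_events: list[RippleEvent],
    window: float = 0.050,
) -> float:
    """Percentage of HPC ripples with an AMY event peak within +/- window."""
    if not hpc_events:
        raise ValueError("percentage undefined: no hippocampal ripples")
    if not amy_events:
        return 0.0
    apeaks = np.array([e.peak for e in amy_events])
    hits = sum(np.min(np.abs(apeaks - e.peak)) <= window for e in hpc_events)
    return 100.0 * hits / len(hpc_events)


def dual_state_proportion(
    power: np.ndarray,
    rate: float,
    event_times: np.ndarray,
) -> tuple[float, float]:
    """Proportion of events in low- vs high-power halves (median split).

    Samples equal to the median are assigned to the low state.
    """
    power = np.asarray(power, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("no events")
    med = np.median(power)
    idx = np.clip(np.round(event_times * rate).astype(int), 0, power.size - 1)
    high = power[idx] > med
    p_high = float(high.mean())
    return 1.0 - p_high, p_high


def events_to_table(events: list[RippleEvent]):
    """Events as a DataFrame suitable for tab-delimited export."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(channel=e.channel, onset_s=e.onset, peak_s=e.peak,
                 offset_s=e.offset, peak_z=e.peak_z, duration_s=e.duration)
            for e in events
        ],
        columns=["channel", "onset_s", "peak_s", "offset_s", "peak_z", "duration_s"],
    )
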