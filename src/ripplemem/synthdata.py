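"""Synthetic task, behavior, and two-region iEEG generator with ground truth.

Emulates an emotional memory encoding and discrimination session: 148
encoding trials (cross fixation 1 s, stimulus 2 s, self-paced valence rating
up to 2 s) followed by a retrieval block of 54 Repeat, 97 Lure, and 139
Novel trials. Lure responses follow a logistic model in stimulus valence,
arousal, and lure-pair similarity with a per-participant random intercept.

The continuous recording covers the encoding block and contains, per
channel, 1/f-shaped Gaussian background with a theta component and optional
60 Hz line noise. Hippocampal channels carry planted ripple bursts
(Hann-windowed 80-150 Hz sinusoids, 30-80 ms) whose post-encoding rate is
modulated by stimulus arousal and later lure discrimination. Each stimulus
owns a random spectral template (30-280 Hz) injected during encoding and
re-injected around planted ripples (amygdala reactivation scaled by
arousal, hippocampal reactivation gated on correct discrimination, with the
amygdala leading by ``amy_lead`` seconds on correct trials). Every planted
event is logged in a ground-truth record so downstream detectors and
similarity analyses can be validated against exact truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .sigproc import Recording

__all__ = [
    "TaskDesign",
    "RecordingParams",
    "GroundTruth",
    "generate_task",
    "generate_recording",
    "encoding_lure_view",
    "write_table",
    "read_table",
]

RETRIEVAL_GAP = 10.0  # seconds between encoding and retrieval blocks


@dataclass
class TaskDesign:
    """Trial counts, epoch durations, and generative behavioral coefficients."""

    n_encoding: int = 148
    n_repeat: int = 54
    n_lure: int = 97
    n_novel: int = 139
    fixation_dur: float = 1.0
    stimulus_dur: float = 2.0
    max_response_dur: float = 2.0
    # logistic model for P(New | Lure), predictors normalized to [0, 1]
    beta_intercept: float = 0.3
    beta_valence: float = 0.3
    beta_arousal: float = 1.5
    beta_similarity: float = -1.5
    intercept_sd: float = 0.5
    repeat_old_acc: float = 0.89
    novel_new_acc: float = 0.94
    rt_mean: float = 1.3
    rt_sd: float = 0.35
    rt_min: float = 0.3

    def __post_init__(self):
        for name in ("n_encoding", "n_repeat", "n_lure", "n_novel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"invalid design: {name} must be positive")
        if self.n_lure > self.n_encoding or self.n_repeat > self.n_encoding:
            raise ValueError("invalid design: more Repeat/Lure probes than encoded stimuli")

    @property
    def n_retrieval(self) -> int:
        return self.n_repeat + self.n_lure + self.n_novel


@dataclass
class RecordingParams:
    """Signal and planted-effect settings for the synthetic recording."""

    rate: float = 1000.0
    n_hpc: int = 1
    n_amy: int = 1
    n_wm: int = 1
    noise_scale: float = 10.0        # microvolts, broadband background SD
    noise_exponent: float = 1.0      # 1/f^a spectral shaping
    theta_freq: float = 6.0
    theta_amp: float = 5.0
    line_freq: float = 60.0
    line_amp: float = 2.0
    # ripples
    ripple_amp_snr: float = 15.0     # burst amplitude in units of band SD
    ripple_band: tuple[float, float] = (80.0, 150.0)
    ripple_dur_range: tuple[float, float] = (0.030, 0.080)
    base_ripple_rate: float = 1.3    # events/s during post-encoding
    arousal_rate_effect: float = 1.5  # log-rate slope vs arousal (0..1)
    correct_rate_effect: float = 1.7  # log-rate slope vs lure correctness
    ripple_margin: float = 0.18      # s from post-encoding epoch edges
    # stimulus templates and reactivation
    template_band: tuple[float, float] = (30.0, 280.0)
    template_gain: float = 4.0       # microvolts, encoding injection SD
    react_gain_amy: float = 5.0      # amygdala reinstatement amplitude when active
    amy_arousal_gate: float = 0.5    # AMY reinstatement present when arousal01 >= gate
    react_gain_hpc: float = 5.0      # gated on correct lure discrimination
    react_halfwidth: float = 0.080   # s, reactivation burst half-width
    react_delay: float = 0.080       # s, HPC reinstatement trails the ripple peak
    react_gain_jitter_sd: float = 0.7  # lognormal sd of shared per-ripple gain
    react_mod_floor: float = 0.7     # ongoing shared fluctuation, rel. bump scale
    react_mod_timescale: float = 0.080  # s, timescale of the ongoing fluctuation
    amy_lead: float = 0.100          # s, AMY precedes HPC on correct trials

    def __post_init__(self):
        if self.rate < 600:
            raise ValueError(
                "sampling rate below 600 Hz cannot represent the 280 Hz analysis ceiling")
        if self.amy_lead < 0:
            raise ValueError("amy_lead must be nonnegative")


@dataclass
class GroundTruth:
    """Exact record of everything planted into the recording."""

    ripples: pd.DataFrame          # trial, time, duration, carrier, region
    reactivations: pd.DataFrame    # trial, region, center, t0, t1, gain
    template_profiles: dict        # stim_id -> spectral envelope (n_rfft,)
    amy_lead: float
    effects: dict                  # generative effect sizes

    @property
    def n_ripples(self) -> int:
        return len(self.ripples)


def _truncnorm_rt(rng, n, mean, sd, lo, hi):
    rt = rng.normal(mean, sd, size=n)
    bad = (rt < lo) | (rt > hi)
    while bad.any():
        rt[bad] = rng.normal(mean, sd, size=bad.sum())
        bad = (rt < lo) | (rt > hi)
    return rt


def generate_task(
    seed: int,
    design: TaskDesign | None = None,
    participant: str = "P01",
    **overrides,
) -> tuple[TaskDesign, pd.DataFrame]:
    """Sample one participant's task run: stimuli, timing, and responses.

    Returns the design and a trial table with one row per encoding and
    retrieval trial (times in seconds from recording start).
    """
    if seed < 0:
        raise ValueError("seed must be a nonnegative integer")
    if design is None:
        design = TaskDesign(**overrides)
    elif overrides:
        design = TaskDesign(**{**asdict(design), **overrides})
    d = design
    rng = np.random.default_rng(seed)

    n_enc = d.n_encoding
    valence = rng.uniform(1, 9, size=n_enc)
    arousal = rng.uniform(1, 9, size=n_enc)
    stim_ids = [f"S{i:04d}" for i in range(n_enc)]

    # Lure parents first, then Repeat parents; a stimulus may serve both
    # roles when the counts demand it (printed counts exceed the encoded set).
    lure_parents = rng.choice(n_enc, size=d.n_lure, replace=False)
    repeat_parents = rng.choice(n_enc, size=d.n_repeat, replace=False)
    lure_sim = np.full(n_enc, np.nan)
    lure_sim[lure_parents] = rng.uniform(1, 8, size=d.n_lure)

    u = rng.normal(0, d.intercept_sd)  # participant random intercept

    rows = []
    t = 0.0
    for i in range(n_enc):
        rt = float(_truncnorm_rt(rng, 1, d.rt_mean, d.rt_sd, d.rt_min,
                                 d.max_response_dur)[0])
        fix_on = t
        stim_on = fix_on + d.fixation_dur
        stim_off = stim_on + d.stimulus_dur
        resp = stim_off + rt
        v = valence[i]
        cat = "negative" if v <= 3.5 else ("positive" if v >= 6 else "neutral")
        rows.append(dict(
            participant=participant, trial=i, phase="encoding", type="Encoding",
            stim_id=stim_ids[i], fixation_onset=fix_on, stim_onset=stim_on,
            stim_offset=stim_off, response_time=resp, rt=rt,
            valence=v, arousal=arousal[i], lure_similarity=lure_sim[i],
            response=cat, correct=np.nan, excluded=False,
        ))
        t = resp
    t += RETRIEVAL_GAP

    probes = ([("Repeat", int(p)) for p in repeat_parents]
              + [("Lure", int(p)) for p in lure_parents]
              + [("Novel", -1 - k) for k in range(d.n_novel)])
    rng.shuffle(probes)

    trial_no = n_enc
    for kind, parent in probes:
        rt = float(_truncnorm_rt(rng, 1, d.rt_mean, d.rt_sd, d.rt_min,
                                 d.max_response_dur)[0])
        fix_on = t
        stim_on = fix_on + d.fixation_dur
        stim_off = stim_on + d.stimulus_dur
        resp_t = stim_off + rt
        if kind == "Novel":
            sid = f"N{-parent - 1:04d}"
            v, a, sim = rng.uniform(1, 9), rng.uniform(1, 9), np.nan
            answer = "New" if rng.uniform() < d.novel_new_acc else "Old"
        elif kind == "Repeat":
            sid = stim_ids[parent]
            v, a, sim = valence[parent], arousal[parent], np.nan
            answer = "Old" if rng.uniform() < d.repeat_old_acc else "New"
        else:
            sid = stim_ids[parent]
            v, a, sim = valence[parent], arousal[parent], lure_sim[parent]
            eta = (d.beta_intercept + u
                   + d.beta_valence * (v - 1) / 8
                   + d.beta_arousal * (a - 1) / 8
                   + d.beta_similarity * (sim - 1) / 7)
            p_new = 1.0 / (1.0 + np.exp(-eta))
            answer = "New" if rng.uniform() < p_new else "Old"
        expected = "Old" if kind == "Repeat" else "New"
        rows.append(dict(
            participant=participant, trial=trial_no, phase="retrieval",
            type=kind, stim_id=sid, fixation_onset=fix_on, stim_onset=stim_on,
            stim_offset=stim_off, response_time=resp_t, rt=rt,
            valence=v, arousal=a, lure_similarity=sim, response=answer,
            correct=(answer == expected), excluded=False,
        ))
        t = resp_t
        trial_no += 1

    return design, pd.DataFrame(rows)


def encoding_lure_view(table: pd.DataFrame) -> pd.DataFrame:
    """Encoding trials of Lure parents, joined with retrieval outcome.

    Adds ``lure_correct`` (later discrimination of the paired Lure probe) and
    ``high_arousal`` (participant-level median split). These are the trials
    entering the ripple-based analyses.
    """
    enc = table[(table["phase"] == "encoding")
                & table["lure_similarity"].notna()].copy()
    lure = table[(table["phase"] == "retrieval") & (table["type"] == "Lure")]
    outcome = lure.set_index("stim_id")["correct"]
    enc["lure_correct"] = enc["stim_id"].map(outcome).astype(bool)
    enc["high_arousal"] = enc["arousal"] > enc["arousal"].median()
    return enc


def _oneoverf_noise(rng, n, rate, exponent, scale):
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    # normalize by the EXPECTED sd, not the realized one: the realized total
    # variance is dominated by a handful of low-frequency components, and
    # dividing by it would rescale the high bands differently per channel
    s2 = shaping**2
    exp_var = (s2[0] + 2.0 * s2[1:-1].sum() + s2[-1]) / n
    return x * (scale / np.sqrt(exp_var))


def _shaped_burst(rng, n, rate, envelope_rfft, amp, window=True):
    """Fresh noise with a fixed spectral envelope, SD = amp (Hann-windowed
    unless ``window`` is False)."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    env = np.interp(f, envelope_rfft[0], envelope_rfft[1])
    x = np.fft.irfft(spec * env, n=n)
    if window:
        x *= np.hanning(n)
    sd = x.std()
    return x * (amp / sd) if sd > 0 else x


def _smoothed_chi(rng, n, rate, timescale):
    """Slow nonnegative fluctuation with unit mean (squared smoothed noise)."""
    from scipy.ndimage import gaussian_filter1d

    z = gaussian_filter1d(rng.standard_normal(n), timescale * rate,
                          mode="reflect")
    u = z**2
    mu = u.mean()
    return u / mu if mu > 0 else u


def _make_template_profile(rng, band, notch=(75.0, 155.0), n_knots=12):
    """Smooth random log-amplitude spectral envelope over ``band``.

    The ripple band (plus guard margins) is notched out so that planted
    stimulus templates and planted ripples occupy disjoint spectral ranges:
    detector validity and reactivation strength stay independently
    controllable, and reactivation cannot masquerade as ripples."""
    f_knots = np.linspace(band[0], band[1], n_knots)
    log_amp = rng.normal(0, 1.2, size=n_knots)
    f_grid = np.linspace(band[0], band[1], 400)
    amp = np.exp(np.interp(f_grid, f_knots, log_amp))
    amp[(f_grid >= notch[0]) & (f_grid <= notch[1])] = 0.0
    f_full = np.concatenate([[0.0, band[0] - 1e-6], f_grid, [band[1] + 1e-6, 1e6]])
    a_full = np.concatenate([[0.0, 0.0], amp, [0.0, 0.0]])
    return f_full, a_full


def generate_recording(
    trial_table: pd.DataFrame,
    params: RecordingParams | None = None,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Synthesize the encoding-block iEEG with planted ripples/reactivation.

    The recording spans the encoding block of ``trial_table``; retrieval
    trials are behavioral-only. Raises if the table's encoding epochs overlap
    or are out of order.
    """
    p = params or RecordingParams()
    rng = np.random.default_rng(seed)
    enc = trial_table[trial_table["phase"] == "encoding"].sort_values("trial")
    if len(enc) == 0:
        raise ValueError("trial table holds no encoding trials")
    starts = enc["fixation_onset"].to_numpy()
    ends = enc["response_time"].to_numpy()
    if np.any(starts[1:] < ends[:-1] - 1e-9):
        raise ValueError("encoding epochs overlap or are out of order")

    rate = p.rate
    duration = float(ends[-1]) + 1.0
    n = int(round(duration * rate))

    names, regions = [], []
    for k in range(p.n_hpc):
        names.append(f"HPC{k + 1}")
        regions.append("HPC")
    for k in range(p.n_amy):
        names.append(f"AMY{k + 1}")
        regions.append("AMY")
    for k in range(p.n_wm):
        names.append(f"WM{k + 1}")
        regions.append("WM")

    sig = np.empty((len(names), n))
    tgrid = np.arange(n) / rate
    for c in range(len(names)):
        x = _oneoverf_noise(rng, n, rate, p.noise_exponent, p.noise_scale)
        x += p.theta_amp * np.sin(2 * np.pi * p.theta_freq * tgrid
                                  + rng.uniform(0, 2 * np.pi))
        if p.line_amp > 0:
            x += p.line_amp * np.sin(2 * np.pi * p.line_freq * tgrid
                                     + rng.uniform(0, 2 * np.pi))
        sig[c] = x

    # band SD of the background sets the ripple burst amplitude
    hpc_idx = [i for i, r in enumerate(regions) if r == "HPC"]
    amy_idx = [i for i, r in enumerate(regions) if r == "AMY"]
    from .ripples import ripple_bandpass_sos

    sos = ripple_bandpass_sos(rate, p.ripple_band)
    band_sd = sps.sosfiltfilt(sos, sig[hpc_idx[0]]).std()

    lure_view = encoding_lure_view(trial_table) if \
        trial_table["lure_similarity"].notna().any() else pd.DataFrame()
    lure_correct = (lure_view.set_index("trial")["lure_correct"]
                    if len(lure_view) else pd.Series(dtype=bool))

    profiles = {}
    ripple_rows, react_rows = [], []
    amp = p.ripple_amp_snr * band_sd

    for _, tr in enc.iterrows():
        sid = tr["stim_id"]
        if sid not in profiles:
            profiles[sid] = _make_template_profile(rng, p.template_band)
        prof = profiles[sid]
        ar01 = (tr["arousal"] - 1) / 8

        # stimulus-specific template during encoding, both regions
        i0 = int(round(tr["stim_onset"] * rate))
        i1 = int(round(tr["stim_offset"] * rate))
        if p.template_gain > 0:
            for c in hpc_idx + amy_idx:
                sig[c, i0:i1] += _shaped_burst(rng, i1 - i0, rate, prof,
                                               p.template_gain)

        # planted post-encoding ripples
        lo = tr["stim_offset"] + p.ripple_margin
        hi = tr["response_time"] - p.ripple_margin
        if hi <= lo:
            continue
        is_lure = tr["trial"] in lure_correct.index
        correct = bool(lure_correct.get(tr["trial"], False))
        log_rate = (np.log(p.base_ripple_rate)
                    + p.arousal_rate_effect * (ar01 - 0.5))
        if is_lure:
            log_rate += p.correct_rate_effect * ((1.0 if correct else 0.0) - 0.5)
        lam = np.exp(log_rate)
        n_rip = rng.poisson(lam * (hi - lo))
        if n_rip == 0:
            continue
        times = np.sort(rng.uniform(lo, hi, size=n_rip))
        # enforce >=600 ms separation so +/-250 ms analysis windows of
        # neighbouring ripples never overlap each other's reinstatement
        keep = [times[0]]
        for tt in times[1:]:
            if tt - keep[-1] > 0.6:
                keep.append(tt)
        for t_peak in keep:
            dur = rng.uniform(*p.ripple_dur_range)
            carrier = rng.uniform(*p.ripple_band)
            if p.ripple_amp_snr > 0:
                m = int(round(dur * rate))
                j0 = int(round((t_peak - dur / 2) * rate))
                tt = np.arange(m) / rate
                burst = np.hanning(m) * np.sin(2 * np.pi * carrier * tt
                                               + rng.uniform(0, 2 * np.pi))
                burst *= amp / max(np.abs(burst).max(), 1e-12)
                for c in hpc_idx:
                    sig[c, j0 : j0 + m] += burst
                ripple_rows.append(dict(trial=int(tr["trial"]), time=t_peak,
                                        duration=dur, carrier=carrier,
                                        region="HPC"))

        # --- reinstatement envelope over the post-encoding window ---
        # One latent modulation process per trial: ripple-locked bumps
        # riding on a slow ongoing fluctuation. The amygdala expresses this
        # envelope directly (amplitude scaled by arousal); on correctly
        # discriminated Lure trials the hippocampus expresses a CAUSALLY
        # smoothed copy (exponential kernel with mean delay amy_lead), so
        # amygdala activity predicts hippocampal activity over a spread of
        # forward lags — the directional coupling the lagged-MI analysis
        # is built to detect.
        w0, w1 = tr["stim_offset"], tr["response_time"]
        k0, k1 = int(round(w0 * rate)), int(round(w1 * rate))
        nw = k1 - k0
        if nw < int(0.1 * rate):
            continue
        tw = w0 + np.arange(nw) / rate
        gammas = np.exp(rng.normal(0, p.react_gain_jitter_sd, size=len(keep)))

        def envelope(shift: float) -> np.ndarray:
            env = np.zeros(nw)
            for t_peak, g in zip(keep, gammas):
                c0 = t_peak + p.react_delay - shift
                env += g * np.exp(-0.5 * ((tw - c0) / (p.react_halfwidth / 2)) ** 2)
            return env

        slow = _smoothed_chi(rng, nw, rate, p.react_mod_timescale)
        lead = p.amy_lead if (is_lure and correct) else 0.0
        m_amy = envelope(lead) + p.react_mod_floor * slow
        if lead > 0:
            # causal exponential smoothing, mean delay = amy_lead
            a = np.exp(-1.0 / (lead * rate))
            m_hpc = sps.lfilter([1.0 - a], [1.0, -a], m_amy)
        else:
            m_hpc = envelope(0.0) + p.react_mod_floor * slow

        g_amy = p.react_gain_amy if ar01 >= p.amy_arousal_gate else 0.0
        g_hpc = p.react_gain_hpc if (is_lure and correct) else 0.0
        ramp = np.ones(nw)
        nr = int(0.02 * rate)
        ramp[:nr] = np.linspace(0, 1, nr)
        ramp[-nr:] = np.linspace(1, 0, nr)
        for region_idx, g, env in ((amy_idx, g_amy, m_amy), (hpc_idx, g_hpc, m_hpc)):
            if g <= 0:
                continue
            carrier_noise = _shaped_burst(rng, nw, rate, prof, 1.0, window=False)
            for c in region_idx:
                sig[c, k0:k1] += g * env * ramp * carrier_noise
        for t_peak, g in zip(keep, gammas):
            if g_hpc > 0:
                react_rows.append(dict(trial=int(tr["trial"]), region="HPC",
                                       center=t_peak + p.react_delay,
                                       t0=max(t_peak + p.react_delay - p.react_halfwidth, w0),
                                       t1=min(t_peak + p.react_delay + p.react_halfwidth, w1),
                                       gain=g_hpc * g))
            if g_amy > 0:
                react_rows.append(dict(trial=int(tr["trial"]), region="AMY",
                                       center=t_peak + p.react_delay - lead,
                                       t0=max(t_peak + p.react_delay - lead - p.react_halfwidth, w0),
                                       t1=min(t_peak + p.react_delay - lead + p.react_halfwidth, w1),
                                       gain=g_amy * g))

    rec = Recording(signal=sig, rate=rate, channels=names, regions=regions)
    gt = GroundTruth(
        ripples=pd.DataFrame(ripple_rows,
                             columns=["trial", "time", "duration", "carrier", "region"]),
        reactivations=pd.DataFrame(react_rows,
                                   columns=["trial", "region", "center", "t0", "t1", "gain"]),
        template_profiles=profiles,
        amy_lead=p.amy_lead,
        effects=dict(arousal_rate_effect=p.arousal_rate_effect,
                     correct_rate_effect=p.correct_rate_effect,
                     react_gain_amy=p.react_gain_amy,
                     react_gain_hpc=p.react_gain_hpc,
                     ripple_amp_snr=p.ripple_amp_snr),
    )
    return rec, gt


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
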