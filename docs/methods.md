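# Methods

## Scope and model

`ripplemem` implements an analysis pipeline for simultaneous hippocampal
(HPC) and amygdala (AMY) intracranial EEG recorded during an emotional
memory encoding/discrimination task, together with a synthetic-data
generator that emulates the task and signal structure so that every stage
can be validated against exact ground truth. The scientific chain is:

1. **Preprocessing** — zero-phase FIR notch at the line frequency and its
   harmonics (2 Hz notch width, transition ~0.25 Hz), demeaning, 4th-order
   zero-phase Butterworth high-pass at 0.3 Hz, anti-aliased integer
   downsampling (low-pass at 0.8 x the new Nyquist), and re-referencing of
   each depth channel to a white-matter channel.
2. **Ripple detection** — analysis epochs concatenated; band-pass 80–150 Hz
   with a 4th-order Chebyshev type II filter applied forward–backward;
   Hilbert analytic amplitude, blanked ±75 ms around concatenation
   boundaries; envelope z-scored over the concatenated trace; events kept
   when the envelope stays above z = 2 for 20–100 ms with a peak above
   z = 5. Chance level comes from running the identical detector on a
   Gaussian surrogate whose spectrum matches the channel PSD (white noise
   shaped in the frequency domain by √PSD). Channels are retained when
   their ripple count z-scored across channels exceeds −2 **and** exceeds
   the surrogate count; the max-count channel per participant is used.
3. **High-frequency activity (HFA)** — ensemble empirical mode
   decomposition (EEMD) of each channel; intrinsic mode functions with an
   energy-weighted Hilbert instantaneous frequency above 30 Hz are
   variance-normalized and summed. This avoids the 1/f-weighted bias a
   plain 30–280 Hz band-pass would impose.
4. **Time–frequency power** — complex Morlet wavelets at 30–280 Hz (1 Hz
   default grid) with cycle numbers n = 2..10, Gaussian width
   B_n = n/(5f); per time–frequency bin the geometric mean of the nine
   cycle-specific magnitudes. Convolution runs over the whole session in
   the Fourier domain; epochs are cut afterwards, so there are no epoch
   edge effects. Per trial, each frequency is z-transformed within the
   epoch (−1 s to response) and the mean pre-stimulus baseline (−1–0 s) is
   subtracted.
5. **Representational similarity** — power-spectral vectors (PSVs) in
   100 ms bins at 10 ms steps (a 2-s encoding epoch gives exactly 200
   bins); stimulus similarity is the Fisher-transformed Spearman
   correlation between each encoding-bin PSV and each response-bin PSV of
   the same trial; the response-bin trace is the unweighted mean over
   encoding bins. Ripple-locked traces sample this trace in ±250 ms windows
   around HPC ripple peaks (10 ms grid); samples overlapping the encoding
   epoch or beyond the response are treated as missing. Chance level:
   ripple times circularly jittered by ±500 ms within the window from
   post-encoding onset to the end of the next fixation (1000 iterations by
   default); the real trace is z-scored against that null
   ("ripple-triggered" similarity) for conditional contrasts.
6. **Statistics** — paired cluster-based permutation tests (per-bin paired
   t, cluster-forming alpha 0.05, max-|cluster sum| null over sign flips,
   exhaustive when 2^n is small), Benjamini–Hochberg FDR, Wilcoxon
   signed-rank (exact for n ≤ 25), and lagged mutual information between
   the two regions' ripple-locked similarity traces: 200 ms bins at 10 ms
   steps over the ±250 ms window; for each time bin the similarity values
   are discretized into uniform-count (quantile) bins across events — the
   identical rule for every participant, region, and condition, which
   makes every marginal uniform and the plug-in bias symmetric between
   directions. The directional index at bin t is the mean plug-in MI with
   all strictly later bins of the other region, and the AMY→HPC minus
   HPC→AMY difference is tested per bin by Wilcoxon and corrected by
   cluster permutation.
7. **Behavior** — discrimination scoring (Repeat→Old, Lure→New,
   Novel→New; participants need ≥85% Novel accuracy), the Lure
   Discrimination Index LDI = P(New|Lure) − P(New|Repeat), and a
   random-intercept logistic model of Lure responses on valence, arousal,
   and lure-pair similarity (each normalized to [0, 1] relative to its
   rating scale), fitted by maximum likelihood with 25-node Gauss–Hermite
   quadrature and analytic gradients.

## Synthetic data generator

`synthdata` simulates one participant per call. The task: 148 encoding
trials (1 s fixation, 2 s stimulus, self-paced rating up to 2 s) and a
retrieval block of 54 Repeat + 97 Lure + 139 Novel probes. Because
54 + 97 > 148, Lure parents are drawn first and Repeat parents may overlap
them (the printed counts exceed the encoded set; the overlap is 3 stimuli
at default counts). Lure responses follow a logistic model with
coefficients (on [0, 1]-scaled predictors) intercept 0.3, valence +0.3,
arousal +1.5, similarity −1.5, participant intercept SD 0.5; Repeat and
Novel accuracies default to 0.89 and 0.94. These effect sizes are free
parameters of the generator — chosen once as moderate, recoverable effects
— since the source analyses report standardized statistics rather than
generative effect sizes.

The recording covers the encoding block: per channel, 1/f-shaped Gaussian
background (exponent 1, 10 µV, normalized by the *expected* rather than
realized SD so channels are statistically exchangeable), a 6 Hz theta
component (5 µV), and 60 Hz line noise (2 µV). Hippocampal channels carry
Hann-windowed ripple bursts (carrier uniform in 80–150 Hz, duration
30–80 ms, amplitude 15× the band SD of the background) whose per-trial
Poisson rate is log-linear in stimulus arousal (slope 1.5 per unit
arousal) and in later Lure discrimination (slope 1.7), base rate 1.3
events/s in the post-encoding window; bursts are kept at least 600 ms
apart so neighbouring ±250 ms analysis windows never overlap each other's
reinstatement (overlap would plant spurious *backward* coupling). Each
stimulus owns a random smooth spectral template over 30–280 Hz, injected
during its encoding epoch (4 µV) in both regions. The ripple band plus
guard margins (75–155 Hz) is notched out of every template so planted
reinstatement cannot masquerade as a ripple and detector validity and
reinstatement strength remain independently controllable.

Reinstatement is modeled as a per-trial nonnegative modulation envelope:
Gaussian bumps (half-width 80 ms) trailing each planted ripple by 80 ms
with shared lognormal per-ripple gains (SD 0.7), plus a shared ongoing
fluctuation (squared smoothed noise, ~80 ms timescale, 0.7 relative
weight). The amygdala expresses this envelope directly (gain 5 µV) on
trials whose normalized arousal exceeds 0.5 — reinstatement of arousing
stimuli is gated, not graded, because rank-based similarity saturates
quickly in injection gain, so graded scaling mostly adds between-region
amplitude noise without producing measurable contrast. On later-correct
Lure trials the hippocampus expresses a *causally smoothed* copy of the
amygdala envelope (exponential kernel, mean delay `amy_lead` = 100 ms,
gain 5 µV): the amygdala therefore predicts hippocampal reinstatement
over a spread of forward lags, which is exactly the structure the
lagged-MI analysis is built to detect. Gains sit deliberately below the
similarity saturation knee so that per-ripple amplitude variation maps
onto similarity ranks. Trailing the ripple by 80 ms keeps the hippocampal
reinstatement clear of the similarity artifact that the ripple itself
produces (the large narrowband burst displaces the ranks of the
ripple-band frequency bins, depressing measured similarity within ±60 ms
of the peak — an artifact shared with real recordings).

A `GroundTruth` record logs every planted burst and reinstatement window,
so recall/FDR/peak-error and reactivation-timing recovery can be measured
exactly.

### What the generator does not emulate

Epileptiform discharges, electrode geometry and volume conduction,
sharp-wave components, non-stationary background, realistic inter-regional
phase coupling, or amygdala ripple-like events. Passing recovery tests on
this generator shows the *pipeline* is correct and calibrated — not that
the biological claims hold in real recordings.

## Numerical choices

- Chebyshev type II corners sit 25% outside the 80–150 Hz passband (the
  type II design is specified by its stopband; corners at 80/150 would
  leave a ~90–135 Hz passband and crush band-edge events).
- Envelope runs separated by <10 ms are merged before duration screening.
  A longer merge gap (30 ms) chains weak sidelobe shoulders into >100 ms
  runs that the duration screen then rejects.
- Fisher transform clipped at |ρ| = 1 − 1e-10; constant PSVs (zero rank
  variance) yield similarity 0 and are flagged.
- Cycle magnitudes are floored at the smallest positive float before the
  geometric mean; the wavelet normalization constant is irrelevant because
  power is z-scored per frequency downstream.
- EEMD uses sign-paired noise (each realization added and subtracted), so
  the averaged IMFs plus residual reconstruct the input to machine
  precision at any ensemble size; sifting stops by the S-number criterion
  (S = 4, max 50 siftings); default ensemble 100, noise SD 0.2× signal SD.
  IMF center frequency is the energy-weighted mean Hilbert instantaneous
  frequency.
- Quantile binning breaks ties by value order then index (stable sort), so
  bin counts differ by at most one and the assignment is deterministic.
- Surrogates scale the white-noise spectrum by amplitude (√PSD), matching
  the stated goal of an identical spectral slope; squaring (multiplying by
  the PSD itself) would distort the slope.
- The GLMM reports Wald standard errors from the observed information;
  apparent separation (|β| > 15) triggers a flagged ridge-penalized refit.
- Random numbers: a single study seed is expanded into independent
  per-stage, per-participant substreams via SHA-256 (`stage_seed`), all
  below 2³¹, so any stage can be re-run in isolation bit-identically.

## Desk-scale study conditions

The validation study (`pipeline.desk_scale_config`) runs 10 synthetic
participants at 600 Hz with 56 encoding trials (50 Lure parents — close
to the task's 97/148 proportion), a 2 Hz wavelet grid, a 6-member EEMD
ensemble capped at 8 modes, 200 jitters and 500 permutations. Analysis
conventions (bands, thresholds, windows, PSV and MI binning geometry)
keep their standard values. One deliberate reduction: the lagged-MI
discretization uses a per-time-bin median split (2 uniform-count bins)
instead of 10. The plug-in MI of N events over a k×k grid needs
N ≫ (k−1)²; at the tens of ripples per scaled participant a 10-bin grid
saturates toward log₂N in both directions and its variance swamps the
directional contrast, while the median split keeps the estimator
informative and low-variance. The 10-bin default remains in place for
full-scale data.

## Known limitations

- The detector's duration screen inherits the classic envelope method's
  blindness to events merged with adjacent band-power elevations.
- The similarity measure is depressed at the ripple peak itself by the
  ripple's own rank displacement of band frequencies (see above); analyses
  of ripple-locked similarity at lag ≈ 0 partially reflect this artifact,
  in synthetic and real data alike.
- Plug-in MI is biased upward at small samples; the per-time-bin
  uniform-count discretization makes the bias symmetric so it cancels in
  the directional contrast, but the estimator's *variance* at desk-scale
  event counts (tens of ripples per participant) is of the same order as
  the planted directional effect. The group-level cluster test on the
  AMY→HPC contrast therefore has limited power at this scale: it recovers
  the planted 100 ms lead on most simulated cohorts but not all, whereas
  the rate, arousal, and outcome recoveries are comfortably powered. A
  reliable directionality detection needs the event counts of a
  full-scale recording session.
- The GLMM supports a single random intercept (participant); random slopes
  are out of scope.
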