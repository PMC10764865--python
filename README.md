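# ripplemem

Analysis pipeline for awake hippocampal ripples and emotional-memory
reactivation in human intracranial EEG, with a synthetic-data generator
that makes every stage testable against exact ground truth.

## The problem

During an emotional memory task, people encode an image, rate its valence
(the *post-encoding* period), and later discriminate repeats from similar
lures. Hippocampal ripples — transient 80–150 Hz oscillations of
20–100 ms — occurring in the post-encoding period are hypothesized to
reinstate the just-encoded stimulus across the hippocampus (HPC) and
amygdala (AMY), and thereby to strengthen the memory of emotionally
arousing stimuli. Testing this requires several non-trivial ingredients
this package provides as a coherent, validated chain:

- **Ripple detection** on band-limited Hilbert envelopes with a
  spectrally matched Gaussian surrogate as chance-level control and
  channel-selection QC;
- **High-frequency activity (30–280 Hz)** reconstructed from ensemble
  empirical mode decomposition (EEMD) rather than a 1/f-biased band-pass;
- **Multi-cycle Morlet power**: at each frequency f the geometric mean of
  magnitudes across cycle numbers n = 2..10, with Gaussian width
  B_n = n/(5f);
- **Stimulus similarity**: Fisher-transformed Spearman correlation
  r(t₁,t₂) between z-scored power-spectral vectors of 100 ms bins from the
  encoding (t₁) and response (t₂) periods of the same trial, averaged into
  ±250 ms ripple-locked traces and tested against a ±500 ms circular
  jitter null;
- **Statistics**: paired cluster-based permutation tests (summed-t cluster
  statistic, sign-flip max-cluster null), Benjamini–Hochberg FDR, exact
  Wilcoxon signed-rank, and lagged mutual information
  MI(X;Y) = H(X) + H(Y) − H(X,Y) on uniform-count-binned similarity
  traces to quantify AMY→HPC directionality;
- **Behavior**: lure discrimination scoring, the Lure Discrimination Index
  LDI = P(New|Lure) − P(New|Repeat), and a random-intercept logistic
  model of trial-level discrimination on valence, arousal, and lure-pair
  similarity (maximum likelihood via Gauss–Hermite quadrature).

The synthetic generator (`ripplemem.synthdata`) emulates the task design
(148 encoding trials; 54/97/139 Repeat/Lure/Novel retrieval probes), 1/f
background with theta and line noise, planted ripple bursts whose rate
depends on arousal and later discrimination, and stimulus-specific
spectral templates reactivated around ripples with the amygdala leading
the hippocampus by 100 ms on correctly discriminated trials — all logged
in a ground-truth record. See `docs/methods.md` for the model and every
numerical choice.

## Worked example

```python
from ripplemem import synthdata, ripples, pipeline

# one synthetic participant: task + behavior + two-region iEEG
design, trials = synthdata.generate_task(seed=0)
print(len(trials[trials.phase == "encoding"]),
      trials[trials.phase == "retrieval"].type.value_counts().to_dict())
# 148 {'Novel': 139, 'Lure': 97, 'Repeat': 54}

_, small = synthdata.generate_task(3, n_encoding=24, n_repeat=3,
                                   n_lure=20, n_novel=5)
rec, truth = synthdata.generate_recording(small, seed=3)
view = synthdata.encoding_lure_view(small)
epochs = [(r.fixation_onset, r.response_time) for _, r in view.iterrows()]
events = ripples.detect_ripples(rec.trace("HPC1"), rec.rate, epochs,
                                channel="HPC1")
chance = ripples.chance_count(rec.trace("HPC1"), rec.rate, epochs, seed=1)
print(len(events), "ripples detected,", truth.n_ripples, "planted,",
      chance, "expected by chance")
# 18 ripples detected, 21 planted, 0.0 expected by chance
# (4 of the 24 encoding trials are not Lure parents, so their planted
#  ripples fall outside the analysis epochs by design)
```

The full study — synthesis, preprocessing, detection with surrogate QC,
EEMD/HFA, wavelet power, ripple-locked similarity with jitter nulls,
conditional cluster tests, and lagged-MI directionality across
participants — runs via

```bash
ripplemem all --seed 7 --out results/run7
```

which writes per-participant trial and ripple tables (tab-delimited,
provenance-stamped with the config hash) and a `summary.json` holding the
group statistics: Wilcoxon p-values for the arousal and discrimination
ripple-rate contrasts, cluster p-values for the regional
similarity-by-condition contrasts, the AMY-vs-HPC similarity peak
latencies, and the per-condition lagged-MI directionality clusters.

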