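# Methods

`callrec` is a framework for designing, tuning and validating automated
call recognizers — detectors that scan long field recordings for the
vocalization of a target species and emit scored candidate matches. Because
real monitoring recordings are rarely shareable, the package ships a
synthetic chorus generator that plays the role of the field data: every
experiment in the package (threshold selection, variable sensitivity
analysis, training-data scaling, transferability) runs end-to-end on
simulated scenes with exact ground truth.

## The synthetic chorus model

A scene is a set of recordings organized as sites × recordings-per-site.
Each recording contains:

- **Calls.** A Poisson number of calls (mean `calls_per_recording`), each a
  train of 1–4 nearly identical syllables — raised-cosine-enveloped tone
  pulses (default 40 ms syllables separated by 30 ms gaps). The syllable
  count is drawn from `syllable_count_probs`. Call intervals may overlap;
  every emitted call appears exactly once in the annotation table.
- **Hierarchical frequency variability.** The dominant frequency of a call
  is `dominant_freq_hz` plus independent Gaussian effects at three levels:
  site (`sd_site_hz`, default 60 Hz), recording within site
  (`sd_recording_hz`, 25 Hz) and call within recording (`sd_call_hz`,
  10 Hz). With the recording- and call-level deviations set to zero, all
  calls at a site share one frequency and the among-site variance of call
  frequency equals `sd_site_hz²` — a property the tests verify.
- **Background noise.** Gaussian white noise (optionally 1/f "pink") at a
  fixed reference RMS. The call gain is calibrated per recording so that the
  *segment-based SNR estimator* (below) recovers the configured `snr_db`:
  if call-containing 1-s grid segments carry mean call power `p_sig` and the
  noise power is `P_n`, the gain solves
  `a² p_sig = P_n (10^(snr/10) − 1)`. Defaults follow the study design this
  emulates: a clean training world near 13 dB and noisier test worlds down
  to ~3 dB.
- **Interferers.** Non-target chirps at `interferer_rate_per_min` (default
  2/min). Half start near the target band and sweep several hundred Hz
  across it; half sit elsewhere in the spectrum. They trigger detections
  without cloning a call, supplying realistic false-positive opportunities.

Dataset groups for transferability mirror the train/A–D design: train
(its own sites, year 1), A (same sites, year 2), B (new sites, year 1), C
(new sites, year 2) and D (a disjoint "region": site effects shifted by
`2·sd_site_hz` and SNR reduced by 3 dB). Every group holds eight
recordings, five with calls and three without.

**What the generator does not emulate:** species-accurate spectra, weather
and recorder artifacts, overlapping choruses of multiple species, and
diurnal call-rate structure. Passing tests therefore demonstrate that the
*framework* behaves correctly (thresholds, penalties, rankings, regressions,
transfer bookkeeping), not that any particular error rate will be achieved
on real recordings.

A symbolic fast path (`synth_match_table`) emits verified TP/FP match tables
directly from annotations — miss probability, extra syllable-level hits,
and a Poisson FP rate — for evaluation-layer tests that need no audio.

## The surrogate recognizer

Commercial recognizers score candidates with proprietary models; here the
detector is a transparent template matcher with the same interface: nine
tunable build variables and matches scored 0–100.

1. **Spectrogram.** Hann window, `fft_size` samples, `fft_overlap`
   fraction; power restricted to the fixed band
   [`band_min_hz`, `band_max_hz`] (the band is excluded from tuning).
2. **Band energy processing.** Per-frame band energy in dB is clamped from
   below at (recording max − `dynamic_range_db`), then a running-average
   background over `background_filter_s` is subtracted.
3. **Syllable segmentation.** Frames more than 6 dB above the median of the
   processed energy are signal (the offset is a documented constant, keeping
   the tunable set at exactly nine). Gaps ≤ `max_syllable_gap_ms` are
   bridged; each bridged syllable remembers how many primitive bursts it
   merged; syllables longer than `max_syllable_ms` are discarded.
4. **Song assembly.** Consecutive syllables with gaps ≤
   `max_syllable_gap_ms` join a candidate song while the span stays ≤
   `max_song_ms`; candidates whose total primitive-burst count falls below
   `min_syllables` are dropped. Counting bursts (rather than post-bridging
   syllables) is what lets `min_syllables` act as a structural filter even
   though bridging and assembly share one gap parameter.
5. **Scoring.** The band-limited log-spectrogram of a candidate is resized
   to `feature_vector_length` × 12 (mean pooling when shrinking, linear
   interpolation when stretching — pooling preserves narrow spectral
   peaks) and mean-centred. The template is the mean feature summary of the
   annotated training calls, extracted identically. The score is
   100·max(0, normalized cross-correlation); zero-scoring candidates are
   dropped. A recording containing an exact copy of the single training
   call scores exactly 100.

With a small `max_syllable_gap_ms`, a 4-syllable call shatters into up to
four single-syllable matches — the mechanism behind conditional
sensitivities above 1.

## Evaluation

Matches are verified by any positive temporal overlap with an annotated
call. Two matching modes exist: `per-match` (default; many matches may hit
one call, so sensitivity can exceed 1) and `per-call` (greedy one-to-one by
descending score, under which tp + fn = number of calls at every
threshold).

- **Precision** = TP/(TP+FP) over matches at/above the threshold;
  1 − precision is the Type I (false discovery) rate.
- **Sensitivity** = retained TP matches / all true calls (detected or not);
  1 − sensitivity is the Type II rate.
- **True negatives** are uncountable in open audio; they are
  operationalized as verified-FP matches scoring below the threshold, which
  makes the ROC a discrimination task over scored candidates. ROC positives
  and negatives are match-level; conditional sensitivity deliberately uses
  the true-call denominator.
- **Threshold.** Candidate thresholds are the unique observed scores;
  Youden's J = tpr + tnr − 1 is maximized, ties resolving to the highest
  threshold (favoring precision; configurable). AUROC is trapezoidal. The
  implementation is verified against an exhaustive sweep and against an
  independent ROC library on random instances.
- **Subsampling penalty.** When multi-syllable hits push |TP| above the
  number of true calls N, each of `n_reps` (default 1000) repetitions
  retains a uniform without-replacement sample of N TPs, keeps all FPs,
  recomputes the Youden threshold on the reduced set, and recomputes the
  conditional metrics; reported penalized metrics are means over
  repetitions, and each repetition's sensitivity is ≤ 1 by construction.
  When no FPs remain the Youden threshold is undefined; the fallback keeps
  every retained TP (threshold = their minimum score), which reproduces the
  canonical worked example (1,000 calls, 1,500 equal-score TPs → penalized
  sensitivity exactly 1). A `recompute_threshold=False` variant freezes the
  full-set threshold instead.

## Variable tuning

Each of the nine build variables is evaluated independently over a grid
with all others held at base values (local, not joint, optimization —
interactions are deliberately out of scope). Per value: train, detect on
every evaluation recording, verify, compute penalized conditional metrics
per recording, and average. Sensitivity of performance to a variable is
ranked by the coefficient of variation (sd/mean) of the metrics across the
grid; CV ≥ 0.1 flags a sensitive variable. The CV can be computed from
penalized (default) or raw conditional sensitivity; the raw variant is the
one that exposes the multi-syllable blow-up of the gap variable, since the
penalty caps exactly the values that make that variable dominant.

Final settings minimize a normalized weighted error
`(w1(1−precision) + w2(1−min(sensitivity,1))) / (w1+w2)` per variable, with
schemes 1:1, 5:1 and 1:5 for different monitoring objectives; ties go to
the value closest to the base setting. A known limitation of local
optimization: independently optimal values can interact destructively
(e.g. a strict burst-count filter combined with a small gap detects
nothing); the default grids therefore hold `min_syllables` flat.

## Training-data scaling

`build_training_subsets` grows training data along one axis at a time —
calls per recording, recordings per site, or sites — holding the other two
constant, with nested (prefix) sampling so each level's calls contain the
previous level's. Achieved counts are recorded when the library runs short.
The relationship between metrics and training amount/source is modelled
with logit-link beta regressions (constant precision φ; boundary responses
shrunk by (y(n−1)+0.5)/n), compared by small-sample AICc
(−2ℓ + 2K + 2K(K+1)/(n−K−1)), Akaike weights and evidence ratios.
Pseudo-R² is the squared correlation between the linear predictor and
logit(y) — a convention, flagged as such. `run_scaling_experiment` wires
this end-to-end: in worlds where site-level frequency variability dominates,
the among-site model out-ranks the among-recording model in most replicate
worlds.

## Transferability

Selected recognizers are applied to the A–D groups using the score
threshold determined on the training group — never re-thresholded on test
data. Metrics are computed per recording (recordings without calls
contribute only to precision; sensitivity is undefined there), averaged per
group, and accompanied by BCa bootstrap confidence intervals with the
recording as the resampling unit (eight per group). Constant samples make
the BCa acceleration undefined; the interval then collapses to the point
(flagged `degenerate`), and non-finite BCa endpoints fall back to
percentile intervals.

The segment SNR estimator samples, without replacement, n (default 10)
disjoint 1-s grid segments overlapping calls and n call-free segments;
SNR = mean(20·log10 RMS) of the first group minus the second. Because the
synthesizer calibrates against this same definition, round-trip recovery
within 1.5 dB is a self-consistency check of both pieces.

The cumulative detection probability over N independent surveys with
per-survey detection probability p is 1 − (1−p)^N.

## Numerical choices and problem sizes

- All randomness flows from explicit seeds; pipeline stages derive named
  substreams from one root seed, so every stage is independently
  reproducible and reruns are byte-identical.
- Scores are clipped to [0, 100]; degenerate (constant) feature blocks
  score 0; spectrogram power gets a 1e-30 floor before dB conversion.
- Default in-package experiment sizes are chosen for desk-scale runs:
  recordings of 15–60 s at 8 kHz, 2–8 sites, grids of 2–3 values per
  variable, penalty reps 30–1000, bootstrap reps ≤ 2000. The statistical
  checks (enumeration agreement, calibration rates, coverage) use the
  replicate counts stated in their tests.
- The acceptance script reports quantities computed at runtime from these
  same components; `results/` directories are outputs, not inputs.

## Known limitations

- The detector is a deliberately simple template matcher; absolute error
  rates are not comparable to commercial recognizers, only the design
  procedure around them is.
- Overlapping calls can merge into a single candidate (or exceed
  `max_syllable_ms` and be discarded); the framework counts them as
  separate annotations regardless.
- Local optimization cannot see variable interactions (see above).
- Beta regression assumes constant dispersion; no dispersion covariates.
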