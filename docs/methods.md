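# Methods

## Latent arousal model

The synthetic generator models per-second brain arousal as a latent level on
the vigilance-score scale (1–6):

    L(t) = start_level + drift_per_min * t / 60 + e(t),   e(t) ~ N(0, volatility^2)

thresholded by five strictly decreasing cutpoints (default 5.5, 4.5, 3.5,
2.5, 1.5) into the six stages.  This is deliberately phenomenological: the
object of interest is the *speed and depth of the vigilance decline*, not a
neural mechanism, and a drifting thresholded diffusion reproduces exactly the
three prototypical regulation patterns.  Preset parameters (chosen once as
the study conditions and not revisited):

| preset      | start | drift/min | volatility | behaviour |
|-------------|-------|-----------|------------|-----------|
| hyperstable | 5.7   | −0.01     | 0.25       | expected latent stays above the 0/A1 cut for 15 min |
| adaptive    | 5.3   | −0.18     | 0.45       | reaches B territory around minute 10 |
| instable    | 2.3   | −0.35     | 0.60       | starts below the B2/3 cut, C within minutes |

Lowering the drift can only deepen the expected stage, so the expected MVV is
monotone in the drift (tested over seed ensembles).

## Signal synthesis

Each stage maps to a spectral recipe: rms amplitudes (µV) per band (delta
1–4, theta 4–8, alpha synthesized at 8.5–11.5, broadband 1–45 Hz) and per
region (occipital / anterior / other).  Band-limited Gaussian noise is shaped
by per-second amplitude envelopes (0.2-s smoothing avoids clicks), plus a 1/f
background whose amplitude is `background_uV / snr`.  Alpha is synthesized
below 12 Hz so it cannot leak into the spindle (sigma) detection band.

Event models use conventional sleep-EEG parameterizations, none of which are
prescribed by the staging definition itself:

- **spindles**: 13.5-Hz bursts of 0.5–1 s, Hann envelope, 25 µV peak,
  strongest centrally;
- **K-complexes**: biphasic one-cycle transients of 0.7–0.9 s normalized to
  120 µV peak-to-peak, strongest frontally;
- **slow eye movements** (SEMs): anti-phase 0.3-Hz EOG excursions of 60 µV,
  gated on during B1 segments and dilated ±0.5 s (a SEM outlasts one epoch);
- **artifact segments**: ±150 µV square bursts.

Every stage-C second receives at least one event by construction
(`graphoelement_rate >= 1`); events are confined to their second so that the
per-second ground-truth labels stay crisp.

What the generator does *not* emulate: volume conduction / forward head
modelling, eye blinks and EMG, inter-subject spectral variability (e.g.
individual alpha frequency), medication effects, and non-stationarities such
as arousals-from-sleep.  Passing round-trip tests therefore show that the
classifier correctly decodes the stage signatures it was designed around —
they do not certify performance on clinical EEG, where thresholds would need
validation against expert staging.

## Feature extraction and staging

Features per 1-s epoch: Hann-periodogram band powers integrated per band and
averaged within region (µV²), total 1–30 Hz power, alpha share, the
anteriorization index (anterior alpha power / occipital alpha power), rms
amplitude, and event flags.  Detectors operate on recording-wide filtered
traces (FFT masking with raised-cosine edges, zero-phase): sigma-band Hilbert
envelope ≥ 3× the 25th-percentile background for ≥ 0.4 s → spindle; < 2.5 Hz
mean trace with a biphasic ≥ 75 µV peak-to-peak transient → K-complex;
0.1–1 Hz EOG difference signal with a ≥ 30 µV excursion sustained ≥ 1 s
(±1-epoch context) → SEM.  Epochs with any |EEG| > 100 µV or a flat channel
are artifacts and never staged.

The classifier cascade (graphoelements first, mirroring sleep-scoring
precedence): C → B2/3 → A split → 0/B1.  Decisions are scale-invariant by
design:

- **alpha dominance** (two-pass): best-region alpha share ≥ 0.45 *and* alpha
  power ≥ 0.25× the median alpha power of provisionally alpha-dominant
  epochs.  The share cut sits well above the chance level of the best-of-three
  -regions statistic on 1-s periodograms (~0.3 for alpha-free epochs) and
  well below genuine alpha epochs (~0.7+); the adaptive floor rejects
  low-alpha epochs in recordings that also contain genuine alpha.
- **theta/delta dominance**: (delta+theta)/total share ≥ 0.65.  A
  recording-median-derived cutoff was rejected because it degenerates on
  single-stage recordings (an all-B2/3 recording would raise its own cutoff
  above itself); the fixed share keeps a wide margin to both B1 (~0.45) and
  B2/3 (~0.95) epochs.
- **A1 vs A2/3**: anteriorization index < 1.0 → A1 (occipital dominance).
- **0 vs B1**: the SEM flag; without EOG a logged fallback uses rms < 0.7×
  the recording median (and the result is flagged by a warning, never a
  silent guess).

The K-complex amplitude criterion (75 µV) is conventionally absolute, so
strict label scale-invariance holds for gain factors that keep K-complexes
above that bound and everything under the artifact bound.  No temporal
smoothing is applied across epochs.

## Arousal parameters

Stage percentages use non-artifact segments as denominator, overall and per
60-epoch block.  MVV is the plain mean of scores (C=1 … 0=6).  The ASS
evaluates, per successive 1-min block on the block's non-artifact segments:
≥ 1/3 B segments (level 2), ≥ 1/3 B2/3 segments (level 3), ≥ 1 C segment
(level 4).  The deepest level ever fulfilled wins; within a level the
earliest fulfilling block's window (minutes 1–5 / 6–10 / 11–15) selects the
score (level 4 → 1/2/3, level 3 → 4/5/6, level 2 → 7/8/9).  If no block
criterion fires, level 1 applies: by default score 11 when < 1/3 of all
segments fall outside {0, A1}, else 10 (the fractional reading); a literal
"only 0/A1 ⇒ 11, only 0/A ⇒ 10" reading is config-selectable and falls back
to the fractional rule when neither set condition holds.  Blocks with > 50%
artifacts are skipped with a warning.  Strict mode requires exactly 15
blocks; lenient mode maps blocks onto thirds of the recording for the window
lookup.  Deepest-level precedence over block order follows the ladder's
ordering (a B2/3 block in minute 2 plus a single C in minute 14 scores 3,
not 4).

## Clinical scoring

The 6-item Bech melancholia subscore sums depressed mood, guilt, work and
activities, retardation, psychic anxiety (the psychic-anxiety item of the
17-item scale) and general somatic symptoms (0–4 each, somatic 0–2).
Missing items are rejected, never imputed.  Response = strictly more than
50% reduction from baseline; the strict inequality changes classifications
at the boundary (8 → 4 is a non-response) and a zero baseline leaves the
response undefined.

## Statistics

Summary-statistic t-tests (Welch and pooled Student) are first-class so that
printed group tables are directly checkable.  Chi-square on 2×2 tables is
Pearson's without continuity correction, df = 1.

The mixed repeated-measures ANOVA uses the classical univariate (split-plot)
approach: each within-subject effect is projected onto an orthonormal
contrast basis; Type-III sums of squares (unweighted group means, as SPSS
reports for unbalanced groups) are tested against the pooled within-group
error.  Greenhouse-Geisser epsilon comes from the pooled within-group
covariance of the contrast scores; Mauchly's W is tested with the standard
chi-square approximation, and the GG-corrected p-value is adopted *only*
when Mauchly's test is significant at 0.05 — reported alongside the
uncorrected p.  For a two-level within factor the F equals the squared
paired t and epsilon is exactly 1 (used as tests).  Because two arousal
outcomes (MVV, ASS) are tested, omnibus results are evaluated at alpha =
0.025.

The ordinal ASS is analysed with the nonparametric ladder (Mann-Whitney U
between groups, Wilcoxon signed-rank within group, Friedman across repeated
conditions); estimating-equation omnibus modelling for ordinal outcomes is
deliberately out of scope.  Exact p-values are used for small untied samples
(full enumeration for the Friedman test when the permutation count permits),
normal/chi-square approximations with tie correction otherwise, and the mode
used is always reported.

## Cohort generator and pipeline

The default cohort reproduces the emulated design: 17 responder patients, 10
non-responders, 16 controls, each with baseline and post-sleep-deprivation
recordings.  Clinical generative parameters (age, sex counts, baseline Bech
subscore means/SDs, reduction fractions 0.755 / 0.18, sleepiness scores)
follow the descriptive statistics of that design; item vectors are filled by
randomized allocation under the per-item caps.  Arousal profiles: patients
hyperstable at baseline; responders destabilise to adaptive after the
intervention while non-responders stay hyperstable; controls go adaptive →
instable.  No effect sizes for the group differences are prescribed
anywhere; these assignments were chosen once to mirror the qualitative
pattern (patients more stable than controls on both days; controls
destabilising most) and are part of the study conditions, not tuning knobs.

The pipeline stages every recording (or, in `ground_truth` mode, consumes
the generator's stage sequences directly — useful for sequence-level
analyses at scale), computes metrics, classifies response, and emits the
report tables.  Per-recording failures are counted as exclusions with
reasons in the run log and never abort a run.  All outputs are deterministic
per cohort seed (seeds propagate cohort → subject → recording).

Problem sizes used in the shipped test suite: 900-s recordings at 250 Hz
with 10 channels (8 EEG + 2 EOG); 20-seed round-trip ensembles; 1,000
random timecourses against the brute-force ASS oracle; 500-replicate null
simulations for the ANOVA type-I rate; and one full 43-subject × 2-day
classify-mode study run.  The 1000-Hz / 31-channel acquisition geometry is
available through configuration.

## Known limitations

- Staging thresholds are declared defaults validated on the generator's
  signatures, not harmonized against any proprietary threshold table or
  expert-staged clinical EEG.
- The ASS window lookup in lenient (non-15-min) mode is an extrapolation;
  the score is defined for 15-min recordings.
- The mixed ANOVA requires a complete, balanced within-subject design;
  subjects with missing cells must be excluded (the error names them).
- Friedman exact enumeration is capped (default 10^5 permutations) and
  skipped in the presence of ties.
- The EDF writer emits plain EDF (16-bit, 1-s records, integer sampling
  rates); EDF+ annotations are not supported.
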