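# Methods

This note documents the models, the numerical choices, and the places where
the design was genuinely open, in the order the pipeline runs.

## Stochastic figure-ground stimuli

A trial is 80 consecutive 50-ms chords (4.0 s at 44.1 kHz). Component
frequencies live on a geometric grid from 1 to 8 kHz in 1/48-octave steps
(145 points), so "same frequency" is exact set membership, not a floating
tolerance. Every chord holds 8 distinct grid components: 6 drawn uniformly
from all subsets with pairwise separation ≥ 0.5 octave, plus 2 drawn freely
from the remaining grid. On figure trials the separated subset is frozen
across the entire second half (segments 41–80) — that repetition is the
"figure" a listener can only find by grouping across frequency; on ground
trials (and in every first half) it is redrawn each segment.

Two design points deserve explanation:

* **Why every segment uses the 6-separated + 2-free recipe.** A strict
  pairwise half-octave constraint on all 8 components is geometrically
  impossible (7 gaps × 0.5 octave > 3 octaves). Constraining only the
  figure, with fully unconstrained backgrounds, creates a subtle confound:
  unconstrained components collide into the same cochlear analysis channel
  more often, and after concave loudness-growth compression the figure
  class carries measurably more integrated current — the very cue the
  stimulus design must exclude. Using the same within-segment recipe for
  both classes makes every segment's acoustic and encoded statistics
  identically distributed, so neither energy nor current can cue the class;
  only the across-segment repetition differs. Both controls below verify
  this.
* **Sampling the separated subset.** Subsets are drawn exactly (no
  rejection) via the gap bijection: sorted grid indices with pairwise index
  gap ≥ 24 map one-to-one onto 6 distinct values from a grid shortened by
  5 × 23, which `numpy` samples directly. The draw is uniform over all
  valid subsets; rejection sampling is hopeless here (acceptance ≈ 2e-5).

Each 50-ms chord is a sum of equal-amplitude sine pips with independent
random phases and 5-ms raised-cosine on/off ramps (the source description
is silent on per-pip ramping; unramped 50-ms gates splatter spectrally).
Pips are re-started each segment, i.e. figure components are not
phase-continuous across segments. Every finished waveform is peak-normalized
to the same value so class membership is not decodable from peak amplitude.
Sessions pre-generate n/2 figure + n/2 ground unique stimuli in
seed-randomized order; every generator is a pure function of (spec, seed).

## Ripple and modulation stimuli

Ripple noise is white noise shaped in the frequency domain: the
log-magnitude envelope is `(depth/2)·sin(2π·density·octaves + phase)` dB
above the 100-Hz band edge (band 100 Hz–8 kHz; "broadband" is not pinned
down further by the task description), so `depth` is the peak-to-trough
spectral contrast in dB. The oddball of a trial carries the same depth with
the phase advanced by π; both standards share one random phase per trial.
Density defaults to 1.25 ripples/octave.

The modulation stimulus sums five carriers (1515, 2350, 3485, 5045,
6990 Hz) with random phases under the envelope `(1 + m·sin 2π·20t)/(1+m)`;
depth is `20·log10(m)` dB so the adaptive track works on the same dB axis
as the ripple task, and m > 1 raises an explicit overmodulation error.
Both stimuli are 500 ms with 50-ms linear ramps. Oddball triplets are
RMS-equalized, then each interval is independently roved uniformly within
±3 dB and the oddball position is uniform over the three slots.

## UML adaptive procedure

The posterior over (α, ln β, γ) lives on a 61 × 21 × 11 grid (α: −42 to
+3 dB; ln β: ±1.5; γ: 0.10–0.60), updated in log space by exact pointwise
Bayes after each Bernoulli response and renormalized with `logsumexp`;
likelihoods are clipped to [1e-12, 1−1e-12] so the log-posterior never
degenerates. Sequential updating is exactly equivalent to a single batch
posterior on the grid (tested to 1e-10).

The published description of this family of procedures fixes the
psychometric family and the "optimally informative next stimulus" idea but
not the specific rule or priors, so:

* **Priors** (pilot values are not public): α ~ N(−18, 10) dB,
  ln β ~ N(0, 0.5), γ ~ Beta(3, 6) (mean 1/3, matching 3AFC chance), all
  evaluated on the grid and configurable.
* **Selection** follows the sweet-point scheme: on the current
  posterior-mean function, the mid point is where the logistic core reaches
  0.707, and the two slope sweet points minimize ψ(1−ψ)/(∂ψ/∂β)² below and
  above α (found numerically on an 801-point level grid). Selection cycles
  mid → high → low and clamps to the stimulus domain (−40 to 0 dB; 0 dB is
  the physical full-modulation limit).
* **Estimates** are posterior means; the crossover estimate is E[α].
  Practice trials are excluded from inference.

With a β = 1, γ = 1/3 observer, 70-trial sessions recover crossovers across
[−30, −5] dB with |bias| ≲ 0.1 dB and MAE ≈ 0.4 dB (200 sessions) — far
inside the 1.5/3-dB acceptance envelope, which leaves room for the less
ideal observers real listeners are. A lapse rate is deliberately not
modelled (the three free parameters are threshold, slope, guess rate); a
lapsing observer will bias the slope and, mildly, the crossover.

## Scoring

d' uses the inverse normal of hit and false-alarm rates with the log-linear
correction (+0.5 per cell, +1 per denominator) applied *always*, not only
at 0/1 rates — this keeps the estimator finite and continuous; `clip`
(1/(2N)) and `none` are available for comparison. The simulated
figure-detection observer is equal-variance SDT with criterion d'/2
(unbiased) unless specified. Speech-in-noise scores are exact word ratios.

## ACE encoder and the current control

The encoder is the standard n-of-m signal path with one canonical
configuration standing in for the heterogeneous clinical maps of a real
cohort: resample to 16 kHz, 128-point Hann FFT at a hop matching 900 pps
per channel, bins 2–63 (187.5–7937.5 Hz) grouped into 22 bands (widths
1,1,…,2,…,8 bins), per-frame selection of the 8 largest band envelopes,
and logarithmic loudness-growth compression
`log(1+ρ·(v−B)/(S−B))/log(1+ρ)` with ρ = 416.2, base level 0.0156 and
saturation 0.5859 re full scale. Amplitudes are dimensionless normalized
current units; "integrated current" is their sum over pulses in a window
(a mean would change nothing in a rank test at equal trial counts).
Patient-specific T/C levels, current spread and loudness summation across
electrodes are out of scope.

The control analysis encodes 60 ground + 60 figure stimuli and compares
integrated current in the 2–4 s window (where the figure lives) with a
two-sided Wilcoxon rank-sum test (normal approximation, tie-corrected).
With the segment recipe above the classes are identically distributed per
segment and the test is null by construction; observed p-values across
seeds fall in ≈ 0.5–0.9.

## Synthetic cohorts and the regression chain

The generator draws standardized predictors (figure-detection d', ripple
crossover, modulation crossover), builds the standardized outcome as
`Σ βᵢ xᵢ + ε`, and back-transforms to natural units with fixed fixture
constants (d' ~ 1.2 ± 0.7; ripple 15 ± 6 dB, floored at 0; modulation
−15 ± 5 dB, capped at 0; speech score 0.55 ± 0.18, clipped to [0, 1];
acoustic threshold 59.4 ± 20.5 dB HL, independent of everything). The
published work prints no per-task means/SDs, so these are plausible values
for a post-lingually deafened CI cohort; clipping affects < 1% of draws.

One structural fact drives the generator's main design decision: for
*independent* standardized predictors, the population R² equals Σβ², and
the published betas (0.292, −0.250, −0.434) give 0.336 — not the published
R² of 0.463. The two numbers are jointly consistent only if the predictors
carry small correlations whose cross-terms contribute the missing ≈ 0.127.
The generator therefore solves `β'Rβ = R²_target` for the
minimal-magnitude, sign-matched equal-|r| off-diagonal structure
(|r| ≈ 0.206 at the defaults) and draws predictors with that correlation;
the betas remain the true standardized coefficients, so a large-n fit
recovers betas *and* R² simultaneously, and the implied bivariate
correlation between figure detection and speech score comes out ≈ 0.43 —
close to the published 0.45 without being targeted. Consequences worth
knowing:

* population pairwise |r| ≈ 0.21 sits below the n = 47 significance bound
  (≈ 0.29), but roughly a quarter of sample correlations per pair will
  nominally exceed it — a single real cohort showing no significant
  predictor correlations is consistent with, but not guaranteed by, this
  structure;
* `target_r2=None` gives exactly independent predictors (population
  R² = 0.336), which is the mode the null collinearity-screen tests use;
* `residual_sd=0` gives a noise-free outcome (R² = 1 up to clipping).

The regression itself z-scores all four variables and fits OLS
(statsmodels): the slopes are the normalized betas, SE/t/p come from the
standardized fit (t is scale-invariant, so this matches the raw-units fit),
partial ρ for each predictor is the correlation of the two residual vectors
after regressing predictor and outcome on the remaining predictors
(cross-checked against an independent implementation in the tests),
adjusted R² = 1 − (1−R²)(n−1)/(n−k−1) — which maps 0.463 to 0.426 at
n = 47, k = 3 — and the F-test is the standard overall test on (k, n−k−1)
degrees of freedom. Two-sided p-values throughout; no multiple-testing
correction is applied anywhere in the chain. The acoustic threshold is
screened for collinearity but never enters the model.

## What the simulations do and do not show

Simulated observers obey the fitted model family exactly (logistic
psychometrics, equal-variance SDT, linear-Gaussian cohort structure). The
recovery results therefore validate the *measurement and inference chain* —
that the procedures estimate what they claim, at the study's trial and
sample sizes — not the behavior of real CI listeners, who lapse, drift,
and violate distributional assumptions in ways no fixture constant
captures. Problem sizes used by the test suite and acceptance script
(200 adaptive sessions, 500 scoring sessions, one 120-stimulus encoded
session, cohorts at n = 47 and 4700) were chosen as the smallest sizes at
which the Monte-Carlo error is comfortably below each tolerance.

## Known limitations

* The ACE configuration is one canonical device; the published control
  p-value depends on the clinical maps and is reproduced as a property
  (p > 0.05), not a number.
* No loudness model: dB SPL levels are metadata, and the ±3 dB rove is in
  digital gain.
* The UML implementation models no lapse rate and treats the guess rate as
  free within 0.10–0.60; sessions from observers far outside the prior's
  support will be prior-dominated early.
* Natural-unit fixture constants are package choices; any future release of
  the raw measures would replace them.
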