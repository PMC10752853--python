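# figground

A simulation and analysis pipeline for a question in computational
audiology: does the ability to *group* spectrally coherent sound elements —
over and above raw spectral and temporal resolution — predict how well
cochlear-implant (CI) users understand speech in noise?

The package is for auditory psychophysicists and CI researchers who want to
(1) synthesize the three stimulus classes used to probe these abilities,
(2) run and validate the adaptive measurement procedures against simulated
observers, (3) verify at the electrodogram level that the figure-ground
stimuli are not trivially decodable from overall current, and (4) fit and
power-check the cohort-level regression model — all without access to raw
subject data.

## What it implements

**Stimuli** (`figground.stimuli`)

* *Stochastic figure-ground (SFG) tone clouds*: 4-s sequences of 80 × 50-ms
  chords, each built from 8 components on a 145-point grid spanning 1–8 kHz
  in 1/48-octave steps. On "figure" trials, 6 components (pairwise ≥ 0.5
  octave apart) repeat through the entire second half; detecting them
  requires cross-frequency grouping.
* *Spectral ripple noise*: broadband noise whose log-magnitude envelope is
  sinusoidal in log-frequency (1.25 ripples/octave); discriminating a
  phase-inverted oddball indexes spectral resolution as a function of
  ripple depth (dB).
* *Amplitude-modulated complexes*: five carriers (1515–6990 Hz) modulated
  at 20 Hz; detecting modulation of depth `20·log10(m)` dB indexes
  temporal-envelope resolution.
* Oddball trial assembly with RMS equalization and ±3 dB level roving, and
  16-bit/44.1-kHz WAV output.

**Adaptive estimation** (`figground.adaptive`) — an updated
maximum-likelihood (UML) Bayesian procedure over the three-parameter
logistic

```
psi(x) = gamma + (1 - gamma) / (1 + exp(-beta (x - alpha)))
```

with exact grid Bayes updates after every trial and sweet-point stimulus
selection. The crossover `alpha` (dB depth) is the per-subject measure of
spectral or temporal fidelity; 70-trial sessions recover it to well within
1 dB of bias.

**Scoring** (`figground.scoring`) — yes/no sensitivity
`d' = z(hit rate) − z(false-alarm rate)` with a log-linear rate correction,
and word-ratio speech-in-noise scores.

**Electrodogram control** (`figground.electrodogram`) — a canonical
22-channel, 8-of-22, 900-pps ACE encoder (FFT filterbank + loudness-growth
compression) and a rank-sum comparison of integrated current between
ground-only and figure+ground stimuli in the 2–4 s window, verifying the
figure cannot be detected from current level alone.

**Cohort statistics** (`figground.stats`, `figground.cohort`) — synthetic
47-subject cohorts whose population structure matches the published model
(normalized β = 0.292 / −0.250 / −0.434 for the SFG, ripple and modulation
measures, R² = 0.463), plus the full inference chain:

```
azbio ~ 1 + sfg_dprime + ripple_crossover_db + tm_crossover_db
```

with normalized β, SE, t, p, partial ρ, R², adjusted R² and the overall
F-test, a predictor collinearity screen, bivariate correlations, and
partial-residual (added-variable) views.

## Worked example

Simulate an adaptive session against a known observer:

```python
import figground as fg

observer = fg.PsychometricParams(alpha=-15.0, beta=1.0, gamma=1/3)
state, est = fg.run_adaptive_session(fg.UMLConfig(), observer, seed=4)
print(f"crossover estimate: {est.alpha:.2f} dB (true -15.00)")
```

```
crossover estimate: -14.17 dB (true -15.00), slope 1.25, guess rate 0.27
```

The 70-trial Bayesian track lands within ~1 dB of the observer's true
crossover. Or run the whole simulated study from the shell:

```bash
figground simulate-study --seed 11 --out study/
# n=47: R^2=0.651, adjusted R^2=0.627, F(3,43)=26.7
```

which writes `cohort.csv`, `collinearity.csv`, `bivariate.csv`,
`regression_table.csv` (one row per predictor: normalized β, SE, t, p,
partial ρ), `regression_model.json` and a partial-residual figure. At
n = 47 the fitted numbers scatter around the generating structure — the
run above drew a cohort with R² = 0.651 against a population value of
0.463; across many seeds the median sample R² is ≈ 0.50 and each predictor
is significant in the majority of cohorts.

Other subcommands: `figground synthesize` (WAV stimulus sets + manifest),
`figground adapt` (one UML session log), `figground electrodogram`
(pulse-pattern CSV + raster), `figground score` (d' from a trial log).

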