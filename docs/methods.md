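# Methods

`erpindiff` re-implements, as one tested pipeline, an individual-differences
analysis of gender-agreement ERPs in heritage bilinguals: language-experience
composite scores from questionnaire data, single-participant quantification
of the N400 and P600 from GAM-smoothed difference waves, and mixed-effects
regressions of those indices on proficiency, exposure/use and formal
instruction crossed with morphological markedness. A synthetic-data module
generates the full study design so that every stage runs, and can be
validated, without any external data.

## Study design being modelled

The task is a grammaticality judgment experiment crossing Grammaticality
(agreeing vs disagreeing postnominal adjective) with noun Markedness
(masculine = unmarked/default, feminine = marked). The two ungrammatical
cells define the two error types: a *Feature Clash* error (masculine noun,
feminine adjective) and a *Default* error (feminine noun, masculine
adjective). Stimuli comprise 900 sentences over three lists of 420: per list,
160 experimental gender trials (40 per condition, half transparent and half
opaque noun endings, all nouns inanimate) and 80 unrelated-study sentences
unique to the list, plus 150 fillers and 30 determiner-noun violations shared
across lists (720 list-unique sentences in total). EEG epochs span −200 to
950 ms around the adjective.

## Composite scores

For each language, the Exposure-and-Use score is
`sum_j w_j * (H_j / K)` over the four modalities (reading, writing, speaking,
listening), with daily hours `H_j`, weights `w_j = .25` and scaling constant
`K = 16`. Hours are deliberately not capped at `K`; the formula is applied
literally, so more than 16 reported hours per day yields a score above 1.

The *Ratio of Exposure and Use* is computed as the Spanish share
`es / (es + en)`. A plain quotient `es / en` is available behind
`ScoreConfig(ratio_convention="quotient")`; the share is the default because
it is bounded in [0, 1] and therefore well-scaled as a regression predictor,
and because the observed distribution of such ratios in this population
(mean ≈ .32, SD ≈ .23) is consistent with a bounded share.

Dominance (`sum_j w_j (P_j/14 + H_j/(2K))`, with self-ratings `P_j` on 1–7)
and Immersion (`0.5 * sum_j w_j ((Age − AoA_j)/Age + YoU/Age)`) are computed
for comparison but are not model predictors: dominance double-dips on
proficiency, which enters the models separately as LexTALE, and immersion has
almost no variance in a cohort homogeneous in age and acquisition onset. The
per-modality AoA entering Immersion is taken to be the language-level age of
first acquisition applied to all four modalities, since modality-resolved
onset ages are not part of the simulated questionnaire.

Before modelling, `screen_predictors` reports pairwise Pearson correlations
among the numeric predictors and a two-sample test of each numeric predictor
across instruction groups, flagging anything with p < .05; constant columns
are flagged rather than raised.

## Synthetic data generator

Each trial's waveform at electrode `e` is

    amplitude(t) = sum_c s_c(condition) * gain_e * A_c(participant, error) * g_c(t)
                   + u_item + eps(t)

with Gaussian component bumps `g_c` (N400: centre 420 ms, width 80 ms,
negative; P600: centre 650 ms, width 150 ms, positive), switched on only for
ungrammatical trials. Defaults: N400 base amplitude −1.8 µV for Default and
−2.4 µV for Feature Clash errors; P600 +2.2 / +2.8 µV — the markedness
asymmetry (larger effects for Feature Clash) built into the means.
`gain_e` is a fixed topography vector with centro-parietal sites (Cz, CP1,
CP2, Pz) at 1.0 falling to 0.8 fronto-laterally, mirroring the
central-posterior scalp distribution of these components.

Participant covariates enter the component amplitude linearly,
`A_c = base_c(error) + sum_k beta[c, error, k] * (x_k − mu_k)`, with numeric
covariates centred at their configured population means so that `base_c` is
the population-mean amplitude while covariate *differences* scale exactly by
`beta`. The default effect map encodes the qualitative pattern the analysis
is designed to detect: LexTALE → P600 +0.10 µV/point for both error types
(≈ 0.9 µV per population SD), Spanish exposure share → N400 −4 µV/unit for
Default errors only (≈ 0.9 µV per SD), and instruction → −1.5 µV on both the
N400 and P600 of Feature Clash errors. Magnitudes were fixed once by power
arithmetic at n = 39 (a detectable but not overwhelming signal); a latency
effect hook exists with the same keying but ships empty, so covariates move
amplitudes, not latencies, by default.

Noise has three levels: a per-item constant offset (SD 1 µV, shared across
participants seeing the item), a per-participant, per-component-and-error
amplitude deviation (SD 0.8 µV — idiosyncratic component reactivity, which
is what gives the mixed models genuine random intercept and slope variance),
and stationary AR(1) noise per trial × electrode (marginal SD 8 µV,
coefficient 0.95 at 250 Hz). AR(1) is a deliberate simplification of the 1/f
spectrum of real EEG: it reproduces the slow autocorrelation that makes
smoothing and pointwise SEs non-trivial at desk scale, but not the
oscillatory structure, ocular artifacts, or channel cross-correlation of
real recordings — so passing tests demonstrate correctness of the analysis
chain, not robustness to every property of real EEG. Gender-assignment
errors are Bernoulli with rate 0.1, a typical accuracy level for heritage
speakers on such tasks.

The default sampling rate is 250 Hz (1000 Hz is supported by configuration);
at 250 Hz the epoch grid runs −200 to 948 ms in 4 ms steps. All randomness
derives from one seed through named substreams (design, cohort, items,
epochs, assignment), making every artifact bit-reproducible.

Cohort distributions mimic the target population: the participant-level
Spanish share of daily use is Beta-distributed with mean .32 and SD .23 (the
ratio score inherits this mean, which a 10,000-draw check confirms to
±0.02); LexTALE is normal (64.7, 8.9) truncated to [0, 100]; age normal
(20, 1.55); Spanish is acquired from birth, English at 3.7 ± 2 years; 18 of
39 participants have formal instruction.

## Preprocessing

Conditioning follows the recording pipeline the epochs are meant to have
seen: optional re-referencing to the mastoid average, a 0.1–30 Hz Butterworth
band-pass of order 2 per edge ("12 dB slope" read as 12 dB/octave, hence
order 2; 12 dB/decade would imply a non-integer order), applied
forward–backward for zero phase so that latency measures are not biased by
filter delay, then baseline correction over −200 to 0 ms and, for the
`correct_only` dataset variant, removal of trials whose noun was assigned
the wrong gender in the assignment task. Filtering is applied per epoch with
100 ms odd-reflection padding — a documented deviation from filtering
continuous data, which the synthetic pipeline never has. Two consequences
are worth knowing: the 0.1 Hz high-pass edge rings for seconds, so its
steady-state gain is only observable on long signals (the tests measure
passband/stopband gains on 40 s sines), and on a 1.15 s epoch the high-pass
mostly acts as a gentle detrend, with baseline correction doing the real
offset removal. The synthetic pipeline skips re-referencing by default
(simulated data are generated already referenced); the operation exists for
real recordings.

## Difference smoothing and index extraction

For each participant × error type × electrode, the model

    amplitude_trial(t) = f0(t) + u_trial * f1(t) + b_item(trial) + eps

is fitted by penalized least squares, where `u` indicates ungrammatical
trials, `f0`/`f1` are cubic B-spline expansions (20 basis functions over the
epoch) with a second-difference penalty, and the item intercept is absorbed
as a ridge-penalized coefficient block — the random-effects-as-penalties
view of a GAM. `f1` is the smoothed ungrammatical-minus-grammatical
difference wave. One smoothing parameter is shared by `f0` and `f1` and
selected per cell by GCV on a 9-point log grid (the item ridge on a 4-point
grid); a fixed-λ mode exists and is checked against a dense generalized-
ridge oracle `(X'X + λD'D)^{-1} X'y` to 1e-8. GCV assumes independent
residuals and therefore undersmooths somewhat under AR(1) noise; the
20-function basis bounds how wiggly the result can get, and the calibration
study (below) shows the downstream inference is unaffected. The pointwise
standard error of `f1` is the smoother sandwich
`se(t)^2 = σ² b(t)' (X'X+P)^{-1} X'X (X'X+P)^{-1} b(t)` restricted to the
`f1` block — a pointwise, not simultaneous, band.

Because balanced cells share one design layout, the expensive
design-dependent factors (Gram blocks, Cholesky factors, effective degrees
of freedom, sandwich profiles) are computed once per layout and reused
across electrodes, participants and Monte-Carlo replicates.

From the fitted curve, inside the N400 search window (200–550 ms) and the
P600 window (400–950 ms):

* **MPL** (Modeled Peak Latency): latency of the windowed extremum of `f1`
  (minimum for the N400, maximum for the P600) on a 1 ms grid, ties broken
  to the earliest latency;
* **NMP** (Normalized Magnitude Peak): `f1(MPL) / (1.96 · se(MPL))`, signed
  — for the N400 a *more negative* NMP means a *larger* effect.

A peak on a window edge sets `boundary_flag`; a windowed magnitude below
1e-6 µV sets `flat_flag` with NMP 0. Flagged rows are kept in the models by
default (a switch drops them). Cells missing either condition side, or with
fewer than two trials per side, are skipped and logged. Note that the two
component templates overlap in time, so the extremum of the noiseless
composite difference curve is shifted slightly away from each bump centre
(the N400 minimum sits near 407 ms, not 420 ms, under the default
templates); recovery tests compare against the analytic composite curve.

## Mixed-effects models

Each of the four responses (N400/P600 × MPL/NMP) is modelled as

    y ~ Error_sum * (LexTale_O_C + Ratio_Exp_Spanish_C + Instruction_sum)

with sum-coded factors — the first level alphabetically maps to +1, so
Default = +1, FeatureClash = −1 and instructed = +1 (these codings are
echoed in every report so coefficient signs are interpretable) — and numeric
predictors centred on the analysis sample. Fitting is REML via statsmodels
MixedLM. The random-effect ladder starts maximal and simplifies until a fit
converges: (participant intercept + Error slope, correlated | uncorrelated |
intercept only) × (participant-by-electrode intercept | none), trying two
optimizers (L-BFGS, then Powell) per rung, with a terminal fixed-effects-only
fallback for data that support no random structure. A by-electrode effect is
represented as a participant × electrode variance component (nested) because
the fitter cannot combine a correlated by-participant slope with a fully
crossed electrode intercept; for balanced designs the variance attribution
is equivalent for the fixed-effect inference of interest. One test
cross-checks the maximal fit against lme4's
`(1 + Error | participant) + (1 | participant:electrode)` estimates.

Inference: degrees of freedom follow a containment-style between–within
rule — terms involving participant-level regressors (all covariate mains and
interactions, and the participant-randomized Error effect) are tested
against `n_participants − p_between` df, purely within-participant terms
against residual df. Confidence intervals are Wald (±1.96 SE). Response
values are exactly linear in the predictors (zero residual variance) are
short-circuited to the exact least-squares solution. VIFs are computed on
the main-effect columns only, since interactions with centred predictors
inflate VIF mechanically.

Post hocs relevel Error Type: each error type in turn becomes the reference
of a dummy-coded refit (same random structure), whose covariate main effects
are the simple slopes within that error type; instruction is reported as the
instructed-minus-uninstructed difference (twice the sum-coded coefficient).
p-values are Bonferroni-multiplied within each predictor's family of two
comparisons and capped at 1. Relevelling is a pure reparameterization:
fitted values agree and the REML criteria differ exactly by the Jacobian of
the coding map, which a test asserts.

## Validation studies and problem sizes

Two Monte-Carlo studies exercise the full chain (simulate → filter →
extract → model) at study scale (39 participants, 12 electrodes, 40
trials/condition, 250 Hz):

* **Null calibration** — all covariate effects zero; the rejection rate of
  each of the twelve Error × covariate interaction terms (3 terms × 4
  models) at α = .05 must lie in the binomial band around .05, taken in its
  simultaneous (Bonferroni-adjusted across the twelve dependent rates) form
  so the family-wise check has the stated 95% coverage. The test suite runs
  50 replicates and the acceptance script 40; one replicate costs roughly
  8 s on one CPU, and these sizes keep the studies inside a desk-scale run
  while leaving the band formula untouched.
* **Directional recovery** — the generator's default effect map on; at least
  80% of replicates (40 in the suite, 30 in the script) must show the
  qualitative target pattern: a significant positive LexTALE main effect on
  P600 NMP, a significant negative Error × Exposure interaction on N400
  NMP, and an exposure simple effect for Default but not Feature Clash
  errors.

## Known limitations

* The generator's AR(1) noise and Gaussian bumps are caricatures of real
  EEG; no ocular artifacts, no 1/f spectrum, no cross-channel covariance,
  no real lexical material (item ids are abstract).
* GCV undersmooths under autocorrelated noise, and the sandwich SE treats
  residuals as independent; both are shared with common GAM practice but
  mean the NMP denominator is somewhat optimistic on strongly autocorrelated
  data.
* The between–within df rule is an approximation chosen for transparency;
  exact finite-sample df for crossed designs would need a Satterthwaite or
  Kenward–Roger machinery the fitting backend does not expose.
* Real-data ingest (long CSV, FIF epochs, BrainVision/EDF segmentation) is
  implemented and unit-tested on synthetic data only; reproduction from the
  original deposit is wired up but requires that data to be present.
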