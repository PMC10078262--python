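# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `idatheta`.

## 1. The observer model: surprise and local redundancy

Movement sequences are categorical streams over {normal, high}. Two
trial-level quantities describe what an ideal observer extracts from
them.

**Surprise** is Shannon information under sequential Dirichlet–
multinomial prediction. With pseudo-counts α (default α = [1, 1], an
unbiased prior in which each label carries the weight of one prior
observation), the predictive probability of label x after history X is

    p(x | X, α) = (k_x + α_x) / (|X| + Σα),

and surprise is I = −log2 p, in bits. On a constant stream surprise at
trial t equals −log2(t/(t+1)) and decreases strictly toward 0; on a
variable stream in which both labels keep occurring it stays bounded away
from 0. The implementation is the incremental counting form; the test
suite checks it against an independent Polya-marginal oracle
(log-gamma marginal-likelihood ratios) for all short sequences.

**Local redundancy** is R_N = ln(k_normal!) + ln(k_high!) over the most
recent min(t, N) trials, N = 6 by default. It is maximal (ln 720 ≈ 6.58)
for a pure window and minimal (2·ln 6 ≈ 3.58) for a balanced one, and
depends only on window counts, never order.

Choices made where the procedure was open:

- *Log base of R_N*: natural log. The base is a constant factor that the
  z-transformation removes, so downstream regression results are
  invariant to it.
- *Window shorter than N at stream start*: the growing window of all
  available trials is used, keeping the predictor defined on every trial.
- *Looked-away trials*: removed from the observed stream **before** any
  history-dependent computation — the observer model only sees what the
  infant saw. The alternative (unseen trials still update the counts) is
  available as `unseen_updates_history=True`, default off.
- *First variable trial*: the first *retained* (looked) trial of the
  variable condition is flagged excluded, since it cannot carry any
  information about variability. Applying the rule after the looked mask
  is the only ordering that makes the retained-count arithmetic
  deterministic regardless of where the looked-away trials fall.
- *z-scoring*: within subject, across all retained trials pooled over
  conditions (mean 0, SD 1, checked to 1e-8).

## 2. The EEG spectral chain

Epochs are trials × channels × samples at 500 Hz, −1.0…+0.5 s around
goal attainment, generated/stored with 0.5 s padding on each side.
Processing order: zero-phase (forward–backward) 4th-order Butterworth
band-pass 1–30 Hz on the padded data; crop padding; per-epoch demeaning;
re-referencing to the average of the two mastoid channels; linear
detrending; Hann-tapered FFT retaining 3–30 Hz; mean power over bins
whose centre lies in the closed 4–5 Hz band. With the 1.5 s window the
bin spacing is 2/3 Hz, so the theta band holds the bins at 4.000 and
4.667 Hz, and the window contains exactly six cycles of 4 Hz.

**Normalization contract.** Power is amplitude-calibrated: a
unit-amplitude sinusoid centred on a bin reads power A²/2 = 0.5 at that
bin (taper coherent gain compensated). Under a Hann taper this is *not*
energy-conserving across bins — sidelobes carry extra energy — which is
irrelevant here because only relative condition differences and
regressions on z-scores are consumed downstream. The filter family
(Butterworth) is a convenience choice; what is tested is the passband
contract (< 5% amplitude attenuation at 4.4 Hz), not the filter brand.

**Inclusion rules**, in order: (1) drop looked-away trials; (2) drop each
subject's first remaining variable-condition trial; (3) drop subjects
with fewer than 8 retained trials in any condition (boundary inclusive).
An exclusion report records counts and reasons.

## 3. Synthetic cohorts

The generator states the emulated world once; its defaults are not tuned.

- 23 subjects × 3 conditions × 20 presented movements (4 blocks × 5).
- Retained-trial counts drawn uniformly from the published
  post-artifact-rejection ranges: 11–20 (normal), 11–20 (high), 9–16
  (variable); the variable condition keeps one extra looked trial because
  its first retained trial is excluded downstream.
- Trial theta: log θ = log m_c + b0 + u_s + b_I·z_surprise +
  b_T·z_trial + ε, with condition medians m_c = 8.53 / 7.84 / 10.35
  (normal / high / variable — the published channel-Fz means, giving
  variable > normal ≈ high), b_I = 0.3, b_T = 0.15, σ_log = 0.6, and a
  subject intercept u_s ~ N(0, τ²) with τ² = ρ/(1−ρ)·σ²/n̄ (ρ = 0.7, the
  repeated-measures correlation the study's power analysis assumed;
  n̄ = 14 retained trials).
- EEG forward model: 1/f-shaped Gaussian background (power ∝ 1/f) plus a
  4.4 Hz sinusoid with random phase per trial (shared across scalp
  channels), whose amplitude is set so the extracted 4–5 Hz band power
  equals the requested trial theta in expectation; the sinusoid gain and
  the expected noise contribution to the band are both calibrated once
  through the actual spectral chain (the noise calibration uses a fixed
  internal seed, so the forward model stays deterministic given its
  seed). Mastoids carry low-amplitude independent noise.
- Behavior: three binaries per subject drawn from logistic models on
  z-scored subject theta in the variable condition, with base rates taken
  from the published outcome tallies (12/22, 14/23, 6/23) and positive
  weight on the two theta-linked outcomes. The published correlations are
  reported with a negative sign for binary-coded outcomes whose coding
  direction is unstated; the generator exposes `binary_coding`
  ("success_high" default → positive correlations; "success_low" flips
  the sign).

What a green test does establish: the estimators recover what this
generator encodes — linear log-scale structure, stationary 1/f noise, an
isolated band-limited oscillation, independent trials given the subject
intercept. What it does not: robustness to artifacts (blinks, motion),
non-stationary backgrounds, volume conduction, or model misspecification
in real infant EEG.

**Recovery cohorts.** Parameter-recovery checks generate from the exact
generative mirror of the fitted Surprise+Trial model (equal condition
medians). With unequal condition medians the condition contrast is
confounded with surprise — the variable condition has both higher
surprise and higher theta — and the pooled two-predictor fit absorbs that
contrast into the surprise slope (visible in the README example). That is
a property of the design, not an estimator defect, so coverage is
assessed where the model is correctly specified.

## 4. Group statistics

The repeated-measures ANOVA is the classical two-way (subject ×
condition) decomposition; degrees of freedom are reported uncorrected
(df = 2, 44 at n = 23, c = 3), with Greenhouse–Geisser ε available as an
optional diagnostic but not applied, matching common practice for this
design. Partial η² = SS_effect/(SS_effect + SS_error) satisfies
pes = df_e·F/(df_e·F + df_err) identically. The Bonferroni correction
(α/3 = 0.0167) applies to the three channel ANOVAs; pairwise paired
t tests are reported at uncorrected p and flagged as such.

Partial correlations use the residual method (linear removal of controls
with intercept, Pearson correlation of residuals), df = n − 2 − k,
p from t = r·√(df/(1−r²)). With zero controls this is exactly Pearson.
Collinear controls or zero residual variance raise informative errors.

**Power.** Monte-Carlo: condition scores are multivariate normal with
unit total SD, compound-symmetric correlation ρ and a fixed mean pattern
scaled so Cohen's f (SD of condition means over within-cell SD) matches
the request. Because the within-subject error variance is (1−ρ)σ², the
standard within-design noncentrality λ = n·m·f²/(1−ρ) arises without any
explicit inflation factor; the simulation agrees with the analytic
noncentral-F power (0.870 at n=20, f=0.25, ρ=0.7) to ±0.01. The mean
pattern's shape is irrelevant given f; a centred linear pattern is used.

## 5. Lognormal GLM and AIC

`LognormalGLM.fit()` maximizes the lognormal likelihood, equivalent to
OLS on log θ with ML dispersion σ̂² = RSS/n. The log-likelihood includes
the Jacobian −Σ log θ_i, so AIC = 2k − 2·logL (k = coefficients +
dispersion) is comparable across response-scale density families.
Standard errors use the unbiased dispersion (RSS/(n−p)), i.e. classical
OLS SEs. Candidate sets {I,T}, {LR,T}, {T}, {I}, {LR} are fitted on an
identical trial set (listwise deletion over the union of predictors,
enforced by an internal invariant) and ranked by AIC with ΔAIC relative
to the best model.

**Response normalization.** A lognormal response must be positive, but a
z-transformed response is not. Default: per-subject division by the
subject median (positivity-preserving, absorbs subject offsets on the log
scale — the pooled fixed-effects fit then needs no random effects). The
z-then-shift alternative (`zscore_shift`, minimum shifted to 0.05) is
provided for comparability but its shift is arbitrary on the log scale;
results are reported for the default. Trial number is z-scored within
subject, like the other predictors.

## 6. Numerical notes

- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; sequence generation keys its stream on
  (seed, CRC32(condition), order index) so it is reproducible across
  processes (no Python string hashing).
- Variable-order generation is rejection sampling over per-video label
  counts {2,3} with maximum run length 2; the published example order
  satisfies these constraints.
- Degenerate ANOVA input (zero condition and zero error variance)
  returns F = 0 rather than NaN.
- `sigma_log` is floored at 1e-12 to keep the likelihood finite in the
  noise-free limit.
- Filter edge transients on non-periodic inputs (e.g. a pure ramp) leave
  residuals below 1% of the input RMS inside the analysis window; the
  0.5 s padding exists precisely to keep these outside it.

## 7. Limitations

- The GLM pools trials across subjects with subject-median normalization
  instead of explicit random slopes; heterogeneous per-subject slopes
  would inflate the pooled dispersion.
- The forward EEG model is a single sinusoid in stationary 1/f noise; it
  validates the spectral chain's calibration, not artifact robustness.
- Published test statistics that depend on the deposited infant
  recordings (F values, condition means' significance pattern, absolute
  AIC values, behavioral correlations) are not reproduction targets of
  the synthetic pipeline; only the design-level power target is.
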