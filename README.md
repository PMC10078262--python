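# idatheta

Tools for studying **how movement variability in infant-directed action
demonstrations drives infants' attention**, indexed by frontal theta-band
EEG power (4–5 Hz at Fz/FCz/Cz). When a caregiver (or, here, an avatar)
shows an infant an action, they can repeat every movement identically or
vary the movement amplitude. Variable demonstrations are both more
*complex* (less redundant) and more *surprising* (less predictable); this
package implements the trial-level modelling that disentangles the two.

The package provides, as a reusable and fully tested pipeline:

- **Experimental design** — per-condition movement-amplitude sequences
  (normal / high / variable; 4 blocks × 5 movements), Latin-square
  counterbalancing of action–condition assignments.
- **Information measures** — per-trial *surprise* under a sequential
  Dirichlet–multinomial observer,
  `I_t = −log2 [(k_x + α_x)/(n + Σα)]` with flat prior α = [1, 1], and
  *local redundancy* `R_N = ln(k_normal!) + ln(k_high!)` over a moving
  window of N = 6 trials.
- **EEG spectral chain** — zero-phase 1–30 Hz band-pass, demeaning,
  mastoid re-referencing, detrending, Hann-tapered FFT (3–30 Hz) over the
  −1.0…+0.5 s epoch around goal attainment, 4–5 Hz band extraction, and
  the trial/subject inclusion rules (looked-away trials dropped, first
  variable trial dropped, ≥ 8 trials per condition).
- **Group statistics** — repeated-measures ANOVA with partial η²,
  Bonferroni-corrected channel follow-ups with paired t tests, partial
  correlations between subject theta and behavioral outcomes, and
  Monte-Carlo power for the three-condition within-subject design.
- **Lognormal GLM model comparison** — `LognormalGLM` /
  `LognormalGLMResults` model objects (statsmodels-style: build, `fit()`,
  `summary()`) for `log θ ~ Normal(Xb, σ²)`, ranked by AIC over the
  candidate predictor sets {I,T}, {LR,T}, {T}, {I}, {LR}
  (I = surprise, LR = local redundancy, T = trial number).
- **Synthetic cohorts** — a generator with known ground truth (lognormal
  trial theta, 1/f EEG with an embedded 4.4 Hz oscillation, binary
  exploration/learning outcomes), so the whole chain is testable without
  any infant recordings.

## Worked example

```python
from idatheta import simulate, glm
from idatheta.stats import power_rm_anova

# a-priori power of the design: n=20, Cohen's f=0.25, rho=0.7
res = power_rm_anova(20, f=0.25, rho=0.7, alpha=0.05, n_sims=5000, seed=1)
print(res.power, res.se)          # 0.874 +/- 0.0047

# synthetic 23-infant cohort, then the trial-level model comparison
truth = simulate.GroundTruth(n_subjects=23, seed=1)
cohort = simulate.simulate_cohort(truth, seed=1)
df = cohort.predictor_frame()
df = df[df.included].rename(columns={"theta_true": "theta_power"})
df["theta_norm"] = glm.normalize_theta(df)          # subject-median scaled
table, fits = glm.compare_models(df, response="theta_norm")
print(table)
print(fits["I, T"].summary())
```

prints

```
model  k       loglik         aic  delta_aic
 I, T  4  -976.230778 1960.461555   0.000000
    I  3 -1010.083815 2026.167629  65.706074
LR, T  4 -1068.616396 2145.232792 184.771237
   LR  3 -1123.584025 2253.168051 292.706496
    T  3 -1148.983462 2303.966925 343.505370

Lognormal GLM (log link on the response scale)
  nobs = 1028, k = 4, sigma_log = 0.6131
  loglik = -976.231, AIC = 1960.46

  term                coef        se        t         p    [0.025    0.975]
  const             0.0200    0.0191    1.043    0.2974   -0.0176    0.0575
  I                 0.4056    0.0200   20.235    0.0000    0.3662    0.4449
  T                 0.1674    0.0200    8.354    0.0000    0.1281    0.2067
```

The simulated power reproduces the design's a-priori target (≈ 0.85).
The model containing Surprise and Trial Number wins the AIC comparison,
and both slopes are positive: more surprising movements and later trials
go with higher frontal theta. (The fitted surprise slope, 0.41, exceeds
the generating within-condition slope of 0.30 because this cohort is
generated with a higher theta median in the variable condition, which the
pooled two-predictor model absorbs into the surprise term.)

A full end-to-end run — synthetic EEG epochs, spectral extraction,
inclusion rules, group statistics and model comparison, with a manifest —
is available from the command line:

```bash
idatheta all --seed 5 --out run_output
```

## Acceptance script

`scripts/acceptance.py` recomputes the Monte-Carlo statistical power of
the three-condition repeated-measures ANOVA at n = 20 subjects,
Cohen's f = 0.25, repeated-measures correlation 0.7 and alpha 0.05
(5000 simulated cohorts) and writes it to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
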