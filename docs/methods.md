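# Methods

## The problem

Standard automated perimetry measures light-sensitivity thresholds (in dB of
stimulus attenuation) at the 54 locations of the 24-2 grid; glaucoma care
tracks these values over years to decide whether an eye is progressing.  Three
features of the data break ordinary least-squares trend analysis:

* **Censoring.**  The instrument cannot report below 0 dB; true thresholds
  beyond the floor are recorded as 0.  Treating recorded zeros as measurements
  drags fitted slopes towards stability (a positive bias on negative slopes),
  worst in eyes with advanced damage where a trail of 0 dB values accumulates.
* **Heteroskedasticity.**  Test-retest SD grows steeply as sensitivity falls —
  from roughly 1 dB near 35 dB to several dB below ~15 dB.
* **Spatial structure.**  Loss follows retinal nerve-fibre bundles, so nearby
  locations progress together; pointwise regressions ignore this, global
  summaries blur it.

## The model

For one eye, the sensitivity at informative location `l` (cluster `c(l)`) and
time `t` (years from baseline) has linear predictor

    mu_l(t) = (b0 + u0_c + w0_l) + (b1 + u1_c + w1_l) * t

with global fixed effects `(b0, b1)`, cluster random effects `(u0_c, u1_c)`
over the six optic-nerve-head sectors of the Garway-Heath map, and location
random effects `(w0_l, w1_l)` nested within clusters.  Random-effect pairs are
zero-mean bivariate normal with unknown covariances.  Three error models:

* `hi_linear` — `y ~ N(mu, sigma^2)`;
* `hi_censored` — the same Gaussian left-censored at 0 dB (a recorded 0
  contributes `P(y* <= 0)`, Tobit-style);
* `hi_hsk` — censored with `sigma = sd(mu)` from the bilinear variability
  model below, i.e. the noise level is imposed as a known function of the
  estimated sensitivity rather than estimated.

Progression evidence is the **P-score**: the posterior ECDF of a slope
evaluated at 0 dB/year (draws exactly at zero take half weight, so a
symmetric posterior scores exactly 0.5).  It is computed identically for the
global slope `b1`, cluster slopes `b1 + u1_c`, and location slopes
`b1 + u1_c + w1_l`.  The expected normal ageing decline is taken as
0 dB/year; a nonzero ageing allowance would simply shift the evaluation
point of the ECDF.

### Priors and initialisation

Fixed effects get normal priors centred on a fast frequentist initialisation
with SD 100 dB (intercept) and 10 dB/year (slope) — effectively flat over the
physiological range.  The initialisation is the pooled OLS of all pointwise
values on time, which for this balanced design (every location observed at
every visit) coincides with the mixed-model ML fixed effects; random-effect
covariance starts are method-of-moments from per-cluster/per-location OLS
deviations.  Random-effect covariances get a *scaled inverse-Wishart* prior:
an inverse-Wishart(df 2, scale 0.001·I) base matrix times redundant
per-component expansion scales with standard-normal priors.  This family is
deliberately weak and lets the variance components collapse towards zero when
the data support no heterogeneity — an earlier plain IW(3, 0.1·I) choice
measurably inflated the slope random-effect variance on stable series and was
replaced after the null-calibration diagnostic below flagged it.  The
residual variance (homoskedastic variants) gets inverse-gamma(0.01, 0.01).

### Sampler

Censored observations are data-augmented with latent values truncated above
at 0 dB, making the homoskedastic variants fully conjugate.  The key design
choice is a *joint* draw of all 118 regression coefficients per sweep: the 52
location blocks are marginalised analytically (a Schur complement of their
independent 2x2 precisions), the reduced 14-dimensional (global + cluster)
Gaussian is sampled, and the location blocks are back-filled from their exact
conditionals.  This removes the slow mixing that one-at-a-time updates suffer
from the intercept/slope redundancy across levels of the hierarchy, and never
forms a large precision matrix.  The expansion scales of the scaled
inverse-Wishart prior get their own exact Gibbs step (given the unscaled
effects they are plain regression coefficients); this parameter-expansion
move breaks the funnel coupling between random effects and their covariance,
which otherwise mixes intractably slowly on heavily censored series — on
20 dB-shifted series it turned 2/12 converged fits at a 4x iteration budget
into 12/12 at the base budget.

`hi_hsk` breaks conjugacy because `sigma` depends on `mu`.  It uses the
centred parameterisation (location lines `gamma_l`, cluster lines `alpha_c`,
global line `beta`): only the 52 `gamma_l` blocks touch the data, and they are
updated in parallel by Metropolis-Hastings with the exact Gaussian conditional
under the current SD field as proposal (acceptance is typically 80-95%);
`(beta, alpha)` given `gamma` is all-Gaussian and drawn jointly and exactly.
Chains start at the OLS location lines: the MH correction cannot accept large
jumps from a data-contradicting start, so overdispersion is placed in the
global line, the residual scale and the covariances instead.

Convergence is declared when the split Gelman-Rubin statistic is at most 1.2
for every monitored parameter (all coefficients, covariance components and
residual SD) across two parallel chains; failing fits are rerun with a
doubled iteration budget up to two times (4x), and are otherwise returned
flagged as non-converged.  Default budget: 1000 warmup + 2000 retained draws
per chain; bulk simulation studies in the test-suite use 300 + 500 (P-score
Monte-Carlo SD about 0.012, small against the decision scales involved).
Per-eye seeds are derived from one master seed and a CRC32 of the eye id, so
cohort runs are reproducible and order-independent.

## Variability model

Test-retest repeats at a location are modelled as censored-Gaussian around the
location's **best available estimate** (BAE) — the median of the repeats,
which unlike the mean is unaffected by floor censoring; locations whose median
is itself 0 dB are excluded outright.  With means fixed at the BAE, log(SD) is
fitted by maximum likelihood as a cubic polynomial in sensitivity, and
separately as a capped bilinear curve: linear for `s >= s*`, constant below
(`slope b1 <= 0`, so the cap is the maximum SD).  The breakpoint is found by
scanning an integer grid (1..30 dB), fitting a free lower-segment slope at
each candidate, and interpolating the zero crossing of that slope scanning
down from the top; degenerate data pin the breakpoint to a grid boundary with
a warning.  All fits floor the SD at 0.1 dB — far below any real perimetric
SD — to keep likelihoods proper; factor-level fits (one SD per rounded
sensitivity, used for the naive-vs-censored comparison) group by
round-half-to-even for determinism.

The packaged default is the synthetic generator's own ground truth
(`b0 = 2.3`, `b1 = -0.06` per dB, breakpoint 12 dB: SD 1.2 dB at 35 dB rising
to a 4.9 dB cap), chosen to match published psychometric estimates of the
sensitivity-variability relationship; the cubic default is a least-squares
fit to the same curve.  Real test-retest data should replace these defaults
via `censored_hetero_fit` / `fit_bilinear_approximation`.

## Benchmark methods

* **Simple linear regression** of global mean sensitivity (MS), cluster MS,
  or pointwise values on time, with one-sided p-values for negative slope.
* **PoPLR**: the 52 pointwise one-sided slope p-values are combined by the
  truncated product method, `S = sum(-ln p)` over `p <= 0.05`, and `S` is
  referred to a null built by permuting whole tests within the series (times
  fixed — spatial correlation within a test is preserved).  `p = (1 + #{S_perm
  >= S_obs}) / (1 + n_perm)` with 5000 random permutations, or every ordering
  except the identity when the series is short enough (<= 7 tests), in which
  case the estimator is exactly the exhaustive enumeration p-value.  Both `S`
  and its p-value serve as progression statistics.

## Evaluation harness

All methods reduce to one progression score per eye, oriented so larger =
more evidence of worsening.  Specificity is always measured on *stable*
series manufactured by pairing each cohort eye with a random test-retest set,
permuting its repeats, keeping 10 and assigning the cohort eye's visit times
— exchangeable repeats cannot carry a trend.  Cutoffs are empirical quantiles
(midpoint interpolation) of the stable-score distribution, applied as
`score > cutoff`, calibrated per truncation length.  Hit-rate curves sweep
all cutoffs; the partial AUC integrates hit-rate over specificity in
[0.9, 1.0] (unnormalised; 0.1 is perfect, 0.005 is chance), taking the best
achievable hit-rate at tied specificities; CIs come from resampling eyes
(2000 bootstrap replicates by default).  Time to progression is the earliest
truncation (4..10 tests) whose score crosses the cutoff — single, unconfirmed
detection — with Kaplan-Meier summaries and pairwise Cox models (eye-level
cluster term, robust variance, Holm-adjusted p-values).  Prediction error
fits the first k tests (k = 4..9) and scores pointwise predictions of tests
k+1..10, clamped to the 0-50 dB instrument range, against the no-change
baseline (pointwise mean of the first two tests).

The downward-shift bias experiment selects series in which 0 dB values make
up under 30% of observations at every location, shifts them by -10/-20 dB,
adds the variance top-up `sqrt(max(0, SD(new)^2 - SD(old)^2))` (polynomial
form) so total variability matches the new sensitivity level, re-censors, and
compares slope estimates between shifted and original series at all three
levels of the hierarchy, split by the sign of the original slope.

## Synthetic cohorts

The generator is the generative mirror of the `hi_hsk` model.  Defaults
emulate a moderately damaged clinic population: baseline global intercept
N(23.5, 3) dB (about -6 dB mean deviation against a ~30 dB normal field),
cluster/location intercept SDs 2.5/3.5 dB (focal baseline damage), 10 visits
over 4-10 years.  Half the eyes progress; progressors combine a diffuse slope
(-0.25 ± 0.15 dB/year) with an extra focal decline (-0.6 ± 0.3 dB/year) in
1-3 randomly chosen sectors — glaucomatous loss deepens along nerve-fibre
bundles, and a purely diffuse generator would make a global-MS regression
look unrealistically competitive with pointwise methods.  Stable eyes are
exactly stable at every level.  Latent values get noise from the variability
model evaluated at the latent mean, then integer rounding (the instrument
reports whole dB), censoring at 0 and clipping at 50.  Blind-spot locations
carry low uninformative values and never enter a fit.

What the generator does *not* emulate: long-term drift unrelated to
progression (media opacity, learning and fatigue effects), non-Gaussian
response tails, episodic unreliable tests, visit-time clustering around
clinical events, and any structure-function correlation beyond the hard
cluster partition.  Passing the harness on this data certifies the machinery
and the relative behaviour of the methods under the stated assumptions — not
clinical performance on real series.

## Problem sizes and numerical choices

The test-suite runs everything at desk scale on one CPU: 500 stable eyes for
P-score calibration, 50 low-censoring eyes for the shift experiment, 200 eyes
for credible-interval coverage and for the method-ordering comparison, 20
eyes at default MCMC settings for the convergence check; bulk fits use the
reduced 300/500 budget.  The acceptance script reproduces the stable-series
P-score mean (500 eyes) and a default-settings convergence diagnostic from
scratch under a caller-supplied seed.

Other numerical choices: truncated-normal draws use inverse-CDF sampling with
tail clipping at 1e-300; 2x2 covariance draws use closed-form Bartlett
factorisations; p-values are clipped to (1e-300, 1 - 1e-300) so degenerate
exact fits stay inside (0, 1); flat pointwise series contribute p = 0.5
(slope 0, undefined t-statistic) to PoPLR rather than an arbitrary extreme.

## Known limitations

* The Garway-Heath location-to-sector table is a good-faith transcription of
  the published map; individual border locations may differ from other
  transcriptions.  Only the partition structure matters for the synthetic
  experiments.
* The P-score is mildly conservative as a frequentist statistic: on truly
  stable synthetic series its distribution is compressed towards 0.5 relative
  to exact uniformity (the acceptance suite measures this), because the
  posterior carries random-effect-variance uncertainty that a fixed-truth
  sampling distribution does not.  Specificity calibration on stable series,
  which is how the score is used for detection, is unaffected — it adapts to
  whatever null distribution the score has.
* On data generated exactly from the model (Gaussian noise, linear latent
  trends), the detection performance of the hierarchical P-score, PoPLR-S and
  global-MS regression nearly ties at desk-scale cohort sizes; the ordering
  measured on large real clinical cohorts, where the idealised assumptions
  fail, is not reproduced by this generator (the ordering check in the
  acceptance suite documents this).
* `hi_hsk` imposes the variability curve as truth; a misspecified curve
  biases its weighting (by design — the model trades robustness for
  psychophysical prior knowledge).
* Non-converged fits are scored conservatively (their draws are used as-is,
  flagged); at default budgets with auto-doubling these are rare.
* Real 0 dB records mix true floor measurements with censored ones; the model
  treats all of them as censored, slightly over-weighting the tail
  probability when a genuine 0 dB sensitivity occurs.
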