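# Methods

## What the package computes

`frailtyscreen` implements the modified Fried physical-frailty phenotype for
older-adult survey cohorts of the LASI (Longitudinal Ageing Study in India)
type, and asks a screening question of it: how well does each of the five
deficits — and each dual-deficit combination — identify the composite
phenotype on its own?

The phenotype is built from raw measures:

* **Exhaustion (E)** — the CES-D tiredness/low-energy item; "often (3-4
  days)" or "most (5-7 days)" in the last week counts as the deficit.
* **Weak grip (G)** — the mean of two dynamometer trials of the dominant
  hand (kg); the weak tail of the distribution within sex x BMI strata
  (BMI quartiles by default) counts as the deficit.
* **Slow walk (W)** — the mean of two timed 4-m walks (s); the slow tail
  within sex x height-median strata counts.
* **Weight loss (L)** — self-reported unintentional weight loss over 12
  months.
* **Low activity (P)** — sports/vigorous activity at most 1-3 times a
  month.

The score S = E+G+W+L+P is 0-5 and a participant is *frail* when
S >= `frail_threshold` (default 3).  Rows with any missing component are
dropped before scoring (complete-case analysis) and the drop count is
reported.

Each deficit, and each of the C(5,2) = 10 unordered pairs combined in
parallel (positive if either deficit is present) or in series (positive only
if both are), is then cross-classified against the frail label in a 2x2
table, yielding sensitivity, specificity, PPV, NPV and prevalence, each with
a Wilson score interval with continuity correction.  Analyses are stratified
by sex throughout, because the deficit most discriminant for frailty differs
between men (grip) and women (physical activity) in the Indian national
data this package emulates.

## Cutoff derivation

Grip and walk cutoffs are stratum-specific quantiles:

* quantile convention: the threshold is the smallest observed value whose
  cumulative fraction reaches the target proportion (`inverted_cdf`); for
  the slow-walk tail, symmetrically, the largest value whose upper-tail
  fraction reaches it.  This is deterministic, has no interpolation, and is
  checkable against a sort-and-scan oracle on integers.
* ties at the threshold are flagged (`<=` for grip, `>=` for walk) so that
  coverage is *at least* the nominal proportion; `flag_strictly_below` is
  available.
* the direction of the walk cut is configurable.  "Bottom quintile of the
  time values" taken literally flags the *fastest* walkers; the construct
  (slow walking = deficit) requires flagging the slowest 20%.  The default
  is `slowest_flagged`; the literal reading remains available as
  `fastest_flagged` and is non-standard.
* quantiles are computed unweighted by default; a `survey_weighted` switch
  uses weighted quantiles instead (survey weights are otherwise used only
  for percentage distributions, mirroring common practice).
* BMI stratification for grip defaults to sex x BMI quartiles (the original
  Fried operationalization, 8 strata); sex x BMI median is available, since
  published descriptions of "adjusted for gender and body mass index" do
  not pin the scheme down.
* a single present trial stands in for the two-trial mean; only when both
  trials are missing does the component (and then the row) drop.  This
  maximizes complete cases.
* cutoffs are derived after complete-case dropping of the measure in
  question (rows missing only *other* components still inform the
  quantile), and can be supplied externally instead.

### Reference-population cutoff proportions

A within-cohort bottom quintile flags 20% by construction, yet the national
estimates this package emulates report 79% weak grip among men.  Those
cutoffs were evidently anchored in a reference population wider than the
60+ analytic sample (the source survey interviewed adults 45+).  The
scoring configuration therefore accepts per-(measure, sex) proportion
overrides, and the synthetic pipeline's default run sets them to the
generator's target marginals — emulating external reference cutoffs while
keeping the quantile machinery identical.  For user-supplied cohorts the
default remains the literal within-cohort 0.20 quintile.

## The synthetic cohort generator

Real LASI microdata are restricted, so the generator produces cohorts with
the statistical structure the analysis assumes.  Per sex, each participant
has an age group a (scores s_a), and a person factor U ~ N(0,1).  The
latent propensity for deficit c is

    X_c = b_c * s_a + r_c * U + sqrt(1 - r_c^2) * eps_c,   eps_c ~ N(0,1),

standard normal within an age group.  The deficit corresponds to
X_c >= t_c, with t_c solved (Brent root-finding on the age-mixture CDF) so
the sex-level marginal equals the target prevalence exactly in expectation.
Questionnaire categories are ordered slices of X_c around t_c; grip is a
decreasing linear map of X_G (sex-specific base and scale, floored at
0.5 kg) and walk time an increasing log-linear map of X_W, with two trials
placed symmetrically around the underlying value so the trial mean is an
exact monotone function of the latent propensity.  Survey weights are
log-normal with mean 1 and configurable dispersion (default sd 0.3);
covariates are drawn independently within sex from the published marginal
distributions.

Defaults were calibrated, before any package test existed, against the
published national estimates: age-group mixes by least squares from the
consistency of per-age and total prevalences; age loadings b_c and age
scores from the per-age prevalence cells; factor loadings r_c from the
combined-frailty cells and per-component sensitivity/specificity, using
Gauss-Hermite quadrature over U with a Poisson-binomial for the score.

Two structural findings from that calibration are worth recording.  First,
a single loading per deficit cannot serve both the age gradient and the
cross-deficit correlation: fitting the age gradients forces correlations
that overshoot the published combined-frailty prevalence by 2-4 points.
Hence the two-part (b_c, r_c) structure.  Second, the published per-age
marginals at 80+ slightly exceed what within-age independence would imply
for the >= 3-of-5 composite, so some fitted r_c are negative (mild negative
residual dependence among the high-prevalence deficits); the resulting
cohort reproduces the published marginals, combined frailty, the
sensitivity geometry (grip and activity above 90%), and the near-perfect
parallel grip+activity marker.

What the generator does **not** emulate: the survey's multistage cluster
design (weights are exchangeable log-normals, not design weights), item
nonresponse patterns (missingness is injected independently at a chosen
rate), covariate-deficit association, and measurement error in BMI/height.
Tests passing on synthetic cohorts therefore validate the pipeline's
machinery and the latent-structure assumptions, not any property of the
real microdata.

## Accuracy statistics and intervals

From TP/FP/FN/TN: sens = TP/(TP+FN), spec = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN), prevalence = (TP+FN)/n.  A zero denominator yields an
explicitly undefined metric with a reason, never a coerced 0 or 1.  The
weighted mode sums survey weights into the cells instead of counting.

Confidence intervals are Wilson score intervals with continuity correction
(Newcombe's closed form), z = 1.959964 at 95%, with the conventional
boundary values at p = 0 and p = 1.  Each metric's interval uses its own
natural denominator (diseased, non-diseased, test-positive, test-negative,
total).  The closed form is verified exhaustively against a brute-force
inversion of the continuity-corrected score test for all n <= 50.

The Bayes identities

    PPV = se*pi / (se*pi + (1-sp)(1-pi))
    NPV = sp*(1-pi) / (sp*(1-pi) + (1-se)*pi)

hold exactly on any 2x2 and are exposed (`ppv_from_bayes`, `npv_from_bayes`,
`validate_against_bayes`) as a cross-column consistency check: on internally
generated tables the discrepancy is floating-point round-off; applied to
published tables rounded to 2 dp, the well-conditioned cells are recovered
to the printed precision.

Pairs default to the parallel (OR) rule: in published dual-marker rows the
combined sensitivity exceeds, and specificity falls below, both components —
the algebraic signature of OR combination.  Serial (AND) is retained; its
dominance property (specificity at least the better component's) is tested
alongside the OR dominances.

## Descriptive tables

Weighted percentage distributions use percent(c) = 100 * sum(w_i : x_i=c) /
sum(w_i).  Association tests are plain Pearson chi-square on unweighted
counts (no design correction; Rao-Scott adjustments are out of scope), with
p-values displayed to 3 decimals and a "<0.001" floor.  The chi-square is
computed via `scipy.stats.chi2_contingency` without continuity correction
and is verified against the textbook formula exhaustively on small tables.
Covariate association is tested across age groups within sex.

## Problem sizes and numerical choices

Default test-suite cohorts are 800-12,000 rows; the full-scale
parameter-recovery check and the acceptance script use the emulated cohort
size (14,885 male / 16,093 female).  Root-finding uses Brent's method
(xtol 1e-12); quadrature uses 80 Gauss-Hermite nodes (calibration only);
negative square-root arguments arising from floating point in the Wilson
closed form are clipped at zero; interval bounds are clipped to [0, 1].
Deterministic outputs: generation is a pure function of the configuration
(seeded via `SeedSequence`), and re-running a pipeline with the same
configuration reproduces byte-identical CSVs.

## Known limitations

* Published confidence-interval widths cannot be reproduced without the
  microdata (the per-metric denominators are not printed); intervals are
  validated by oracle instead.
* Whether the published 2x2 tables were weighted is not recoverable; both
  modes are exposed, unweighted is the default.
* The generated inter-deficit correlation structure is a calibrated model,
  not an estimate of the survey's; quantities that depend on the full joint
  distribution beyond the fitted moments (e.g. triple-deficit patterns)
  should not be read off the synthetic cohort.
* Single-row grip/walk flag helpers require externally supplied,
  single-stratum cutoffs; stratified flagging is the vectorized
  `score_and_classify` path.
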