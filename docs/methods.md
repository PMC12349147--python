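# Methods

This note documents the models, numerical choices, and design decisions
behind `brevity`, in the spirit of a statistical package's methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and cleaning

The unit of observation is one produced phrase: population, species, bird
(annotation) identifier, phrase-type label, duration in seconds. One
annotation is treated as one bird — archives generally cannot link
recordings made on different days to the same individual, and treating
annotations as birds is the conservative reading. Durations must be strictly
positive; units are seconds and are never inferred. Polysyllabic phrases are
whatever the input rows delimit; no re-segmentation is attempted.

Cleaning applies two rules. The optional label rule (off by default, for
archives whose type labels are 2–3 alphabetic characters) drops rows whose
labels do not match — such labels are likely data-entry errors, and only the
offending rows are dropped, not the whole annotation. The single-type rule
(always on) drops annotations left with fewer than two distinct types: such
annotations may be alarm calls governed by different rules, and they carry
no within-bird concordance information regardless. Cleaning is idempotent
and reports per-rule removal counts as JSON.

## Per-bird concordance and weighting

Kendall's $\tau_B$ (tie corrections in both margins) is computed by scipy;
an all-pairs counting oracle in the test suite verifies it independently. A
bird whose durations or usage counts are completely tied has an *undefined*
$\tau$ and is excluded and reported — scoring it zero would silently shrink
$\bar\tau$ toward the null. The null-variance weight $v_k$ depends only on
repertoire size $n_k$ (distinct types, regardless of how often each was
sung). Equal weighting is available (`weights="equal"`).

## Type centers: one-way random-intercept REML

The expected log duration of each type is the intercept of
$a_{\cdot j\cdot} = \bar a_j + B_j\gamma_j + \varepsilon_j$ with
$\gamma \sim N(0, \sigma^2_{\gamma j})$ per bird and
$\varepsilon \sim N(0, \sigma^2_{\varepsilon j})$ per instance, fitted by
REML. The covariance is $\sigma^2_\varepsilon(I + \lambda ZZ^\top)$ with
$\lambda = \sigma^2_\gamma/\sigma^2_\varepsilon$, so the criterion profiles
to a one-dimensional search over $\lambda$, solved by bounded scalar
minimization on $[0, 10^8]$ with absolute tolerance $10^{-10}$; the boundary
$\lambda = 0$ is checked explicitly. Each objective evaluation is
$O(\text{birds})$ after one pass of per-group sufficient statistics, which
is what makes simulation studies with thousands of fits cheap. Degenerate
inputs bypass optimization with closed forms: one observation gives that
observation with zero variances; one bird gives its mean,
$\sigma^2_\gamma = 0$, and the sample variance; all-singleton groups leave
$\lambda$ unidentifiable and are fit at $\lambda = 0$. The implementation is
validated against lme4 (frozen estimates for 50 seeded unbalanced fixtures,
agreement to $10^{-6}$) and against statsmodels' MixedLM live.

With `center="median"`, the type center is the median of per-bird medians
and no variance components are estimated; the permutation scheme is
unchanged. The rationale for offering it: some authors prefer medians for
skewed durations, though on the log scale means and medians nearly agree.

## The permutation null

A replicate draws one uniform permutation of the type centers and one global
sign, forms $M = X \pm D$ on the support of the count matrix, recomputes
per-bird $\tau$ on $(M[\cdot,k], f_{\cdot k})$, and recombines with the
observed weights. Design choices:

* **One sign per replicate for the whole matrix**, not per bird or entry:
  the deviation structure is treated as a single learned object whose
  orientation, not its content, is unknown under the null.
* **Bird set fixed at the observed data's defined-$\tau$ birds.** If a
  permutation's ties make some bird's $\tau$ undefined, that bird is dropped
  from that replicate and the replicate is flagged (`n_flagged_replicates`);
  replicates where no bird survives are excluded from the p-value
  denominator.
* **p-value is the plain proportion** of null draws $\le$ the observed
  statistic, as the statistic's definition requires; an opt-in
  $(r+1)/(m+1)$ estimator guarantees nonzero p for users who need it.
* **Detection threshold** is the empirical $\alpha$-quantile of the null
  sample with linear interpolation between order statistics (the quantile
  convention is a choice; the concept does not fix one).
* **Population-level concordance** $\tau_B(f_j, \bar a_j)$ is tested against
  the same stream of center permutations (deviations do not enter a
  population-level statistic). This is the minimal construction consistent
  with the individual-level null; it is documented, not claimed canonical.
* The observed $\bar\tau$ is computed through the same pair-count engine at
  the identity permutation with the + sign, so the reconstruction identity
  ($\bar\tau_p = \bar\tau$ at identity/+) holds exactly in floating point.

The inner loop is vectorized: $\tau_B$ depends on the data only through
signs of pairwise differences, so per-bird pair indices, count-difference
signs, and tie counts are precomputed once, and each replicate costs one
gather, one subtraction, and a few bincounts. `exhaustive_null` enumerates
all $n!\cdot 2$ sign-flipped permutations for small repertoires (default
cap $n \le 6$) and is the exactness oracle for the Monte Carlo path.

## Cross-population synthesis

`meta_tau` fits an intercept-only random-intercept model of the
per-population $\bar\tau$ with species as the grouping factor (REML,
unweighted — each population is one estimate, and weighting by $\bar v$ is
offered only as a simple inverse-variance synthesis). The one-tailed p-value
for a negative intercept uses a t distribution with species-level degrees of
freedom (number of species − 1), a deliberately conservative convention;
other df conventions exist and give slightly different p-values.

`detection_regression` fits $\ln(\text{repertoire size})$ on
$\ln(-\text{detection threshold})$ with species random intercepts and
back-transforms the fixed-part prediction. Both variables live naturally on
multiplicative scales: repertoire sizes span orders of magnitude, and the
threshold's magnitude shrinks roughly geometrically as repertoires grow, so
the log–log specification is the one under which the relationship is close
to linear and the confidence interval is symmetric. The 95% interval for the
expectation is Wald (normal quantile) on the log scale using the
fixed-effect covariance, i.e. conditional on the variance components, as is
standard for mixed-model predictions.

`compare_groups` is the Welch unequal-variance t-test with
Welch–Satterthwaite degrees of freedom, for comparing per-species mean
concordances between communication systems (e.g. birdsong vs written
language).

## Text baseline

Tokenization: NFKC compatibility normalization, case-folding, maximal runs
of letter characters in any script; digits and punctuation separate tokens;
length is the normalized character count. This is a documented dialect
choice — "character" is not well defined across scripts — and no stop-word
removal or stemming is applied. Per-document $\tau_B$ values can be pooled
with the same inverse-variance weighting, treating documents as individuals.

## Synthetic generator

`SynthParams` defaults describe a modest archive-like population: 30 phrase
types in the population, 10 birds in 5 tutor lineages (2 birds per lineage
share a 10-type repertoire subset and a deviation profile), 20 songs × 15
notes = 300 phrases per bird. Log-scale type centers are
$N(-1, 0.4^2)$ — median phrase ≈ 0.37 s, types spanning roughly 0.15–1 s —
with among-bird deviation scale 0.15 and within-bird rendition noise 0.3,
i.e. ~15% and ~30% coefficients of variation, plausible for field
recordings. Because durations are lognormal, the raw-duration spread among
birds scales with the mean across types while the log-duration spread does
not, matching the empirical motivation for log transformation.

Usage frequencies come from a Gaussian copula: per bird, a usage propensity
$z_w = \rho z_a + \sqrt{1-\rho^2}\,\eta$ correlates with the standardized
type center $z_a$, and multinomial counts are drawn with probabilities
$\propto e^{z_w}$. The copula correlation `effect` maps to the estimand by
$\tau = (2/\pi)\arcsin\rho$, so the generator's ZLA strength is controlled
on the same scale the test measures. `effect = 0` is the null;
`effect = −1` with zero noise gives every bird a perfectly discordant
repertoire.

Misclassification operators: `perturb_split` relabels each instance of the
longest fraction of types to one of two daughter labels at random —
errors concentrated on long types, the anticonservative direction.
`perturb_merge` merges disjoint *adjacent-by-duration* pairs of types chosen
at random across the whole duration range — only similar types get confused,
but not preferentially short ones. The distinction matters: merging
concentrated on short types would systematically inflate short-type
frequencies and bias the observed concordance itself negative (an
anticonservative, duration-dependent error), whereas duration-unbiased
merging only coarsens the repertoire and leaves the test conservative. The
operators are built to probe these two directions separately.

## What the synthetic tests do and do not show

The generator matches the analysis's structural assumptions: shared learned
repertoires, lognormal durations, within/among-bird variance layers, and a
controllable duration–frequency dependence. Passing type-I and power checks
under it shows the machinery is correct *under those assumptions*. Real
song differs in ways the generator does not emulate: song-level syntax and
sequential dependence, duration drift within bouts, observer-dependent
classification, unequal recording effort per bird, and repertoire sizes
correlated with sampling depth. Results on real archives inherit those
caveats, particularly the classification ones probed by the perturbation
operators.

## Problem sizes used in the checks

The routine checks use the generator's default population (10 birds, 30
types, ~3,000 phrases) with 400–1,000 permutation replicates per test and
300–500 simulated datasets per operating-characteristic estimate; exact-null
comparisons use repertoires of ≤ 5 types where the $n!\cdot 2$ enumeration
is small. These sizes make the suite quick while keeping Monte-Carlo error
well inside the asserted bands.

## Known limitations

* The REML machinery covers only the one-way random-intercept family used
  here (plus fixed covariates); no slopes, crossed, or nested designs.
* The population-level p-value construction is one reasonable choice; the
  individual-level test is the primary inference.
* The detection threshold depends on repertoire structure, bird count, and
  sharing, not repertoire size alone; the planning regression summarizes a
  trend, not a law.
* p-values are not corrected for testing multiple populations; synthesis
  across populations is the intended remedy.
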