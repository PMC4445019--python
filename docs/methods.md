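# Methods

This note documents the statistical machinery behind `probank`: the models,
the estimation choices, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the known limits of
each component.

## The graded response model

All response modelling uses Samejima's graded response model on the
logistic metric without the 1.7 scaling constant, matching the convention
of the big PRO measurement systems whose metrics banks built with this
toolkit are typically linked onto. An item is a slope `a > 0` plus strictly
increasing thresholds `b_1 < ... < b_{m-1}`; category probabilities are
adjacent differences of the logistic boundary curves. Fisher information is
computed analytically from the boundary-curve derivatives.

Trait scores are expected-a-posteriori (EAP) estimates: posterior mean and
SD of θ under a normal prior on a fixed quadrature grid. The default grid is
49 equally spaced points on [−6, 6], a standard CAT-engine choice; against a
10,001-point brute-force integration the estimates agree to four decimals
(tested), so the grid is not a practical source of error. An empty or
all-missing response pattern returns the prior mean and SD by definition —
that is the correct posterior, not an error condition.

Reported scores use the T metric: `T = 50 + 10·θ`, so the reference
population mean maps to 50 and one reference SD to 10 points. Response
categories are coded 1..m internally; reverse-coding negatively worded
items is an ingestion concern, not a model concern.

## Synthetic data

Field-test samples behind published banks are essentially never public, so
the generator is the package's test bed. Its defaults mirror a realistic
calibration study: n = 877 respondents (a typical multi-site field-test
size, and ≥ 500 as GRM stability guidance requires), five-category items,
θ ~ N(0, 1), slopes log-normal with median 1.7 and log-SD 0.35
(PROMIS-like), and each item's thresholds drawn uniformly over [−2.5, 2.5]
(sorted, with a 0.15 minimum gap so no category is structurally empty). Six
binary person covariates of the kind DIF analyses in rehabilitation
medicine condition on (age group, sex, education, diagnosis, completeness
of injury, time since injury) are assigned independently of θ, so injected
DIF is never confounded with true group differences (impact). Missingness
defaults to zero, reflecting interviewer-administered data collection;
a completely-at-random rate is available.

Local dependence is induced through a shared item-specific factor: for a
contaminated pair, the effective trait feeding each item is
`sqrt(1−s)·θ + sqrt(s)·u` with `u` shared by the pair only. This keeps the
marginal item distributions near-model while violating conditional
independence — exactly the violation the LID screen targets — and `s` is
the proportion of specific common variance, restricted to [0, 1). Uniform
DIF shifts the focal group's thresholds before generation; a slope ratio is
available for non-uniform DIF. The expected residual correlation of an
LID-contaminated pair scales with the pair's discrimination
(≈ s·a²/(a² + π²/3) for equal slopes), so at strength 0.5 weakly
discriminating pairs sit near the 0.2 screening boundary while strongly
discriminating pairs exceed it clearly.

What the generator does **not** emulate: multidimensionality beyond the
induced violations, non-normal trait distributions, response styles,
careless responding, planned-missingness designs, and item-position
effects. Passing tests therefore demonstrate that each procedure behaves
correctly when its own assumptions hold (plus the specific violations
injected), not that it is robust to everything real data can do.

## Dimensionality and local dependence

The screen operates on polychoric correlations: thresholds fixed at
inverse-normal marginal proportions, then pairwise maximum likelihood for
the correlation (two-step estimator). The bivariate normal CDF is computed
from Owen's T function, which is vectorised and matches
`scipy.stats.multivariate_normal` to ~1e-15 (tested). Items with a single
observed category are rejected by name. With extremely skewed margins in
opposite directions the pairwise likelihood can be nearly flat in ρ; the
generator's threshold design avoids this regime, and real pools that hit
it need category collapsing first.

The one-factor model is fitted by unweighted least squares on the
polychoric matrix — a deliberately dependency-light estimator that is
entirely adequate for screening decisions. Fit indices use a
chi-square-type statistic, (n−1) times the sum of squared off-diagonal
residuals, with the independence model (all off-diagonals zero) as the
baseline for CFI/TLI and RMSEA from the scaled discrepancy. These are
screening indices: their absolute calibration is approximate, but they are
exactly zero-residual-consistent (perfect one-factor input gives CFI = 1,
RMSEA = 0) and they separate clean from contaminated pools sharply at the
conventional gates — acceptable CFI/TLI ≥ 0.90 and RMSEA ≤ 0.08, good at
0.95 and 0.06. A non-PSD input matrix is ridge-repaired and flagged;
Heywood loadings are clamped to 0.999 and flagged.

LID is flagged where |observed − λ_i·λ_j| > 0.2, strictly: 0.21 flags,
0.19 does not. The prune loop removes, per wave, every item with loading
below 0.30 and the lower-loading member of each flagged pair (preserving
bank information), then refits; it stops when a wave triggers nothing, and
raises (carrying the partial audit) if removal would push the pool below a
configurable floor of 4. One wave may remove several items; refitting
happens between waves, not within.

## Calibration

Marginal maximum likelihood via EM: the E-step computes posterior weights
per person over the quadrature grid (θ ~ N(0, 1) identification); the
M-step maximises each item's expected complete-data log-likelihood with an
analytic gradient. Thresholds are parameterised as first threshold plus
positive increments, so estimated category boundaries can never cross, and
the slope as a log — the estimate is unconstrained internally but always
valid externally. Convergence is declared when the largest absolute
parameter change in a cycle falls below 1e-4 (cycle cap 500; hitting the
cap flags the result rather than raising). The quadrature is the same
49-point grid as scoring; estimates are stable to ~4 decimals against a
much denser grid. The marginal log-likelihood trace is retained and is
non-decreasing (a property test).

Categories observed fewer than 10 times are merged into an adjacent
category before estimation and logged; the result carries the category
maps so downstream consumers can recode raw data. Missing responses are
ignorable — they contribute no likelihood factor. Standard errors come from
the empirical cross-product of per-person score vectors of the marginal
log-likelihood (central differences, exploiting the product structure over
items).

Item fit is the summed-score S-X² statistic: expected category frequencies
conditional on the total score are obtained from the Lord–Wingersky
recursion over the quadrature grid and compared with observed frequencies;
adjacent cells are collapsed until all expected counts are ≥ 1.  Degrees
of freedom are cells minus score groups (each group's frequencies sum to
its size) minus the item's parameter count, floored at skip; items with
too few usable score groups are skipped with a log entry. Under model-true
data the rejection rate at α = 0.05 stays near nominal (tested by
simulation), and a non-monotone item is detected overwhelmingly. The test
requires complete response vectors; incomplete rows are excluded.

## DIF screening

For each item and grouping variable, three nested cumulative-logit models
(trait; trait + group; trait + group + trait×group, with the trait matched
by EAP score, not raw sums) are fitted via statsmodels' ordered model.
Uniform and non-uniform effects are tested by likelihood ratio; an item is
flagged only when the joint 2-df test has p < 0.01 **and** the McFadden
pseudo-R² gain is at least 0.02. The two-criterion rule is the standard
guard against flagging trivially small but significant DIF at field-test
sample sizes; both thresholds are configuration. Variables with fewer than
two levels of at least 50 persons are skipped with a log entry. Flagged
items are reported, never auto-removed; an optional purification loop
re-scores on unflagged items and repeats. At the default settings the
false-flag rate on null data is well under 5% and a 0.7-SD uniform
threshold shift at n = 1,000 is detected essentially always (both tested
by simulation).

## Linking

Stocking–Lord: (A, B) minimise the normal-density-weighted integrated
squared difference between the anchor sets' test characteristic curves,
reference versus transformed-new, over 161 points on [−4, 4]. The weighting
concentrates the fit where respondents actually are. Optimisation is
Nelder–Mead from the identity (1, 0) with A parameterised on the log scale;
the transformation is one-way (new metric onto the fixed reference), as
when a condition-specific bank is placed on a general-population metric.
Transforming a bank divides slopes by A and maps thresholds b → A·b + B
(scores θ → A·θ + B), leaving every category probability invariant — an
exact algebraic identity, tested on grids. With exact parameters the
constants are recovered to better than 3 decimals. With estimated
parameters at n = 2,000 per group the per-replicate spread of the recovered
constants is ~0.04, dominated by finite-sample identification of each
population's latent scale (the sample's realised trait mean/SD is absorbed
into the calibration); this component shrinks only with sample size, not
with more anchors. Recovery is unbiased (checked over independent seeds).

## CAT engine

Selection is maximum Fisher information at the current EAP point estimate
(the first item at the prior mean), ties broken by lowest item id for
bit-reproducibility. Posterior-weighted information selection is a known
alternative; the rule is an enum so variants can be added without touching
session logic. Stopping follows the default administration rules of the
large PRO CAT platforms: no stopping check until 4 items have been
answered, stop at the first check with SE < 0.3 on the θ metric
(equivalently 3 T-score points — the threshold is configuration, on the θ
scale), hard cap at 12 items (or the bank size if smaller). Precision-
stopped sessions therefore always end below 0.3; cap-stopped sessions
report whatever precision they reached. The combined administration mode
gives any short-form item the CAT did not select exactly once, so CAT and
short-form scores are both computable with no duplicate administration.
Batch studies draw each simulee's full-bank response pattern once and
replay the CAT against it, so CAT, short-form, and full-bank scores are
computed from the same responses; summary correlations use T-metric
scores.

## Short forms

Items are ranked into five location quintiles (location = mean of the
item's thresholds; quintiles by rank with equal counts, boundary ties to
the lower quintile) and the highest-slope item per quintile is taken
first. The default then expands toward the 8-item target by taking a
second item from the extreme quintiles inward (1st, 5th, 2nd, 4th, 3rd) —
fixed forms lose precision at the tails first, so the tails get
reinforcements first. Sizes always land in the conventional 7–10 band; at
most 2 items come from any quintile. Slope ties resolve to the lower item
id. Real instrument development adds a clinical review (wording,
redundancy, content coverage) on top of the psychometric rule; that step
is inherently non-algorithmic and is supported only through pinned/banned
item lists.

## Reliability

Cronbach's alpha is computed from item and total variances on listwise-
complete rows (a warning fires under 30 rows), with corrected item-total
correlations excluding the focal item. ICC(2,1) — two-way random effects,
absolute agreement, single measurement — is computed from the person ×
occasion ANOVA mean squares with the standard F-distribution confidence
bounds (McGraw & Wong), and is cross-checked against an independent
implementation in the test suite. Pearson r carries a Fisher-z interval.
Both r and ICC are reported because they answer different questions
(consistency versus agreement); the conventional interpretive bands
(> 0.80 good, 0.70–0.80 acceptable) are reporting conventions, not
enforced thresholds.

## Pipeline

Stage order is fixed: screen → calibrate → item fit → DIF → (recalibrate
if flagged items are configured for removal) → optional linking → short
form → CAT study → reliability. Every stage logs item counts in/removed/
retained, all randomness derives from the single configured seed, and the
summary JSON of two runs with identical configuration is identical. DIF
removal is off by default (flags are evidence for review, not verdicts).

## Problem sizes in tests

The test suite exercises each claim at the smallest size that gives the
statistic clear resolution: parameter recovery at 50 replicates of
n = 1,000 × 20 items; DIF error rates at 5 null and 12 power replicates of
n = 1,000; linking recovery at 5 replicates of n = 2,000 per group;
stopping-rule conformance over 1,000 simulated sessions; short-form sizing
over 100 random banks. These sizes are the package's own validation
choices and are trivially increased in user scripts.

## Known limitations

Unidimensional GRM only — no multidimensional IRT, no mixed 2PL/graded
pools, no Bayesian (MCMC) estimation, no plausible values. The ULS fit
indices are screening heuristics, not substitutes for a full SEM engine.
DIF screening offers the ordinal-logistic family only (no Mantel–Haenszel
or SIBTEST) and no effect-size salience classification beyond ΔR².
Linking implements Stocking–Lord only (no Haebara, mean/sigma, or
concurrent calibration). The CAT engine has no exposure control, content
balancing, or response-time modelling.
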