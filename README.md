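# probank

Item-bank engineering for patient-reported outcomes (PROs): a Python
toolkit for building, calibrating, and deploying IRT item banks of the kind
used by the large PRO measurement systems (PROMIS, Neuro-QOL, and their
condition-specific descendants). It is aimed at psychometricians and
methods-oriented clinical researchers who need the full quantitative
development sequence — dimensionality screening, graded-response-model
calibration, item-fit and DIF assessment, metric linking, computer-adaptive
testing, short-form construction, and reliability analysis — as a
scriptable, testable library rather than a point-and-click platform.

## The model

Responses to an ordinal item with *m* categories are described by
Samejima's graded response model (GRM). For item *j* with discrimination
*a<sub>j</sub>* > 0 and ordered thresholds
*b<sub>j1</sub> < … < b<sub>j,m−1</sub>*, the boundary curves are

> P\*<sub>jk</sub>(θ) = 1 / (1 + exp(−a<sub>j</sub>(θ − b<sub>jk</sub>))),  k = 1, …, m−1,

and the probability of responding in category *k* is the adjacent
difference P<sub>jk</sub>(θ) = P\*<sub>j,k−1</sub>(θ) − P\*<sub>jk</sub>(θ)
(with P\*<sub>j0</sub> = 1, P\*<sub>jm</sub> = 0). The logistic metric is
used without the 1.7 scaling constant, following PROMIS convention. The
latent trait θ is identified as N(0, 1) in the calibration population and
reported on the T metric (mean 50, SD 10).

On top of the model the package provides:

* **`simulate`** — synthetic response data with known truth: heterogeneous
  trait, six person covariates, optional local-dependence and DIF
  contamination, and two-population anchor designs with known linking
  constants.
* **`dimensionality`** — polychoric correlations, one-factor ULS fit with
  CFI/TLI/RMSEA, the residual-correlation (> 0.2) local-dependence screen,
  and an iterative prune loop (loading floor 0.30).
* **`calibrate`** — marginal maximum-likelihood EM calibration with
  monotone threshold parameterisation, empirical-cross-product standard
  errors, and Orlando–Thissen S-X² item fit.
* **`dif`** — ordinal-logistic DIF screening (uniform + non-uniform) with
  the p < 0.01 ∧ ΔR² ≥ 0.02 flagging rule.
* **`linking`** — Stocking–Lord estimation of (A, B) transformation
  constants from anchor items and the corresponding bank/score transforms.
* **`cat`** — an adaptive testing engine: maximum-information selection at
  the current EAP estimate, minimum 4 / maximum 12 items, stop when the
  standard error falls below 0.3, plus the combined CAT + short-form
  administration mode and batch simulation studies.
* **`shortform`** — fixed-form selection by location quintiles and maximum
  slope (7–10 items).
* **`reliability`** — Cronbach's alpha, corrected item-total correlations,
  test-retest Pearson r and ICC(2,1) with confidence intervals.
* **`pipeline`** — the whole sequence from one YAML/dict configuration,
  with a thin `probank` CLI over it.

## Worked example

`examples/06_cat_and_shortform.py` builds a 30-item synthetic bank,
selects a short form, runs one adaptive session, and then a 1,000-simulee
study:

```text
short form (8 items): ['item012', 'item024', 'item029', 'item028',
                       'item016', 'item011', 'item002', 'item014']
CAT gave 11 items, stopped on precision: theta 1.36 (SE 0.30), T 63.6
short-form score from the combined run: T 59.9
CAT vs SF Pearson r over 1,000 simulees: 0.960; mean CAT length 10.0 items
```

The adaptive session stopped as soon as its standard error dropped below
0.3 on the θ metric (3 T-score points); the short-form score for the same
respondent is computed from the combined item set without re-administering
anything; and across 1,000 simulees the two administration modes agree at
r ≈ 0.96 because both score the same latent trait on the same metric.
The other scripts in `examples/` demonstrate screening, calibration with
parameter recovery, DIF detection, linking, reliability, and the full
pipeline, each printing the quantities it computes.

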