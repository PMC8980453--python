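# Methods

## The measurement model

Each respondent carries a latent indicator `Z ~ Bernoulli(π_i)` of
support for the sensitive attitude. The four survey arms observe:

* **LRE4** (list control): the count of endorsed control items,
  `C_i ∈ {0..4}`;
* **LRE5** (list treatment): `C_i + Z_i` — list responses are assumed
  fully truthful ("no liars"), the identifying assumption of the
  item-count technique;
* **DQ4**: each control item answered openly and truthfully;
* **DQ5**: the control items plus the sensitive card, where social
  desirability acts *only* on the sensitive card: a supporter admits
  support with probability `r_i` and a non-supporter falsely endorses
  with probability `f_i`.

Two further assumptions are built into the generator, and therefore hold
by construction in everything the tests measure:

* **no design effects** — adding the sensitive card never changes a
  control-item response, so the LRE4/LRE5 control distributions are
  identical and the additional-item diagnostic has its nominal type-I
  error;
* **honest control reporting under DQ** — the direct arms answer control
  cards truthfully, which is what makes the DQ4-vs-DQ5 comparison a pure
  test of contamination.

The list estimator is the difference in mean counts with unpooled
variance (the arms differ in size and the treatment count carries the
extra Bernoulli variance of the sensitive item):

```
π̂ = Ȳ_5 − Ȳ_4,   SE² = s²_5/n_5 + s²_4/n_4
```

It is exactly unbiased for the population mean of `π_i` and may go
slightly negative by sampling noise; no truncation is applied to the
point estimate, and CI endpoints are clipped to [0, 1] only at the
reporting layer.

## Concealment parameterisation

Calibration works from a published pair of proportions per subgroup: the
direct-question estimate `d` and the list estimate `l`. Latent support is
set to `π = l`; the direct-reporting process is chosen so the expected
direct "yes" rate equals `d`:

* understatement (`d ≤ l`): `r = d/l`, `f = 0` (concealment);
* overstatement (`d > l`): `r = 1`, `f = (d − l)/(1 − l)` (false
  endorsement).

Either way `π·r + (1−π)·f = d`, a property the test suite checks for all
inputs.

## Additive subgroup calibration

Published subgroup tables report *marginal* estimates per covariate
level. Marginals do not identify a joint model, and the printed rows are
mutually inconsistent at the second decimal (the covariate-weighted means
do not exactly reproduce the printed overall row). The generator
therefore uses an additive rate model on the probability scale:

```
π_i = clip( π_all + Σ_c ( π_{c, level_i(c)} − mean_c ) , 0, 1 )
```

where `mean_c` is the population-weighted mean of the two printed levels
of covariate `c`. Centring each covariate's effects makes every printed
marginal reproduce in expectation, up to the rounding inconsistency of
the source table (within ±0.03 in the calibration tests) and up to
clipping, which never binds for the shipped calibration. The direct-
question rate uses the same construction, and each respondent's
`(π, r, f)` are derived from their two additive rates.

The printed standard errors in the source subgroup table are numerically
inconsistent with the confidence intervals printed in the accompanying
narrative; the calibration uses the estimates and the narrative CIs and
ignores the table SE column.

## Control-item model

The four control items are: one unpopular item, one near-universal item,
and a mutually incompatible pair drawn from a three-way categorical
(first / second / neither). Incompatibility makes a count of 4
structurally impossible and a count of 0 requires three independently
unlikely events — exactly the floor/ceiling protection the list needs to
preserve anonymity.

Defaults (a repository calibration, not field measurements):
`p_rare = 0.40`, `p_popular = 0.95`, pair weights `(0.60, 0.37, 0.03)`.
These give a closed-form mean count of 2.32, inside the 2.2–2.4 band the
field data showed, SD ≈ 0.56, and a floor+ceiling probability of
`0.60 × 0.05 × 0.03 = 0.09%`. Note that with a strict incompatible pair
the mean count is at most `p_rare + p_popular + 1`, so matching the
observed mean ≈ 2.3 forces both Bernoulli items to be fairly popular;
"rare" is relative (40% vs 95%), which is consistent with the observed
absence of floor effects.

## Survey design replication

* Arm allocation uses largest-remainder rounding of `n × fraction`, ties
  broken by arm-label order: 809 → 162 direct / 647 list; 162 → 81/81;
  647 → 324/323 (the 324/323 split is a package convention — the source
  reports only the family totals).
* Covariate marginals are matched exactly via stratified assignment with
  a seeded shuffle; the joint structure is independent by default. A
  `joint_cells` option fixes the two-way cell counts of one covariate
  pair *within the list family* (published interaction tables count
  list-arm respondents only); the direct arms then receive the
  complementary margins with a rounded-product joint fill. Only one pair
  can be fixed at a time — the published two-way tables are not mutually
  consistent (one education×age panel sums to 290 where the education
  margin is 294), so a full joint replication is not well defined.
* All randomness flows from a single `numpy` Generator in documented
  order (covariates, arms, then responses in id order), so a seed plus a
  configuration reproduces every record bit-for-bit.

## Diagnostics

The two-sample Kolmogorov–Smirnov statistic is the ECDF supremum over
the observed support, well defined under the heavy ties of small integer
counts. The asymptotic p-value uses the limiting Kolmogorov distribution
at the standard effective size `n_x n_y/(n_x+n_y)`; it matches R's
`ks.test(exact = FALSE)` to 10 decimals on untied data and is
conservative (larger p) under ties. The exact option enumerates all
splits of the pooled sample when `n_x + n_y ≤ 20` (for untied data this
reproduces the classical exact two-sample KS distribution, verified
against R) and otherwise uses random permutations with an add-one
correction. On heavily tied tiny samples the asymptotic and exact
p-values can differ by more than 0.1; the exact permutation p is the
reference there.

The additional-item test compares the *control-item counts* of the two
direct arms by default, excluding the five-card arm's sensitive response:
both samples then live on the 0–4 scale, and the test targets
contamination of the non-sensitive responses. `include_sensitive=True`
gives the alternative reading (raw totals).

## Reanalysis of printed results

Where only estimates and 95% CIs are printed, the standard error is
recovered as full CI width / (2 z). The default z for reanalysis is the
hand-rounded 1.96 (internally the package uses the exact quantile
1.959964; the difference is negligible but 1.96 matches published
arithmetic). Agreement is evaluated at the printed precision of each
p-value. One published contrast (the overall direct-vs-list comparison,
printed p = .12) cannot be recovered from its own printed inputs — the
rounded CIs back-compute to p ≈ .17 — and is reported as discrepant
rather than forced.

## Problem sizes and tolerances in the test suite

* Estimator calibration: 2,000 replicates at the study's arm sizes
  (324/323) for each generating π in {0, 0.17, 0.28, 0.45, 0.62};
  unbiasedness is asserted within 3.5 Monte-Carlo standard errors and
  coverage within 95% ± 1.5 points.
* Control-model checks use 100,000 draws (Monte-Carlo SE on the mean
  count ≈ 0.002).
* KS type-I error uses 500 replicates at the direct-arm sizes (81/81).
* Power-pattern checks (concealment detected for the low-education-style
  subgroup but not the high-education-style one) use 300 replicates at
  the corresponding subgroup arm sizes.

## What the synthetic data do and do not show

The generator reproduces the design exactly (allocation, marginals,
optional interaction cells) and the published estimates in expectation,
with truthful list reporting and concealment confined to the sensitive
card under direct questioning. It does **not** model household or
within-couple correlation, interviewer effects, nonresponse (the field
survey recorded none), measurement error in covariates, or any violation
of the no-liars / no-design-effect assumptions. Passing tests therefore
demonstrate that the *estimators and diagnostics* behave correctly when
the design assumptions hold — they cannot certify those assumptions in
real field data, which is precisely what the additional-item diagnostic
and floor/ceiling checks are for.

## Known limitations

* The additive calibration cannot reconcile genuinely inconsistent
  printed marginals; it centres the inconsistency instead of resolving
  it.
* Subgroup contrasts treat estimates as independent normals; for the
  small published interaction cells (n ≈ 43) the normal approximation is
  rough, matching the published analysis rather than improving on it.
* No regression-based (maximum-likelihood) list-experiment estimators
  are included; the published multivariate models were reported as
  ill-fitting and are out of scope.
* No multiple-testing correction is applied anywhere; tables report raw
  p-values.
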