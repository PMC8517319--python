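# Methods

## The Health Equity Metric

Health equity, as operationalized here, asks how close a population
comes to the level of health its most advantaged members demonstrate is
attainable. For individual coded health `y_i`, benchmark `ȳ*`, survey
weight `w_i`, and scale parameters `α > 1`, `β > 0`:

    d_i  = max{ (ȳ* − y_i)/ȳ*, 0 }
    HEM  = rescale × ( 1 − Σ w_i (β·d_i)^α / Σ w_i )

Defaults are `α = 2.5`, `β = 2`, `rescale = 1000`. Three properties
drive everything downstream:

* **Censoring above the benchmark.** Individuals at or above `ȳ*`
  contribute zero deficit — the metric does not reward surpluses, so a
  deficit-free population scores exactly 1000 and the attainable range
  is `1000·(1 − β^α)` (≈ −4657 at the defaults) to 1000.
* **Convexity.** With `α > 1`, concentrating a fixed total deficit on
  fewer individuals lowers the metric. This is what separates the HEM
  from a group-mean disparity: the four-scenario illustration holds the
  privileged/non-privileged mean gap at exactly 20 while reshaping
  within-group distributions, and the metric falls monotonically as
  deficits concentrate.
* **Affinity in the mean contribution.** The HEM is an affine transform
  of the weighted mean of `c_i = (β·d_i)^α`, so standard survey
  machinery for a weighted mean carries over directly to point
  estimates and variances.

### Benchmark

The default benchmark is the survey-weighted median coded health of the
most socially privileged identifiable subgroup — white, non-Latinx boys
in households at ≥400% of the federal poverty line — recomputed within
each survey year. The weighted median is the *smallest value at which
cumulative normalized weight reaches 1/2*, without interpolation: on the
discrete coded scales (e.g. the five general-health weights) an
interpolated median could take unattainable values, and the chosen
definition agrees exactly with the unweighted median of the record set
expanded by integer weights. A population-wide weighted 90th percentile
is available as a robustness alternative (same quantile definition).

Choices that were genuinely open, and how they were fixed:

* **Per-year benchmark** (not pooled over the study period): annual
  equity estimates should compare each year's population with that
  year's attainable health; a pooled benchmark would conflate secular
  change in the privileged group with equity change. A pooled option
  (`BenchmarkSpec(per_year=False)`) is retained.
* **Weighted benchmark**: the median uses survey weights, consistent
  with every other estimate.
* **Benchmark treated as fixed in the variance**: the sampling
  variability of a median taken over a privileged cell of hundreds to
  thousands of records is second-order relative to the mean-contribution
  variance; replicating the benchmark inside a jackknife is a noted
  extension, not implemented.
* **Small cells**: a privileged cell below 50 records (configurable)
  triggers a warning rather than an error — conventional small-cell
  hygiene, not a hard statistical threshold.

## Measure coding

Six parent-reported child-health measures are coded so that *higher is
always better*:

| measure | ages | scale | coding |
|---|---|---|---|
| general_health | 0–17 | {0.401 … 0.983} | Van Doorslaer–Jones weights: 0.983 excellent, 0.931 very good, 0.841 good, 0.707 fair, 0.401 poor |
| school_days | 5–17 | 0–40 | 40 − min(days missed, 40); top-code at 40 |
| sdq | 4–17 | 0–10 | 10 − Σ of five items scored 0/1/2 |
| emotional_difficulties | 4–17 | 0–3 | 3 none, 2 minor, 1 definite, 0 severe |
| toddler_mhi | 2–3 | 0–8 | 8 − Σ of four items scored 0/1/2 |
| toddler_depression | 2–3 | 1–3 | 3 not true, 2 sometimes, 1 often |

The SDQ and toddler-MHI availability calendars (SDQ absent in 1997 and
2009; emotional difficulties absent in 1997) are encoded in the measure
registry; unavailable measure-years are simply absent from series, never
interpolated.

Two instrument ambiguities are handled explicitly:

* **SDQ polarity.** The five abbreviated-SDQ prompts mix strengths
  ("gets along", "good attention span", "well-behaved") and
  difficulties ("unhappy", "worried"), yet the printed scoring treats
  all five identically. The default implements the printed scoring;
  `flip_strength_items=True` reverse-scores the three positively-worded
  prompts before summing for users who judge that to be the intended
  instrument.
* **Toddler depression** enters analyses on its reversed 1–3 scale as
  printed, not rescaled to start at 0; the published sample means near
  1.9 (higher = better) are consistent with this reversal.

**Missing items**: a record missing any item of a multi-item scale is
excluded from that measure's analyses (complete-case per measure, coded
NaN). Item missingness in the emulated survey is low, so the bias risk
of this simple rule is small relative to its transparency.

## Survey estimation

Point estimates are Hájek-style weighted means. Variances use
**stratified between-PSU linearization**: with linearized values `z_i`
(zero outside the estimation domain) and PSU totals `Z_hk` in stratum
`h`,

    var = Σ_h  n_h/(n_h − 1)  Σ_k (Z_hk − Z̄_h)²

* For the HEM, `z_i = w_i (c_i − θ)/Σ_domain w`, `θ` the weighted mean
  contribution; `SE(HEM) = rescale × SE(θ)`.
* For a disparity gap, both group means are linearized jointly on the
  full frame (`u_i = w_i(y_i − ȳ_A)/W_A` in group A, the negative
  analogue in group B, zero elsewhere), so within-PSU covariance
  between the groups is retained.
* **Domain estimation**: subgroup analyses (age bands, regions,
  age-restricted measures) keep every record in the design with zero
  influence outside the domain, rather than subsetting the frame — the
  standard practice that prevents spurious single-PSU strata when a
  subgroup is thin.
* A stratum genuinely containing one PSU raises an error by default;
  `single_psu="center"` scores the lone PSU against the grand mean of
  PSU totals (the conservative "centered" convention).

**Income imputation.** Household income arrives as m replicates (five
by default). Only income-defined quantities differ across replicates —
the privileged benchmark cell and the income contrast — but each
replicate recomputes the full estimate, and Rubin's rules pool them:
point = mean of points; total variance = within + (1 + 1/m)·between;
CI from a normal approximation on the pooled SE. Race contrasts use a
single computation since race is observed. How design-based variance
should compose with imputation variance is not uniquely determined;
composing linearization within replicates with Rubin's rules between
them is the conventional choice and the one implemented.

## Trend inference

For an annual series {(year_t, est_t, se_t)} with at least three
distinct years, each replication redraws every year's value from
Normal(est_t, se_t²) and fits OLS of value on calendar year; the median
of the simulated slopes is reported with the 2.5th/97.5th percentiles
as a 95% credible interval, and the trend is "significant" when the
interval excludes zero. Numerical choices:

* the year covariate is centered at the series midpoint (slope
  unchanged, intercept well-conditioned);
* draws are plain normals, not truncated to the metric's feasible
  range;
* the OLS fit is unweighted across years — the annual uncertainty is
  already propagated through the draws, and inverse-variance weighting
  would double-count it;
* with all SEs zero the procedure degenerates to the closed-form OLS
  slope exactly (every draw identical), which the tests pin to 1e-12;
* under a null design (true slope zero, honest SEs) the credible
  interval excludes zero in ≈5% of runs — the procedure is essentially
  a parametric bootstrap of the sampling distribution of the OLS slope,
  so its "significance" calibrates like a 5% test. The suite verifies
  5% ± 3 points over 500 runs.

Baseline comparisons across strata use a classical one-way ANOVA
(scipy), with one guard: identical group means give F = 0, p = 1
directly rather than scipy's 0/0 NaN.

## Synthetic microdata

The generator emulates the structural features of NHIS sample-child
extracts that the estimators exercise, not the survey itself:

* per-year samples drawn uniformly from 8,000–14,000 children; ages
  from the four published bands (22/22.5/28/27.5%), sex ≈51% male;
* race/ethnicity (white non-Latinx 58%, Black 15%, Latinx 21%, other
  6%) with income distributions conditional on race chosen so the
  privileged cell — white non-Latinx boys at ≥400% FPL — is ≈11% of
  children, inside the published 9.7–12.4% band;
* for each measure a latent higher-is-better health value
  `baseline + income offset + race offset + slope·(year − y₀) + N(0, σ)`
  discretized onto the raw response scale (categories, item points,
  day counts). Baselines and gradients are calibrated so the coded
  population means land near the published descriptive table (general
  health ≈ 0.94, school-loss days ≈ 36.5, SDQ ≈ 8.3, emotional
  difficulties ≈ 2.73, toddler MHI ≈ 6.7, toddler depression ≈ 1.9)
  with advantaged cells healthier;
* design fields: 50 strata × 2 PSUs (configurable; analyses at a few
  hundred records per year should scale the design down so PSUs stay
  populated), weights log-normal with σ = 0.5 normalized to mean 1;
* income missing for 25% of records; five imputation replicates redraw
  missing categories from the race-conditional income distribution,
  observed records keep their category in every replicate;
* optional embedded linear trends per measure and subgroup
  (`embed_known_trend`), validated so no group's latent mean drifts
  more than 10% of the scale width past either end of the coded range —
  modest overshoot is representable (responses pile up at the boundary
  category, e.g. zero school-loss days), gross overshoot is not.

**Scenario populations.** The four two-group illustrations fix the
privileged mean at 60 and non-privileged at 40 on a 0–100 scale
(100,000 draws per group): (1) both groups N(mean, 8); (2)
non-privileged spread doubled; (3) both spreads doubled; (4) each group
an equal-weight mixture at ±12 about its mean with component spread 4 —
the intersectional case where each group hides a worse-off subgroup.
Only the means are pinned by the construction; the shapes are one
consistent choice. Values are *not* clipped to [0, 100]: spreads are
chosen so out-of-range mass is negligible, and clipping would shift the
means and break the exact disparity-invariance property.

**What passing tests do not show.** The generator has no nonresponse
adjustment, post-stratification raking, multi-stage clustering with
unequal selection, questionnaire redesigns, or item-level missingness
patterns; weights are independent of health. Tests against it validate
the estimators' internal correctness (formulas, design variance
algebra, MI pooling, trend calibration, parameter recovery), not the
substantive published trend findings, which require the restricted-use
microdata.

## Problem sizes in the suite

The test suite runs on scaled-down populations chosen to keep Monte
Carlo error well below the asserted tolerances: routine fixtures use
6 years × 3,000 children; the trend-calibration check uses 500
simulated series at 10,000 replications each; trend recovery uses 100
populations of 22 years × 1,000 children (25 strata) with an embedded
improvement of 0.2 school-loss days per year for below-400%-FPL
children — a gap closure of ≈4 days over the period, comparable in
spirit to observed secular improvements; scenario checks use the full
100,000 per group.

## Known limitations

* The benchmark's sampling variability is ignored in the SE; for very
  small privileged cells the CI is anticoverage-prone (hence the
  warning).
* Rubin's rules assume normal pooled estimates; on discrete benchmark
  scales the between-imputation component can be lumpy when the
  privileged median sits between two categories.
* The trend model is a single straight line; joinpoint or segmented
  alternatives are out of scope.
* Disparities are absolute differences in means; ratio or
  regression-adjusted disparities are out of scope, as are
  decompositions of equity change into group contributions.
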