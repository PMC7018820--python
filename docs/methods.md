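# Methods

This note documents the modelling assumptions behind `flowcascade`, the
defaults of its tunable parameters and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical and
design decisions taken where several readings were possible.

## The cascade

The package models the propagation of climate-model disagreement through an
eco-hydrological impact chain. The unit of analysis is one catchment with
an ensemble of N climate models (default 16), three 20-year periods
(baseline 1998–2017, horizons 2046–2065 and 2080–2099), a set of biological
sampling sites, and a set of macroinvertebrate species whose abundance
responds unimodally to a single flow statistic.

**dh4.** The flow statistic is the maximum 30-day moving-average flow
(m³ s⁻¹) within a 12-month window. Conventions:

* Moving averages use trailing 30-day windows *fully contained* in the
  12-month window — a 365-day window has 365 − 30 + 1 = 336 candidates; no
  partial windows. This is standard IHA practice.
* A "12-month window" is always 365 days long, leap years included as
  ordinary days, so the statistic stays comparable across years.
* Annual values for projections use windows ending on a configurable
  anchor (month, day), default December 31 — calendar-year-ending windows.
  For observed biology the window ends on the biological sampling date.
* A year whose window would extend before the series start is omitted with
  a warning rather than silently computed on partial data.

Series are stored on real calendar dates; leap days are kept to avoid a
silent multi-day drift over 20-year periods.

**Site extrapolation.** Discharge is transferred from a subbasin outlet to
a site strictly proportionally, by the ratio of flow accumulations
(contributing areas). No rainfall-runoff correction or calibrated exponent
is applied; contributing area is the only scaling basis used. The
operation is linear, so composed scalings multiply.

**Abundance.** Preference curves are parametric and unimodal; the shipped
form is Gaussian, `A(dh4) = A_peak exp(−(dh4 − opt)²/2b²)`, behind a
registry so other unimodal forms can be added. Curves are consumed as
parameters (species id, optimum, breadth, peak, fitted range) — fitting
them from survey data is outside this package's scope. dh4 values outside
a curve's fitted range are clamped to the nearest range edge before
evaluation, never extrapolated, and clamp events are tallied in the run
diagnostics. Predicted abundances stay continuous; rounding to integer
counts would inject unstated noise before the averaging steps.
Predictions are made only at (species, site) pairs with recorded abundance
> 0 — species are not assumed to colonize new sites.

**MAV, ΔMAV, SR.** The 20 annual abundances of a period average into the
mean abundance value (MAV); a period with a different number of annual
values is an error unless explicitly overridden. Per site,
ΔMAV = MAV_horizon − MAV_baseline, expressed as a percent of the baseline
MAV. The species response SR for one model and horizon is the *unweighted
mean of the per-site percent changes* over the species' occupied sites
(`sr_mode="mean_pct"`, the default). The alternative reading — average the
deltas first, then divide by the averaged baseline MAV — is implemented as
`sr_mode="pooled_pct"`. Sites with a baseline MAV of exactly 0 have an
undefined percent change; they are excluded from SR (not capped or set to
±∞) and counted in the diagnostics, which is conservative and visible.

**Ensemble weighting.** Model skill is judged on the baseline period only:
for each climate model, an IHA summary vector is computed from its
baseline-period series at the retained sites, and likewise for the
observation-forced series. Because both vectors travel the same
discharge-to-metric path, hydrological-model error cancels out of the
comparison. All vectors (N models + observed) are standardized jointly
(z-score per metric, n−1 sd; zero-spread metrics dropped with a warning),
and each model's distance is the Euclidean distance of its standardized
vector to the observed one. The default metric set is dh4 plus simple
magnitude statistics (annual mean/max/min and the 12 monthly means,
averaged over years then sites); the weighting *procedure* is the
reproducible content here, and the metric list is configurable.

Weights form a ladder on [1, 2]: the N models, ranked by ascending
distance, receive the N equally spaced values spanning [1, 2] inclusive —
spacing 1/(N−1), which for N = 16 is 1/15 ≈ 0.0667 (0.07 at two decimals).
Ties get the mean of the ladder weights their ranks span. An alternative
"step" mode with spacing 1/N (maximum weight 2 − 1/N) is available for the
reading in which the spacing is one over the number of models. Ensemble
summaries report simple mean, weighted mean (Σwᵢxᵢ/Σwᵢ), n−1 sd,
CV = sd/|mean| (flagged undefined at zero mean) and quartiles. When no
observation-forced series exists, weights fall back to uniform with a
warning and the weighted mean degenerates to the simple mean.

**Trait grouping.** Affinities follow the 0–10 scale of the
freshwaterecology.info database for three flow-related traits: current
preference, stream zonation preference, feeding type. Assignment rules,
in order of precedence:

1. exactly one category with affinity ≥ 7 → that category;
2. several categories ≥ 7 → the affinities are spread → "generalist";
3. feeding type only: exactly one pair of categories with ≥ 5 each → the
   dual category (grazer-shredder, grazer-gatherer, gatherer-shredder);
   several qualifying pairs → "generalist";
4. otherwise "generalist"; missing data → "unknown".

The single-category ≥ 7 rule deliberately beats the dual ≥ 5/≥ 5 rule when
both apply, since ≥ 7 is the primary indicator of a strong preference.
"Indifferent" is a genuine database category and is never merged with the
inferred "generalist". A coverage report warns when fewer than 80 % of the
species have data for a trait. Group responses (trait categories and
taxonomic orders alike) are per-model means of the member species' SRs,
then ensemble-summarized like any other per-model quantity.

**Significance.** Percent data are normalized with an arcsine-square-root
transform before testing. The classic transform is defined on [0, 1];
percent *changes* are signed and unbounded above, so the package uses the
odd extension sign(p)·arcsin(√(|p|/100)) with inputs clipped to
[−100, 100] (clip events counted). Two per-species flags follow boxplot
annotation conventions: "vs zero" — two-sided one-sample t-test of the
species' across-model SRs against 0, α = 0.01; "vs grand mean" — one-sided
one-sample t-test of the species' |SR| sample against the scalar grand
mean of |SR| over all species and models of that horizon, α = 0.05. The
grand-mean construction is not uniquely determined by its verbal
description; the adopted form is isolated in one operation
(`t_test_vs_grand_mean`) so alternatives can be swapped. Whether the
transform precedes *all* tests or only ANOVA is likewise ambiguous; the
default transforms before every test (`arcsine_before_tests=True`).
One-way ANOVA and paired t-tests are provided for group and
between-catchment comparisons. t and F statistics come from scipy;
degenerate inputs (zero spread) raise `UndefinedStatisticError` instead of
returning silent NaNs, with one exception: a zero-spread sample lying
exactly on the null value is reported as (t = 0, p = 1), the clean null.
No multiple-testing correction is applied.

## The synthetic-data generator

The generator emulates the statistical structure the cascade assumes —
not process hydrology. Daily flows are lognormal with a sinusoidal
seasonal cycle and an AR(1) log-anomaly:

    Q(t) = exp( log(q_s · FA) + A sin(2π·doy(t)/365 + φ) + ε(t) ),
    ε(t) = ρ ε(t−1) + η(t)

with specific discharge q_s = 0.012 m³ s⁻¹ km⁻², flow accumulation FA
drawn per outlet from U(40, 200) km² (sites at U(0.5, 1) of their
outlet's FA), seasonal amplitude A = 0.6 peaking in mid-January, ρ = 0.85
and marginal anomaly sd 0.35 — values chosen once to give perennial
streams of ~0.5–2 m³ s⁻¹ with a realistic winter-high regime and weekly
scale persistence. Each climate model draws *one* multiplicative trend
per horizon, δ ~ Normal(Δ_h, σ_spread) (truncated below at −0.9), applied
to its horizon flows; because dh4 is positively homogeneous, a
multiplicative flow shift propagates linearly into dh4. Two archetypes
fix the trend parameters: **mountainous** Δ = 0 with σ_spread = 0.15
(models disagree about the sign of change) and **lowland**
Δ_2050 = +0.08, Δ_2090 = +0.13 with σ_spread = 0.03 (consistent wetting).
An observation-forced series ("observed") exists for the baseline period
only and anchors the skill weighting and the species construction.

Species: half the species (configurable) are specialists with niche
breadth 8–15 % of their optimum, the rest generalists with 50–100 %.
Optima anchor at one site's observed dh4, jittered within ±0.5 breadths;
a species occupies the sites within 2 breadths of its optimum
(specialists capped at their 3 nearest sites), and its observed abundance
there is the curve evaluated at the site's observed dh4 (optional Poisson
count noise, off by default since the cascade consumes continuous
values). Trait affinities are generated consistently with the niche —
e.g. an optimum above the median site dh4 yields a strong rheophil /
downstream affinity, generalists get low spread affinities, and half the
generalists carry a dual-feeding signature — so the trait-assignment
rules are exercised by construction. A fifth of the sites receive a
"poor"/"bad" ecological status to exercise the input filter. All
randomness descends from one seed through four named substreams (sites,
discharge, trends, species), so any stage regenerates independently and
byte-identically.

What the generator does **not** emulate: spatially correlated weather
across sites (site anomalies are independent), process hydrology
(snowmelt, baseflow recession, floods have no physical basis), dam
operations, bias-corrected climate grids, species interactions, and
observation error in the biological sampling. Passing tests therefore
demonstrate that the *pipeline* recovers the structures it assumes — trend
spread cascading into SR spread, specialists responding more strongly than
generalists, consistent trends producing significant responses — not that
any real catchment behaves this way.

## Problem sizes and numerical choices

The default miniature study is 10 sites, 16 climate models, 12 species and
three 20-year daily periods (≈ 3.6 M flow values); it generates in well
under a second and the full fit takes about one more. The test suite's
replicated checks use 20 seed replicates of that default scenario for the
specialist/generalist contrast and single default-size scenarios
elsewhere; these sizes make the whole suite run in under a minute while
keeping every stochastic margin wide.

* dh4 uses a cumulative-sum rolling mean; equality with the exhaustive
  window enumeration is asserted to 1e-12 relative tolerance.
* Weight-ladder ties use scipy's average ranks, which reproduces the
  mean-of-spanned-weights tie policy exactly.
* The exact-zero null contract (identical baseline and horizon discharge
  ⇒ SR ≡ 0) holds bitwise only when the horizon calendar has the same
  leap-day alignment as the baseline; 1998–2017 and 2046–2065 align,
  2080–2099 does not, so the null fixture pins horizon period definitions
  to the baseline years instead of copying arrays across misaligned
  calendars.
* CSV round trips compare floats at double precision via `repr`-level
  formatting; pandas' writer may differ in the last ulp, which is treated
  as equal.

## Known limitations

* The IHA vector for weighting is a 16-metric magnitude summary, not the
  full catalogue of IHA indicators; weights depend (mildly) on that choice.
* The Gaussian curve is a stand-in family: real fitted flow-abundance
  relationships can be skewed or multimodal, and the registry accepts new
  forms but ships only one.
* SR averages percent changes over sites, which hides site-specific
  losses by construction; the pooled mode changes the estimate but not
  that limitation.
* The vs-grand-mean flag tests against the grand mean as a fixed scalar,
  ignoring its own sampling uncertainty.
* With 16 models, t-tests at df = 15 on arcsine-transformed percentages
  are approximate at best near the ±100 % clip boundary.
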