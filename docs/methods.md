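# Methods

## The decay model

Biomolecule content per gram dry sediment is modelled as a power function
of sediment age, `Y(t) = a · t^b` with `b ≤ 0`. This is the
reactivity-continuum view of organic-matter degradation: the bulk pool is
a mixture of fractions with different intrinsic reactivities, the labile
fractions disappear first, and the apparent first-order rate of the
remaining pool therefore declines with age roughly as `k/t`. The fitted
exponent magnitude `k = −b` is called the decay constant.

**Fitting.** Power fits are ordinary least squares on `(ln t, ln Y)`, not
nonlinear least squares in raw space. Two reasons: contents and gene copy
numbers are strictly positive and span up to four orders of magnitude
down-core, so multiplicative lognormal error is the natural noise model;
and the log–log R² then measures variance explained on the scale where
the noise is homoscedastic. A raw-space NLS variant is available
(`method="nls"`) for sensitivity analysis. Exponential fits are OLS on
`(t, ln Y)` and linear fits are OLS on `(t, Y)`; each model's R² is
reported in its own fitted space, and `compare_models` ranks the three by
R² with ties broken in favour of power, then exponential (the
mechanistically motivated default first, making the ranking
deterministic).

**Data policy.** Points with `Y ≤ 0` (non-detects) are excluded from
log fits and counted; an optional pseudo-value of half the smallest
positive value in the series can be imputed instead (off by default — no
detection limits are available to justify a particular floor). Ages
`t ≤ 0` (the surface layer) are excluded from power fits, since `ln t` is
undefined or degenerate there. A fit needs at least 3 usable points. A
constant profile is reported as slope 0, R² = 0, p = 1 ("no decay")
rather than an error.

**Reliability flag.** A fit is flagged unreliable when the slope is
nonsignificant (p > 0.05) or the coefficient of determination is low
(R² < 0.2); both inequalities are strict, so boundary values are not
flagged.

## Age-dependent half-lives

Under `Y = a·t^(−k)` the time for the pool at age `t` to halve satisfies
`((t + D)/t)^(−k) = 1/2`, giving the exact halving time

```
D(t) = t · (2^(1/k) − 1)          (formula "exact_halving", default)
```

An alternative derives from the instantaneous rate `k/t`:
`D(t) = ln(2) · t / k` (`"instantaneous_rate"`). Both are linear in `t`
— which is exactly why published half-life tables over an age ladder
have every column equal to the age-1 column times the age — and strictly
decreasing in `k` at fixed `t`. For `k ≤ 0` the half-life is infinite
(no net decay) and a warning is emitted.

Because per-biomolecule decay constants behind published half-life
ladders are usually not printed, the package supports a calibration mode:
`calibrate_k_from_h1(h1)` inverts the chosen formula at age 1 y
(`k = ln 2 / ln(1 + h1)` for exact halving), after which
`half_life_schedule` reproduces a full ladder row. The round trip
`half_life(calibrate_k_from_h1(h1), 1) == h1` holds to 1e-12 relative
error.

## Group contrasts

Decay-constant averages are arithmetic means with sample SD (ddof = 1;
single-member groups report SD 0), computed over power fits only. Groups
in which no decay constant is positive ("content did not decrease over
time") are marked not-applicable instead of averaged away silently.

Pairwise contrasts use the two-sided Wilcoxon rank-sum test. The group
sizes that matter here are 3 (stations within a lake) and 5 (lakes), so
the test is computed **exactly** by full enumeration of all
`C(n_x+n_y, n_x)` rank assignments whenever `n_x + n_y ≤ 12` and the
pooled sample has no ties; two-sided p is the doubled smaller tail,
capped at 1. With ties, mid-ranks are used and p comes from a seeded
10,000-draw label permutation; larger samples use the normal
approximation with tie and continuity corrections. Multiple-testing
adjustment defaults to none (raw p-values, matching the conventional
presentation of such panels); Holm is available. Note the hard floor of
exact tests: at n = 3 vs 3 the smallest achievable two-sided p is 0.1,
so station-level contrasts can never be significant at α = 0.05.

Pearson correlations default to log10-transforming both variables, since
cross-molecule correlations involve quantities on very different scales;
the p-value is the usual two-sided t test on the correlation.

## Community operations

Relative abundances are per-sample fractions (rows sum to 1; zero-count
samples are excluded with a warning). The qPCR/amplicon cross-check
multiplies group-specific relative abundances (taxa collapsed to organism
groups first) by each sample's total gene copy number; summing the group
estimates recovers the total exactly because fractions sum to 1.

Bray–Curtis dissimilarity is computed on relative abundances (hence
invariant to sequencing depth); Jaccard on presence/absence is available
as an alternative since the appropriate metric is a study-level choice.
ANOSIM uses the standard rank statistic
`R = (r̄_between − r̄_within) / (N(N−1)/4)` over the `N(N−1)/2` pairwise
dissimilarities, with a seeded label-permutation p-value carrying the +1
correction (`p = (1 + #{R* ≥ R}) / (n_perm + 1)`, default 999
permutations, so p > 0 always and has resolution 1/(n_perm+1)). Every
group must contain at least 2 samples.

## Preservation-scenario classifier

The three candidate preservation mechanisms make distinct, testable
predictions about fitted decay constants:

| scenario | prediction |
|---|---|
| adsorption/complexation | DNA is chemically equivalent across source organisms, so DNA `k` should not differ between groups |
| chemical reactivity | within a group, DNA (labile) should decay significantly faster than the group's resistant compound |
| biotic exclusion | DNA shielded inside resistant structures decays in step with the shielding compound (within-group `k` indistinguishable) while DNA `k` still differs across groups |

`classify_group` fixes this as an ordered rule over Wilcoxon contrasts at
α = 0.05: (i) all cross-group DNA contrasts nonsignificant →
adsorption/complexation; else (ii) within-group DNA significantly faster
than the resistant compound → chemical reactivity; else (iii)
within-group contrast nonsignificant → biotic exclusion; else
indeterminate (DNA significantly *slower* than the resistant compound
fits no mechanism). The ordering and α are configurable. Using
failure-to-reject as "similar" conflates low power with similarity, so
calls based on groups with fewer than 4 decay constants carry a
`low_power` flag. This rule is an operationalization of a narrative
framework, not a claim that the mechanisms are mutually exclusive in
nature.

## Age model

Depth→age assignment is piecewise-linear interpolation over dated
anchors (strictly monotone in depth and age), i.e. constant sedimentation
rate per segment. Beyond the anchor range the nearest segment's rate is
extrapolated; an optional cap prevents silently absurd extrapolated ages.
Layer ages use the midpoint convention. This stage is assignment
plumbing: actual radionuclide modelling (CRS/CIC) happens upstream and
enters only through the anchor table.

## Synthetic data generator

`simulate_profile` draws `Y_i = a · t_i^b · exp(ε_i)`,
`ε_i ~ N(0, σ²)`, from one seeded generator; an optional detection limit
censors low values to missing with a recorded count. The default noise
level is σ_log = 0.3, comparable to the residual scatter around power
fits in real multiproxy profiles; the default core geometry is 20 layers
over 40 cm spanning 180 years at constant sedimentation rate (a ~600-year
variant is a one-line spec change). The default analyte panel encodes
decay constants near values reported for Swiss lake cores — diatom DNA
k ≈ 1.57, green algal DNA k ≈ 0.70, vascular plant DNA k ≈ 0.12, lipid
biomarkers k ≈ 0.45–0.61 — as calibration inputs, with DNA markers at
three stations and biomarkers only at the deepest station (12 series
total), mirroring the usual measurement design.

`simulate_community` builds group intensities `I_g(t) = A_g · t^(−k_g)`,
sets the total copy number to `ΣI_g` times lognormal noise
(σ_log = 0.2), and draws read counts Dirichlet-multinomial around the
proportions `I_g/ΣI` (concentration 200, read depth 50,000, 3 taxa per
group with fixed geometric within-group weights). Because fractions and
totals derive from the same intensities, the partition-conservation
invariant holds by construction. Setting the concentration to `None`/∞
and disabling multinomial sampling (largest-remainder rounding instead)
gives the noise-free limit in which read fractions equal the exact
proportions up to 1/read-depth.

Scenario presets use five single-station lakes (so each analyte yields 5
decay constants): exact rank tests at n = 3 vs 3 cannot reach p < 0.05,
making the classifier undecidable at station level, while at n = 5 vs 5
the smallest exact p is ≈ 0.008. Under these presets the classifier
recovers the generating scenario in ≳ 90% of seeded runs at the default
noise level.

**What the generator does not emulate:** PCR primer bias, chimeras and
sequencing error; spatial heterogeneity between stations beyond
independent noise; bioturbation and turbidites (age reversals); real
detection-limit structure; correlated noise between analytes measured on
the same extract. Passing pipeline tests on synthetic cores therefore
demonstrates statistical correctness of the estimators under the assumed
noise model, not robustness to these real-data complications.

## Numerical choices and edge cases

* OLS via `scipy.stats.linregress`; Holm via statsmodels; distances via
  `scipy.spatial.distance`; everything else is implemented here.
* Exact Wilcoxon enumeration is capped at `n_x + n_y = 12`
  (`C(12,6) = 924` assignments, trivially fast and covering the study's
  group sizes).
* Ties in model ranking: power > exponential > linear.
* Degenerate inputs: constant series → zero slope, p = 1; zero-variance
  variables in correlations/regressions → error (except constant
  *response* fractions, reported as slope 0, p = 1); `k ≤ 0` → infinite
  half-life with warning; non-monotone age anchors → hard error naming
  the offending pair.
* CSV round-trips: fits are written with `repr` floats and read with the
  round-trip parser, so write-then-read is exact.
* All stochastic routines (permutation tests, simulation) take an
  explicit seed; fixture bundles are byte-identical under the same seed
  and spec.

## Problem sizes used in the test suite

Synthetic checks run at desk scale: 500 seeds for exponent-recovery and
model-selection rates, 50 seeds per preservation scenario, 1,000 null
replicates for test-size calibration, 500 runs for ANOSIM p-uniformity
(199 permutations each), and 20 seeded instances for the grid-search
oracle. These sizes give Monte-Carlo error comfortably inside the asserted
margins while keeping the whole suite under a minute of compute.

## Known limitations

* The power law is an *apparent* kinetic description of a mixed pool; the
  package deliberately does not fit reactive-continuum (gamma) models or
  multi-G mixtures.
* Decay constants from profiles conflate degradation with changes in
  deposition flux; the fitted `k` is a net attenuation rate. Correlation
  analyses between independent proxies are the guard against
  over-interpreting any single profile.
* The scenario classifier inherits the power of its rank tests; with few
  lakes, "biotic exclusion" and "adsorption" calls lean on non-rejection
  and should be read alongside the `low_power` flag.
* ANOSIM assumes exchangeability under the null; strong depth
  autocorrelation within cores can inflate significance.
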