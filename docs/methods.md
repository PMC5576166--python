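# Methods

## Model and data

The unit of analysis is an administrative region with population `P_l`
(persons), land area `A_l` (km²), and raw counts of physicians, nurses and
hospital beds. Raw counts are the only stored quantities; every density is
recomputed at full precision and rounded only at report time (round-half-up,
1 decimal for densities, 2 decimals for Gini coefficients). The packaged
Mongolia 2014 table stores raw counts whose column sums equal the national
totals exactly (population 2 995 949; area 1 564 964 km²; physicians 9 364;
nurses 11 053; beds 20 890); the published derived-density columns are
internally inconsistent for several rows (a run of rural physician densities
all printed as 18.4, and demographic densities such as the capital's 306.5
where population/area gives 289.7), which is why they are never stored.

Two **weight bases** drive everything downstream: each region is treated as
`f_l` atomic units — `P_l` persons (per-capita view) or `A_l` km²
(geographic view) — each unit carrying the region's density
`x_l = count/f_l` (scaled per 10 000 persons or per 1 000 km² for
reporting).

## Settlement classification

Urban: population density strictly above 200 persons/km²; suburban:
strictly above 10; rural otherwise. "Higher than" is read as a strict
inequality, so a region exactly at a boundary falls to the lower category.
Group means are unweighted arithmetic means over the member regions'
full-precision densities — the convention under which the packaged table's
published group rows reproduce (the rural per-area physician mean 2.7 is
the unweighted mean, not the pooled ratio 2.0).

WHO workforce thresholds apply to the physicians+nurses per-10 000 density:
below 22.8 → below the minimum essential-coverage standard; [22.8, 44.5) →
meets the minimum; ≥ 44.5 → meets the SDG-era target. Boundaries are
inclusive at the named threshold.

## Lorenz and Gini

Regions are sorted ascending by density on the chosen basis (ties broken by
region name; the coefficient is provably tie-order invariant and a test
asserts it). The Lorenz curve's point `k` is the cumulative weight share
against the cumulative resource share after the `k`-th region; ascending
ordering makes the chord slopes non-decreasing (convexity).

Three routes to the coefficient:

* **Trapezoid** (primary, reported): `G = 1 − Σ Δp (q_k + q_{k−1})`. Exact
  for grouped data under the n-denominator (mean-absolute-difference)
  convention and indifferent to fractional weights, which the area basis
  needs.
* **Grouped concentration ratio**:
  `R = Σ (i_{l−1} + i_l − 1) f_l x_l / ((n−1) A_n) − 1` with `i_l` the
  cumulative count of atomic units. This is the only reading of the formula
  under which equality gives exactly 0 and perfect concentration exactly 1;
  it uses an (n−1) denominator, so `R = G·n/(n−1)` and `|R − G| ≤ 1/n`. At
  national weights (n ≈ 3×10⁶ persons or 1.6×10⁶ km²) the two agree beyond
  five decimals; both are exposed, trapezoid is what reports print.
* **Oracle**: expand regions into atomic units and evaluate
  `Σ_ij |y_i − y_j| / (2 n² ȳ)` by literal double loop. Quadratic on
  purpose; it refuses instances beyond 10⁴ units. Used only to verify the
  other two in tests.

Degenerate inputs: an all-zero resource raises a degenerate-curve error
(share of nothing is undefined); a single atomic unit raises a domain error
(the (n−1) denominator vanishes).

## Urban/rural comparison

Per-region densities for one resource and basis are pooled as
urban+suburban (group A) versus rural (group B) and compared with a
two-sided Mann–Whitney U test. Two methods:

* **Asymptotic** (default): tie-corrected normal approximation with a 0.5
  continuity correction, via `scipy.stats.mannwhitneyu`. Default because it
  is the convention under which small province-level comparisons are
  conventionally reported: at 3 vs 19 with complete separation it gives
  p = 0.0074, whereas exact enumeration gives 2/C(22,3) ≈ 0.0013.
* **Exact**: full enumeration of all C(n1+n2, n1) assignments of the pooled
  midranks, so it stays exact under ties; two-sided p doubles the smaller
  tail, capped at 1. Refused beyond 10⁶ assignments. Recommended for small
  tie-free data; `method="auto"` picks it when feasible.

The asymptotic p is within 0.05 absolute of the exact p for tie-free groups
of at least 3 each (checked exhaustively over rank patterns); at 2 vs 2 the
gap can reach 0.09, so no such envelope is claimed there.

## Supply categories

Cut-offs come from Fisher–Jenks natural breaks: the contiguous partition of
the sorted densities minimizing total within-class sum of squared
deviations, solved exactly by dynamic programming — deterministic, no seed,
standard for choropleth classing (the reason it was chosen over k-means).
Default k = 4 classes mapped red/orange/yellow/green from lowest to
highest; breakpoints sit at midpoints between adjacent classes, and a value
exactly on a breakpoint joins the higher class. On the area basis, any
density ≤ 1 per 1 000 km² is forced red (inadequate supply) regardless of
clustering; the override can only relabel values that are already at the
bottom of a monotone scheme, so monotonicity of category in value is
preserved (asserted by test). No published breakpoints exist to validate
against, so this stage is validated by exhaustive-search equivalence and
the forced-red rule.

`NaturalBreaks` is a scikit-learn-style estimator (`fit`/`predict`,
`breakpoints_`, `inertia_`) so it composes with sklearn tooling; the rest
of the package is deliberately plain functions over a validated table,
since nothing else here is fit/predict-shaped.

## Synthetic generator

`SyntheticSpec` defaults describe the study-like shape: 22 regions, a
3-million national population and 1.5-million-km² area split by a symmetric
Dirichlet with concentration 0.5 (small concentration yields the
one-dominant-region profile of the packaged table), densities log-normal
with median 30 per 10 000 (≈ the national physician density) and σ = 0.4.
`population_concentration=None` means exactly equal shares — the regime in
which the closed-form log-normal Gini `2Φ(σ/√2) − 1` applies without
weighting noise, used for calibration. Counts are rounded integers, so
σ = 0 gives Gini ≤ 0.01 rather than exactly 0 for region populations
≥ 10⁵; the tolerance is stated in the tests rather than hidden.

`generate_separated_groups` designates the first `n_urban` regions as
urban (area shrunk so population density exceeds 200/km²) and caps the
rest at 5 persons/km² so membership never depends on the density draws;
`shift` multiplies the designated regions' densities. `shift=1` is the null
configuration: over 200 seeds the 5 %-level comparison rejects at
0.01–0.09 (the test's asserted band; the exact achievable level at 3 vs 19
is ≈ 0.04 because the U distribution is discrete).

What the generator does not emulate: spatial autocorrelation, correlated
resources within a region, or any systematic density–size relationship.
Passing calibration therefore shows the estimators are correct under
exchangeable heavy-tailed inputs, not that real national data meet those
assumptions.

## Problem sizes and numerical choices

Everything in the default pipeline is closed-form or O(n²) at n = 22 and
runs in well under a minute. Calibration tests use 100–200 regions × 3–5
seeds for closed-form recovery (Monte-Carlo tolerance ±0.05) and 200 seeds
for the type-I-error band. Brute-force oracles are capped (10⁴ units for
the Gini oracle, 10⁶ assignments for exact enumeration, n ≤ 15 for
exhaustive partition search) — they are verification instruments, not
production paths.

## Known limitations

* Group means, thresholds, and the urban/rural split follow the packaged
  study's conventions; other national tables may need different
  demarcations (both thresholds are module constants).
* No confidence intervals or bootstrap for the Gini coefficients, and no
  within/between decomposition; coefficients are point estimates.
* No multiple-testing adjustment across the six rank tests.
* No cartography: supply categories are emitted as CSV joinable to any
  mapping tool; the category logic, not the map, is the deliverable.
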