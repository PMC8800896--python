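# Methods

## Models

**Monotone homogeneity model (MHM).** Persons hold a latent health level θ;
responses to J ordinal items (levels 1..L) are unidimensional, locally
independent, and each item step response function (ISRF)
P(X_i ≥ k | θ) is non-decreasing in θ. Under the MHM the unweighted level
sum score (LSS = ΣX_i) stochastically orders persons on θ, which is the
whole justification for using it. **Double monotonicity** adds
non-intersecting response functions, so the items keep one ordering along θ;
we check its observable consequence, manifest invariant item ordering
(MIIO), rather than ISRF non-intersection itself.

All diagnostics are manifest: they condition on *rest scores* (the LSS minus
the item(s) under inspection), never on an estimated θ.

## Conventions and estimators

**Covariance convention.** Every scalability ratio uses population (1/N)
covariances in numerator and normalizer; the ratios are invariant to the
ddof choice as long as both match. Reliability coefficients are likewise
ddof-invariant.

**Maximum covariance.** Covmax(i, j) is the covariance of the comonotonic
(Fréchet-upper-bound) coupling of the two items' level marginals, computed
by walking the merged cumulative-frequency breakpoints (equivalent to
pairing the two sorted samples). The test suite proves equality with
brute-force coupling enumeration (all small marginal pairs) and with a
transportation-LP oracle (random larger marginals).

**H coefficients.** H_ij = Cov_ij / Covmax_ij; H_i and H_s are
ratio-of-sums over the relevant pairs (algebraically the normed item–rest
covariance; H_s is thereby a weighted mean of the H_i and lies between their
extremes). Zero-variance items give NaN H plus an explicit
`undefined_items` flag — never silent exclusion. Negative H_ij are
reported as MHM violations.

**Positivity tests.** z_ij = r_ij·√(N−1) for Cov_ij > 0 (normal theory).
The AISP applies a Bonferroni correction over all J(J−1)/2 pairs; the paper
trail behind this choice is that the original software's internal test is
unpublished, so a conventional, documented test was preferred.

**Standard errors.** Seeded nonparametric person-resampling bootstrap
(default B = 1000). Identical asymptotics to the delta method but far
easier to verify; a delta-method slot is left as an extension point. On the
calibrated cohort at N = 20,000 and B = 500 the scale SE is ≈ 0.005,
matching the magnitude printed for the original data (0.007 at N = 7933).

**AISP.** Hierarchical variant only (no genetic algorithm): seed each scale
with the largest significantly-positive H_ij ≥ c; grow by the candidate
maximizing the scale's H subject to H with the selection ≥ c and
significantly positive covariances with all selected items; repeat on
leftovers. Ties break toward the lowest item index, making runs
byte-reproducible. The lower-bound sweep defaults to c = 0.00..0.55 in
steps of 0.05 — twelve runs; the end point is configurable because
"0 to 0.5 by 0.05" and "12 runs" cannot both hold. Exclusion thresholds
are refined by bisection to 0.001 on the c-grid, exploiting that selection
is monotone non-increasing in c.

**Rest-score groups.** Adjacent rest-score values merge left-to-right until
each group holds ≥ minsize persons; an undersized trailing remainder merges
into the last group. Default minsize: ⌊N/10⌋ for N ≥ 500, else ⌊N/5⌋ with a
floor of 50. The original software's automatic rule is undocumented, so
this rule is stated and test-pinned; grouped results can differ at group
boundaries from other implementations.

**Monotonicity check.** For each step k and ordered group pair g < g′, a
violation is flagged when P̂_g(X ≥ k) − P̂_g′(X ≥ k) > minvi (default 0.03),
with a one-sided two-proportion z-test per flagged comparison. All
(step, group-pair) comparisons count as active (#ac).

**crit composite.** The original severity index's constants are not
published; ours is the documented composite
`crit = round(50·max(0, 0.3 − H_i) + √#vi + 100·#vi/#ac + 100·maxvi +
10·√zmax)`, exactly 0 when nothing is flagged, monotone in #vi and maxvi.
Constants live in `monotonicity.CRIT_WEIGHTS`. Cross-implementation crit
values are not comparable and nothing downstream depends on them.

**MIIO.** Items are ordered by mean score with *higher mean = easier to
endorse* (more problems reported); reports list the easiest item first.
Pair rest scores use the other J−2 items (hence J ≥ 3), groups are shared
within a pair, and a reversal counts when the harder item's conditional mean
exceeds the easier item's by more than (L−1)·0.03 (0.12 for five levels),
with a one-sided paired t-test (α = 0.05, uncorrected) per flagged reversal.
Ties in item means are flagged, since invariant ordering is ill-defined
under ties. Backward selection removes the item with the most significant
violations (ties: larger crit, then lower index) until no flagged reversal
remains, stopping at J = 3; whether the original ranks by significant count
or by crit is unstated, so the implemented rule is documented here.

**H^T.** The scale H of the transposed matrix (persons as items) after
dropping constant-pattern persons. Both Σcov and Σcovmax over all person
pairs reduce to column sums of the raw and row-sorted matrices, so the
computation is O(NJ log J) rather than O(N²J) and agrees exactly with
`compute_h_scale` on the transposed matrix (tested).

**Reliability.** λ₂ from the classical covariance formula (always ≥
Cronbach's α; tested as an invariant). The Molenaar–Sijtsma ρ works on item
steps: between-item step covariances are used as observed; within-item joint
step probabilities — which would require independent replications — are
approximated by sorting all steps by popularity and interpolating each
needed joint linearly in the marginal from the nearest steps of *other*
items (ratio extrapolation toward 0, complement-ratio toward 1, at the
edges), symmetrized and clamped to the Fréchet bounds (diagonal to
[π², π]). This is the 1988 ordering-based construction; with duplicated
items it returns exactly 1, under independence ≈ 0.

## The synthetic-data generator

The generator is a graded response model: P(X_i ≥ k | θ) =
logistic(a_i(θ − b_ik)), θ ~ N(0,1), b_i1 < … < b_i,L−1. Logistic ISRFs are
monotone, so GRM data satisfy the MHM by construction; equal discriminations
give non-intersecting ISRFs, i.e. an IIO-true fixture. The GRM is purely a
test harness — no parametric model is fitted anywhere in the analysis.

**EQ-5D-5L preset.** Step locations are root-found (Gauss–Hermite
quadrature, 101 nodes) so marginal step-endorsement rates match the
level frequencies of a published six-country survey sample (N = 7933); the
constants ship in `presets/eq5d5l_grm.json` and a test re-derives them. The
printed survey table shows identical frequency rows for MO and UA —
possibly a typesetting duplication — and the preset uses the values as
printed. Discriminations are equal at a = 3.3 and the AD item's effective
trait is 0.55·θ + 0.835·θ₂ (θ₂ independent), fixed once so the preset
reproduces the survey's qualitative regime: H_i(AD) ≈ 0.38 (weak but above
0.3), H_s ≈ 0.56 (strong), four-item H_s ≈ 0.71, two MIIO violations in the
AD–MO and AD–UA pairs, and backward removal of AD. Only marginals and
qualitative H structure are calibrated; the preset makes no claim to the
survey's joint distribution, observed profile counts, or country
correlation structure — so tests passing on the preset demonstrate that the
*methods* behave correctly under the published regime, not that any real
dataset fits the MHM.

**Subgroups.** `DEFAULT_STRATA` mixes a healthier stratum (θ shift −0.9), a
generic chronic stratum (+0.25), and a depression-like stratum (+0.25 with
AD's step locations shifted 1.4 down, making AD much easier to endorse
there) — enough real heterogeneity that stratified runs reproduce the
qualitative subgroup pattern: a weaker scale among the healthy, and no AD
removal in the depression-like stratum, where AD's curve sits clearly above
MO's and UA's.

**Violation injectors.**
- `nonmonotone_step` subtracts `magnitude` from one step's probability over
  a trait window, then restores cumulative coherence. Default: the first
  step over θ ∈ (1.0, 3.5). The window sits where that step's curve has
  saturated because a dip on a still-rising stretch is averaged away by
  rest-score grouping; manifest detectability also improves when the
  *other* items are highly discriminating (the power fixture uses a = 4
  neighbours around an a = 2 target and minsize 250).
- `crossing_irf` multiplies the target's discrimination. Conditional-mean
  reversals given rest scores are heavily attenuated near the response
  scale's ceiling/floor, so the crossing power fixture uses narrow step
  spacing (±0.75, ±0.25) and tight item locations (0.3 apart) at a = 1.2,
  which puts the crossing inside the observable rest range (manifest
  reversals ≈ 0.26 on average).
- `second_dimension` rebalances the target's trait onto an independent
  factor with the given loading.
With magnitude 0 (or multiplier 1) every injector reproduces the base draw
byte for byte; the random stream draws θ₂ unconditionally to keep streams
aligned across variants.

## Problem sizes and numerical choices

Power and recovery suites run 100–200 seeded replications at N = 5000
(detection thresholds ≥ 95%); limit-case checks use N = 20,000; the preset
contract and the acceptance script use N = 50,000, where the O(N) H^T path
matters. Boundary conventions: scale classes are closed on the left (H_s =
0.3 → weak, 0.4 → moderate, 0.5 → strong); H^T classes follow < 0.3 too
low, 0.3–0.4 low, 0.4–0.5 moderate, > 0.5 high. Degenerate inputs
(constant items, constant persons, zero total variance, N < minsize) yield
flagged NaN/degenerate results, not exceptions, except where the operation
is undefined by construction (MIIO with J = 2).

## Limitations

- Missing data: listwise deletion (count logged) or hard error only;
  pairwise deletion is not implemented because the LSS and rest scores are
  undefined per-person under it.
- No kernel-smoothed response functions; grouped empirical estimates only.
- No delta-method SEs, no polychoric alternatives, no latent-class
  reliability, no parametric θ estimation, no utility value sets or VAS
  handling.
- crit values are implementation-specific by necessity (see above).
- The MS-ρ interpolation variant is one of several in the literature; the
  choice is logged in this note and in the code.
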