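# Methods

This note documents the statistical procedures implemented in
`metalscreen`, the defaults they ship with, and what the synthetic-data
machinery does and does not establish.

## Censoring model and limit construction

Detection limits are built from instrument blanks taken through the full
preparation procedure: LoD = 3·SD, LoQ = 10·SD, with SD the *sample*
standard deviation (n−1 denominator; with ~10 blanks the choice matters
at the few-percent level, and the sample SD is the unbiased-variance
convention). Constant blanks make the limits degenerate and raise an
error rather than returning LoD = 0.

Published limit pairs for serum As (0.2/0.55), Cd (0.006/0.019),
Hg (0.2/0.83) and Pb (0.6/2.1 µg/L) are shipped as constants and used
verbatim; note they are not internally consistent with a single blank SD
(0.55/0.2 ≠ 10/3), which is expected when each limit is rounded
independently — therefore the package accepts limits either computed
from blanks or supplied directly. Acute-exposure upper limits
(As 20, Pb/Hg/Cd 50 µg/L) flag toxicity.

Category intervals are half-open: [0, LoD) `below_lod`, [LoD, LoQ)
`lod_loq`, [LoQ, toxic) `quantified`, [toxic, ∞) `toxic`. A value equal
to the LoD is thus "detected, not quantified" and a value equal to the
LoQ is quantified; the convention follows the "Undetected < LOD" /
"Quantified ≥ LOQ" reading of standard prevalence tables. Toxic is a
sub-state of quantified when counting "detected" and "quantified".
Percentages in prevalence tables round half-up to one decimal.

## Censored percentiles

Summaries are rank-based. Records are ordered
`below_lod < lod_loq < numeric ascending`; the p-th percentile is located
by the linear-interpolation rule on order statistics (h = (n−1)p/100).
If either bracketing order statistic is censored, the censored *label* is
emitted (the later statistic wins when both are censored, which keeps the
output monotone in p); numeric interpolation happens only inside the
quantified tail. This never converts censored mass into numbers.

## Substitution

Spatial statistics and interpolation need complete numeric vectors, so
censored records are substituted by an explicit, recorded scheme:
`half_lod_mid` (LoD/2 and the LoD–LoQ midpoint; default), `lod_sqrt2`
(LoD/√2, the classic nondetect convention), or `category_rank` (ordinal
encoding, invariant to any monotone numeric scheme and useful as a
sensitivity check). The scheme is stamped into downstream result objects.
Model-based censored estimation (MLE, Kaplan–Meier-type) is deliberately
out of scope: with >80% censoring for some analytes, such fits hinge on
distributional assumptions the data cannot check.

## Group comparison

The Kruskal–Wallis statistic uses mid-ranks, the tie-correction factor
C = 1 − Σ(t³−t)/(N³−N), and the chi-square reference with g−1 degrees of
freedom (scipy's implementation backs the computation). The chi-square
approximation is used even for small groups to match standard survey
practice; an exact Monte-Carlo permutation option exists but is off by
default. p-values are raw — one test per outcome × metal at α = 0.05,
with the absence of multiplicity correction flagged in the output
metadata. IQR is p75 − p25 with linear interpolation, the same quantile
rule as the numeric branch of the censored percentiles.

## Spatial weights and Lee's L

Weights are k nearest neighbours (default k = 4) by haversine distance
(mean Earth radius 6 371 008.8 m), ties broken by ascending record index
for determinism, no symmetrization (the standard k-NN construction is
asymmetric), row-standardized by default so each neighbour carries
weight 1/k. Row standardization is what gives the global L its [−1, 1]
range; binary weights are available for sensitivity analysis. Weights
serialize to the GAL neighbour-list text format.

Global statistic and local decomposition, with x̃ the centred spatial lag:

    L  = n / Σ_i(Σ_j w_ij)² · Σ_i x̃_i ỹ_i / (‖x−x̄‖‖y−ȳ‖)
    L_i = n · x̃_i ỹ_i / (‖x−x̄‖‖y−ȳ‖)

`mean(L_i) = L` holds exactly under row standardization and is asserted
to 1e-10 in the tests. The Monte-Carlo test applies one shared random
relocation of the (x_i, y_i) *pairs* per permutation: joint relocation is
the correct null for "no spatial association" because it preserves the
in-situ correlation of the pair while destroying the spatial
arrangement (independent permutation of x and y would instead test the
composite null of no correlation at all). The p-value uses the +1
correction, `p = (1 + #extreme)/(1 + n_perm)`, so it is never 0; the
two-sided p doubles the smaller tail, capped at 1. At n_perm = 199 this
discrete rule has exact size 8/200 = 0.04 at nominal α = 0.05 — slightly
conservative, as permutation tests with doubling are. Local significance
ranks each site's observed L_i within its own permutation null.

## IDW interpolation

Predictions are inverse-distance weighted means, `ẑ(s0) = Σ z_i d_i^−p /
Σ d_i^−p`, haversine distances, exact at observation sites (a zero
distance short-circuits to that observation). Predictions are convex
combinations, hence bounded by the observed range, and converge to
nearest-neighbour as p → ∞. The power is chosen by leave-one-out RMSE
over the ladder {0.5, 1, …, 4}, ties to the smallest power (the smoother
surface). Display scale factors for maps are presentation metadata and
never enter statistics. Kriging is out of scope: with strongly clustered
sample points, variogram fitting is fragile, which is exactly the regime
IDW is chosen for.

A note on "recovering" the power: leave-one-out RMSE on noise-free
samples of a *smooth* surface is minimized at the largest candidate power
(the nearest neighbour is locally the best predictor), so recovery is
only well defined on data that are an exact fixed point of the held-out
IDW smoother at the generating power. The test suite constructs such
fixtures (interior values solve z_A = (I − S_AA)⁻¹ S_AB z_B; anchor
sites are duplicated so they are exactly self-predicting at every power)
and verifies zero LOO-RMSE at, and selection of, the generating power.

## Synthetic cohort generator

The generator emulates a clustered child biomonitoring survey: n = 412
children in 5 cluster areas inside a ~0.1° × 0.1° box near 5.4° S,
16.6° E; cluster centroids uniform in an inset of the box and children
uniform in a 1 200 m disk around their centroid (the three-stage survey
design is simplified to centroid + isotropic dispersion, since design
weights are not used downstream).

Each log-concentration field is Gaussian with exponential spatial
covariance C(d) = sill·exp(−d/range), range 2 500 m by default (a
regional gradient visible across an ~11 km window), plus an
individual-level component carrying `micro_frac = 0.3` of the variance —
person-to-person and assay variability that always overlays any regional
gradient in serum biomarkers. Cross-correlated pairs use a linear model
of coregionalization, `Z_cov = ρ·Z_metal + √(1−ρ²)·Z_indep`, with
defaults ρ(Hg, Se) = +0.5 and ρ(As, Zn) = −0.5 — one spatial-dependency
and one spatial-discrepancy pair, the two signals the analysis is built
to detect. Realized fields are standardized in-sample (an affine map,
invisible to Lee's L and to every rank statistic) so that each simulated
cohort's censoring fractions and deficiency prevalences sit at their
configured targets instead of drifting with the random regional level.

Marginals are calibrated in closed form:

- per metal, (µ, σ) of the lognormal solve the two Gaussian quantile
  equations P(X < LoD) and P(X < LoQ) set to the published censoring
  fractions (As 4.4%/40.3%, Hg 34.0%/91.7%, Cd 80.6%/99.0%,
  Pb 86.9%/96.1%). Published percentile tables are not arithmetically
  consistent with these fractions (a median of 1.88 µg/L is impossible
  when 40% of the sample is below 0.55 µg/L), so calibration follows the
  count-based fractions;
- per covariate, the spread derives from the published median and
  deficiency prevalence (e.g. Zn: median 61.6 µg/dL, P(<65) = 64.6%;
  Hb: mean 10.4 g/dL, P(<11) = 68%). The selenium threshold is explicit
  config — reference texts quote 7.0 µg/dL while serum panels report
  µg/L; the default 70 µg/L (with Se in µg/L) is the only reading
  consistent with an 86.9% prevalence at a median of 52.7 µg/L.

All randomness flows from one integer seed through `SeedSequence`
spawns: stream 0 sites, then one stream per analyte field, then one per
covariate field. Output is bitwise-reproducible for a fixed config.

What the generator does *not* emulate: survey design weights, covariate
missingness, measurement bias near the LoQ, non-stationary or
anisotropic spatial structure, and household clustering below the
village scale. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of configured effects under a
stationary isotropic model — not that real surveys have those properties.

## Pipeline

Stages run in order: limits → classification → prevalence → censored
percentiles → Kruskal–Wallis screen → spatial statistics → IDW surfaces,
with the spatial stage gated on the screen: a (metal, nutrient) pair
enters Lee's L and mapping only if its Kruskal–Wallis p < α (a config
flag forces all pairs). Coordinates are privacy-displaced before any
output by one shared geodesic translation — 200 m at bearing 45° by
default (the displacement distance is occasionally quoted in millimetres
in survey ethics text; 200 m is the privacy-meaningful reading and both
are accepted via config). Because every point moves identically,
pairwise distances change by far less than 0.1% at survey scale and
k-NN structure is provably unchanged in the tests. Reports echo the
config, list every written file, and carry warnings for the substitution
scheme and the absence of multiplicity correction. Everything is
reproducible from (config, seed).

## Problem sizes used in the checks

The self-checks run at the survey's own scale where that is cheap
(n = 412 cohorts for sign recovery and power) and at reduced but
statistically adequate sizes elsewhere: 4 000 null datasets of n = 100
sites for permutation calibration (Monte-Carlo error ~0.003 on the
rate), 10 000 null simulations for Kruskal–Wallis calibration, 100
seeded replicates for sign recovery, 50 for permutation power, 20 random
small instances (n ≤ 12) for exact oracle equivalence of the vectorized
Lee's L at 1e-12.

## Known limitations

- The censored-percentile rule emits labels whenever the interpolation
  interval touches censored mass; other defensible conventions exist
  (nearest-rank, label only when both endpoints are censored) and are
  not currently configurable.
- k-NN weight asymmetry means Lee's L here matches the standard k-NN
  construction; symmetrized variants would change values slightly.
- IDW power selection is limited to the candidate ladder; no continuous
  optimisation.
- The exact Kruskal–Wallis permutation option shuffles labels rather
  than enumerating, so very small groups get Monte-Carlo rather than
  exact p-values.
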