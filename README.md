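# metalscreen

Censored heavy-metal biomarker screening with bivariate spatial
association and inverse-distance mapping.

## The problem

Trace-metal biomonitoring surveys (serum As, Cd, Hg, Pb in children, via
ICP-MS) produce heavily **left-censored** data: a concentration is only
reported as a number when it exceeds the limit of quantification (LoQ);
below that it is either "detected but not quantified" (between the limit
of detection LoD and the LoQ) or indistinguishable from blank noise
(below the LoD). With 65%+ of records censored, means are meaningless and
naive substitution fabricates data. At the same time, the interesting
epidemiological questions are *spatial*: does the metal co-locate with a
micronutrient deficit across the survey region?

`metalscreen` implements the full analysis chain for this setting, for
epidemiologists and exposure scientists working with clustered,
georeferenced cohort data:

- **detection limits** from instrument blanks: LoD = 3·SD, LoQ = 10·SD;
- three-state **censoring classification** ([0, LoD) / [LoD, LoQ) /
  [LoQ, ∞)) with a toxicity flag, prevalence tables, and **rank-based
  censored percentiles** that report a censored order statistic as a
  label, never an invented number;
- **Kruskal–Wallis screening** (tie-corrected, chi-square reference) of
  nutrition outcomes across censoring categories;
- **Lee's L** bivariate spatial association under k-nearest-neighbour
  weights, global and local, with Monte-Carlo permutation inference;
- **IDW interpolation** with leave-one-out cross-validated power choice;
- a **synthetic cohort generator** (spatially autocorrelated,
  cross-correlated, lognormal, left-censored fields) so the whole
  pipeline runs and is testable with no external data;
- privacy-preserving systematic **coordinate displacement** for
  published maps.

## The core statistic

For variables x, y at n sites with spatial weights `w_ij` (k-NN, row
standardized), write the centred spatial lag `x̃_i = Σ_j w_ij (x_j − x̄)`.
Lee's L is

    L = n / Σ_i(Σ_j w_ij)² · Σ_i x̃_i ỹ_i / (‖x − x̄‖ ‖y − ȳ‖)

with local decomposition `L_i = n x̃_i ỹ_i / (‖x − x̄‖ ‖y − ȳ‖)`, so that
`mean(L_i) = L` under row standardization and `L ∈ [−1, 1]`. L > 0 is
spatial dependency (the variables are high in the same places), L < 0
spatial discrepancy. Significance comes from jointly relocating the
(x_i, y_i) pairs across sites — the null is "no spatial association"
while the aspatial correlation is preserved — with
`p = (1 + #extreme) / (1 + n_perm)`.

## Worked example

```python
from metalscreen import (SimConfig, generate_cohort, knn_weights,
                         lee_mc, substitute)

cohort = generate_cohort(SimConfig(seed=1))           # 412 children, 5 clusters
W = knn_weights(cohort.coords(), k=4)
x = substitute(cohort.observed["Hg"], "half_lod_mid") # censored -> numeric, recorded
res = lee_mc(x.values, cohort.covariates["se"].to_numpy(), W,
             n_perm=999, seed=5)
print(f"L = {res.L:+.3f}, p = {res.p_value:.4f}")
```

prints

```
L = +0.468, p = 0.0020
```

meaning serum mercury and selenium are strongly spatially associated in
this simulated survey (the generator's configured Hg–Se latent
cross-correlation is +0.5): high-Hg sites are also high-Se sites, and
fewer than 2 in 1000 random relocations of the observation pairs produce
as extreme a value. The `examples/` directory walks through each
capability (cohort generation, censoring tables, group comparison,
spatial association, mapping, the full pipeline), and the
`metalscreen` CLI exposes `simulate`, `screen`, `compare`, `spatial`,
`map` and `run-all` subcommands.

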