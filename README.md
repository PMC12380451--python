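# scinsight2

Covariate-adjusted integration of single-cell RNA-seq samples with a
Poisson generalized linear latent variable model (GLLVM).

## The problem

Joint analyses of scRNA-seq samples from multiple subjects must separate
cellular identity from everything that varies *between* subjects —
technical batch effects and subject-level biology such as age, sex, BMI or
disease condition.  Most integration methods either ignore covariates or
accept only discrete ones.  This package models both discrete and
continuous subject-level covariates explicitly: counts are adjusted for
their effects *inside* the likelihood, and the remaining variation is
captured by low-dimensional cell embeddings ("metagene" scores) used for
joint clustering across samples.

## The model

For cell i and gene j, with K subjects contributing N cells and M shared
genes:

    y_ij ~ Poisson(mu_ij)
    log(mu_ij) = beta0_j + log(s_i) + x_i' beta_j + u_i' lambda_j

- `s_i` — library-size factor: total counts of cell i over the median,
- `x_i` — the covariate row of the cell's subject (continuous covariates
  standardized over subjects, categorical ones reference-coded),
- `u_i in R^P` — the cell's scores on P latent metagenes, with a
  N(0, sigma^2 I) prior,
- `lambda_j` — gene loadings; Lambda's leading P x P block is upper
  triangular with positive diagonal (identifiability).

Estimation maximizes a Laplace-type approximation of the marginal
likelihood (the asymptotically dominated log-determinant term is dropped;
a diagnostic retains it) by first-order optimization with sigma profiled
in closed form.  The number of metagenes P is chosen by a
clustering-stability consensus: B seeded fits per candidate, consensus
co-membership entropy E_p per candidate, smallest local minimum wins.
Embeddings are normalized and clustered with Louvain on a shared-
nearest-neighbor graph.  Details: `docs/methods.md`.

## Worked example

```python
import numpy as np
from scinsight2 import (
    config_from_preset, simulate_dataset, fit,
    normalize_embeddings, cluster_cells, ari,
)

# 10 subjects x 100 cells, 400 genes; age/gender/BMI shift 100 genes each,
# disease condition is a planted null covariate; 8 cell types, 5 true factors
truth = simulate_dataset(config_from_preset("setting1-smoke", seed=1))

res = fit(truth.dataset, truth.design, P=4, seed=1)
labels = cluster_cells(normalize_embeddings(res.params.U), seed=1).labels
print(f"clusters: {labels.max() + 1}")
print(f"ARI vs planted cell types: {ari(truth.cell_types, labels):.3f}")
print(f"sigma: {res.params.sigma:.3f}, epochs: {res.n_iter}")
```

prints

```
clusters: 8
ARI vs planted cell types: 1.000
sigma: 0.109, epochs: 1153
```

The fit recovers the eight planted cell types exactly despite three
covariates each perturbing a quarter of the genes; the estimated
coefficients for the null condition covariate shrink toward zero while the
affected-gene coefficients match the planted signs (see
`tests/test_acceptance.py`).

The same pipeline is available from the shell:

```sh
scinsight2 simulate --preset setting1-smoke --seed 1 --out-dir sim/
scinsight2 fit --counts sim/counts.mtx --cell-meta sim/cells.tsv \
    --covariates sim/covariates.tsv --n-factors 4 --seed 1 --out fit/ \
    --min-cells-per-gene 0 --min-genes-per-cell 0
scinsight2 cluster --embeddings fit/ --seed 1 --out labels.tsv
scinsight2 evaluate --embeddings fit/ --labels labels.tsv \
    --truth-labels sim/truth_cell_types.tsv --cell-meta sim/cells.tsv \
    --covariates sim/covariates.tsv --out metrics.json
scinsight2 select-k --counts sim/counts.mtx --cell-meta sim/cells.tsv \
    --covariates sim/covariates.tsv --candidates 3:6 --n-runs 5 --out sel/
```

Every command writes a JSON manifest (config, seeds, input digests) and is
bitwise-reproducible when re-run with the same inputs on one thread.

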