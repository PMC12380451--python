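# Methods

## The model

scinsight2 harmonizes K single-cell RNA-seq samples, one per subject, while
adjusting for subject-level covariates that may be discrete (gender, disease
condition) or continuous (age, BMI).  The concatenated counts Y (N cells x M
genes) follow a Poisson generalized linear latent variable model (GLLVM)
with a log link:

    y_ij ~ Poisson(mu_ij),
    log(mu_ij) = eta_ij = beta0_j + log(s_i) + x_i' beta_j + u_i' lambda_j

where s_i = l_i / median(l) is the cell's library-size factor (l_i the row
sum of counts), x_i the D-vector of covariates of the cell's subject
(continuous covariates standardized over the K subject values, categorical
covariates reference-coded), u_i in R^P the cell's latent "metagene" scores,
and lambda_j the gene's loadings.  Identifiability is imposed in the
standard factor-analysis way: u_i ~ N(0, sigma^2 I_P) a priori, and the
loading matrix Lambda (P x M) has an upper-triangular leading P x P block
with strictly positive diagonal.  Conditional on u_i, counts are
independent across genes.

## Estimation

The marginal likelihood integrates u_i out of each cell's contribution.  A
Laplace expansion of that integral around the per-cell mode gives, per cell,

    l_i ≈ -1/2 log|Lambda W~ Lambda' + sigma^-2 I_P|
          + sum_j (y_ij eta~_ij - mu~_ij) - ||u~_i||^2/(2 sigma^2) - P log sigma

with W~ the diagonal matrix of fitted means at the mode.  For large M the
log-determinant term is dominated by the data term and is dropped from the
training objective, which (negated, with the embeddings kept as free
parameters) becomes

    Q = sum_ij (mu_ij - y_ij eta_ij) + sum_i ||u_i||^2/(2 sigma^2) + N P log sigma.

This is the negative Poisson log-likelihood up to the y!-only constant plus
a Gaussian shrinkage penalty on the embeddings.  Note the data term is
written with the sign forced by the Poisson kernel exp(y eta - mu); the
alternative sign would make the objective unbounded below.

`laplace_marginal_loglik` retains the full per-cell Laplace value including
the log-determinant term (mode found by Newton's method on the exact
gradient and Hessian), so the magnitude of the dropped term can be audited;
tests verify it against adaptive 1-D quadrature on P=1 problems and confirm
the term's relative size shrinks as genes are added.

### Optimization

Q is minimized jointly over {beta0, B, Lambda, U} with full-batch Adam
(step size 0.01, default at most 4000 epochs) and these numerical choices:

- **sigma** has a closed-form minimizer sqrt(sum ||u_i||^2 / (N P)) and is
  profiled out after every accepted step, floored at 1e-4.
- **Loading constraint**: entries below the diagonal of Lambda's leading
  block are structurally excluded from the parameter vector; diagonal
  entries are optimized through a softplus reparameterization so they stay
  positive without projection steps.
- **Monotonicity guard**: a step that would raise Q by more than 1e-8
  relative is rejected and the effective learning rate halved, so the
  recorded objective trace is monotone non-increasing within that slack.
- **Stopping**: relative change of Q below 1e-8 over a 10-epoch window.
  Profiles of downstream clustering accuracy against optimization depth
  showed that looser tolerances leave the factor subspace visibly
  unconverged even when Q has nearly plateaued, so the default is
  deliberately tight.
- **Overflow**: eta is clipped at 30 (mu <= ~1e13), logged when triggered.
- **Memory**: mu is never fully materialized for large gene counts; the
  fused objective+gradient pass walks gene blocks (default 2048 columns)
  against the sparse count matrix.

### Initialization

The warm start matters more than any other optimizer choice.  A
covariate-only model is fitted first: per-gene OLS of log1p(y/s) on the
design seeds (beta0, B), and 300 Adam epochs on the factor-free Poisson
likelihood refine them (the OLS seed alone under-corrects strong effects
because of the log1p bias at low counts).  U and Lambda then start from a
rank-P truncated SVD of the log-ratio residuals log((y + 1/2)/(mu_hat + 1/2))
of that covariate-only fit.  Starting the factors on covariate-adjusted
residuals is essential: with B = 0 the covariate effects dominate the top
singular directions, and the factor subspace begins — and tends to stay —
aligned with the covariates instead of the cells.  The fit seed controls a
small Gaussian jitter (SD 0.01) on the warm start so repeated
initializations differ; everything else is deterministic.

## Choosing the number of metagenes

For each candidate P in an ordered set A the model is fitted B times
(default 10) with seeds base_seed + b, each fit is clustered, and the B
binary cell-cell co-membership matrices are averaged into a consensus
matrix C-bar.  The consensus index

    E_p = - sum_ij C-bar_ij log2(C-bar_ij)      (0 log 0 := 0)

is 0 exactly when co-membership is unanimous across runs.  Candidates whose
index is lower than both neighbors form the admissible set; the smallest is
selected.  Two conventions were open and are resolved as follows: endpoints
are admitted when lower than their single neighbor (preserving the
parsimony preference on monotone profiles), and an empty admissible set
falls back to the global minimum with a logged warning.  Above 5000 cells
the N^2 consensus matrices are computed on a seeded subsample of 5000 cells.

## Post-processing and clustering

Fitted embeddings are refined before clustering: each factor column is
scaled to unit SD, then each cell row to unit Euclidean norm, so clustering
compares metagene score profiles rather than magnitudes and is invariant to
the overall scale of U.  (This scheme is this package's own choice of
refinement; alternatives `none` and `column_scale` are available via the
`normalization` argument.)  Cells are clustered by Louvain modularity
optimization on a shared-nearest-neighbor graph: k nearest neighbors per
cell (Euclidean, self included), edges weighted by the Jaccard overlap of
neighbor sets.  Defaults are k = 50 and resolution 1.0: at the ~1000-cell
scale used throughout the tests, smaller neighborhoods (k = 20) make the
Jaccard graph fragment well-separated groups into 15-19 pieces, while k = 50
recovers the planted granularity robustly.  Both are configurable, and k
should be revisited for much larger or much smaller datasets.

## Evaluation metrics

- **Covariate-specific integration index**: for each cell, the fraction of
  same-covariate-value cells among its k1 = 50 nearest neighbors is compared
  with the fraction among its k2 = 500 nearest neighbors; the index is the
  mean of 1 - |difference|, in [0, 1], higher meaning the covariate is as
  common locally as at meso scale (well mixed).  Neighborhoods exclude the
  query cell; distance ties are broken by ascending cell index so the index
  is reproducible.  The pipeline computes it on the normalized embeddings.
- **iLISI**: per-cell inverse Simpson's index of sample membership over a
  Gaussian-kernel neighborhood whose bandwidth matches a perplexity
  (default 30); 1 = fully segregated, K = fully mixed.
- **ARI** and **silhouette** are the standard definitions (delegated to
  scikit-learn; an independent pair-enumeration oracle cross-checks ARI in
  the tests).
- **Relative contrast** scores each metagene by |top cluster mean - mean of
  other cluster means| / top cluster mean over cluster-averaged expression;
  metagenes above 0.5 are flagged representative and the top 4 reported.

## The synthetic-data generator

The generator reproduces a multi-subject design with known ground truth.
Defaults: K = 10 subjects, 500 cells each, M = 2000 genes, 5 true metagenes.
Per subject: age ~ U(20, 70), BMI ~ U(16, 24), gender uniform on {F, M},
condition uniform on {healthy, mild, severe}; age and BMI are standardized
in the design.  Gene intercepts are N(0, 1).  Age, gender and BMI each
affect a random 300 genes (disjointly drawn per covariate) with
coefficients +-Uniform(1, 1.5) (equal sign probability); the condition
covariate affects nothing — a planted null whose estimated coefficients
should shrink toward zero.  Eight cell types have fixed 8 x 5 mean codes in
metagene space (each type high, value 1, on a unique set of 1-2 factors — a
stand-in with the "distinct types, shared factors" structure; the matrix is
configurable), and embeddings are N(mean[type], 0.1) — deliberately not the
model's Gaussian prior.  Loadings are N(0, 1/P) projected to the
identifiability constraint.  Library sizes are lognormal(meanlog 7.5,
sdlog 0.5) (median ~1800 counts; an empirical file of sizes can be supplied
instead).  Counts are one multinomial draw per cell: size = the cell's
library size, probabilities = softmax(eta) where eta omits the log(s_i)
offset (additive per-cell constants cancel in softmax), so row sums equal
library sizes exactly.

Setting 2 makes types condition-exclusive (type 1 only in healthy, type 2
only in mild, severe lacking both, remaining types uniform); setting 3
makes types 1-2 age-dependent (shares 0.3/0.1 under age 30, 0.2/0.2 at
30-44, 0.1/0.3 at 45+).  Presets `setting1-strong` and `setting1-stronger`
raise coefficient magnitudes to Uniform(1.5, 2) and Uniform(2, 2.5);
`setting1-collinear` ties condition to age rank (4 youngest -> first level,
middle 4 -> second, 2 oldest -> third; defined only for K = 10).  The
`*-smoke` presets scale to 100 cells/subject, 400 genes and 100 affected
genes per covariate for desk-scale runs.

What the generator does *not* emulate: overdispersion beyond multinomial
sampling, dropout, doublets, ambient RNA, or real gene-level count
distributions (library-size scale only).  Passing tests therefore
demonstrate correctness of the machinery and robustness to covariate
confounding and moderate model misspecification (non-Gaussian embeddings,
multinomial rather than Poisson counts), not performance on real tissue.

## Known limitations

- The Poisson likelihood leaves overdispersion to the latent factors and
  covariates; a negative-binomial likelihood is out of scope.
- The profile objective is, in principle, unbounded along the direction
  that shrinks U while inflating Lambda (the dropped log-determinant term
  is what penalizes it); the sigma floor and finite optimization keep fits
  away from that degeneracy in practice, but extremely long runs at tiny
  tolerances are not advised.
- Joint full-batch optimization holds N x P embeddings in memory and scales
  to tens of thousands of cells; no stochastic minibatching is provided.
- The covariate model is linear on the log scale; nonlinear covariate
  effects are not represented.

## Problem sizes in the tests and acceptance script

End-to-end checks run the smoke-scale design (1000 cells x 400 genes,
100 affected genes per covariate) — clustering accuracy as the median ARI
over three simulation seeds, and consensus selection over candidates
{3,...,6} with B = 5 runs capped at 1500 epochs each.  Estimation
properties (gradient/finite-difference agreement, Laplace vs quadrature,
sigma stationarity, coefficient recovery with >95% sign agreement and
null-covariate shrinkage) run on 300 x 120 model-generated data.
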