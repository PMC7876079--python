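# Methods

## Model and assumptions

The package treats a microbiome dataset as a samples × taxa abundance
matrix whose rows carry only relative information (compositionality):
library sizes are set by the sequencing process and may vary by orders
of magnitude, so all compositional analyses go through the centered
log-ratio transform, clr(x)_k = log(x_k / G(x)). clr requires strictly
positive entries; zeros are handled by adding a pseudocount to *every*
entry (not only the zero cells), which keeps the perturbation uniform
across samples. The default pseudocount is 0.5 — half of one read on the
count scale — and is configurable. Cumulative sum scaling (CSS,
default quantile 0.5) is available as the count normalization applied
before the non-compositional kernels (Jensen–Shannon, quantitative
Jaccard), so that the compositional and non-compositional routes are
comparable.

Every analysis consumes an N×N symmetric positive semi-definite kernel
matrix. The same matrix feeds the C-SVM / ε-SVR (classification /
regression), kernel PCA (ordination) and, for linear-type kernels, the
signature extraction. Natural logarithms are used throughout (clr and
the Jensen–Shannon kernel), and kernel matrices are stored dense with
sample order equal to the table's row order.

### Kernel conventions

* **qJac**: implemented as the ratio of sums Σ_k min / Σ_k max (the
  standard Ružička similarity). A pair of all-zero samples is defined as
  similarity 1 (identical samples) with a warning, keeping the diagonal
  consistent.
* **JSK**: defined for relative frequencies; count input is closed to
  proportions with a warning rather than rejected. The zero convention
  0·ln(0/a) = 0 applies; values lie in [1 − ln 2, 1].
* **cRBF / fRBF**: one shared bandwidth γ per kernel matrix. The
  `median_heuristic_gamma` helper (1 / median pairwise squared distance)
  provides a data-driven anchor for tuning grids.
* Diagonals of RBF-type kernels are set to exactly 1 to remove rounding
  residue; constructed matrices are symmetrized once
  ((K + Kᵀ)/2) after a 1e-10 relative symmetry check.

### Functional (longitudinal) kernels

Discrete mode is the default: with few time points, interpolating
between measurements is less reliable than using the series itself, so
fLin/fRBF operate on a common, evenly spaced grid and refuse irregular
grids or missing samples (directing the caller to continuous mode)
rather than silently averaging spacings. Multivariate combination sums
per-taxon linear kernels (fLin', equal to Δt times a linear kernel on
the N×(D·T) taxon-major flattened matrix) and multiplies per-taxon RBF
kernels (fRBF', equal to an RBF kernel on the flattened matrix, one
shared γ).

Continuous mode reconstructs each series by piecewise-linear
interpolation — chosen for determinism and exactness on polygonal
inputs — on the union of the two sampling grids restricted to the
integration interval. The integrand (product or squared difference of
two piecewise-linear functions) is piecewise quadratic, so per-segment
Simpson quadrature integrates it exactly; no adaptive refinement is
needed. Extrapolation beyond a series' sampled support is refused.

Preprocessing order for compositional longitudinal data: pseudocount →
clr per (individual, time point) sample → functional kernel; recorded in
provenance.

## Multiple kernel learning

The consensus kernel is K* = Σ β_z K_z with β_z ≥ 0. β is normalized to
Σβ = 1: the scale of K* is redundant with the SVM cost parameter, so the
simplex removes a spurious degree of freedom. Matrices are
cosine-normalized (unit diagonal) before combination so that β values
are comparable across kernels of different scales; with a single matrix
(M = 1) the kernel is returned untouched.

* **Supervised**: an exhaustive grid on the unit simplex (steps of 1/10
  for M ≤ 3, 1/4 otherwise, configurable) scored by repeated k-fold
  cross-validated SVM performance, jointly with the SVM cost. The grid
  contains the one-hot corners, so the consensus never scores worse (in
  training CV) than the best single kernel on the same grid. Ties are
  broken toward the most uniform β (maximum entropy), then the smaller
  cost. A transparent grid search was preferred over gradient MKL
  because it is reproducible, exhaustive at these small M, and matches
  the cross-validation-based tuning protocol used everywhere else.
* **Unsupervised consensus**: maximizing the average Frobenius-cosine
  similarity of K*(β) with the bank is a Rayleigh quotient of the M×M
  similarity matrix of the centered, cosine-normalized kernels; β is its
  leading eigenvector (non-negative by Perron–Frobenius when the
  similarity matrix is non-negative; negative entries, which indicate
  anti-correlated kernels, are clipped at zero with a warning) and
  normalized to sum 1.

Spatio-temporal data composes the two mechanisms: one functional kernel
matrix per site, then MKL across sites. Hierarchical integration is
expressed by nesting calls.

## Evaluation harness

The replicated hold-out protocol: `n_replicates` (default 40) random
80/20 train/test partitions; within each training portion,
hyperparameters (SVM cost, and γ when a candidate-bandwidth family of
matrices is supplied) are tuned by `inner_folds`-fold CV (default 5)
repeated `inner_repeats` times (default 5) with reshuffling — "5 × 5" is
read as repeated 5-fold CV; the final model is refit on the whole
training set and scored once on the test set. Candidate-γ kernel
matrices are computed once up front and sub-indexed per replicate, so γ
tuning never recomputes features. The test block of the kernel matrix is
indexed only at final scoring (verified by a corruption test: perturbing
test rows/columns leaves the tuned hyperparameters unchanged).

Grouped designs (e.g., litters of full sibs) use group-aware splitting:
no group ever spans train and test, asserted on every replicate. For
comparing per-time-point models against longitudinal ones, the harness
can score on one randomly chosen row per test group
(`test_one_per_group`), equalizing test-set sizes between protocols.

Metrics: accuracy for classification; NMSE = MSE / Var(y_test)
(population variance) for regression, so the trivial mean predictor
scores ≈ 1. NMSE on a constant test target is an error. Tuning ties
break toward the smaller cost (stronger regularization) and smaller γ.
Multi-class classification is handled one-vs-one by the underlying SVM;
signatures are restricted to binary models. All randomness derives from
a single integer seed via seed sequences, making reports bit-reproducible.

Default grids: cost ∈ {0.01, 0.1, 1, 10, 100}; γ grids are the caller's
choice, typically the median heuristic × {0.25, 1, 4} or a log-spaced
range.

## Kernel PCA

K is double-centered (J K J with J = I − 11ᵀ/N), eigendecomposed, and
projections are returned as u_c √λ_c sorted by decreasing eigenvalue, so
the per-component variance of the projections is λ_c / N and a linear
kernel reproduces feature-space PCA scores exactly. Sign convention: the
largest-magnitude loading of each component is positive. Requests beyond
the number of positive eigenvalues truncate with a warning; tiny
negative eigenvalues are clipped at zero.

## Signatures

For a binary cLin SVM, w_k = Σ_i α_i y_i clr(x_i)_k over support samples
(for SVR the dual coefficients α − α* are used directly, without a y_i
factor, per standard support-vector-regression duality); importance_k =
(w_k)², normalized to sum 1 after any aggregation. Spatial aggregation
is the β-weighted sum of the *unnormalized* per-site (w_k)² — the
algebraically equivalent view is scaling each site's feature map by
√β_z. Longitudinal importance sums (w_{k,t})² over the T time
coordinates of taxon k in the taxon-major flattened layout.
Normalization to relative values happens after aggregation, so site/time
contributions are weighted on the raw scale. Non-linear kernels are
rejected: they have no explicit hyperplane, and permutation-based
importances are out of scope. Top-fraction selection keeps
⌈fraction · D⌉ taxa, ties at the cutoff broken by lexical taxon id, and
reports their cumulative share of total importance. Per-replicate
signatures can be averaged with across-replicate standard errors.

## Synthetic data generator

Compositions are logistic-normal: a latent N(0, σ²) vector per sample on
the clr scale, pushed through a softmax, so planted clr-scale effects
are exactly what the compositional kernels and linear signatures should
recover — recovery is a well-posed test. Defaults (fixed once as
realistic for genus-level data): latent sd 1.0; per-taxon baseline
log-abundances N(0, 1) (taxa differ in mean abundance); library sizes
log-normal with median 10⁴ and σ = 1 (order-of-magnitude spread);
multinomial count sampling; total zero fraction 0.1, reached by thinning
beyond the natural sampling zeros (the most abundant taxon per sample is
protected). Classification plants ±effect/2 clr shifts on the
informative taxa in balanced classes; regression makes the target a
linear function of the informative latent coordinates plus noise.

Multi-site tables share a per-individual latent component (weight √ρ,
ρ = site correlation) plus site-specific innovations; signal is planted
only in the informative sites; ρ = 1 reuses the same random stream per
site so tables are identical. Longitudinal tables use an equicorrelated
trajectory (individual baseline + per-time innovation, equal weights)
with the class shift applied only at the informative time points — all
other time points are exchangeable between classes, i.e. carry strictly
zero signal.

### What the generator does and does not emulate

It reproduces compositionality, sparsity, variable library sizes,
between-individual structure and plantable spatial/temporal signal. It
does not emulate phylogenetic correlation between taxa, overdispersion
beyond the logistic-normal–multinomial, batch effects, or weak diffuse
signal spread over many taxa. Consequently, passing recovery tests shows
the machinery is correct under its own generative assumptions, not that
comparable accuracies will be reached on any real dataset.

One consequence is worth stating explicitly: because non-informative
time points carry strictly zero signal, concatenating them dilutes the
longitudinal RBF distance, and the single-informative-day model scores
slightly *higher* (≈ 3–7 accuracy points at the default problem sizes)
than fRBF' on the full trajectory. On real data, where "uninformative"
time points typically retain weak residual signal, longitudinal kernels
can instead gain a few points over the best single day. A stronger
shared individual baseline does not change this ordering, since the
isotropic RBF cannot form baseline-correcting contrasts.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipelines at
moderate sizes chosen as the package's own defaults: single-point
recovery at n = 150 individuals × 200 taxa (10 informative, effect 2,
40 seeds); MKL site selection at n = 100 × 100 taxa × 2 sites (10–20
seeded runs); longitudinal localization at n = 150 × 100 taxa × 3 days
(10–20 harness replicates, inner 5-fold CV repeated twice, cost grid
{0.1, 1, 10}, γ = median heuristic × {0.25, 1, 4}); kernel validity on
50 random tables up to N = 100, D = 500. Timing checks: cLin at
N = 100, D = 1000 and fRBF' at N = 100, D = 500, T = 3, both well under
their single-CPU bounds (the kernels are O(N²D) and O(N²TD) matrix
computations).

## Known limitations

* Supervised MKL is exhaustive on a simplex lattice; it is intended for
  small numbers of kernels (M ≤ ~5).
* Signatures require linear-type kernels and binary (or regression)
  models; one-vs-one multi-class hyperplanes are not aggregated.
* The continuous functional kernels integrate piecewise-linear
  reconstructions; spline or autoregressive trajectory models and
  time-warping alignment are out of scope.
* Kernel matrices are dense; no sparse backends or phylogeny-aware
  (UniFrac/PhILR-type) kernels.
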