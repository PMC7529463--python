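# Methods

This note documents the models, estimators, numerical choices and known
limitations of `rmtot`. It is written for a reader who wants to know exactly
what each stage computes and what the test suite does and does not establish.

## Data model and normalization

The unit of analysis is a cells × genes matrix of non-negative counts.
QC removes cells with fewer than `min_genes` detected genes (default 500,
strict: a 500-gene cell is kept) or a mitochondrial transcript fraction
strictly greater than `max_mito` (default 0.10; a cell at exactly 10% is
kept). Mitochondrial genes are recognized by a configurable ID prefix
(default `mt-`, case-insensitive) or an explicit ID list, which takes
precedence. Normalization is log2(1+TPM) with TPM = counts-per-million: 3'-tag
droplet chemistry reads transcript ends, so no gene-length correction is
applied. Per cell, Σ_g (2^value − 1) = 10⁶ exactly; this is a tested
invariant.

Aggregation of multiple samples concatenates rows over an identical gene set
(order is harmonized automatically; a genuine set difference is an error that
names the offending genes). `center_per_sample` equalizes each gene's
per-sample mean to its global mean — a deliberately minimal fallback for data
whose batch correction happened upstream in an external tool; it can produce
small negative values, which downstream standardization tolerates.

## Spectral model

For the standardized matrix X (genes centered and, by default, scaled to unit
variance), the Wishart matrix is W = (1/P)XXᵀ. Under pure noise the
eigenvalue density follows the Marchenko-Pastur law with parameter
γ = N/P and scale σ²; the support edges are a± = σ²(1±√γ)². For γ > 1 the
model carries an atom of mass 1−1/γ at zero; the fitted CDF accounts for it.

**Why per-gene scaling is the default.** With genes of heterogeneous variance
the spectrum is a mixture of MP laws and no single σ² fits it: on the default
synthetic dataset a global-σ fit covers only ~75% of the spectrum, while
after unit-scaling the MP fit covers ~97%. Global-σ mode remains available
(`scale_genes=False`) and is used in tests whose inputs have homogeneous
variance by construction (i.i.d. Gaussian matrices, spiked models).

**σ² estimation.** Iterative trimming: starting from the mean of all
eigenvalues, σ² is updated so that the mean of the eigenvalues inside the
current support matches the model's conditional bulk mean, the support is
recomputed, and out-of-support eigenvalues are excluded; the loop stops when
the bulk set stabilizes (≤ 20 iterations). Spikes well above the bulk are
excluded after the first iteration and do not bias the fit (tested to 1%).
The fit quality is reported as the Kolmogorov-Smirnov distance between the
bulk empirical CDF and the conditioned MP CDF.

**Signal threshold.** The largest noise eigenvalue fluctuates around a₊ on
the Tracy-Widom scale σ²·((√P+√N)/P)·(1/√P+1/√N)^{1/3}. Eigenvalues are
called signal only above a₊ plus `edge_allowance` (default 3) times that
scale; at the default, pure-noise matrices yield zero signal eigenvectors in
≥ 95% of seeds while strong planted spikes are recovered exactly (tested over
20 seeds for k ∈ {0, 1, 3}). The reported `noise_fraction` is the share of
eigenvalues inside [a₋, a₊] itself, without the allowance.

**Eigenvector universality.** A noise eigenvector has components
≈ Normal(0, 1/N); localization is measured by the inverse participation
ratio IPR = Σ_α ψ(α)⁴ (1/N for the flat vector, ≈3/N for Gaussian vectors, 1
for a basis vector). A vector is delocalized when IPR ≤ c·log(N)/N (default
c = 3) and either the KS test of its components against Normal(0, 1/N) does
not reject at `alpha_delocalization` (default 0.001) or IPR < 1.5/N. The
1.5/N clause exists because the exactly uniform vector — maximally
delocalized — fails any component-histogram test; it sits just above the
flat-vector minimum so Gaussian vectors still answer to the KS test. A vector
spread evenly over, say, 20% of cells (IPR ≈ 5/N, bimodal components) is
correctly called localized.

**Sparsity artifacts.** Droplet sparsity can manufacture localized
eigenvectors that carry no biology. Two signatures are flagged on localized
eigenvectors:

- *detection-depth structure*: loadings correlating with the per-cell number
  of detected genes at |r| > 0.5 — the direction is explained by how many
  genes each cell expresses (e.g. a block of cells with structurally missing
  genes);
- *gene-marginal sparsity*: overlap (Jaccard of the top-50 loading cells
  > 0.25) with a localized eigenvector of a null obtained by permuting each
  gene's full column across cells, which preserves per-gene zero fractions
  and value histograms but destroys all cell-level structure. This rule is
  additionally gated on eigenvalue magnitude (real λ within 1.5× the null's
  at the same rank): value-level biological signal produces eigenvalues the
  null cannot reach, and only sparsity-compatible magnitudes may be flagged.

The null deliberately does **not** preserve which entries are zero. In
droplet data, marker genes are detected essentially only in their own
population, so the zero pattern itself carries the biology; a zero-preserving
null reproduces genuine population eigenvectors and would flag them as fake
(we measured Jaccard 0.5–0.7 between such null eigenvectors and real
population directions before adopting the column-permutation null).

*Known limitation:* when marker expression is effectively on/off (log2 shifts
around 3 and above under dropout), the biological signal lives almost
entirely in the zero pattern and its eigenvalue can still track per-cell
detection counts; the detection-depth rule may then withhold genuine
directions from the signal set. The procedure is conservative by design —
withheld directions become `sparsity_fake`, never phantom signal.

**Projection and gene selection.** Latent coordinates are ψᵢ·√(Nλᵢ) on the
signal set, so the coordinate Gram matrix is diag(Nλᵢ); the denoised matrix
is the signal-subspace reconstruction Ψ_s Ψ_sᵀ X of the standardized matrix
(mean-zero, real-valued). Signal genes: for standardized gene column x_g,
T_g = ‖Ψ_sᵀx_g‖²/σ̂² is χ²_k under the noise null (k = number of signal
eigenvectors); upper-tail p-values are BH-adjusted and selected at
`fdr_signal_genes` (default 0.05). Calibration is tested on held-out null
genes alongside a planted direction.

## Clustering

Leiden community detection (modularity with resolution parameter, fixed seed)
on a union-symmetrized k-NN graph (k = 15, Euclidean metric in the latent
space) across a grid of 20 log-spaced resolutions in [0.05, 2.0]. For each
partition the mean silhouette s = (b−a)/max(a,b) is computed in the latent
space — not on the graph and not in a 2-D embedding, whose stochasticity
would contaminate model selection. The resolution maximizing the mean
silhouette wins; ties break toward fewer clusters, then smaller resolution.
Conventions: singleton clusters and the degenerate a = b = 0 case score 0, so
sweeps never crash; partitions with a single cluster are recorded as
undefined and excluded from selection. Above 20,000 cells the silhouette is
computed on a stratified seeded subsample of 10,000 (a documented
approximation; exactness against brute force is tested below that size).
Sub-clustering reruns the sweep on one cluster's cells (floor: 20 cells),
reusing the restricted latent space by default, and namespaces labels as
`parent.child`; a homogeneous subset surfaces as a "no substructure" error
rather than a silent single cluster.

## Optimal transport

Populations are uniform distributions over their cells' latent coordinates;
the ground metric is Euclidean distance between coordinates as produced (no
eigenvalue re-weighting; an option exists). The Wasserstein-1 distance is
solved:

- *exactly* for plans up to `exact_threshold` = 4·10⁶ variables — equal-size
  instances via the assignment problem, unequal via the transport LP (HiGHS).
  At the population size cap of 2000 cells (larger populations are subsampled
  with a recorded seed) the LP takes ~2 s, so the exact route is the default
  throughout the pipeline;
- *approximately* beyond that by log-domain Sinkhorn with ε annealed from
  0.05× the median pairwise cost downward by halving over 6 stages (warm-started
  potentials, ≤ 3000 iterations total, per-stage tolerance with plateau
  detection). The final plan is rounded onto the transport polytope, so the
  reported value is the cost of an exactly feasible plan; raw fixed-ε
  Sinkhorn would report W₁(μ,μ) > 0, which the annealing and rounding remove.
  Agreement with the exact LP is tested to < 1% relative error.

The distance matrix is symmetrized by computing each unordered pair once.
Heatmap ordering is average-linkage agglomeration; the tree is canonical
Saitou-Nei neighbor joining (via scikit-bio) with branch lengths in
Wasserstein units. Negative NJ branch lengths — possible on non-additive
input — are retained and flagged, with an option to clamp them to zero; on
exactly additive input the tree reproduces all pairwise distances to 10⁻⁹
(tested).

## Cross-species analysis

Ortholog tables are resolved strictly one-to-one (ambiguous genes dropped and
counted; the table is always a user-supplied file). Both matrices are
restricted to resolved pairs, normalized per species, and any pair with mean
normalized expression strictly below 0.1 in *either* species is removed (the
filter can alternatively operate on the TPM scale). The merged matrix is
denoised exactly like a single-species one — the shared latent space is the
only cross-species alignment, with no additional batch correction. Cross
distances use the same OT solvers; validation checks that each declared
conserved pair attains its row minimum. On the paired generator's default
conditions (3 conserved populations, 2 private per species, species noise
0.25 log2 units), conserved-pair argmin accuracy is ≥ 90% over 10 seeds
(tested; measured 100%).

## Differential expression

One-vs-rest per population on the denoised matrix. The t statistic uses
deliberately overestimated variance: se² = v₁/n₁ + v₂/n₁ with n₁ the focal
group's size for *both* terms, inflating the standard error whenever the
focal group is the smaller one (the statistic is verified against the cited
implementation's scores to 10⁻⁵ in a cross-check test). Degrees of freedom
are Welch-Satterthwaite on the same inflated terms. BH adjustment is applied
across genes within each comparison; selection at corrected p < 0.001. The
Wilcoxon rank-sum p-value is reported alongside; the t-test alone decides
selection, with t/Wilcoxon selection overlap ≥ 80% on planted markers kept as
a consistency property. Constant genes yield t = 0, p = 1; populations under
3 cells are skipped with a warning.

## Synthetic data generator

The generator emulates the statistical regime of a 10x-style droplet
experiment; all parameters are package conventions (no external dataset
prescribes them) and these are the defaults:

- **Populations**: 8 (2000 cells, 10000 genes in the default dataset),
  equal proportions, arranged on a random binary tree with branch lengths
  ~U(0.75, 1.25). Each tree edge owns a disjoint block of marker genes
  (fraction 0.02 of genes per edge) shifted by `marker_shift` × branch length
  (default 2.0 log2 units) in all populations below the edge, so squared
  centroid distances add along tree paths and tree recovery has a ground
  truth.
- **Counts**: per-gene base abundances 2^Normal(0, 1.5); negative binomial
  with dispersion θ = 2 (θ → ∞ gives the Poisson limit, used in closed-form
  tests); library sizes LogNormal(8.6, 0.35) — median ≈ 2900 UMIs/cell.
- **Dropout**: multiplicative Bernoulli mask with logistic probability in the
  gene's log2 mean expression at the reference depth (midpoint 0, slope 1) —
  experiment-level dropout, as in standard simulators. Keying dropout to each
  cell's own depth instead would induce a per-cell variance profile that
  visibly deforms the MP bulk (measured: 84% vs 97% of eigenvalues in
  support) and has no counterpart in the exchangeable-noise model the
  spectral analysis assumes.
- **Mitochondria**: 13 genes holding 2% of pre-dropout expression with a
  per-cell LogNormal(0, 0.5) multiplier; observed median mito fraction
  ≈ 3.7% with ≈ 3% of cells above the 10% QC cutoff.
- **Resulting regime**: ≈ 89% zeros, ≈ 93% of cells pass QC.
- **Species pairs**: conserved populations share log2 mean vectors on
  ortholog genes up to species noise (Normal, default sd 0.25); private
  populations carry their own marker blocks at 1.5× shift; gene namespaces
  are disjoint with a one-to-one ortholog table covering `ortholog_fraction`
  of genes. A `sampling="expected"` mode emits deterministic expected counts
  for construction-exact tests.
- **Seeding**: one integer seed; every stage draws from a named CRC32-derived
  sub-stream, so identical seeds give bit-identical datasets and any stage is
  reproducible in isolation.

What the generator does *not* emulate: gene-length/GC bias, ambient RNA,
doublets, batch effects beyond per-sample mean shifts, spliced/unspliced
structure, and cell-depth-coupled dropout (see above). Tests passing on this
generator therefore demonstrate correctness of the algorithms under the
stated statistical model, not robustness to every artifact of real droplet
data.

## Problem sizes in the test suite

Tests run the full chain at reduced but non-trivial sizes chosen to keep the
suite fast while preserving the spectral regimes of interest: the default
2000 × 10000 dataset for the noise-fraction check, 1000 × 5000 Gaussian
matrices for MP-law conformance, 400 × 2000 spiked matrices over 20 seeds for
detection counts, a 1200 × 4000 six-population dataset for clustering
recovery, and 400-cell-per-species pairs over 10 seeds for cross-species
validation. The pipeline's own defaults are the larger study-scale settings.
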