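# rmtot

Random-matrix-theory denoising and optimal-transport population distances for
single-cell RNA-seq expression data.

## The problem

A droplet single-cell experiment yields a cells × genes count matrix that is
overwhelmingly noise: 95% or more of its spectral content is indistinguishable
from a random matrix, and the sparsity of the data (most entries are zero)
manufactures *fake* structure on top of that. Before asking biological
questions — how many cell populations are there, how similar are they, which
populations are conserved between mouse and human — the signal has to be
separated from both the noise and the sparsity artifacts.

`rmtot` implements that analysis chain for computational biologists:

1. **QC + normalization** — remove cells with fewer than 500 detected genes or
   more than 10% mitochondrial transcripts; normalize to log2(1+TPM)
   (counts-per-million for 3'-tag data).
2. **Spectral denoising** — for the gene-standardized matrix X (N cells × P
   genes), form the Wishart matrix W = (1/P)XXᵀ. If X were pure noise, the
   eigenvalue density of W would follow the Marchenko-Pastur (MP) law on
   [a₋, a₊], a± = σ²(1 ± √γ)², γ = N/P, and every eigenvector ψᵢ would be
   delocalized (components ≈ Normal(0, 1/N)). The package fits the MP bulk by
   iterative trimming, tests each eigenvector's delocalization (inverse
   participation ratio Σψ⁴ + a Kolmogorov-Smirnov test), flags localized
   eigenvectors attributable to sparsity against a column-permutation null,
   and classifies every eigenvector as noise / sparsity artifact / signal.
   Cells are projected onto the signal eigenvectors; a chi-squared variance
   test selects signal-carrying genes at a chosen FDR.
3. **Clustering** — Leiden community detection on a k-NN graph of the latent
   space, with the resolution parameter chosen to maximize the mean
   silhouette s = (b−a)/max(a,b); optional sub-clustering of any cluster.
4. **Population distances** — each population is a uniform distribution over
   its cells in latent space; phenotypic distance is the Wasserstein-1 (earth
   mover's) distance under the Euclidean ground metric, solved exactly as a
   transport LP for all practical sizes (an annealed Sinkhorn solver covers
   larger instances and is validated against the LP). The distance matrix is
   rendered as an average-linkage ordering for heatmaps and a neighbor-joining
   tree with branch lengths in Wasserstein units.
5. **Cross-species matching** — two species' matrices are restricted to
   one-to-one orthologs, normalized, filtered on mean expression, merged and
   denoised together; each population's best cross-species match is the
   argmin of its row of the cross-species Wasserstein matrix, and declared
   conserved pairs are validated against that argmin.
6. **Differential expression** — one-vs-rest t-tests on the denoised matrix
   with deliberately overestimated variance (both variance terms divided by
   the focal group's size), Benjamini-Hochberg adjustment, selection at
   corrected p < 0.001, with Wilcoxon rank-sum p-values as a consistency
   check.

A synthetic-data generator with full ground truth (planted populations on an
explicit tree, marker blocks, negative-binomial counts, dropout, library-size
variation, mitochondrial genes, paired pseudo-species with conserved
populations) makes the entire chain testable without any external download.

## Worked example

```bash
python examples/01_denoise_and_cluster.py
```

prints (exact numbers, fixed seed):

```
cells passing QC:        1195 / 1200
noise fraction:          0.992
signal eigenvectors:     6
selected resolution:     0.050
clusters found:          6 (planted: 6)
mean silhouette:         0.616
ARI vs planted labels:   1.000
```

99.2% of the spectrum sits inside the fitted MP support — compatible with a
random matrix — and the six eigenvectors above the bulk edge carry the six
planted populations, which silhouette-selected Leiden clustering recovers
perfectly (adjusted Rand index 1.0). The other examples cover population
distance matrices and NJ trees (`02`), cross-species matching (`03`, all
three conserved populations attain their row minimum) and marker discovery
(`04`, the top statistics land on the planted marker blocks).

There is also a thin CLI over the same library for batch runs:

```bash
rmtot run simulate --outdir out --seed 1
rmtot run all --outdir out --seed 1   # qc -> normalize -> denoise -> cluster -> distances -> tree -> de
```

Every stage writes TSV/Matrix Market/newick artifacts plus a manifest with
input hashes and parameters, and reruns are byte-identical at a fixed seed.

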