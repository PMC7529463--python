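"""Denoise a droplet-like count matrix and cluster the signal latent space.

Generates a synthetic dataset with six planted populations, applies QC and
log2(1+TPM) normalization, separates signal from noise with the
Marchenko-Pastur fit, and selects the Leiden resolution that maximizes the
mean silhouette. The adjusted Rand index against the planted labels shows how
well the pipeline recovers the ground truth.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from rmtot import SimulationParams, generate_counts, normalize_log_tpm, qc_filter, rmt_pipeline
from rmtot.cluster import cluster_latent

params = SimulationParams(n_cells=1200, n_genes=4000, n_populations=6, seed=5)
counts, truth = generate_counts(params)
filtered, records = qc_filter(counts)
kept = np.isin(counts.cell_ids, filtered.cell_ids)
norm = normalize_log_tpm(filtered)

spec, latent = rmt_pipeline(norm, seed=5)
assignment, sweep = cluster_latent(latent, seed=5)
ari = adjusted_rand_score(truth.labels[kept], assignment.labels)

print(f"cells passing QC:        {filtered.n_cells} / {counts.n_cells}")
print(f"noise fraction:          {spec.noise_fraction:.3f}")
print(f"signal eigenvectors:     {latent.k}")
print(f"selected resolution:     {assignment.resolution:.3f}")
print(f"clusters found:          {assignment.n_clusters} (planted: 6)")
print(f"mean silhouette:         {assignment.mean_silhouette:.3f}")
print(f"ARI vs planted labels:   {ari:.3f}")
print()
print("The noise fraction is the share of Wishart eigenvalues inside the")
print("Marchenko-Pastur support: everything there is indistinguishable from a")
print("random matrix, and only the few signal eigenvectors above the bulk edge")
print("carry the population structure the clustering then recovers.")
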