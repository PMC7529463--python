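"""Leiden clustering on a k-NN graph with silhouette-driven model selection.

The number of clusters is not fixed a priori: Leiden runs across a grid of
resolution parameters, the mean silhouette coefficient s = (b - a)/max(a, b)
is computed in the latent space for each partition, and the resolution that
maximizes it wins. Sub-clustering repeats the same strategy on one cluster's
cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from ._util import split_rng
from .rmt import LatentSpace

__all__ = [
    "ClusterAssignment",
    "knn_graph",
    "silhouette_mean",
    "leiden_sweep",
    "select_partition",
    "cluster_latent",
    "subcluster",
    "default_resolution_grid",
]


def default_resolution_grid(n: int = 20, lo: float = 0.05, hi: float = 2.0) -> np.ndarray:
    return np.geomspace(lo, hi, n)


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # one string label per cell
    resolution: float
    n_clusters: int
    mean_silhouette: float
    per_cell_silhouette: np.ndarray
    seed: int = 0

    def counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()


def _coords(latent: LatentSpace | np.ndarray) -> np.ndarray:
    return latent.coordinates if isinstance(latent, LatentSpace) else np.asarray(latent, float)


def knn_graph(latent: LatentSpace | np.ndarray, k: int = 15) -> ig.Graph:
    """Union-symmetrized k-nearest-neighbor graph under Euclidean distance."""
    X = _coords(latent)
    n = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = set()
    for i in range(n):
        for j in idx[i]:
            if j != i:
                edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def silhouette_mean(
    latent: LatentSpace | np.ndarray,
    labels: np.ndarray,
    subsample_threshold: int = 20000,
    subsample_n: int = 10000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Mean and per-cell silhouette in the latent space.

    Conventions: cells in singleton clusters score 0, and the degenerate
    a = b = 0 case scores 0, so resolution sweeps never crash. Above
    ``subsample_threshold`` cells, a stratified seeded subsample of
    ``subsample_n`` is scored instead (per-cell values are NaN off-sample and
    the mean is taken over the sample) — a documented approximation.
    """
    X = _coords(latent)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = X.shape[0]
    if n <= subsample_threshold:
        s = np.nan_to_num(silhouette_samples(X, labels))
        return float(np.mean(s)), s
    rng = split_rng(seed, "silhouette-subsample")
    take: list[np.ndarray] = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        quota = max(2, int(round(subsample_n * len(members) / n)))
        take.append(rng.permutation(members)[:quota])
    sel = np.sort(np.concatenate(take))
    if len(np.unique(labels[sel])) < 2:
        raise ValueError("subsample collapsed to a single cluster")
    s_sel = np.nan_to_num(silhouette_samples(X[sel], labels[sel]))
    s = np.full(n, np.nan)
    s[sel] = s_sel
    return float(np.mean(s_sel)), s


@dataclass
class SweepEntry:
    resolution: float
    labels: np.ndarray
    n_clusters: int
    mean_silhouette: float | None  # None when the partition has one cluster
    per_cell_silhouette: np.ndarray | None


def leiden_sweep(
    graph: ig.Graph,
    latent: LatentSpace | np.ndarray,
    resolutions: np.ndarray | None = None,
    seed: int = 0,
    subsample_threshold: int = 20000,
) -> list[SweepEntry]:
    """One Leiden run per resolution at a fixed seed; the silhouette is
    computed in the latent space, not on the graph."""
    if resolutions is None:
        resolutions = default_resolution_grid()
    resolutions = np.asarray(resolutions, dtype=float)
    if resolutions.size == 0:
        raise ValueError("resolution grid is empty")
    out = []
    for r in resolutions:
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(r),
            seed=int(seed),
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
        ncl = len(np.unique(labels))
        if ncl < 2:
            out.append(SweepEntry(float(r), labels, ncl, None, None))
            continue
        mean_s, per_cell = silhouette_mean(
            latent, labels, subsample_threshold=subsample_threshold, seed=seed
        )
        out.append(SweepEntry(float(r), labels, ncl, mean_s, per_cell))
    return out


def sweep_report(sweep: list[SweepEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "resolution": [e.resolution for e in sweep],
            "n_clusters": [e.n_clusters for e in sweep],
            "mean_silhouette": [e.mean_silhouette for e in sweep],
        }
    )


def select_partition(sweep: list[SweepEntry], seed: int = 0) -> ClusterAssignment:
    """Argmax of mean silhouette; ties go to fewer clusters, then smaller
    resolution. Entries with an undefined silhouette are excluded."""
    defined = [e for e in sweep if e.mean_silhouette is not None]
    if not defined:
        raise ValueError("no resolution produced a partition with a defined silhouette")
    best = min(defined, key=lambda e: (-e.mean_silhouette, e.n_clusters, e.resolution))
    return ClusterAssignment(
        labels=np.asarray([str(c) for c in best.labels], dtype=object),
        resolution=best.resolution,
        n_clusters=best.n_clusters,
        mean_silhouette=best.mean_silhouette,
        per_cell_silhouette=best.per_cell_silhouette,
        seed=seed,
    )


def cluster_latent(
    latent: LatentSpace | np.ndarray,
    k: int = 15,
    resolutions: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[ClusterAssignment, list[SweepEntry]]:
    """k-NN graph + resolution sweep + silhouette-maximizing selection."""
    g = knn_graph(latent, k=k)
    sweep = leiden_sweep(g, latent, resolutions, seed=seed)
    return select_partition(sweep, seed=seed), sweep


def subcluster(
    latent: LatentSpace | np.ndarray,
    assignment: ClusterAssignment,
    target_label: str,
    k: int = 15,
    resolutions: np.ndarray | None = None,
    seed: int = 0,
    min_cells: int = 20,
) -> tuple[ClusterAssignment, np.ndarray]:
    """Repeat the sweep-and-select strategy on the cells of one cluster.

    Returns the sub-assignment (labels namespaced ``parent.child``) and the
    indices of the subset cells in the parent ordering. The latent space is
    reused restricted to the subset (re-denoising the subset is a caller
    choice).
    """
    X = _coords(latent)
    idx = np.flatnonzero(assignment.labels == target_label)
    if len(idx) < min_cells:
        raise ValueError(
            f"cluster {target_label!r} has {len(idx)} cells; need at least {min_cells}"
        )
    sub = X[idx]
    kk = min(k, len(idx) - 1)
    g = knn_graph(sub, k=kk)
    sweep = leiden_sweep(g, sub, resolutions, seed=seed)
    try:
        chosen = select_partition(sweep, seed=seed)
    except ValueError as e:
        raise ValueError(f"no substructure in cluster {target_label!r}") from e
    chosen.labels = np.asarray(
        [f"{target_label}.{c}" for c in chosen.labels], dtype=object
    )
    return chosen, idx
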