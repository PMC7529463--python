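"""Synthetic droplet-style count data with planted ground truth.

The generator emulates the statistical structure the denoising/clustering/
optimal-transport pipeline assumes: negative-binomial counts with lognormal
library sizes, logistic dropout concentrated at low expression, a small block
of mitochondrial genes with per-cell variability, and cell populations whose
mean expression vectors sit on an explicit binary tree (so that phenotypic
distances between populations are hierarchically structured and tree-recovery
has a ground truth). Paired pseudo-species datasets share conserved
populations over an ortholog gene map, providing ground truth for
cross-species population matching.

All draws descend from one integer seed through named sub-streams, so the same
seed reproduces the same dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._util import split_rng
from .io_preprocess import ExpressionMatrix

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "generate_counts",
    "generate_species_pair",
    "planted_spike_matrix",
]


@dataclass
class SimulationParams:
    """Knobs of the count generator; defaults emulate a 10x-like regime
    (median 2-5k UMIs per cell, ~90% zeros).

    ``marker_shift`` is in log2 units per unit branch length; ``dispersion``
    is the negative-binomial size parameter theta (variance = m + m^2/theta;
    ``inf`` gives the Poisson limit). ``dropout`` is ``(midpoint, slope)`` of
    a logistic in log2 mean counts; a non-positive slope disables dropout.
    """

    n_cells: int = 2000
    n_genes: int = 10000
    n_populations: int = 8
    population_proportions: np.ndarray | None = None
    marker_fraction: float = 0.02
    marker_shift: float = 2.0
    dispersion: float = 2.0
    library_size_lognormal: tuple[float, float] = (8.6, 0.35)
    dropout: tuple[float, float] = (0.0, 1.0)
    n_mito: int = 13
    mito_fraction_mean: float = 0.02
    mito_cell_sd: float = 0.5
    base_log2_sd: float = 1.5
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.population_proportions is None:
            return np.full(self.n_populations, 1.0 / self.n_populations)
        p = np.asarray(self.population_proportions, dtype=float)
        if len(p) != self.n_populations or not np.isclose(p.sum(), 1.0):
            raise ValueError("population_proportions must be a simplex of length n_populations")
        return p


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated dataset."""

    labels: Any  # per-cell population labels (array), or dict of arrays for pairs
    marker_sets: dict  # population -> (gene indices, log2 shifts)
    population_tree: str  # newick over population labels, branch lengths in log2-shift units
    species_map: list | None
    seed: int
    population_log2_means: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# planted population tree
# ---------------------------------------------------------------------------


def _build_tree(pops: list[int], rng: np.random.Generator) -> Any:
    """Random binary hierarchy over population indices: nested tuples
    ``(left, right, length_left, length_right)``; a leaf is the index itself."""
    if len(pops) == 1:
        return pops[0]
    cut = int(rng.integers(1, len(pops)))
    left = _build_tree(pops[:cut], rng)
    right = _build_tree(pops[cut:], rng)
    ll = float(rng.uniform(0.75, 1.25))
    lr = float(rng.uniform(0.75, 1.25))
    return (left, right, ll, lr)


def _tree_newick(node: Any) -> str:
    def rec(n: Any) -> str:
        if isinstance(n, int):
            return f"pop{n}"
        left, right, ll, lr = n
        return f"({rec(left)}:{ll:.6f},{rec(right)}:{lr:.6f})"

    return rec(node) + ";"


def _tree_edges(node: Any) -> list[tuple[list[int], float]]:
    """All edges as (leaf indices below the edge, branch length)."""
    edges: list[tuple[list[int], float]] = []

    def leaves(n: Any) -> list[int]:
        if isinstance(n, int):
            return [n]
        return leaves(n[0]) + leaves(n[1])

    def rec(n: Any) -> None:
        if isinstance(n, int):
            return
        left, right, ll, lr = n
        edges.append((leaves(left), ll))
        edges.append((leaves(right), lr))
        rec(left)
        rec(right)

    rec(node)
    return edges


def _population_log2_means(
    p: SimulationParams, rng: np.random.Generator, n_pops: int
) -> tuple[np.ndarray, dict, str, np.ndarray]:
    """Base gene abundances plus tree-structured marker shifts.

    Returns (pop x gene log2 relative means, marker_sets, newick, base means).
    Marker sets are disjoint across tree edges so squared centroid distances
    add along tree paths.
    """
    n_markers = int(round(p.marker_fraction * p.n_genes))
    if p.marker_shift != 0 and n_markers < 1:
        raise ValueError("infeasible marker design: marker_fraction * n_genes < 1")
    base = rng.normal(0.0, p.base_log2_sd, size=p.n_genes)
    tree = _build_tree(list(range(n_pops)), rng)
    edges = _tree_edges(tree) if n_pops > 1 else []
    pool = rng.permutation(p.n_genes - p.n_mito) + p.n_mito  # never mark mito genes
    if len(edges) * n_markers > len(pool):
        raise ValueError("infeasible marker design: not enough genes for disjoint edge markers")
    L = np.tile(base, (n_pops, 1))
    marker_sets: dict = {}
    cursor = 0
    for leaf_set, length in edges:
        genes = np.sort(pool[cursor : cursor + n_markers])
        cursor += n_markers
        shift = p.marker_shift * length
        L[np.asarray(leaf_set)[:, None], genes[None, :]] += shift
        if len(leaf_set) == 1:
            marker_sets[f"pop{leaf_set[0]}"] = (genes, np.full(len(genes), shift))
    for k in range(n_pops):  # populations from single-leaf trees
        marker_sets.setdefault(f"pop{k}", (np.asarray([], dtype=int), np.asarray([])))
    return L, marker_sets, _tree_newick(tree), base


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _weights_from_log2_means(p: SimulationParams, L: np.ndarray) -> np.ndarray:
    """Relative expression weights per population; mitochondrial genes get a
    fixed expected share ``mito_fraction_mean`` of each cell's transcripts."""
    w = np.exp2(L)
    w[:, : p.n_mito] = 0.0
    w /= w.sum(axis=1, keepdims=True)
    if p.n_mito > 0:
        f = p.mito_fraction_mean
        w *= 1.0 - f
        w[:, : p.n_mito] = f / p.n_mito
    return w


def _sample_counts(
    p: SimulationParams,
    weights: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    sampling: str = "nb",
) -> sp.csr_matrix:
    mu_lib, sd_lib = p.library_size_lognormal
    lib = rng.lognormal(mu_lib, sd_lib, size=len(labels))
    mid, slope = p.dropout
    # dropout probability is a logistic in the gene's mean expression at a
    # reference depth (as in experiment-level dropout of standard simulators);
    # keying it to each cell's own depth would induce a per-cell variance
    # profile that has no counterpart in the exchangeable-noise model the
    # downstream spectral analysis assumes.
    lib_ref = float(np.exp(mu_lib))
    blocks = []
    chunk = 512
    for start in range(0, len(labels), chunk):
        idx = slice(start, min(start + chunk, len(labels)))
        mu = lib[idx, None] * weights[labels[idx]]
        if p.n_mito > 0 and p.mito_cell_sd > 0:
            mito_mult = rng.lognormal(0.0, p.mito_cell_sd, size=mu.shape[0])
            mu[:, : p.n_mito] *= mito_mult[:, None]
        if sampling == "expected":
            counts = mu
        elif np.isinf(p.dispersion):
            counts = rng.poisson(mu).astype(np.float64)
        else:
            lam = rng.gamma(shape=p.dispersion, scale=mu / p.dispersion)
            counts = rng.poisson(lam).astype(np.float64)
        if slope > 0 and sampling != "expected":
            mu_ref = lib_ref * weights[labels[idx]]
            with np.errstate(divide="ignore"):
                logmu = np.log2(np.maximum(mu_ref, 1e-12))
            p_drop = 1.0 / (1.0 + np.exp(slope * (logmu - mid)))
            counts *= rng.random(size=counts.shape) >= p_drop
        blocks.append(sp.csr_matrix(counts))
    return sp.vstack(blocks, format="csr")


def _gene_ids(p: SimulationParams, prefix: str = "gene") -> np.ndarray:
    width = len(str(p.n_genes))
    ids = [f"mt-{i + 1}" for i in range(p.n_mito)]
    ids += [f"{prefix}{i:0{width}d}" for i in range(p.n_mito, p.n_genes)]
    return np.asarray(ids, dtype=object)


def generate_counts(
    p: SimulationParams, sampling: str = "nb"
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate one raw-counts dataset with planted populations.

    ``sampling="expected"`` emits the (deterministic) expected counts instead
    of negative-binomial draws — useful for closed-form checks.
    """
    if p.n_populations < 1 or p.n_cells < 1 or p.n_genes < 2:
        raise ValueError("invalid simulation sizes")
    rng_struct = split_rng(p.seed, "structure")
    rng_cells = split_rng(p.seed, "cells")
    L, marker_sets, newick, _ = _population_log2_means(p, rng_struct, p.n_populations)
    weights = _weights_from_log2_means(p, L)
    labels = rng_cells.choice(p.n_populations, size=p.n_cells, p=p.proportions())
    counts = _sample_counts(p, weights, labels, split_rng(p.seed, "counts"), sampling)
    width = len(str(p.n_cells))
    m = ExpressionMatrix(
        values=counts,
        cell_ids=np.asarray([f"cell{i:0{width}d}" for i in range(p.n_cells)], dtype=object),
        gene_ids=_gene_ids(p),
        species="synthetic",
        stage="raw_counts",
    )
    truth = SyntheticTruth(
        labels=np.asarray([f"pop{k}" for k in labels], dtype=object),
        marker_sets=marker_sets,
        population_tree=newick,
        species_map=None,
        seed=p.seed,
        population_log2_means=L,
    )
    return m, truth


# ---------------------------------------------------------------------------
# paired pseudo-species
# ---------------------------------------------------------------------------


def generate_species_pair(
    p: SimulationParams,
    n_conserved: int = 3,
    n_private_each: int = 2,
    ortholog_fraction: float = 0.9,
    species_noise: float = 0.25,
    sampling: str = "nb",
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Two datasets over distinct gene namespaces sharing conserved populations.

    Conserved populations have identical log2 mean vectors on ortholog genes up
    to ``species_noise`` (log2 sd); private populations exist in one species
    only and carry their own marker blocks. The returned two-column ortholog
    table covers ``ortholog_fraction`` of genes, one-to-one.
    """
    if n_conserved < 1:
        raise ValueError("n_conserved must be >= 1")
    if ortholog_fraction <= 0:
        raise ValueError("ortholog_fraction = 0 leaves the cross-species analysis undefined")
    rng = split_rng(p.seed, "pair-structure")
    n_pops = n_conserved + n_private_each
    # shared (ancestral) structure over conserved + a pool of private archetypes
    L_cons, marker_sets, newick, base = _population_log2_means(p, rng, n_conserved)
    n_markers = max(1, int(round(p.marker_fraction * p.n_genes)))

    used = set()
    for g, _ in marker_sets.values():
        used.update(int(x) for x in g)

    def private_means(rng_s: np.random.Generator, count: int) -> tuple[np.ndarray, list]:
        rows, sets = [], []
        free = np.asarray(
            [g for g in range(p.n_mito, p.n_genes) if g not in used], dtype=int
        )
        pick = rng_s.permutation(free)
        for j in range(count):
            genes = np.sort(pick[j * n_markers : (j + 1) * n_markers])
            used.update(int(x) for x in genes)
            row = base.copy()
            row[genes] += p.marker_shift * 1.5  # private pops sit far from everything
            rows.append(row)
            sets.append(genes)
        return (np.vstack(rows) if rows else np.empty((0, p.n_genes))), sets

    priv_a, sets_a = private_means(split_rng(p.seed, "private-a"), n_private_each)
    priv_b, sets_b = private_means(split_rng(p.seed, "private-b"), n_private_each)

    def species_dataset(
        tag: str, L_priv: np.ndarray, rng_key: str
    ) -> tuple[ExpressionMatrix, np.ndarray]:
        rng_s = split_rng(p.seed, rng_key)
        L = np.vstack([L_cons, L_priv]) if len(L_priv) else L_cons.copy()
        if species_noise > 0:
            L = L + rng_s.normal(0.0, species_noise, size=L.shape)
        weights = _weights_from_log2_means(p, L)
        labels = rng_s.choice(n_pops, size=p.n_cells, p=np.full(n_pops, 1.0 / n_pops))
        counts = _sample_counts(p, weights, labels, split_rng(p.seed, rng_key + "-counts"), sampling)
        width = len(str(p.n_cells))
        gene_prefix = f"g{tag}_"
        gids = np.asarray(
            [f"mt-{tag}-{i + 1}" for i in range(p.n_mito)]
            + [f"{gene_prefix}{i:05d}" for i in range(p.n_mito, p.n_genes)],
            dtype=object,
        )
        m = ExpressionMatrix(
            values=counts,
            cell_ids=np.asarray(
                [f"{tag}cell{i:0{width}d}" for i in range(p.n_cells)], dtype=object
            ),
            gene_ids=gids,
            species="synthetic",
            sample_ids=np.asarray([f"species_{tag}"] * p.n_cells, dtype=object),
            stage="raw_counts",
        )
        names = [f"pop{k}" for k in range(n_conserved)] + [
            f"{tag}_priv{j}" for j in range(n_private_each)
        ]
        return m, np.asarray([names[k] for k in labels], dtype=object)

    mat_a, labels_a = species_dataset("A", priv_a, "species-a")
    mat_b, labels_b = species_dataset("B", priv_b, "species-b")

    n_orth = int(round(ortholog_fraction * p.n_genes))
    orth_idx = np.sort(split_rng(p.seed, "orthologs").permutation(p.n_genes)[:n_orth])
    table = pd.DataFrame(
        {
            "gene_a": mat_a.gene_ids[orth_idx],
            "gene_b": mat_b.gene_ids[orth_idx],
        }
    )
    table = table.iloc[split_rng(p.seed, "ortholog-order").permutation(len(table))].reset_index(
        drop=True
    )

    species_map = [
        {"species_a": f"pop{k}", "species_b": f"pop{k}", "conserved": True}
        for k in range(n_conserved)
    ]
    species_map += [
        {"species_a": f"A_priv{j}", "species_b": None, "conserved": False}
        for j in range(n_private_each)
    ]
    species_map += [
        {"species_a": None, "species_b": f"B_priv{j}", "conserved": False}
        for j in range(n_private_each)
    ]
    truth = SyntheticTruth(
        labels={"a": labels_a, "b": labels_b},
        marker_sets=marker_sets,
        population_tree=newick,
        species_map=species_map,
        seed=p.seed,
        extras={"private_marker_sets": {"a": sets_a, "b": sets_b}},
    )
    return mat_a, mat_b, table, truth


# ---------------------------------------------------------------------------
# spiked Wishart test harness
# ---------------------------------------------------------------------------


def planted_spike_matrix(
    n: int, p: int, k: int, strengths: list[float] | None = None, seed: int = 0
) -> tuple[np.ndarray, dict]:
    """An i.i.d. standard Gaussian n x p matrix plus ``k`` rank-one planted
    components; spike ``s`` contributes approximately ``s`` to the Wishart
    eigenvalue above the Marchenko-Pastur bulk when ``s`` is large.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    strengths = list(strengths) if strengths is not None else []
    if len(strengths) != k:
        raise ValueError("strengths must have length k")
    rng = split_rng(seed, "spikes")
    X = rng.standard_normal((n, p))
    if k == 0:
        return X, {"u": np.empty((n, 0)), "v": np.empty((p, 0)), "strengths": []}
    U, _ = np.linalg.qr(rng.standard_normal((n, k)))
    V, _ = np.linalg.qr(rng.standard_normal((p, k)))
    for i, s in enumerate(strengths):
        X += np.sqrt(max(s, 0.0) * p) * np.outer(U[:, i], V[:, i])
    return X, {"u": U, "v": V, "strengths": strengths}
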