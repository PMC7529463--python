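"""Cross-species population matching in a common ortholog latent space.

Two datasets (e.g. human and mouse prostate) are restricted to one-to-one
ortholog gene pairs, normalized per species, filtered on mean expression,
merged, and denoised together so both species' cells share one latent space.
Population similarity across species is then the Wasserstein-1 distance
between cross-species population pairs; a human population's best mouse match
is the column argmin of its row, and declared conserved pairs are validated
by checking they attain that row minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import split_rng
from .io_preprocess import ExpressionMatrix, aggregate_samples, normalize_log_tpm
from .ot import wasserstein1
from .rmt import LatentSpace, SpectralDecomposition, rmt_pipeline

__all__ = [
    "OrthologMap",
    "CrossSpeciesResult",
    "resolve_orthologs",
    "harmonize",
    "common_latent",
    "cross_distance",
    "validate_conserved",
]


@dataclass
class OrthologMap:
    pairs: pd.DataFrame  # columns gene_a, gene_b; strictly one-to-one
    n_dropped: int
    provenance: str = ""


def resolve_orthologs(raw: pd.DataFrame, provenance: str = "") -> OrthologMap:
    """Strict one-to-one resolution: duplicate rows are deduplicated, and any
    gene participating in more than one pair (on either side) is dropped."""
    if raw.shape[1] < 2:
        raise ValueError("ortholog table needs two columns")
    t = raw.iloc[:, :2].copy()
    t.columns = ["gene_a", "gene_b"]
    t = t.drop_duplicates()
    n0 = len(t)
    ok_a = t["gene_a"].map(t["gene_a"].value_counts()) == 1
    ok_b = t["gene_b"].map(t["gene_b"].value_counts()) == 1
    t = t[ok_a & ok_b].reset_index(drop=True)
    if len(t) == 0:
        raise ValueError("no one-to-one ortholog pairs remain after resolution")
    return OrthologMap(pairs=t, n_dropped=n0 - len(t), provenance=provenance)


def harmonize(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    orth: OrthologMap,
    min_mean: float = 0.1,
    min_genes: int = 50,
    filter_scale: str = "normalized",
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Merge two species' raw-count matrices over their ortholog pairs.

    Both matrices are restricted to resolved ortholog pairs, normalized per
    species to log2(1+TPM), and any pair whose mean expression is strictly
    below ``min_mean`` in EITHER species is dropped (``filter_scale`` chooses
    whether that mean is taken on the normalized values, the default, or on
    TPM). Returns the row-concatenated matrix on the species-A gene namespace
    plus a per-cell species tag array ("a"/"b").
    """
    if a.stage != "raw_counts" or b.stage != "raw_counts":
        raise ValueError("harmonize expects raw counts for both species")
    if filter_scale not in ("normalized", "tpm"):
        raise ValueError("filter_scale must be 'normalized' or 'tpm'")
    pos_a = {g: i for i, g in enumerate(a.gene_ids)}
    pos_b = {g: i for i, g in enumerate(b.gene_ids)}
    pairs = orth.pairs[
        orth.pairs["gene_a"].isin(pos_a) & orth.pairs["gene_b"].isin(pos_b)
    ]
    if len(pairs) < min_genes:
        raise ValueError(
            f"only {len(pairs)} ortholog pairs map into both matrices (need {min_genes})"
        )
    ia = np.asarray([pos_a[g] for g in pairs["gene_a"]])
    ib = np.asarray([pos_b[g] for g in pairs["gene_b"]])
    a_sub = a.subset_genes(ia)
    b_sub = b.subset_genes(ib)
    a_norm = normalize_log_tpm(a_sub)
    b_norm = normalize_log_tpm(b_sub)

    def gene_means(norm: ExpressionMatrix) -> np.ndarray:
        vals = norm.values
        if filter_scale == "tpm":
            vals = vals.copy()
            vals.data = np.exp2(vals.data) - 1.0
        return np.asarray(vals.mean(axis=0)).ravel()

    keep = (gene_means(a_norm) >= min_mean) & (gene_means(b_norm) >= min_mean)
    if keep.sum() < min_genes:
        raise ValueError(
            f"only {int(keep.sum())} ortholog pairs pass the mean >= {min_mean} filter "
            f"in both species (need {min_genes})"
        )
    a_norm = a_norm.subset_genes(np.flatnonzero(keep))
    b_norm = b_norm.subset_genes(np.flatnonzero(keep))
    # common namespace: species-A gene ids
    b_norm.gene_ids = a_norm.gene_ids.copy()
    merged = aggregate_samples([a_norm, b_norm])
    species = np.asarray(["a"] * a_norm.n_cells + ["b"] * b_norm.n_cells, dtype=object)
    return merged, species


def common_latent(
    merged: ExpressionMatrix,
    seed: int = 0,
    **rmt_kwargs,
) -> tuple[SpectralDecomposition, LatentSpace]:
    """Denoise the merged matrix so both species share one latent space."""
    return rmt_pipeline(merged, seed=seed, **rmt_kwargs)


@dataclass
class CrossSpeciesResult:
    matrix: pd.DataFrame  # rows: species-A populations, cols: species-B populations
    argmin: pd.Series  # per species-A population, the nearest species-B population

    def transpose(self) -> "CrossSpeciesResult":
        t = self.matrix.T
        return CrossSpeciesResult(matrix=t, argmin=t.idxmin(axis=1))


def cross_distance(
    latent: LatentSpace | np.ndarray,
    species: np.ndarray,
    labels: np.ndarray,
    epsilon: float | None = None,
    exact: bool | None = None,
    exact_threshold: int = 4 * 10**6,
    size_cap: int = 2000,
    seed: int = 0,
) -> CrossSpeciesResult:
    """Full species-A x species-B Wasserstein matrix with per-row argmin."""
    X = latent.coordinates if isinstance(latent, LatentSpace) else np.asarray(latent, float)
    species = np.asarray(species).astype(str)
    labels = np.asarray(labels).astype(str)
    tags = sorted(set(species))
    if len(tags) != 2:
        raise ValueError(f"expected exactly 2 species tags, got {tags}")
    ta, tb = tags

    def pops(tag: str) -> dict[str, np.ndarray]:
        out = {}
        for name in sorted(set(labels[species == tag])):
            idx = np.flatnonzero((species == tag) & (labels == name))
            if len(idx) > size_cap:
                rng = split_rng(seed, "cross-subsample", tag, name)
                idx = np.sort(rng.permutation(idx)[:size_cap])
            out[name] = X[idx]
        if not out:
            raise ValueError(f"no populations for species {tag!r}")
        return out

    pa, pb = pops(ta), pops(tb)
    D = pd.DataFrame(index=list(pa), columns=list(pb), dtype=float)
    for na_, A in pa.items():
        for nb_, B in pb.items():
            D.loc[na_, nb_] = wasserstein1(
                A, B, epsilon=epsilon, exact=exact, exact_threshold=exact_threshold
            ).value
    return CrossSpeciesResult(matrix=D, argmin=D.idxmin(axis=1))


def validate_conserved(
    result: CrossSpeciesResult,
    declared_pairs: list[tuple[str, str]],
) -> dict:
    """Check each declared conserved (species-A, species-B) pair attains the
    row minimum of the cross-species distance matrix."""
    report: dict = {"pairs": {}, "n_pass": 0, "n_total": len(declared_pairs)}
    for pa, pb in declared_pairs:
        if pa not in result.matrix.index:
            raise ValueError(f"unknown species-A population {pa!r}")
        if pb not in result.matrix.columns:
            raise ValueError(f"unknown species-B population {pb!r}")
        ok = result.argmin[pa] == pb
        report["pairs"][f"{pa}|{pb}"] = bool(ok)
        report["n_pass"] += int(ok)
    report["pass_fraction"] = (
        report["n_pass"] / report["n_total"] if report["n_total"] else 1.0
    )
    return report
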