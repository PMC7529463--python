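"""Expression-matrix container, 10x-style I/O, cell QC and log2(1+TPM) normalization.

Cells are rows in memory; on disk the Matrix Market triplet follows the 10x
convention of genes as rows and cells as columns (the reader transposes).
TPM here is counts-per-million: 3'-tag droplet protocols sample transcript
ends, so no gene-length correction applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "CellQCRecord",
    "read_matrix",
    "write_matrix",
    "qc_filter",
    "normalize_log_tpm",
    "aggregate_samples",
    "mito_gene_mask",
    "write_qc_report",
]

#: Upper bound for any log2(1+TPM) value (a cell expressing a single gene).
LOG_TPM_MAX = float(np.log2(1 + 1e6))


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers and provenance tags.

    ``values`` is a CSR sparse matrix (raw counts or log2(1+TPM) values).
    ``stage`` records whether normalization has been applied; operations that
    require one stage or the other check it and refuse to proceed otherwise.
    """

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    species: str = "synthetic"
    sample_ids: np.ndarray | None = None
    stage: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.sample_ids is None:
            self.sample_ids = np.asarray(["sample0"] * self.n_cells, dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.validate()

    # -- basic properties -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cell ids / {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(self.sample_ids) != self.n_cells:
            raise ValueError("sample_ids length mismatch")
        data = self.values.data
        if data.size:
            if not np.all(np.isfinite(data)):
                raise ValueError("values contain non-finite entries")
            # batch-corrected normalized matrices may carry small negatives;
            # counts never may
            if self.stage == "raw_counts" and data.min() < 0:
                raise ValueError("values contain negative entries")
        if self.stage not in ("raw_counts", "normalized"):
            raise ValueError(f"unknown stage {self.stage!r}")

    def toarray(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values[index],
            cell_ids=self.cell_ids[index],
            sample_ids=self.sample_ids[index],
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        return replace(
            self,
            values=sp.csr_matrix(self.values[:, index]),
            gene_ids=self.gene_ids[index],
        )

    def to_anndata(self):
        """Convenience export for interoperability with the scanpy ecosystem."""
        import anndata

        return anndata.AnnData(
            X=self.values.copy(),
            obs=pd.DataFrame(
                {"sample_id": self.sample_ids, "species": self.species},
                index=list(self.cell_ids),
            ),
            var=pd.DataFrame(index=list(self.gene_ids)),
        )


@dataclass(frozen=True)
class CellQCRecord:
    cell_id: str
    genes_detected: int
    mito_fraction: float
    passed: bool


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def _dedupe(ids: Sequence[str]) -> np.ndarray:
    """Disambiguate duplicate IDs by appending an occurrence index (pandas style)."""
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        k = seen.get(g, 0)
        out.append(g if k == 0 else f"{g}.{k}")
        seen[g] = k + 1
    return np.asarray(out, dtype=object)


def read_matrix(
    path: str | Path,
    format: str = "mtx_triplet",
    species: str = "synthetic",
    sample_id: str | None = None,
) -> ExpressionMatrix:
    """Read a raw-counts matrix from disk.

    ``mtx_triplet`` expects a directory with ``matrix.mtx``, ``barcodes.tsv``
    and ``features.tsv`` (genes as triplet rows, 10x convention; transposed to
    cells x genes in memory). ``delimited`` expects a TSV with a header row of
    gene IDs and the first column holding cell IDs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "mtx_triplet":
        mtx = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
        for f in (mtx, barcodes, features):
            if not f.exists():
                raise FileNotFoundError(f"missing companion file: {f}")
        try:
            m = scipy.io.mmread(str(mtx))
        except Exception as e:  # malformed header or truncated entries
            raise ValueError(f"malformed Matrix Market file {mtx}: {e}") from e
        m = sp.csr_matrix(m).T  # genes x cells on disk -> cells x genes
        cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).to_numpy()
        feats = pd.read_csv(features, sep="\t", header=None)
        gene_ids = feats[0].astype(str).to_numpy()
        if m.shape[0] != len(cell_ids) or m.shape[1] != len(gene_ids):
            raise ValueError(
                f"triplet dimensions {m.T.shape} (genes x cells) do not match "
                f"{len(gene_ids)} features / {len(cell_ids)} barcodes"
            )
    elif format == "delimited":
        df = pd.read_csv(path, sep="\t", index_col=0)
        m = sp.csr_matrix(df.to_numpy())
        cell_ids = df.index.astype(str).to_numpy()
        gene_ids = df.columns.astype(str).to_numpy()
    else:
        raise ValueError(f"unknown format {format!r}")
    if m.nnz and m.data.min() < 0:
        raise ValueError("negative entries in count matrix")
    return ExpressionMatrix(
        values=m,
        cell_ids=_dedupe(cell_ids),
        gene_ids=_dedupe(gene_ids),
        species=species,
        sample_ids=None if sample_id is None else np.asarray([sample_id] * m.shape[0], dtype=object),
        stage="raw_counts",
    )


def write_matrix(m: ExpressionMatrix, path: str | Path, format: str = "mtx_triplet") -> None:
    """Write a matrix in the same dialect :func:`read_matrix` consumes."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        # genes x cells on disk, entries in canonical row-major order so
        # writes are byte-reproducible regardless of in-memory layout
        vals = m.values.T.tocsr().tocoo()
        if m.stage == "raw_counts":
            vals = vals.astype(np.int64)
        scipy.io.mmwrite(str(path / "matrix.mtx"), vals)
        pd.Series(list(m.cell_ids)).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
        pd.DataFrame({"id": list(m.gene_ids), "symbol": list(m.gene_ids)}).to_csv(
            path / "features.tsv", sep="\t", header=False, index=False
        )
    elif format == "delimited":
        df = pd.DataFrame(m.toarray(), index=list(m.cell_ids), columns=list(m.gene_ids))
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def mito_gene_mask(
    gene_ids: Iterable[str],
    mito_gene_ids: set[str] | None = None,
    prefix: str = "mt-",
) -> np.ndarray:
    """Boolean mask of mitochondrial genes: explicit list wins over the prefix rule."""
    gene_ids = np.asarray(list(gene_ids), dtype=object)
    if mito_gene_ids is not None:
        return np.asarray([g in mito_gene_ids for g in gene_ids])
    p = prefix.lower()
    return np.asarray([str(g).lower().startswith(p) for g in gene_ids])


def qc_filter(
    m: ExpressionMatrix,
    mito_gene_ids: set[str] | None = None,
    min_genes: int = 500,
    max_mito: float = 0.10,
    mito_prefix: str = "mt-",
) -> tuple[ExpressionMatrix, list[CellQCRecord]]:
    """Remove cells with fewer than ``min_genes`` genes detected or a
    mitochondrial transcript fraction strictly greater than ``max_mito``.

    Both boundaries follow the strict reading of the filtering rule: a cell
    with exactly ``min_genes`` genes or exactly ``max_mito`` mito fraction is
    kept. Records are returned for every input cell.
    """
    if m.stage != "raw_counts":
        raise ValueError("qc_filter expects raw counts")
    mask = mito_gene_mask(m.gene_ids, mito_gene_ids, mito_prefix)
    if mito_gene_ids is not None and len(mito_gene_ids) > 0 and not mask.any():
        warnings.warn("supplied mito_gene_ids are disjoint from gene_ids; mito fraction is 0")
    genes_detected = np.asarray((m.values > 0).sum(axis=1)).ravel()
    totals = np.asarray(m.values.sum(axis=1)).ravel()
    mito_counts = (
        np.asarray(m.values[:, mask].sum(axis=1)).ravel() if mask.any() else np.zeros(m.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)
    passed = (genes_detected >= min_genes) & (mito_frac <= max_mito)
    records = [
        CellQCRecord(str(c), int(g), float(f), bool(p))
        for c, g, f, p in zip(m.cell_ids, genes_detected, mito_frac, passed)
    ]
    return m.subset_cells(np.flatnonzero(passed)), records


def write_qc_report(records: list[CellQCRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "genes_detected": [r.genes_detected for r in records],
            "mito_fraction": [r.mito_fraction for r in records],
            "passed": [r.passed for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def normalize_log_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize each cell to log2(1 + TPM).

    TPM_g = counts_g / total_counts * 1e6 (counts-per-million; no gene-length
    term for 3'-tag data). Zero entries map to zero, so sparsity is preserved.
    """
    if m.stage != "raw_counts":
        raise ValueError("normalize_log_tpm expects raw counts")
    totals = np.asarray(m.values.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ValueError(
            "cells with zero total counts present; run qc_filter before normalizing"
        )
    scaled = sp.diags(1e6 / totals) @ m.values.astype(np.float64)
    scaled = sp.csr_matrix(scaled)
    scaled.data = np.log2(1.0 + scaled.data)
    return replace(m, values=scaled, stage="normalized")


def aggregate_samples(
    ms: Sequence[ExpressionMatrix],
    batch_correct: str = "none",
) -> ExpressionMatrix:
    """Row-concatenate samples sharing a gene set; optionally equalize per-sample
    gene means to the global gene mean (``center_per_sample``), a deliberately
    simple fallback for externally produced batch-corrected input.
    """
    if not ms:
        raise ValueError("no matrices to aggregate")
    if batch_correct not in ("none", "center_per_sample"):
        raise ValueError(f"unknown batch_correct {batch_correct!r}")
    ref = ms[0]
    for other in ms[1:]:
        if set(other.gene_ids) != set(ref.gene_ids):
            diff = sorted(set(other.gene_ids) ^ set(ref.gene_ids))
            raise ValueError(f"gene sets differ; symmetric difference: {diff}")
        if other.stage != ref.stage:
            raise ValueError("cannot aggregate matrices at different stages")
    # align column order to the first matrix
    aligned = [ref]
    order = {g: i for i, g in enumerate(ref.gene_ids)}
    for other in ms[1:]:
        if not np.array_equal(other.gene_ids, ref.gene_ids):
            idx = np.asarray([order[g] for g in other.gene_ids])
            inv = np.empty_like(idx)
            inv[idx] = np.arange(len(idx))
            other = other.subset_genes(inv)
        aligned.append(other)

    cell_ids = np.concatenate([a.cell_ids for a in aligned])
    sample_ids = np.concatenate([a.sample_ids for a in aligned])
    if len(set(cell_ids)) != len(cell_ids):  # disambiguate collisions across samples
        cell_ids = np.asarray(
            [f"{s}:{c}" for s, c in zip(sample_ids, cell_ids)], dtype=object
        )
        cell_ids = _dedupe(cell_ids)
    values = sp.vstack([a.values for a in aligned], format="csr")
    species = ref.species if len({a.species for a in aligned}) == 1 else "synthetic"

    if batch_correct == "center_per_sample" and len(set(sample_ids)) > 1:
        dense = np.asarray(values.todense(), dtype=np.float64)
        global_mean = dense.mean(axis=0)
        for s in np.unique(sample_ids):
            rows = sample_ids == s
            dense[rows] += global_mean - dense[rows].mean(axis=0)
        values = sp.csr_matrix(dense)

    return ExpressionMatrix(
        values=values,
        cell_ids=cell_ids,
        gene_ids=ref.gene_ids.copy(),
        species=species,
        sample_ids=sample_ids,
        stage=ref.stage,
    )
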