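"""Differential expression between populations on the denoised matrix.

One-vs-rest t-tests per population per gene with a deliberately overestimated
variance: both group variance terms are divided by the focal group's size
n_g rather than each group's own size, inflating the standard error (and so
making the test conservative for the usual case of a small focal population
against a large rest). P-values are Benjamini-Hochberg adjusted within each
comparison and genes pass at adjusted p below the threshold (default 0.001).
A Wilcoxon rank-sum p-value is reported alongside as a consistency check; the
t-test decides selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_preprocess import ExpressionMatrix

__all__ = ["DEResult", "de_test", "bh_adjust", "dotplot_summary"]


@dataclass
class DEResult:
    table: pd.DataFrame  # population, gene, mean_diff, t, p, p_adj, p_wilcoxon, selected
    threshold: float

    def selected(self, population: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["selected"]]
        return t if population is None else t[t["population"] == population]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN inputs propagate as NaN and
    do not count toward the number of tests."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        _, adj, _, _ = multipletests(p[ok], method="fdr_bh")
        out[ok] = adj
    return out


def _overestim_t(
    x1: np.ndarray, x2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene t statistic with both variance terms divided by the focal
    group's n; Welch-Satterthwaite df on the same inflated terms."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    t1 = v1 / n1
    t2 = v2 / n1  # overestimation: focal n for the rest group too
    se = np.sqrt(t1 + t2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / np.where(se > 0, se, 1.0), 0.0)
        df = np.where(
            se > 0,
            (t1 + t2) ** 2 / (t1**2 / (n1 - 1) + t2**2 / (n2 - 1)),
            1.0,
        )
    p = np.where(se > 0, 2 * stats.t.sf(np.abs(t), df), 1.0)
    return t, p, m1 - m2


def de_test(
    denoised: ExpressionMatrix,
    labels: np.ndarray,
    threshold: float = 0.001,
    min_cells: int = 3,
    wilcoxon: bool = True,
) -> DEResult:
    """One-vs-rest differential expression over all populations.

    Populations with fewer than ``min_cells`` cells are skipped with a
    warning. BH adjustment is applied across genes within each one-vs-rest
    comparison.
    """
    labels = np.asarray(labels).astype(str)
    X = denoised.toarray().astype(np.float64)
    pops = sorted(set(labels))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    frames = []
    for pop in pops:
        mask = labels == pop
        n1, n2 = int(mask.sum()), int((~mask).sum())
        if n1 < min_cells or n2 < min_cells:
            warnings.warn(f"population {pop!r} has too few cells ({n1}); skipped")
            continue
        x1, x2 = X[mask], X[~mask]
        t, p, diff = _overestim_t(x1, x2)
        p_adj = bh_adjust(p)
        if wilcoxon:
            with np.errstate(invalid="ignore"):
                pw = stats.mannwhitneyu(
                    x1, x2, axis=0, alternative="two-sided", method="asymptotic"
                ).pvalue
            pw = np.where(np.isfinite(pw), pw, 1.0)
        else:
            pw = np.full(X.shape[1], np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "population": pop,
                    "gene": denoised.gene_ids,
                    "mean_diff": diff,
                    "t": t,
                    "p": p,
                    "p_adj": p_adj,
                    "p_wilcoxon": pw,
                    "selected": p_adj < threshold,
                }
            )
        )
    if not frames:
        raise ValueError("no population had enough cells to test")
    return DEResult(table=pd.concat(frames, ignore_index=True), threshold=threshold)


def dotplot_summary(
    m: ExpressionMatrix, labels: np.ndarray, genes: list[str] | None = None
) -> pd.DataFrame:
    """Mean expression and fraction of expressing cells per population per
    gene — the numbers behind a marker dot plot."""
    labels = np.asarray(labels).astype(str)
    gidx = (
        np.arange(m.n_genes)
        if genes is None
        else np.asarray([int(np.flatnonzero(m.gene_ids == g)[0]) for g in genes])
    )
    X = m.toarray()[:, gidx]
    rows = []
    for pop in sorted(set(labels)):
        sub = X[labels == pop]
        for j, g in enumerate(m.gene_ids[gidx]):
            rows.append(
                {
                    "population": pop,
                    "gene": g,
                    "mean_expression": float(sub[:, j].mean()),
                    "fraction_expressing": float((sub[:, j] > 0).mean()),
                }
            )
    return pd.DataFrame(rows)
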