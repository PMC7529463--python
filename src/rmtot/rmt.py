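"""Random-matrix-theory denoising of expression matrices.

The pipeline treats the cells-by-genes matrix X (gene-standardized) through
its Wishart matrix W = (1/P) X X^T. If X were pure noise, the eigenvalue
density of W would follow the Marchenko-Pastur (MP) law on [a-, a+] with
a± = sigma^2 (1 ± sqrt(gamma))^2, gamma = N/P, and every eigenvector would be
delocalized (components ~ Normal(0, 1/N)). Deviations carry signal, with one
important confounder: the zero pattern of droplet data creates localized
eigenvectors that look like signal but are artifacts of sparsity. The module
fits the MP bulk, tests eigenvector delocalization, flags sparsity artifacts
against a zero-pattern-preserving permutation null, classifies eigenvectors as
noise / sparsity_fake / signal, and projects cells onto the signal eigenvectors
to produce the latent space used by clustering and optimal transport.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import split_rng
from .io_preprocess import ExpressionMatrix

__all__ = [
    "MPModel",
    "SpectralDecomposition",
    "LatentSpace",
    "SignalGeneTable",
    "wishart_spectrum",
    "mp_bounds",
    "fit_mp",
    "eigenvector_delocalization_test",
    "flag_sparsity_artifacts",
    "classify_signal",
    "project_to_latent",
    "denoised_matrix",
    "signal_genes",
    "rmt_pipeline",
]


# ---------------------------------------------------------------------------
# Marchenko-Pastur model
# ---------------------------------------------------------------------------


def mp_bounds(sigma2: float, gamma: float) -> tuple[float, float]:
    """Support edges of the MP law: a± = sigma^2 (1 ± sqrt(gamma))^2."""
    if sigma2 <= 0 or gamma <= 0:
        raise ValueError("sigma2 and gamma must be positive")
    r = np.sqrt(gamma)
    return float(sigma2 * (1 - r) ** 2), float(sigma2 * (1 + r) ** 2)


@dataclass
class MPModel:
    """Fitted Marchenko-Pastur model.

    For gamma > 1 (more cells than genes) the spectrum carries an atom of mass
    1 - 1/gamma at zero; the continuous density integrates to min(1, 1/gamma).
    """

    sigma2: float
    gamma: float
    ks_distance: float | None = None

    def __post_init__(self) -> None:
        self.a_minus, self.a_plus = mp_bounds(self.sigma2, self.gamma)

    def density(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        out = np.zeros_like(lam)
        inside = (lam > self.a_minus) & (lam < self.a_plus)
        x = lam[inside]
        out[inside] = np.sqrt((self.a_plus - x) * (x - self.a_minus)) / (
            2 * np.pi * self.gamma * self.sigma2 * x
        )
        return out

    def _grid(self, n: int = 4000) -> tuple[np.ndarray, np.ndarray]:
        x = np.linspace(self.a_minus, self.a_plus, n)
        c = np.concatenate(
            [[0.0], np.cumsum((self.density(x[1:]) + self.density(x[:-1])) / 2 * np.diff(x))]
        )
        # rescale to the analytic mass of the continuous part (trapezoid
        # slightly undershoots at the square-root edges)
        c *= min(1.0, 1.0 / self.gamma) / c[-1]
        return x, c

    def cdf(self, lam: np.ndarray) -> np.ndarray:
        """CDF of the full eigenvalue law (atom at 0 included when gamma > 1)."""
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        x, c = self._grid()
        atom = max(0.0, 1.0 - 1.0 / self.gamma)
        out = atom + np.interp(lam, x, c, left=0.0, right=c[-1])
        out[lam < 0] = 0.0
        if self.gamma > 1:
            out[(lam >= 0) & (lam < self.a_minus)] = atom
        return np.clip(out, 0.0, 1.0)

    def bulk_cdf(self, lam: np.ndarray) -> np.ndarray:
        """CDF of the continuous part conditioned on [a-, a+]."""
        x, c = self._grid()
        return np.interp(np.asarray(lam, dtype=float), x, c / c[-1], left=0.0, right=1.0)

    def bulk_mean(self) -> float:
        """Mean of the continuous part conditioned on the support."""
        x, _ = self._grid()
        d = self.density(x)
        return float(np.trapezoid(x * d, x) / np.trapezoid(d, x))

    def sample_bulk(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-transform draws from the conditioned continuous part."""
        x, c = self._grid()
        return np.interp(rng.random(n), c / c[-1], x)


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------


@dataclass
class SpectralDecomposition:
    """Eigenpairs of the Wishart matrix with per-eigenvector class labels.

    ``eigenvalues`` are descending; ``eigenvectors[:, i]`` is the unit-norm
    psi_i with the sign fixed so its largest-magnitude component is positive.
    ``classes`` entries are one of {"noise", "sparsity_fake", "signal"} (None
    until classification). The standardized matrix is retained privately so
    that projection and gene tests reuse the exact centering/scaling.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    gamma: float
    classes: np.ndarray | None = None
    mp: MPModel | None = None
    noise_fraction: float | None = None
    _X_std: np.ndarray | None = field(default=None, repr=False)
    _kept_genes: np.ndarray | None = field(default=None, repr=False)
    _centered: bool = field(default=True, repr=False)
    _scaled: bool = field(default=True, repr=False)

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    def signal_indices(self) -> np.ndarray:
        if self.classes is None:
            raise ValueError("run classify_signal first")
        return np.flatnonzero(self.classes == "signal")

    def report(self, alpha: float = 0.001) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            ipr, p, deloc = eigenvector_delocalization_test(self.eigenvectors[:, i], alpha=alpha)
            rows.append(
                {
                    "index": i,
                    "eigenvalue": self.eigenvalues[i],
                    "class": None if self.classes is None else self.classes[i],
                    "ipr": ipr,
                    "delocalization_p": p,
                    "delocalized": deloc,
                }
            )
        return pd.DataFrame(rows)


def _standardize(
    m: ExpressionMatrix, center_genes: bool = True, scale_genes: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Dense per-gene standardized matrix; constant genes are dropped."""
    X = m.toarray().astype(np.float64)
    sd = X.std(axis=0)
    keep = sd > 1e-12 if X.shape[0] > 1 else np.ones(X.shape[1], dtype=bool)
    if X.shape[0] > 1 and (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} constant gene columns before the spectrum")
        X = X[:, keep]
        sd = sd[keep]
    if center_genes:
        X = X - X.mean(axis=0)
    if scale_genes and X.shape[0] > 1:
        X = X / sd
    return X, np.flatnonzero(keep)


def wishart_spectrum(
    m: ExpressionMatrix,
    center_genes: bool = True,
    scale_genes: bool = True,
) -> SpectralDecomposition:
    """Eigenpairs of W = (1/P) X X^T on the gene-standardized matrix.

    Deterministic up to the fixed sign convention (largest-magnitude component
    of each eigenvector positive). ``scale_genes`` divides each gene by its
    standard deviation; with it off, a single global sigma^2 is left to the MP
    fit.
    """
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes")
    X, kept = _standardize(m, center_genes, scale_genes)
    n, p = X.shape
    W = (X @ X.T) / p
    vals, vecs = np.linalg.eigh(W)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    flip = vecs[np.argmax(np.abs(vecs), axis=0), np.arange(n)] < 0
    vecs[:, flip] *= -1.0
    return SpectralDecomposition(
        eigenvalues=vals,
        eigenvectors=vecs,
        gamma=n / p,
        _X_std=X,
        _kept_genes=kept,
        _centered=center_genes,
        _scaled=scale_genes,
    )


# ---------------------------------------------------------------------------
# MP fit
# ---------------------------------------------------------------------------


def fit_mp(
    eigenvalues: np.ndarray,
    gamma: float,
    max_iter: int = 20,
    edge_tol: float = 1e-9,
) -> MPModel:
    """Fit sigma^2 to the bulk by iterative trimming.

    sigma^2 is chosen so the mean of the in-support eigenvalues matches the
    model's conditional bulk mean; eigenvalues outside the current [a-, a+]
    are excluded and the fit repeats until the bulk set stabilizes. The KS
    distance between the bulk empirical CDF and the conditioned MP CDF is
    reported on the fitted model.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    if len(lam) < 10:
        raise ValueError("need at least 10 eigenvalues to fit the MP bulk")
    if np.allclose(lam, lam[0]):
        model = MPModel(sigma2=float(max(lam[0], 1e-12)), gamma=gamma, ks_distance=1.0)
        return model
    bulk = lam[lam > 1e-12] if gamma > 1 else lam
    if len(bulk) == 0:
        raise ValueError("no bulk eigenvalues remain; cannot fit MP model")
    sigma2 = float(np.mean(bulk))
    for _ in range(max_iter):
        model = MPModel(sigma2=sigma2, gamma=gamma)
        new_bulk = lam[(lam >= model.a_minus - edge_tol) & (lam <= model.a_plus + edge_tol)]
        if len(new_bulk) == 0:
            raise ValueError("no bulk eigenvalues remain; cannot fit MP model")
        new_sigma2 = sigma2 * float(np.mean(new_bulk)) / model.bulk_mean()
        stable = len(new_bulk) == len(bulk) and np.allclose(new_sigma2, sigma2, rtol=1e-10)
        bulk, sigma2 = new_bulk, new_sigma2
        if stable:
            break
    model = MPModel(sigma2=sigma2, gamma=gamma)
    ecdf = np.arange(1, len(bulk) + 1) / len(bulk)
    ks = float(np.max(np.abs(model.bulk_cdf(np.sort(bulk)) - ecdf)))
    model.ks_distance = ks
    return model


# ---------------------------------------------------------------------------
# eigenvector universality
# ---------------------------------------------------------------------------


def eigenvector_delocalization_test(
    psi: np.ndarray,
    alpha: float = 0.001,
    ipr_c: float = 3.0,
) -> tuple[float, float, bool]:
    """Inverse participation ratio and Gaussian-component test for one
    eigenvector.

    A delocalized random eigenvector has components ~ Normal(0, 1/N), hence
    IPR = sum(psi^4) near 3/N; localized vectors concentrate mass on few
    cells and have large IPR. The vector counts as delocalized when its IPR is
    below ``ipr_c * log(N) / N`` and either the Kolmogorov-Smirnov test
    against Normal(0, 1/N) does not reject at ``alpha`` or the IPR is below
    1.5/N — flatter than any random vector (the minimum is 1/N, attained by
    the exactly uniform vector, which no histogram test should call
    localized).
    """
    psi = np.asarray(psi, dtype=float)
    n = len(psi)
    nrm = np.linalg.norm(psi)
    if abs(nrm - 1.0) > 1e-8:
        raise ValueError("eigenvector must be unit norm")
    ipr = float(np.sum(psi**4))
    p_value = float(stats.kstest(psi, "norm", args=(0.0, 1.0 / np.sqrt(n))).pvalue)
    delocalized = ipr <= ipr_c * np.log(n) / n and (p_value >= alpha or ipr <= 1.5 / n)
    return ipr, p_value, delocalized


def _localized_set(spec: SpectralDecomposition, alpha: float, ipr_c: float) -> np.ndarray:
    mask = np.zeros(spec.n, dtype=bool)
    for i in range(spec.n):
        _, _, deloc = eigenvector_delocalization_test(
            spec.eigenvectors[:, i], alpha=alpha, ipr_c=ipr_c
        )
        mask[i] = not deloc
    return mask


def _permute_genes_across_cells(
    values: sp.csr_matrix, rng: np.random.Generator
) -> sp.csr_matrix:
    """Independently permute each gene's full value column (zeros included)
    across cells. Each gene keeps its marginal distribution — zero fraction,
    value histogram — but every trace of cell-level structure (which cells
    co-express, per-cell detection depth) is destroyed."""
    csc = values.tocsc(copy=True)
    n = csc.shape[0]
    for j in range(csc.shape[1]):
        lo, hi = csc.indptr[j], csc.indptr[j + 1]
        if hi > lo:
            csc.indices[lo:hi] = np.sort(rng.choice(n, size=hi - lo, replace=False))
            csc.data[lo:hi] = rng.permutation(csc.data[lo:hi])
    return csc.tocsr()


def flag_sparsity_artifacts(
    m: ExpressionMatrix,
    spec: SpectralDecomposition,
    n_null: int = 10,
    jaccard_threshold: float = 0.25,
    top_q: int = 50,
    detected_corr_threshold: float = 0.5,
    null_gate_factor: float = 1.5,
    alpha: float = 0.001,
    ipr_c: float = 3.0,
    min_zero_fraction: float = 0.05,
    seed: int = 0,
) -> SpectralDecomposition:
    """Label localized eigenvectors attributable to sparsity (rather than
    biology) as ``sparsity_fake``.

    Two signatures are checked on every localized eigenvector of the real
    spectrum:

    * gene-marginal sparsity: the null permutes each gene's full column
      across cells (``n_null`` times), preserving per-gene zero fractions and
      value histograms while destroying all cell-level structure. Localized
      eigenvectors arising in that null reflect sparsity marginals alone; a
      real eigenvector whose top-``top_q`` loading cells overlap a null one
      (Jaccard above ``jaccard_threshold``) and whose eigenvalue the null
      reproduces (within ``null_gate_factor`` at the same rank) is flagged.
      The eigenvalue gate matters because value-level biological signal
      produces eigenvalues the null cannot reach.
    * detection-depth structure: loadings that track the per-cell number of
      detected genes (|r| above ``detected_corr_threshold``) are flagged
      outright — the direction is explained by how many genes each cell
      expresses, the classic droplet sparsity artifact.

    A null that instead preserved exactly which entries are zero would be
    blind here: in droplet data marker genes are detected only in their own
    population, so the zero pattern itself carries the biology and such a
    null reproduces genuine population eigenvectors.
    """
    classes = np.full(spec.n, None, dtype=object)
    zero_fraction = 1.0 - m.values.nnz / (m.n_cells * m.n_genes)
    if zero_fraction < min_zero_fraction:
        return replace(spec, classes=classes)

    localized = _localized_set(spec, alpha, ipr_c)
    if not localized.any():
        return replace(spec, classes=classes)

    detected = np.asarray((m.values > 0).sum(axis=1)).ravel().astype(float)
    det_centered = detected - detected.mean()
    det_norm = np.linalg.norm(det_centered)

    q = min(top_q, spec.n)
    null_supports: list[set[int]] = []
    null_lambda_max = np.zeros(spec.n)
    rng = split_rng(seed, "sparsity-null")
    for _ in range(n_null):
        shuffled = replace(m, values=_permute_genes_across_cells(m.values, rng))
        nspec = wishart_spectrum(
            shuffled,
            center_genes=spec._centered,
            scale_genes=spec._scaled,
        )
        k = min(spec.n, nspec.n)
        null_lambda_max[:k] = np.maximum(null_lambda_max[:k], nspec.eigenvalues[:k])
        nloc = _localized_set(nspec, alpha, ipr_c)
        for i in np.flatnonzero(nloc):
            v = np.abs(nspec.eigenvectors[:, i])
            null_supports.append(set(np.argsort(v)[::-1][:q].tolist()))

    for i in np.flatnonzero(localized):
        psi = spec.eigenvectors[:, i]
        support = set(np.argsort(np.abs(psi))[::-1][:q].tolist())
        jac = max(
            (len(support & s) / len(support | s) for s in null_supports),
            default=0.0,
        )
        marginal_fake = (
            jac > jaccard_threshold
            and spec.eigenvalues[i] <= null_gate_factor * null_lambda_max[i]
        )
        r = 0.0
        if det_norm > 0:
            r = float(np.dot(psi, det_centered) / det_norm)  # psi is unit norm
        if marginal_fake or abs(r) > detected_corr_threshold:
            classes[i] = "sparsity_fake"
    return replace(spec, classes=classes)


# ---------------------------------------------------------------------------
# classification and projection
# ---------------------------------------------------------------------------


def tw_edge_allowance(mp: MPModel, n: int) -> float:
    """Scale of the largest-eigenvalue fluctuation at the bulk edge.

    The largest noise eigenvalue sits at a+ plus a Tracy-Widom fluctuation of
    this order; the signal threshold adds a multiple of it so that pure noise
    is not called signal.
    """
    p = n / mp.gamma
    return float(
        mp.sigma2 * ((np.sqrt(p) + np.sqrt(n)) / p) * (1 / np.sqrt(p) + 1 / np.sqrt(n)) ** (1 / 3)
    )


def classify_signal(
    spec: SpectralDecomposition,
    mp: MPModel | None = None,
    edge_allowance: float = 3.0,
) -> SpectralDecomposition:
    """Assign noise / sparsity_fake / signal to every eigenvector.

    Signal = eigenvalue above a+ plus ``edge_allowance`` Tracy-Widom units and
    not flagged as a sparsity artifact. Localized eigenvectors inside the bulk
    are never signal. Also records ``noise_fraction``, the share of
    eigenvalues inside [a-, a+].
    """
    mp = mp or spec.mp
    if mp is None:
        mp = fit_mp(spec.eigenvalues, spec.gamma)
    classes = (
        spec.classes.copy() if spec.classes is not None else np.full(spec.n, None, dtype=object)
    )
    threshold = mp.a_plus + edge_allowance * tw_edge_allowance(mp, spec.n)
    for i in range(spec.n):
        if classes[i] == "sparsity_fake":
            continue
        classes[i] = "signal" if spec.eigenvalues[i] > threshold else "noise"
    inside = np.sum((spec.eigenvalues >= mp.a_minus) & (spec.eigenvalues <= mp.a_plus))
    return replace(
        spec,
        classes=classes,
        mp=mp,
        noise_fraction=float(inside / spec.n),
    )


@dataclass
class LatentSpace:
    """Cell coordinates on the signal eigenvectors (N x k)."""

    coordinates: np.ndarray
    signal_indices: np.ndarray
    source: str = ""

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        cols = [f"sv{i}" for i in self.signal_indices]
        idx = None if cell_ids is None else list(cell_ids)
        return pd.DataFrame(self.coordinates, columns=cols, index=idx)


def project_to_latent(m: ExpressionMatrix, spec: SpectralDecomposition) -> LatentSpace:
    """Latent coordinates: column i is psi_i scaled by sqrt(N * lambda_i), so
    the coordinates' Gram matrix is diagonal with entries N * lambda_i."""
    idx = spec.signal_indices()
    if len(idx) == 0:
        raise ValueError(
            "no signal eigenvectors; nothing to project (check classification, or the "
            "dataset may be pure noise)"
        )
    scale = np.sqrt(spec.n * np.clip(spec.eigenvalues[idx], 0.0, None))
    return LatentSpace(
        coordinates=spec.eigenvectors[:, idx] * scale[None, :],
        signal_indices=idx,
        source=f"{m.species}:{m.n_cells}x{m.n_genes}",
    )


def denoised_matrix(
    m: ExpressionMatrix,
    spec: SpectralDecomposition,
    keep: str = "signal",
) -> ExpressionMatrix:
    """Signal-subspace reconstruction of the standardized matrix.

    ``keep`` may be "signal", "noise" or "all". The result holds standardized
    residual-scale values (mean-zero per gene, real-valued), tagged
    ``normalized`` for downstream stages.
    """
    if spec._X_std is None:
        raise ValueError("decomposition was not built by wishart_spectrum")
    if keep == "all":
        idx = np.arange(spec.n)
    else:
        if spec.classes is None:
            raise ValueError("run classify_signal first")
        idx = np.flatnonzero(spec.classes == keep)
        if len(idx) == 0:
            raise ValueError(f"no '{keep}' eigenvectors to reconstruct from")
    psi = spec.eigenvectors[:, idx]
    Xd = psi @ (psi.T @ spec._X_std)
    return ExpressionMatrix(
        values=sp.csr_matrix(Xd),
        cell_ids=m.cell_ids.copy(),
        gene_ids=m.gene_ids[spec._kept_genes].copy(),
        species=m.species,
        sample_ids=m.sample_ids.copy(),
        stage="normalized",
    )


@dataclass
class SignalGeneTable:
    table: pd.DataFrame  # gene, statistic, p, p_adj, selected
    k: int
    fdr: float


def signal_genes(
    m: ExpressionMatrix,
    spec: SpectralDecomposition,
    fdr: float = 0.05,
) -> SignalGeneTable:
    """Chi-squared variance test for signal-like genes.

    For standardized gene column g, T_g = ||Psi_s^T x_g||^2 / sigma2_hat is
    chi-squared with k degrees of freedom under the pure-noise null (k =
    number of signal eigenvectors); genes whose projection onto the signal
    subspace carries excess variance get small upper-tail p-values, adjusted
    by Benjamini-Hochberg and selected at the given FDR.
    """
    if spec._X_std is None or spec.mp is None:
        raise ValueError("need a classified decomposition built by wishart_spectrum")
    idx = spec.signal_indices()
    if len(idx) == 0:
        raise ValueError("no signal eigenvectors")
    psi = spec.eigenvectors[:, idx]
    t = np.sum((psi.T @ spec._X_std) ** 2, axis=0) / spec.mp.sigma2
    p = stats.chi2.sf(t, df=len(idx))
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "gene": m.gene_ids[spec._kept_genes],
            "statistic": t,
            "p": p,
            "p_adj": p_adj,
            "selected": p_adj < fdr,
        }
    )
    return SignalGeneTable(table=table, k=len(idx), fdr=fdr)


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------


def rmt_pipeline(
    m: ExpressionMatrix,
    seed: int = 0,
    center_genes: bool = True,
    scale_genes: bool = True,
    flag_sparsity: bool = True,
    edge_allowance: float = 3.0,
    n_null: int = 10,
) -> tuple[SpectralDecomposition, LatentSpace]:
    """Spectrum -> MP fit -> sparsity flags -> classification -> latent space."""
    spec = wishart_spectrum(m, center_genes=center_genes, scale_genes=scale_genes)
    mp = fit_mp(spec.eigenvalues, spec.gamma)
    if flag_sparsity:
        spec = flag_sparsity_artifacts(m, spec, n_null=n_null, seed=seed)
    spec = classify_signal(spec, mp=mp, edge_allowance=edge_allowance)
    return spec, project_to_latent(m, spec)
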