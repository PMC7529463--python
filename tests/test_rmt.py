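"""Marchenko-Pastur model, Wishart spectra, eigenvector universality tests,
sparsity-artifact flagging, classification and projection."""

import numpy as np
import pytest
import scipy.sparse as sp

from rmtot import (
    ExpressionMatrix,
    classify_signal,
    denoised_matrix,
    eigenvector_delocalization_test,
    fit_mp,
    flag_sparsity_artifacts,
    mp_bounds,
    project_to_latent,
    signal_genes,
    wishart_spectrum,
)
from rmtot.rmt import MPModel, _localized_set

from conftest import gaussian_matrix, make_matrix


# ---------------------------------------------------------------------------
# MP model
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sigma2,gamma,expected",
    [
        (1.0, 1.0, (0.0, 4.0)),
        (1.0, 0.25, (0.25, 2.25)),
        (2.0, 0.25, (0.5, 4.5)),
    ],
)
def test_mp_bounds_closed_forms(sigma2, gamma, expected):
    a_minus, a_plus = mp_bounds(sigma2, gamma)
    assert a_minus == pytest.approx(expected[0], abs=1e-12)
    assert a_plus == pytest.approx(expected[1], abs=1e-12)


def test_mp_bounds_scale_linearly_in_sigma2():
    for c in (0.5, 3.0):
        am, ap = mp_bounds(1.3, 0.4)
        am_c, ap_c = mp_bounds(c * 1.3, 0.4)
        assert am_c == pytest.approx(c * am, rel=1e-12)
        assert ap_c == pytest.approx(c * ap, rel=1e-12)


def test_mp_density_normalizes_and_cdf_monotone():
    from scipy.integrate import quad

    model = MPModel(sigma2=1.2, gamma=0.5)
    total, _ = quad(model.density, model.a_minus, model.a_plus, limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)
    grid = np.linspace(-0.5, model.a_plus + 1, 500)
    cdf = model.cdf(grid)
    assert np.all(np.diff(cdf) >= -1e-12)
    assert cdf[0] == 0.0 and cdf[-1] == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# Wishart spectrum
# ---------------------------------------------------------------------------


def test_near_constant_matrix_drops_genes_and_has_flat_spectrum():
    V = np.full((5, 50), 3.0)
    V[0, 0] += 1e-6  # all but one gene are constant and get dropped
    with pytest.warns(UserWarning, match="constant"):
        spec = wishart_spectrum(make_matrix(V, stage="normalized"), scale_genes=False)
    assert np.all(spec.eigenvalues[1:] < 1e-10)


def test_single_cell_spectrum_closed_form():
    V = np.arange(1.0, 7.0).reshape(1, 6)
    spec = wishart_spectrum(
        make_matrix(V, stage="normalized"), center_genes=False, scale_genes=False
    )
    assert spec.eigenvalues[0] == pytest.approx(np.sum(V**2) / 6, rel=1e-12)


def test_eigenvectors_orthonormal_and_sign_fixed(small_denoised):
    spec = small_denoised["spec"]
    gram = spec.eigenvectors.T @ spec.eigenvectors
    assert np.max(np.abs(gram - np.eye(spec.n))) < 1e-8
    peaks = spec.eigenvectors[np.argmax(np.abs(spec.eigenvectors), axis=0), np.arange(spec.n)]
    assert np.all(peaks > 0)


def test_gaussian_top_eigenvalue_near_mp_edge():
    spec = wishart_spectrum(gaussian_matrix(500, 5000, seed=8), scale_genes=False)
    _, a_plus = mp_bounds(1.0, 0.1)
    assert abs(spec.eigenvalues[0] - a_plus) / a_plus < 0.05


def test_cell_permutation_equivariance():
    m = gaussian_matrix(80, 400, seed=3)
    rng = np.random.default_rng(0)
    perm = rng.permutation(80)
    m_perm = make_matrix(m.toarray()[perm], stage="normalized")
    s1 = classify_signal(wishart_spectrum(m), edge_allowance=-10.0)
    s2 = classify_signal(wishart_spectrum(m_perm), edge_allowance=-10.0)
    l1 = project_to_latent(m, s1)
    l2 = project_to_latent(m_perm, s2)
    np.testing.assert_allclose(
        np.abs(l2.coordinates), np.abs(l1.coordinates[perm]), atol=1e-8
    )


# ---------------------------------------------------------------------------
# MP fit
# ---------------------------------------------------------------------------


def test_fit_recovers_sigma2_from_exact_mp_sample():
    model = MPModel(sigma2=1.0, gamma=0.2)
    lam = model.sample_bulk(2000, np.random.default_rng(1))
    fitted = fit_mp(lam, 0.2)
    assert abs(fitted.sigma2 - 1.0) < 0.02


def test_fit_ignores_spikes():
    model = MPModel(sigma2=1.0, gamma=0.2)
    lam = model.sample_bulk(2000, np.random.default_rng(1))
    bulk_only = fit_mp(lam, 0.2)
    with_spikes = fit_mp(np.concatenate([lam, [10.0, 12.0, 15.0]]), 0.2)
    assert abs(with_spikes.sigma2 - bulk_only.sigma2) / bulk_only.sigma2 < 0.01


def test_fit_degenerate_all_equal():
    fitted = fit_mp(np.full(50, 2.5), 0.3)
    assert fitted.sigma2 == pytest.approx(2.5)
    assert fitted.ks_distance > 0.5


def test_fit_requires_enough_eigenvalues():
    with pytest.raises(ValueError, match="at least 10"):
        fit_mp(np.ones(5), 0.5)


# ---------------------------------------------------------------------------
# eigenvector delocalization
# ---------------------------------------------------------------------------


def test_uniform_vector_is_delocalized():
    n = 1000
    ipr, _, deloc = eigenvector_delocalization_test(np.full(n, 1 / np.sqrt(n)))
    assert ipr == pytest.approx(1 / n, rel=1e-9)
    assert deloc


def test_basis_vector_is_localized():
    e1 = np.zeros(1000)
    e1[0] = 1.0
    ipr, _, deloc = eigenvector_delocalization_test(e1)
    assert ipr == pytest.approx(1.0)
    assert not deloc


def test_norm_violation_rejected():
    with pytest.raises(ValueError, match="unit norm"):
        eigenvector_delocalization_test(np.ones(10))


def test_gaussian_vectors_delocalized_in_999_of_1000_seeds():
    rng = np.random.default_rng(2)
    n_ok = 0
    for _ in range(1000):
        v = rng.standard_normal(2000)
        v /= np.linalg.norm(v)
        n_ok += eigenvector_delocalization_test(v, alpha=0.001)[2]
    assert n_ok >= 990


def test_block_vector_is_localized():
    """Mass spread evenly over 20% of cells: flat histogram tails but clearly
    structured; must be called localized for the artifact flagging to work."""
    n = 500
    v = np.zeros(n)
    v[:100] = 1 / 10.0
    _, _, deloc = eigenvector_delocalization_test(v)
    assert not deloc


# ---------------------------------------------------------------------------
# sparsity-artifact flagging
# ---------------------------------------------------------------------------


def test_dense_matrix_has_no_fakes():
    m = gaussian_matrix(100, 500, seed=4)
    spec = wishart_spectrum(m)
    flagged = flag_sparsity_artifacts(m, spec, seed=0)
    assert not np.any(flagged.classes == "sparsity_fake")


def test_zero_block_flagged_and_bulk_recovers_mp():
    """A structural zero block with no planted biology must be flagged as a
    sparsity artifact, and the remaining spectrum must fit MP (KS < 0.03)."""
    from rmtot import SimulationParams, generate_counts, normalize_log_tpm, qc_filter

    p = SimulationParams(
        n_cells=500, n_genes=2500, n_populations=1, marker_shift=0.0, seed=11
    )
    m, _ = generate_counts(p)
    V = m.toarray()
    V[:100, 100:700] = 0.0
    blocked = make_matrix(V)
    filtered, _ = qc_filter(blocked, min_genes=1)
    norm = normalize_log_tpm(filtered)
    spec = wishart_spectrum(norm)
    localized = _localized_set(spec, 0.001, 3.0)
    assert localized.any()
    flagged = flag_sparsity_artifacts(norm, spec, seed=1)
    fakes = np.flatnonzero(flagged.classes == "sparsity_fake")
    assert len(fakes) >= 1
    assert set(np.flatnonzero(localized)) >= set(fakes)
    keep = np.ones(spec.n, dtype=bool)
    keep[fakes] = False
    refit = fit_mp(spec.eigenvalues[keep], spec.gamma)
    assert refit.ks_distance < 0.03


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def test_classification_partitions_all_eigenvectors(small_denoised):
    spec = small_denoised["spec"]
    assert set(spec.classes) <= {"noise", "sparsity_fake", "signal"}
    assert spec.noise_fraction is not None
    assert 0 <= spec.noise_fraction <= 1


def test_classify_spiked_matrix_counts():
    from rmtot import planted_spike_matrix

    X, _ = planted_spike_matrix(400, 2000, 3, [15.0, 10.0, 8.0], seed=2)
    m = make_matrix(X, stage="normalized")
    spec = wishart_spectrum(m, scale_genes=False)
    spec = classify_signal(spec)
    assert len(spec.signal_indices()) == 3


# ---------------------------------------------------------------------------
# projection and reconstruction
# ---------------------------------------------------------------------------


def test_full_eigenbasis_reconstructs_standardized_matrix(small_denoised):
    spec = small_denoised["spec"]
    m = small_denoised["norm"]
    full = denoised_matrix(m, spec, keep="all")
    np.testing.assert_allclose(full.toarray(), spec._X_std, atol=1e-8)


def test_latent_gram_matrix_is_n_lambda_diagonal(small_denoised):
    spec = small_denoised["spec"]
    latent = small_denoised["latent"]
    gram = latent.coordinates.T @ latent.coordinates
    expected = spec.n * spec.eigenvalues[spec.signal_indices()]
    np.testing.assert_allclose(np.diag(gram), expected, rtol=1e-6)
    off = gram - np.diag(np.diag(gram))
    assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(gram))


def test_single_signal_eigenvector_latent_is_scaled_loading():
    from rmtot import planted_spike_matrix

    X, _ = planted_spike_matrix(200, 1000, 1, [20.0], seed=5)
    m = make_matrix(X, stage="normalized")
    spec = classify_signal(wishart_spectrum(m, scale_genes=False))
    assert len(spec.signal_indices()) == 1
    latent = project_to_latent(m, spec)
    i = spec.signal_indices()[0]
    scale = np.sqrt(spec.n * spec.eigenvalues[i])
    np.testing.assert_allclose(latent.coordinates[:, 0], scale * spec.eigenvectors[:, i])


def test_projection_requires_signal():
    m = gaussian_matrix(100, 1000, seed=6)
    spec = classify_signal(wishart_spectrum(m, scale_genes=False))
    assert len(spec.signal_indices()) == 0
    with pytest.raises(ValueError, match="no signal"):
        project_to_latent(m, spec)


# ---------------------------------------------------------------------------
# signal genes
# ---------------------------------------------------------------------------


def test_signal_gene_null_calibration_and_power():
    """One strong planted direction carried by the first 50 genes: held-out
    null genes are selected at no more than the nominal FDR (within 3 SE),
    while the carrier genes are recovered with high power."""
    null_rates, powers = [], []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        X = rng.standard_normal((200, 1000))
        u = rng.standard_normal(200)
        u /= np.linalg.norm(u)
        w = rng.uniform(4.0, 6.0, 50)
        X[:, :50] += np.outer(u, w) * np.sqrt(200)
        m = make_matrix(X, stage="normalized")
        spec = classify_signal(wishart_spectrum(m, scale_genes=False))
        assert len(spec.signal_indices()) >= 1
        table = signal_genes(m, spec, fdr=0.05).table
        is_carrier = np.asarray([g in {f"g{j}" for j in range(50)} for g in table["gene"]])
        null_rates.append(table.loc[~is_carrier, "selected"].mean())
        powers.append(table.loc[is_carrier, "selected"].mean())
    n_null = 5 * 950
    se = np.sqrt(0.05 * 0.95 / n_null)
    assert np.mean(null_rates) <= 0.05 + 3 * se
    assert np.mean(powers) >= 0.95


def test_signal_genes_recover_planted_markers(small_denoised):
    spec = small_denoised["spec"]
    norm = small_denoised["norm"]
    truth = small_denoised["truth"]
    table = signal_genes(norm, spec, fdr=0.05).table
    marker_ids = set()
    for genes, _ in truth.marker_sets.values():
        marker_ids.update(norm.gene_ids[g] for g in genes if g < norm.n_genes)
    sel = set(table.loc[table["selected"], "gene"])
    marker_ids &= set(table["gene"])  # markers surviving QC/constant-drop
    power = len(marker_ids & sel) / len(marker_ids)
    assert power >= 0.95
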