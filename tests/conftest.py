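import numpy as np
import pytest
import scipy.sparse as sp

from rmtot import (
    ExpressionMatrix,
    SimulationParams,
    generate_counts,
    normalize_log_tpm,
    qc_filter,
)


def make_matrix(values, stage="raw_counts", gene_ids=None, cell_ids=None, **kw):
    """Build an ExpressionMatrix from a dense array with auto-generated ids."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(
        values=sp.csr_matrix(values),
        cell_ids=cell_ids if cell_ids is not None else [f"c{i}" for i in range(n)],
        gene_ids=gene_ids if gene_ids is not None else [f"g{j}" for j in range(p)],
        stage=stage,
        **kw,
    )


def gaussian_matrix(n, p, seed=0, stage="normalized"):
    rng = np.random.default_rng(seed)
    return make_matrix(rng.standard_normal((n, p)), stage=stage)


@pytest.fixture(scope="session")
def small_dataset():
    """A 4-population droplet-like dataset shared across module tests."""
    params = SimulationParams(n_cells=600, n_genes=3000, n_populations=4, seed=13)
    m, truth = generate_counts(params)
    filtered, records = qc_filter(m)
    keep = np.isin(m.cell_ids, filtered.cell_ids)
    norm = normalize_log_tpm(filtered)
    return {
        "params": params,
        "raw": m,
        "filtered": filtered,
        "norm": norm,
        "labels": truth.labels[keep],
        "truth": truth,
        "records": records,
    }


@pytest.fixture(scope="session")
def small_denoised(small_dataset):
    from rmtot import rmt_pipeline

    spec, latent = rmt_pipeline(small_dataset["norm"], seed=13)
    return {"spec": spec, "latent": latent, **small_dataset}
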