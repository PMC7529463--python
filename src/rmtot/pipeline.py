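"""Stage orchestration: run the analysis end-to-end on a directory layout.

Each stage reads the previous stage's artifacts from the output directory,
writes its own (TSV/Matrix Market/JSON/newick), and drops a manifest with
input hashes, parameters and the seed so any artifact can be reproduced from
inputs alone. Stages: simulate, qc, normalize, denoise, cluster, distances,
tree, de, crossspecies, all.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import cross_species as cs
from . import de as de_mod
from . import ot as ot_mod
from . import rmt
from .io_preprocess import (
    ExpressionMatrix,
    normalize_log_tpm,
    qc_filter,
    read_matrix,
    write_matrix,
    write_qc_report,
)
from .synthetic import SimulationParams, generate_counts, generate_species_pair

__all__ = ["RunConfig", "run", "STAGES"]

STAGES = [
    "simulate",
    "qc",
    "normalize",
    "denoise",
    "cluster",
    "distances",
    "tree",
    "de",
    "crossspecies",
    "all",
]


@dataclass
class RunConfig:
    """Flat configuration; every field has a default so ``simulate`` + ``all``
    works with zero configuration. Unknown keys in a config file are rejected."""

    outdir: str = "rmtot_out"
    seed: int = 0
    # input (omit to use the simulate stage's output)
    input_path: str | None = None
    input_format: str = "mtx_triplet"
    # simulation
    n_cells: int = 2000
    n_genes: int = 10000
    n_populations: int = 8
    marker_fraction: float = 0.02
    marker_shift: float = 2.0
    dispersion: float = 2.0
    # qc
    min_genes: int = 500
    max_mito: float = 0.10
    batch_correct: str = "none"
    # denoising
    scale_genes: bool = True
    alpha_delocalization: float = 0.001
    n_null_permutations: int = 10
    edge_allowance: float = 3.0
    fdr_signal_genes: float = 0.05
    # clustering
    knn_k: int = 15
    resolution_min: float = 0.05
    resolution_max: float = 2.0
    resolution_steps: int = 20
    # optimal transport
    epsilon_scale: float | None = None
    size_cap: int = 2000
    exact_threshold: int = 4 * 10**6
    # differential expression
    de_threshold: float = 0.001
    # cross-species
    n_conserved: int = 3
    n_private_each: int = 2
    ortholog_fraction: float = 0.9
    species_noise: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_params(self) -> SimulationParams:
        return SimulationParams(
            n_cells=self.n_cells,
            n_genes=self.n_genes,
            n_populations=self.n_populations,
            marker_fraction=self.marker_fraction,
            marker_shift=self.marker_shift,
            dispersion=self.dispersion,
            seed=self.seed,
        )

    def resolutions(self) -> np.ndarray:
        return np.geomspace(self.resolution_min, self.resolution_max, self.resolution_steps)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest(cfg: RunConfig, stage: str, inputs: list[Path]) -> None:
    out = Path(cfg.outdir) / "manifests"
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "stage": stage,
        "seed": cfg.seed,
        "params": dataclasses.asdict(cfg),
        "inputs": {str(p): _sha256(p) for p in inputs if p.is_file()},
    }
    (out / f"{stage}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the {producing_stage!r} stage first"
        )
    return path


def _load_matrix_dir(path: Path, stage_tag: str) -> ExpressionMatrix:
    m = read_matrix(path, format="mtx_triplet")
    return dataclasses.replace(m, stage=stage_tag)


def _denoise_in_memory(cfg: RunConfig, norm: ExpressionMatrix):
    return rmt.rmt_pipeline(
        norm,
        seed=cfg.seed,
        scale_genes=cfg.scale_genes,
        n_null=cfg.n_null_permutations,
        edge_allowance=cfg.edge_allowance,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig) -> None:
    out = Path(cfg.outdir) / "sim"
    m, truth = generate_counts(cfg.sim_params())
    write_matrix(m, out)
    pd.DataFrame({"cell_id": list(m.cell_ids), "label": list(truth.labels)}).to_csv(
        out / "truth_labels.tsv", sep="\t", index=False
    )
    (out / "truth.json").write_text(
        json.dumps(
            {
                "population_tree": truth.population_tree,
                "marker_sets": {
                    k: [int(g) for g in v[0]] for k, v in truth.marker_sets.items()
                },
                "seed": truth.seed,
            },
            indent=2,
        )
    )
    _manifest(cfg, "simulate", [])


def _input_matrix(cfg: RunConfig) -> ExpressionMatrix:
    if cfg.input_path is not None:
        return read_matrix(cfg.input_path, format=cfg.input_format)
    return _load_matrix_dir(
        _require(Path(cfg.outdir) / "sim" / "matrix.mtx", "simulate").parent, "raw_counts"
    )


def _stage_qc(cfg: RunConfig) -> None:
    m = _input_matrix(cfg)
    filtered, records = qc_filter(m, min_genes=cfg.min_genes, max_mito=cfg.max_mito)
    out = Path(cfg.outdir) / "qc"
    write_matrix(filtered, out)
    write_qc_report(records, out / "qc_report.tsv")
    _manifest(cfg, "qc", [out / "qc_report.tsv"])


def _stage_normalize(cfg: RunConfig) -> None:
    src = _require(Path(cfg.outdir) / "qc" / "matrix.mtx", "qc").parent
    m = _load_matrix_dir(src, "raw_counts")
    norm = normalize_log_tpm(m)
    out = Path(cfg.outdir) / "norm"
    write_matrix(norm, out)
    _manifest(cfg, "normalize", [src / "matrix.mtx"])


def _load_normalized(cfg: RunConfig) -> ExpressionMatrix:
    src = _require(Path(cfg.outdir) / "norm" / "matrix.mtx", "normalize").parent
    return _load_matrix_dir(src, "normalized")


def _stage_denoise(cfg: RunConfig) -> None:
    norm = _load_normalized(cfg)
    spec, latent = _denoise_in_memory(cfg, norm)
    out = Path(cfg.outdir) / "latent"
    out.mkdir(parents=True, exist_ok=True)
    latent.to_frame(norm.cell_ids).to_csv(out / "latent.tsv", sep="\t")
    spec.report(alpha=cfg.alpha_delocalization).to_csv(
        out / "spectrum.tsv", sep="\t", index=False
    )
    sig = rmt.signal_genes(norm, spec, fdr=cfg.fdr_signal_genes)
    sig.table.to_csv(out / "signal_genes.tsv", sep="\t", index=False)
    _manifest(cfg, "denoise", [Path(cfg.outdir) / "norm" / "matrix.mtx"])


def _load_latent(cfg: RunConfig) -> tuple[pd.DataFrame, rmt.LatentSpace]:
    path = _require(Path(cfg.outdir) / "latent" / "latent.tsv", "denoise")
    df = pd.read_csv(path, sep="\t", index_col=0)
    idx = np.asarray([int(c[2:]) for c in df.columns])
    return df, rmt.LatentSpace(coordinates=df.to_numpy(), signal_indices=idx)


def _stage_cluster(cfg: RunConfig) -> None:
    df, latent = _load_latent(cfg)
    assignment, sweep = cl.cluster_latent(
        latent, k=cfg.knn_k, resolutions=cfg.resolutions(), seed=cfg.seed
    )
    out = Path(cfg.outdir) / "clusters"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cell_id": df.index, "label": assignment.labels}).to_csv(
        out / "labels.tsv", sep="\t", index=False
    )
    cl.sweep_report(sweep).to_csv(out / "sweep.tsv", sep="\t", index=False)
    (out / "selection.json").write_text(
        json.dumps(
            {
                "resolution": assignment.resolution,
                "n_clusters": assignment.n_clusters,
                "mean_silhouette": assignment.mean_silhouette,
                "seed": assignment.seed,
            },
            indent=2,
        )
    )
    _manifest(cfg, "cluster", [Path(cfg.outdir) / "latent" / "latent.tsv"])


def _load_labels(cfg: RunConfig) -> np.ndarray:
    path = _require(Path(cfg.outdir) / "clusters" / "labels.tsv", "cluster")
    return pd.read_csv(path, sep="\t")["label"].astype(str).to_numpy()


def _stage_distances(cfg: RunConfig) -> None:
    _, latent = _load_latent(cfg)
    labels = _load_labels(cfg)
    wm = ot_mod.population_distance_matrix(
        latent,
        labels,
        epsilon=cfg.epsilon_scale,
        size_cap=cfg.size_cap,
        exact_threshold=cfg.exact_threshold,
        seed=cfg.seed,
    )
    out = Path(cfg.outdir) / "distances"
    out.mkdir(parents=True, exist_ok=True)
    wm.to_frame().to_csv(out / "wasserstein.tsv", sep="\t")
    order, _ = ot_mod.hierarchical_order(wm)
    (out / "heatmap_order.txt").write_text("\n".join(order) + "\n")
    _manifest(cfg, "distances", [Path(cfg.outdir) / "clusters" / "labels.tsv"])


def _stage_tree(cfg: RunConfig) -> None:
    path = _require(Path(cfg.outdir) / "distances" / "wasserstein.tsv", "distances")
    df = pd.read_csv(path, sep="\t", index_col=0)
    wm = ot_mod.WassersteinMatrix(labels=[str(x) for x in df.index], D=df.to_numpy())
    tree = ot_mod.nj_tree(wm)
    out = Path(cfg.outdir) / "distances"
    (out / "tree.nwk").write_text(tree.newick + "\n")
    _manifest(cfg, "tree", [path])


def _stage_de(cfg: RunConfig) -> None:
    norm = _load_normalized(cfg)
    labels = _load_labels(cfg)
    spec, _ = _denoise_in_memory(cfg, norm)
    denoised = rmt.denoised_matrix(norm, spec)
    res = de_mod.de_test(denoised, labels, threshold=cfg.de_threshold)
    out = Path(cfg.outdir) / "de"
    out.mkdir(parents=True, exist_ok=True)
    res.table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    de_mod.dotplot_summary(norm, labels).to_csv(out / "dotplot.tsv", sep="\t", index=False)
    _manifest(
        cfg,
        "de",
        [Path(cfg.outdir) / "norm" / "matrix.mtx", Path(cfg.outdir) / "clusters" / "labels.tsv"],
    )


def _stage_crossspecies(cfg: RunConfig) -> None:
    a, b, table, truth = generate_species_pair(
        cfg.sim_params(),
        n_conserved=cfg.n_conserved,
        n_private_each=cfg.n_private_each,
        ortholog_fraction=cfg.ortholog_fraction,
        species_noise=cfg.species_noise,
    )
    orth = cs.resolve_orthologs(table, provenance="synthetic pair")
    merged, species = cs.harmonize(a, b, orth)
    _, latent = cs.common_latent(
        merged, seed=cfg.seed, scale_genes=cfg.scale_genes, n_null=cfg.n_null_permutations
    )
    labels = np.concatenate([truth.labels["a"], truth.labels["b"]])
    result = cs.cross_distance(
        latent, species, labels, size_cap=cfg.size_cap, exact_threshold=cfg.exact_threshold
    )
    declared = [
        (e["species_a"], e["species_b"]) for e in truth.species_map if e["conserved"]
    ]
    report = cs.validate_conserved(result, declared)
    out = Path(cfg.outdir) / "cross"
    out.mkdir(parents=True, exist_ok=True)
    result.matrix.to_csv(out / "cross_matrix.tsv", sep="\t")
    (out / "validation.json").write_text(json.dumps(report, indent=2))
    _manifest(cfg, "crossspecies", [])


def run(stage: str, cfg: RunConfig) -> None:
    """Execute one stage (or ``all``), writing artifacts under ``cfg.outdir``."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    # echo the configuration verbatim next to the artifacts
    (Path(cfg.outdir) / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    )
    dispatch = {
        "simulate": [_stage_simulate],
        "qc": [_stage_qc],
        "normalize": [_stage_normalize],
        "denoise": [_stage_denoise],
        "cluster": [_stage_cluster],
        "distances": [_stage_distances],
        "tree": [_stage_tree],
        "de": [_stage_de],
        "crossspecies": [_stage_crossspecies],
        "all": [
            _stage_qc,
            _stage_normalize,
            _stage_denoise,
            _stage_cluster,
            _stage_distances,
            _stage_tree,
            _stage_de,
        ],
    }
    for fn in dispatch[stage]:
        fn(cfg)
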