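"""End-to-end pipeline: harmonize -> CCA -> hybrid graph -> two-stage
training -> k-NN label transfer -> metrics report, plus component ablations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .graph import ProximityParams, build_hybrid_graph, cca_project, save_graph
from .io import (
    FeatureMatrix,
    LabelSet,
    harmonize_features,
    normalize_counts,
    write_labels,
    write_transfer_result,
)
from .metrics import evaluate_all, transfer_accuracy
from .model import (
    AutoencoderConfig,
    MMDConfig,
    TrainConfig,
    train,
)
from .simulate import SimScenario, get_preset, simulate
from .transfer import knn_transfer, novelty_report

log = logging.getLogger("omicbridge")

ABLATABLE = ("mmd", "cosine", "gcn", "autoencoder")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default."""

    # preprocessing
    normalize: bool = True
    target_sum: float = 1e4
    # graph
    d_cca: int = 20
    k_mnn: int = 20
    sigma: float | None = None        # None -> median-distance heuristic
    weighted_edges: bool = False
    # autoencoder
    n_sub: int = 8
    s_sub: int | None = None
    latent_dim: int = 32
    ae_hidden: int = 16
    # losses / training
    lambda_mmd: float = 1.0
    lambda_cos: float = 0.1
    lambda_ce: float = 1.0
    mmd_bandwidths: list[float] | None = None
    mmd_estimator: str = "biased"
    epochs_stage1: int = 60
    epochs_stage2: int = 150
    lr: float = 1e-3
    batch_size: int = 256
    gcn_hidden: int = 64
    single_conv: bool = False
    # transfer / evaluation
    k_transfer: int = 30
    conf_threshold: float = 0.60
    k_eval: int = 30
    transfer_mode: str = "knn"        # or "gcn": argmax of the GCN softmax
    identity_graph: bool = False      # replace the hybrid graph by I (ablation)
    seed: int = 0

    def __post_init__(self):
        if self.transfer_mode not in ("knn", "gcn"):
            raise ValueError("transfer_mode must be 'knn' or 'gcn'")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Plain-text ``key = value`` config; '#' starts a comment."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{ln}: unknown option '{key}'")
            kwargs[key] = _coerce(raw)
        return cls(**kwargs)


def _coerce(raw: str):
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", ""):
        return None
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        pass
    if "," in raw:
        return [_coerce(tok.strip()) for tok in raw.split(",")]
    return raw


@dataclass
class PipelineResult:
    embedding: np.ndarray
    cell_ids: list[str]
    modalities: np.ndarray
    transfer: object
    metrics: dict[str, float]
    state: object
    graph: object
    projection: object
    accuracy: float | None = None
    per_type_f1: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(
    config: RunConfig,
    src: FeatureMatrix,
    src_labels: LabelSet,
    tgt: FeatureMatrix,
    tgt_truth: LabelSet | None = None,
    pairing: np.ndarray | None = None,
    outdir=None,
) -> PipelineResult:
    """Run the full integration and label transfer; optionally write
    embeddings, transfer TSV, metrics JSON and a reproducibility manifest."""
    _stage("harmonize")
    src, tgt = harmonize_features(src, tgt)
    if config.normalize:
        src = normalize_counts(src, target_sum=config.target_sum)
        tgt = normalize_counts(tgt, target_sum=config.target_sum)

    _stage("cca")
    d_cca = min(config.d_cca, min(src.n_cells, tgt.n_cells, src.n_features) - 1)
    proj = cca_project(src, tgt, d_cca=max(1, d_cca))

    _stage("hybrid graph")
    graph = build_hybrid_graph(
        proj,
        ProximityParams(sigma=config.sigma, k_mnn=config.k_mnn),
        weighted=config.weighted_edges,
    )
    if config.identity_graph:
        from .graph import HybridGraph, normalize_adjacency

        graph = normalize_adjacency(
            HybridGraph(graph.n_s, graph.n_t, np.zeros_like(graph.adjacency))
        )

    _stage("train")
    ae_cfg = AutoencoderConfig(
        n_sub=config.n_sub, s_sub=config.s_sub,
        latent_dim=config.latent_dim, hidden=config.ae_hidden,
    )
    mmd_cfg = MMDConfig(bandwidths=config.mmd_bandwidths, estimator=config.mmd_estimator)
    tr_cfg = TrainConfig(
        lambda_mmd=config.lambda_mmd, lambda_cos=config.lambda_cos,
        lambda_ce=config.lambda_ce, epochs_stage1=config.epochs_stage1,
        epochs_stage2=config.epochs_stage2, lr=config.lr,
        batch_size=config.batch_size, gcn_hidden=config.gcn_hidden,
        single_conv=config.single_conv, seed=config.seed,
    )
    state, emb = train(src, src_labels, tgt, graph, ae_cfg, mmd_cfg, tr_cfg)

    _stage("transfer")
    n_s = src.n_cells
    src_emb, tgt_emb = emb.values[:n_s], emb.values[n_s:]
    labels_arr = src_labels.labels_for(src.cell_ids)
    if config.transfer_mode == "gcn":
        probs = state.probabilities[n_s:]
        idx = probs.argmax(axis=1)
        from .io import TransferResult

        result = TransferResult(
            cell_ids=list(tgt.cell_ids),
            predicted_labels=[state.classes[i] for i in idx],
            confidences=probs[np.arange(len(idx)), idx],
            conf_threshold=config.conf_threshold,
        )
    else:
        result = knn_transfer(
            src_emb, labels_arr, tgt_emb,
            k=min(config.k_transfer, n_s),
            conf_threshold=config.conf_threshold,
            tgt_cell_ids=tgt.cell_ids,
        )

    _stage("metrics")
    celltypes = np.concatenate(
        [labels_arr, tgt_truth.labels_for(tgt.cell_ids)]
    ) if tgt_truth is not None else np.concatenate(
        [labels_arr, np.asarray(result.predicted_labels)]
    )
    k_eval = min(config.k_eval, emb.values.shape[0] - 1)
    metrics = evaluate_all(
        emb.values,
        emb.modalities,
        celltypes,
        emb_single=np.vstack([proj.src_coords, proj.tgt_coords]),
        paired_src=src_emb[pairing] if pairing is not None else None,
        paired_tgt=tgt_emb if pairing is not None else None,
        k_eval=k_eval,
        seed=config.seed,
    )

    accuracy, f1_table = None, None
    if tgt_truth is not None:
        shared = set(src_labels.classes) & set(tgt_truth.classes)
        accuracy, f1_table = transfer_accuracy(result, tgt_truth, shared)
        metrics["transfer_accuracy"] = accuracy

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_source": int(n_s),
        "n_target": int(tgt.n_cells),
        "n_features": int(src.n_features),
        "versions": {
            "omicbridge": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
    }

    res = PipelineResult(
        embedding=emb.values, cell_ids=emb.cell_ids, modalities=emb.modalities,
        transfer=result, metrics=metrics, state=state, graph=graph,
        projection=proj, accuracy=accuracy, per_type_f1=f1_table,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(res, Path(outdir))
    return res


def _write_outputs(res: PipelineResult, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    emb_df = pd.DataFrame(res.embedding, index=res.cell_ids)
    emb_df.insert(0, "modality", res.modalities)
    emb_df.index.name = "cell_id"
    emb_df.to_csv(outdir / "embedding.tsv", sep="\t", float_format="%.10g")
    write_transfer_result(res.transfer, outdir / "transfer.tsv")
    (outdir / "metrics.json").write_text(
        json.dumps(res.metrics, indent=2, sort_keys=True) + "\n"
    )
    if res.per_type_f1 is not None:
        res.per_type_f1.to_csv(outdir / "per_type_f1.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(res.manifest, indent=2, sort_keys=True) + "\n"
    )
    save_graph(res.graph, outdir / "hybrid_graph.mtx")


def ablate(
    config: RunConfig,
    components: list[str],
    src: FeatureMatrix,
    src_labels: LabelSet,
    tgt: FeatureMatrix,
    tgt_truth: LabelSet | None = None,
    pairing: np.ndarray | None = None,
) -> pd.DataFrame:
    """Metric deltas (ablated - full) for each named component."""
    full = run_pipeline(config, src, src_labels, tgt, tgt_truth, pairing)
    rows = []
    for comp in components:
        if comp not in ABLATABLE:
            raise ValueError(f"unknown component '{comp}'; options {ABLATABLE}")
        cfg = _ablated_config(config, comp)
        res = run_pipeline(cfg, src, src_labels, tgt, tgt_truth, pairing)
        for key, val in res.metrics.items():
            if key in full.metrics:
                rows.append(
                    {
                        "component": comp,
                        "metric": key,
                        "full": full.metrics[key],
                        "ablated": val,
                        "delta": val - full.metrics[key],
                    }
                )
    return pd.DataFrame(rows)


def _ablated_config(config: RunConfig, component: str) -> RunConfig:
    """Pipeline config with one model component switched off."""
    cfg = dataclasses.replace(config)
    if component == "mmd":
        cfg.lambda_mmd = 0.0
    elif component == "cosine":
        cfg.lambda_cos = 0.0
    elif component == "gcn":
        # no neighborhood aggregation: plain classifier on an edgeless graph
        cfg.single_conv = True
        cfg.identity_graph = True
    elif component == "autoencoder":
        cfg.epochs_stage1 = 0  # untrained AE = fixed random projection
    return cfg


def simulate_and_run(
    config: RunConfig, scenario: SimScenario | str, outdir=None
) -> PipelineResult:
    """Convenience wrapper: simulate a scenario (or preset name) and run."""
    scn = get_preset(scenario, seed=config.seed) if isinstance(scenario, str) else scenario
    src, src_lab, tgt, tgt_lab, pairing = simulate(scn)
    return run_pipeline(config, src, src_lab, tgt, tgt_lab, pairing, outdir=outdir)


def write_simulation(scn: SimScenario, outdir):
    """Write a simulated dataset as MTX triplets + label TSVs + scenario JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .io import write_feature_matrix

    src, src_lab, tgt, tgt_lab, pairing = simulate(scn)
    write_feature_matrix(src, outdir / "source.mtx", outdir / "source_cells.txt",
                         outdir / "source_features.txt")
    write_feature_matrix(tgt, outdir / "target.mtx", outdir / "target_cells.txt",
                         outdir / "target_features.txt")
    write_labels(src_lab, outdir / "source_labels.tsv")
    write_labels(tgt_lab, outdir / "target_labels.tsv")
    scn_dict = dataclasses.asdict(scn)
    scn_dict = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in scn_dict.items()}
    (outdir / "scenario.json").write_text(json.dumps(scn_dict, indent=2) + "\n")
    if pairing is not None:
        np.savetxt(outdir / "pairing.tsv", pairing, fmt="%d")
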