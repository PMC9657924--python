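"""End-to-end orchestration: simulate/read -> QC -> normalize -> impute ->
score -> classify -> characterize, with a JSON manifest for reproducibility.

A single global seed fans out to per-stage seeds by fixed offsets (simulation
+0, diffusion +1, permutation +2, clustering +3), so any stage can be rerun
in isolation with the seed recorded in the manifest. The manifest lists every
written artifact with a SHA-256 checksum, echoes all parameters, and records
cell/gene counts at each stage boundary. A rerun with ``resume=True`` reuses
the cached imputed matrix when the upstream parameters are unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (GeneSetCollection, read_gmt,
                      read_group_map, read_mtx, write_table)
from .characterization import (ClusterParams, cell_entropy, cluster_cells,
                               entropy_by_cluster, marker_summary)
from .imputation import DiffusionParams, build_markov, diffuse
from .preprocess import QCThresholds, compute_qc, filter_cells, lognormalize
from .signature_scoring import ScoringParams, score_matrix
from .synthetic_cohort import SimConfig, demo_tmm_collection, simulate_cohort
from .tmm_classification import PermutationParams, call_tmm_types, tmm_frequency

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("tmm_scell")


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of simulate / inputs is set."""

    outdir: str = "tmm_out"
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: dict | None = None  # matrix / genes / cells paths (+ orientation)
    gmt: str | None = None
    groups: str | None = None
    mito_prefix: str = "MT-"
    qc: QCThresholds = field(default_factory=QCThresholds)
    impute: DiffusionParams = field(default_factory=DiffusionParams)
    score: ScoringParams = field(default_factory=ScoringParams)
    classify: PermutationParams = field(default_factory=PermutationParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of simulate / inputs must be given")


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key in ("outdir", "seed", "gmt", "groups", "mito_prefix", "markers",
                "inputs"):
        if key in raw:
            kwargs[key] = raw[key]
    if "simulate" in raw and raw["simulate"] is not None:
        kwargs["simulate"] = SimConfig(**raw["simulate"])
    sections = {
        "qc": QCThresholds, "impute": DiffusionParams, "score": ScoringParams,
        "classify": PermutationParams, "cluster": ClusterParams,
    }
    for key, cls in sections.items():
        if key in raw and raw[key] is not None:
            kwargs[key] = cls(**raw[key])
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_echo(config: PipelineConfig) -> dict:
    echo = {}
    for key, val in asdict(config).items():
        echo[key] = val
    return echo


def _upstream_hash(config: PipelineConfig) -> str:
    """Hash of everything that determines the imputed matrix."""
    parts = {
        "seed": config.seed,
        "simulate": asdict(config.simulate) if config.simulate else None,
        "inputs": config.inputs,
        "qc": asdict(config.qc),
        "impute": asdict(config.impute),
        "mito_prefix": config.mito_prefix,
    }
    return hashlib.sha256(
        json.dumps(parts, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full analysis; returns the manifest (also written as JSON).

    Any stage failure re-raises with the stage name attached and leaves a
    partial manifest (``failed_stage`` set, artifacts written so far listed)
    in the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[dict] = []
    stages: list[dict] = []
    current = {"stage": "init"}
    manifest_path = outdir / "manifest.json"
    up_hash = _upstream_hash(config)
    try:
        return _run_stages(config, resume, outdir, artifacts, stages,
                           current, manifest_path, up_hash)
    except Exception as exc:
        partial = {
            "version": __version__,
            "seed": config.seed,
            "failed_stage": current["stage"],
            "error": str(exc),
            "parameters": _params_echo(config),
            "stages": stages,
            "artifacts": artifacts,
        }
        manifest_path.write_text(json.dumps(partial, indent=2, default=str))
        raise RuntimeError(f"stage {current['stage']}: {exc}") from exc


def _run_stages(config, resume, outdir, artifacts, stages, current,
                manifest_path, up_hash) -> dict:
    def record(path: Path, stage: str) -> None:
        artifacts.append({
            "path": path.name, "stage": stage, "sha256": _sha256(path),
        })

    def stage_log(stage: str, **info) -> None:
        log.info("stage %s: %s", stage, info)
        stages.append({"stage": stage, **info})

    def begin(stage: str) -> None:
        current["stage"] = stage

    cached = _load_cached(manifest_path, up_hash, outdir) if resume else None
    if cached is not None:
        imputed, gene_ids, cell_ids, truth, sets = cached
        stage_log("resume", reused="imputed matrix", upstream_hash=up_hash)
    else:
        begin("simulate" if config.simulate is not None else "read")
        # ---- acquire counts -------------------------------------------------
        truth = None
        if config.simulate is not None:
            sim_cfg = SimConfig(**{**asdict(config.simulate),
                                   "seed": config.seed})
            sets = _load_sets(config, sim_cfg.n_genes)
            counts, truth = simulate_cohort(sim_cfg, sets)
            write_table(truth, outdir / "truth.tsv")
            record(outdir / "truth.tsv", "simulate")
            stage_log("simulate", n_cells=counts.n_cells, n_genes=counts.n_genes)
        else:
            inp = dict(config.inputs)
            counts = read_mtx(inp["matrix"], inp["genes"], inp["cells"],
                              orientation=inp.get("orientation", "genes-by-cells"))
            sets = _load_sets(config, counts.n_genes)
            stage_log("read", n_cells=counts.n_cells, n_genes=counts.n_genes)

        begin("qc")
        # ---- QC + filter ----------------------------------------------------
        mito = [g for g in counts.gene_ids if g.startswith(config.mito_prefix)]
        qc = compute_qc(counts, mito)
        write_table(qc, outdir / "qc.tsv")
        record(outdir / "qc.tsv", "qc")
        kept = filter_cells(qc, config.qc)
        counts = counts.subset_cells(kept)
        if truth is not None:
            truth = truth[truth["cell_id"].isin(kept)].reset_index(drop=True)
        stage_log("filter", n_cells=counts.n_cells, n_genes=counts.n_genes)
        if counts.n_cells == 0:
            raise RuntimeError("no cells pass QC")

        begin("impute")
        # ---- normalize + impute --------------------------------------------
        norm = lognormalize(counts)
        diff = DiffusionParams(**{**asdict(config.impute),
                                  "seed": config.seed + 1})
        if diff.t > 0:
            markov = build_markov(norm, diff)
            imputed = diffuse(norm, markov, diff.t)
        else:
            imputed = norm
        gene_ids, cell_ids = counts.gene_ids, counts.cell_ids
        _write_matrix(imputed, gene_ids, cell_ids, outdir / "imputed.tsv.gz")
        record(outdir / "imputed.tsv.gz", "impute")
        stage_log("impute", t=diff.t, n_cells=len(cell_ids))

    begin("score")
    # ---- score --------------------------------------------------------------
    result = score_matrix(imputed, gene_ids, cell_ids, sets, config.score)
    scores_out = result.scores.reset_index()
    write_table(scores_out, outdir / "scores.tsv")
    record(outdir / "scores.tsv", "score")
    stage_log("score", n_sets=result.scores.shape[1],
              skipped=len(result.skipped))

    begin("classify")
    # ---- classify -----------------------------------------------------------
    perm = PermutationParams(**{**asdict(config.classify),
                                "seed": config.seed + 2})
    calls, qvalues = call_tmm_types(imputed, gene_ids, cell_ids, sets, perm,
                                    config.score)
    write_table(calls, outdir / "tmm_calls.tsv")
    record(outdir / "tmm_calls.tsv", "classify")
    write_table(qvalues.reset_index(), outdir / "tmm_qvalues.tsv")
    record(outdir / "tmm_qvalues.tsv", "classify")
    if truth is not None:
        freq = tmm_frequency(calls, truth[["cell_id", "cell_type"]])
        write_table(freq, outdir / "tmm_frequency.tsv")
        record(outdir / "tmm_frequency.tsv", "classify")
    counts_by_label = calls["label"].value_counts().to_dict()
    stage_log("classify", **{str(k): int(v) for k, v in counts_by_label.items()})

    begin("characterize")
    # ---- characterize -------------------------------------------------------
    entropy = cell_entropy(np.asarray(imputed) + 1e-12)
    clus = ClusterParams(**{**asdict(config.cluster), "seed": config.seed + 3})
    labels = cluster_cells(imputed, clus)
    ent_table = entropy_by_cluster(entropy, labels, calls)
    write_table(ent_table, outdir / "entropy_by_cluster.tsv")
    record(outdir / "entropy_by_cluster.tsv", "characterize")
    if config.markers:
        mk = marker_summary(imputed, gene_ids, config.markers, calls)
        write_table(mk, outdir / "marker_summary.tsv")
        record(outdir / "marker_summary.tsv", "characterize")
    stage_log("characterize", n_clusters=clus.n_clusters)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "upstream_hash": up_hash,
        "parameters": _params_echo(config),
        "stages": stages,
        "artifacts": artifacts,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _load_sets(config: PipelineConfig, n_genes: int) -> GeneSetCollection:
    if config.gmt is not None:
        mapping = read_group_map(config.groups) if config.groups else None
        return read_gmt(config.gmt, mapping)
    return demo_tmm_collection(n_genes)


def _write_matrix(matrix, gene_ids, cell_ids, path: Path) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(cell_ids),
                      columns=list(gene_ids))
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t", float_format="%.8g")


def _load_cached(manifest_path: Path, up_hash: str, outdir: Path):
    """Reload the imputed matrix from a previous run when parameters match."""
    if not manifest_path.exists():
        return None
    try:
        old = json.loads(manifest_path.read_text())
    except json.JSONDecodeError:
        return None
    if old.get("upstream_hash") != up_hash:
        return None
    imputed_path = outdir / "imputed.tsv.gz"
    truth_path = outdir / "truth.tsv"
    if not imputed_path.exists():
        return None
    df = pd.read_csv(imputed_path, sep="\t", index_col="cell_id")
    gene_ids = list(df.columns)
    cell_ids = [str(c) for c in df.index]
    truth = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        truth = truth[truth["cell_id"].isin(cell_ids)].reset_index(drop=True)
    sets = None
    cfg_gmt = old.get("parameters", {}).get("gmt")
    if cfg_gmt:
        mapping_path = old.get("parameters", {}).get("groups")
        mapping = read_group_map(mapping_path) if mapping_path else None
        sets = read_gmt(cfg_gmt, mapping)
    else:
        sets = demo_tmm_collection(len(gene_ids))
    return df.to_numpy(), gene_ids, cell_ids, truth, sets
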