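"""End-to-end orchestration: adjust, contrast, score TFs, filter trios, export.

Stages run strictly in order — data adjustment, differential expression,
TF impact scoring, trio filtering, network assembly — and every stage logs
its input/output dimensions. Any stage failure aborts with an error naming
the stage. A manifest echoing the configuration makes a run reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexp import classify_de, reverter_diff
from .network import build_networks, hri_table, write_edges_tsv, write_sif
from .pcit import pcit_per_condition
from .preprocess import preprocess, read_expression
from .rif import build_rif_input, rif_scores, significant_tfs
from .types import ConditionDesign, ExpressionMatrix, TFCatalog

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_analysis", "PipelineError"]


@dataclass
class AnalysisResult:
    """In-memory results of the full stage chain."""

    norm: ExpressionMatrix
    diff: pd.DataFrame
    de: object
    rif: pd.DataFrame
    sig_tfs: list[str]
    net_ref: object
    net_alt: object
    hri: pd.DataFrame


def analyze(
    m: ExpressionMatrix,
    design: ConditionDesign,
    tfs: TFCatalog,
    de_cutoff: float = 1.96,
    rif_cutoff: float = 1.96,
    pcit_node_policy: str = "de_plus_sig_tfs",
    pcit_variant: str = "corrected",
) -> AnalysisResult:
    """Run the stage chain on in-memory inputs; no files written."""
    norm, _ = preprocess(m)
    diff = reverter_diff(norm, design)
    de = classify_de(diff, de_cutoff, tfs)
    rif = rif_scores(build_rif_input(norm, de, tfs, design))
    sig = significant_tfs(rif, rif_cutoff)
    tf_pool = sig if pcit_node_policy == "de_plus_sig_tfs" else tfs.present_in(norm)[0]
    nodes = list(dict.fromkeys(de.de_genes + list(tf_pool)))
    p_ref, p_alt = pcit_per_condition(norm, design, nodes, variant=pcit_variant)
    net_ref, net_alt = build_networks(
        p_ref, p_alt, tfs, labels=(design.reference, design.alternate)
    )
    hri = hri_table(net_ref, net_alt, rif)
    return AnalysisResult(norm, diff, de, rif, sig, net_ref, net_alt, hri)


class PipelineError(RuntimeError):
    """Stage failure; ``stage`` names the step that raised."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    input: str
    design: str
    tf_catalog: str
    outdir: str
    fmt: str = "tsv"  # tsv | csv | mtx
    kind: str = "counts"  # counts | normalized
    row_names: str | None = None
    col_names: str | None = None
    reference: str | None = None
    de_cutoff: float = 1.96
    rif_cutoff: float = 1.96
    pcit_node_policy: str = "de_plus_sig_tfs"  # or de_plus_all_tfs
    pcit_variant: str = "corrected"  # or as_printed
    hri_all_tfs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.de_cutoff <= 0 or self.rif_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.pcit_node_policy not in ("de_plus_sig_tfs", "de_plus_all_tfs"):
            raise ValueError(f"unknown pcit_node_policy {self.pcit_node_policy!r}")


def _float_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_analysis(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the whole pipeline, writing every artifact under ``cfg.outdir``.

    Returns a name -> path map of the written artifacts.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        log.info("stage %s", name)
        return name

    # --- data adjustment -------------------------------------------------
    name = stage("preprocess")
    try:
        raw = read_expression(cfg.input, cfg.fmt, cfg.kind, cfg.row_names, cfg.col_names)
        design = ConditionDesign.from_file(cfg.design, cfg.reference)
        design.check_covers(raw.sample_ids)
        tfs = TFCatalog.from_file(cfg.tf_catalog)
        _, absent = tfs.present_in(raw)
        if absent:
            log.warning("%d catalog TFs absent from the matrix: %s",
                        len(absent), ", ".join(absent[:10]))
        norm, report = preprocess(raw)
        log.info("preprocess: %d -> %d genes, %d samples", raw.n_genes, norm.n_genes,
                 norm.n_samples)
        artifacts["normalized_matrix"] = outdir / "normalized_matrix.tsv"
        _float_csv(norm.to_frame(), artifacts["normalized_matrix"], index_label="gene")
        artifacts["filter_report"] = outdir / "filter_report.tsv"
        report.write_tsv(artifacts["filter_report"])
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError(name, e) from e

    # --- differential expression ----------------------------------------
    name = stage("diffexp")
    try:
        diff = reverter_diff(norm, design)
        de = classify_de(diff, cfg.de_cutoff, tfs)
        counts = de.counts()
        log.info("diffexp: %(up)d up, %(down)d down, %(ns)d ns", counts)
        artifacts["diff_table"] = outdir / "diff_table.tsv"
        _float_csv(diff, artifacts["diff_table"])
        artifacts["de_classification"] = outdir / "de_classification.tsv"
        _float_csv(de.frame, artifacts["de_classification"])
    except Exception as e:
        raise PipelineError(name, e) from e

    # --- TF impact scores ------------------------------------------------
    name = stage("rif")
    try:
        rif_in = build_rif_input(norm, de, tfs, design)
        rif = rif_scores(rif_in)
        sig = significant_tfs(rif, cfg.rif_cutoff)
        log.info("rif: %d TFs scored, %d significant", len(rif), len(sig))
        artifacts["rif_table"] = outdir / "rif_table.tsv"
        _float_csv(rif, artifacts["rif_table"])
        artifacts["significant_tfs"] = outdir / "significant_tfs.txt"
        artifacts["significant_tfs"].write_text("".join(t + "\n" for t in sig))
    except Exception as e:
        raise PipelineError(name, e) from e

    # --- trio filtering --------------------------------------------------
    name = stage("pcit")
    try:
        tf_pool = sig if cfg.pcit_node_policy == "de_plus_sig_tfs" else list(
            tfs.present_in(norm)[0]
        )
        node_set = list(dict.fromkeys(de.de_genes + [t for t in tf_pool]))
        if len(node_set) < 2:
            raise ValueError("fewer than 2 nodes selected for network reconstruction")
        p_ref, p_alt = pcit_per_condition(norm, design, node_set, variant=cfg.pcit_variant)
        log.info("pcit: %d nodes, %d/%d significant pairs (ref/alt)",
                 len(node_set), len(p_ref.edges()), len(p_alt.edges()))
    except Exception as e:
        raise PipelineError(name, e) from e

    # --- network assembly ------------------------------------------------
    name = stage("network")
    try:
        net_ref, net_alt = build_networks(
            p_ref, p_alt, tfs, labels=(design.reference, design.alternate)
        )
        for net in (net_ref, net_alt):
            artifacts[f"edges_{net.condition}"] = outdir / f"edges_{net.condition}.tsv"
            write_edges_tsv(net, artifacts[f"edges_{net.condition}"])
            artifacts[f"sif_{net.condition}"] = outdir / f"edges_{net.condition}.sif"
            write_sif(net, artifacts[f"sif_{net.condition}"])
        hri = hri_table(net_ref, net_alt, rif, significant_only=not cfg.hri_all_tfs)
        artifacts["hri_table"] = outdir / "hri_table.tsv"
        _float_csv(hri, artifacts["hri_table"])
    except Exception as e:
        raise PipelineError(name, e) from e

    # --- manifest --------------------------------------------------------
    manifest = {
        "config": asdict(cfg),
        "versions": {
            "regwire": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": cfg.seed,
        "dimensions": {
            "input_genes": raw.n_genes,
            "filtered_genes": norm.n_genes,
            "samples": norm.n_samples,
            "de_genes": len(de.de_genes),
            "tfs_scored": int(len(rif)),
            "tfs_significant": len(sig),
            "network_nodes": len(node_set),
            "edges_ref": len(p_ref.edges()),
            "edges_alt": len(p_alt.edges()),
        },
    }
    artifacts["manifest"] = outdir / "manifest.json"
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return artifacts
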