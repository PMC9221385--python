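"""End-to-end orchestration driven by a single YAML config.

Stages run in fixed order — data (synthetic or user files) -> log/z
transform -> signature derivation -> signature comparison -> genotype
contrasts -> embedding -> recovery metrics (when ground truth exists) —
and every numeric in the report is reproducible from config + seed +
inputs. Any stage failure aborts with the stage name; pre-flight
validation of input paths touches no output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import (
    AnalysisConfig,
    ExpressionMatrix,
    GeneSet,
    SampleAnnotation,
    ValidationError,
    ensure_log2,
    read_expression_matrix,
    read_gmt,
    read_sample_annotation,
    write_expression_matrix,
    write_gmt,
    write_sample_annotation,
)
from .simulate import SyntheticConfig, SyntheticTruth, generate_dataset, truth_recall_precision
from .derive import BaitSignatureDeriver, Signature
from .compare import compare_signatures
from .contrast import contrast_groups, zscore
from .embedding import embed_samples

logger = logging.getLogger("baitsig")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict):
        raise ValidationError("pipeline config must be a mapping")
    return cfg


def _preflight(cfg: dict) -> None:
    """Validate inputs before any computation or output writing."""
    if "synthetic" in cfg:
        SyntheticConfig(**cfg["synthetic"])  # raises on infeasible config
        return
    inputs = cfg.get("inputs")
    if not inputs:
        raise ValidationError("config needs either a 'synthetic' block or an 'inputs' block")
    for key in ("matrix", "metadata", "baits"):
        if key not in inputs:
            raise ValidationError(f"inputs block missing required key {key!r}")
        if not Path(inputs[key]).exists():
            raise ValidationError(f"input file for {key!r} not found: {inputs[key]}")
    if "references" in cfg and not Path(cfg["references"]).exists():
        raise ValidationError(f"references GMT not found: {cfg['references']}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("data")
def _load_data(cfg: dict):
    if "synthetic" in cfg:
        scfg = SyntheticConfig(**cfg["synthetic"])
        matrix, ann, truth = generate_dataset(scfg)
        baits = GeneSet("baits", "synthetic baits", frozenset(truth.bait_ids))
        return matrix, ann, baits, truth
    inputs = cfg["inputs"]
    matrix = read_expression_matrix(inputs["matrix"], inputs.get("scale", "linear"))
    ann = read_sample_annotation(inputs["metadata"])
    bait_sets = read_gmt(inputs["baits"])
    if not bait_sets:
        raise ValidationError(f"no gene sets in {inputs['baits']}")
    return matrix, ann, bait_sets[0], None


def run_pipeline(config: str | Path | dict, output_dir: str | Path | None = None) -> dict:
    """Run all stages and return the report dict (also written to
    ``<output_dir>/report.json`` plus TSV/GMT artifacts when an output
    directory is configured)."""
    cfg = _load_config(config)
    _preflight(cfg)

    analysis = AnalysisConfig(**cfg.get("analysis", {}))
    seed = int(cfg.get("seed", analysis.random_seed))

    matrix, ann, baits, truth = _load_data(cfg)
    log_m = ensure_log2(matrix, analysis.log_pseudocount)

    deriver = _stage("derive")(lambda: BaitSignatureDeriver(
        baits=sorted(baits.members),
        r_threshold=analysis.r_threshold,
        p_threshold=analysis.p_threshold,
        min_overlap_k=analysis.min_overlap_k,
        top_overlap_k=analysis.top_overlap_k,
        direction=analysis.direction,
    ).fit(log_m))()
    signature = deriver.signature_
    top_signature = deriver.top_signature_

    # Comparison stage: user-supplied references, or truth-derived sets on
    # synthetic data so the stage is always exercised.
    universe = set(log_m.gene_ids)
    if "references" in cfg:
        refs = read_gmt(cfg["references"])
    elif truth is not None:
        refs = [
            GeneSet("planted-module", "ground-truth module", frozenset(truth.module_ids)),
            GeneSet("background-50", "first 50 background genes",
                    frozenset(truth.background_ids[:50])),
        ]
    else:
        refs = []
    overlap_block = None
    if refs:
        report_cmp = _stage("compare")(compare_signatures)(signature, refs, universe)
        overlap_block = {
            "per_reference": {
                name: {k: (float(v) if k != "intersection_size" else int(v))
                       for k, v in row.items()}
                for name, row in report_cmp.per_reference.iterrows()
            },
            "union_coverage": float(report_cmp.union_coverage),
            "universe_size": int(report_cmp.universe_size),
        }

    # Contrast stage on HIF target panels (truth panels on synthetic data,
    # user GMT otherwise) against the configured reference group.
    z = _stage("zscore")(zscore)(log_m, analysis.z_ddof)
    reference_group = cfg.get("reference_group", "normal")
    panels: list[GeneSet] = []
    if "panels" in cfg:
        panels = read_gmt(cfg["panels"])
    elif truth is not None:
        panels = [
            GeneSet("HIF1A-targets", "planted HIF1a panel", frozenset(truth.hif1_panel_ids)),
            GeneSet("HIF2A-targets", "planted HIF2a panel", frozenset(truth.hif2_panel_ids)),
        ]
    contrast_tables: dict[str, pd.DataFrame] = {}
    contrast_block = {}
    for panel in panels:
        tbl = _stage("contrast")(contrast_groups)(z, ann, panel, reference_group)
        contrast_tables[panel.name] = tbl
        sig_frac = (
            tbl.assign(sig=(tbl["p_adj"] < 0.01) & (tbl["direction"] > 0))
            .groupby("group")["sig"].mean()
        )
        contrast_block[panel.name] = {g: float(v) for g, v in sig_frac.items()}

    # Embedding stage on the derived signature (fall back to the full
    # signature if the top-ranking subset is too small to embed).
    emb_cfg = cfg.get("embedding", {})
    perplexity = float(emb_cfg.get("perplexity", 10.0))
    emb_sig = top_signature if len(top_signature) >= 2 else signature
    embedding_block = None
    if len(emb_sig) >= 2:
        emb = _stage("embed")(embed_samples)(z, emb_sig, ann, perplexity=perplexity, seed=seed)
        embedding_block = {
            "signature": emb_sig.name,
            "parameters": emb.parameters,
            "silhouette_pseudohypoxic_vs_other": float(emb.silhouette),
            "silhouette_by_grouping": {k: float(v) for k, v in emb.silhouette_by_grouping.items()},
        }

    recovery_block = None
    if truth is not None:
        recall, precision = truth_recall_precision(signature, truth)
        recovery_block = {"recall": float(recall), "precision": float(precision),
                          "module_size": len(truth.module_ids)}

    report = {
        "tool": {"name": "baitsig", "version": __version__},
        "config": {
            "analysis": analysis.to_dict(),
            "seed": seed,
            "synthetic": cfg.get("synthetic"),
            "inputs": cfg.get("inputs"),
            "reference_group": reference_group,
        },
        "signature": {
            "name": signature.name,
            "size": len(signature),
            "members": list(signature.members),
            "top_ranking_size": len(top_signature),
            "top_ranking_members": list(top_signature.members),
            "provenance": signature.provenance,
        },
        "overlap": overlap_block,
        "contrast": contrast_block,
        "embedding": embedding_block,
        "recovery": recovery_block,
        "timestamps": {"completed": datetime.now(timezone.utc).isoformat()},
    }

    out_dir = output_dir or cfg.get("output_dir")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        write_gmt([signature.to_geneset(), top_signature.to_geneset()], out / "signatures.gmt")
        deriver.overlap_counts_.sort_values(ascending=False).to_csv(
            out / "overlap_counts.tsv", sep="\t", header=["overlap_count"], index_label="gene")
        for name, tbl in contrast_tables.items():
            tbl.to_csv(out / f"contrast_{name}.tsv", sep="\t", index=False)
        if truth is not None:
            write_expression_matrix(matrix, out / "expression.tsv")
            write_sample_annotation(ann, out / "samples.tsv")
            with open(out / "truth.json", "w") as fh:
                json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
    return report


def demo_config(seed: int = 1) -> dict:
    """The default demo: synthetic cohort at the stated-world defaults."""
    return {
        "synthetic": asdict(SyntheticConfig(seed=seed)),
        "analysis": {"random_seed": seed},
        "seed": seed,
        "reference_group": "normal",
        "embedding": {"perplexity": 10.0},
    }
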