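"""End-to-end orchestration: load -> collapse -> DEG -> cascade -> enrichment.

``run_pipeline`` executes the full analysis for one dataset and writes all
tables plus a run manifest (config echo, seed, package versions, stage
timings, per-stage gene counts, and a SHA-256 checksum of every output
file). Identical config and seed yield byte-identical outputs; inputs are
never mutated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

import senosyn

from .data_model import (
    Arm,
    DPTS,
    ExpressionDataset,
    Level,
    collapse_probes_iqr,
    read_expression,
    read_gmt,
    read_probe_map,
)
from .permnull import Comparison, DEGThresholds, DEGTable, build_null, call_degs
from .cascade import CascadeResult, run_cascade
from .enrichment import enrich, write_enrichment_tsv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "required_comparisons", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; all fields have explicit defaults."""

    matrix_path: str = ""
    design_path: str = ""
    probe_map_path: str = ""  # empty: data already at gene level
    gmt_process_path: str = ""  # empty: skip process enrichment
    gmt_tf_path: str = ""  # empty: skip TF enrichment
    outdir: str = "pipeline_out"
    seed: int = 0
    n_perm: int = 10_000
    estimator: str = "kde"  # kde | gaussian_fit
    variance: str = "pooled"  # pooled | welch
    alpha: float = 0.05
    lfc_cutoff: float = 0.58
    restoration_mode: str = "opposite"  # opposite | strict
    synag_mode: str = "and"  # and | or
    major_min: int = 10  # groups must exceed this strictly
    count_min_process: int = 3
    count_min_tf: int = 1


@dataclass
class PipelineResult:
    dataset: ExpressionDataset
    deg_tables: dict[str, DEGTable]
    cascade: CascadeResult
    enrichment: dict[str, dict[str, list]]
    manifest: dict


def required_comparisons() -> list[tuple[str, Comparison, int]]:
    """All (key, comparison, dpt) triples the cascade consumes."""
    out: list[tuple[str, Comparison, int]] = []
    for dpt in DPTS:
        out.append(
            (f"old_vs_young_dpt{dpt}",
             Comparison(f"old/young@{dpt}", Arm.OLD_DMSO, Arm.YOUNG, dpt, None), dpt)
        )
    for drug, arm in (("KU", Arm.OLD_KU), ("Y", Arm.OLD_Y), ("KUY", Arm.OLD_KUY)):
        for dpt in DPTS:
            out.append(
                (f"{drug}_vs_dmso_dpt{dpt}",
                 Comparison(f"{drug}/DMSO@{dpt}", arm, Arm.OLD_DMSO, dpt, dpt), dpt)
            )
    for single, arm in (("KU", Arm.OLD_KU), ("Y", Arm.OLD_Y)):
        for dpt in DPTS:
            out.append(
                (f"KUY_vs_{single}_dpt{dpt}",
                 Comparison(f"KU+Y/{single}@{dpt}", Arm.OLD_KUY, arm, dpt, dpt), dpt)
            )
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def compute_deg_tables(
    dataset: ExpressionDataset, cfg: PipelineConfig
) -> dict[str, DEGTable]:
    """One DEG table per required comparison, each with its own empirical null."""
    thr = DEGThresholds(alpha=cfg.alpha, lfc_cutoff=cfg.lfc_cutoff)
    tables: dict[str, DEGTable] = {}
    for i, (key, cmp, _) in enumerate(required_comparisons()):
        null = build_null(
            dataset, cmp, n_perm=cfg.n_perm, seed=cfg.seed + i,
            estimator=cfg.estimator, variance=cfg.variance,  # type: ignore[arg-type]
        )
        tables[key] = call_degs(dataset, cmp, null, thr)
        logger.info(
            "DEG %-22s significant=%d (null: %s, %d perms%s)",
            key, len(tables[key].significant()), cfg.estimator, null.n_perm,
            ", exhaustive" if null.exhaustive else "",
        )
    return tables


def cascade_from_tables(tables: dict[str, DEGTable], cfg: PipelineConfig) -> CascadeResult:
    old_young = {d: tables[f"old_vs_young_dpt{d}"] for d in DPTS}
    drug_dmso = {
        (drug, d): tables[f"{drug}_vs_dmso_dpt{d}"]
        for drug in ("KU", "Y", "KUY") for d in DPTS
    }
    kuy_ku = {d: tables[f"KUY_vs_KU_dpt{d}"] for d in DPTS}
    kuy_y = {d: tables[f"KUY_vs_Y_dpt{d}"] for d in DPTS}
    return run_cascade(
        old_young, drug_dmso, kuy_ku, kuy_y,
        restoration_mode=cfg.restoration_mode,  # type: ignore[arg-type]
        synag_mode=cfg.synag_mode,  # type: ignore[arg-type]
        major_min=cfg.major_min,
        lfc_cutoff=cfg.lfc_cutoff,
    )


def run_pipeline(
    cfg: PipelineConfig, dataset: ExpressionDataset | None = None
) -> PipelineResult:
    """Run the full analysis; ``dataset`` overrides the config input paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    if dataset is None:
        if not cfg.matrix_path or not cfg.design_path:
            raise ValueError("config must set matrix_path and design_path")
        level = Level.PROBE if cfg.probe_map_path else Level.GENE
        dataset = read_expression(cfg.matrix_path, cfg.design_path, level=level)
        if cfg.probe_map_path:
            dataset = collapse_probes_iqr(dataset, read_probe_map(cfg.probe_map_path))
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tables = compute_deg_tables(dataset, cfg)
    timings["deg"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cascade = cascade_from_tables(tables, cfg)
    timings["cascade"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    enrichment_out: dict[str, dict[str, list]] = {}
    universe = dataset.feature_ids
    for kind, path, count_min in (
        ("process", cfg.gmt_process_path, cfg.count_min_process),
        ("tf", cfg.gmt_tf_path, cfg.count_min_tf),
    ):
        if not path:
            continue
        collection = read_gmt(path, universe=universe)
        enrichment_out[kind] = {}
        for label, genes in sorted(cascade.major_groups.items()):
            enrichment_out[kind][label] = enrich(
                genes, collection, count_min=count_min, alpha=cfg.alpha
            )
    timings["enrichment"] = time.perf_counter() - t0

    # write outputs
    t0 = time.perf_counter()
    outputs: list[Path] = []
    for key, table in sorted(tables.items()):
        p = outdir / f"deg_{key}.tsv"
        table.write_tsv(p)
        outputs.append(p)
    p = outdir / "cascade.json"
    cascade.to_json(p)
    outputs.append(p)
    for stage, genes in [
        ("sags", sorted(cascade.sags)),
        *[(f"dags_{d}", sorted(g)) for d, g in sorted(cascade.dags.items())],
        *[(f"synags_dpt{d}", sorted(h)) for d, h in sorted(cascade.synags.items())],
    ]:
        p = outdir / f"genes_{stage}.tsv"
        p.write_text("gene_id\n" + "".join(f"{g}\n" for g in genes))
        outputs.append(p)
    p = outdir / "venn_counts.tsv"
    p.write_text(
        "region\tcount\n"
        + "".join(f"{k}\t{v}\n" for k, v in cascade.venn.items())
    )
    outputs.append(p)
    for kind, per_group in enrichment_out.items():
        for label, records in per_group.items():
            p = outdir / f"enrichment_{kind}_{label}.tsv"
            write_enrichment_tsv(records, p)
            outputs.append(p)
    timings["write"] = time.perf_counter() - t0

    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "versions": {
            "senosyn": senosyn.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "n_features": dataset.n_features,
        "n_samples": dataset.n_samples,
        "stage_counts": cascade.stage_counts(),
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    logger.info("pipeline funnel: %s", manifest["stage_counts"])
    return PipelineResult(dataset, tables, cascade, enrichment_out, manifest)
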