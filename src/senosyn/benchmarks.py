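"""Validation benchmarks: calibration, exact oracles, planted-truth recovery.

Each function here re-runs a slice of the pipeline under controlled synthetic
conditions and returns a scalar quality metric, so the statistical behavior
of the method can be verified end to end:

* false-positive calibration of the permutation empirical null,
* agreement of the smoothed p-value with the exhaustive permutation fraction,
* exactness of the hypergeometric tail against rational arithmetic,
* sensitivity/FDR of the cascade against planted truth,
* CDI algebraic identities and round trips,
* nesting/partition invariants and byte-level determinism of full runs.
"""

from __future__ import annotations

import hashlib
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Arm, DPTS, ExpressionDataset
from .permnull import Comparison, DEGThresholds, build_null, call_degs
from .pipeline import PipelineConfig, compute_deg_tables, cascade_from_tables, run_pipeline
from .enrichment import hypergeom_upper
from .simulate import SimConfig, simulate_expression, simulate_phenotypes
from .synergy import cdi, cdi_from_panel

__all__ = [
    "null_calibration_fraction",
    "perm_oracle_max_deviation",
    "exact_hypergeom_upper",
    "hypergeom_oracle_max_rel_error",
    "planted_truth_recovery",
    "cdi_identity_max_error",
    "cdi_roundtrip_max_error",
    "pipeline_invariants_and_determinism",
]

_CMP = Comparison("old/young@3", Arm.OLD_DMSO, Arm.YOUNG, 3, None)


def null_calibration_fraction(
    seed: int,
    n_genes: int = 2000,
    n_replicates: int = 4,
    sigma: float = 0.25,
    n_perm: int = 1000,
) -> float:
    """Fraction of genes called p < 0.05 on a dataset with no planted effects."""
    cfg = SimConfig(
        n_genes=n_genes, n_replicates=n_replicates, sigma_noise=sigma,
        frac_sag=0.0, seed=seed,
    )
    dataset, _ = simulate_expression(cfg)
    null = build_null(dataset, _CMP, n_perm=n_perm, seed=seed)
    table = call_degs(dataset, _CMP, null, DEGThresholds())
    return float((table.frame["p"] < 0.05).mean())


def _balanced_dataset(rng: np.random.Generator, n_genes: int, r: int) -> ExpressionDataset:
    values = rng.normal(size=(n_genes, 2 * r))
    rows = []
    for j in range(2 * r):
        arm = "OLD_DMSO" if j < r else "YOUNG"
        rows.append((f"s{j}", arm, 3 if j < r else 0, j % r + 1))
    design = pd.DataFrame(rows, columns=["sample_id", "arm", "dpt", "replicate"])
    matrix = pd.DataFrame(
        values, index=pd.Index([f"g{i}" for i in range(n_genes)], name="feature_id"),
        columns=design["sample_id"],
    )
    return ExpressionDataset(values=matrix, design=design)


def perm_oracle_max_deviation(seed: int, n_genes: int = 100) -> float:
    """Max |KDE p - exhaustive permutation two-tailed fraction| per gene.

    For 2-vs-2 and 3-vs-3 designs every distinct label assignment is
    enumerated, so the pooled permutation two-tailed fraction is exact; the
    smoothed empirical p should track it gene by gene.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for r in (2, 3):
        dataset = _balanced_dataset(rng, n_genes, r)
        null = build_null(dataset, _CMP, n_perm=10_000, seed=seed)
        assert null.exhaustive
        table = call_degs(dataset, _CMP, null, DEGThresholds())
        abs_pool = np.abs(null.pooled_t)
        for t_obs, p in zip(table.frame["t"], table.frame["p"]):
            frac = float(np.mean(abs_pool >= abs(t_obs) - 1e-12))
            worst = max(worst, abs(p - frac))
    return worst


def exact_hypergeom_upper(k: int, n: int, K: int, N: int) -> Fraction:
    """Rational-arithmetic Pr(X >= k), the independent combinatorial oracle."""
    total = comb(N, n)
    return sum(
        (Fraction(comb(K, i) * comb(N - K, n - i), total)
         for i in range(k, min(n, K) + 1)),
        Fraction(0),
    )


def hypergeom_oracle_max_rel_error(n_max: int = 60) -> float:
    """Max relative error of the log-space tail vs exact enumeration, N <= n_max."""
    worst = 0.0
    for N in range(2, n_max + 1, 7):
        for K in range(0, N + 1, max(1, N // 5)):
            for n in range(1, N + 1, max(1, N // 5)):
                for k in range(0, min(n, K) + 1):
                    expect = float(exact_hypergeom_upper(k, n, K, N))
                    got = hypergeom_upper(k, n, K, N)
                    if expect > 0:
                        worst = max(worst, abs(got - expect) / expect)
    return worst


def planted_truth_recovery(
    seed: int, sim: SimConfig | None = None, n_perm: int = 1000
) -> tuple[float, float]:
    """(sensitivity, FDR) of recovered SynAGs vs planted truth, per (gene, DPT)."""
    cfg = sim if sim is not None else SimConfig(seed=seed)
    if cfg.seed != seed:
        cfg = SimConfig(**{**cfg.__dict__, "seed": seed})
    dataset, truth = simulate_expression(cfg)
    pcfg = PipelineConfig(seed=seed, n_perm=n_perm)
    tables = compute_deg_tables(dataset, pcfg)
    cascade = cascade_from_tables(tables, pcfg)
    truth_sets = truth.synags_by_dpt()
    tp = fp = fn = 0
    for dpt in DPTS:
        planted = set(truth_sets[dpt])
        found = set(cascade.synags[dpt])
        tp += len(planted & found)
        fp += len(found - planted)
        fn += len(planted - found)
    sensitivity = tp / (tp + fn) if tp + fn else 1.0
    fdr = fp / (tp + fp) if tp + fp else 0.0
    return sensitivity, fdr


def cdi_identity_max_error(seed: int, n: int = 1000) -> float:
    """Max |CDI(A*B, A, B) - 1| over random positive efficacies."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n):
        A, B = rng.uniform(0.05, 20.0, size=2)
        value, _ = cdi(A * B, A, B)
        worst = max(worst, abs(value - 1.0))
    return worst


def cdi_roundtrip_max_error(seed: int, n: int = 50) -> float:
    """Max |recovered - target| CDI from zero-noise simulated phenotype panels."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n):
        effA, effB = rng.uniform(0.2, 3.0, size=2)
        target = rng.uniform(0.3, 3.0)
        panel = simulate_phenotypes(effA, effB, target, noise_cv=0.0)
        (rec,) = cdi_from_panel(panel)
        worst = max(worst, abs(rec.cdi - target))
    return worst


def pipeline_invariants_and_determinism(
    seed: int, workdir: str | Path, n_genes: int = 300, n_perm: int = 300
) -> dict[str, float]:
    """Run the pipeline twice; check nesting, partition, and byte-identity."""
    dataset, _ = simulate_expression(
        SimConfig(n_genes=n_genes, n_replicates=3, seed=seed)
    )
    workdir = Path(workdir)
    digests = []
    results = []
    for tag in ("a", "b"):
        cfg = PipelineConfig(outdir=str(workdir / tag), seed=seed, n_perm=n_perm)
        res = run_pipeline(cfg, dataset=dataset)
        results.append(res)
        digest = hashlib.sha256()
        for name in sorted(res.manifest["outputs"]):
            digest.update((workdir / tag / name).read_bytes())
        digests.append(digest.hexdigest())

    cascade = results[0].cascade
    cascade.check_nesting()  # raises on violation
    group_total = sum(len(v) for v in cascade.groups.values())
    return {
        "nesting_ok": 1.0,
        "partition_ok": float(group_total == len(cascade.synag_union)),
        "byte_identical": float(digests[0] == digests[1]),
    }
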