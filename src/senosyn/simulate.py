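"""Synthetic expression and phenotype data with planted, known truth.

The generator emulates the study design the pipeline targets: five condition
arms — young (low-passage) fibroblasts plus senescent cells under DMSO, KU,
Y, or KU+Y — sampled at 3, 8, and 15 days post treatment with replicates, on
the log2 intensity scale with additive Gaussian noise (the standard model
for normalized log-intensity microarray data).

Effects compose per gene:

* planted **SAGs** shift all senescent arms by ``delta_sen`` (log2, signed);
* planted **DAGs** have ``delta_restore * delta_sen`` subtracted back toward
  the young baseline in every treated arm (KU, Y, and KU+Y share one
  restoration program, so combination-vs-single contrasts isolate synergy);
* planted **SynAGs** additionally shift the KU+Y arm by ``delta_syn`` in a
  planted direction at planted timepoints, with temporal patterns drawn
  from the seven major single-direction patterns.

Truth labels are returned alongside the matrix and respect the cascade
nesting (SynAG => DAG_KUY => SAG), so recovery of the planted structure can
be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Arm, DPTS, ExpressionDataset, Level
from .cascade import MAJOR_PATTERNS

__all__ = ["SimConfig", "SimTruth", "simulate_expression", "simulate_phenotypes"]

#: Default pattern weights: the seven major-group sizes observed in the
#: reference time course (EML-UP, ML-UP, M-UP, L-UP, E-DOWN, M-DOWN, L-DOWN).
DEFAULT_PATTERN_WEIGHTS = (10.0, 68.0, 105.0, 377.0, 11.0, 10.0, 314.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted-effect expression simulator (log2 scale)."""

    n_genes: int = 2000
    n_replicates: int = 4
    baseline_range: tuple[float, float] = (6.0, 12.0)
    sigma_noise: float = 0.25
    frac_sag: float = 0.2
    frac_dag_given_sag: float = 0.5
    frac_synag_given_dag: float = 0.5
    delta_sen: float = 2.0
    delta_restore: float = 0.75
    delta_syn: float = 1.0
    pattern_weights: tuple[float, ...] = DEFAULT_PATTERN_WEIGHTS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_sag", "frac_dag_given_sag", "frac_synag_given_dag"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if len(self.pattern_weights) != len(MAJOR_PATTERNS):
            raise ValueError(
                f"pattern_weights needs {len(MAJOR_PATTERNS)} entries"
            )


@dataclass
class SimTruth:
    """Planted labels per gene; nesting mirrors the selection cascade."""

    sag_direction: dict[str, str]  # gene -> U/D for planted SAGs
    dags: dict[str, set[str]]  # drug -> planted restored genes
    synag_pattern: dict[str, tuple[str, str, str]]  # gene -> per-DPT U/D/N

    @property
    def sags(self) -> set[str]:
        return set(self.sag_direction)

    def synags_by_dpt(self) -> dict[int, dict[str, str]]:
        out: dict[int, dict[str, str]] = {d: {} for d in DPTS}
        for gene, pattern in self.synag_pattern.items():
            for dpt, s in zip(DPTS, pattern):
                if s != "N":
                    out[dpt][gene] = s
        return out

    def check_nesting(self) -> None:
        assert set(self.synag_pattern) <= self.dags["KUY"] <= self.sags

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sag_direction": dict(sorted(self.sag_direction.items())),
            "dags": {d: sorted(g) for d, g in self.dags.items()},
            "synag_pattern": {
                g: list(p) for g, p in sorted(self.synag_pattern.items())
            },
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


_DRUG_ARM = {"KU": Arm.OLD_KU, "Y": Arm.OLD_Y, "KUY": Arm.OLD_KUY}


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionDataset, SimTruth]:
    """Simulate a gene-level dataset for the five-arm time course.

    Identical config (including seed) yields a bit-identical matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    baseline = rng.uniform(*cfg.baseline_range, size=cfg.n_genes)

    # plant the nested truth: SAG -> per-drug DAG -> SynAG with a pattern
    n_sag = round(cfg.frac_sag * cfg.n_genes)
    sag_idx = rng.choice(cfg.n_genes, size=n_sag, replace=False)
    sag_sign = rng.choice([1.0, -1.0], size=n_sag)
    sag_direction = {
        genes[i]: ("U" if s > 0 else "D") for i, s in zip(sag_idx, sag_sign)
    }
    sign_of = {genes[i]: s for i, s in zip(sag_idx, sag_sign)}

    # one common restoration program: the same planted DAG set is restored by
    # KU, Y, and KU+Y alike, so the combination-vs-single-drug contrasts
    # contain only the planted synergy shifts (asymmetric per-drug restoration
    # would itself be a combination-vs-single signal and leave the planted
    # SynAG truth ill-defined)
    n_dag = round(cfg.frac_dag_given_sag * n_sag)
    pick = rng.choice(sag_idx, size=n_dag, replace=False)
    dag_set = {genes[i] for i in pick}
    dags: dict[str, set[str]] = {drug: set(dag_set) for drug in ("KU", "Y", "KUY")}

    kuy_list = sorted(dags["KUY"])
    n_syn = round(cfg.frac_synag_given_dag * len(kuy_list))
    syn_genes = [kuy_list[i] for i in rng.choice(len(kuy_list), n_syn, replace=False)]
    weights = np.asarray(cfg.pattern_weights, dtype=float)
    weights = weights / weights.sum()
    pattern_idx = rng.choice(len(MAJOR_PATTERNS), size=n_syn, p=weights)
    synag_pattern = {g: MAJOR_PATTERNS[j] for g, j in zip(syn_genes, pattern_idx)}

    truth = SimTruth(sag_direction=sag_direction, dags=dags, synag_pattern=synag_pattern)
    truth.check_nesting()

    # assemble design: young (dpt=0) + 4 senescent arms x 3 DPT, r replicates
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        rows.append((f"YOUNG_r{rep}", Arm.YOUNG, 0, rep))
    for arm in (Arm.OLD_DMSO, Arm.OLD_KU, Arm.OLD_Y, Arm.OLD_KUY):
        for dpt in DPTS:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append((f"{arm.value}_d{dpt:02d}_r{rep}", arm, dpt, rep))
    design = pd.DataFrame(rows, columns=["sample_id", "arm", "dpt", "replicate"])

    syn_shift = {  # (gene, dpt) -> signed delta_syn
        (g, dpt): (cfg.delta_syn if s == "U" else -cfg.delta_syn)
        for g, pat in synag_pattern.items()
        for dpt, s in zip(DPTS, pat)
        if s != "N"
    }

    means = np.empty((cfg.n_genes, len(design)))
    for j, (_, arm, dpt, _) in enumerate(rows):
        col = baseline.copy()
        if arm is not Arm.YOUNG:
            for gi, s in zip(sag_idx, sag_sign):
                col[gi] += cfg.delta_sen * s
            if arm in (Arm.OLD_KU, Arm.OLD_Y, Arm.OLD_KUY):
                drug = {Arm.OLD_KU: "KU", Arm.OLD_Y: "Y", Arm.OLD_KUY: "KUY"}[arm]
                for g in dags[drug]:
                    gi = int(g[1:])
                    col[gi] -= cfg.delta_restore * cfg.delta_sen * sign_of[g]
            if arm is Arm.OLD_KUY:
                for g in syn_genes:
                    shift = syn_shift.get((g, dpt))
                    if shift is not None:
                        col[int(g[1:])] += shift
        means[:, j] = col

    values = means + rng.normal(0.0, cfg.sigma_noise, size=means.shape)
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="feature_id"),
                          columns=design["sample_id"])
    dataset = ExpressionDataset(values=matrix, design=design, level=Level.GENE)
    return dataset, truth


def simulate_phenotypes(
    effA: float,
    effB: float,
    target_cdi: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    phenotype: str = "proliferation",
    dpt: int = 8,
) -> pd.DataFrame:
    """Simulate one phenotype panel row set with a known CDI.

    The control (DMSO) mean is 1, single-drug means are ``effA`` and
    ``effB``, and the combination mean is ``target_cdi * effA * effB`` so
    that the recovered CDI equals ``target_cdi`` exactly at zero noise.
    Noise is multiplicative log-normal with coefficient of variation
    ``noise_cv`` and unit mean.
    """
    if effA <= 0 or effB <= 0 or target_cdi <= 0:
        raise ValueError("efficacies and target CDI must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    means = {
        "OLD_DMSO": 1.0,
        "OLD_KU": effA,
        "OLD_Y": effB,
        "OLD_KUY": target_cdi * effA * effB,
    }
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        mu = -0.5 * sigma**2  # unit-mean log-normal
        for arm in means:
            means[arm] *= float(rng.lognormal(mu, sigma))
    return pd.DataFrame(
        {
            "phenotype": phenotype,
            "dpt": dpt,
            "arm": list(means),
            "mean": [means[a] for a in means],
        }
    )
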