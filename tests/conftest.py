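"""Shared fixtures: tiny hand-built datasets and DEG-table constructors."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from senosyn.data_model import Arm, ExpressionDataset, Level
from senosyn.permnull import DEGTable


def make_dataset(
    values: np.ndarray,
    arms: list[str],
    dpts: list[int],
    gene_ids: list[str] | None = None,
    level: Level = Level.GENE,
) -> ExpressionDataset:
    """Build an ExpressionDataset from a matrix and per-sample arm/dpt lists."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    reps: dict[tuple[str, int], int] = {}
    rows = []
    for j, (arm, dpt) in enumerate(zip(arms, dpts)):
        reps[(arm, dpt)] = reps.get((arm, dpt), 0) + 1
        rows.append((f"s{j}", arm, dpt, reps[(arm, dpt)]))
    design = pd.DataFrame(rows, columns=["sample_id", "arm", "dpt", "replicate"])
    matrix = pd.DataFrame(
        values, index=pd.Index(gene_ids, name="feature_id"),
        columns=design["sample_id"],
    )
    return ExpressionDataset(values=matrix, design=design, level=level)


def make_deg_table(
    comparison: str, calls: dict[str, tuple[str, float]]
) -> DEGTable:
    """DEGTable from gene -> (direction, log2fc); p set consistently with direction."""
    rows = []
    for gene, (direction, lfc) in calls.items():
        p = 0.01 if direction != "NS" else 0.5
        rows.append((gene, lfc / 0.3 if lfc else 0.0, lfc, p, direction))
    frame = pd.DataFrame(rows, columns=["gene_id", "t", "log2fc", "p", "direction"])
    return DEGTable(comparison=comparison, frame=frame)


@pytest.fixture
def two_vs_two_dataset() -> ExpressionDataset:
    """One comparison cell: 2 old-DMSO vs 2 young samples, 3 genes."""
    values = np.array(
        [
            [2.0, 4.0, 1.0, 3.0],
            [5.0, 5.5, 5.2, 5.1],
            [8.0, 8.4, 6.0, 6.2],
        ]
    )
    return make_dataset(
        values, ["OLD_DMSO", "OLD_DMSO", "YOUNG", "YOUNG"], [3, 3, 0, 0]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
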