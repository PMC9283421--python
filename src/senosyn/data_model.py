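"""Core data containers and file I/O shared by every analysis stage.

The experiment design is a five-arm time course on human diploid fibroblasts
(HDFs): low-passage ("young") cells profiled once, plus high-passage
("old", replicatively senescent) cells treated with DMSO vehicle, the ATM
inhibitor KU-60019 (KU), the ROCK inhibitor Y-27632 (Y), or the combination
(KU+Y), each sampled at 3, 8, and 15 days post treatment (DPT).

Expression values are log2 intensities, assumed already normalized; no array
preprocessing is performed here. Probe-level matrices are collapsed to gene
level by keeping, per gene, the probe with the largest interquartile range
(IQR) of expression across all samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Arm",
    "Level",
    "DataError",
    "ExpressionDataset",
    "GeneSetCollection",
    "ARMS",
    "DPTS",
    "read_design",
    "read_expression",
    "write_expression",
    "read_probe_map",
    "collapse_probes_iqr",
    "read_gmt",
]


class Arm(str, Enum):
    """Condition arm of the study design."""

    YOUNG = "YOUNG"
    OLD_DMSO = "OLD_DMSO"
    OLD_KU = "OLD_KU"
    OLD_Y = "OLD_Y"
    OLD_KUY = "OLD_KUY"


class Level(str, Enum):
    PROBE = "PROBE"
    GENE = "GENE"


#: All arms, in design-sheet order.
ARMS = tuple(Arm)

#: Treatment timepoints, days post treatment.
DPTS = (3, 8, 15)


class DataError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class ExpressionDataset:
    """A log2 expression matrix bound to its sample design.

    Parameters
    ----------
    values
        features x samples matrix of log2 intensities. Index holds the
        feature ids (probes or genes), columns the sample ids.
    design
        One row per sample with columns ``sample_id``, ``arm``, ``dpt``,
        ``replicate``, ordered exactly as the matrix columns.
    level
        Whether rows are probes or genes.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    level: Level = Level.GENE

    def __post_init__(self) -> None:
        self.level = Level(self.level)
        design = self.design.reset_index(drop=True)
        required = {"sample_id", "arm", "dpt", "replicate"}
        missing = required - set(design.columns)
        if missing:
            raise DataError(f"design sheet missing columns: {sorted(missing)}")
        design["arm"] = design["arm"].map(
            lambda a: a if isinstance(a, Arm) else Arm(str(a))
        )
        design["dpt"] = design["dpt"].astype(int)
        design["replicate"] = design["replicate"].astype(int)
        if (design["replicate"] < 1).any():
            raise DataError("replicate numbers must be positive")
        if design["sample_id"].duplicated().any():
            dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DataError(f"duplicate sample_id in design: {dup!r}")
        if list(self.values.columns) != list(design["sample_id"]):
            raise DataError("matrix columns do not match design sample order")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataError(f"duplicate feature_id: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise DataError(
                f"non-finite expression value at feature "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        self.design = design

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_samples(self, arm: Arm | str, dpt: int | None = None) -> list[str]:
        """Sample ids for one (arm, dpt) cell.

        YOUNG samples have no treatment timepoint: every comparison against
        YOUNG pools all young replicates regardless of ``dpt``.
        """
        arm = Arm(arm)
        mask = self.design["arm"] == arm
        if arm is not Arm.YOUNG and dpt is not None:
            mask &= self.design["dpt"] == int(dpt)
        return list(self.design.loc[mask, "sample_id"])

    def submatrix(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.values.loc[:, list(sample_ids)].to_numpy(dtype=float)


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe (for over-representation tests)."""

    sets: dict[str, list[str]]
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.universe:
            members: set[str] = set()
            for genes in self.sets.values():
                members.update(genes)
            self.universe = sorted(members)


def read_design(design_path: str | Path) -> pd.DataFrame:
    """Read a design sheet (CSV or TSV; columns sample_id, arm, dpt, replicate)."""
    design = pd.read_csv(design_path, sep=None, engine="python", dtype=str)
    design.columns = [c.strip() for c in design.columns]
    required = {"sample_id", "arm", "dpt", "replicate"}
    if not required <= set(design.columns):
        raise DataError(
            f"design sheet {design_path} must have columns {sorted(required)}, "
            f"got {list(design.columns)}"
        )
    return design


def read_expression(
    matrix_path: str | Path,
    design_path: str | Path,
    level: Level | str = Level.GENE,
) -> ExpressionDataset:
    """Load an expression TSV and its design sheet into an :class:`ExpressionDataset`.

    The matrix is tab-separated with header ``feature_id`` followed by sample
    ids; the design sheet is CSV/TSV with columns ``sample_id``, ``arm``,
    ``dpt``, ``replicate``. Columns are returned in design-sheet order.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    design = read_design(design_path)

    missing = [s for s in design["sample_id"] if s not in raw.columns]
    if missing:
        raise DataError(
            f"sample {missing[0]!r} listed in design but absent from matrix header"
        )

    raw = raw.loc[:, list(design["sample_id"])]
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric expression value {raw.iat[i, j]!r} at feature "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    if values.isna().to_numpy().any():
        i, j = np.argwhere(values.isna().to_numpy())[0]
        raise DataError(
            f"missing expression value at feature {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}"
        )
    # final parse via Python's correctly-rounded float for bit-exact round trips
    exact = raw.map(float)
    return ExpressionDataset(values=exact, design=design, level=level)


def write_expression(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    design_path: str | Path | None = None,
) -> None:
    """Write the matrix as TSV (and optionally the design sheet as CSV).

    Uses repr-round-trip float formatting so read-back is bit-identical.
    """
    out = dataset.values.copy()
    out.index.name = "feature_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.17g")
    if design_path is not None:
        design = dataset.design.copy()
        design["arm"] = [a.value for a in design["arm"]]
        design.to_csv(design_path, index=False)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    """Read a two-column probe->gene TSV (header probe_id, gene_id)."""
    pmap = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(pmap.columns):
        raise DataError(
            f"probe map {path} must have columns probe_id, gene_id, "
            f"got {list(pmap.columns)}"
        )
    if pmap["probe_id"].duplicated().any():
        dup = pmap.loc[pmap["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise DataError(f"probe {dup!r} mapped to more than one gene")
    return pmap


def _iqr(row: np.ndarray) -> float:
    q1, q3 = np.percentile(row, [25.0, 75.0])  # linear-interpolation quantiles
    return float(q3 - q1)


def collapse_probes_iqr(
    dataset: ExpressionDataset, probe_map: pd.DataFrame
) -> ExpressionDataset:
    """Collapse a probe-level matrix to gene level by the largest-IQR rule.

    For each gene the representative row is the probe whose expression values
    have the largest interquartile range across all samples; IQR ties break to
    the lexicographically smallest probe id, so the result is independent of
    input row order. Probes absent from the map are dropped (count logged).
    """
    if dataset.level is not Level.PROBE:
        raise DataError("collapse_probes_iqr requires a PROBE-level dataset")
    mapping = dict(zip(probe_map["probe_id"], probe_map["gene_id"]))
    probes = [p for p in dataset.feature_ids if p in mapping]
    n_dropped = dataset.n_features - len(probes)
    if n_dropped:
        logger.info("collapse_probes_iqr: dropped %d unmapped probes", n_dropped)
    if not probes:
        raise DataError("no probe in the matrix is present in the probe map")

    sub = dataset.values.loc[probes]
    iqrs = pd.Series(
        np.subtract(*np.percentile(sub.to_numpy(dtype=float), [75.0, 25.0], axis=1)),
        index=sub.index,
    )
    winners: dict[str, str] = {}
    frame = pd.DataFrame({"gene": [mapping[p] for p in probes], "iqr": iqrs.loc[probes]})
    # sort by probe_id so idxmax's first-occurrence rule is the lexicographic tie-break
    frame = frame.sort_index()
    for gene, grp in frame.groupby("gene", sort=True):
        winners[str(gene)] = str(grp["iqr"].idxmax())

    genes = sorted(winners)
    collapsed = sub.loc[[winners[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name="feature_id")
    return ExpressionDataset(
        values=collapsed, design=dataset.design.copy(), level=Level.GENE
    )


def read_gmt(path: str | Path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, member genes).

    Duplicate members within a set are removed (first occurrence kept).
    The universe defaults to the union of all members unless overridden.
    """
    sets: dict[str, list[str]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name = fields[0]
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = members
    if n_lines == 0:
        raise DataError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets, universe=list(universe) if universe else [])
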