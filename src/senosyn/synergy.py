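"""Phenotype-level synergy scoring and small quantification utilities.

The coefficient of drug interaction (CDI) quantifies synergy of a drug
combination from treatment efficacies:

    CDI = AB / (A x B)

where A and B are the efficacies of the single treatments and AB of the
combination, each the treated/control mean ratio of a phenotype measurement
(proliferation, SA-beta-gal, lipofuscin, mitochondrial readouts, ...).
CDI > 1 indicates synergistic activation, CDI < 1 synergistic inhibition,
CDI = 1 multiplicative independence.

Also here: the comparative-Ct (delta-delta-Ct) method for qRT-PCR relative
quantification, and the rule classifier for mitochondrial morphology
(fraction of per-cell mitochondria longer than 10 um).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CDIRecord",
    "efficacy",
    "cdi",
    "cdi_from_panel",
    "ddct",
    "classify_mito",
    "MITO_LONG_THRESHOLD_UM",
]

Call = Literal["SYNERGISTIC_ACTIVATION", "SYNERGISTIC_INHIBITION", "INDEPENDENT"]

#: Mitochondria longer than this are counted as elongated.
MITO_LONG_THRESHOLD_UM = 10.0

#: |CDI - 1| below this is treated as multiplicative independence.
_CDI_TOL = 1e-12


def efficacy(mean_drug: float, mean_control: float, mode: str = "ratio") -> float:
    """Treatment efficacy of one phenotype measurement.

    Default is the treated/control mean ratio. ``mode="log2"`` returns the
    absolute log2 fold change instead (an alternative reading of efficacy
    for displays given as log2 changes); it errors on a zero fold change
    since CDI needs strictly positive efficacies.
    """
    if mean_drug <= 0 or mean_control <= 0:
        raise ValueError("phenotype means must be positive")
    ratio = mean_drug / mean_control
    if mode == "ratio":
        return ratio
    if mode == "log2":
        lfc = abs(math.log2(ratio))
        if lfc == 0.0:
            raise ValueError("log2 efficacy is zero; CDI undefined in log2 mode")
        return lfc
    raise ValueError(f"unknown efficacy mode {mode!r}")


def cdi(AB: float, A: float, B: float) -> tuple[float, Call]:
    """Coefficient of drug interaction AB/(A*B) and its synergy call."""
    if AB <= 0 or A <= 0 or B <= 0:
        raise ValueError("efficacies must be positive")
    value = AB / (A * B)
    if abs(value - 1.0) <= _CDI_TOL:
        call: Call = "INDEPENDENT"
    elif value > 1.0:
        call = "SYNERGISTIC_ACTIVATION"
    else:
        call = "SYNERGISTIC_INHIBITION"
    return value, call


@dataclass(frozen=True)
class CDIRecord:
    phenotype: str
    dpt: int
    A: float  # efficacy of KU
    B: float  # efficacy of Y
    AB: float  # efficacy of KU+Y
    cdi: float
    call: Call


def cdi_from_panel(panel: pd.DataFrame, mode: str = "ratio") -> list[CDIRecord]:
    """Compute CDI per (phenotype, dpt) from a long-format phenotype panel.

    ``panel`` columns: phenotype, dpt, arm, mean — with arms OLD_DMSO (the
    control), OLD_KU, OLD_Y, OLD_KUY. All means must be positive.
    """
    required = {"phenotype", "dpt", "arm", "mean"}
    if not required <= set(panel.columns):
        raise ValueError(f"panel needs columns {sorted(required)}")
    records = []
    for (phenotype, dpt), grp in panel.groupby(["phenotype", "dpt"], sort=True):
        means = dict(zip(grp["arm"].astype(str), grp["mean"].astype(float)))
        missing = {"OLD_DMSO", "OLD_KU", "OLD_Y", "OLD_KUY"} - set(means)
        if missing:
            raise ValueError(
                f"panel for ({phenotype}, {dpt}) missing arms {sorted(missing)}"
            )
        ctrl = means["OLD_DMSO"]
        A = efficacy(means["OLD_KU"], ctrl, mode=mode)
        B = efficacy(means["OLD_Y"], ctrl, mode=mode)
        AB = efficacy(means["OLD_KUY"], ctrl, mode=mode)
        value, call = cdi(AB, A, B)
        records.append(
            CDIRecord(str(phenotype), int(dpt), A, B, AB, value, call)
        )
    return records


def ddct(
    table: pd.DataFrame,
    control_condition: str,
) -> dict[str, float]:
    """Comparative-Ct relative expression, 2^(-ddCt), per condition.

    ``table`` columns: condition, ct_target, ct_reference (the reference is
    a housekeeping transcript such as RPS11). dCt = Ct_target - Ct_reference
    per condition; ddCt subtracts the control condition's dCt; the returned
    relative expression is 2^(-ddCt), exactly 1 for the control.
    """
    required = {"condition", "ct_target", "ct_reference"}
    if not required <= set(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    ct = table.copy()
    ct["ct_target"] = ct["ct_target"].astype(float)
    ct["ct_reference"] = ct["ct_reference"].astype(float)
    for col in ("ct_target", "ct_reference"):
        bad = ~((ct[col] > 0) & (ct[col] < 45))
        if bad.any():
            cond = ct.loc[bad, "condition"].iloc[0]
            raise ValueError(f"Ct value out of range (0, 45) for {cond!r}")
    dct = dict(zip(ct["condition"], ct["ct_target"] - ct["ct_reference"]))
    if control_condition not in dct:
        raise ValueError(f"control condition {control_condition!r} not in table")
    base = dct[control_condition]
    out = {cond: float(2.0 ** -(d - base)) for cond, d in dct.items()}
    out[control_condition] = 1.0  # exact by construction
    return out


def classify_mito(
    lengths: Sequence[float],
    long_threshold: float = MITO_LONG_THRESHOLD_UM,
) -> str:
    """Classify one cell's mitochondrial morphology from per-mitochondrion lengths.

    The cell is ELONGATED when more than 70% of its mitochondria exceed the
    length threshold (10 um), FRAGMENTED when fewer than 30% do, and
    INTERMEDIATE in between (both boundaries inclusive to INTERMEDIATE).
    """
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size == 0:
        raise ValueError("lengths must be non-empty")
    if (arr <= 0).any():
        raise ValueError("mitochondrial lengths must be positive")
    pct = 100.0 * float(np.count_nonzero(arr > long_threshold)) / arr.size
    if pct > 70.0:
        return "ELONGATED"
    if pct < 30.0:
        return "FRAGMENTED"
    return "INTERMEDIATE"
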