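"""The SAG -> DAG -> SynAG selection cascade and temporal pattern grouping.

Starting from per-timepoint differential-expression tables, three nested gene
sets are selected:

* **SAGs** (senescence-associated genes): up- or downregulated in senescent
  vs young cells at one or more timepoints.
* **DAGs** (drug-associated genes): SAGs whose expression a treatment
  *restores* — significant in the drug-vs-DMSO comparison with direction
  opposite to the senescence change at a timepoint where that change is
  non-NS.
* **SynAGs** (synergism-associated genes): combination-treatment DAGs that
  are additionally differential, in the same direction, in the combination
  vs *each* single drug at a given timepoint.

SynAGs are then grouped by their temporal up/down pattern over the three
timepoints; groups with strictly more than 10 members are "major".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

from .data_model import DPTS
from .permnull import DEGTable

__all__ = [
    "GeneStatus",
    "CascadeResult",
    "PATTERN_LABELS",
    "MAJOR_PATTERNS",
    "pattern_label",
    "select_sags",
    "select_dags",
    "select_synags",
    "assign_temporal_groups",
    "venn_counts",
    "run_cascade",
]

Drug = Literal["KU", "Y", "KUY"]
DRUGS: tuple[Drug, ...] = ("KU", "Y", "KUY")

#: Canonical names for the common single-direction temporal patterns
#: (E/M/L = early/mid/late = 3/8/15 days post treatment).
PATTERN_LABELS: dict[tuple[str, str, str], str] = {
    ("U", "U", "U"): "EML-UP",
    ("N", "U", "U"): "ML-UP",
    ("N", "U", "N"): "M-UP",
    ("N", "N", "U"): "L-UP",
    ("D", "N", "N"): "E-DOWN",
    ("N", "D", "N"): "M-DOWN",
    ("N", "N", "D"): "L-DOWN",
}

#: The seven patterns observed as major groups in the reference design.
MAJOR_PATTERNS: tuple[tuple[str, str, str], ...] = tuple(PATTERN_LABELS)


@dataclass
class GeneStatus:
    """Per-timepoint direction calls (U / D / N) and log2FCs for one gene."""

    gene_id: str
    directions: dict[int, str] = field(default_factory=dict)
    log2fc: dict[int, float] = field(default_factory=dict)

    def triple(self, dpts: tuple[int, ...] = DPTS) -> tuple[str, ...]:
        return tuple(self.directions.get(d, "N") for d in dpts)


def pattern_label(triple: tuple[str, ...]) -> str:
    """Canonical label for a temporal pattern; unnamed patterns use the triple."""
    if all(s == "N" for s in triple):
        raise ValueError("pattern (N,N,N) is not a valid SynAG pattern")
    return PATTERN_LABELS.get(tuple(triple), "-".join(triple))


def _short(direction: str) -> str:
    return {"UP": "U", "DOWN": "D", "NS": "N"}[direction]


def select_sags(deg_old_vs_young: Mapping[int, DEGTable]) -> dict[str, GeneStatus]:
    """Genes up- or downregulated in old vs young at >= 1 timepoint."""
    if not deg_old_vs_young:
        raise ValueError("no old-vs-young DEG tables supplied")
    sags: dict[str, GeneStatus] = {}
    for dpt, table in sorted(deg_old_vs_young.items()):
        for gene, direction in zip(table.frame["gene_id"], table.frame["direction"]):
            if direction == "NS":
                continue
            status = sags.setdefault(gene, GeneStatus(gene))
            status.directions[dpt] = _short(direction)
            status.log2fc[dpt] = table.log2fc_of(gene)
    return sags


RestorationMode = Literal["opposite", "strict"]


def select_dags(
    sags: Mapping[str, GeneStatus],
    deg_drug_vs_dmso: Mapping[tuple[str, int], DEGTable],
    drugs: tuple[Drug, ...] = DRUGS,
    dpts: tuple[int, ...] = DPTS,
    mode: RestorationMode = "opposite",
    lfc_cutoff: float = 0.58,
) -> dict[str, set[str]]:
    """SAGs restored by each treatment.

    A SAG joins DAG_drug when, at >= 1 timepoint where its senescence
    direction is non-NS, the drug-vs-DMSO call is significant and opposite
    to the senescence direction. ``mode="strict"`` additionally requires the
    drug-induced shift to cover at least the senescence shift minus
    ``lfc_cutoff`` (the treated mean moved to within the fold-change cutoff
    of the young mean).
    """
    for drug in drugs:
        for dpt in dpts:
            if (drug, dpt) not in deg_drug_vs_dmso:
                raise ValueError(f"missing drug-vs-DMSO DEG table for ({drug}, {dpt})")
    dags: dict[str, set[str]] = {drug: set() for drug in drugs}
    for gene, status in sags.items():
        for drug in drugs:
            for dpt in dpts:
                sen = status.directions.get(dpt, "N")
                if sen == "N":
                    continue
                table = deg_drug_vs_dmso[(drug, dpt)]
                call = _short(table.direction_of(gene))
                if call == "N" or call == sen:
                    continue
                if mode == "strict":
                    # young-anchoring: (old-young) + (drug-DMSO) estimates the
                    # residual treated-vs-young shift; require it within cutoff
                    sen_lfc = status.log2fc.get(dpt)
                    rest_lfc = table.log2fc_of(gene)
                    if sen_lfc is not None and abs(sen_lfc + rest_lfc) > lfc_cutoff:
                        continue
                dags[drug].add(gene)
                break
    return dags


SynagMode = Literal["and", "or"]


def select_synags(
    dag_kuy: set[str],
    deg_kuy_vs_ku: Mapping[int, DEGTable],
    deg_kuy_vs_y: Mapping[int, DEGTable],
    dpts: tuple[int, ...] = DPTS,
    mode: SynagMode = "and",
) -> dict[int, dict[str, str]]:
    """Combination-DAGs differential vs the single drugs, per timepoint.

    Default ``mode="and"``: the gene must be significant with the same
    direction in both combination-vs-KU and combination-vs-Y at the
    timepoint. ``mode="or"``: significance in either comparison suffices,
    but conflicting significant directions still exclude the gene.
    Returns, per timepoint, a mapping gene -> direction (U/D).
    """
    synags: dict[int, dict[str, str]] = {}
    for dpt in dpts:
        if dpt not in deg_kuy_vs_ku or dpt not in deg_kuy_vs_y:
            raise ValueError(f"missing combination comparison at {dpt} DPT")
        vs_ku = deg_kuy_vs_ku[dpt]
        vs_y = deg_kuy_vs_y[dpt]
        hits: dict[str, str] = {}
        for gene in sorted(dag_kuy):
            a = _short(vs_ku.direction_of(gene))
            b = _short(vs_y.direction_of(gene))
            if mode == "and":
                if a != "N" and a == b:
                    hits[gene] = a
            else:  # or
                calls = {c for c in (a, b) if c != "N"}
                if len(calls) == 1:
                    hits[gene] = calls.pop()
        synags[dpt] = hits
    return synags


def assign_temporal_groups(
    synags: Mapping[int, Mapping[str, str]],
    dpts: tuple[int, ...] = DPTS,
    major_min: int = 10,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Group SynAGs by temporal pattern; major groups have > ``major_min`` genes."""
    union = sorted({g for hits in synags.values() for g in hits})
    groups: dict[str, list[str]] = {}
    for gene in union:
        triple = tuple(synags.get(d, {}).get(gene, "N") for d in dpts)
        label = pattern_label(triple)  # raises on all-N, an internal inconsistency
        groups.setdefault(label, []).append(gene)
    major = {k: v for k, v in groups.items() if len(v) > major_min}
    return groups, major


_VENN_REGIONS = (
    "dpt3_only",
    "dpt8_only",
    "dpt15_only",
    "dpt3_dpt8",
    "dpt3_dpt15",
    "dpt8_dpt15",
    "dpt3_dpt8_dpt15",
)


def venn_counts(synags: Mapping[int, Mapping[str, str]]) -> dict[str, int]:
    """Counts of the 7 disjoint regions of the 3-timepoint Venn decomposition."""
    s3 = set(synags.get(3, {}))
    s8 = set(synags.get(8, {}))
    s15 = set(synags.get(15, {}))
    return {
        "dpt3_only": len(s3 - s8 - s15),
        "dpt8_only": len(s8 - s3 - s15),
        "dpt15_only": len(s15 - s3 - s8),
        "dpt3_dpt8": len((s3 & s8) - s15),
        "dpt3_dpt15": len((s3 & s15) - s8),
        "dpt8_dpt15": len((s8 & s15) - s3),
        "dpt3_dpt8_dpt15": len(s3 & s8 & s15),
    }


@dataclass
class CascadeResult:
    """All cascade stages for one analysis run."""

    sags: dict[str, GeneStatus]
    dags: dict[str, set[str]]
    synags: dict[int, dict[str, str]]
    groups: dict[str, list[str]]
    major_groups: dict[str, list[str]]
    venn: dict[str, int]

    @property
    def synag_union(self) -> set[str]:
        return {g for hits in self.synags.values() for g in hits}

    def stage_counts(self) -> dict[str, int]:
        counts = {"sags": len(self.sags)}
        for drug, genes in self.dags.items():
            counts[f"dags_{drug}"] = len(genes)
        counts["dags_union"] = len(set().union(*self.dags.values())) if self.dags else 0
        for dpt, hits in sorted(self.synags.items()):
            counts[f"synags_dpt{dpt}"] = len(hits)
        counts["synags_union"] = len(self.synag_union)
        counts["groups"] = len(self.groups)
        counts["major_groups"] = len(self.major_groups)
        return counts

    def check_nesting(self) -> None:
        """Assert SynAG(dpt) <= DAG_KUY <= SAG; raises AssertionError otherwise."""
        sag_set = set(self.sags)
        kuy = self.dags.get("KUY", set())
        assert kuy <= sag_set, "DAG_KUY not contained in SAGs"
        for dpt, hits in self.synags.items():
            assert set(hits) <= kuy, f"SynAG({dpt}) not contained in DAG_KUY"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sags": sorted(self.sags),
            "dags": {d: sorted(g) for d, g in self.dags.items()},
            "synags_by_dpt": {
                str(d): dict(sorted(h.items())) for d, h in self.synags.items()
            },
            "groups": {k: sorted(v) for k, v in sorted(self.groups.items())},
            "major_groups": {
                k: sorted(v) for k, v in sorted(self.major_groups.items())
            },
            "venn": self.venn,
            "stage_counts": self.stage_counts(),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def run_cascade(
    deg_old_vs_young: Mapping[int, DEGTable],
    deg_drug_vs_dmso: Mapping[tuple[str, int], DEGTable],
    deg_kuy_vs_ku: Mapping[int, DEGTable],
    deg_kuy_vs_y: Mapping[int, DEGTable],
    restoration_mode: RestorationMode = "opposite",
    synag_mode: SynagMode = "and",
    major_min: int = 10,
    lfc_cutoff: float = 0.58,
) -> CascadeResult:
    """Run the full SAG -> DAG -> SynAG cascade from pre-computed DEG tables."""
    sags = select_sags(deg_old_vs_young)
    dags = select_dags(
        sags, deg_drug_vs_dmso, mode=restoration_mode, lfc_cutoff=lfc_cutoff
    )
    synags = select_synags(dags["KUY"], deg_kuy_vs_ku, deg_kuy_vs_y, mode=synag_mode)
    groups, major = assign_temporal_groups(synags, major_min=major_min)
    result = CascadeResult(
        sags=sags,
        dags=dags,
        synags=synags,
        groups=groups,
        major_groups=major,
        venn=venn_counts(synags),
    )
    result.check_nesting()
    return result
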