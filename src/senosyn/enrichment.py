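"""Hypergeometric over-representation analysis (ORA) of gene lists.

A query gene list (e.g. one temporal group of SynAGs) is tested against each
set of a collection (biological-process terms, transcription-factor target
sets) with the one-sided upper-tail hypergeometric probability

    p = Pr(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the universe size, K the gene-set size, n the query size and k
the overlap. A set "passes" when p < 0.05 and the overlap count reaches
``count_min`` (3 for process collections, 1 for TF-target collections).
Raw p-values are thresholded directly; no multiple-testing correction is
applied, mirroring the selection procedure this pipeline implements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from .data_model import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentRecord", "hypergeom_upper", "enrich", "write_enrichment_tsv"]


@dataclass(frozen=True)
class EnrichmentRecord:
    """Overlap counts and upper-tail hypergeometric p for one gene set."""

    set_name: str
    k: int  # overlap
    n: int  # query size (within universe)
    K: int  # set size
    N: int  # universe size
    p: float
    passes: bool


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Pr(X >= k) for X ~ Hypergeometric(N, K, n), stable in log space.

    Conventions: N population size, K marked items, n draws, k observed
    overlap. ``k = 0`` returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    # survival function of the hypergeometric at k-1 == Pr(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    count_min: int = 3,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Test a query gene list against every non-empty set of a collection.

    Query genes outside the universe are dropped (count logged). Records are
    returned sorted by ascending p (ties by set name); ``passes`` is true
    when p < ``alpha`` and the overlap count is at least ``count_min``.
    """
    universe = set(collection.universe)
    query_all = set(query)
    query_in = query_all & universe
    dropped = len(query_all) - len(query_in)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the universe", dropped)
    if not query_in:
        raise ValueError("query is empty after intersection with the universe")

    N = len(universe)
    n = len(query_in)
    records = []
    for name, members in collection.sets.items():
        members_in = set(members) & universe
        K = len(members_in)
        if K == 0:
            continue
        k = len(query_in & members_in)
        p = hypergeom_upper(k, n, K, N)
        records.append(
            EnrichmentRecord(
                set_name=name, k=k, n=n, K=K, N=N, p=p,
                passes=(p < alpha and k >= count_min),
            )
        )
    records.sort(key=lambda r: (r.p, r.set_name))
    return records


def write_enrichment_tsv(records: list[EnrichmentRecord], path: str | Path) -> None:
    frame = pd.DataFrame([r.__dict__ for r in records])
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
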