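"""Annotation-term over-representation with Bonferroni and FDR control.

For a query set Q (e.g. a module's species) against a background universe U,
each term T is scored with the one-sided hypergeometric tail

    p = P(X >= |Q_a ∩ T|),   X ~ Hypergeom(|U|, |T|, |Q_a|)

where Q_a is the annotated part of the query (the "List Total" convention).
Bonferroni multiplies by the number of tested terms (terms with at least one
query member, by default); FDR is Benjamini–Hochberg step-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

AnnotationTable = dict[str, tuple[str, frozenset[str]]]


class EnrichmentInputError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    count: int
    list_total: int
    p_raw: float
    p_bonferroni: float
    p_fdr: float
    significant: bool


def hypergeometric_tail(k: int, big_n: int, big_k: int, n_draws: int) -> float:
    """P(X >= k) for X ~ Hypergeom(big_n population, big_k successes, n_draws)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, big_n, big_k, n_draws))


def enrich(query: frozenset[str] | set[str], annotations: AnnotationTable,
           background: frozenset[str] | set[str], alpha: float = 0.01,
           tested_terms: str = "hit") -> list[EnrichmentRow]:
    """Score every annotation term against the query set.

    ``tested_terms='hit'`` corrects over terms with >= 1 query member (the
    DAVID convention); ``'all'`` corrects over the whole table.  Rows whose
    Bonferroni- and FDR-adjusted values are both <= alpha are flagged
    significant.  Results sorted by raw p then term id.
    """
    query = frozenset(query)
    background = frozenset(background)
    if not query or not background:
        raise EnrichmentInputError("query and background must be non-empty")
    missing = query - background
    if missing:
        raise EnrichmentInputError(
            f"query ids absent from background: {sorted(missing)}"
        )
    outside = [
        tid for tid, (_, members) in annotations.items()
        if not members <= background
    ]
    if outside:
        raise EnrichmentInputError(
            f"terms with members outside the background: {sorted(outside)}"
        )

    annotated_universe: set[str] = set()
    for _, members in annotations.values():
        annotated_universe |= members
    list_total = len(query & annotated_universe)
    if list_total == 0:
        log.warning("query has no annotated member; empty enrichment result")
        return []

    hits = {
        tid: len(query & members)
        for tid, (_, members) in annotations.items()
    }
    if tested_terms == "hit":
        tested = [tid for tid, k in hits.items() if k > 0]
    elif tested_terms == "all":
        tested = list(annotations)
    else:
        raise ValueError(f"unknown tested_terms mode {tested_terms!r}")
    if not tested:
        return []

    raw = {
        tid: hypergeometric_tail(
            hits[tid], len(background), len(annotations[tid][1]), list_total
        )
        for tid in tested
    }
    order = sorted(tested, key=lambda t: (raw[t], t))
    pvals = [raw[t] for t in order]
    m = len(order)
    bonf = [min(1.0, p * m) for p in pvals]
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    return [
        EnrichmentRow(
            term_id=tid,
            term_name=annotations[tid][0],
            count=hits[tid],
            list_total=list_total,
            p_raw=pvals[i],
            p_bonferroni=bonf[i],
            p_fdr=float(fdr[i]),
            significant=bonf[i] <= alpha and fdr[i] <= alpha,
        )
        for i, tid in enumerate(order)
    ]


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Table shaped like a DAVID pathway report."""
    return pd.DataFrame(
        [
            {
                "Pathway": f"{r.term_id}:{r.term_name}",
                "Count": r.count,
                "List Total": r.list_total,
                "Bonferroni": r.p_bonferroni,
                "FDR": r.p_fdr,
            }
            for r in rows
        ],
        columns=["Pathway", "Count", "List Total", "Bonferroni", "FDR"],
    )
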