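"""Feature overlap (genes, QTLs, assembly gaps) and gene-set enrichment.

A CNVR is genic when it overlaps at least one gene by >= 1 bp; the same
rule applies to QTL categories and gaps.  Enrichment replaces the external
annotation services with a generic hypergeometric upper-tail test over
user-supplied gene sets, Benjamini-Hochberg corrected across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import IntervalRecord
from ._intervals import build_trees, query

__all__ = ["overlap_features", "gap_overlap", "enrich", "OverlapResult"]


@dataclass
class OverlapResult:
    hits: list            # per-CNVR list of overlapping IntervalRecords
    genic_count: int      # CNVRs overlapping >= 1 feature of category 'gene'
    intergenic_count: int
    category_counts: dict  # feature category -> number of CNVRs hitting it


def overlap_features(
    cnvrs: Sequence,
    features: Sequence[IntervalRecord],
    gene_category: str = "gene",
) -> OverlapResult:
    """Per-CNVR feature hit lists plus genic/intergenic and category tallies."""
    trees = build_trees(features)
    hits = []
    genic = 0
    cat_counts: dict = {}
    for r in cnvrs:
        found = sorted(
            query(trees, r.chrom, r.start, r.end),
            key=lambda f: (f.start, f.end, f.id),
        )
        hits.append(found)
        cats = {f.category for f in found}
        for c in cats:
            cat_counts[c] = cat_counts.get(c, 0) + 1
        if gene_category in cats:
            genic += 1
    return OverlapResult(
        hits=hits,
        genic_count=genic,
        intergenic_count=len(hits) - genic,
        category_counts=cat_counts,
    )


def gap_overlap(
    calls: Sequence,
    gaps: Sequence[IntervalRecord],
    min_gap: int = 1_000,
) -> dict:
    """How many calls touch an assembly gap (and how many gaps are touched).

    Gaps shorter than ``min_gap`` are ignored, mirroring the convention of
    counting only gaps larger than 1 kb in the assembly.
    """
    big_gaps = [g for g in gaps if g.length >= min_gap]
    trees = build_trees(big_gaps)
    n_calls_hit = 0
    gaps_hit = set()
    for c in calls:
        found = query(trees, c.chrom, c.start, c.end)
        if found:
            n_calls_hit += 1
            gaps_hit.update((g.chrom, g.start, g.end) for g in found)
    n_calls = len(list(calls)) if not hasattr(calls, "__len__") else len(calls)
    return {
        "n_calls": n_calls,
        "n_calls_overlapping": n_calls_hit,
        "fraction_calls_overlapping": n_calls_hit / n_calls if n_calls else 0.0,
        "n_gaps_considered": len(big_gaps),
        "n_gaps_hit": len(gaps_hit),
        "fraction_gaps_hit": len(gaps_hit) / len(big_gaps) if big_gaps else 0.0,
    }


def enrich(
    hit_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of *hit_genes* in each gene set.

    For a universe of N genes, a set of K, and n hits of which k fall in the
    set, the upper-tail P is ``P(X >= k)`` for X ~ Hypergeom(N, K, n).
    Benjamini-Hochberg q-values are computed across the supplied sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    hits = set(hit_genes)
    if not hits <= universe:
        raise ValueError("hit genes outside the universe")
    n_univ, n_hits = len(universe), len(hits)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(hits & members)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_hits))
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": k,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    return df
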