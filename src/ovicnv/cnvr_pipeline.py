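"""Aggregate per-sample CNV calls into CNVRs and summarise their distribution.

CNVRs are the single-linkage (transitive) union of calls overlapping by at
least 1 bp across all samples; merged regions shorter than 1 kb are removed
AFTER merging.  A region's state is loss/gain when every contributing call
agrees, and "both" otherwise; its frequency is the percentage of the
post-QC cohort carrying at least one overlapping CNV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CNVCall, CNVR, GenomeBuild
from ._intervals import merge_chained

__all__ = [
    "merge_to_cnvrs",
    "assign_state",
    "summarize",
    "ChromosomeSummary",
    "LENGTH_BINS_KB",
    "MIN_CNVR_LENGTH",
]

MIN_CNVR_LENGTH = 1_000  # bp

# histogram bin edges in kb: <10, 10-50, 50-100, 100-500, 500-1000, >1000
LENGTH_BINS_KB = (0, 10, 50, 100, 500, 1000, float("inf"))
LENGTH_BIN_LABELS = ("<10", "10-50", "50-100", "100-500", "500-1000", ">1000")


def assign_state(calls: Sequence[CNVCall]) -> str:
    """State of a region from its contributing calls: loss, gain or both."""
    if not calls:
        raise ValueError("a CNVR needs at least one contributing CNV")
    if any(c.cn == 2 for c in calls):
        raise ValueError("contributing CNV with cn=2 is impossible")
    states = {c.state for c in calls}
    if states == {"loss"}:
        return "loss"
    if states == {"gain"}:
        return "gain"
    return "both"


def merge_to_cnvrs(
    calls: Sequence[CNVCall],
    cohort_size: int,
    min_len: int = MIN_CNVR_LENGTH,
) -> list[CNVR]:
    """Merge overlapping calls (>= 1 bp) across samples into CNVRs.

    The union is transitive (single linkage), so a region may span calls
    that never directly overlap each other.  The length filter applies to
    the merged regions, not the input calls.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    n_distinct = len({c.sample for c in calls})
    if cohort_size < n_distinct:
        raise ValueError(
            f"cohort_size {cohort_size} < {n_distinct} distinct samples in calls"
        )
    out = []
    for chrom, start, end, members in merge_chained(calls):
        if end - start + 1 < min_len:
            continue
        samples = tuple(sorted({c.sample for c in members}))
        out.append(
            CNVR(
                chrom=chrom,
                start=start,
                end=end,
                state=assign_state(members),
                samples=samples,
                n_cnvs=len(members),
                frequency=100.0 * len(samples) / cohort_size,
            )
        )
    return out


@dataclass
class ChromosomeSummary:
    """Per-chromosome CNVR distribution plus the genome-wide count~length fit."""

    table: pd.DataFrame          # one row per chromosome
    length_histogram: pd.Series  # fraction of CNVRs per length bin (kb)
    regression_slope: float      # CNVR count per bp of chromosome
    regression_intercept: float
    r_squared: float


def length_histogram(lengths_bp: Sequence[int]) -> pd.Series:
    """Fractions of regions per length bin (kb); fractions sum to 1."""
    kb = np.asarray(lengths_bp, dtype=float) / 1e3
    counts = np.histogram(kb, bins=np.array(LENGTH_BINS_KB))[0]
    frac = counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.Series(frac, index=list(LENGTH_BIN_LABELS), name="fraction")


def summarize(cnvrs: Sequence[CNVR], genome: GenomeBuild) -> ChromosomeSummary:
    """Per-chromosome counts, coverage and spacing; count-vs-length OLS.

    Inter-CNVR distance between neighbours is ``next.start - current.end - 1``;
    chromosomes with fewer than two CNVRs report the spacing columns as NaN.
    """
    rows = []
    for chrom, clen in genome.lengths.items():
        regs = sorted(
            (r for r in cnvrs if r.chrom == chrom), key=lambda r: r.start
        )
        total = sum(r.length for r in regs)
        dists = [
            regs[i + 1].start - regs[i].end - 1 for i in range(len(regs) - 1)
        ]
        rows.append(
            {
                "chrom": chrom,
                "chrom_length": clen,
                "cnvr_count": len(regs),
                "total_cnvr_length": total,
                "average_size": total / len(regs) if regs else np.nan,
                "coverage_pct": 100.0 * total / clen,
                "mean_distance": float(np.mean(dists)) if dists else np.nan,
                "min_distance": float(np.min(dists)) if dists else np.nan,
                "max_distance": float(np.max(dists)) if dists else np.nan,
            }
        )
    table = pd.DataFrame(rows)

    x = table["chrom_length"].to_numpy(dtype=float)
    y = table["cnvr_count"].to_numpy(dtype=float)
    if len(x) >= 2 and np.ptp(x) > 0:
        res = stats.linregress(x, y)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    else:
        slope = intercept = r2 = float("nan")
    return ChromosomeSummary(
        table=table,
        length_histogram=length_histogram([r.length for r in cnvrs]),
        regression_slope=float(slope),
        regression_intercept=float(intercept),
        r_squared=float(r2),
    )
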