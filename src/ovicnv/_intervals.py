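"""Interval-overlap plumbing shared by the merging/comparison/annotation steps.

All public pipeline semantics use 1-based inclusive coordinates with the
1-bp overlap rule: [s1,e1] and [s2,e2] overlap iff s2 <= e1 and s1 <= e2.
intervaltree uses half-open intervals, so queries add 1 to the end.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

from intervaltree import IntervalTree


def build_trees(items: Iterable) -> dict:
    """One IntervalTree per chromosome from objects with chrom/start/end."""
    trees: dict = defaultdict(IntervalTree)
    for it in items:
        trees[it.chrom].addi(it.start, it.end + 1, it)
    return dict(trees)


def query(trees: dict, chrom: str, start: int, end: int) -> list:
    """All stored objects overlapping [start, end] by >= 1 bp."""
    tree = trees.get(chrom)
    if tree is None:
        return []
    return [iv.data for iv in tree.overlap(start, end + 1)]


def overlaps_any(trees: dict, chrom: str, start: int, end: int) -> bool:
    tree = trees.get(chrom)
    return tree is not None and bool(tree.overlap(start, end + 1))


def merge_chained(intervals: Iterable) -> list[tuple[str, int, int, list]]:
    """Single-linkage (transitive) union of intervals per chromosome.

    Returns (chrom, start, end, members) tuples; intervals join iff they
    overlap by >= 1 bp, and merging chains, so a merged region may span
    members that do not directly overlap each other.
    """
    by_chrom: dict = defaultdict(list)
    for it in intervals:
        by_chrom[it.chrom].append(it)
    merged = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end, members = None, None, []
        for it in items:
            if cur_start is None:
                cur_start, cur_end, members = it.start, it.end, [it]
            elif it.start <= cur_end:  # >=1 bp overlap (1-based inclusive)
                cur_end = max(cur_end, it.end)
                members.append(it)
            else:
                merged.append((chrom, cur_start, cur_end, members))
                cur_start, cur_end, members = it.start, it.end, [it]
        if cur_start is not None:
            merged.append((chrom, cur_start, cur_end, members))
    return merged
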