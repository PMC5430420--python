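"""Cross-study CNVR comparison: novelty, composite set, ordination, breed-specific.

All overlap tests use the same >= 1 bp rule as CNVR merging.  The composite
set is the single-linkage union-merge of every study's regions; each study's
presence across composite regions forms a binary matrix that feeds PCA
(row-centered, unscaled) and average-linkage hierarchical clustering on
Jaccard distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import Region, StudyDataset
from ._intervals import build_trees, merge_chained, overlaps_any, query

__all__ = [
    "classify_novelty",
    "build_composite",
    "ordinate",
    "breed_specific",
    "CompositeResult",
    "OrdinationResult",
]


def classify_novelty(
    query_regions: Sequence,
    references: Sequence[StudyDataset],
) -> tuple[list[bool], dict]:
    """Flag each query CNVR as known (overlaps any reference by >= 1 bp).

    Returns (known_flags, per_study_counts) where each per-study count is
    the number of query regions overlapping that study.
    """
    trees = {ds.label: build_trees(ds.regions) for ds in references}
    known = []
    counts = {ds.label: 0 for ds in references}
    for q in query_regions:
        hit_any = False
        for label, tr in trees.items():
            if overlaps_any(tr, q.chrom, q.start, q.end):
                counts[label] += 1
                hit_any = True
        known.append(hit_any)
    return known, counts


@dataclass
class CompositeResult:
    regions: list              # merged composite Regions, sorted
    presence: np.ndarray       # studies x composite regions, {0,1}
    study_labels: list


def build_composite(datasets: Sequence[StudyDataset]) -> CompositeResult:
    """Union-merge all studies' CNVRs and build the binary presence matrix."""
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to build a composite")
    all_regions = [r for ds in datasets for r in ds.regions]
    merged = [
        Region(chrom=c, start=s, end=e)
        for c, s, e, _ in merge_chained(all_regions)
    ]
    merged.sort(key=lambda r: (r.chrom, r.start))
    labels = [ds.label for ds in datasets]
    presence = np.zeros((len(datasets), len(merged)), dtype=np.int8)
    for i, ds in enumerate(datasets):
        trees = build_trees(ds.regions)
        for j, reg in enumerate(merged):
            if overlaps_any(trees, reg.chrom, reg.start, reg.end):
                presence[i, j] = 1
    return CompositeResult(regions=merged, presence=presence, study_labels=labels)


@dataclass
class OrdinationResult:
    scores: np.ndarray            # studies x components (PC scores)
    components: np.ndarray        # components x regions, orthonormal
    explained_variance: np.ndarray
    linkage: np.ndarray           # scipy linkage matrix (average, Jaccard)
    jaccard_distances: np.ndarray  # condensed distance vector
    study_labels: list


def ordinate(
    presence: np.ndarray,
    study_labels: Optional[Sequence[str]] = None,
) -> OrdinationResult:
    """PCA and hierarchical clustering of the study presence matrix.

    PCA: each study's row is centered on its own mean (binary data are not
    scaled) and the centered matrix is decomposed by SVD; scores are the
    projections U @ diag(S), components the right singular vectors, and
    explained variances S^2 / (n_regions - 1).  Clustering: average linkage
    on pairwise Jaccard distance between the raw presence rows.
    """
    presence = np.asarray(presence, dtype=float)
    if presence.ndim != 2 or presence.shape[0] < 2 or presence.shape[1] < 2:
        raise ValueError("presence matrix must be >= 2 studies x >= 2 regions")
    if study_labels is None:
        study_labels = [f"study{i + 1}" for i in range(presence.shape[0])]

    centered = presence - presence.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("presence matrix has zero variance in every row")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    explained = s**2 / (presence.shape[1] - 1)

    dist = pdist(presence.astype(bool), metric="jaccard")
    link = hierarchy.linkage(dist, method="average")
    return OrdinationResult(
        scores=scores,
        components=vt,
        explained_variance=explained,
        linkage=link,
        jaccard_distances=dist,
        study_labels=list(study_labels),
    )


def dendrogram_newick(result: OrdinationResult) -> str:
    """Serialise the clustering as a Newick string with merge heights."""
    tree = hierarchy.to_tree(result.linkage)
    labels = result.study_labels

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def breed_specific(
    datasets: Sequence[StudyDataset],
    min_len: int = 100_000,
) -> tuple[dict, dict]:
    """Breed-private CNVRs after a minimum-length filter.

    Per dataset: drop regions shorter than ``min_len``, re-merge within the
    dataset, then keep the merged regions overlapping (>= 1 bp) no filtered
    region of any other dataset.  Also returns Venn membership counts keyed
    by the sorted tuple of breeds sharing each merged region.
    """
    filtered_merged = {}
    for ds in datasets:
        keep = [r for r in ds.regions if r.length >= min_len]
        filtered_merged[ds.label] = [
            Region(chrom=c, start=s, end=e) for c, s, e, _ in merge_chained(keep)
        ]
    trees = {lab: build_trees(regs) for lab, regs in filtered_merged.items()}

    specific = {}
    for lab, regs in filtered_merged.items():
        specific[lab] = [
            r
            for r in regs
            if not any(
                overlaps_any(tr, r.chrom, r.start, r.end)
                for other, tr in trees.items()
                if other != lab
            )
        ]

    # Venn counts over the composite of all filtered regions, each counted once
    composite = [
        Region(chrom=c, start=s, end=e)
        for c, s, e, _ in merge_chained(
            r for regs in filtered_merged.values() for r in regs
        )
    ]
    venn: dict = {}
    for r in composite:
        members = tuple(
            sorted(
                lab
                for lab, tr in trees.items()
                if overlaps_any(tr, r.chrom, r.start, r.end)
            )
        )
        venn[members] = venn.get(members, 0) + 1
    return specific, venn
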