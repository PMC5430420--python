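"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive (per-base bitmaps, all-pairs scans,
exhaustive enumeration) and shares no code with the implementation paths it
checks.  Intended for toy instances only (chromosomes <= ~1 Mb).
"""

from __future__ import annotations

import math

import numpy as np


def bitmap_union(intervals, chrom_len):
    """Per-base boolean cover of 1-based inclusive (start, end) pairs."""
    cover = np.zeros(chrom_len + 1, dtype=bool)  # index 0 unused
    for s, e in intervals:
        cover[s : e + 1] = True
    return cover


def bitmap_merged_blocks(intervals, chrom_len):
    """Maximal runs of covered bases -> list of (start, end)."""
    cover = bitmap_union(intervals, chrom_len)
    blocks = []
    i = 1
    while i <= chrom_len:
        if cover[i]:
            j = i
            while j + 1 <= chrom_len and cover[j + 1]:
                j += 1
            blocks.append((i, j))
            i = j + 1
        else:
            i += 1
    return blocks


def pairs_overlap(a, b):
    """1-bp overlap rule on 1-based inclusive intervals."""
    return a[0] <= b[1] and b[0] <= a[1]


def all_pairs_hits(queries, references):
    """For each query (chrom, s, e): indices of references overlapping it."""
    out = []
    for qc, qs, qe in queries:
        out.append(
            [
                i
                for i, (rc, rs, re_) in enumerate(references)
                if rc == qc and pairs_overlap((qs, qe), (rs, re_))
            ]
        )
    return out


def hypergeom_upper_p(n_universe, n_set, n_hits, k):
    """P(X >= k) by direct summation of hypergeometric terms via math.comb."""
    total = math.comb(n_universe, n_hits)
    acc = 0
    for x in range(k, min(n_set, n_hits) + 1):
        acc += math.comb(n_set, x) * math.comb(n_universe - n_set, n_hits - x)
    return acc / total


def hwe_exact_p(n_aa, n_ab, n_bb):
    """Exact conditional Hardy-Weinberg test (two-sided, by probability).

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of tables no more likely than the
    observed one.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def log_prob(nab):
        naa = (n_a - nab) // 2
        nbb = n - naa - nab
        return (
            math.lgamma(n + 1)
            - math.lgamma(naa + 1)
            - math.lgamma(nab + 1)
            - math.lgamma(nbb + 1)
            + nab * math.log(2)
            + math.lgamma(n_a + 1)
            + math.lgamma(2 * n - n_a + 1)
            - math.lgamma(2 * n + 1)
        )

    feasible = [
        nab
        for nab in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
        if (n_a - nab) >= 0 and (n - (n_a - nab) // 2 - nab) >= 0
    ]
    probs = {nab: math.exp(log_prob(nab)) for nab in feasible}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs + 1e-12)


def pearson_r(x, y):
    """Textbook covariance-formula Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def pca_scores_eigh(matrix):
    """PC scores via an explicit Gram-matrix eigen-solve on row-centered data.

    Returns scores (rows x components) sorted by decreasing eigenvalue; each
    column is determined up to sign.
    """
    x = np.asarray(matrix, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    gram = xc @ xc.T
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    return vecs * np.sqrt(np.maximum(vals, 0.0))
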