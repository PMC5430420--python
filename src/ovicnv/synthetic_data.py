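"""Synthetic SNP-array cohorts with known CNV truth.

Emulates the statistical structure the downstream analysis assumes: a
multi-chromosome autosomal genome, a dense uniform marker map, per-sample
CNV truth with a strong loss excess (~10:1 loss:gain), copy-number-shifted
LRR with Gaussian noise, genotype-mixture BAF, per-sample artifact knobs
(BAF drift, LRR waviness) and multi-study CNVR tables with controlled
overlap.  Everything is deterministic given ``SimulationConfig.seed``
(numpy ``default_rng``, i.e. the PCG64 generator, is used throughout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import GenomeBuild, MarkerMap, Region, SampleSignal, StudyDataset, TruthCNV
from ._intervals import build_trees, overlaps_any

__all__ = [
    "SimulationConfig",
    "SyntheticStudySet",
    "simulate_truth",
    "simulate_signals",
    "simulate_study_tables",
    "sample_ids",
]

# Canonical Illumina-array per-copy-number LRR means.
DEFAULT_LRR_MEANS = {0: -3.5, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68}

# Scaled-down autosomal genome: 5 chromosomes, 75 Mb total.
DEFAULT_CHROM_LENGTHS = {
    "1": 20_000_000,
    "2": 18_000_000,
    "3": 15_000_000,
    "4": 12_000_000,
    "5": 10_000_000,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the real experiment where it states them (48 animals,
    ~10:1 loss:gain odds) and a desk-scale genome elsewhere.
    """

    seed: int = 0
    n_samples: int = 48
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    markers_per_mb: float = 230.0          # ~600K probes over a 2.6-Gb genome
    cnv_rate_per_mb: float = 0.042         # expected CNVs per sample per Mb
    cnv_length_bounds: tuple = (50_000, 300_000)  # log-uniform, bp
    loss_gain_odds: float = 10.0
    lrr_means: dict = field(default_factory=lambda: dict(DEFAULT_LRR_MEANS))
    lrr_sd: float = 0.2
    baf_sd: float = 0.03
    baf_drift: float = 0.0                 # fraction of hom BAFs pushed into drift bands
    waviness_amplitude: float = 0.0        # LRR sine amplitude
    waviness_period: float = 8_000_000.0   # bp
    genotype_missing_rate: float = 0.005
    pfb_beta: tuple = (0.7, 0.7)

    def __post_init__(self):
        if self.cnv_rate_per_mb < 0 or self.markers_per_mb <= 0:
            raise ValueError("rates must be non-negative, density positive")
        if self.loss_gain_odds <= 0:
            raise ValueError("loss:gain odds must be positive")
        lo, hi = self.cnv_length_bounds
        if lo < 1_000 or hi < lo:
            raise ValueError("CNV length bounds must be >= 1 kb and ordered")
        if not 0 <= self.baf_drift <= 1:
            raise ValueError("baf_drift fraction must lie in [0, 1]")

    @property
    def genome(self) -> GenomeBuild:
        return GenomeBuild(lengths=self.chrom_lengths)


def sample_ids(config: SimulationConfig) -> list[str]:
    width = max(2, len(str(config.n_samples)))
    return [f"S{i + 1:0{width}d}" for i in range(config.n_samples)]


def _unique_positions(rng, length: int, n: int) -> np.ndarray:
    """n distinct uniform positions in 1..length, sorted."""
    if n > length:
        raise ValueError("more markers than base pairs")
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.1) + 10))
    while pos.size < n:
        pos = np.unique(
            np.concatenate([pos, rng.integers(1, length + 1, size=n)])
        )
    return np.sort(rng.choice(pos, size=n, replace=False))


def _draw_cn(rng, odds: float) -> int:
    """Copy number for one event: loss with prob odds/(odds+1)."""
    if rng.random() < odds / (odds + 1.0):
        return 1 if rng.random() < 0.9 else 0
    return 3 if rng.random() < 0.9 else 4


def simulate_truth(
    config: SimulationConfig,
) -> tuple[list[TruthCNV], MarkerMap, GenomeBuild]:
    """Draw the marker map and per-sample ground-truth CNVs.

    CNV counts per sample/chromosome are Poisson with mean
    ``cnv_rate_per_mb * Mb``; lengths are log-uniform within the configured
    bounds; placements that would overlap an existing CNV of the same
    sample are rejected (truth stays unambiguous).  PFB is Beta-distributed
    and clamped to [0.01, 0.99].
    """
    rng = np.random.default_rng([config.seed, 1])
    genome = config.genome

    ids, chroms, poss = [], [], []
    for chrom, length in genome.lengths.items():
        n = max(2, int(round(length / 1e6 * config.markers_per_mb)))
        pos = _unique_positions(rng, length, n)
        ids.extend(f"snp{chrom}_{i + 1}" for i in range(n))
        chroms.extend([chrom] * n)
        poss.append(pos)
    pfb = np.clip(
        rng.beta(*config.pfb_beta, size=len(ids)), 0.01, 0.99
    )
    marker_map = MarkerMap(ids, chroms, np.concatenate(poss), pfb)

    lo, hi = config.cnv_length_bounds
    if lo * config.markers_per_mb / 1e6 < 1:
        warnings.warn(
            "marker density too low to cover the shortest CNV with >= 1 marker"
        )

    truth: list[TruthCNV] = []
    for sample in sample_ids(config):
        for chrom, length in genome.lengths.items():
            n_cnv = rng.poisson(config.cnv_rate_per_mb * length / 1e6)
            placed: list[tuple[int, int]] = []
            for _ in range(n_cnv):
                for _try in range(100):
                    seg_len = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
                    seg_len = min(seg_len, length)
                    start = int(rng.integers(1, length - seg_len + 2))
                    end = start + seg_len - 1
                    if all(e < start or s > end for s, e in placed):
                        placed.append((start, end))
                        truth.append(
                            TruthCNV(
                                sample=sample,
                                chrom=chrom,
                                start=start,
                                end=end,
                                cn=_draw_cn(rng, config.loss_gain_odds),
                            )
                        )
                        break
    return truth, marker_map, genome


_GT_CODES = np.array(["AA", "AB", "BB"], dtype=object)
_DRIFT_BANDS = ((0.20, 0.25), (0.75, 0.80))


def simulate_signals(
    truth: Sequence[TruthCNV],
    marker_map: MarkerMap,
    config: SimulationConfig,
    samples: Optional[Sequence[str]] = None,
) -> list[SampleSignal]:
    """Generate LRR/BAF/genotype vectors for each sample given the truth.

    LRR ~ Normal(mu[cn], lrr_sd) with mu[2] = 0, plus an optional sinusoidal
    waviness component.  BAF is drawn from the genotype mixture implied by
    PFB and copy number: B-allele dosage b ~ Binomial(cn, PFB), cluster mean
    b/cn, Gaussian noise clipped to [0, 1]; cn = 0 markers are uniform noise.
    Reported genotypes are the diploid array calls (AA/AB/BB).
    """
    rng = np.random.default_rng([config.seed, 2])
    if samples is None:
        samples = sample_ids(config)
    n = len(marker_map)
    pfb = marker_map.pfb
    mu = np.array([config.lrr_means[cn] for cn in range(5)])

    by_sample: dict = {s: [] for s in samples}
    for t in truth:
        if t.sample in by_sample:
            by_sample[t.sample].append(t)

    out = []
    for sample in samples:
        cn = np.full(n, 2, dtype=np.int64)
        for t in by_sample[sample]:
            sl = marker_map.chrom_slice(t.chrom)
            pos = marker_map.pos[sl]
            hit = (pos >= t.start) & (pos <= t.end)
            cn[np.arange(sl.start, sl.stop)[hit]] = t.cn

        lrr = mu[cn] + rng.normal(0.0, config.lrr_sd, size=n)
        if config.waviness_amplitude > 0:
            lrr += config.waviness_amplitude * np.sin(
                2 * np.pi * marker_map.pos / config.waviness_period
            )

        # diploid genotype calls, used for BAF at cn=2 and for the GType column
        b_dip = rng.binomial(2, pfb)
        genotype = _GT_CODES[b_dip].copy()
        if config.genotype_missing_rate > 0:
            miss = rng.random(n) < config.genotype_missing_rate
            genotype[miss] = "NC"

        baf = np.empty(n)
        for state in np.unique(cn):
            m = cn == state
            if state == 0:
                baf[m] = rng.random(m.sum())
            elif state == 2:
                baf[m] = b_dip[m] / 2.0 + rng.normal(0, config.baf_sd, m.sum())
            else:
                b = rng.binomial(state, pfb[m])
                baf[m] = b / state + rng.normal(0, config.baf_sd, m.sum())
        baf = np.clip(baf, 0.0, 1.0)

        if config.baf_drift > 0:
            hom = np.flatnonzero((b_dip != 1) & (cn == 2))
            k = int(round(config.baf_drift * hom.size))
            if k:
                pick = rng.choice(hom, size=k, replace=False)
                band = rng.integers(0, 2, size=k)
                lo = np.where(band == 0, _DRIFT_BANDS[0][0], _DRIFT_BANDS[1][0])
                hi = np.where(band == 0, _DRIFT_BANDS[0][1], _DRIFT_BANDS[1][1])
                baf[pick] = rng.uniform(lo, hi)

        out.append(SampleSignal(sample=sample, lrr=lrr, baf=baf, genotype=genotype))
    return out


@dataclass
class SyntheticStudySet:
    """Study tables plus the generator's bookkeeping for testing."""

    datasets: list
    shared: list          # Regions every study received (pre-jitter coords)
    private: dict         # study label -> list of Regions unique to it

    def private_counts(self) -> dict:
        return {label: len(regs) for label, regs in self.private.items()}


def simulate_study_tables(
    base_regions: Sequence[Region],
    n_studies: int,
    overlap_fraction: float,
    seed: int,
    jitter: float = 0.0,
) -> SyntheticStudySet:
    """Build several studies' CNVR tables with controlled overlap.

    A fraction ``overlap_fraction`` of the base regions is shared by every
    study (boundaries jittered by up to ``jitter`` x region length); the
    remaining slots are filled with per-study private regions placed so they
    overlap nothing else.  ``overlap_fraction=1, jitter=0`` yields identical
    studies; ``overlap_fraction=0`` yields pairwise-disjoint studies.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng([seed, 3])
    base = sorted(base_regions, key=lambda r: (r.chrom, r.start, r.end))
    n_base = len(base)
    k_shared = int(round(overlap_fraction * n_base))
    order = rng.permutation(n_base)
    shared = [base[i] for i in order[:k_shared]]
    n_private = n_base - k_shared

    # occupied space: everything already placed, grown as we add privates
    occupied = list(base)
    chrom_span = {}
    for r in base:
        chrom_span[r.chrom] = max(chrom_span.get(r.chrom, 0), r.end)
    chroms = sorted(chrom_span)
    lengths = np.array([r.length for r in base]) if base else np.array([100_000])

    def jittered(r: Region) -> Region:
        if jitter <= 0:
            return r
        d = int(r.length * jitter)
        s = max(1, r.start + int(rng.integers(-d, d + 1)))
        e = max(s, r.end + int(rng.integers(-d, d + 1)))
        return Region(chrom=r.chrom, start=s, end=e, state=r.state)

    datasets, private = [], {}
    for i in range(n_studies):
        label = f"study{i + 1}"
        mine = []
        trees = build_trees(occupied)
        for _ in range(n_private):
            for _try in range(500):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                seg_len = int(rng.choice(lengths))
                span = max(chrom_span[chrom] * 2, seg_len * 10)
                start = int(rng.integers(1, span - seg_len + 2))
                end = start + seg_len - 1
                if not overlaps_any(trees, chrom, start, end):
                    reg = Region(chrom=chrom, start=start, end=end)
                    mine.append(reg)
                    occupied.append(reg)
                    trees = build_trees(occupied)
                    break
        private[label] = sorted(mine, key=lambda r: (r.chrom, r.start))
        regions = [jittered(r) for r in shared] + mine
        datasets.append(StudyDataset(label=label, regions=regions))
    return SyntheticStudySet(datasets=datasets, shared=shared, private=private)
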