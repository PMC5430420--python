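"""Core domain types shared across the pipeline.

Coordinates are 1-based, inclusive throughout (PennCNV convention:
``length = end - start + 1``).  BED files are converted at the I/O boundary.
Chromosome labels are normalised by stripping a leading ``chr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np


def normalize_chrom(chrom: str | int) -> str:
    """Strip a leading ``chr`` prefix and return the label as a string."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if not c:
        raise ValueError("empty chromosome label")
    return c


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths plus optional assembly-gap intervals.

    Autosomes are conventionally labelled ``"1"``..``"26"`` for the ovine
    genome, but any unique labels are accepted.
    """

    lengths: Mapping[str, int]
    gaps: Mapping[str, Sequence[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {normalize_chrom(c): int(n) for c, n in self.lengths.items()}
        if len(lengths) != len(self.lengths):
            raise ValueError("chromosome names not unique after normalisation")
        for c, n in lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {n}")
        gaps = {}
        for c, ivs in self.gaps.items():
            c = normalize_chrom(c)
            if c not in lengths:
                raise ValueError(f"gap on unknown chromosome {c}")
            for s, e in ivs:
                if not (1 <= s <= e <= lengths[c]):
                    raise ValueError(
                        f"gap [{s},{e}] outside chromosome {c} (1..{lengths[c]})"
                    )
            gaps[c] = sorted((int(s), int(e)) for s, e in ivs)
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "gaps", gaps)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def total_length(self) -> int:
        return sum(self.lengths.values())


class MarkerMap:
    """Ordered SNP marker map: id, chromosome, 1-based position, PFB.

    Markers must be sorted with strictly increasing positions within each
    chromosome; ids must be unique; PFB values lie in [0, 1] (NaN allowed
    until filled by :func:`ovicnv.qc.compute_pfb`).
    """

    def __init__(self, ids, chrom, pos, pfb=None):
        self.ids = np.asarray(ids, dtype=object)
        self.chrom = np.asarray([normalize_chrom(c) for c in chrom], dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        n = len(self.ids)
        if not (len(self.chrom) == len(self.pos) == n):
            raise ValueError("marker map columns have unequal lengths")
        if pfb is None:
            self.pfb = np.full(n, np.nan)
        else:
            self.pfb = np.asarray(pfb, dtype=float)
            finite = self.pfb[np.isfinite(self.pfb)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("PFB values outside [0, 1]")
        if len(set(self.ids)) != n:
            raise ValueError("marker ids not unique")
        # strictly increasing positions within each chromosome block
        self._index = {}
        start = 0
        for i in range(1, n + 1):
            if i == n or self.chrom[i] != self.chrom[start]:
                c = self.chrom[start]
                if c in self._index:
                    raise ValueError(f"chromosome {c} markers not contiguous")
                block = self.pos[start:i]
                if np.any(np.diff(block) <= 0):
                    raise ValueError(
                        f"positions not strictly increasing on chromosome {c}"
                    )
                self._index[c] = (start, i)
                start = i

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._index)

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index range of one chromosome's markers."""
        start, stop = self._index[normalize_chrom(chrom)]
        return slice(start, stop)

    def id_index(self) -> dict:
        return {m: i for i, m in enumerate(self.ids)}


@dataclass
class SampleSignal:
    """Per-sample LRR/BAF/genotype vectors aligned to a :class:`MarkerMap`.

    Missing LRR/BAF are NaN; missing genotypes are ``"NC"``.  Genotypes are
    the diploid array calls (``AA``/``AB``/``BB``) regardless of copy number.
    """

    sample: str
    lrr: np.ndarray
    baf: np.ndarray
    genotype: Optional[np.ndarray] = None

    def __post_init__(self):
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        if self.lrr.shape != self.baf.shape:
            raise ValueError("LRR and BAF lengths differ")
        finite = self.baf[np.isfinite(self.baf)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError(f"BAF outside [0, 1] for sample {self.sample}")
        if self.genotype is not None:
            self.genotype = np.asarray(self.genotype, dtype=object)
            if self.genotype.shape != self.lrr.shape:
                raise ValueError("genotype length differs from signal length")

    def __len__(self) -> int:
        return len(self.lrr)


@dataclass(frozen=True)
class CNVCall:
    """One contiguous copy-number segment in one sample."""

    sample: str
    chrom: str
    start: int
    end: int
    cn: int
    num_snps: int
    mean_lrr: float = float("nan")

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.cn == 2:
            raise ValueError("cn=2 is the diploid background, not a CNV")
        if not 0 <= self.cn <= 4:
            raise ValueError(f"copy number {self.cn} outside supported range 0..4")
        if self.num_snps < 1:
            raise ValueError("a call must span at least one SNP")

    @property
    def state(self) -> str:
        return "loss" if self.cn < 2 else "gain"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TruthCNV:
    """Simulation ground truth: one injected CNV in one sample (cn != 2)."""

    sample: str
    chrom: str
    start: int
    end: int
    cn: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end < self.start:
            raise ValueError("end < start")
        if self.cn == 2 or not 0 <= self.cn <= 4:
            raise ValueError(f"invalid truth copy number {self.cn}")

    @property
    def state(self) -> str:
        return "loss" if self.cn < 2 else "gain"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CNVR:
    """Copy-number-variable region: union of overlapping CNVs across samples."""

    chrom: str
    start: int
    end: int
    state: str  # loss | gain | both
    samples: tuple
    n_cnvs: int
    frequency: float  # percent of cohort carrying >=1 overlapping CNV

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end < self.start:
            raise ValueError("end < start")
        if self.state not in ("loss", "gain", "both"):
            raise ValueError(f"invalid CNVR state {self.state}")
        if not (0 < self.frequency <= 100):
            raise ValueError("frequency must be in (0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IntervalRecord:
    """Generic labelled genomic interval (gene, QTL class, assembly gap...)."""

    chrom: str
    start: int
    end: int
    id: str = ""
    category: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval [{self.start},{self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Region:
    """Bare interval with optional state, as found in published CNVR tables."""

    chrom: str
    start: int
    end: int
    state: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end < self.start:
            raise ValueError("end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class StudyDataset:
    """A labelled collection of CNVRs from one study/breed."""

    label: str
    regions: list
    platform: str = ""

    def __post_init__(self):
        self.regions = sorted(
            (r if isinstance(r, Region) else Region(*r) for r in self.regions),
            key=lambda r: (r.chrom, r.start, r.end),
        )

    def __len__(self) -> int:
        return len(self.regions)


def sort_intervals(items: Iterable) -> list:
    """Sort any objects with chrom/start/end by (chromosome, start, end)."""
    return sorted(items, key=lambda r: (r.chrom, r.start, r.end))
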