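"""Sample- and marker-level quality control, plus PFB computation.

Sample filters (all must hold to pass):

* genotype call rate >= 0.90
* SD of autosomal LRR < 0.30
* BAF drift < 0.01 — fraction of BAFs in the artifact bands
  [0.20, 0.25] u [0.75, 0.80]
* waviness factor < 0.05 — SD of per-window (default 1 Mb) median LRR,
  a GC-free proxy for long-range intensity waves

Marker filters: missingness <= 0.10, MAF >= 0.05, and Hardy-Weinberg
chi-square P above a Bonferroni-adjusted 1e-5 threshold (raw
P >= 1e-5 / n_markers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import MarkerMap, SampleSignal

__all__ = [
    "SampleQC",
    "MarkerQC",
    "compute_sample_qc",
    "compute_marker_qc",
    "compute_pfb",
    "CALL_RATE_MIN",
    "SD_LRR_MAX",
    "BAF_DRIFT_MAX",
    "WAVINESS_MAX",
    "MISSINGNESS_MAX",
    "MAF_MIN",
    "HWE_ALPHA",
]

CALL_RATE_MIN = 0.90
SD_LRR_MAX = 0.30
BAF_DRIFT_MAX = 0.01
WAVINESS_MAX = 0.05
MISSINGNESS_MAX = 0.10
MAF_MIN = 0.05
HWE_ALPHA = 1e-5

_DRIFT_LO = (0.20, 0.25)
_DRIFT_HI = (0.75, 0.80)


@dataclass(frozen=True)
class SampleQC:
    sample: str
    call_rate: float
    sd_lrr: float
    baf_drift: float
    waviness: float

    @property
    def passed(self) -> bool:
        return (
            self.call_rate >= CALL_RATE_MIN
            and self.sd_lrr < SD_LRR_MAX
            and self.baf_drift < BAF_DRIFT_MAX
            and self.waviness < WAVINESS_MAX
        )


@dataclass(frozen=True)
class MarkerQC:
    marker: str
    missingness: float
    maf: float
    hwe_p: float
    hwe_threshold: float

    @property
    def passed(self) -> bool:
        return (
            self.missingness <= MISSINGNESS_MAX
            and self.maf >= MAF_MIN
            and self.hwe_p >= self.hwe_threshold
        )


def compute_sample_qc(
    signal: SampleSignal,
    marker_map: MarkerMap,
    window_size: int = 1_000_000,
) -> SampleQC:
    """Per-sample QC metrics from a signal aligned to *marker_map*.

    Missing LRR/BAF values are excluded from every statistic rather than
    treated as zero.  Call rate is 1.0 when no genotype column is present.
    """
    lrr_ok = np.isfinite(signal.lrr)
    baf_ok = np.isfinite(signal.baf)
    if lrr_ok.sum() < 2:
        raise ValueError(
            f"sample {signal.sample}: fewer than 2 non-missing LRR markers"
        )
    sd_lrr = float(np.std(signal.lrr[lrr_ok], ddof=1))

    baf = signal.baf[baf_ok]
    in_bands = ((baf >= _DRIFT_LO[0]) & (baf <= _DRIFT_LO[1])) | (
        (baf >= _DRIFT_HI[0]) & (baf <= _DRIFT_HI[1])
    )
    baf_drift = float(in_bands.mean()) if baf.size else 0.0

    medians = []
    for chrom in marker_map.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        pos = marker_map.pos[sl]
        lrr = signal.lrr[sl]
        win = (pos - 1) // window_size
        for w in np.unique(win):
            vals = lrr[(win == w) & np.isfinite(lrr)]
            if vals.size:
                medians.append(np.median(vals))
    waviness = float(np.std(medians, ddof=0)) if len(medians) > 1 else 0.0

    if signal.genotype is not None:
        call_rate = float(np.mean(signal.genotype != "NC"))
    else:
        call_rate = 1.0

    return SampleQC(
        sample=signal.sample,
        call_rate=call_rate,
        sd_lrr=sd_lrr,
        baf_drift=baf_drift,
        waviness=waviness,
    )


def hwe_chi2_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg chi-square goodness-of-fit P (1 df).

    Monomorphic markers are defined to have P = 1.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)  # A-allele frequency
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def compute_marker_qc(
    genotypes: np.ndarray,
    marker_map: MarkerMap,
    hwe_alpha: float = HWE_ALPHA,
) -> list[MarkerQC]:
    """Marker QC over a (samples x markers) genotype matrix of AA/AB/BB/NC.

    The HWE threshold is Bonferroni-adjusted: a marker fails when its raw
    chi-square P falls below ``hwe_alpha / n_markers``.
    """
    genotypes = np.asarray(genotypes, dtype=object)
    if genotypes.ndim != 2 or genotypes.shape[1] != len(marker_map):
        raise ValueError("genotype matrix must be samples x markers")
    n_markers = genotypes.shape[1]
    threshold = hwe_alpha / n_markers
    out = []
    for j in range(n_markers):
        col = genotypes[:, j]
        n_aa = int(np.sum(col == "AA"))
        n_ab = int(np.sum(col == "AB"))
        n_bb = int(np.sum(col == "BB"))
        n_called = n_aa + n_ab + n_bb
        missing = 1.0 - n_called / genotypes.shape[0]
        if n_called:
            freq_b = (2 * n_bb + n_ab) / (2 * n_called)
            maf = min(freq_b, 1 - freq_b)
        else:
            maf = 0.0
        out.append(
            MarkerQC(
                marker=marker_map.ids[j],
                missingness=missing,
                maf=maf,
                hwe_p=hwe_chi2_p(n_aa, n_ab, n_bb),
                hwe_threshold=threshold,
            )
        )
    return out


def compute_pfb(
    signals: Sequence[SampleSignal],
    marker_map: MarkerMap,
) -> MarkerMap:
    """Population frequency of the B allele: per-marker mean non-missing BAF.

    Values are clamped to [0.01, 0.99]; an all-missing marker gets PFB 0.5
    with a warning.
    """
    if not signals:
        raise ValueError("no signals supplied")
    baf = np.vstack([s.baf for s in signals])
    if baf.shape[1] != len(marker_map):
        raise ValueError("signals not aligned to marker map")
    ok = np.isfinite(baf)
    counts = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        pfb = np.where(counts > 0, np.nansum(np.where(ok, baf, 0), axis=0), np.nan)
        pfb = pfb / np.where(counts > 0, counts, 1)
    if np.any(counts == 0):
        warnings.warn(
            f"{int(np.sum(counts == 0))} markers have no non-missing BAF; "
            "PFB set to 0.5"
        )
        pfb[counts == 0] = 0.5
    pfb = np.clip(pfb, 0.01, 0.99)
    return MarkerMap(marker_map.ids, marker_map.chrom, marker_map.pos, pfb)
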