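"""Hidden Markov model segmentation of LRR/BAF signals into copy-number calls.

The model follows the classic SNP-array CNV-calling design: five hidden
states, one per copy number 0-4 (diploid cn=2 is the background; the
copy-neutral LOH state of some callers is omitted because only losses and
gains are analysed downstream).  Per marker, the emission combines

* an LRR term — Gaussian at the state's mean intensity shift, and
* a BAF term — a PFB-weighted mixture over the genotype clusters the state
  allows (cn=2 -> {0, 1/2, 1}; cn=1 -> {0, 1}; cn=3 -> {0, 1/3, 2/3, 1};
  cn=4 -> {0, 1/4, 1/2, 3/4, 1}; cn=0 -> uniform on [0, 1]).  Mixture
  weights are Binomial(cn, PFB) over B-allele dosage; the boundary clusters
  at 0 and 1 are half-Gaussians.

Transitions decay with inter-marker distance:
``P(stay) = 1 - (1 - p_stay) * (1 - exp(-d / d0))``, with the off-diagonal
mass split uniformly.  Decoding is Viterbi in log space, so chromosomes of
10^6 markers stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import CNVCall, MarkerMap, SampleSignal, TruthCNV
from .synthetic_data import DEFAULT_LRR_MEANS

__all__ = [
    "HMMSpec",
    "emission_loglik",
    "viterbi_segment",
    "evaluate_calls",
    "STATES",
]

STATES = (0, 1, 2, 3, 4)

_LOG_2PI = np.log(2 * np.pi)


@dataclass
class HMMSpec:
    """Parameters of the copy-number HMM.

    Emission SDs are deliberately a little wider than typical array noise so
    the decoder tolerates real-data dispersion; ``d0`` sets the genomic
    distance (bp) over which the self-transition relaxes toward ``p_stay``.
    """

    lrr_means: dict = field(default_factory=lambda: dict(DEFAULT_LRR_MEANS))
    lrr_sds: dict = field(
        default_factory=lambda: {cn: 0.25 for cn in STATES}
    )
    baf_sd: float = 0.05
    p_stay: float = 0.999
    d0: float = 100_000.0
    min_snps: int = 3
    start_prob: dict = field(
        default_factory=lambda: {0: 0.001, 1: 0.004, 2: 0.99, 3: 0.004, 4: 0.001}
    )
    distance_decay: bool = True

    def __post_init__(self):
        if not 0 < self.p_stay < 1:
            raise ValueError("p_stay must lie in (0, 1)")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        total = sum(self.start_prob.values())
        self.start_prob = {s: p / total for s, p in self.start_prob.items()}

    def transition_logmatrix(self, distance: float) -> np.ndarray:
        """5x5 log-transition matrix for one inter-marker gap (rows sum to 1)."""
        if self.distance_decay:
            stay = 1 - (1 - self.p_stay) * (1 - np.exp(-distance / self.d0))
        else:
            stay = self.p_stay
        k = len(STATES)
        mat = np.full((k, k), (1 - stay) / (k - 1))
        np.fill_diagonal(mat, stay)
        return np.log(mat)


def _log_norm_pdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI


def emission_loglik(
    lrr,
    baf,
    pfb,
    state: int,
    hmm: Optional[HMMSpec] = None,
) -> np.ndarray:
    """Per-marker emission log-likelihood under one copy-number state.

    Vectorised over markers.  Missing LRR or BAF (NaN) contributes 0 to the
    corresponding term, so an all-missing marker is effectively skipped.
    """
    if hmm is None:
        hmm = HMMSpec()
    if state not in STATES:
        raise ValueError(f"unknown state {state}")
    lrr = np.atleast_1d(np.asarray(lrr, dtype=float))
    baf = np.atleast_1d(np.asarray(baf, dtype=float))
    pfb = np.atleast_1d(np.asarray(pfb, dtype=float))
    if np.any((pfb < 0) | (pfb > 1)):
        raise ValueError("PFB outside [0, 1]")
    finite_baf = baf[np.isfinite(baf)]
    if finite_baf.size and np.any((finite_baf < 0) | (finite_baf > 1)):
        raise ValueError("BAF outside [0, 1]")

    ll = np.zeros(lrr.shape)
    ok = np.isfinite(lrr)
    ll[ok] = _log_norm_pdf(lrr[ok], hmm.lrr_means[state], hmm.lrr_sds[state])

    okb = np.isfinite(baf)
    if okb.any():
        ll[okb] += _baf_mixture_loglik(baf[okb], pfb[okb], state, hmm.baf_sd)
    return ll


def _baf_mixture_loglik(baf, pfb, state, baf_sd) -> np.ndarray:
    """Log of the state's BAF mixture density at each marker."""
    if state == 0:
        return np.zeros(baf.shape)  # uniform density 1 on [0, 1]
    from scipy.stats import binom

    dens = np.zeros(baf.shape)
    for b in range(state + 1):
        w = binom.pmf(b, state, pfb)
        mean = b / state
        comp = np.exp(_log_norm_pdf(baf, mean, baf_sd))
        if mean in (0.0, 1.0):
            comp = 2.0 * comp  # half-Gaussian folded at the boundary
        dens += w * comp
    return np.log(np.maximum(dens, 1e-300))


def baf_mixture_density(x, pfb: float, state: int, baf_sd: float = 0.05):
    """The BAF mixture density itself (for quadrature / diagnostics)."""
    if state == 0:
        return np.ones_like(np.asarray(x, dtype=float))
    x = np.asarray(x, dtype=float)
    return np.exp(_baf_mixture_loglik(x, np.full(x.shape, pfb), state, baf_sd))


def _emission_matrix(lrr, baf, pfb, hmm: HMMSpec) -> np.ndarray:
    return np.vstack(
        [emission_loglik(lrr, baf, pfb, s, hmm) for s in STATES]
    )


def viterbi_segment(
    signal: SampleSignal,
    marker_map: MarkerMap,
    hmm: Optional[HMMSpec] = None,
) -> list[CNVCall]:
    """Decode the MAP copy-number path per chromosome and emit CNV calls.

    Maximal runs of a non-diploid state spanning at least ``hmm.min_snps``
    markers become calls with boundaries at the run's first/last marker
    positions; shorter runs are absorbed into the diploid background.
    """
    if hmm is None:
        hmm = HMMSpec()
    if len(signal) != len(marker_map):
        raise ValueError("signal not aligned to marker map")
    calls: list[CNVCall] = []
    log_start = np.log([hmm.start_prob[s] for s in STATES])

    for chrom in marker_map.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        pos = marker_map.pos[sl]
        n = pos.size
        if n < hmm.min_snps:
            warnings.warn(
                f"chromosome {chrom}: only {n} markers (< min_snps); skipped"
            )
            continue
        emis = _emission_matrix(
            signal.lrr[sl], signal.baf[sl], marker_map.pfb[sl], hmm
        )  # (5, n)
        path = _viterbi(emis, pos, hmm, log_start)
        calls.extend(_path_to_calls(path, pos, signal, sl, chrom, hmm))
    return calls


def _viterbi(emis: np.ndarray, pos: np.ndarray, hmm: HMMSpec, log_start):
    k, n = emis.shape
    delta = log_start + emis[:, 0]
    back = np.zeros((n, k), dtype=np.int8)
    for i in range(1, n):
        log_a = hmm.transition_logmatrix(float(pos[i] - pos[i - 1]))
        cand = delta[:, None] + log_a  # (from, to)
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], np.arange(k)] + emis[:, i]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    if not np.isfinite(delta[path[-1]]):
        raise FloatingPointError("Viterbi score not finite")
    return path


def _path_to_calls(path, pos, signal, sl, chrom, hmm):
    calls = []
    n = path.size
    i = 0
    while i < n:
        if path[i] == 2:
            i += 1
            continue
        j = i
        while j + 1 < n and path[j + 1] == path[i]:
            j += 1
        run_len = j - i + 1
        if run_len >= hmm.min_snps:
            lrr = signal.lrr[sl][i : j + 1]
            lrr = lrr[np.isfinite(lrr)]
            calls.append(
                CNVCall(
                    sample=signal.sample,
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[j]),
                    cn=int(path[i]),
                    num_snps=run_len,
                    mean_lrr=float(np.mean(lrr)) if lrr.size else float("nan"),
                )
            )
        i = j + 1
    return calls


def _boundary_marker_indices(marker_map: MarkerMap, chrom, start, end):
    """Indices (within the chromosome) of the first/last marker in [start, end]."""
    sl = marker_map.chrom_slice(chrom)
    pos = marker_map.pos[sl]
    lo = int(np.searchsorted(pos, start, side="left"))
    hi = int(np.searchsorted(pos, end, side="right")) - 1
    if hi < lo:
        return None
    return lo, hi


def evaluate_calls(
    calls: Sequence[CNVCall],
    truth: Sequence[TruthCNV],
    marker_map: MarkerMap,
    tol_markers: int = 2,
) -> dict:
    """Breakpoint-tolerant precision/recall of calls against simulated truth.

    A call matches a truth event when sample, chromosome and direction
    (loss/gain) agree and both boundary markers lie within ``tol_markers``
    marker indices of the truth event's boundary markers.  Truth events that
    contain no marker are excluded from the recall denominator.
    """
    truth_idx = {}
    n_truth_eval = 0
    for t in truth:
        b = _boundary_marker_indices(marker_map, t.chrom, t.start, t.end)
        if b is None:
            continue
        n_truth_eval += 1
        truth_idx.setdefault((t.sample, t.chrom, t.state), []).append((b, t))

    matched_truth = set()
    n_call_matched = 0
    for c in calls:
        b = _boundary_marker_indices(marker_map, c.chrom, c.start, c.end)
        if b is None:
            continue
        hit = False
        for (tb, t) in truth_idx.get((c.sample, c.chrom, c.state), []):
            if abs(b[0] - tb[0]) <= tol_markers and abs(b[1] - tb[1]) <= tol_markers:
                hit = True
                matched_truth.add(id(t))
        if hit:
            n_call_matched += 1

    precision = n_call_matched / len(calls) if calls else float("nan")
    recall = len(matched_truth) / n_truth_eval if n_truth_eval else float("nan")
    return {
        "n_calls": len(calls),
        "n_truth": n_truth_eval,
        "precision": precision,
        "recall": recall,
    }
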