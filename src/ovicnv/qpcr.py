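"""qPCR copy-number estimation by the 2^-ddCT method.

ddCT = (CT_target,test - CT_ref,test) - (CT_target,calibrator - CT_ref,calibrator)

Fold change is 2^-ddCT; the diploid-normalized ratio NR = 2 * 2^-ddCT puts
the estimate on the copy-number scale: NR ~ 2 means normal, ~1 one copy
deleted, ~0 both copies deleted, and >= ~3 one or more copies gained.
Amplification efficiency is fixed at perfect doubling; replicate CTs are
averaged before the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "QPCRRecord",
    "QPCRResult",
    "ddct",
    "interpret_nr",
    "concordance",
    "CT_CEILING",
]

CT_CEILING = 40.0  # cycles; a fully deleted target never amplifies

_CTLike = Union[float, Sequence[float]]


def _mean_ct(value: _CTLike, name: str) -> float:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 0 or np.any(~np.isfinite(arr)):
        raise ValueError(f"missing or non-finite CT for {name}")
    if np.any(arr <= 0):
        raise ValueError(f"CT values must be positive ({name})")
    return float(arr.mean())


@dataclass(frozen=True)
class QPCRRecord:
    """CT quadruple (target/reference gene x test/calibrator sample).

    Each field accepts a scalar or a sequence of replicate CTs (averaged).
    """

    assay: str
    ct_target_test: _CTLike
    ct_ref_test: _CTLike
    ct_target_cal: _CTLike
    ct_ref_cal: _CTLike


@dataclass(frozen=True)
class QPCRResult:
    assay: str
    ddct: float
    fold_change: float
    nr: float
    status: str

    def __post_init__(self):
        if self.nr <= 0:
            raise ValueError("NR must be positive")


def ddct(record: QPCRRecord) -> QPCRResult:
    """Compute ddCT, fold change 2^-ddCT and NR = 2 * 2^-ddCT for one assay."""
    tgt_test = _mean_ct(record.ct_target_test, "target/test")
    ref_test = _mean_ct(record.ct_ref_test, "reference/test")
    tgt_cal = _mean_ct(record.ct_target_cal, "target/calibrator")
    ref_cal = _mean_ct(record.ct_ref_cal, "reference/calibrator")
    delta_delta = (tgt_test - ref_test) - (tgt_cal - ref_cal)
    fold = 2.0 ** (-delta_delta)
    nr = 2.0 * fold
    return QPCRResult(
        assay=record.assay,
        ddct=delta_delta,
        fold_change=fold,
        nr=nr,
        status=interpret_nr(nr),
    )


def interpret_nr(nr: float) -> str:
    """Map a diploid-normalized ratio to a copy-number status.

    Thresholds sit at the midpoints between the integer-copy ratios
    (0, 1, 2, 3): <0.5 double-deletion, <1.5 single-deletion, <2.5 normal,
    else gain.
    """
    if nr <= 0:
        raise ValueError("NR must be positive")
    if nr < 0.5:
        return "double-deletion"
    if nr < 1.5:
        return "single-deletion"
    if nr < 2.5:
        return "normal"
    return "gain"


def concordance(predicted_cn: Sequence[float], nrs: Sequence[float]) -> dict:
    """Pearson correlation between array copy-number predictions and qPCR NRs."""
    x = np.asarray(predicted_cn, dtype=float)
    y = np.asarray(nrs, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "n": int(x.size)}
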