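"""True-positive-rate estimation from orthogonal validation and
count correction.

Called SNVs are spot-checked by an orthogonal genotyping assay; the
confirmed fraction is the true-positive rate (TPR) of SNV calling, and
raw called-SNV counts are corrected by multiplying with the TPR and
rounding half-up.  Only false positives are corrected for; sensitivity
(false negatives) is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy.stats import binomtest

from .errors import DataError, ValidationError

__all__ = ["ValidationResult", "CorrectedCount", "estimate_tpr", "correct_count"]


@dataclass(frozen=True)
class ValidationResult:
    """TPR estimate with its Clopper-Pearson 95% interval."""

    n_assayed: int
    n_confirmed: int
    tpr: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class CorrectedCount:
    raw: int
    tpr: float
    corrected: int


def estimate_tpr(table: pd.DataFrame, confidence: float = 0.95) -> ValidationResult:
    """Estimate the calling TPR from a validation outcome table.

    ``table`` needs a boolean ``confirmed`` column; each row is one
    assayed call.  The interval is exact (Clopper-Pearson).
    """
    if table is None or len(table) == 0:
        raise DataError("validation table is empty")
    if "confirmed" not in table.columns:
        raise DataError("validation table lacks a 'confirmed' column")
    n = int(len(table))
    k = int(table["confirmed"].astype(bool).sum())
    ci = binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
    return ValidationResult(
        n_assayed=n,
        n_confirmed=k,
        tpr=k / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def _round_half_up(x: Decimal) -> int:
    return int(x.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def correct_count(raw: int, tpr: float) -> CorrectedCount:
    """Correct a raw called-SNV count by the validation TPR.

    ``corrected = round_half_up(raw * tpr)``, computed in decimal
    arithmetic so half-way products round deterministically upward.
    """
    if raw < 0:
        raise ValidationError("raw count must be non-negative")
    if not 0.0 <= tpr <= 1.0:
        raise ValidationError("tpr must be in [0, 1]")
    corrected = _round_half_up(Decimal(int(raw)) * Decimal(repr(float(tpr))))
    return CorrectedCount(raw=int(raw), tpr=float(tpr), corrected=corrected)
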