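"""Clonal-origin inference: the paired-line de novo bound and
VAF-spectrum model selection.

Two iPSC lines derived from distinct cells of one tiny neurosphere
share almost all pre-existing (category I) mutations; mutations unique
to either line are de novo (reprogramming, category II; culture,
category III) plus the handful of category I mutations private to each
founder-cell path within the neurosphere.  The validation-corrected
unique counts therefore *upper-bound* the de novo burden per line, and
their share of each line's total observable SNVs bounds the de novo
fraction.

Clonality itself is read off the variant-allele-frequency spectrum: a
line clonally expanded from a single cell shows its somatic SNVs at VAF
~0.5 (heterozygous, present in every cell), so the spectrum median sits
in a clonal band around 0.5.  Three lineage models are distinguished:

- model 1 (single-cell origin at reprogramming): clonal spectrum, and
  per-line unique SNV counts far exceeding the de novo bound when the
  lines come from unrelated parental cells;
- model 2 (clonal expansion already before reprogramming): rejected
  when vector integration-site (or SNV) VAFs are clonal, placing the
  expansion no earlier than induction;
- model 3 (two picked colonies are subclones of one parental cell):
  rejected when each line's unique count exceeds the de novo bound by a
  configurable factor, with a two-sided binomial count test as backing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binomtest

from .errors import DataError, ValidationError
from .filtering import VariantCall
from .validation import correct_count

__all__ = [
    "PairedComparison",
    "SpectrumSummary",
    "ClonalityVerdict",
    "denovo_upper_bound",
    "vaf_spectrum",
    "select_model",
]


@dataclass(frozen=True)
class PairedComparison:
    """Unique/shared SNV partition of two iPSC lines against one
    germline control, raw and TPR-corrected, with de novo bounds."""

    line_a: str
    line_b: str
    raw_unique_a: int
    raw_unique_b: int
    raw_shared: int
    tpr: float
    corrected_unique_a: int
    corrected_unique_b: int
    corrected_shared: int
    corrected_total_a: int
    corrected_total_b: int
    denovo_fraction_a: float  # percent, reported to 1 decimal
    denovo_fraction_b: float

    @property
    def denovo_bound(self) -> int:
        """Upper bound on the per-line de novo (II + III) count."""
        return max(self.corrected_unique_a, self.corrected_unique_b)

    @property
    def identity_percent(self) -> float:
        """Lower bound on the fraction of the line's profile inherited
        from its progenitor cell: 100 minus the larger de novo fraction."""
        return 100.0 - max(self.denovo_fraction_a, self.denovo_fraction_b)


def denovo_upper_bound(
    raw_unique_a: int,
    raw_unique_b: int,
    raw_shared: int,
    tpr: float,
    totals: tuple[int, int] | None = None,
    corrected_totals: tuple[int, int] | None = None,
    line_a: str = "A",
    line_b: str = "B",
) -> PairedComparison:
    """Bound the per-line de novo mutation burden from a paired design.

    ``totals`` are per-line raw observable SNV counts (corrected here
    with the same TPR); ``corrected_totals`` supplies already-corrected
    totals directly.  Without either, totals default to unique + shared.
    De novo fractions are percentages rounded to one decimal.
    """
    for name, v in (("raw_unique_a", raw_unique_a), ("raw_unique_b", raw_unique_b),
                    ("raw_shared", raw_shared)):
        if v < 0:
            raise ValidationError(f"{name} must be non-negative")
    if not 0.0 < tpr <= 1.0:
        raise ValidationError("tpr must be in (0, 1]")
    cu_a = correct_count(raw_unique_a, tpr).corrected
    cu_b = correct_count(raw_unique_b, tpr).corrected
    cs = correct_count(raw_shared, tpr).corrected
    if corrected_totals is not None:
        ct_a, ct_b = int(corrected_totals[0]), int(corrected_totals[1])
    elif totals is not None:
        ct_a = correct_count(totals[0], tpr).corrected
        ct_b = correct_count(totals[1], tpr).corrected
    else:
        ct_a, ct_b = cu_a + cs, cu_b + cs
    if ct_a == 0 or ct_b == 0:
        raise DataError("corrected total SNV count is zero")
    return PairedComparison(
        line_a=line_a,
        line_b=line_b,
        raw_unique_a=int(raw_unique_a),
        raw_unique_b=int(raw_unique_b),
        raw_shared=int(raw_shared),
        tpr=float(tpr),
        corrected_unique_a=cu_a,
        corrected_unique_b=cu_b,
        corrected_shared=cs,
        corrected_total_a=ct_a,
        corrected_total_b=ct_b,
        denovo_fraction_a=round(100.0 * cu_a / ct_a, 1),
        denovo_fraction_b=round(100.0 * cu_b / ct_b, 1),
    )


@dataclass(frozen=True)
class SpectrumSummary:
    """Box-plot statistics of a VAF spectrum (Tukey whiskers)."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def vaf_spectrum(calls: Sequence[VariantCall] | Sequence[float]) -> SpectrumSummary:
    """Summarise a VAF spectrum as box-plot statistics.

    Accepts calls or bare VAF values.  Whiskers are Tukey: the most
    extreme observations within 1.5 IQR of the quartiles.
    """
    vals = np.asarray(
        [c.vaf if isinstance(c, VariantCall) else float(c) for c in calls],
        dtype=float,
    )
    if vals.size == 0:
        raise DataError("cannot summarise an empty VAF spectrum")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    return SpectrumSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n=int(vals.size),
    )


@dataclass(frozen=True)
class ClonalityVerdict:
    median_vaf: float
    iqr: float
    selected_model: str  # model_1 | model_2 | model_3 | indeterminate
    evidence: tuple[str, ...] = field(default_factory=tuple)


def _excess_over_bound(unique: int, bound: int, factor: float, alpha: float) -> tuple[bool, float]:
    """Is ``unique`` significantly more than ``factor`` times ``bound``?

    Significance uses the conditional binomial comparison of two counts
    (given the total, a count from the same rate is Binomial(n, 1/2))."""
    if unique + bound == 0:
        return False, 1.0
    p = binomtest(unique, unique + bound, 0.5, alternative="two-sided").pvalue
    return (unique > factor * bound) and (p < alpha), float(p)


def select_model(
    spectrum: SpectrumSummary,
    paired: PairedComparison,
    integration_site_vafs: Sequence[float] | None = None,
    denovo_bound: int | None = None,
    clonal_band: tuple[float, float] = (0.4, 0.6),
    model3_factor: float = 3.0,
    alpha: float = 1e-4,
    min_snvs: int = 20,
) -> ClonalityVerdict:
    """Select among the three lineage models for a pair of iPSC lines.

    ``paired`` describes the pair under scrutiny; ``denovo_bound`` is
    the externally estimated per-line de novo upper bound (from the
    neurosphere design experiment).  When omitted, the pair's own
    corrected unique counts serve as the bound, which is conservative.
    With too few SNVs the verdict is ``indeterminate``, never forced.
    """
    evidence: list[str] = []
    if spectrum.n < min_snvs:
        return ClonalityVerdict(
            median_vaf=spectrum.median,
            iqr=spectrum.iqr,
            selected_model="indeterminate",
            evidence=(f"only {spectrum.n} SNVs (< {min_snvs}); spectrum unstable",),
        )
    bound = paired.denovo_bound if denovo_bound is None else int(denovo_bound)
    lo, hi = clonal_band

    med_clonal = lo <= spectrum.median <= hi
    if integration_site_vafs is not None and len(integration_site_vafs) > 0:
        int_med = float(np.median(np.asarray(integration_site_vafs, dtype=float)))
        model2_rejected = lo <= int_med <= hi
        evidence.append(
            f"integration-site VAF median {int_med:.3f} "
            f"{'inside' if model2_rejected else 'outside'} clonal band {clonal_band}"
        )
    else:
        model2_rejected = med_clonal
        evidence.append(
            f"SNV VAF median {spectrum.median:.3f} "
            f"{'inside' if med_clonal else 'outside'} clonal band {clonal_band}"
        )

    exc_a, p_a = _excess_over_bound(paired.corrected_unique_a, bound, model3_factor, alpha)
    exc_b, p_b = _excess_over_bound(paired.corrected_unique_b, bound, model3_factor, alpha)
    model3_rejected = exc_a and exc_b
    evidence.append(
        f"unique counts ({paired.corrected_unique_a}, {paired.corrected_unique_b}) "
        f"vs de novo bound {bound}, factor {model3_factor}; "
        f"binomial p = ({p_a:.2e}, {p_b:.2e})"
    )

    if not med_clonal:
        if spectrum.median < lo:
            selected = "model_2"
            evidence.append(
                "subclonal spectrum: expansion predates reprogramming or the "
                "line is a cell mixture"
            )
        else:
            selected = "indeterminate"
            evidence.append("median VAF above clonal band; evidence inconsistent")
    elif not model3_rejected:
        selected = "model_3"
        evidence.append(
            "unique counts comparable to the de novo bound: the two lines "
            "likely share a single parental cell"
        )
    elif model2_rejected:
        selected = "model_1"
        evidence.append(
            "clonal spectrum and unique-SNV excess over the de novo bound: "
            "each line is a single-cell clone founded at reprogramming"
        )
    else:
        selected = "model_2"

    return ClonalityVerdict(
        median_vaf=spectrum.median,
        iqr=spectrum.iqr,
        selected_model=selected,
        evidence=tuple(evidence),
    )
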