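"""Somatic SNV filtering for case/control sample pairs.

A candidate somatic single-nucleotide variant in an iPSC line, called
against its parental-cell (germline) control, is retained only if it
looks like a clonal heterozygous mutation supported by well-behaved
sequencing evidence.  The four filtering criteria, applied in fixed
order, are:

1. coverage/quality — site depth >= 15 and Phred base quality > 15;
2. VAF band — variant allele frequency within [0.3, 0.7], while the
   control sample shows 0 or 1 (wild type or homozygous germline);
3. strand support — at least two alt-supporting reads on each strand;
4. known-polymorphism exclusion — sites present in a dbSNP-style
   exclusion list are dropped.

Each rejected call is attributed to the *first* failing criterion, so a
:class:`FilterReport` partitions the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError

__all__ = [
    "VariantCall",
    "FilterReport",
    "FilterThresholds",
    "filter_somatic",
    "partition_unique_shared",
    "call_key",
]

#: Rejection reasons in attribution order.  ``malformed`` records are
#: rejected before any scientific criterion is evaluated.
REJECTION_ORDER = (
    "malformed",
    "coverage_quality",
    "vaf_band",
    "control_vaf",
    "strand",
    "known_snp",
)


@dataclass(frozen=True)
class VariantCall:
    """One candidate somatic SNV with read-level evidence.

    Coordinates are 1-based (VCF convention); ``vaf`` is the
    alt-supporting read fraction in the case sample and ``control_vaf``
    the same fraction in the matched control.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_fwd: int
    alt_rev: int
    base_quality: float
    vaf: float
    control_vaf: float
    in_known_snp: bool = False

    def is_well_formed(self) -> bool:
        """Check the record invariants without raising."""
        try:
            return (
                self.pos >= 1
                and len(self.ref) == 1
                and len(self.alt) == 1
                and self.ref != self.alt
                and self.depth >= 0
                and self.alt_fwd >= 0
                and self.alt_rev >= 0
                and self.alt_fwd + self.alt_rev <= self.depth
                and 0.0 <= self.vaf <= 1.0
                and 0.0 <= self.control_vaf <= 1.0
            )
        except TypeError:
            return False


@dataclass(frozen=True)
class FilterThresholds:
    """Config-exposed thresholds of the four-criteria somatic filter.

    ``control_epsilon`` relaxes the "0 or 1 in the control" rule to
    ``control_vaf <= eps`` or ``>= 1 - eps``; the default 0 is the
    strict literal reading, but sequencing error makes exact 0/1
    fragile on real data, hence the knob.
    """

    min_depth: int = 15
    min_base_quality: float = 15.0  # strict: quality must exceed this
    vaf_low: float = 0.3
    vaf_high: float = 0.7
    control_epsilon: float = 0.0
    min_alt_fwd: int = 2
    min_alt_rev: int = 2


@dataclass
class FilterReport:
    """Accounting of a filtering run: every input call is either passed
    or attributed to exactly one rejection reason."""

    n_input: int = 0
    n_pass: int = 0
    rejections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for reason in REJECTION_ORDER:
            self.rejections.setdefault(reason, 0)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejections.values())

    def check(self) -> None:
        if self.n_input != self.n_pass + self.n_rejected:
            raise DataError("filter report does not partition the input")


def filter_somatic(
    calls: Sequence[VariantCall],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantCall], FilterReport]:
    """Apply the four-criteria somatic SNV filter.

    Returns the passing calls (input order preserved) and a
    :class:`FilterReport`.  Malformed records are rejected with an
    explicit reason, never silently dropped.
    """
    th = thresholds or FilterThresholds()
    report = FilterReport(n_input=len(calls))
    passing: list[VariantCall] = []
    if not calls:
        return passing, report

    ok = np.array([c.is_well_formed() for c in calls], dtype=bool)
    # Vectorised criterion evaluation; malformed rows are excluded from
    # every criterion and attributed first.
    depth = np.array([c.depth if ok[i] else 0 for i, c in enumerate(calls)], float)
    bq = np.array([c.base_quality if ok[i] else 0 for i, c in enumerate(calls)], float)
    vaf = np.array([c.vaf if ok[i] else 0 for i, c in enumerate(calls)], float)
    cvaf = np.array([c.control_vaf if ok[i] else 0 for i, c in enumerate(calls)], float)
    fwd = np.array([c.alt_fwd if ok[i] else 0 for i, c in enumerate(calls)], float)
    rev = np.array([c.alt_rev if ok[i] else 0 for i, c in enumerate(calls)], float)
    known = np.array([bool(c.in_known_snp) for c in calls], dtype=bool)

    crit = {
        "coverage_quality": (depth >= th.min_depth) & (bq > th.min_base_quality),
        "vaf_band": (vaf >= th.vaf_low) & (vaf <= th.vaf_high),
        "control_vaf": (cvaf <= th.control_epsilon) | (cvaf >= 1.0 - th.control_epsilon),
        "strand": (fwd >= th.min_alt_fwd) & (rev >= th.min_alt_rev),
        "known_snp": ~known,
    }

    reason = np.full(len(calls), "", dtype=object)
    reason[~ok] = "malformed"
    undecided = ok.copy()
    for name in REJECTION_ORDER[1:]:
        fails = undecided & ~crit[name]
        reason[fails] = name
        undecided &= ~fails

    for i, c in enumerate(calls):
        if undecided[i]:
            passing.append(c)
            report.n_pass += 1
        else:
            report.rejections[str(reason[i])] += 1
    report.check()
    return passing, report


def call_key(call: VariantCall) -> tuple[str, int, str]:
    """Identity of a call for cross-sample comparison."""
    return (call.chrom, call.pos, call.alt)


def partition_unique_shared(
    calls_a: Iterable[VariantCall],
    calls_b: Iterable[VariantCall],
) -> tuple[list[VariantCall], list[VariantCall], list[VariantCall]]:
    """Partition two filtered callsets into unique and shared SNVs.

    Shared means identical ``(chrom, pos, alt)`` in both callsets; the
    shared list holds the representative calls from sample A.  Raises
    :class:`DataError` on duplicate keys within one callset, which would
    violate the upstream filtering invariant.
    """
    a = list(calls_a)
    b = list(calls_b)
    keys_a = {call_key(c) for c in a}
    keys_b = {call_key(c) for c in b}
    if len(keys_a) != len(a):
        raise DataError("duplicate (chrom, pos, alt) in callset A")
    if len(keys_b) != len(b):
        raise DataError("duplicate (chrom, pos, alt) in callset B")
    shared_keys = keys_a & keys_b
    unique_a = [c for c in a if call_key(c) not in shared_keys]
    unique_b = [c for c in b if call_key(c) not in shared_keys]
    shared = [c for c in a if call_key(c) in shared_keys]
    return unique_a, unique_b, shared
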