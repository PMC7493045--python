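"""Copy-number aberration detection with replication-timing correction.

Pluripotent cells spend a large share of the cell cycle in S phase, so
their read-depth profiles carry a dosage imprint of replication timing:
early-replicating regions look like gains and late ones like losses
(pseudo-CNAs).  Normalising a pluripotent sample's binned depth by an
*independent pluripotent* control line cancels this shared dosage term,
leaving true copy-number differences as log2-ratio shifts.  The
corrected profile is then segmented by threshold-merge and segments are
classified by their sharing pattern across the paired lines and the
germline control:

- shared by both paired lines, absent from the germline control ->
  pre-existing (category I, arose in vivo in the founder lineage);
- private to one line -> post-reprogramming (category II/III);
- present in the germline control -> germline background, excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .synthetic import DepthProfile

__all__ = [
    "CNASegment",
    "CNAThresholds",
    "bin_depth",
    "rt_correct",
    "segment_and_call",
    "classify_origin",
]


@dataclass(frozen=True)
class CNAThresholds:
    """Segmentation thresholds (log2-ratio units, lengths in bp).

    Defaults are sized for chromosome-arm-scale single-copy events
    (log2(3/2) ~ 0.585 for a one-copy gain) on 500-kb bins.
    """

    gain_threshold: float = 0.3
    loss_threshold: float = 0.3
    min_segment_length: int = 5_000_000
    min_control_depth: float = 5.0


@dataclass(frozen=True)
class CNASegment:
    chrom: str
    start: int
    end: int
    mean_log2_ratio: float
    call: str  # gain | loss
    origin: str = "unknown"  # pre_existing | post_reprogramming | unknown
    sample_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def fold_change(self) -> float:
        """Copy-dosage fold change, comparable to qPCR estimates."""
        return float(2.0 ** self.mean_log2_ratio)


def bin_depth(
    coverage: pd.DataFrame,
    bin_size: int,
    sample_id: str = "",
    sample_type: str = "pluripotent",
    chrom_lengths: dict[str, int] | None = None,
) -> DepthProfile:
    """Aggregate a bedGraph-style coverage track into fixed-size bins.

    ``coverage`` columns: chrom, start, end (0-based half-open), value;
    intervals must be sorted and non-overlapping per chromosome.  Bin
    depth is the coverage-weighted mean over covered positions; bins
    with under half their positions covered are masked (NaN).
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    required = {"chrom", "start", "end", "value"}
    if not required.issubset(coverage.columns):
        raise DataError(f"coverage track needs columns {sorted(required)}")
    rows = []
    for chrom, grp in coverage.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        vals = grp["value"].to_numpy(dtype=float)
        if np.any(np.diff(starts) < 0) or np.any(ends <= starts):
            raise DataError(f"coverage track unsorted or malformed on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise DataError(f"overlapping coverage intervals on {chrom}")
        chrom_end = (
            chrom_lengths[chrom] if chrom_lengths and chrom in chrom_lengths
            else int(ends.max())
        )
        n_bins = int(np.ceil(chrom_end / bin_size))
        weight = np.zeros(n_bins)
        total = np.zeros(n_bins)
        for s, e, v in zip(starts, ends, vals):
            b0, b1 = s // bin_size, (e - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(s, b * bin_size)
                hi = min(e, (b + 1) * bin_size)
                weight[b] += hi - lo
                total[b] += (hi - lo) * v
        bin_starts = np.arange(n_bins) * bin_size
        bin_ends = np.minimum(bin_starts + bin_size, chrom_end)
        widths = bin_ends - bin_starts
        with np.errstate(invalid="ignore"):
            mean = np.where(weight > 0, total / np.maximum(weight, 1), np.nan)
        mean = np.where(weight >= 0.5 * widths, mean, np.nan)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": bin_starts, "end": bin_ends, "depth": mean}
            )
        )
    bins = pd.concat(rows, ignore_index=True)
    return DepthProfile(
        bins=bins, bin_size=bin_size, sample_id=sample_id, sample_type=sample_type
    )


def _check_same_binning(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if len(a) != len(b) or not (
        (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
        and (a["start"].to_numpy() == b["start"].to_numpy()).all()
        and (a["end"].to_numpy() == b["end"].to_numpy()).all()
    ):
        raise DataError("depth profiles are not on identical bins")


def rt_correct(
    sample: DepthProfile,
    control_ipsc: DepthProfile,
    min_control_depth: float = 5.0,
) -> pd.DataFrame:
    """Replication-timing-corrected log2-ratio profile.

    Per bin the raw ratio is ``log2(sample/control)``; the profile is
    then centred by subtracting its median, which normalises library
    size on both sides (equivalent to dividing each profile by its own
    median when no large aberration is present, but robust to one: a
    chromosome-arm-scale CNA shifts a per-sample median, whereas the
    median of the ratio profile stays anchored at copy-neutral bins).
    The control must be a pluripotent line — only then does it share
    the RT dosage whose cancellation is the point of the correction; a
    somatic (e.g. NSC) control is refused.  Bins masked in either
    profile or with control depth below ``min_control_depth`` are NaN.
    """
    if control_ipsc.sample_type != "pluripotent":
        raise ValidationError(
            "RT-dosage control must be a pluripotent sample; a somatic control "
            "does not share the extended-S-phase dosage effect"
        )
    _check_same_binning(sample.bins, control_ipsc.bins)
    s = sample.bins["depth"].to_numpy(dtype=float)
    c = control_ipsc.bins["depth"].to_numpy(dtype=float)
    ok = np.isfinite(s) & np.isfinite(c) & (c >= min_control_depth) & (s > 0)
    if not ok.any():
        raise DataError("no usable bins shared by sample and control")
    ratio = np.full(len(s), np.nan)
    ratio[ok] = np.log2(s[ok] / c[ok])
    ratio[ok] -= np.median(ratio[ok])
    out = sample.bins[["chrom", "start", "end"]].copy()
    out["log2_ratio"] = ratio
    return out


def segment_and_call(
    corrected: pd.DataFrame,
    thresholds: CNAThresholds | None = None,
    sample_id: str = "",
) -> list[CNASegment]:
    """Threshold-merge segmentation of a corrected log2-ratio profile.

    Consecutive bins beyond +gain / -loss thresholds on one chromosome
    are merged; segments shorter than ``min_segment_length`` are
    dropped.  (The segmentation is deliberately behind this single
    function so a CBS-style method could be swapped in.)
    """
    th = thresholds or CNAThresholds()
    segments: list[CNASegment] = []
    for chrom, grp in corrected.groupby("chrom", sort=True):
        r = grp["log2_ratio"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        state = np.where(
            np.isnan(r), 0, np.where(r >= th.gain_threshold, 1,
                                     np.where(r <= -th.loss_threshold, -1, 0))
        )
        i = 0
        while i < len(r):
            if state[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(r) and state[j + 1] == state[i]:
                j += 1
            seg_start, seg_end = int(starts[i]), int(ends[j])
            if seg_end - seg_start >= th.min_segment_length:
                segments.append(
                    CNASegment(
                        chrom=str(chrom),
                        start=seg_start,
                        end=seg_end,
                        mean_log2_ratio=float(np.mean(r[i : j + 1])),
                        call="gain" if state[i] == 1 else "loss",
                        sample_id=sample_id,
                    )
                )
            i = j + 1
    return segments


def _reciprocal_overlap(a: CNASegment, b: CNASegment) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def _matches(seg: CNASegment, others: Sequence[CNASegment], min_overlap: float) -> bool:
    return any(
        seg.call == o.call and _reciprocal_overlap(seg, o) >= min_overlap
        for o in others
    )


def classify_origin(
    segments_a: Sequence[CNASegment],
    segments_b: Sequence[CNASegment],
    segments_control: Sequence[CNASegment],
    min_reciprocal_overlap: float = 0.5,
) -> tuple[list[CNASegment], list[CNASegment]]:
    """Label somatic CNA segments by lineage origin.

    Returns ``(somatic, excluded)``: segments present in the germline
    control go to ``excluded``; of the rest, segments shared between the
    paired lines (reciprocal overlap with matching call) are
    ``pre_existing``, private ones ``post_reprogramming``.
    """
    somatic: list[CNASegment] = []
    excluded: list[CNASegment] = []
    for own, other in ((segments_a, segments_b), (segments_b, segments_a)):
        for seg in own:
            if _matches(seg, segments_control, min_reciprocal_overlap):
                excluded.append(replace(seg, origin="germline_background"))
            elif _matches(seg, other, min_reciprocal_overlap):
                somatic.append(replace(seg, origin="pre_existing"))
            else:
                somatic.append(replace(seg, origin="post_reprogramming"))
    return somatic, excluded
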