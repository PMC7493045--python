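"""Signatures of somatic SNVs: substitution spectra, replication-timing
enrichment, chromatin-accessibility correlation, and per-cell loads.

Somatic SNV catalogues from clonally amplified single cells show
reproducible signatures: a C>A component on top of the ubiquitous C>T
(absent from germline SNP spectra), enrichment in late-replicating
DNA, and a negative correlation between mutation density and DNase I
hypersensitive site (DHS) density in 10-Mb windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ValidationError
from .filtering import VariantCall
from .synthetic import SUBSTITUTION_CLASSES, RTTrack

__all__ = [
    "SpectrumCounts",
    "BinnedDensity",
    "RTEnrichment",
    "LoadComparison",
    "spectrum",
    "compare_spectra",
    "rt_enrichment",
    "binned_density",
    "dhs_correlation",
    "load_comparison",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def collapse_substitution(ref: str, alt: str) -> str:
    """Map a substitution to its pyrimidine-reference class.

    Purine-reference substitutions are complemented (G>A becomes C>T),
    so applying the collapse to an already-collapsed class is a no-op.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    key = f"{ref}>{alt}"
    if key not in SUBSTITUTION_CLASSES:
        raise DataError(f"not a single-base substitution: {ref}>{alt}")
    return key


@dataclass(frozen=True)
class SpectrumCounts:
    """Strand-collapsed six-class substitution counts."""

    counts: tuple[int, ...]  # ordered as SUBSTITUTION_CLASSES
    source: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def proportions(self) -> tuple[float, ...]:
        t = self.total
        if t == 0:
            raise DataError("zero-total spectrum has no proportions")
        return tuple(c / t for c in self.counts)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(SUBSTITUTION_CLASSES, self.counts))


def spectrum(
    snvs: Iterable[VariantCall] | Iterable[tuple[str, str]] | pd.DataFrame,
    source: str = "",
) -> SpectrumCounts:
    """Count substitutions into the six pyrimidine-reference classes.

    Accepts calls, (ref, alt) pairs, or a DataFrame with ref/alt
    columns.
    """
    if isinstance(snvs, pd.DataFrame):
        pairs = zip(snvs["ref"], snvs["alt"])
    else:
        pairs = (
            (s.ref, s.alt) if isinstance(s, VariantCall) else (s[0], s[1])
            for s in snvs
        )
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    for ref, alt in pairs:
        counts[collapse_substitution(ref, alt)] += 1
    return SpectrumCounts(
        counts=tuple(counts[c] for c in SUBSTITUTION_CLASSES), source=source
    )


def compare_spectra(
    a: SpectrumCounts,
    b: SpectrumCounts,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, str]:
    """Chi-square comparison of two spectra on the 2x6 table.

    Returns ``(statistic, p_value, method)``.  When any expected cell
    falls below 5 the asymptotic p-value is unreliable, so a seeded
    permutation null of the same statistic is used instead.
    """
    if a.total == 0 or b.total == 0:
        raise DataError("cannot compare a zero-total spectrum")
    table = np.array([a.counts, b.counts], dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 1.0, "degenerate"
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected >= 5).all():
        return float(chi2), float(p), "chi2"
    # permutation null: shuffle spectrum labels over pooled observations
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(table.shape[1]), table.sum(axis=0).astype(int))
    n_a = int(table[0].sum())
    exceed = 0
    for _ in range(n_resamples):
        rng.shuffle(labels)
        ca = np.bincount(labels[:n_a], minlength=table.shape[1])
        cb = np.bincount(labels[n_a:], minlength=table.shape[1])
        t = np.array([ca, cb], dtype=float)
        keep2 = t.sum(axis=0) > 0
        stat, _, _, _ = stats.chi2_contingency(t[:, keep2], correction=False)
        if stat >= chi2 - 1e-12:
            exceed += 1
    return float(chi2), (exceed + 1) / (n_resamples + 1), "permutation"


@dataclass(frozen=True)
class RTEnrichment:
    """Late-replicating-region enrichment of somatic SNVs."""

    n_late: int
    n_early: int
    n_excluded: int
    late_fraction: float
    expected_fraction: float  # length fraction of late regions
    p_value: float


def rt_enrichment(
    snvs: pd.DataFrame,
    rt: RTTrack,
    noise_floor: float = 0.1,
) -> RTEnrichment:
    """Exact binomial test of SNV occurrence in late-replicating DNA.

    Bins with signal above ``noise_floor`` are early, below the
    negative floor late; bins within the floor, and SNVs falling in
    them or outside the track, are excluded but counted.  The expected
    late fraction is the length share of late regions among classified
    regions (callable length).
    """
    bins = rt.bins
    value = bins["value"].to_numpy(dtype=float)
    width = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    early = value > noise_floor
    late = value < -noise_floor
    len_early, len_late = width[early].sum(), width[late].sum()
    if len_early + len_late == 0:
        raise DataError("RT track has no bins beyond the noise floor")
    expected = len_late / (len_early + len_late)

    n_late = n_early = n_excluded = 0
    for chrom, grp in snvs.groupby("chrom", sort=False):
        sel = bins["chrom"] == chrom
        if not sel.any():
            n_excluded += len(grp)
            continue
        b = bins.loc[sel]
        starts = b["start"].to_numpy()
        ends = b["end"].to_numpy()
        v = b["value"].to_numpy(dtype=float)
        idx = np.searchsorted(starts, grp["pos"].to_numpy() - 1, side="right") - 1
        for i, p in zip(idx, grp["pos"].to_numpy()):
            if i < 0 or p - 1 >= ends[i]:
                n_excluded += 1
            elif v[i] > noise_floor:
                n_early += 1
            elif v[i] < -noise_floor:
                n_late += 1
            else:
                n_excluded += 1
    n = n_late + n_early
    if n == 0:
        raise DataError("no SNVs fall in classified RT regions")
    p_value = stats.binomtest(n_late, n, expected, alternative="two-sided").pvalue
    return RTEnrichment(
        n_late=n_late,
        n_early=n_early,
        n_excluded=n_excluded,
        late_fraction=n_late / n,
        expected_fraction=float(expected),
        p_value=float(p_value),
    )


@dataclass(frozen=True)
class BinnedDensity:
    """Per-bin SNV and DHS counts on a fixed-width genomic grid."""

    bins: pd.DataFrame  # chrom, start, end, snv_density, dhs_density
    bin_size: int


def binned_density(
    snvs: pd.DataFrame,
    dhs: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = 10_000_000,
) -> BinnedDensity:
    """Count SNVs (1-based ``pos``) and DHS sites (0-based ``start``)
    per fixed-width bin; the default 10-Mb width matches the scale at
    which DHS density is conventionally summarised."""
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_size))
        starts = np.arange(n_bins) * bin_size
        s_counts = np.zeros(n_bins)
        d_counts = np.zeros(n_bins)
        sp = snvs.loc[snvs["chrom"] == chrom, "pos"].to_numpy() - 1
        dp = dhs.loc[dhs["chrom"] == chrom, "start"].to_numpy()
        np.add.at(s_counts, np.clip(sp // bin_size, 0, n_bins - 1), 1)
        np.add.at(d_counts, np.clip(dp // bin_size, 0, n_bins - 1), 1)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_size, length),
                    "snv_density": s_counts,
                    "dhs_density": d_counts,
                }
            )
        )
    return BinnedDensity(bins=pd.concat(rows, ignore_index=True), bin_size=bin_size)


def dhs_correlation(
    snv_density: Sequence[float],
    dhs_density: Sequence[float],
    min_bins: int = 10,
) -> tuple[float, float]:
    """Spearman rank correlation between SNV and DHS densities.

    Ties are handled by average ranks.  Constant tracks have no rank
    order, so rho is returned as NaN.
    """
    x = np.asarray(snv_density, dtype=float)
    y = np.asarray(dhs_density, dtype=float)
    if x.shape != y.shape:
        raise DataError("density tracks differ in length")
    if x.size < min_bins:
        raise DataError(f"need at least {min_bins} informative bins")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class LoadComparison:
    fold_change: float
    p_value: float | None
    test: str


def load_comparison(
    loads_group1: Sequence[float],
    loads_group2: Sequence[float],
) -> LoadComparison:
    """Per-cell mutation-load comparison between two cell groups.

    Fold change is mean(group1)/mean(group2); with at least two cells
    per group a two-sided Welch t-test accompanies it.
    """
    g1 = np.asarray(loads_group1, dtype=float)
    g2 = np.asarray(loads_group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise DataError("each group needs at least one per-cell load")
    if g2.mean() == 0:
        raise DataError("zero mean load in the denominator group")
    fold = float(g1.mean() / g2.mean())
    if g1.size >= 2 and g2.size >= 2:
        import warnings

        with warnings.catch_warnings():
            # constant groups make the t denominator degenerate; the fold
            # change is still well-defined and the p-value is reported as-is
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(g1, g2, equal_var=False)
        return LoadComparison(fold_change=fold, p_value=float(p), test="welch")
    return LoadComparison(fold_change=fold, p_value=None, test="fold_only")
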