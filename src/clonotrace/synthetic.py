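"""Forward simulation of the single-cell cloning design.

The generative model follows the experimental scheme the analysis
assumes: a zygote divides ``divisions_to_founder`` times down to one
neural-stem-cell founder, accumulating *category I* (pre-existing, in
vivo) mutations at ``mu_division`` per daughter per division; the
founder grows ex vivo into a tiny neurosphere of ``2**neurosphere_divisions``
cells (50-100 cells for the defaults); at least two cells of that
neurosphere are independently reprogrammed into iPSC lines, each picking
up *category II* (reprogramming) mutations; each line then accumulates
*category III* (culture) mutations over ``n_passages`` passages.

Every category I/II mutation is clonal in the lines that carry it
(heterozygous, true VAF 0.5).  Category III mutations arising before
``fixation_passage`` are likewise clonal; later ones are subclonal with
VAF drawn Uniform(0.05, 0.3).

Sequencing evidence is emulated at the read-count level: per site,
depth ~ Poisson(mean_coverage x RT dosage x copy/2), alt reads ~
Binomial(depth, true VAF), and a forward/reverse strand split.  The
replication-timing (RT) dosage term models the extended S phase of
pluripotent cells, which inflates coverage of early-replicating regions
and produces pseudo copy-number aberrations; non-pluripotent samples
(the parental NSC control) have no RT dosage.

All randomness flows from ``SimConfig.seed`` through named sub-streams,
so every output is bit-reproducible and independent of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .filtering import VariantCall

__all__ = [
    "SimConfig",
    "CNASegmentSpec",
    "LineageTruth",
    "DepthProfile",
    "RTTrack",
    "CONTROL_SAMPLE",
    "CONTROL_IPSC_SAMPLE",
    "simulate_lineage",
    "simulate_regular_pair",
    "simulate_subclone_pair",
    "simulate_mixture_line",
    "simulate_callset",
    "simulate_depth_and_rt",
    "simulate_dhs_sites",
    "simulate_validation",
    "sample_positions_with_rt_bias",
]

#: Sample id of the parental-cell germline control.
CONTROL_SAMPLE = "NSC"
#: Sample id of the independent pluripotent line used as RT-dosage control.
CONTROL_IPSC_SAMPLE = "control-iPSC"

#: Pyrimidine-reference substitution classes, in canonical order.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_CLASS_PAIRS = tuple(c.split(">") for c in SUBSTITUTION_CLASSES)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class CNASegmentSpec:
    """A true copy-number segment planted in the simulation.

    ``origin_stage`` controls which samples carry it:

    - ``"germline"`` — every sample including the NSC control;
    - ``"pre_existing"`` — the paired iPSC clones only (a somatic CNA of
      their common founder cell, mosaic in the NSC bulk and absent from
      the independent control iPSC line);
    - a clone id — that clone only (post-reprogramming).
    """

    chrom: str
    start: int
    end: int
    copy_number: int
    origin_stage: str

    def carried_by(self, sample_id: str, clone_ids: Sequence[str]) -> bool:
        if self.origin_stage == "germline":
            return True
        if self.origin_stage == "pre_existing":
            return sample_id in clone_ids
        return sample_id == self.origin_stage


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the lineage + sequencing simulation.

    Mutation rates are Poisson means; ``mu_division`` applies per
    daughter cell per division both in vivo and within the neurosphere.
    Defaults are scaled so a paired-clone comparison lands in the regime
    the design targets: ~1.2k shared pre-existing SNVs against a few
    dozen clone-private ones.
    """

    genome_length: int = 200_000_000
    n_chromosomes: int = 4
    divisions_to_founder: int = 400
    mu_division: float = 3.0
    neurosphere_divisions: int = 6  # 2**6 = 64 cells, within the 50-100 design
    mu_reprogramming: float = 10.0
    mu_culture_per_passage: float = 2.0
    n_passages: int = 7
    fixation_passage: int = 2
    mean_coverage: float = 40.0
    strand_bias: float = 0.5
    base_quality: int = 30
    rt_amplitude: float = 0.3
    cna_segments: tuple[CNASegmentSpec, ...] = ()
    seed: int = 0
    # --- beyond the core design knobs ---
    n_clones: int = 2
    n_germline_snps: int = 1000
    germline_hom_fraction: float = 0.33
    #: divergence (divisions per branch) between the parental cells of a
    #: "regular reprogramming experiment" pair, whose two colonies come
    #: from unrelated somatic cells rather than one tiny neurosphere
    regular_divergence_divisions: int = 100
    somatic_class_probs: tuple[float, ...] = (0.25, 0.08, 0.35, 0.08, 0.16, 0.08)
    germline_class_probs: tuple[float, ...] = (0.08, 0.09, 0.40, 0.06, 0.31, 0.06)
    bin_size: int = 500_000
    depth_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValidationError("genome_length must be positive")
        if self.n_chromosomes <= 0:
            raise ValidationError("n_chromosomes must be positive")
        for name in (
            "mu_division",
            "mu_reprogramming",
            "mu_culture_per_passage",
            "rt_amplitude",
            "mean_coverage",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.strand_bias <= 1.0:
            raise ValidationError("strand_bias must be in [0, 1]")
        if self.neurosphere_divisions < 1:
            raise ValidationError("neurosphere_divisions must be >= 1")
        if self.n_clones < 2:
            raise ValidationError("need at least two clones per neurosphere")
        if self.n_clones > 2 ** self.neurosphere_divisions:
            raise ValidationError("more clones requested than neurosphere cells")
        for probs in (self.somatic_class_probs, self.germline_class_probs):
            if len(probs) != 6 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValidationError("class probabilities must be a 6-simplex")

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chromosomes

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    @property
    def clone_ids(self) -> tuple[str, ...]:
        return tuple(f"iPSC-{i + 1}" for i in range(self.n_clones))

    def contigs(self) -> dict[str, int]:
        return {name: self.chrom_length for name in self.chrom_names}


def _rng(seed: int, *keys: str) -> np.random.Generator:
    """Named, order-independent RNG sub-stream."""
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# Lineage truth
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "category", "true_vaf", "stage", "carried_by"]


@dataclass
class LineageTruth:
    """Truth-tagged mutation set for one simulated experiment.

    ``mutations`` has one row per distinct genomic site with columns
    chrom, pos (1-based), ref, alt, category (``I``/``II``/``III``/
    ``germline``), true_vaf (VAF in a carrying clone), stage (which
    lineage step introduced it), and carried_by (frozenset of sample
    ids).  No two rows share (chrom, pos).
    """

    mutations: pd.DataFrame
    clone_ids: tuple[str, ...]
    config: SimConfig

    def carried_mask(self, sample_id: str) -> np.ndarray:
        return np.array(
            [sample_id in s for s in self.mutations["carried_by"]], dtype=bool
        )

    def subset(self, sample_id: str) -> pd.DataFrame:
        return self.mutations.loc[self.carried_mask(sample_id)]

    def somatic(self) -> pd.DataFrame:
        return self.mutations.loc[self.mutations["category"] != "germline"]

    def true_denovo_count(self, clone_id: str) -> int:
        """True category II + III burden of one clone."""
        sub = self.subset(clone_id)
        return int(sub["category"].isin(["II", "III"]).sum())


class _PositionSampler:
    """Uniform collision-free genomic positions over the toy genome."""

    def __init__(self, config: SimConfig) -> None:
        self.config = config
        self.used: set[int] = set()

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Return (chrom index, 1-based pos) for n new sites."""
        g = self.config.chrom_length * self.config.n_chromosomes
        if len(self.used) + n > g:
            raise DataError("toy genome saturated: cannot place more mutations")
        out: list[int] = []
        attempts = 0
        while len(out) < n:
            need = n - len(out)
            cand = rng.integers(0, g, size=max(need * 2, 16))
            for x in cand:
                xi = int(x)
                if xi not in self.used:
                    self.used.add(xi)
                    out.append(xi)
                    if len(out) == n:
                        break
            attempts += 1
            if attempts > 10_000:
                raise DataError("position sampling failed to converge")
        lin = np.array(out, dtype=np.int64)
        chrom_idx = lin // self.config.chrom_length
        pos = lin % self.config.chrom_length + 1
        return chrom_idx, pos


def _draw_alleles(
    n: int, class_probs: Sequence[float], rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """ref/alt bases for n mutations from the 6-class probability vector,
    with a random strand so purine-reference representations occur."""
    cls = rng.choice(6, size=n, p=np.asarray(class_probs, dtype=float))
    flip = rng.random(n) < 0.5
    refs, alts = [], []
    for c, f in zip(cls, flip):
        ref, alt = _CLASS_PAIRS[c]
        if f:
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        refs.append(ref)
        alts.append(alt)
    return refs, alts


def _emit(
    rows: list[dict],
    n: int,
    category: str,
    vafs: np.ndarray | float,
    stage: str,
    carried_by: frozenset,
    class_probs: Sequence[float],
    sampler: _PositionSampler,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    if n == 0:
        return
    chrom_idx, pos = sampler.draw(n, rng)
    refs, alts = _draw_alleles(n, class_probs, rng)
    vaf_arr = np.broadcast_to(np.asarray(vafs, dtype=float), (n,))
    names = config.chrom_names
    for i in range(n):
        rows.append(
            {
                "chrom": names[chrom_idx[i]],
                "pos": int(pos[i]),
                "ref": refs[i],
                "alt": alts[i],
                "category": category,
                "true_vaf": float(vaf_arr[i]),
                "stage": stage,
                "carried_by": carried_by,
            }
        )


def _finalise(rows: list[dict], clone_ids: Sequence[str], config: SimConfig) -> LineageTruth:
    if rows:
        df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=TRUTH_COLUMNS)
    return LineageTruth(mutations=df, clone_ids=tuple(clone_ids), config=config)


def _germline_rows(
    rows: list[dict],
    carried_by: frozenset,
    sampler: _PositionSampler,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    n = config.n_germline_snps
    if n == 0:
        return
    hom = rng.random(n) < config.germline_hom_fraction
    vafs = np.where(hom, 1.0, 0.5)
    _emit(
        rows, n, "germline", vafs, "germline", carried_by,
        config.germline_class_probs, sampler, config, rng,
    )


def _culture_rows(
    rows: list[dict],
    clone: str,
    sampler: _PositionSampler,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    for passage in range(1, config.n_passages + 1):
        k = int(rng.poisson(config.mu_culture_per_passage))
        if k == 0:
            continue
        if passage < config.fixation_passage:
            vafs: np.ndarray | float = 0.5
        else:
            vafs = rng.uniform(0.05, 0.3, size=k)
        _emit(
            rows, k, "III", vafs, f"culture_p{passage}", frozenset([clone]),
            config.somatic_class_probs, sampler, config, rng,
        )


def _reprogramming_rows(
    rows: list[dict],
    clone: str,
    sampler: _PositionSampler,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    k = int(rng.poisson(config.mu_reprogramming))
    _emit(
        rows, k, "II", 0.5, "reprogramming", frozenset([clone]),
        config.somatic_class_probs, sampler, config, rng,
    )


def simulate_lineage(config: SimConfig) -> LineageTruth:
    """Simulate the neurosphere design: ``n_clones`` iPSC lines derived
    from distinct cells of one founder-derived neurosphere.

    Category I mutations of a clone are the union of mutations on its
    founder-cell lineage path (zygote -> founder -> neurosphere leaf);
    those on the shared zygote->founder path are carried by every clone.
    """
    rng = _rng(config.seed, "lineage")
    sampler = _PositionSampler(config)
    rows: list[dict] = []
    clones = config.clone_ids
    all_samples = frozenset(clones) | {CONTROL_SAMPLE, CONTROL_IPSC_SAMPLE}

    _germline_rows(rows, all_samples, sampler, config, rng)

    # zygote -> founder: category I shared by all clones (mosaic in the
    # NSC bulk, hence absent from the control callset).
    n_founder = int(rng.poisson(config.mu_division * config.divisions_to_founder))
    _emit(
        rows, n_founder, "I", 0.5, "founder_path", frozenset(clones),
        config.somatic_class_probs, sampler, config, rng,
    )

    # neurosphere binary tree: leaves after `neurosphere_divisions`
    # synchronous divisions; clones are distinct random leaves.  Only
    # edges ancestral to a chosen leaf can contribute observable
    # category I mutations, so only those are simulated.
    depth = config.neurosphere_divisions
    leaves = rng.choice(2 ** depth, size=config.n_clones, replace=False)
    leaf_nodes = [int(2 ** depth + leaf) for leaf in leaves]  # heap indexing, root=1
    ancestry = {clone: set() for clone in clones}
    for clone, node in zip(clones, leaf_nodes):
        while node > 1:
            ancestry[clone].add(node)
            node //= 2
    edges = sorted(set().union(*ancestry.values()))
    for node in edges:
        carriers = frozenset(c for c in clones if node in ancestry[c])
        k = int(rng.poisson(config.mu_division))
        _emit(
            rows, k, "I", 0.5, f"neurosphere_edge_{node}", carriers,
            config.somatic_class_probs, sampler, config, rng,
        )

    for clone in clones:
        _reprogramming_rows(rows, clone, sampler, config, rng)
        _culture_rows(rows, clone, sampler, config, rng)

    return _finalise(rows, clones, config)


def simulate_regular_pair(config: SimConfig) -> LineageTruth:
    """Simulate two iPSC lines from a *regular* reprogramming experiment:
    two colonies picked from the same dish but descending from unrelated
    somatic cells, whose parental lineages diverged
    ``regular_divergence_divisions`` divisions before sampling."""
    rng = _rng(config.seed, "regular_pair")
    sampler = _PositionSampler(config)
    rows: list[dict] = []
    clones = ("regular-A", "regular-B")
    all_samples = frozenset(clones) | {CONTROL_SAMPLE, CONTROL_IPSC_SAMPLE}

    _germline_rows(rows, all_samples, sampler, config, rng)

    shared_divs = max(config.divisions_to_founder - config.regular_divergence_divisions, 0)
    n_shared = int(rng.poisson(config.mu_division * shared_divs))
    _emit(
        rows, n_shared, "I", 0.5, "shared_path", frozenset(clones),
        config.somatic_class_probs, sampler, config, rng,
    )
    for clone in clones:
        k = int(rng.poisson(config.mu_division * config.regular_divergence_divisions))
        _emit(
            rows, k, "I", 0.5, f"private_path_{clone}", frozenset([clone]),
            config.somatic_class_probs, sampler, config, rng,
        )
        _reprogramming_rows(rows, clone, sampler, config, rng)
        _culture_rows(rows, clone, sampler, config, rng)
    return _finalise(rows, clones, config)


def simulate_subclone_pair(config: SimConfig) -> LineageTruth:
    """Simulate two colonies picked from the *same* reprogrammed clone
    (subclones): they share all category I and II mutations and differ
    only in culture (category III) mutations."""
    rng = _rng(config.seed, "subclone_pair")
    sampler = _PositionSampler(config)
    rows: list[dict] = []
    clones = ("subclone-A", "subclone-B")
    all_samples = frozenset(clones) | {CONTROL_SAMPLE, CONTROL_IPSC_SAMPLE}

    _germline_rows(rows, all_samples, sampler, config, rng)
    n_pre = int(rng.poisson(config.mu_division * config.divisions_to_founder))
    _emit(
        rows, n_pre, "I", 0.5, "shared_path", frozenset(clones),
        config.somatic_class_probs, sampler, config, rng,
    )
    k = int(rng.poisson(config.mu_reprogramming))
    _emit(
        rows, k, "II", 0.5, "reprogramming", frozenset(clones),
        config.somatic_class_probs, sampler, config, rng,
    )
    for clone in clones:
        _culture_rows(rows, clone, sampler, config, rng)
    return _finalise(rows, clones, config)


def simulate_mixture_line(config: SimConfig, cell_fraction: float = 0.5) -> LineageTruth:
    """Simulate a non-clonal 'line' that is a mixture of two unrelated
    cells at the given cell fraction: each contributor's private clonal
    mutations appear at VAF 0.5 x fraction (0.25 for a 50/50 mix)."""
    rng = _rng(config.seed, "mixture")
    sampler = _PositionSampler(config)
    rows: list[dict] = []
    clone = "mixture-line"
    all_samples = frozenset([clone, CONTROL_SAMPLE, CONTROL_IPSC_SAMPLE])

    _germline_rows(rows, all_samples, sampler, config, rng)
    for which, frac in (("cellA", cell_fraction), ("cellB", 1.0 - cell_fraction)):
        k = int(rng.poisson(config.mu_division * config.divisions_to_founder))
        _emit(
            rows, k, "I", 0.5 * frac, f"private_{which}", frozenset([clone]),
            config.somatic_class_probs, sampler, config, rng,
        )
    return _finalise(rows, [clone, clone], config)


# ---------------------------------------------------------------------------
# Replication-timing signal
# ---------------------------------------------------------------------------

_RT_HARMONICS = 8


def _rt_phases(config: SimConfig) -> np.ndarray:
    rng = _rng(config.seed, "rt")
    return rng.uniform(0, 2 * np.pi, size=(config.n_chromosomes, _RT_HARMONICS))


def rt_signal(config: SimConfig, chrom_idx: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Standardised smooth RT field (log2(Early/Late)-like, unit variance
    over positions) at 0-based positions on the given chromosomes."""
    phases = _rt_phases(config)
    L = config.chrom_length
    x = np.asarray(pos, dtype=float) / L
    ci = np.asarray(chrom_idx, dtype=int)
    amps = 1.0 / np.arange(1, _RT_HARMONICS + 1)
    sd = np.sqrt(np.sum(amps**2) / 2.0)
    s = np.zeros_like(x)
    for k in range(_RT_HARMONICS):
        s += amps[k] * np.sin(2 * np.pi * (k + 1) * x + phases[ci, k])
    return s / sd


def _rt_dosage(config: SimConfig, chrom_idx: np.ndarray, pos: np.ndarray,
               pluripotent: bool) -> np.ndarray:
    if not pluripotent or config.rt_amplitude == 0:
        return np.ones(len(np.atleast_1d(pos)), dtype=float)
    z = rt_signal(config, chrom_idx, pos)
    return np.clip(1.0 + config.rt_amplitude * z, 0.0, None)


def _copy_number(
    config: SimConfig,
    sample_id: str,
    chrom: Iterable[str],
    pos: np.ndarray,
) -> np.ndarray:
    cn = np.full(len(pos), 2.0)
    clones = tuple(config.clone_ids)
    chrom = np.asarray(list(chrom))
    for seg in config.cna_segments:
        if not seg.carried_by(sample_id, clones):
            continue
        inside = (chrom == seg.chrom) & (pos - 1 >= seg.start) & (pos - 1 < seg.end)
        cn[inside] = seg.copy_number
    return cn


# ---------------------------------------------------------------------------
# Read-level callsets
# ---------------------------------------------------------------------------

def simulate_callset(
    truth: LineageTruth,
    clone_id: str,
    config: SimConfig | None = None,
) -> list[VariantCall]:
    """Emit sequencing-evidence calls for one sample.

    For an iPSC clone, calls cover every site the clone carries
    (somatic mutations plus germline SNPs); ``control_vaf`` is obtained
    by simulating control (NSC) reads at the same sites, where somatic
    sites have true VAF 0 and germline sites 0.5 or 1.  For
    ``clone_id == "NSC"`` the control's own callset (germline SNPs) is
    returned with itself as the reference.
    """
    config = config or truth.config
    known = set(truth.clone_ids) | {CONTROL_SAMPLE}
    if clone_id not in known:
        raise ValidationError(f"unknown sample {clone_id!r}")
    rng = _rng(config.seed, "callset", clone_id)

    sub = truth.subset(clone_id)
    n = len(sub)
    if n == 0:
        return []
    chrom = sub["chrom"].to_numpy()
    pos = sub["pos"].to_numpy(dtype=np.int64)
    chrom_idx = np.array([int(c[3:]) - 1 for c in chrom])
    true_vaf = sub["true_vaf"].to_numpy(dtype=float)
    is_germline = (sub["category"] == "germline").to_numpy()

    pluripotent = clone_id != CONTROL_SAMPLE
    dosage = _rt_dosage(config, chrom_idx, pos - 1, pluripotent)
    copies = _copy_number(config, clone_id, chrom, pos)
    expected = config.mean_coverage * dosage * copies / 2.0
    depth = rng.poisson(expected)
    alt = rng.binomial(depth, true_vaf)
    fwd = rng.binomial(alt, config.strand_bias)
    vaf = np.divide(alt, depth, out=np.zeros(n, dtype=float), where=depth > 0)

    # matched-control evidence at the same sites
    ctrl_vaf_true = np.where(is_germline, true_vaf, 0.0)
    ctrl_copies = _copy_number(config, CONTROL_SAMPLE, chrom, pos)
    ctrl_depth = rng.poisson(config.mean_coverage * ctrl_copies / 2.0)
    ctrl_alt = rng.binomial(ctrl_depth, ctrl_vaf_true)
    control_vaf = np.divide(
        ctrl_alt, ctrl_depth, out=np.zeros(n, dtype=float), where=ctrl_depth > 0
    )
    if clone_id == CONTROL_SAMPLE:
        control_vaf = vaf

    refs = sub["ref"].to_numpy()
    alts = sub["alt"].to_numpy()
    return [
        VariantCall(
            chrom=str(chrom[i]),
            pos=int(pos[i]),
            ref=str(refs[i]),
            alt=str(alts[i]),
            depth=int(depth[i]),
            alt_fwd=int(fwd[i]),
            alt_rev=int(alt[i] - fwd[i]),
            base_quality=float(config.base_quality),
            vaf=float(vaf[i]),
            control_vaf=float(control_vaf[i]),
            in_known_snp=bool(is_germline[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Depth profiles and tracks
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Binned mean read depth for one sample.

    ``bins`` columns: chrom, start, end (0-based half-open), depth.
    ``sample_type`` is 'pluripotent' or 'somatic'; only a pluripotent
    sample is a valid RT-dosage control downstream.
    """

    bins: pd.DataFrame
    bin_size: int
    sample_id: str
    sample_type: str = "pluripotent"


@dataclass
class RTTrack:
    """Replication timing as log2(Early/Late) signal on the same bins."""

    bins: pd.DataFrame  # chrom, start, end, value


def _genome_bins(config: SimConfig) -> pd.DataFrame:
    rows = []
    for ci, name in enumerate(config.chrom_names):
        starts = np.arange(0, config.chrom_length, config.bin_size)
        ends = np.minimum(starts + config.bin_size, config.chrom_length)
        rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def simulate_depth_and_rt(
    config: SimConfig,
    sample_ids: Sequence[str] | None = None,
) -> tuple[dict[str, DepthProfile], RTTrack]:
    """Binned depth profiles for the paired clones, the independent
    control iPSC line and the NSC sample, plus the shared RT track.

    Pluripotent samples share the RT dosage (extended S phase); the NSC
    sample does not.  CNA segments apply per ``CNASegmentSpec.origin_stage``.
    """
    bins = _genome_bins(config)
    chrom_idx = bins["chrom"].str[3:].astype(int).to_numpy() - 1
    mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
    z = rt_signal(config, chrom_idx, mid)
    rt = RTTrack(bins=bins.assign(value=z))

    if sample_ids is None:
        sample_ids = list(config.clone_ids) + [CONTROL_IPSC_SAMPLE, CONTROL_SAMPLE]
    profiles: dict[str, DepthProfile] = {}
    for sid in sample_ids:
        pluripotent = sid != CONTROL_SAMPLE
        dosage = np.clip(
            1.0 + (config.rt_amplitude if pluripotent else 0.0) * z, 0.0, None
        )
        copies = _copy_number(config, sid, bins["chrom"], mid.astype(np.int64) + 1)
        expected = config.mean_coverage * dosage * copies / 2.0
        if np.any(expected < 0):  # pragma: no cover - clip above prevents this
            expected = np.clip(expected, 0.0, None)
        rng = _rng(config.seed, "depth", sid)
        noise = rng.lognormal(mean=0.0, sigma=config.depth_noise_sd, size=len(bins))
        profiles[sid] = DepthProfile(
            bins=bins.assign(depth=expected * noise),
            bin_size=config.bin_size,
            sample_id=sid,
            sample_type="pluripotent" if pluripotent else "somatic",
        )
    return profiles, rt


def simulate_dhs_sites(config: SimConfig, n_sites: int = 5000) -> pd.DataFrame:
    """DNase I hypersensitive site positions (BED-style, 0-based
    half-open 1-bp features) with smoothly varying genomic density."""
    rng = _rng(config.seed, "dhs")
    g = config.chrom_length * config.n_chromosomes
    lin = np.sort(rng.integers(0, g, size=n_sites * 3))
    chrom_idx = lin // config.chrom_length
    pos = lin % config.chrom_length
    # thin by a smooth acceptance field so density varies along the genome
    field = rt_signal(config, chrom_idx, pos)
    accept = rng.random(len(lin)) < 1.0 / (1.0 + np.exp(-1.5 * field))
    chrom_idx, pos = chrom_idx[accept][:n_sites], pos[accept][:n_sites]
    names = config.chrom_names
    return pd.DataFrame(
        {
            "chrom": [names[i] for i in chrom_idx],
            "start": pos,
            "end": pos + 1,
        }
    )


def sample_positions_with_rt_bias(
    n: int,
    rt: RTTrack,
    late_multiplier: float = 1.0,
    noise_floor: float = 0.1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample SNV positions over the RT-binned genome with an optional
    late-replicating placement bias (weight ``late_multiplier`` for bins
    with signal < -noise_floor, 1 otherwise)."""
    rng = rng or np.random.default_rng(0)
    bins = rt.bins
    width = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    weight = np.where(bins["value"].to_numpy() < -noise_floor, late_multiplier, 1.0)
    p = width * weight
    p /= p.sum()
    idx = rng.choice(len(bins), size=n, p=p)
    offset = rng.integers(0, (bins["end"] - bins["start"]).to_numpy()[idx])
    return pd.DataFrame(
        {
            "chrom": bins["chrom"].to_numpy()[idx],
            "pos": bins["start"].to_numpy()[idx] + offset + 1,
        }
    )


# ---------------------------------------------------------------------------
# Validation outcomes
# ---------------------------------------------------------------------------

def simulate_validation(
    calls: Sequence[VariantCall],
    truth: LineageTruth,
    fp_rate: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emulate an orthogonal genotyping assay on called SNVs.

    Each input call is labelled confirmed/not by truth lookup (a real
    somatic mutation validates); additionally a fraction ``fp_rate`` of
    the *emitted* table are spiked non-truth sites labelled false, so
    the expected true-positive rate of the table is ``1 - fp_rate``
    when the input calls are all genuine.
    """
    if not 0.0 <= fp_rate <= 1.0:
        raise ValidationError("fp_rate must be in [0, 1]")
    config = truth.config
    rng = _rng(config.seed if seed is None else seed, "validation")
    somatic_sites = {
        (r.chrom, r.pos) for r in truth.somatic().itertuples(index=False)
    }
    rows = [
        {
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "confirmed": (c.chrom, c.pos) in somatic_sites,
        }
        for c in calls
    ]
    n_true = len(rows)
    if fp_rate >= 1.0:
        rows = []
        n_true = 0
        n_fp = max(len(calls), 1)
    else:
        n_fp = int(round(n_true * fp_rate / (1.0 - fp_rate)))
    if n_fp:
        sampler = _PositionSampler(config)
        sampler.used = {
            r["pos"] - 1 + (int(r["chrom"][3:]) - 1) * config.chrom_length
            for r in rows
        }
        chrom_idx, pos = sampler.draw(n_fp, rng)
        refs, alts = _draw_alleles(n_fp, config.somatic_class_probs, rng)
        names = config.chrom_names
        for i in range(n_fp):
            rows.append(
                {
                    "chrom": names[chrom_idx[i]],
                    "pos": int(pos[i]),
                    "ref": refs[i],
                    "alt": alts[i],
                    "confirmed": False,
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "confirmed"])
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: a copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
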