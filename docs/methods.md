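# Methods

## Generative model

The simulator follows the lineage the analysis assumes.  A zygote
undergoes `divisions_to_founder` divisions to one somatic founder cell;
each division adds `Poisson(mu_division)` category-I mutations, so the
founder carries a `Poisson(divisions × mu)` pre-existing burden shared
by everything derived from it.  The founder grows ex vivo into a binary
neurosphere tree of depth `neurosphere_divisions` (synchronous
divisions, leaves = cells); only edges ancestral to a sampled clone are
simulated, since mutations elsewhere are unobservable.  Two or more
leaves are reprogrammed into iPSC clones, each acquiring
`Poisson(mu_reprogramming)` category-II mutations, then
`Poisson(mu_culture_per_passage)` category-III mutations per passage
over `n_passages` passages.  Category I/II mutations and pre-fixation
culture mutations are clonal in their carrier (true VAF 0.5); culture
mutations from `fixation_passage` onward are subclonal with VAF ~
Uniform(0.05, 0.3).  Germline SNPs (VAF 0.5 or 1) are shared by every
sample and flagged as known polymorphisms.

Sequencing evidence per site: depth ~ Poisson(mean_coverage × RT dosage
× copy/2), alt reads ~ Binomial(depth, VAF), forward-strand alt reads ~
Binomial(alt, strand_bias).  The RT dosage term is
`max(0, 1 + rt_amplitude × z)` where `z` is a smooth standardised
replication-timing field (per-chromosome sum of eight harmonics with
seeded phases, analytically standardised); it applies to pluripotent
samples only, modelling their extended S phase.  Matched-control
(NSC) reads are simulated at the same sites with somatic VAF 0 and
germline VAF 0.5/1.  All randomness derives from `SimConfig.seed`
through named sub-streams (CRC32 of stream name), making every output
bit-reproducible and independent of call order.

### Default parameters

| parameter | default | why |
|---|---|---|
| `genome_length`, `n_chromosomes` | 2×10⁸ bp, 4 | toy genome large enough for a 38-Mb CNA per chromosome |
| `divisions_to_founder × mu_division` | 400 × 3 | effective in vivo burden ≈ 1200 category-I SNVs, the scale of the shared-SNV counts in the reference design |
| `neurosphere_divisions` | 6 | 2⁶ = 64 cells, inside the 50–100-cell neurosphere design |
| `mu_reprogramming` | 10 | a few dozen clone-private de novo SNVs per induction |
| `mu_culture_per_passage × n_passages` | 2 × 7 | passage-7 lines; `fixation_passage=2` makes early culture mutations clonal, later ones subclonal |
| `mean_coverage` | 40 | 40× WGS |
| `rt_amplitude` | 0.3 | ±30% dosage per RT s.d., enough that pseudo-CNAs dominate raw ratios |
| `base_quality`, `strand_bias` | 30, 0.5 | well-behaved sequencing |
| `n_germline_snps` | 1000 | token germline background for control/known-SNP logic (real genomes have orders of magnitude more; density is irrelevant to the statistics tested) |

The per-division rate is a single knob applied both in vivo and in the
neurosphere; its product with the division count is what matters for
each compartment, and the defaults were fixed once to land the
shared/unique counts at the reference scale (~1.2k shared, tens
unique), then left alone.

## Filtering and the paired bound

A call passes iff depth ≥ 15, base quality > 15 (strict), VAF ∈
[0.3, 0.7] (closed), control VAF 0 or 1 (within a config-exposed ε,
default 0), ≥ 2 alt reads per strand, and not a known polymorphism.
Rejections are attributed to the first failing criterion in that fixed
order; malformed records are rejected with an explicit reason first.
Filtering is idempotent and monotone in each threshold.

Unique/shared partitioning keys on (chrom, pos, alt).  Note a
real-data effect the simulator reproduces: a truly shared mutation that
drops out of *one* line's callset (read sampling, low RT dosage
coverage) is counted as unique to the other line.  This only inflates
the unique counts, so the de novo bound stays an upper bound — the
direction the design needs.

Counts are corrected by `round_half_up(raw × TPR)` in decimal
arithmetic.  Half-up reproduces the reference corrections except one:
1277 × 0.814 = 1039.478 → 1039 where the reference prints 1040,
consistent with an unrounded TPR upstream; we keep strict half-up and
pin the ±1 in a test.  The TPR interval is exact Clopper–Pearson.

## Model selection

"Close to 0.5" is operationalised as median VAF ∈ [0.4, 0.6]
(config-exposed; no numeric band is standard).  Model 2 is rejected
when integration-site VAFs (or, absent those, the SNV spectrum median)
are clonal; model 3 when each line's corrected unique count exceeds the
externally supplied de novo bound by factor 3 *and* the two-sided
conditional binomial test on the count pair (x successes of x+bound at
p = 1/2 — the standard conditional comparison of two Poisson counts)
is significant at α = 10⁻⁴.  Model 1 requires both rejections plus a
clonal median.  Fewer than 20 SNVs ⇒ indeterminate, never a forced
verdict.  The bound itself comes from the neurosphere design pair; the
pipeline evaluates verdicts on a separately simulated
regular-experiment pair (unrelated parental cells, divergence
`regular_divergence_divisions` = 100 divisions/branch), mirroring how
the bound from the controlled design is applied to ordinary
reprogramming experiments.

## CNA detection

Depth is binned at 500 kb (chromosome-arm-scale events are the target;
bins under 50% covered are masked).  The corrected profile is
`log2(sample/control)` minus its median, with the control required to
be pluripotent — an NSC control does not share the S-phase dosage and
is refused by type.  Median-centring the *ratio* (rather than dividing
each profile by its own median) keeps the copy-neutral baseline at 0
even when a 38-Mb gain shifts a per-sample median, and makes calls
invariant to library size.  Segmentation is threshold-merge:
consecutive bins beyond ±0.3 log2, minimum segment 5 Mb — sized so a
single-copy ~38-Mb gain (log2 1.5 ≈ 0.585) is comfortably detected;
the function boundary isolates it so a CBS-style method could be
swapped in.  Origin classification uses ≥ 50% reciprocal overlap with
matching call direction: shared by the paired lines and absent from
the control ⇒ pre-existing; private ⇒ post-reprogramming; present in
the control ⇒ germline background, excluded.  No GC correction is
applied (the simulator generates none; a known limitation on real
data).

## Signatures

Substitutions are collapsed to the six pyrimidine-reference classes
(purine references complemented; the collapse is involution-safe).
Two spectra are compared by χ² on the 2×6 table; when any expected
cell < 5 the asymptotic p is replaced by a seeded permutation null of
the same statistic (no r×c exact test exists in SciPy).  RT enrichment
classifies early/late by the sign of the log2(Early/Late) signal
outside a ±0.1 noise floor and tests the late SNV count with an exact
two-sided binomial against the late length share of *classified*
(callable) regions; SNVs in excluded bins are reported, not dropped.
DHS correlation is Spearman with average ranks on 10-Mb bins (≥ 10
informative bins; constant tracks yield NaN by definition).  Load
comparison is mean fold change with a Welch t-test when n ≥ 2 per
group.

## What the simulator does and does not emulate

Emulated: clonal VAF structure, Poisson lineage burdens, binomial read
sampling and strand split, RT-dosage pseudo-CNAs, true CNA segments by
origin stage, configurable somatic (C>A/C>T-elevated) vs germline
substitution class frequencies, validation false-positive spiking.
Not emulated: trinucleotide context, GC/mappability bias, alignment
and calling artifacts, indels/SVs beyond copy segments, FASTQ/BAM-level
data, chromatin- or RT-dependent *mutation* rates (positions are
uniform, so the pipeline's DHS-correlation and RT-enrichment stages are
null demonstrations on default synthetic data; their power is tested
with explicitly biased placement).  Passing tests therefore validate
the statistical machinery under the model's assumptions, not the
behaviour of any particular real dataset.

## Problem sizes and numerics

The test suite uses 500 seeded replicates of the default design for
bound/spectrum calibration, 200 for model-selection and power checks,
500 for the p-value-uniformity KS check (α = 0.01; n = 1000 SNVs per
replicate keeps binomial discreteness negligible), and 10⁴ randomised
records against the brute-force filter predicate; the whole suite runs
in about half a minute on one CPU.  `scripts/acceptance.py` scales the
replicate study to 100 + 50 replicates and finishes in seconds.
Reported fractions are rounded to one decimal only at the reporting
boundary; corrections use decimal half-up; RNG streams are named and
seeded, and tests are derandomised.
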