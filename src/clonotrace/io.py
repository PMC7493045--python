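"""File I/O at the pipeline boundary.

Variant calls travel as uncompressed VCF v4.2 (pysam) with read-level
evidence in INFO fields DP, ALT_FWD, ALT_REV, BQ, VAF; simulation truth
tags live in a sidecar TSV, never in the analysis-facing VCF.  Interval
tracks are bedGraph/BED with 0-based half-open coordinates; VCF
positions are 1-based and converted exactly once, here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
import yaml

from .errors import DataError
from .filtering import VariantCall, call_key
from .synthetic import LineageTruth

__all__ = [
    "write_vcf",
    "read_vcf",
    "attach_control",
    "flag_known_snps",
    "write_bedgraph",
    "read_bedgraph",
    "write_bed",
    "read_bed",
    "write_truth_tsv",
    "write_validation_tsv",
    "read_validation_tsv",
    "write_config_echo",
]

_INFO_FIELDS = (
    ("DP", "1", "Integer", "Total read depth at the site"),
    ("ALT_FWD", "1", "Integer", "Alt-supporting reads on the forward strand"),
    ("ALT_REV", "1", "Integer", "Alt-supporting reads on the reverse strand"),
    ("BQ", "1", "Float", "Mean Phred-scaled base quality of alt reads"),
    ("VAF", "1", "Float", "Variant allele frequency"),
)


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    sample_id: str,
    contigs: dict[str, int],
) -> None:
    """Write calls as an uncompressed VCF v4.2."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for fid, num, typ, desc in _INFO_FIELDS:
        header.info.add(fid, num, typ, desc)
    header.add_meta("source", value=f"clonotrace sample={sample_id}")
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in ordered:
            rec = out.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                stop=c.pos,
                alleles=(c.ref, c.alt),
            )
            rec.info["DP"] = int(c.depth)
            rec.info["ALT_FWD"] = int(c.alt_fwd)
            rec.info["ALT_REV"] = int(c.alt_rev)
            rec.info["BQ"] = float(c.base_quality)
            rec.info["VAF"] = float(c.vaf)
            out.write(rec)


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read a clonotrace VCF back into calls.

    ``control_vaf`` is initialised to 0 and ``in_known_snp`` to False;
    use :func:`attach_control` and :func:`flag_known_snps` to populate
    them from the matched control VCF and the exclusion BED.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            info = rec.info
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    depth=int(info.get("DP", 0)),
                    alt_fwd=int(info.get("ALT_FWD", 0)),
                    alt_rev=int(info.get("ALT_REV", 0)),
                    base_quality=float(info.get("BQ", 0.0)),
                    vaf=float(info.get("VAF", 0.0)),
                    control_vaf=0.0,
                    in_known_snp=False,
                )
            )
    return calls


def attach_control(
    case_calls: Iterable[VariantCall],
    control_calls: Iterable[VariantCall],
) -> list[VariantCall]:
    """Fill ``control_vaf`` of case calls from the control callset.

    Sites absent from the control VCF are taken as VAF 0 (no alt
    evidence in the control).
    """
    from dataclasses import replace

    lookup = {call_key(c): c.vaf for c in control_calls}
    return [
        replace(c, control_vaf=float(lookup.get(call_key(c), 0.0)))
        for c in case_calls
    ]


def flag_known_snps(
    calls: Iterable[VariantCall],
    known_bed: pd.DataFrame,
) -> list[VariantCall]:
    """Set ``in_known_snp`` for calls whose position falls inside a
    known-polymorphism BED interval (0-based half-open)."""
    from dataclasses import replace

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in known_bed.itertuples(index=False):
        by_chrom.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    out = []
    for c in calls:
        hit = any(s <= c.pos - 1 < e for s, e in by_chrom.get(c.chrom, ()))
        out.append(replace(c, in_known_snp=hit))
    return out


def write_bedgraph(df: pd.DataFrame, path: str | Path, value_col: str = "value") -> None:
    df[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    if df[["start", "end"]].isna().any().any():
        raise DataError(f"malformed bedGraph: {path}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                       names=["chrom", "start", "end"])


def write_truth_tsv(truth: LineageTruth, path: str | Path) -> None:
    """Sidecar truth table: one row per mutation with category, true
    VAF, lineage stage, and carrier sample ids."""
    df = truth.mutations.copy()
    df["carried_by"] = [",".join(sorted(s)) for s in df["carried_by"]]
    df.to_csv(path, sep="\t", index=False)


def write_validation_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_validation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "confirmed" not in df.columns:
        raise DataError(f"validation table lacks 'confirmed' column: {path}")
    df["confirmed"] = df["confirmed"].astype(bool)
    return df


def write_config_echo(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
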