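"""Readers and writers for the standard formats the pipeline exchanges.

VCF v4.2 is the call-table interchange format (depth, alt reads and VAF in
INFO as DP/AO/AF; the truth VCF additionally carries PROC/PAIR/ZYG/CF);
reading goes through pysam so any spec-conformant file works. FASTA is
read through pyfaidx. BED (0-based half-open) and bedGraph go through
pandas. Multi-allelic VCF records are split into biallelic rows on read.
"""
from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
import pysam
from pyfaidx import Fasta

from .synthetic import SyntheticGenome

CALL_COLUMNS = ["contig", "pos", "ref", "alt", "depth", "alt_reads", "vaf"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: SyntheticGenome, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome.names:
            fh.write(f">{name}\n")
            seq = genome.sequence(name)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> SyntheticGenome:
    fa = Fasta(str(path))
    genome = SyntheticGenome([(name, str(fa[name][:])) for name in fa.keys()])
    fa.close()
    return genome


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_HEADERS = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alt-supporting reads">',
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency">',
    '##INFO=<ID=PROC,Number=1,Type=String,Description="Planted mutational process">',
    '##INFO=<ID=PAIR,Number=1,Type=String,Description="Tandem pair id">',
    '##INFO=<ID=ZYG,Number=1,Type=String,Description="True zygosity">',
    '##INFO=<ID=CF,Number=1,Type=Float,Description="True cell fraction">',
]


def write_vcf(calls: pd.DataFrame, path,
              contig_lengths: dict[str, int] | None = None,
              sample: str = "") -> None:
    """Write a call table as uncompressed VCF v4.2.

    Optional columns process/pair_id/zygosity/cell_fraction are emitted as
    PROC/PAIR/ZYG/CF INFO keys (truth VCF only).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if sample:
            fh.write(f"##SAMPLE=<ID={sample}>\n")
        if contig_lengths:
            for name, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={ln}>\n")
        else:
            for name in pd.unique(calls["contig"]):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write("\n".join(_INFO_HEADERS) + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in calls.iterrows():
            info = []
            if "depth" in calls.columns and pd.notna(row.get("depth")):
                info.append(f"DP={int(row['depth'])}")
            if "alt_reads" in calls.columns and pd.notna(row.get("alt_reads")):
                info.append(f"AO={int(row['alt_reads'])}")
            if "vaf" in calls.columns and pd.notna(row.get("vaf")):
                info.append(f"AF={row['vaf']:.6g}")
            if row.get("process"):
                info.append(f"PROC={row['process']}")
            if row.get("pair_id"):
                info.append(f"PAIR={row['pair_id']}")
            if row.get("zygosity"):
                info.append(f"ZYG={row['zygosity']}")
            if "cell_fraction" in calls.columns and pd.notna(
                    row.get("cell_fraction")):
                info.append(f"CF={row['cell_fraction']:.6g}")
            fh.write(f"{row['contig']}\t{int(row['pos'])}\t.\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t{';'.join(info) or '.'}\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into the call-table frame (multi-allelic records split;
    SNV records only)."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        declared = set(vf.header.info.keys())

        def get(info, key):
            if key not in declared or key not in info:
                return None
            val = info.get(key)
            return val[0] if isinstance(val, tuple) else val

        for rec in vf:
            info = rec.info
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue
                depth = get(info, "DP")
                ao = get(info, "AO")
                af = get(info, "AF")
                if depth and ao is not None:
                    # recompute instead of trusting the float32 AF field,
                    # so VAF-window boundaries survive a round-trip
                    vaf = ao / depth
                else:
                    vaf = float(af) if af is not None else float("nan")
                row = {
                    "contig": rec.contig, "pos": rec.pos,
                    "ref": rec.ref, "alt": alt,
                    "depth": depth if depth is not None else pd.NA,
                    "alt_reads": ao if ao is not None else pd.NA,
                    "vaf": vaf,
                }
                for key, col in (("PROC", "process"), ("PAIR", "pair_id"),
                                 ("ZYG", "zygosity")):
                    val = get(info, key)
                    if val is not None:
                        row[col] = val
                cf = get(info, "CF")
                if cf is not None:
                    row["cell_fraction"] = float(cf)
                rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return df


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = ["contig", "start", "end"]
    extra = [c for c in ("strand",) if c in intervals.columns]
    out = intervals[cols].copy()
    if extra:
        out["name"] = "."
        out["score"] = 0
        out["strand"] = intervals["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "contig", 1: "start", 2: "end"})
    if df.shape[1] >= 6:
        df = df.rename(columns={5: "strand"})
        return df[["contig", "start", "end", "strand"]]
    return df[["contig", "start", "end"]]


def write_bedgraph(track: pd.DataFrame, path, value_col: str = "value") -> None:
    track[["contig", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["contig", "start", "end", "value"])
    return df
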