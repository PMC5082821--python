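"""Clonality rules for structural variants and mobile-element insertions.

A structural variant is clonal (present in the progenitor cell) when
strictly more than 30% of the reads at its junction support the novel
junction and the matched blood sample has zero supporting reads; calls in
supplied centromere/telomere exclusion intervals are dropped. For a
retrotransposon insertion the allele-frequency estimate is the ratio of
discordant repeat-anchored mate (RAM) read pairs to RAM plus concordant
pairs spanning the breakpoint; in duplicated regions the concordant count
is first scaled by (genome average depth / local depth), assuming the
insertion allele sits in a single copy of the duplicated region — an upper
bound of the event clonality. Frequencies well below the heterozygous
window mark events acquired during the clonal expansion, not in the
progenitor.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .filtering import HET_WINDOW, HOM_THRESHOLD, _in_blacklist, _interval_tree

SV_TYPES = ("deletion", "duplication", "inversion", "translocation")


@dataclass(frozen=True)
class SVCall:
    """One structural-variant junction call with read support."""

    sv_type: str
    contig: str
    start: int
    end: int
    supporting_reads: int
    total_reads: int
    blood_supporting_reads: int = 0

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if min(self.supporting_reads, self.total_reads,
               self.blood_supporting_reads) < 0:
            raise ValueError("read counts must be non-negative")
        if self.supporting_reads > self.total_reads:
            raise ValueError("supporting reads cannot exceed total reads")


@dataclass(frozen=True)
class InsertionCall:
    """One mobile-element insertion call with RAM/concordant support."""

    element_class: str          # L1 / Alu / SVA
    contig: str
    pos: int
    ram_count: int
    concordant_count: int
    local_depth: float
    genome_average_depth: float

    def __post_init__(self):
        if min(self.ram_count, self.concordant_count) < 0:
            raise ValueError("read-pair counts must be non-negative")
        if self.genome_average_depth <= 0:
            raise ValueError("genome average depth must be positive")
        if self.local_depth < 0:
            raise ValueError("local depth must be non-negative")


def filter_clonal_sv(calls: list[SVCall], min_fraction: float = 0.30,
                     exclude: pd.DataFrame | None = None) -> list[SVCall]:
    """Clonal SVs: support fraction strictly > min_fraction and zero blood
    support; calls whose start falls in an exclusion interval (e.g.
    centromeres/telomeres) are dropped; zero-total calls are skipped with
    a warning."""
    trees = _interval_tree(exclude)
    out = []
    for call in calls:
        if call.total_reads == 0:
            warnings.warn(
                f"SV at {call.contig}:{call.start} has no reads; skipped")
            continue
        tree = trees.get(call.contig)
        if tree is not None and tree.overlaps_point(call.start):
            continue
        if call.supporting_reads / call.total_reads > min_fraction \
                and call.blood_supporting_reads == 0:
            out.append(call)
    return out


def insertion_clonality(call: InsertionCall) -> float:
    """Allele-frequency estimate RAM / (RAM + concordant); NaN when both
    counts are zero."""
    denom = call.ram_count + call.concordant_count
    if denom == 0:
        return float("nan")
    return call.ram_count / denom


def cn_adjusted_clonality(call: InsertionCall) -> float:
    """Copy-number-adjusted allele frequency: the concordant count is
    scaled by genome-average/local depth before the ratio (upper bound of
    the event clonality in duplicated regions)."""
    if call.local_depth == 0:
        raise ValueError("local depth must be positive for adjustment")
    adj_concordant = call.concordant_count * (
        call.genome_average_depth / call.local_depth)
    denom = call.ram_count + adj_concordant
    if denom == 0:
        return float("nan")
    return call.ram_count / denom


def classify_subclonal(frequency: float,
                       het_window: tuple[float, float] = HET_WINDOW,
                       hom_threshold: float = HOM_THRESHOLD) -> str:
    """'clonal-het' in the heterozygous VAF window, 'clonal-hom' above the
    homozygous threshold, else 'subclonal' (acquired during expansion)."""
    if not 0 <= frequency <= 1:
        raise ValueError("frequency must be in [0, 1]")
    if frequency > hom_threshold:
        return "clonal-hom"
    if het_window[0] <= frequency <= het_window[1]:
        return "clonal-het"
    return "subclonal"


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

SV_TSV_COLUMNS = ["sv_type", "contig", "start", "end", "supporting_reads",
                  "total_reads", "blood_supporting_reads"]
INS_TSV_COLUMNS = ["element_class", "contig", "pos", "ram_count",
                   "concordant_count", "local_depth", "genome_average_depth"]


def read_sv_tsv(path) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t")
    return [SVCall(**{k: row[k] for k in SV_TSV_COLUMNS})
            for _, row in df.iterrows()]


def read_insertion_tsv(path) -> list[InsertionCall]:
    df = pd.read_csv(path, sep="\t")
    return [InsertionCall(**{k: row[k] for k in INS_TSV_COLUMNS})
            for _, row in df.iterrows()]


def clonality_table(sv_calls: list[SVCall],
                    insertion_calls: list[InsertionCall],
                    min_fraction: float = 0.30,
                    exclude: pd.DataFrame | None = None) -> pd.DataFrame:
    """Combined table: clonal SVs plus insertions with raw and
    copy-number-adjusted allele-frequency estimates and labels."""
    rows = []
    for sv in filter_clonal_sv(sv_calls, min_fraction, exclude):
        rows.append({
            "kind": "SV", "type": sv.sv_type, "contig": sv.contig,
            "start": sv.start, "end": sv.end,
            "support_fraction": sv.supporting_reads / sv.total_reads,
            "frequency": float("nan"), "label": "clonal",
        })
    for ins in insertion_calls:
        freq = insertion_clonality(ins)
        adj = cn_adjusted_clonality(ins) if ins.local_depth > 0 else float("nan")
        rows.append({
            "kind": "insertion", "type": ins.element_class,
            "contig": ins.contig, "start": ins.pos, "end": ins.pos,
            "support_fraction": float("nan"),
            "frequency": freq,
            "frequency_cn_adjusted": adj,
            "label": classify_subclonal(freq) if freq == freq else "undefined",
        })
    return pd.DataFrame(rows)
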