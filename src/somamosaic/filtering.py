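"""Consensus somatic SNV filtering and zygosity classification.

A candidate call survives iff it is reported by all three callers, has
depth >= 10 with >= 3 alt-supporting reads, does not overlap the dbSNP-like
or simple-repeat blacklists, is absent from the matched blood table
(the somatic definition), and has a clonal allele frequency: heterozygous
at VAF in [0.45, 0.55], homozygous at VAF > 0.90; everything else is
discarded as subclonal or artefactual. The VAF windows are closed at 0.45
and 0.55 and strictly open at 0.90, following the wording "between ... and"
versus "greater than".

Call tables are pandas DataFrames with columns contig, pos (1-based), ref,
alt, depth, alt_reads, vaf; records are keyed by (contig, pos, ref, alt).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

KEY = ["contig", "pos", "ref", "alt"]

HET_WINDOW = (0.45, 0.55)
HOM_THRESHOLD = 0.90


@dataclass
class MutationCatalog:
    """Filtered clonal SNV set for one clone plus its sample metadata."""

    calls: pd.DataFrame
    donor: str = ""
    site: str = ""          # 'forearm' or 'hip'
    clone_id: str = ""
    age: float = float("nan")

    @property
    def mutation_load(self) -> int:
        return len(self.calls)


def _check_unique(table: pd.DataFrame, label: str) -> None:
    if table.duplicated(KEY).any():
        dup = table.loc[table.duplicated(KEY), KEY].iloc[0].tolist()
        raise ValueError(f"duplicate key {tuple(dup)} in table {label!r}")


def split_multiallelic(table: pd.DataFrame) -> pd.DataFrame:
    """Split comma-separated alt alleles into biallelic records (the VAF
    and alt-read columns are carried unchanged onto each split record)."""
    multi = table["alt"].astype(str).str.contains(",")
    if not multi.any():
        return table
    rows = [table.loc[~multi]]
    expanded = table.loc[multi].copy()
    expanded["alt"] = expanded["alt"].str.split(",")
    rows.append(expanded.explode("alt"))
    return pd.concat(rows, ignore_index=True)


def intersect_callers(tables: Mapping[str, pd.DataFrame],
                      primary: str | None = None) -> pd.DataFrame:
    """Calls present in every caller's table; depth/alt-reads/VAF taken
    from the designated primary caller (default: the first)."""
    if not tables:
        raise ValueError("no caller tables given")
    names = list(tables)
    if primary is None:
        primary = names[0]
    if primary not in tables:
        raise ValueError(f"primary caller {primary!r} not among {names}")
    for name, tab in tables.items():
        _check_unique(tab, name)
    keys = None
    for name in names:
        k = pd.MultiIndex.from_frame(tables[name][KEY])
        keys = k if keys is None else keys.intersection(k)
    base = tables[primary].set_index(pd.MultiIndex.from_frame(
        tables[primary][KEY]))
    out = base.loc[keys].reset_index(drop=True)
    out["callers"] = ",".join(sorted(names))
    return out.sort_values(["contig", "pos"], kind="stable",
                           ignore_index=True)


def _interval_tree(intervals: pd.DataFrame | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if intervals is None or len(intervals) == 0:
        return trees
    for contig, start, end in zip(intervals["contig"], intervals["start"],
                                  intervals["end"]):
        if end <= start or start < 0:
            raise ValueError(f"malformed interval {contig}:{start}-{end}")
        trees.setdefault(contig, IntervalTree()).addi(int(start), int(end))
    return trees


def _in_blacklist(calls: pd.DataFrame,
                  trees: dict[str, IntervalTree]) -> np.ndarray:
    if not trees:
        return np.zeros(len(calls), dtype=bool)
    hit = np.zeros(len(calls), dtype=bool)
    for i, (contig, pos) in enumerate(zip(calls["contig"], calls["pos"])):
        tree = trees.get(contig)
        if tree is not None and tree.overlaps_point(int(pos) - 1):
            hit[i] = True
    return hit


def apply_site_filters(calls: pd.DataFrame,
                       blood_calls: pd.DataFrame | None = None,
                       blacklist_snp: pd.DataFrame | None = None,
                       blacklist_repeats: pd.DataFrame | None = None,
                       min_depth: int = 10,
                       min_alt: int = 3) -> pd.DataFrame:
    """Depth/alt-read thresholds, blacklist exclusion (by position overlap
    with 0-based half-open BED intervals) and blood subtraction (absence of
    the exact key from the blood table)."""
    keep = (calls["depth"] >= min_depth) & (calls["alt_reads"] >= min_alt)
    keep &= ~_in_blacklist(calls, _interval_tree(blacklist_snp))
    keep &= ~_in_blacklist(calls, _interval_tree(blacklist_repeats))
    out = calls.loc[keep]
    if blood_calls is not None and len(blood_calls):
        blood_keys = pd.MultiIndex.from_frame(blood_calls[KEY])
        own = pd.MultiIndex.from_frame(out[KEY])
        out = out.loc[~own.isin(blood_keys)]
    return out.reset_index(drop=True)


def classify_zygosity(calls: pd.DataFrame,
                      het_window: tuple[float, float] = HET_WINDOW,
                      hom_threshold: float = HOM_THRESHOLD,
                      ) -> tuple[pd.DataFrame, float]:
    """Label calls het/hom by VAF and drop the rest; returns the labelled
    table and the fraction of input calls retained."""
    vaf = calls["vaf"].to_numpy(dtype=float)
    het = (vaf >= het_window[0]) & (vaf <= het_window[1])
    hom = vaf > hom_threshold
    out = calls.loc[het | hom].copy()
    out["zygosity"] = np.where(out["vaf"] > hom_threshold, "hom", "het")
    frac = len(out) / len(calls) if len(calls) else float("nan")
    return out.reset_index(drop=True), frac


def call_loh(clone_calls: pd.DataFrame, blood_calls: pd.DataFrame,
             het_window: tuple[float, float] = HET_WINDOW,
             hom_threshold: float = HOM_THRESHOLD) -> pd.DataFrame:
    """Loss-of-heterozygosity events: sites heterozygous in blood
    (VAF in [0.45, 0.55]) and homozygous in the clone (VAF > 0.90)."""
    merged = clone_calls.merge(blood_calls, on=KEY,
                               suffixes=("_clone", "_blood"))
    mask = (merged["vaf_blood"] >= het_window[0]) \
        & (merged["vaf_blood"] <= het_window[1]) \
        & (merged["vaf_clone"] > hom_threshold)
    return merged.loc[mask].reset_index(drop=True)


def find_shared_snvs(catalogs: Mapping[str, pd.DataFrame],
                     het_window: tuple[float, float] = HET_WINDOW,
                     hom_threshold: float = HOM_THRESHOLD) -> pd.DataFrame:
    """Records present in >= 2 catalogs with a qualifying VAF (het window
    or above the hom threshold) in at least one of the sharing samples.
    Returns key columns plus the tuple of sharing sample ids."""
    if len(catalogs) < 2:
        raise ValueError("need at least two catalogs")
    frames = []
    for sample, cat in catalogs.items():
        sub = cat[KEY + ["vaf"]].copy()
        sub["sample"] = sample
        frames.append(sub)
    allc = pd.concat(frames, ignore_index=True)
    vaf = allc["vaf"]
    allc["qualifies"] = ((vaf >= het_window[0]) & (vaf <= het_window[1])) \
        | (vaf > hom_threshold)
    rows = []
    for key, grp in allc.groupby(KEY):
        samples = tuple(sorted(grp["sample"].unique()))
        if len(samples) >= 2 and grp["qualifies"].any():
            rows.append((*key, samples))
    return pd.DataFrame(rows, columns=KEY + ["samples"])


def vaf_histogram(calls: pd.DataFrame, bin_width: float = 0.05):
    """Binned VAF counts over [0, 1] plus the two summary fractions
    (het window 45-55%, hom > 90%). Returns (counts, edges, frac_het,
    frac_hom); counts sum to the number of calls."""
    edges = np.round(np.arange(0, 1 + bin_width / 2, bin_width), 10)
    vaf = calls["vaf"].to_numpy(dtype=float) if len(calls) else np.array([])
    counts, _ = np.histogram(vaf, bins=edges)
    n = len(vaf)
    frac_het = float(((vaf >= 0.45) & (vaf <= 0.55)).sum() / n) if n else 0.0
    frac_hom = float((vaf > 0.90).sum() / n) if n else 0.0
    return counts, edges, frac_het, frac_hom


def expected_bulk_load(clone_exonic_count: int, n_clones: int = 10) -> int:
    """Expected bulk-exome mutation count under the minimum-clonal-lineage
    model: the clone's exonic count times the number of lineages."""
    if clone_exonic_count < 0 or n_clones < 0:
        raise ValueError("counts must be non-negative")
    return int(clone_exonic_count) * int(n_clones)


def consensus_catalog(tables: Mapping[str, pd.DataFrame],
                      blood_calls: pd.DataFrame | None = None,
                      blacklist_snp: pd.DataFrame | None = None,
                      blacklist_repeats: pd.DataFrame | None = None,
                      min_depth: int = 10, min_alt: int = 3,
                      het_window: tuple[float, float] = HET_WINDOW,
                      hom_threshold: float = HOM_THRESHOLD,
                      primary: str | None = None,
                      donor: str = "", site: str = "", clone_id: str = "",
                      age: float = float("nan"),
                      ) -> tuple[MutationCatalog, dict[str, int]]:
    """Full filter chain; returns the catalog and per-stage record counts
    (for the monotonicity audit at stage boundaries)."""
    stage_counts: dict[str, int] = {
        f"input_{name}": len(tab) for name, tab in tables.items()}
    consensus = intersect_callers(tables, primary=primary)
    stage_counts["consensus"] = len(consensus)
    filtered = apply_site_filters(consensus, blood_calls, blacklist_snp,
                                  blacklist_repeats, min_depth, min_alt)
    stage_counts["site_filters"] = len(filtered)
    labelled, _ = classify_zygosity(filtered, het_window, hom_threshold)
    stage_counts["zygosity"] = len(labelled)
    catalog = MutationCatalog(labelled, donor=donor, site=site,
                              clone_id=clone_id, age=age)
    return catalog, stage_counts
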