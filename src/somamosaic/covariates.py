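"""Mutation density against genomic covariates, and transcription-strand bias.

The genome is tiled into fixed-width windows (1 Mb by default; the last
window of a contig may be shorter). Replication timing is summarised per
window as the length-weighted mean of the (already wavelet-smoothed)
signal; DNase I hypersensitivity as the count of peaks whose midpoint
falls in the window. Window values are ranked into k equal-population
bins (k = 5), and the mean mutation density (mutations/Mb) per bin is
summarised by the least-squares slope over bin index — a positive slope
means denser mutations toward late-replicating / closed-chromatin windows.
Equal-width binning is available via bin_mode="width".

For transcription-strand bias, each pyrimidine-context mutation inside a
gene is labelled by whether the strand carrying the mutated pyrimidine is
the gene's coding (non-transcribed) or template (transcribed) strand;
transcription-coupled repair depletes the transcribed strand, so the
one-sided binomial test expects an excess on the non-transcribed strand.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import dna
from .signatures import bh_adjust, uv_signature_mask
from .synthetic import SyntheticGenome


def make_windows(lengths: Mapping[str, int],
                 size: int = 1_000_000) -> pd.DataFrame:
    """Tile each contig with fixed-width windows (last may be shorter)."""
    if size <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for contig, ln in lengths.items():
        for i in range(int(np.ceil(ln / size))):
            rows.append((contig, i * size, min((i + 1) * size, ln)))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def window_covariate(track: pd.DataFrame, windows: pd.DataFrame,
                     mode: str = "mean") -> np.ndarray:
    """Per-window covariate value from an interval track.

    mode='mean': length-weighted mean of the track's `value` column over
    each window (replication timing). mode='count': number of track
    intervals whose midpoint falls in the window (DNase peaks; a peak
    straddling a boundary is assigned by its midpoint). Windows without
    any overlap get NaN in 'mean' mode; if nothing overlaps anywhere a
    ValueError is raised.
    """
    if mode not in ("mean", "count"):
        raise ValueError("mode must be 'mean' or 'count'")
    win_index: dict[str, list[int]] = {}
    for i, (contig, start) in enumerate(zip(windows["contig"],
                                            windows["start"])):
        win_index.setdefault(contig, []).append(i)
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    if mode == "count":
        out = np.zeros(len(windows))
        hit_any = False
        for contig, s, e in zip(track["contig"], track["start"],
                                track["end"]):
            mid = (int(s) + int(e)) // 2
            for i in win_index.get(contig, ()):
                if starts[i] <= mid < ends[i]:
                    out[i] += 1
                    hit_any = True
                    break
        if len(track) and not hit_any:
            raise ValueError("track does not overlap the windows anywhere")
        return out
    total = np.zeros(len(windows))
    weight = np.zeros(len(windows))
    for contig, s, e, v in zip(track["contig"], track["start"],
                               track["end"], track["value"]):
        for i in win_index.get(contig, ()):
            ov = min(int(e), ends[i]) - max(int(s), starts[i])
            if ov > 0:
                total[i] += float(v) * ov
                weight[i] += ov
    if weight.sum() == 0:
        raise ValueError("track does not overlap the windows anywhere")
    out = np.full(len(windows), np.nan)
    ok = weight > 0
    out[ok] = total[ok] / weight[ok]
    return out


def mutation_counts(catalog: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Number of catalog records per window."""
    out = np.zeros(len(windows))
    by_contig: dict[str, list[int]] = {}
    for i, contig in enumerate(windows["contig"]):
        by_contig.setdefault(contig, []).append(i)
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    for contig, pos in zip(catalog["contig"], catalog["pos"]):
        p0 = int(pos) - 1
        for i in by_contig.get(contig, ()):
            if starts[i] <= p0 < ends[i]:
                out[i] += 1
                break
    return out


def mutation_density(catalog: pd.DataFrame,
                     windows: pd.DataFrame) -> np.ndarray:
    """Mutations per Mb per window."""
    counts = mutation_counts(catalog, windows)
    span_mb = (windows["end"] - windows["start"]).to_numpy() / 1e6
    return counts / span_mb


def quantile_bins(values: np.ndarray, k: int = 5,
                  mode: str = "population") -> np.ndarray:
    """Assign each window a bin index 1..k by its covariate value.

    mode='population' (default): equal-population bins whose sizes differ
    by at most 1, ties broken by window order (stable sort).
    mode='width': k equal-width value bins. NaN values get bin 0.
    """
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if ok.sum() < k:
        raise ValueError(f"need >= {k} non-missing values, got {int(ok.sum())}")
    out = np.zeros(len(values), dtype=int)
    if mode == "population":
        idx = np.flatnonzero(ok)
        order = idx[np.argsort(values[idx], kind="stable")]
        for b, chunk in enumerate(np.array_split(order, k), start=1):
            out[chunk] = b
    elif mode == "width":
        v = values[ok]
        edges = np.linspace(v.min(), v.max(), k + 1)
        bins = np.clip(np.searchsorted(edges, v, side="right"), 1, k)
        out[ok] = bins
    else:
        raise ValueError("mode must be 'population' or 'width'")
    return out


def density_by_bin(densities: np.ndarray, bins: np.ndarray,
                   k: int = 5) -> tuple[np.ndarray, float]:
    """Mean window density per bin, plus the least-squares slope of mean
    density against bin index 1..k. Empty bins contribute mean 0."""
    densities = np.asarray(densities, dtype=float)
    bins = np.asarray(bins)
    means = np.zeros(k)
    for b in range(1, k + 1):
        sel = bins == b
        if sel.any():
            means[b - 1] = densities[sel].mean()
    if np.allclose(means, 0):
        return means, 0.0
    slope = float(np.polyfit(np.arange(1, k + 1), means, 1)[0])
    return means, slope


# ---------------------------------------------------------------------------
# transcription-strand bias
# ---------------------------------------------------------------------------

@dataclass
class StrandCounts:
    """Per-sample strand-resolved mutation counts with test results."""

    sample: str
    signature_class: str
    non_transcribed: int
    transcribed: int
    p: float = float("nan")
    q: float = float("nan")


def assign_transcription_strand(catalog: pd.DataFrame,
                                genes: pd.DataFrame) -> np.ndarray:
    """Label each mutation 'transcribed', 'non-transcribed', 'intergenic'
    or 'ambiguous'.

    The strand carrying the mutated pyrimidine (the forward strand when
    ref is C/T, else the reverse) is compared to the gene's strands: equal
    to the coding strand means the lesion sits on the non-transcribed
    strand. Mutations under overlapping genes of opposite strands are
    'ambiguous' and excluded from testing.
    """
    labels = np.full(len(catalog), "intergenic", dtype=object)
    if len(genes) == 0:
        return labels
    by_contig: dict[str, pd.DataFrame] = {
        c: sub for c, sub in genes.groupby("contig")}
    for i, (contig, pos, ref) in enumerate(zip(
            catalog["contig"], catalog["pos"], catalog["ref"])):
        sub = by_contig.get(contig)
        if sub is None:
            continue
        p0 = int(pos) - 1
        hit = sub.loc[(sub["start"] <= p0) & (p0 < sub["end"])]
        if len(hit) == 0:
            continue
        strands = set(hit["strand"])
        if len(strands) > 1:
            labels[i] = "ambiguous"
            continue
        gene_strand = strands.pop()
        pyr_strand = "+" if ref in dna.PYRIMIDINES else "-"
        labels[i] = ("non-transcribed" if pyr_strand == gene_strand
                     else "transcribed")
    return labels


def strand_bias_test(non_transcribed: int, transcribed: int) -> float:
    """One-sided binomial tail P(X >= non_transcribed | n, 0.5); NaN when
    there are no strand-assigned mutations."""
    n = non_transcribed + transcribed
    if n == 0:
        return float("nan")
    return float(stats.binomtest(non_transcribed, n, 0.5,
                                 alternative="greater").pvalue)


def strand_bias_table(counts: list[StrandCounts]) -> list[StrandCounts]:
    """Run the binomial test per entry and BH-adjust across the family."""
    for c in counts:
        c.p = strand_bias_test(c.non_transcribed, c.transcribed)
    qs = bh_adjust([c.p for c in counts])
    for c, q in zip(counts, qs):
        c.q = float(q)
    return counts


def uv_strand_counts(genome: SyntheticGenome, catalog: pd.DataFrame,
                     genes: pd.DataFrame, sample: str = "sample",
                     ) -> StrandCounts:
    """Strand counts for UV-signature mutations (yCn→yTn, nTt→nCt, tandem
    CC→TT members, counted once) inside unambiguous genes."""
    uv = uv_signature_mask(genome, catalog)
    labels = assign_transcription_strand(catalog, genes)
    return StrandCounts(
        sample, "UV",
        int(((labels == "non-transcribed") & uv).sum()),
        int(((labels == "transcribed") & uv).sum()))


def non_uv_control(genome: SyntheticGenome, catalog: pd.DataFrame,
                   genes: pd.DataFrame, sample: str = "sample",
                   ) -> StrandCounts:
    """Control strand counts: pyrimidine-context mutations matching no UV
    signature, tested identically. Together with the UV set this partitions
    the catalog (CC→TT members are counted once, in the UV set)."""
    uv = uv_signature_mask(genome, catalog)
    labels = assign_transcription_strand(catalog, genes)
    ctl = ~uv
    return StrandCounts(
        sample, "non-UV",
        int(((labels == "non-transcribed") & ctl).sum()),
        int(((labels == "transcribed") & ctl).sum()))
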