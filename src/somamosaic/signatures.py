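"""Mechanistic knowledge-based mutation-signature statistics.

A signature motif is a trinucleotide with the mutated base in the centre
(capitalised in the conventional notation): nCg→nTg, yCn→yTn, nTt→nCt and
so on, where n is any base, y a pyrimidine (C/T) and r a purine (A/G).
For each sample and motif we ask whether mutations of the central base
land inside the motif more often than the motif occurs among the central
base's occurrences in the local sequence context — the 41-nt windows
centred on the mutated residues. Both strands are always counted: every
motif is also matched as its reverse complement.

    enrichment = [mutations(motif) * context(base)]
               / [mutations(base)  * context(motif)]

Significance is a one-sided Fisher's exact test on the 2x2 table of
mutations in/out of the motif against context bases in/out of the motif,
Benjamini-Hochberg corrected across samples within each motif family.
For enriched, significant samples the minimum mutation load attributable
to the motif's mechanism is mutations(motif) * (E-1)/E — the excess over
what a context-blind process would have produced in-motif; otherwise the
load is 0 (the "zero rule").

Context bases are counted only at window positions where the full
trinucleotide is visible (both neighbours inside the window); counting
edge centres in context(base) but never in context(motif) would bias
enrichment upward by a few percent.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import dna
from .synthetic import SyntheticGenome

_SET_CODES = {
    "n": frozenset("ACGT"),
    "y": frozenset("CT"),
    "r": frozenset("AG"),
    "a": frozenset("A"), "c": frozenset("C"),
    "g": frozenset("G"), "t": frozenset("T"),
}


@dataclass(frozen=True)
class SignatureMotif:
    """Trinucleotide mutation signature: 5' set, mutated base, 3' set, target."""

    five_prime: frozenset
    base: str
    three_prime: frozenset
    target: str

    def __post_init__(self):
        if self.base not in dna.BASES or self.target not in dna.BASES:
            raise ValueError("mutated base and target must be in ACGT")
        if self.base == self.target:
            raise ValueError("target must differ from the mutated base")
        if not self.five_prime or not self.three_prime:
            raise ValueError("flank sets must be non-empty")
        if set(self.five_prime) - dna.BASES or set(self.three_prime) - dna.BASES:
            raise ValueError("flank sets must be subsets of ACGT")

    @classmethod
    def parse(cls, notation: str) -> "SignatureMotif":
        """Parse e.g. 'nTt>nCt', 'yCn→yTn' (ambiguity codes n/y/r, or a
        literal lowercase base, in the flanks; centre uppercase)."""
        s = notation.replace("→", ">").replace("->", ">")
        left, _, right = s.partition(">")
        left, right = left.strip(), right.strip()
        if len(left) != 3 or len(right) != 3:
            raise ValueError(f"cannot parse motif notation {notation!r}")
        return cls(_SET_CODES[left[0].lower()], left[1].upper(),
                   _SET_CODES[left[2].lower()], right[1].upper())

    @property
    def name(self) -> str:
        rev = {v: k for k, v in _SET_CODES.items() if len(v) > 1}
        def code(s):
            return rev.get(s, next(iter(s)).lower() if len(s) == 1 else "n")
        return f"{code(self.five_prime)}{self.base}{code(self.three_prime)}"

    def __str__(self) -> str:
        n = self.name
        return f"{n[0]}{self.base}{n[2]}>{n[0]}{self.target}{n[2]}"


#: The signature set analysed throughout: CpG deamination (nCg and its
#: purine/pyrimidine 5' partition) and the UV photoproduct signatures
#: (yCn, and nTt with its partition).
TABLE_MOTIFS: dict[str, SignatureMotif] = {
    name: SignatureMotif.parse(s) for name, s in [
        ("nCg", "nCg>nTg"), ("rCg", "rCg>rTg"), ("yCg", "yCg>yTg"),
        ("yCn", "yCn>yTn"),
        ("nTt", "nTt>nCt"), ("rTt", "rTt>rCt"), ("yTt", "yTt>yCt"),
    ]
}

UV_MOTIF_NAMES = ("yCn", "nTt")


@dataclass
class ContextCounts:
    """Counts feeding one enrichment computation."""

    mutations_in_motif: int
    mutations_base: int
    context_in_motif: int
    context_base: int

    def __post_init__(self):
        if self.mutations_in_motif > self.mutations_base:
            raise ValueError("mutations(motif) cannot exceed mutations(base)")
        if self.context_in_motif > self.context_base:
            raise ValueError("context(motif) cannot exceed context(base)")
        if min(self.mutations_in_motif, self.mutations_base,
               self.context_in_motif, self.context_base) < 0:
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# context extraction and motif counting
# ---------------------------------------------------------------------------

def extract_contexts(genome: SyntheticGenome, catalog: pd.DataFrame,
                     window: int = 41) -> list[tuple[str, int]]:
    """41-nt windows (truncated at contig ends) around each catalog record.

    Returns (sequence, centre index) pairs; raises if a record's position
    is off-contig or its ref disagrees with the genome.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    flank = window // 2
    out = []
    for contig, pos, ref in zip(catalog["contig"], catalog["pos"],
                                catalog["ref"]):
        seq, centre = genome.context(contig, int(pos) - 1, flank)
        if seq[centre] != ref:
            raise ValueError(
                f"catalog ref {ref!r} does not match genome base "
                f"{seq[centre]!r} at {contig}:{pos}")
        out.append((seq, centre))
    return out


def count_motif(contexts: Iterable[str | tuple[str, int]],
                motif: SignatureMotif) -> ContextCounts:
    """Count motif and central-base occurrences over both strands of the
    given context sequences (mutation fields are left at 0).

    Every position whose visible trinucleotide matches counts, including
    overlapping occurrences; N never matches and positions lacking a
    neighbour within the window are excluded from both counts.
    """
    seqs = [c[0] if isinstance(c, tuple) else c for c in contexts]
    c_in, c_base = _scan_contexts(seqs, motif)
    return ContextCounts(0, 0, c_in, c_base)


def _scan_contexts(seqs: Sequence[str], motif: SignatureMotif):
    if not seqs:
        return 0, 0
    # concatenate with N separators so 3-mers never span two windows
    joined = ("N".join(seqs)).upper()
    x = dna.encode(joined)
    if len(x) < 3:
        return 0, 0
    left, mid, right = x[:-2], x[1:-1], x[2:]
    five = dna.member_mask(motif.five_prime)
    three = dna.member_mask(motif.three_prime)
    cfive = dna.member_mask({dna.COMPLEMENT[b] for b in motif.five_prime})
    cthree = dna.member_mask({dna.COMPLEMENT[b] for b in motif.three_prime})
    cb = dna.CODE[motif.base]
    ccb = dna.CODE[dna.COMPLEMENT[motif.base]]
    valid = (left != dna.N) & (mid != dna.N) & (right != dna.N)
    fwd_centre = valid & (mid == cb)
    rev_centre = valid & (mid == ccb)
    c_base = int(fwd_centre.sum() + rev_centre.sum())
    c_in = int((fwd_centre & five[left] & three[right]).sum()
               + (rev_centre & cthree[left] & cfive[right]).sum())
    return c_in, c_base


def _class_mask(catalog: pd.DataFrame, motif: SignatureMotif) -> np.ndarray:
    ref = catalog["ref"].to_numpy()
    alt = catalog["alt"].to_numpy()
    cb, tg = motif.base, motif.target
    ccb, ctg = dna.COMPLEMENT[cb], dna.COMPLEMENT[tg]
    return ((ref == cb) & (alt == tg)) | ((ref == ccb) & (alt == ctg))


def mutations_in_motif_mask(genome: SyntheticGenome, catalog: pd.DataFrame,
                            motif: SignatureMotif) -> np.ndarray:
    """Boolean per-record mask: record is a motif-class mutation whose
    immediate context matches the motif (on the strand carrying the motif's
    central base). Records at contig ends never match."""
    cls = _class_mask(catalog, motif)
    out = np.zeros(len(catalog), dtype=bool)
    if not cls.any():
        return out
    cfive = {dna.COMPLEMENT[b] for b in motif.five_prime}
    cthree = {dna.COMPLEMENT[b] for b in motif.three_prime}
    idx = np.flatnonzero(cls)
    contigs = catalog["contig"].to_numpy()
    poss = catalog["pos"].to_numpy()
    refs = catalog["ref"].to_numpy()
    for i in idx:
        contig, p0, ref = contigs[i], int(poss[i]) - 1, refs[i]
        seq = genome.sequence(contig)
        if p0 <= 0 or p0 >= len(seq) - 1:
            continue
        if ref == motif.base:
            out[i] = (seq[p0 - 1] in motif.five_prime
                      and seq[p0 + 1] in motif.three_prime)
        else:
            out[i] = seq[p0 - 1] in cthree and seq[p0 + 1] in cfive
    return out


def motif_counts(genome: SyntheticGenome, catalog: pd.DataFrame,
                 motif: SignatureMotif, window: int = 41) -> ContextCounts:
    """Full ContextCounts for one catalog and motif: mutation counts over
    the motif's substitution class, context counts over the 41-nt windows
    around that class's mutations."""
    cls = _class_mask(catalog, motif)
    sub = catalog.loc[cls]
    m_base = int(cls.sum())
    m_in = int(mutations_in_motif_mask(genome, sub, motif).sum())
    ctxs = extract_contexts(genome, sub, window)
    c_in, c_base = _scan_contexts([s for s, _ in ctxs], motif)
    return ContextCounts(m_in, m_base, c_in, c_base)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def enrichment(counts: ContextCounts) -> float:
    """Fold enrichment; NaN when undefined (no class mutations or no motif
    occurrences in context), 0 when no in-motif mutations."""
    if counts.mutations_base == 0 or counts.context_in_motif == 0:
        return float("nan")
    return (counts.mutations_in_motif * counts.context_base) / (
        counts.mutations_base * counts.context_in_motif)


def fisher_one_sided(counts: ContextCounts) -> float:
    """One-sided (greater) Fisher's exact test: mutations in/out of motif
    against context bases in/out of motif."""
    m_in = counts.mutations_in_motif
    m_out = counts.mutations_base - m_in
    c_in = counts.context_in_motif
    c_out = counts.context_base - c_in
    if min(m_out, c_out) < 0:
        raise ValueError("derived table cells must be non-negative")
    if counts.mutations_base == 0:
        return 1.0
    return float(stats.fisher_exact(
        [[m_in, m_out], [c_in, c_out]], alternative="greater")[1])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (NaN passed through)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must be in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def min_mutation_load(counts: ContextCounts, enrichment_value: float,
                      q: float, alpha: float = 0.05) -> float:
    """Minimum mutation load: mutations(motif) * (E-1)/E when E > 1 and
    q < alpha, else 0 (zero rule; undefined enrichment also gives 0)."""
    e = enrichment_value
    if not np.isfinite(e) or e <= 1 or not (q < alpha):
        return 0.0
    return counts.mutations_in_motif * (e - 1) / e


def count_cc_tt(catalog: pd.DataFrame) -> int:
    """Tandem CC→TT dinucleotide changes: adjacent-position pairs reading
    CC→TT on either strand (GG→AA on forward is CC→TT on the reverse).
    Each adjacent pair counts once."""
    if len(catalog) == 0:
        return 0
    df = catalog.sort_values(["contig", "pos"], kind="stable")
    contig = df["contig"].to_numpy()
    pos = df["pos"].to_numpy()
    ref = df["ref"].to_numpy()
    alt = df["alt"].to_numpy()
    adj = (contig[:-1] == contig[1:]) & (pos[1:] == pos[:-1] + 1)
    cc = (ref[:-1] == "C") & (alt[:-1] == "T") & (ref[1:] == "C") & (alt[1:] == "T")
    gg = (ref[:-1] == "G") & (alt[:-1] == "A") & (ref[1:] == "G") & (alt[1:] == "A")
    return int((adj & (cc | gg)).sum())


def uv_min_load_total(load_ycn: float, load_ntt: float,
                      cc_tt_pairs: int, snvs_per_pair: int = 2) -> float:
    """UV-attributable minimum load: yCn→yTn load + nTt→nCt load + the
    tandem CC→TT contribution. Each tandem pair is two SNVs in the catalog,
    so it contributes 2 by default, keeping load units = SNV count."""
    return float(load_ycn) + float(load_ntt) + snvs_per_pair * int(cc_tt_pairs)


def cc_tt_member_mask(catalog: pd.DataFrame) -> np.ndarray:
    """Mask of records belonging to an adjacent CC→TT (or GG→AA) pair."""
    out = np.zeros(len(catalog), dtype=bool)
    if len(catalog) == 0:
        return out
    order = catalog.sort_values(["contig", "pos"], kind="stable").index
    df = catalog.loc[order]
    contig = df["contig"].to_numpy()
    pos = df["pos"].to_numpy()
    ref = df["ref"].to_numpy()
    alt = df["alt"].to_numpy()
    adj = (contig[:-1] == contig[1:]) & (pos[1:] == pos[:-1] + 1)
    cc = (ref[:-1] == "C") & (alt[:-1] == "T") & (ref[1:] == "C") & (alt[1:] == "T")
    gg = (ref[:-1] == "G") & (alt[:-1] == "A") & (ref[1:] == "G") & (alt[1:] == "A")
    pair = adj & (cc | gg)
    flat = np.zeros(len(df), dtype=bool)
    flat[:-1] |= pair
    flat[1:] |= pair
    pos_in_catalog = {ix: i for i, ix in enumerate(catalog.index)}
    for ix, hit in zip(order, flat):
        if hit:
            out[pos_in_catalog[ix]] = True
    return out


def uv_signature_mask(genome: SyntheticGenome,
                      catalog: pd.DataFrame) -> np.ndarray:
    """Records conforming to any UV signature: yCn→yTn, nTt→nCt, or
    membership in a tandem CC→TT pair (union; each record counted once)."""
    mask = cc_tt_member_mask(catalog)
    for name in UV_MOTIF_NAMES:
        mask |= mutations_in_motif_mask(genome, catalog, TABLE_MOTIFS[name])
    return mask


# ---------------------------------------------------------------------------
# per-sample tables
# ---------------------------------------------------------------------------

def enrichment_table(
    genome: SyntheticGenome,
    catalogs: Mapping[str, pd.DataFrame],
    motifs: Mapping[str, SignatureMotif] = TABLE_MOTIFS,
    alpha: float = 0.05,
    bh_scope: str = "per-motif",
    window: int = 41,
) -> pd.DataFrame:
    """Enrichment, Fisher p, BH q and minimum load per (sample, motif).

    bh_scope: 'per-motif' corrects across samples within each motif family
    (default, matching the per-signature presentation); 'per-sample'
    corrects across motifs within each sample.
    """
    if bh_scope not in ("per-motif", "per-sample"):
        raise ValueError("bh_scope must be 'per-motif' or 'per-sample'")
    rows = []
    for sample, cat in catalogs.items():
        for mname, motif in motifs.items():
            counts = motif_counts(genome, cat, motif, window)
            e = enrichment(counts)
            p = fisher_one_sided(counts) if np.isfinite(e) else np.nan
            rows.append({
                "sample": sample, "motif": mname,
                "mutations_in_motif": counts.mutations_in_motif,
                "mutations_base": counts.mutations_base,
                "context_in_motif": counts.context_in_motif,
                "context_base": counts.context_base,
                "enrichment": e, "p": p,
            })
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    group_col = "motif" if bh_scope == "per-motif" else "sample"
    for _, idx in table.groupby(group_col).groups.items():
        table.loc[idx, "q"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    loads = []
    for _, r in table.iterrows():
        counts = ContextCounts(
            int(r["mutations_in_motif"]), int(r["mutations_base"]),
            int(r["context_in_motif"]), int(r["context_base"]))
        loads.append(min_mutation_load(counts, r["enrichment"], r["q"], alpha))
    table["min_load"] = loads
    return table


def partition_analysis(genome: SyntheticGenome, catalog: pd.DataFrame,
                       window: int = 41) -> pd.DataFrame:
    """Enrichment table for the purine/pyrimidine 5' partitions of the nCg
    and nTt motifs (rCg/yCg, rTt/yTt) plus the parents, for one catalog.
    The partition mutation counts reconcile: rXy + yXy = nXy."""
    names = ["nCg", "rCg", "yCg", "nTt", "rTt", "yTt"]
    return enrichment_table(
        genome, {"sample": catalog},
        {n: TABLE_MOTIFS[n] for n in names}, window=window,
        bh_scope="per-sample")
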