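"""Synthetic data generator with known ground truth.

Emulates the study design end to end on a small scale: a diploid-like
random reference, germline heterozygous variants, somatic mutations planted
by motif-conditional mutational processes (UV photoproduct signatures,
CpG deamination, uniform background), noisy per-caller call tables with a
matched blood table, 1-Mb-window covariate tracks carrying a planted
mutation-density gradient, and non-overlapping gene annotations with
strand, so that every downstream stage can be tested against truth.

Mutational processes
--------------------
UV_YC      yCn→yTn : C→T where the 5' neighbour (on the pyrimidine strand)
                     is a pyrimidine — cytosine-containing pyrimidine dimers.
UV_TT5     nTt→nCt : T→C at the 5' T of a TT dinucleotide.
UV_CCTT    CC→TT   : tandem dinucleotide change, emitted as two adjacent
                     SNV records sharing a pair id.
CPG_DEAM   nCg→nTg : deamination of methylated CpG cytosines.
BACKGROUND          : uniform over positions and substitutions.

Motif processes plant mutations with the motif read on the strand carrying
the pyrimidine (the 5' T for nTt); ref/alt are then recorded on the forward
strand, so a reverse-orientation UV_YC lesion appears as G→A. Within genes,
UV-process lesions fall on the transcribed (template) strand with
probability tcr_factor/(1+tcr_factor), emulating transcription-coupled
repair of the template strand.

All coordinates in emitted tables are 1-based (VCF dialect); sequence
indexing is 0-based internally. All randomness flows from one explicit seed
through numpy's SeedSequence spawning; there is no global state.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dna

PROCESSES = ("UV_YC", "UV_TT5", "UV_CCTT", "CPG_DEAM", "BACKGROUND")
UV_PROCESSES = frozenset({"UV_YC", "UV_TT5", "UV_CCTT"})

TRUTH_COLUMNS = [
    "contig", "pos", "ref", "alt", "process", "pair_id",
    "pyrimidine_strand", "zygosity", "cell_fraction",
]
CALL_COLUMNS = ["contig", "pos", "ref", "alt", "depth", "alt_reads", "vaf"]


class SyntheticGenome:
    """An in-memory haploid reference; diploidy enters only as the 2x
    factor in rate arithmetic."""

    def __init__(self, contigs: Sequence[tuple[str, str]]):
        names = [n for n, _ in contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        self._seqs: dict[str, str] = {}
        self._codes: dict[str, np.ndarray] = {}
        for name, seq in contigs:
            seq = seq.upper()
            if set(seq) - dna.BASES:
                raise ValueError(
                    f"contig {name!r} contains characters outside ACGT")
            self._seqs[name] = seq
            self._codes[name] = dna.encode(seq)

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def sequence(self, name: str) -> str:
        return self._seqs[name]

    def codes(self, name: str) -> np.ndarray:
        """uint8 code array for a contig (A=0,C=1,G=2,T=3). Do not mutate."""
        return self._codes[name]

    def base(self, name: str, pos0: int) -> str:
        return self._seqs[name][pos0]

    def context(self, name: str, pos0: int, flank: int = 20) -> tuple[str, int]:
        """Window of up to 2*flank+1 bases around pos0, truncated at contig
        ends. Returns (sequence, index of the centre within it)."""
        seq = self._seqs[name]
        if not 0 <= pos0 < len(seq):
            raise ValueError(f"position {pos0} outside contig {name!r}")
        lo = max(0, pos0 - flank)
        return seq[lo:pos0 + flank + 1], pos0 - lo

    def gc_fraction(self) -> float:
        gc = sum(
            int(((c == dna.C) | (c == dna.G)).sum()) for c in self._codes.values())
        return gc / self.total_length

    def reverse_complemented(self) -> "SyntheticGenome":
        return SyntheticGenome(
            [(n, dna.revcomp(s)) for n, s in self._seqs.items()])


@dataclass(frozen=True)
class ProcessMix:
    """Mixture of mutational processes used when planting somatic mutations.

    weights map process name -> non-negative weight summing to 1;
    tcr_factor in (0, 1] multiplies the acceptance probability of UV
    lesions on the transcribed strand of genes (1 = no strand preference).
    """

    weights: Mapping[str, float]
    n_mutations: int
    tcr_factor: float = 1.0

    def __post_init__(self):
        unknown = set(self.weights) - set(PROCESSES)
        if unknown:
            raise ValueError(f"unknown processes: {sorted(unknown)}")
        w = np.array([self.weights.get(p, 0.0) for p in PROCESSES], float)
        if (w < 0).any():
            raise ValueError("process weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"process weights must sum to 1, got {w.sum()}")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")
        if not 0 < self.tcr_factor <= 1:
            raise ValueError("tcr_factor must be in (0, 1]")
        object.__setattr__(self, "weights", dict(self.weights))

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights.get(p, 0.0) for p in PROCESSES], float)

    @classmethod
    def single(cls, process: str, n_mutations: int, tcr_factor: float = 1.0):
        return cls({process: 1.0}, n_mutations, tcr_factor)

    @classmethod
    def default(cls, n_mutations: int = 3000, tcr_factor: float = 0.5):
        """Forearm-like mixture: UV-dominated with a CpG clock and
        unattributed background."""
        return cls(
            {"UV_YC": 0.35, "UV_TT5": 0.15, "UV_CCTT": 0.05,
             "CPG_DEAM": 0.10, "BACKGROUND": 0.35},
            n_mutations, tcr_factor)


def generate_reference(length: int, gc_fraction: float = 0.41,
                       seed: int = 0, n_contigs: int = 1,
                       name_prefix: str = "chr") -> SyntheticGenome:
    """i.i.d. random genome with P(G)+P(C) = gc_fraction.

    The default GC of 0.41 matches the human genome average.
    """
    if length < 10_000:
        raise ValueError(f"genome length must be >= 10000, got {length}")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if n_contigs < 1 or length // n_contigs < 1:
        raise ValueError("invalid contig count")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    per = [length // n_contigs] * n_contigs
    per[-1] += length - sum(per)
    contigs = []
    for i, ln in enumerate(per, start=1):
        codes = rng.choice(4, size=ln, p=p).astype(np.uint8)
        contigs.append((f"{name_prefix}{i}", dna.decode(codes)))
    return SyntheticGenome(contigs)


def plant_germline(genome: SyntheticGenome, density: float = 0.001,
                   seed: int = 0) -> pd.DataFrame:
    """Heterozygous germline SNVs at fixed density (default 1/1000 bp).

    Values exist only to exercise the blood-subtraction and LOH filters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name in genome.names:
        codes = genome.codes(name)
        n = int(round(density * len(codes)))
        if n == 0:
            continue
        pos0 = rng.choice(len(codes), size=n, replace=False)
        pos0.sort()
        for p in pos0:
            ref_c = codes[p]
            alt_c = (ref_c + 1 + rng.integers(3)) % 4
            rows.append((name, int(p) + 1, dna.decode(np.array([ref_c], np.uint8)),
                         dna.decode(np.array([alt_c], np.uint8))))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# eligible-site enumeration per process
# ---------------------------------------------------------------------------

_DEC = "ACGT"


def _eligible_sites(codes: np.ndarray, process: str):
    """Return (pos0 array, ref codes, alt codes, pyr-strand '+' mask) of
    eligible sites for a motif process on one contig. For UV_CCTT, pos0 is
    the first position of the pair. BACKGROUND is handled separately."""
    x = codes
    A_, C_, G_, T_ = dna.A, dna.C, dna.G, dna.T
    prev = np.empty_like(x); prev[0] = dna.N; prev[1:] = x[:-1]
    nxt = np.empty_like(x); nxt[-1] = dna.N; nxt[:-1] = x[1:]
    if process == "UV_YC":
        fwd = (x == C_) & ((prev == C_) | (prev == T_))
        rev = (x == G_) & ((nxt == A_) | (nxt == G_))
        ref_alt = {True: (C_, T_), False: (G_, A_)}
    elif process == "UV_TT5":
        fwd = (x == T_) & (nxt == T_)
        rev = (x == A_) & (prev == A_)
        ref_alt = {True: (T_, C_), False: (A_, G_)}
    elif process == "CPG_DEAM":
        fwd = (x == C_) & (nxt == G_)
        rev = (x == G_) & (prev == C_)
        ref_alt = {True: (C_, T_), False: (G_, A_)}
    elif process == "UV_CCTT":
        fwd = (x == C_) & (nxt == C_)
        rev = (x == G_) & (nxt == G_)  # GG on forward = CC on reverse
        ref_alt = {True: (C_, T_), False: (G_, A_)}
    else:  # pragma: no cover
        raise ValueError(process)
    pos = np.flatnonzero(fwd | rev)
    is_fwd = fwd[pos]
    ref = np.where(is_fwd, ref_alt[True][0], ref_alt[False][0]).astype(np.uint8)
    alt = np.where(is_fwd, ref_alt[True][1], ref_alt[False][1]).astype(np.uint8)
    return pos, ref, alt, is_fwd


class _GeneIndex:
    """Per-contig sorted non-overlapping gene intervals for strand lookup."""

    def __init__(self, genes: pd.DataFrame | None):
        self._by_contig: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if genes is None or len(genes) == 0:
            return
        for contig, sub in genes.groupby("contig"):
            sub = sub.sort_values("start")
            self._by_contig[contig] = (
                sub["start"].to_numpy(), sub["end"].to_numpy(),
                sub["strand"].to_numpy())

    def strand_at(self, contig: str, pos0: np.ndarray) -> np.ndarray:
        """Gene strand per position: '+', '-', or '' for intergenic."""
        out = np.full(len(pos0), "", dtype=object)
        if contig not in self._by_contig:
            return out
        starts, ends, strands = self._by_contig[contig]
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        out[ok] = strands[idx[ok]]
        return out


def plant_somatic_mutations(
    genome: SyntheticGenome,
    mix: ProcessMix,
    genes: pd.DataFrame | None = None,
    seed: int = 0,
    density: pd.DataFrame | None = None,
    zygosity_weights: tuple[float, float, float] = (0.85, 0.05, 0.10),
    subclonal_fraction_range: tuple[float, float] = (0.04, 0.5),
) -> pd.DataFrame:
    """Plant process-labelled somatic mutations; returns the truth table.

    Columns: contig, pos (1-based), ref, alt, process, pair_id,
    pyrimidine_strand, zygosity, cell_fraction. A UV_CCTT event emits two
    adjacent records sharing pair_id, zygosity and cell fraction.

    `density`, if given, is the covariate-track frame from
    :func:`emit_covariate_tracks`; its latent per-window multiplier weights
    site selection for every process, planting the density gradient.
    """
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(mix.n_mutations, mix.weight_vector())
    gene_index = _GeneIndex(genes)
    window_size = None
    dens_mult: dict[str, np.ndarray] = {}
    if density is not None and len(density):
        window_size = int(density.attrs.get("window_size", 1_000_000))
        for contig, sub in density.groupby("contig"):
            dens_mult[contig] = sub.sort_values("start")[
                "latent_multiplier"].to_numpy()

    contig_names = genome.names
    contig_lengths = np.array([genome.lengths[n] for n in contig_names])
    used: set[tuple[int, int]] = set()
    zyg_labels = np.array(["het", "hom", "subclonal"])
    rows: list[tuple] = []
    pair_counter = 0

    def site_weight(ci: int, pos0: np.ndarray) -> np.ndarray:
        if window_size is None:
            return np.ones(len(pos0))
        mult = dens_mult.get(contig_names[ci])
        if mult is None:
            return np.ones(len(pos0))
        return mult[np.minimum(pos0 // window_size, len(mult) - 1)]

    def draw_zygosity():
        z = zyg_labels[rng.choice(3, p=np.asarray(zygosity_weights, float))]
        if z == "subclonal":
            cf = float(rng.uniform(*subclonal_fraction_range))
        else:
            cf = 1.0
        return str(z), cf

    for proc, n_needed in zip(PROCESSES, counts):
        if n_needed == 0:
            continue
        if proc == "BACKGROUND":
            # uniform over all genome positions
            pool_pos = [np.arange(contig_lengths[ci]) for ci in range(len(contig_names))]
            pool_ci = np.concatenate([
                np.full(len(p), ci) for ci, p in enumerate(pool_pos)])
            pool_pos = np.concatenate(pool_pos)
            pool_ref = np.concatenate([genome.codes(n) for n in contig_names])
            pool_alt = None
            pool_fwd = None
        else:
            parts = [(_eligible_sites(genome.codes(n), proc), ci)
                     for ci, n in enumerate(contig_names)]
            if all(len(p[0][0]) == 0 for p in parts):
                raise ValueError(
                    f"no eligible site in genome for weighted process {proc}")
            pool_ci = np.concatenate([
                np.full(len(p[0]), ci) for (p, ci) in parts])
            pool_pos = np.concatenate([p[0] for p, _ in parts])
            pool_ref = np.concatenate([p[1] for p, _ in parts])
            pool_alt = np.concatenate([p[2] for p, _ in parts])
            pool_fwd = np.concatenate([p[3] for p, _ in parts])

        if window_size is not None:
            w = np.empty(len(pool_pos))
            for ci in range(len(contig_names)):
                m = pool_ci == ci
                w[m] = site_weight(ci, pool_pos[m])
            p_norm = w / w.sum()
        else:
            p_norm = None

        accepted = 0
        attempts = 0
        max_attempts = 200 * int(n_needed) + 10_000
        while accepted < n_needed:
            batch = min(max(4 * (n_needed - accepted), 64), len(pool_pos))
            idx = rng.choice(len(pool_pos), size=batch, p=p_norm)
            g_strand = {}
            for ci in np.unique(pool_ci[idx]):
                sel = idx[pool_ci[idx] == ci]
                g_strand.update(zip(sel.tolist(), gene_index.strand_at(
                    contig_names[ci], pool_pos[sel])))
            for j in idx:
                attempts += 1
                if accepted >= n_needed:
                    break
                ci = int(pool_ci[j]); p0 = int(pool_pos[j])
                key = (ci, p0)
                if proc == "UV_CCTT":
                    if key in used or (ci, p0 + 1) in used:
                        continue
                else:
                    if key in used:
                        continue
                if proc == "BACKGROUND":
                    ref_c = int(pool_ref[j])
                    alt_c = (ref_c + 1 + int(rng.integers(3))) % 4
                    pyr_fwd = ref_c in (dna.C, dna.T)
                else:
                    ref_c = int(pool_ref[j]); alt_c = int(pool_alt[j])
                    pyr_fwd = bool(pool_fwd[j])
                    if proc in UV_PROCESSES and mix.tcr_factor < 1:
                        gs = g_strand.get(int(j), "")
                        if gs:
                            lesion_strand = "+" if pyr_fwd else "-"
                            template = "-" if gs == "+" else "+"
                            if lesion_strand == template and \
                                    rng.random() > mix.tcr_factor:
                                continue
                zyg, cf = draw_zygosity()
                strand = "+" if pyr_fwd else "-"
                if proc == "UV_CCTT":
                    pair_counter += 1
                    pid = f"cc_tt_{pair_counter}"
                    used.add(key); used.add((ci, p0 + 1))
                    for off in (0, 1):
                        rows.append((contig_names[ci], p0 + off + 1,
                                     _DEC[ref_c], _DEC[alt_c], proc, pid,
                                     strand, zyg, cf))
                else:
                    used.add(key)
                    rows.append((contig_names[ci], p0 + 1, _DEC[ref_c],
                                 _DEC[alt_c], proc, "", strand, zyg, cf))
                accepted += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not place {n_needed} {proc} mutations "
                    f"(placed {accepted}); genome too small or too constrained")
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return truth.sort_values(["contig", "pos"], kind="stable",
                             ignore_index=True)


# ---------------------------------------------------------------------------
# caller tables
# ---------------------------------------------------------------------------

_ZYG_P = {"het": 0.5, "hom": 0.97}


def emit_caller_tables(
    truth: pd.DataFrame,
    germline: pd.DataFrame | None = None,
    genome: SyntheticGenome | None = None,
    depth_mean: float = 50,
    fp_rate_per_caller: float = 0.0,
    fn_rate_per_caller: float = 0.0,
    seed: int = 0,
    callers: Sequence[str] = ("A", "B", "C"),
    exact_vaf: bool = False,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Emit noisy per-caller call tables and the matched blood table.

    One sequencing outcome (depth ~ Poisson(depth_mean); alt reads binomial
    with p = 0.5 het / 0.97 hom / cell_fraction/2 subclonal) is shared by
    all callers; each caller then independently drops records at
    fn_rate_per_caller and adds unlabeled false positives at
    fp_rate_per_caller (expected count = rate x true records). Germline
    variants appear in the clone tables (they are present in the clone's
    DNA) and are the only records in the blood table.

    exact_vaf=True removes read-sampling noise as well: depth is fixed at
    depth_mean and alt reads at round(depth x p), so every clonal het/hom
    record lands inside its allele-frequency window (the fully-noise-off
    regime in which the filter chain recovers the planted truth exactly).
    """
    if depth_mean < 10:
        raise ValueError("depth_mean must be >= 10")
    if fp_rate_per_caller > 0 and genome is None:
        raise ValueError("genome required to generate false-positive records")
    rng = np.random.default_rng(seed)

    recs = truth[["contig", "pos", "ref", "alt"]].copy()
    p_alt = np.where(
        truth["zygosity"].eq("subclonal"),
        truth["cell_fraction"].to_numpy() / 2.0,
        truth["zygosity"].map(_ZYG_P).to_numpy(dtype=float))
    if germline is not None and len(germline):
        g = germline[["contig", "pos", "ref", "alt"]].copy()
        # a germline variant falling on a planted somatic position would
        # create a duplicate call key; the somatic record wins
        somatic_pos = set(zip(recs["contig"], recs["pos"]))
        g = g.loc[[key not in somatic_pos
                   for key in zip(g["contig"], g["pos"])]]
        germline = g
        recs = pd.concat([recs, g], ignore_index=True)
        p_alt = np.concatenate([p_alt, np.full(len(g), 0.5)])
    n = len(recs)
    if exact_vaf:
        depth = np.full(n, int(round(depth_mean)))
        alt_reads = np.round(depth * p_alt).astype(int)
    else:
        depth = np.maximum(rng.poisson(depth_mean, size=n), 1)
        alt_reads = rng.binomial(depth, p_alt)
    base = recs.assign(depth=depth, alt_reads=alt_reads,
                       vaf=alt_reads / depth)

    tables: dict[str, pd.DataFrame] = {}
    occupied = set(zip(recs["contig"], recs["pos"]))
    for caller in callers:
        keep = rng.random(n) >= fn_rate_per_caller
        tab = base.loc[keep].copy()
        if fp_rate_per_caller > 0:
            n_fp = rng.poisson(fp_rate_per_caller * max(len(truth), 1))
            fp_rows = []
            tries = 0
            while len(fp_rows) < n_fp and tries < 100 * n_fp + 100:
                tries += 1
                contig = genome.names[rng.integers(len(genome.names))]
                p0 = int(rng.integers(genome.lengths[contig]))
                if (contig, p0 + 1) in occupied:
                    continue
                ref = genome.base(contig, p0)
                alt = _DEC[(dna.CODE[ref] + 1 + int(rng.integers(3))) % 4]
                d = max(int(rng.poisson(depth_mean)), 1)
                a = int(rng.binomial(d, rng.uniform(0.1, 0.6)))
                fp_rows.append((contig, p0 + 1, ref, alt, d, a, a / d))
            if fp_rows:
                tab = pd.concat(
                    [tab, pd.DataFrame(fp_rows, columns=CALL_COLUMNS)],
                    ignore_index=True)
        tables[caller] = tab.sort_values(
            ["contig", "pos"], kind="stable", ignore_index=True)

    if germline is not None and len(germline):
        gm = germline[["contig", "pos", "ref", "alt"]].copy()
        gd = np.maximum(rng.poisson(depth_mean, size=len(gm)), 1)
        ga = rng.binomial(gd, 0.5)
        blood = gm.assign(depth=gd, alt_reads=ga, vaf=ga / gd)
    else:
        blood = pd.DataFrame(columns=CALL_COLUMNS)
    return tables, blood


# ---------------------------------------------------------------------------
# covariate tracks and genes
# ---------------------------------------------------------------------------

def emit_covariate_tracks(genome: SyntheticGenome, gradient_strength: float,
                          seed: int = 0,
                          window_size: int = 1_000_000) -> pd.DataFrame:
    """Per-window covariate tracks with a planted density gradient.

    The latent mutation-density multiplier ramps exp(gradient * u) with u
    linear in window order from -1 to 1 (constant when gradient = 0). The
    replication-timing proxy increases with the multiplier plus gaussian
    noise (read it as a "lateness" score: larger = later replication =
    denser mutations); the DNase peak count is Poisson with intensity
    inversely proportional to the multiplier (open chromatin = fewer
    mutations). attrs['window_size'] records the tiling width.
    """
    rows = []
    for name in genome.names:
        ln = genome.lengths[name]
        n_win = int(np.ceil(ln / window_size))
        for i in range(n_win):
            rows.append((name, i * window_size, min((i + 1) * window_size, ln)))
    if len(rows) < 2:
        raise ValueError("genome must span at least 2 windows")
    df = pd.DataFrame(rows, columns=["contig", "start", "end"])
    rng = np.random.default_rng(seed)
    k = len(df)
    u = np.linspace(-1.0, 1.0, k)
    mult = np.exp(gradient_strength * u)
    df["latent_multiplier"] = mult
    df["rep_timing"] = 50.0 + 20.0 * gradient_strength * u + rng.normal(0, 1.0, k)
    df["dnase_peaks"] = rng.poisson(30.0 / mult)
    df.attrs["window_size"] = int(window_size)
    return df


def emit_genes(genome: SyntheticGenome, n_genes: int, seed: int = 0,
               length_range: tuple[int, int] = (5_000, 20_000)) -> pd.DataFrame:
    """Non-overlapping gene intervals with Bernoulli(0.5) strands.

    Columns: contig, start, end (0-based half-open), strand.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    cols = ["contig", "start", "end", "strand"]
    if n_genes == 0:
        return pd.DataFrame(columns=cols)
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in genome.names}
    rows = []
    tries = 0
    max_tries = 1000 * n_genes + 1000
    lengths = genome.lengths
    while len(rows) < n_genes:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_genes} non-overlapping genes "
                f"(placed {len(rows)})")
        contig = genome.names[rng.integers(len(genome.names))]
        glen = int(rng.integers(length_range[0], length_range[1] + 1))
        if glen >= lengths[contig]:
            continue
        start = int(rng.integers(lengths[contig] - glen))
        end = start + glen
        if any(start < e and s < end for s, e in placed[contig]):
            continue
        placed[contig].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((contig, start, end, strand))
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["contig", "start"], ignore_index=True)
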