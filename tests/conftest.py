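"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorised code paths: motif
occurrences are counted by a quadratic character scan over both strands,
and exact tail probabilities are accumulated term by term from factorials.
"""
import math

import numpy as np
import pytest

from somamosaic import synthetic as syn

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
SETS = {"n": set("ACGT"), "y": set("CT"), "r": set("AG"),
        "a": {"A"}, "c": {"C"}, "g": {"G"}, "t": {"T"}}


def revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq))


def brute_motif_scan(seq, five, centre, three):
    """Count motif matches and centre-base occurrences on both strands of
    one window, restricted to positions with both neighbours visible."""
    n_in = n_base = 0
    for strand_seq in (seq, revcomp(seq)):
        for i in range(1, len(strand_seq) - 1):
            if strand_seq[i] == centre:
                n_base += 1
                if strand_seq[i - 1] in five and strand_seq[i + 1] in three:
                    n_in += 1
    return n_in, n_base


def brute_hypergeom_tail_p(m_in, m_out, c_in, c_out):
    """One-sided Fisher p: P(X >= m_in) for X hypergeometric with
    (c_in + m_in) in-motif successes among all entries, summed term by
    term from binomial coefficients."""
    K = m_in + c_in          # in-motif column total
    N = m_in + m_out + c_in + c_out
    n = m_in + m_out         # mutation row total
    p = 0.0
    for k in range(m_in, min(K, n) + 1):
        p += (math.comb(K, k) * math.comb(N - K, n - k)) / math.comb(N, n)
    return p


def brute_binom_tail_p(k, n, p=0.5):
    """P(X >= k) for X ~ Binomial(n, p), summed term by term."""
    return sum(math.comb(n, i) * p**i * (1 - p)**(n - i)
               for i in range(k, n + 1))


def brute_bh(pvals):
    """Benjamini-Hochberg step-up by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


@pytest.fixture(scope="session")
def genome():
    """100-kb random reference at human-like GC."""
    return syn.generate_reference(100_000, 0.41, seed=7)


@pytest.fixture(scope="session")
def genes(genome):
    return syn.emit_genes(genome, 5, seed=1)


@pytest.fixture(scope="session")
def default_truth(genome, genes):
    mix = syn.ProcessMix.default(2000)
    return syn.plant_somatic_mutations(genome, mix, genes, seed=3)
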