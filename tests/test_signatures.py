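"""Motif algebra, enrichment/Fisher/BH/load statistics, tandem counting.

Expected values come from independent brute-force oracles in conftest:
quadratic two-strand motif scans, term-by-term hypergeometric tails, and
a hand-rolled BH step-up.
"""
import numpy as np
import pandas as pd
import pytest

from conftest import (brute_bh, brute_hypergeom_tail_p, brute_motif_scan,
                      revcomp)
from somamosaic import synthetic as syn
from somamosaic.signatures import (
    TABLE_MOTIFS, ContextCounts, SignatureMotif, bh_adjust, count_cc_tt,
    count_motif, enrichment, enrichment_table, extract_contexts,
    fisher_one_sided, min_mutation_load, motif_counts, partition_analysis,
    uv_min_load_total, uv_signature_mask)


class TestMotifParsing:
    def test_parse_and_roundtrip(self):
        m = SignatureMotif.parse("nTt→nCt")
        assert m.base == "T" and m.target == "C"
        assert m.five_prime == frozenset("ACGT")
        assert m.three_prime == frozenset("T")
        assert str(m) == "nTt>nCt"

    def test_invalid_motifs_rejected(self):
        with pytest.raises(ValueError):
            SignatureMotif.parse("nT")
        with pytest.raises(ValueError):
            SignatureMotif(frozenset("A"), "T", frozenset("T"), "T")

    def test_table_set_complete(self):
        assert set(TABLE_MOTIFS) == {"nCg", "rCg", "yCg", "yCn",
                                     "nTt", "rTt", "yTt"}


class TestContextExtraction:
    def test_mid_contig_window(self, genome):
        cat = pd.DataFrame({"contig": ["chr1"], "pos": [500],
                            "ref": [genome.base("chr1", 499)],
                            "alt": ["A"]})
        [(seq, centre)] = extract_contexts(genome, cat)
        assert len(seq) == 41 and centre == 20
        assert seq == genome.sequence("chr1")[479:520]

    def test_truncated_at_contig_start(self, genome):
        cat = pd.DataFrame({"contig": ["chr1"], "pos": [5],
                            "ref": [genome.base("chr1", 4)], "alt": ["A"]})
        [(seq, centre)] = extract_contexts(genome, cat)
        assert centre == 4 and len(seq) == 25

    def test_ref_mismatch_raises(self, genome):
        wrong = "A" if genome.base("chr1", 499) != "A" else "C"
        cat = pd.DataFrame({"contig": ["chr1"], "pos": [500],
                            "ref": [wrong], "alt": ["G"]})
        with pytest.raises(ValueError, match="does not match"):
            extract_contexts(genome, cat)

    def test_off_contig_raises(self, genome):
        cat = pd.DataFrame({"contig": ["chr1"], "pos": [10**7],
                            "ref": ["A"], "alt": ["C"]})
        with pytest.raises(ValueError, match="outside"):
            extract_contexts(genome, cat)


class TestMotifCounting:
    @pytest.mark.parametrize("motif_name", list(TABLE_MOTIFS))
    def test_matches_brute_force_on_random_windows(self, motif_name):
        """Vectorised counts equal a quadratic two-strand scan on 100
        random 200-bp windows."""
        rng = np.random.default_rng(2024)
        motif = TABLE_MOTIFS[motif_name]
        five = set(motif.five_prime)
        three = set(motif.three_prime)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            c = count_motif([seq], motif)
            b_in, b_base = brute_motif_scan(seq, five, motif.base, three)
            assert (c.context_in_motif, c.context_base) == (b_in, b_base)

    def test_small_window_by_hand(self):
        # 'ttTtt': forward nTt matches at interior T positions 1,2,3;
        # reverse strand is 'aaAaa' with no T at all
        c = count_motif(["TTTTT"], TABLE_MOTIFS["nTt"])
        assert c.context_in_motif == 3
        assert c.context_base == 3  # interior positions only, fwd strand

    def test_identity_motif_equals_base_count(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        m_all = SignatureMotif(frozenset("ACGT"), "C", frozenset("ACGT"), "T")
        c = count_motif([seq], m_all)
        assert c.context_in_motif == c.context_base

    def test_all_n_context_counts_nothing(self):
        c = count_motif(["N" * 41], TABLE_MOTIFS["nTt"])
        assert c.context_in_motif == 0 and c.context_base == 0

    def test_overlapping_occurrences_all_counted(self):
        # TTT: nTt at positions 0-2 and 1-3 overlap; both count
        c = count_motif(["ATTTTA"], TABLE_MOTIFS["nTt"])
        assert c.context_in_motif == 3


class TestEnrichmentStatistics:
    def test_enrichment_formula(self):
        c = ContextCounts(8, 10, 400, 1000)
        assert enrichment(c) == pytest.approx(2.0)

    def test_enrichment_identity(self):
        c = ContextCounts(10, 10, 400, 400)
        assert enrichment(c) == pytest.approx(1.0)

    def test_enrichment_undefined_flagged(self):
        assert np.isnan(enrichment(ContextCounts(0, 0, 10, 100)))
        assert np.isnan(enrichment(ContextCounts(0, 5, 0, 100)))

    def test_enrichment_zero_when_no_in_motif_mutations(self):
        assert enrichment(ContextCounts(0, 5, 10, 100)) == 0.0

    def test_fisher_matches_brute_hypergeometric(self):
        c = ContextCounts(8, 10, 400, 1000)
        expected = brute_hypergeom_tail_p(8, 2, 400, 600)
        assert fisher_one_sided(c) == pytest.approx(expected, rel=1e-12)

    def test_fisher_proportional_split_not_significant(self):
        # mutations split exactly as the context splits: no excess
        c = ContextCounts(40, 100, 400, 1000)
        assert fisher_one_sided(c) >= 0.5

    def test_fisher_no_mutations(self):
        assert fisher_one_sided(ContextCounts(0, 0, 400, 1000)) == 1.0

    def test_bh_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_bh_matches_hand_rolled_on_random_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=20)
        assert np.allclose(bh_adjust(p), brute_bh(list(p)))

    def test_bh_q_at_least_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestMinLoad:
    def test_load_formula(self):
        c = ContextCounts(8, 10, 400, 1000)
        assert min_mutation_load(c, 2.0, 0.001) == pytest.approx(4.0)

    @pytest.mark.parametrize("e,q,expect_zero", [
        (0.8, 0.001, True),   # not enriched
        (1.5, 0.2, True),     # not significant
        (1.0, 0.001, True),   # boundary: E must exceed 1
        (float("nan"), 0.001, True),
        (1.5, 0.01, False),
    ])
    def test_zero_rule(self, e, q, expect_zero):
        c = ContextCounts(30, 60, 100, 1000)
        load = min_mutation_load(c, e, q)
        if expect_zero:
            assert load == 0.0
        else:
            assert load == pytest.approx(30 * (1.5 - 1) / 1.5)

    def test_zero_rule_exhaustive_grid(self):
        """Zero rule over a grid of counts, enrichments and q-values."""
        for m_in in (0, 1, 7, 30):
            for e in (0.0, 0.5, 1.0, 1.2, 3.0):
                for q in (0.001, 0.049, 0.05, 0.51):
                    c = ContextCounts(m_in, m_in + 10, 50, 500)
                    load = min_mutation_load(c, e, q)
                    if e > 1 and q < 0.05:
                        assert load == pytest.approx(m_in * (e - 1) / e)
                    else:
                        assert load == 0.0
                    assert 0 <= load <= m_in


class TestTandemCounting:
    def _cat(self, rows):
        return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])

    def test_adjacent_cc_tt(self):
        cat = self._cat([("c", 10, "C", "T"), ("c", 11, "C", "T")])
        assert count_cc_tt(cat) == 1

    def test_adjacent_gg_aa_is_reverse_strand_cc_tt(self):
        cat = self._cat([("c", 10, "G", "A"), ("c", 11, "G", "A")])
        assert count_cc_tt(cat) == 1

    def test_isolated_and_distant_calls(self):
        cat = self._cat([("c", 10, "C", "T"), ("c", 13, "C", "T")])
        assert count_cc_tt(cat) == 0

    def test_mixed_pair_not_counted(self):
        cat = self._cat([("c", 10, "C", "T"), ("c", 11, "G", "A")])
        assert count_cc_tt(cat) == 0

    def test_different_contigs_not_adjacent(self):
        cat = self._cat([("a", 10, "C", "T"), ("b", 11, "C", "T")])
        assert count_cc_tt(cat) == 0

    def test_planted_pairs_recovered(self, genome):
        truth = syn.plant_somatic_mutations(
            genome, syn.ProcessMix.single("UV_CCTT", 25), seed=6)
        assert count_cc_tt(truth) == 25

    def test_uv_total_arithmetic(self):
        assert uv_min_load_total(100, 50, 5) == 160
        assert uv_min_load_total(0, 0, 0) == 0
        assert uv_min_load_total(0, 0, 3) == 6


class TestPartition:
    def test_counts_reconcile(self, genome, default_truth):
        table = partition_analysis(genome, default_truth).set_index("motif")
        for parent, parts in (("nCg", ("rCg", "yCg")),
                              ("nTt", ("rTt", "yTt"))):
            assert (table.loc[parts[0], "mutations_in_motif"]
                    + table.loc[parts[1], "mutations_in_motif"]
                    == table.loc[parent, "mutations_in_motif"])

    def test_rtt_only_catalog_enriches_rtt_over_ytt(self, genome):
        # plant nTt mutations, then keep only those with a purine 5'
        truth = syn.plant_somatic_mutations(
            genome, syn.ProcessMix.single("UV_TT5", 1500), seed=8)
        from somamosaic.signatures import mutations_in_motif_mask
        rtt = mutations_in_motif_mask(genome, truth, TABLE_MOTIFS["rTt"])
        cat = truth.loc[rtt]
        table = partition_analysis(genome, cat).set_index("motif")
        assert table.loc["rTt", "enrichment"] > table.loc["yTt", "enrichment"]

    def test_empty_catalog_all_zero(self, genome):
        empty = pd.DataFrame(columns=["contig", "pos", "ref", "alt"])
        table = partition_analysis(genome, empty)
        assert (table["mutations_base"] == 0).all()
        assert (table["min_load"] == 0).all()


class TestStrandSymmetry:
    def test_everything_invariant_under_reverse_complement(self, genome):
        """Reverse-complementing the genome and flipping every call leaves
        enrichment, p and load unchanged."""
        truth = syn.plant_somatic_mutations(
            genome, syn.ProcessMix.default(800), seed=10)
        flipped_genome = genome.reverse_complemented()
        L = genome.lengths
        flipped = truth.copy()
        flipped["pos"] = flipped.apply(
            lambda r: L[r["contig"]] - r["pos"] + 1, axis=1)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        flipped["ref"] = flipped["ref"].map(comp)
        flipped["alt"] = flipped["alt"].map(comp)
        a = enrichment_table(genome, {"s": truth})
        b = enrichment_table(flipped_genome, {"s": flipped})
        for col in ("mutations_in_motif", "mutations_base",
                    "context_in_motif", "context_base"):
            assert (a[col] == b[col]).all(), col
        assert np.allclose(a["enrichment"], b["enrichment"], equal_nan=True)
        assert np.allclose(a["p"], b["p"], equal_nan=True)
        assert np.allclose(a["min_load"], b["min_load"])


class TestCalibrationAndRecovery:
    def test_background_enrichment_near_one(self, genome):
        """A context-blind catalog shows no preference for any motif,
        within sampling error."""
        truth = syn.plant_somatic_mutations(
            genome, syn.ProcessMix.single("BACKGROUND", 5000), seed=14)
        table = enrichment_table(genome, {"s": truth})
        for _, r in table.iterrows():
            # binomial sampling error of E around 1
            se = np.sqrt(1.0 / max(r["mutations_in_motif"], 1))
            assert abs(r["enrichment"] - 1) < 4 * se + 0.02, r["motif"]

    def test_min_load_recovers_planted_excess(self, genome):
        """Planted yCn load: the estimator returns the in-motif excess
        over the context-expected null count — at most the planted count,
        and close to the analytic expectation m_in - m_base * c_ratio."""
        k = 2000
        mix = syn.ProcessMix({"UV_YC": 0.4, "BACKGROUND": 0.6}, 5000)
        truth = syn.plant_somatic_mutations(genome, mix, seed=15)
        k_planted = (truth["process"] == "UV_YC").sum()
        table = enrichment_table(genome, {"s": truth}).set_index("motif")
        r = table.loc["yCn"]
        load = r["min_load"]
        assert 0 < load <= 1.05 * k_planted
        analytic = r["mutations_in_motif"] - r["mutations_base"] * (
            r["context_in_motif"] / r["context_base"])
        assert load == pytest.approx(analytic, rel=0.05)

    def test_uv_mask_counts_each_record_once(self, genome, default_truth):
        mask = uv_signature_mask(genome, default_truth)
        # all planted UV records conform; the mask is a superset
        uv_planted = default_truth["process"].isin(
            ["UV_YC", "UV_TT5", "UV_CCTT"])
        assert (mask | ~uv_planted).all()
        assert mask.dtype == bool and len(mask) == len(default_truth)
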