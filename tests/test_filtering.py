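"""Consensus filtering, zygosity windows, LOH, shared SNVs, histograms."""
import itertools

import numpy as np
import pandas as pd
import pytest

from somamosaic import filtering as flt
from somamosaic import synthetic as syn


def _table(rows):
    return pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "depth", "alt_reads",
                       "vaf"])


ROW = ("chr1", 100, "C", "T", 50, 25, 0.5)


class TestIntersectCallers:
    def test_identical_tables_pass_through(self):
        t = _table([ROW, ("chr1", 200, "G", "A", 40, 20, 0.5)])
        out = flt.intersect_callers({"A": t, "B": t.copy(), "C": t.copy()})
        assert len(out) == 2

    def test_record_missing_from_one_caller_excluded(self):
        t = _table([ROW, ("chr1", 200, "G", "A", 40, 20, 0.5)])
        t_short = _table([ROW])
        out = flt.intersect_callers({"A": t, "B": t.copy(), "C": t_short})
        assert len(out) == 1 and out.loc[0, "pos"] == 100

    def test_duplicate_key_rejected(self):
        t = _table([ROW, ROW])
        with pytest.raises(ValueError, match="duplicate key"):
            flt.intersect_callers({"A": t, "B": t.copy()})

    def test_depth_taken_from_primary(self):
        a = _table([("chr1", 100, "C", "T", 50, 25, 0.5)])
        b = _table([("chr1", 100, "C", "T", 99, 99, 1.0)])
        out = flt.intersect_callers({"A": a, "B": b}, primary="B")
        assert out.loc[0, "depth"] == 99

    def test_triple_intersection_retention(self, genome, default_truth):
        """fn = 0.1 per caller gives ~0.9^3 consensus retention."""
        fracs = []
        for seed in range(10):
            tables, _ = syn.emit_caller_tables(
                default_truth, None, genome, 50, 0.0, 0.1, seed=seed)
            out = flt.intersect_callers(tables)
            fracs.append(len(out) / len(default_truth))
        assert abs(np.mean(fracs) - 0.9**3) < 0.01


class TestSiteFilters:
    def test_depth_threshold(self):
        t = _table([("chr1", 100, "C", "T", 9, 5, 0.55)])
        assert len(flt.apply_site_filters(t)) == 0

    def test_min_counts_retained(self):
        # the thresholds exactly at their boundaries: 10x depth, 3 alt reads
        t = _table([("chr1", 100, "C", "T", 10, 3, 0.3)])
        assert len(flt.apply_site_filters(t)) == 1

    def test_blood_subtraction(self):
        t = _table([ROW])
        blood = _table([ROW])
        assert len(flt.apply_site_filters(t, blood_calls=blood)) == 0

    def test_blacklist_overlap(self):
        t = _table([ROW])
        bl = pd.DataFrame({"contig": ["chr1"], "start": [90], "end": [105]})
        assert len(flt.apply_site_filters(t, blacklist_snp=bl)) == 0
        miss = pd.DataFrame({"contig": ["chr1"], "start": [200],
                             "end": [300]})
        assert len(flt.apply_site_filters(t, blacklist_snp=miss)) == 1

    def test_malformed_interval_rejected(self):
        t = _table([ROW])
        bad = pd.DataFrame({"contig": ["chr1"], "start": [105], "end": [90]})
        with pytest.raises(ValueError, match="malformed"):
            flt.apply_site_filters(t, blacklist_snp=bad)

    def test_filters_commute_and_shrink(self):
        """Filter stages only remove records and yield the same final set
        in any order."""
        rng = np.random.default_rng(0)
        n = 300
        rows = []
        for p, d, a in zip(rng.choice(10_000, n, replace=False),
                           rng.integers(5, 80, n), rng.integers(0, 40, n)):
            a = min(int(a), int(d))
            rows.append(("chr1", int(p), "C", "T", int(d), a, a / d))
        calls = _table(rows)
        blood = calls.sample(30, random_state=1)
        bl = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [2000]})

        def stage_depth(c):
            return c.loc[(c["depth"] >= 10) & (c["alt_reads"] >= 3)]

        def stage_blood(c):
            return flt.apply_site_filters(c, blood_calls=blood,
                                          min_depth=0, min_alt=0)

        def stage_blacklist(c):
            return flt.apply_site_filters(c, blacklist_snp=bl,
                                          min_depth=0, min_alt=0)

        stages = [stage_depth, stage_blood, stage_blacklist]
        results = []
        for order in itertools.permutations(stages):
            c = calls
            for f in order:
                nxt = f(c)
                assert len(nxt) <= len(c)
                c = nxt
            results.append(set(map(tuple, c[flt.KEY].values)))
        assert all(r == results[0] for r in results)


class TestZygosity:
    @pytest.mark.parametrize("vaf,label", [
        (0.50, "het"), (0.45, "het"), (0.55, "het"),
        (0.95, "hom"), (0.901, "hom")])
    def test_labels(self, vaf, label):
        t = _table([("chr1", 100, "C", "T", 100, int(vaf * 100), vaf)])
        out, frac = flt.classify_zygosity(t)
        assert out.loc[0, "zygosity"] == label and frac == 1.0

    @pytest.mark.parametrize("vaf", [0.70, 0.44, 0.56, 0.90, 0.30, 0.0])
    def test_discarded(self, vaf):
        t = _table([("chr1", 100, "C", "T", 100, int(vaf * 100), vaf)])
        out, frac = flt.classify_zygosity(t)
        assert len(out) == 0 and frac == 0.0

    def test_discarded_calls_all_outside_windows(self, genome, default_truth):
        tables, _ = syn.emit_caller_tables(
            default_truth, None, genome, 50, 0.0, 0.0, seed=9)
        calls = tables["A"]
        out, _ = flt.classify_zygosity(calls)
        kept = set(map(tuple, out[flt.KEY].values))
        dropped = calls.loc[[tuple(r) not in kept
                             for r in calls[flt.KEY].values]]
        v = dropped["vaf"]
        assert ((v < 0.45) | ((v > 0.55) & (v <= 0.90))).all()


class TestLoh:
    def _pair(self, blood_vaf, clone_vaf):
        clone = _table([("chr1", 100, "C", "T", 100,
                         int(clone_vaf * 100), clone_vaf)])
        blood = _table([("chr1", 100, "C", "T", 100,
                         int(blood_vaf * 100), blood_vaf)])
        return clone, blood

    def test_loh_called(self):
        clone, blood = self._pair(0.50, 0.95)
        assert len(flt.call_loh(clone, blood)) == 1

    def test_still_het_in_clone(self):
        clone, blood = self._pair(0.50, 0.52)
        assert len(flt.call_loh(clone, blood)) == 0

    def test_germline_hom_not_loh(self):
        clone, blood = self._pair(0.95, 0.95)
        assert len(flt.call_loh(clone, blood)) == 0


class TestSharedSnvs:
    def _cat(self, keys, vaf=0.5):
        return _table([(c, p, r, a, 50, int(vaf * 50), vaf)
                       for c, p, r, a in keys])

    def test_shared_record_found(self):
        k = ("chr1", 100, "C", "T")
        out = flt.find_shared_snvs({
            "s1": self._cat([k, ("chr1", 200, "G", "A")]),
            "s2": self._cat([k])})
        assert len(out) == 1 and out.loc[0, "samples"] == ("s1", "s2")

    def test_disjoint_catalogs_empty(self):
        out = flt.find_shared_snvs({
            "s1": self._cat([("chr1", 100, "C", "T")]),
            "s2": self._cat([("chr1", 200, "G", "A")])})
        assert len(out) == 0

    def test_three_catalogs_exhaustive(self):
        """Toy exhaustive check: every pair/triple sharing pattern is
        reported with exactly the sharing samples' ids."""
        keys = {
            "k12": ("chr1", 10, "C", "T"), "k13": ("chr1", 20, "G", "A"),
            "k23": ("chr1", 30, "A", "G"), "k123": ("chr1", 40, "T", "C"),
            "k1": ("chr1", 50, "C", "A")}
        cats = {
            "s1": self._cat([keys["k12"], keys["k13"], keys["k123"],
                             keys["k1"]]),
            "s2": self._cat([keys["k12"], keys["k23"], keys["k123"]]),
            "s3": self._cat([keys["k13"], keys["k23"], keys["k123"]])}
        out = flt.find_shared_snvs(cats)
        got = {tuple(r[:4]): r[4] for r in out.itertuples(index=False)}
        assert got[keys["k12"]] == ("s1", "s2")
        assert got[keys["k13"]] == ("s1", "s3")
        assert got[keys["k23"]] == ("s2", "s3")
        assert got[keys["k123"]] == ("s1", "s2", "s3")
        assert keys["k1"] not in got

    def test_non_qualifying_vaf_excluded(self):
        k = ("chr1", 100, "C", "T")
        out = flt.find_shared_snvs({
            "s1": self._cat([k], vaf=0.2), "s2": self._cat([k], vaf=0.3)})
        assert len(out) == 0


class TestVafHistogram:
    def test_single_bin(self):
        t = _table([("chr1", i, "C", "T", 100, 50, 0.5)
                    for i in range(1, 11)])
        counts, edges, frac_het, frac_hom = flt.vaf_histogram(t)
        assert counts.sum() == 10
        assert (counts > 0).sum() == 1
        assert frac_het == 1.0 and frac_hom == 0.0

    def test_uniform_vafs_spread(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(size=2000)
        t = _table([("chr1", i + 1, "C", "T", 100, int(x * 100), x)
                    for i, x in enumerate(v)])
        counts, edges, _, _ = flt.vaf_histogram(t)
        assert len(counts) == 20 and counts.sum() == 2000
        assert abs(counts - 100).max() < 5 * np.sqrt(100)

    def test_empty(self):
        counts, edges, frac_het, frac_hom = flt.vaf_histogram(_table([]))
        assert counts.sum() == 0 and frac_het == 0.0


class TestBulkLoad:
    @pytest.mark.parametrize("count,expected", [(83, 830), (0, 0), (38, 380)])
    def test_multiply_by_clone_count(self, count, expected):
        assert flt.expected_bulk_load(count) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            flt.expected_bulk_load(-1)


class TestEndToEndRecovery:
    def test_noise_off_recovers_planted_truth_exactly(self, genome, genes):
        mix = syn.ProcessMix.default(1500)
        truth = syn.plant_somatic_mutations(genome, mix, genes, seed=31)
        germ = syn.plant_germline(genome, seed=32)
        tables, blood = syn.emit_caller_tables(
            truth, germ, genome, 50, 0.0, 0.0, seed=33, exact_vaf=True)
        catalog, counts = flt.consensus_catalog(tables, blood)
        planted = set(map(tuple, truth.loc[
            truth["zygosity"].isin(["het", "hom"]), flt.KEY].values))
        got = set(map(tuple, catalog.calls[flt.KEY].values))
        assert got == planted
        # monotone stage counts
        stage_order = ["consensus", "site_filters", "zygosity"]
        sizes = [counts[s] for s in stage_order]
        assert sizes == sorted(sizes, reverse=True)
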