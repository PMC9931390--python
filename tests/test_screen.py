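"""Barcode screen: counting, normalization, NB Wald test, hits, overlaps, sets."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO
from scipy import stats as sps

from gemscreen.screen import (CountTable, call_hits, classify_slow_growers,
                              count_barcodes, estimate_size_factors,
                              filter_low_counts, fisher_overlap, set_enrichment,
                              wald_enrichment)
from gemscreen.synthetic import (ScreenSimConfig, make_barcode_db,
                                 simulate_screen_counts, simulate_screen_reads)


def _fasta(records):
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    buf.seek(0)
    return buf


def _fastq(records):
    buf = io.StringIO()
    SeqIO.write(records, buf, "fastq")
    buf.seek(0)
    return buf


class TestCountBarcodes:
    def test_constructed_fixture_and_conservation(self):
        recs = make_barcode_db(3, seed=1)
        seqs = {r.id: str(r.seq) for r in recs}
        reads = simulate_screen_reads({"s0000": 100, "s0001": 50}, seqs, 0.0, seed=2)
        counts, unassigned = count_barcodes(_fastq(reads), _fasta(recs))
        assert counts["s0000"] == 100 and counts["s0001"] == 50
        assert counts["s0002"] == 0 and unassigned == 0
        assert counts.sum() + unassigned == len(reads)

    def test_foreign_read_unassigned(self):
        recs = make_barcode_db(2, seed=1)
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        junk = SeqRecord(Seq("T" * 60), id="junk")
        junk.letter_annotations["phred_quality"] = [30] * 60
        counts, unassigned = count_barcodes(_fastq([junk]), _fasta(recs))
        assert unassigned == 1 and counts.sum() == 0

    def test_one_mismatch_rescue_recovers_errored_reads(self):
        # at 1% per-base errors, only reads with >= 2 errors inside the
        # 20-bp barcode (~1.7% of reads) escape single-mismatch rescue
        recs = make_barcode_db(8, seed=3)
        seqs = {r.id: str(r.seq) for r in recs}
        truth = {r.id: 120 for r in recs}
        reads = simulate_screen_reads(truth, seqs, error_rate=0.01, seed=4)
        counts, _ = count_barcodes(_fastq(reads), _fasta(recs), max_mismatch=1)
        total_truth = sum(truth.values())
        assert abs(counts.sum() - total_truth) / total_truth <= 0.02
        exact, _ = count_barcodes(_fastq(reads), _fasta(recs), max_mismatch=0)
        assert counts.sum() > exact.sum()  # rescue recovers additional reads

    def test_duplicate_barcode_rejected(self):
        recs = make_barcode_db(2, seed=1)
        recs[1].seq = recs[0].seq
        with pytest.raises(ValueError, match="duplicate"):
            count_barcodes(_fastq([]), _fasta(recs))


class TestFilterAndSizeFactors:
    def test_low_count_filter(self, small_table):
        t = small_table
        t.counts.loc["s4"] = 9  # below threshold everywhere
        kept = filter_low_counts(t, 10)
        assert "s4" not in kept.counts.index
        assert len(kept.counts) == 4
        assert filter_low_counts(t, 0).counts.shape == t.counts.shape

    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [10, 20]}, index=["x", "y"])
        t = CountTable(counts, pd.Series({"a": "control", "b": "drug"}))
        np.testing.assert_allclose(estimate_size_factors(t), [1.0, 1.0])

    def test_doubled_sample_hand_computation(self):
        counts = pd.DataFrame({"a": [100, 40, 8], "b": [200, 80, 16]},
                              index=["x", "y", "z"])
        t = CountTable(counts, pd.Series({"a": "control", "b": "drug"}))
        sf = estimate_size_factors(t)
        np.testing.assert_allclose(sf, [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12)

    def test_scaling_property(self, rng):
        counts = pd.DataFrame(rng.poisson(100, (50, 4)) + 1,
                              columns=list("abcd"),
                              index=[f"s{i}" for i in range(50)])
        cond = pd.Series({"a": "control", "b": "control", "c": "drug", "d": "drug"})
        sf1 = estimate_size_factors(CountTable(counts, cond)).to_numpy()
        scaled = counts.copy()
        scaled["c"] = (scaled["c"] * 3)
        sf2 = estimate_size_factors(CountTable(scaled, cond)).to_numpy()
        assert sf2[2] / sf1[2] == pytest.approx(3 * sf2[0] / sf1[0], rel=1e-9)


class TestWaldEnrichment:
    def test_identical_conditions_null(self, small_table):
        counts = small_table.counts.copy()
        counts[["drug_1", "drug_2", "drug_3"]] = counts[
            ["control_1", "control_2", "control_3"]].to_numpy()
        t = CountTable(counts, small_table.condition)
        res = wald_enrichment(t)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-9)
        assert (res["q"] > 0.9).all()

    def test_planted_resistor_round_trip(self):
        """Planted 32-fold resistors recover log2fc ~ 5 with q < 0.05."""
        planted = [(f"s{i:04d}", 5.0) for i in range(5)]
        cfg = ScreenSimConfig(n_strains=3680, depth=1e6,
                              planted_resistors=planted, seed=11)
        table = filter_low_counts(simulate_screen_counts(cfg), 10)
        res = wald_enrichment(table)
        errs = [abs(res.loc[s, "log2fc"] - 5.0) for s, _ in planted]
        assert np.median(errs) < 0.3
        assert all(res.loc[s, "q"] < 0.05 for s, _ in planted)

    def test_bh_monotone_and_q_at_least_p(self, small_table):
        res = wald_enrichment(small_table)
        assert (res["q"] >= res["p"] - 1e-15).all()
        by_p = res.sort_values("p")
        assert by_p["q"].is_monotonic_increasing

    def test_null_fdr_calibration(self):
        """Fraction of null strains at q<0.05 stays at the nominal level."""
        fracs = []
        for seed in range(5):
            cfg = ScreenSimConfig(n_strains=3000, depth=1e6, seed=seed)
            table = filter_low_counts(simulate_screen_counts(cfg), 10)
            fracs.append((wald_enrichment(table)["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.07


class TestHitCalling:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "q"],
                            index=[f"s{i}" for i in range(len(rows))])

    def test_threshold_logic(self):
        stats_df = self._stats([(4.1, 0.01), (3.9, 0.001), (-4.2, 0.04), (4.5, 0.2)])
        hits = call_hits(stats_df)
        assert hits.resistant == ("s0",)
        assert hits.sensitive == ("s2",)

    def test_empty_and_reorder_invariance(self):
        assert call_hits(pd.DataFrame(columns=["log2fc", "q"])).resistant == ()
        stats_df = self._stats([(4.1, 0.01), (-4.2, 0.04), (0.0, 0.9)])
        shuffled = stats_df.iloc[[2, 0, 1]]
        assert set(call_hits(stats_df).resistant) == set(call_hits(shuffled).resistant)
        assert set(call_hits(stats_df).sensitive) == set(call_hits(shuffled).sensitive)


class TestFisherOverlap:
    def test_two_by_two_enumeration(self):
        universe = {"a", "b", "c", "d"}
        table, p = fisher_overlap({"a", "b"}, {"a", "b"}, universe)
        np.testing.assert_array_equal(table, [[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 6)

    def test_annotated_equals_universe(self):
        universe = set("abcdef")
        _, p = fisher_overlap({"a", "b"}, universe, universe)
        assert p == pytest.approx(1.0)

    def test_equals_hypergeometric_enumeration(self, rng):
        """Exact tail equals brute-force enumeration over overlap values."""
        universe = [f"u{i}" for i in range(10)]
        for _ in range(20):
            hits = set(rng.choice(universe, rng.integers(1, 8), replace=False))
            ann = set(rng.choice(universe, rng.integers(1, 8), replace=False))
            _, p = fisher_overlap(hits, ann, universe)
            k = len(hits & ann)
            brute = sum(sps.hypergeom.pmf(x, 10, len(ann), len(hits))
                        for x in range(k, min(len(ann), len(hits)) + 1))
            assert p == pytest.approx(brute, rel=1e-9)

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            fisher_overlap(set(), set(), set())


class TestSlowGrowers:
    def test_cutoff_is_strict(self):
        od = pd.Series({"a": 0.10, "b": 0.12, "c": 0.11})
        assert classify_slow_growers(od) == {"a"}

    def test_counts_by_construction(self):
        od = pd.Series({f"s{i}": v for i, v in
                        enumerate([0.05, 0.09, 0.3, 0.5, 0.2, 0.4])})
        assert len(classify_slow_growers(od)) == 2


class TestSetEnrichment:
    def _stats_from_lfc(self, lfc):
        return pd.DataFrame({"log2fc": lfc},
                            index=[f"s{i}" for i in range(len(lfc))])

    def test_null_sets_uniform_p(self, rng):
        """Member/background from one distribution -> uniform p (KS)."""
        pvals = []
        for _ in range(200):
            lfc = rng.normal(0, 1, 300)
            stats_df = self._stats_from_lfc(lfc)
            members = list(stats_df.index[rng.choice(300, 20, replace=False)])
            out = set_enrichment(stats_df, {"null_set": members})
            pvals.append(out.loc["null_set", "p_up"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_shifted_set_detected(self, rng):
        lfc = rng.normal(0, 1, 300)
        lfc[:20] += 4.0
        stats_df = self._stats_from_lfc(lfc)
        out = set_enrichment(stats_df, {"shifted": [f"s{i}" for i in range(20)]})
        assert out.loc["shifted", "q_up"] < 0.1

    def test_degenerate_sets_skipped(self, rng):
        stats_df = self._stats_from_lfc(rng.normal(0, 1, 30))
        with pytest.warns(UserWarning):
            out = set_enrichment(stats_df, {"tiny": ["s0", "s1"]})
        assert len(out) == 0
        with pytest.warns(UserWarning):
            out = set_enrichment(stats_df, {"all": list(stats_df.index)})
        assert len(out) == 0


class TestSimulator:
    def test_determinism(self):
        cfg = ScreenSimConfig(n_strains=100, depth=1e4, seed=9)
        a = simulate_screen_counts(cfg)
        b = simulate_screen_counts(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_null_model_ratios_near_one(self):
        cfg = ScreenSimConfig(n_strains=50, depth=1e7, dispersion=1e-9, seed=1)
        t = simulate_screen_counts(cfg)
        drug = t.counts[t.samples("drug")].mean(axis=1)
        ctrl = t.counts[t.samples("control")].mean(axis=1)
        assert np.abs(np.log2(drug / ctrl)).max() < 0.05

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ScreenSimConfig(n_strains=0)
        with pytest.raises(ValueError):
            ScreenSimConfig(n_strains=10, planted_resistors=[("s0099", 5.0)])
        with pytest.raises(ValueError):
            ScreenSimConfig(n_strains=10, planted_resistors=[("s0001", 5.0)],
                            planted_sensitives=[("s0001", -5.0)])
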