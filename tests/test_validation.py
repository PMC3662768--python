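import numpy as np
import pytest
from scipy.stats import chi2

from venomics.validation import (
    DEFAULT_EVALUE_EDGES,
    bin_evalues,
    best_hits,
    compare_distributions,
    domain_overlap,
    load_signal_predictions,
    predict_signal,
    read_blast_tabular,
    signal_enrichment,
)


class TestPredictSignal:
    def test_canonical_tripartite_signal_called(self):
        seq = "MK" + "L" * 10 + "ASA" + "DEQNRKDEQNRKDEQNRK"
        p = predict_signal(seq, "x")
        assert p.call
        assert p.cleavage_position == 15  # right after the A-S-A motif
        assert p.score >= 1.5

    def test_acidic_core_rejected(self):
        p = predict_signal("M" + "D" * 20 + "AGAGAGAGAG")
        assert not p.call and p.cleavage_position is None

    def test_short_protein_never_called(self):
        assert not predict_signal("MKLLLLLLLL").call

    def test_missing_n_region_charge_rejected(self):
        seq = "MA" + "L" * 10 + "ASA" + "DEQNDEQNDEQN"
        assert not predict_signal(seq).call

    def test_no_small_residue_cleavage_site_rejected(self):
        seq = "MK" + "L" * 12 + "WWWWWWWWWWWWWWWWWWWWWWWW"
        assert not predict_signal(seq).call

    def test_external_predictions_import(self, tmp_path):
        p = tmp_path / "sig.tsv"
        p.write_text(
            "protein_id\tcall\tposition\np1\tTrue\t19\np2\tFalse\t\n"
        )
        preds = load_signal_predictions(p)
        assert preds["p1"].call and preds["p1"].cleavage_position == 19
        assert not preds["p2"].call


class TestSignalEnrichment:
    def test_reported_venom_body_contrast_is_significant(self):
        chi, pct_venom, pct_body = signal_enrichment((39, 129), (1133, 21496))
        assert chi.p_value < 1e-4
        assert pct_venom == 30 and pct_body == 5

    def test_identical_proportions_give_zero_statistic(self):
        chi, _, _ = signal_enrichment((10, 100), (10, 100))
        assert chi.statistic == pytest.approx(0.0)
        assert chi.p_value == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # all four expected counts are 5: statistic = 4 * 25/5 = 20
        chi, _, _ = signal_enrichment((10, 10), (0, 10))
        assert chi.statistic == pytest.approx(20.0)
        assert chi.df == 1
        assert chi.p_value == pytest.approx(chi2.sf(20.0, 1))

    def test_group_swap_invariance(self):
        a, _, _ = signal_enrichment((39, 129), (1133, 21496))
        b, _, _ = signal_enrichment((1133, 21496), (39, 129))
        assert a.statistic == pytest.approx(b.statistic)

    def test_zero_marginal_signaled(self):
        with pytest.raises(ValueError, match="marginal"):
            signal_enrichment((0, 10), (0, 10))


class TestBinEvalues:
    EDGES = (1e-100, 1e-50, 1e-10, 1e-3)

    def test_interval_membership(self):
        d = bin_evalues([1e-60], self.EDGES)
        assert d.counts == (0, 1, 0, 0, 0)

    def test_empty_input(self):
        assert bin_evalues([], self.EDGES).counts == (0, 0, 0, 0, 0)

    def test_edge_value_falls_in_more_significant_bin(self):
        d = bin_evalues([1e-50], self.EDGES)
        assert d.counts == (0, 1, 0, 0, 0)

    def test_counts_conserve_input_size(self):
        rng = np.random.default_rng(3)
        vals = 10.0 ** rng.uniform(-120, 2, size=500)
        d = bin_evalues(vals, DEFAULT_EVALUE_EDGES)
        assert sum(d.counts) == 500
        assert len(d.counts) == len(DEFAULT_EVALUE_EDGES) + 1


class TestCompareDistributions:
    def test_identical_distributions(self):
        a = bin_evalues([1e-60, 1e-5, 1e-5, 2.0], self.EDGES, "a")
        b = bin_evalues([1e-60, 1e-5, 1e-5, 2.0], self.EDGES, "b")
        r = compare_distributions(a, b)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    EDGES = (1e-100, 1e-50, 1e-10, 1e-3)

    def test_disjoint_two_bin_case(self):
        a = bin_evalues([1e-200] * 10, self.EDGES, "a")
        b = bin_evalues([1e-60] * 10, self.EDGES, "b")
        r = compare_distributions(a, b)
        assert r.statistic == pytest.approx(20.0)
        assert r.df == 1

    def test_statistic_scales_with_proportional_counts(self):
        rng = np.random.default_rng(5)
        vals_a = 10.0 ** rng.uniform(-90, 0, size=60)
        vals_b = 10.0 ** rng.uniform(-60, 0, size=60)
        a, b = bin_evalues(vals_a, self.EDGES), bin_evalues(vals_b, self.EDGES)
        r1 = compare_distributions(a, b)
        a10 = type(a)(a.label, a.bin_edges, tuple(10 * c for c in a.counts))
        b10 = type(b)(b.label, b.bin_edges, tuple(10 * c for c in b.counts))
        r10 = compare_distributions(a10, b10)
        assert r10.statistic == pytest.approx(10 * r1.statistic)

    def test_single_shared_bin_is_undefined(self):
        a = bin_evalues([1e-60] * 5, self.EDGES)
        b = bin_evalues([1e-60] * 3, self.EDGES)
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_distributions(a, b)

    def test_mismatched_edges_rejected(self):
        a = bin_evalues([1.0], self.EDGES)
        b = bin_evalues([1.0], DEFAULT_EVALUE_EDGES)
        with pytest.raises(ValueError, match="different bin edges"):
            compare_distributions(a, b)


class TestDomainOverlap:
    def test_worked_example(self):
        v = domain_overlap({"a", "b"}, {"b", "c"}, {"b", "d"})
        assert v["ABC"] == 1
        assert (v["A_only"], v["B_only"], v["C_only"]) == (1, 1, 1)
        assert v["AB_only"] == v["AC_only"] == v["BC_only"] == 0

    def test_disjoint_sets(self):
        v = domain_overlap({"a"}, {"b"}, {"c"})
        assert v["ABC"] == 0 and sum(v.values()) == 3

    def test_identical_sets_all_triple(self):
        v = domain_overlap({"x", "y"}, {"x", "y"}, {"x", "y"})
        assert v == {
            "A_only": 0, "B_only": 0, "C_only": 0,
            "AB_only": 0, "AC_only": 0, "BC_only": 0, "ABC": 2,
        }

    def test_regions_sum_to_union(self):
        A, B, C = {"a", "b", "c"}, {"b", "c", "d"}, {"c", "e"}
        assert sum(domain_overlap(A, B, C).values()) == len(A | B | C)


def test_blast_best_hit_per_query(tmp_path):
    rows = [
        "q1\ts1\t90\t50\t1\t0\t1\t50\t1\t50\t1e-30\t100",
        "q1\ts2\t88\t50\t2\t0\t1\t50\t1\t50\t1e-40\t120",
        "q2\ts3\t80\t40\t3\t0\t1\t40\t1\t40\t1e-5\t60",
        "q2\ts4\t80\t40\t3\t0\t1\t40\t1\t40\t1e-5\t80",
    ]
    p = tmp_path / "hits.tsv"
    p.write_text("\n".join(rows) + "\n")
    df = read_blast_tabular(p)
    best = best_hits(df)
    assert len(best) == 2
    assert best.set_index("query").loc["q1", "subject"] == "s2"  # lower E-value
    assert best.set_index("query").loc["q2", "subject"] == "s4"  # tie -> bitscore
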