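import itertools

import pytest
from hypothesis import given, settings, strategies as st

from venomics.peptide_id import (
    FilterConfig,
    PeptideObservation,
    coverage_fraction,
    filter_peptides,
    infer_proteins,
    map_peptides,
    spectral_summary,
)
from venomics.translation import OrfSegment


def obs(seq, p=0.9, z=2, spc=1):
    return PeptideObservation(seq, p, z, spc)


def orf(tid, seq, frame=1, start=0):
    return OrfSegment(tid, frame, start, start + len(seq), seq)


class TestFilterPeptides:
    @pytest.mark.parametrize(
        "o,kept",
        [
            (obs("AAAA", p=0.9, z=2), False),  # length 4 fails the strict >4
            (obs("AAAAAAAAAA", p=0.5, z=2), False),  # probability 0.5 fails >0.5
            (obs("AAAAAAAAAA", p=0.9, z=1), False),  # +1 charge excluded
            (obs("AAAAA", p=0.51, z=2), True),  # all strict thresholds met
        ],
    )
    def test_strict_cascade(self, o, kept):
        assert (filter_peptides([o]) == [o]) is kept

    def test_idempotent(self):
        pool = [
            obs("AAAA"), obs("AAAAAA", p=0.3), obs("CCCCC", z=1),
            obs("DDDDD", p=0.8, z=3), obs("EEEEEE"),
        ]
        once = filter_peptides(pool)
        assert filter_peptides(once) == once


class TestMapPeptides:
    def test_substring_placement(self):
        matches, left = map_peptides([obs("GGSAK")], [orf("t1", "MGGSAKW")])
        assert len(matches) == 1 and not left
        m = matches[0]
        assert (m.transcript_id, m.aa_start, m.unique_flag) == ("t1", 1, True)

    def test_isoleucine_leucine_equivalence(self):
        matches, left = map_peptides([obs("GISAK")], [orf("t1", "MGLSAKW")])
        assert len(matches) == 1 and not left
        matches, left = map_peptides(
            [obs("GISAK")], [orf("t1", "MGLSAKW")], il_equivalence=False
        )
        assert not matches and len(left) == 1

    def test_multi_transcript_hit_is_not_unique(self):
        matches, _ = map_peptides(
            [obs("PEPTIDEK")],
            [orf("t1", "AAPEPTIDEKAA"), orf("t2", "PEPTIDEKGG")],
        )
        assert len(matches) == 2
        assert all(not m.unique_flag for m in matches)

    def test_multiple_placements_within_one_transcript_stay_unique(self):
        matches, _ = map_peptides(
            [obs("AGAGK")], [orf("t1", "AGAGKWWAGAGKW")]
        )
        assert len(matches) == 2
        assert all(m.unique_flag for m in matches)
        assert sorted(m.aa_start for m in matches) == [0, 7]

    def test_unmatched_reported(self):
        matches, left = map_peptides([obs("WWWWW")], [orf("t1", "AAAAA")])
        assert not matches and len(left) == 1


class TestInferProteins:
    def test_single_peptide_never_identified(self):
        observations = [obs("MAGICPEPK", p=0.99)]
        matches, _ = map_peptides(observations, [orf("t1", "AAMAGICPEPKDD")])
        assert infer_proteins(matches, observations) == []

    def test_two_good_peptides_identified_with_product_probability(self):
        observations = [obs("AAAAWK", p=0.9), obs("CCCCWK", p=0.9)]
        matches, _ = map_peptides(observations, [orf("t1", "AAAAWKGGCCCCWKGG")])
        idents = infer_proteins(matches, observations)
        assert len(idents) == 1
        assert idents[0].protein_probability == pytest.approx(0.99)
        assert idents[0].distinct_peptides == 2
        assert idents[0].normalized_spectral_abundance == pytest.approx(1.0)

    def test_protein_probability_monotone_in_added_peptides(self):
        seqs = ["AADDWK", "CCEEWK", "GGFFWK", "HHMMWK"]
        target = "".join(seqs)
        probs = []
        for n in range(2, len(seqs) + 1):
            observations = [obs(s, p=0.6) for s in seqs[:n]]
            matches, _ = map_peptides(observations, [orf("t1", target)])
            idents = infer_proteins(matches, observations)
            probs.append(idents[0].protein_probability)
        assert probs == sorted(probs)

    def test_razor_assigns_shared_peptide_to_strongest_protein(self):
        shared = "SHAREDPK"
        t1 = "AAAAWK" + shared + "CCCCWK"  # two unique peptides
        t2 = shared + "GGGG"  # only the shared peptide
        observations = [obs("AAAAWK"), obs("CCCCWK"), obs(shared)]
        matches, _ = map_peptides(observations, [orf("t1", t1), orf("t2", t2)])
        idents = infer_proteins(matches, observations)
        assert [i.transcript_id for i in idents] == ["t1"]
        assert idents[0].distinct_peptides == 3

    def test_razor_conserves_peptides(self):
        # every retained peptide is credited to exactly one transcript
        shared = "SHAREDPK"
        observations = [obs("AAAAWK"), obs("CCCCWK"), obs("DDDDWK"), obs(shared)]
        orfs = [
            orf("t1", "AAAAWK" + shared + "CCCCWK"),
            orf("t2", "DDDDWK" + shared + "DDDDWKEE"),
        ]
        matches, _ = map_peptides(observations, orfs)
        idents = infer_proteins(
            matches, observations, FilterConfig(min_peptides_per_protein=1)
        )
        credited = list(
            itertools.chain.from_iterable(i.peptides for i in idents)
        )
        assert len(credited) == len(set(credited)) == 4

    def test_low_probability_pair_rejected_by_protein_threshold(self):
        observations = [obs("AAAAWK", p=0.51), obs("CCCCWK", p=0.51)]
        matches, _ = map_peptides(observations, [orf("t1", "AAAAWKCCCCWK")])
        # 1 - 0.49^2 = 0.7599 > 0.7 passes; drop to 0.4 evidence and it fails
        assert len(infer_proteins(matches, observations)) == 1
        weak = [obs("AAAAWK", p=0.4), obs("CCCCWK", p=0.4)]
        matches, _ = map_peptides(weak, [orf("t1", "AAAAWKCCCCWK")])
        assert infer_proteins(
            matches, weak, FilterConfig(min_peptide_prob_exclusive=0.0)
        ) == []


class TestCoverage:
    def test_overlapping_intervals_merge(self):
        assert coverage_fraction([(10, 20), (15, 30)], 100) == pytest.approx(0.20)

    def test_full_span(self):
        assert coverage_fraction([(0, 80)], 80) == 1.0

    def test_disjoint_additive(self):
        assert coverage_fraction([(0, 5), (50, 55)], 100) == pytest.approx(0.10)

    @given(
        st.lists(
            st.tuples(st.integers(0, 90), st.integers(1, 30)).map(
                lambda ab: (ab[0], ab[0] + ab[1])
            ),
            max_size=12,
        )
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_order_invariant_and_monotone(self, intervals):
        base = coverage_fraction(intervals, 120)
        assert coverage_fraction(list(reversed(intervals)), 120) == base
        assert 0.0 <= base <= 1.0
        assert coverage_fraction(intervals + [(0, 10)], 120) >= base


class TestSpectralSummary:
    def test_equal_proteins_split_abundance(self):
        observations = [
            obs("AAAAWK", spc=3), obs("CCCCWK", spc=3),
            obs("DDDDWK", spc=3), obs("EEEEWK", spc=3),
        ]
        orfs = [orf("t1", "AAAAWKCCCCWK"), orf("t2", "DDDDWKEEEEWK")]
        matches, _ = map_peptides(observations, orfs)
        idents = infer_proteins(matches, observations)
        assert [i.normalized_spectral_abundance for i in idents] == pytest.approx(
            [0.5, 0.5]
        )
        summary = spectral_summary(idents, 2917, 2686)
        assert summary["peptide_retention_pct"] == 92
        assert summary["mean_peptide_hits"] == 2.0

    def test_empty_identifications(self):
        assert spectral_summary([]) == {"n_proteins": 0}
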