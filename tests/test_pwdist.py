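import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import mutate_positions, random_seq
from oracles import brute_force_nw_score, kmer_multiset_distance
from slpotu.pwdist import (
    AlignScoring,
    error_distribution,
    error_rate,
    kmer_distance,
    nw_align,
    pair_distance,
    quickdist,
    sparse_distances,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestNWAlign:
    def test_identical_sequences(self, scoring):
        al = nw_align("ACGTACGT", "ACGTACGT", scoring)
        assert al.substitutions == 0
        assert al.gap_events == 0
        assert al.columns == 8
        assert quickdist(al) == 0.0

    def test_single_deletion_example_matches_enumeration(self, scoring):
        al = nw_align("ACGT", "AGT", scoring)
        assert al.gap_events == 1
        assert al.gap_columns == 1
        expected = brute_force_nw_score(
            "ACGT", "AGT", scoring.match_reward, -scoring.mismatch_penalty,
            scoring.gap_open, scoring.gap_extend, scoring.end_gaps_free,
        )
        assert al.score == pytest.approx(expected)

    @given(a=dna, b=dna, end_free=st.booleans())
    @settings(max_examples=60, deadline=None)
    def test_score_matches_exhaustive_enumeration(self, a, b, end_free):
        sc = AlignScoring(end_gaps_free=end_free)
        al = nw_align(a, b, sc)
        expected = brute_force_nw_score(
            a, b, sc.match_reward, -sc.mismatch_penalty,
            sc.gap_open, sc.gap_extend, end_free,
        )
        assert al.score == pytest.approx(expected)

    def test_alignment_recovers_inputs(self, scoring):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = random_seq(rng, int(rng.integers(20, 80)))
            b = random_seq(rng, int(rng.integers(20, 80)))
            al = nw_align(a, b, scoring)
            assert al.aligned_a.replace("-", "") == a
            assert al.aligned_b.replace("-", "") == b
            assert len(al.aligned_a) == len(al.aligned_b) == al.columns

    def test_empty_sequence_rejected(self, scoring):
        with pytest.raises(ValueError):
            nw_align("", "ACGT", scoring)


class TestQuickdist:
    def test_single_substitution_on_60nt(self, scoring):
        rng = np.random.default_rng(1)
        t = random_seq(rng, 60)
        v = mutate_positions(t, [30], rng)
        d = pair_distance(t, v, scoring)
        assert d == pytest.approx(1 / 60)
        assert d < 0.02  # inside the preclustering width

    def test_multicolumn_gap_counts_one_event(self, scoring):
        rng = np.random.default_rng(2)
        t = random_seq(rng, 60)
        v = t[:20] + t[23:]  # one internal 3-nt deletion
        al = nw_align(t, v, scoring)
        assert al.internal_gap_events == 1
        assert al.internal_gap_columns == 3
        assert quickdist(al) == pytest.approx(1 / 60)
        # per-column counting is the alternative convention
        assert quickdist(al, gap_per_column=True) == pytest.approx(3 / 60)

    def test_symmetry_under_canonical_ordering(self, scoring):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = random_seq(rng, 60)
            v = mutate_positions(t, rng.choice(60, size=2, replace=False), rng)
            assert pair_distance(t, v, scoring) == pair_distance(v, t, scoring)

    def test_identity_is_zero(self, scoring):
        assert pair_distance("ACGTACGT", "ACGTACGT", scoring) == 0.0

    def test_zero_length_alignment_rejected(self, scoring):
        al = nw_align("A", "A", scoring)
        al.columns = 0
        with pytest.raises(ValueError):
            quickdist(al)


class TestKmerDistance:
    def test_identical_and_disjoint(self):
        assert kmer_distance("ACGTACGTACGT", "ACGTACGTACGT", k=6) == 0.0
        assert kmer_distance("AAAAAAAA", "CCCCCCCC", k=6) == 1.0

    @given(a=st.text(alphabet="ACGT", min_size=8, max_size=30),
           b=st.text(alphabet="ACGT", min_size=8, max_size=30),
           k=st.integers(min_value=2, max_value=6))
    @settings(max_examples=60, deadline=None)
    def test_matches_counter_oracle(self, a, b, k):
        assert kmer_distance(a, b, k) == pytest.approx(
            kmer_multiset_distance(a, b, k)
        )

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            kmer_distance("ACGTACGT", "ACGTACGT", k=0)


class TestSparseDistances:
    def test_single_sequence_empty(self, make_unique):
        sd = sparse_distances([make_unique("ACGTACGTACGT", 1)], cutoff=0.03)
        assert len(sd) == 0

    def test_cutoff_zero_on_distinct_sequences(self, make_unique):
        rng = np.random.default_rng(4)
        seqs = {random_seq(rng, 30) for _ in range(10)}
        uniq = [make_unique(s, 1, f"u{i}") for i, s in enumerate(sorted(seqs))]
        assert len(sparse_distances(uniq, cutoff=0.0)) == 0

    def test_matches_all_pairs_oracle(self, make_unique, scoring):
        rng = np.random.default_rng(5)
        t = random_seq(rng, 60)
        seqs = {t}
        while len(seqs) < 50:
            k = int(rng.integers(1, 4))
            seqs.add(mutate_positions(t, rng.choice(60, size=k, replace=False), rng))
        uniq = [make_unique(s, 1, f"u{i}") for i, s in enumerate(sorted(seqs))]
        sd = sparse_distances(uniq, cutoff=0.03)
        expected = {}
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                d = pair_distance(uniq[i].sequence, uniq[j].sequence, scoring)
                if d <= 0.03:
                    expected[(i, j)] = pytest.approx(d)
        assert {(i, j): d for i, j, d in sd.entries} == expected

    def test_prescreen_loses_no_close_pair(self, make_unique):
        # >= 200 pairs within 5% divergence: prescreen must be conservative
        rng = np.random.default_rng(6)
        t = random_seq(rng, 60)
        seqs = {t}
        while len(seqs) < 40:
            k = int(rng.integers(1, 3))
            seqs.add(mutate_positions(t, rng.choice(60, size=k, replace=False), rng))
        uniq = [make_unique(s, 1, f"u{i}") for i, s in enumerate(sorted(seqs))]
        with_screen = sparse_distances(uniq, cutoff=0.05, use_prescreen=True)
        without = sparse_distances(uniq, cutoff=0.05, use_prescreen=False)
        assert len(without) >= 200
        assert with_screen.entries == without.entries

    def test_duplicate_sequences_rejected(self, make_unique):
        u = make_unique("ACGTACGTACGT", 1)
        with pytest.raises(ValueError):
            sparse_distances([u, make_unique("ACGTACGTACGT", 2, "x")])


class TestErrorRate:
    def test_identical_read_has_zero_rate(self, five_templates, scoring):
        t = five_templates[0]
        obs = error_rate(t.bases, [(x.id, x.bases) for x in five_templates], scoring)
        assert obs.n_errors == 0
        assert obs.error_rate == 0.0
        assert obs.template_id == t.id

    def test_single_substitution_rate(self, five_templates, scoring):
        rng = np.random.default_rng(7)
        t = five_templates[2]
        read = mutate_positions(t.bases, [10], rng)
        obs = error_rate(read, [(x.id, x.bases) for x in five_templates], scoring)
        assert obs.template_id == t.id
        assert obs.n_errors == 1
        assert obs.error_rate == pytest.approx(1 / 60)

    def test_long_insertion_counts_one_event(self, five_templates, scoring):
        t = five_templates[1]
        read = t.bases[:30] + "ACGT" + t.bases[30:]  # 4-nt insertion
        obs = error_rate(read, [(x.id, x.bases) for x in five_templates], scoring)
        assert obs.n_errors == 1
        assert obs.error_rate == pytest.approx(1 / 60)


class TestErrorDistribution:
    def test_zero_rate_puts_all_mass_at_zero(self):
        df = error_distribution([0, 0, 1], template_length=60, per_base_rate=0.0)
        assert df.loc[df.n_errors == 0, "expected_binomial_count"].iloc[0] == 3

    def test_expected_counts_sum_to_n(self):
        rng = np.random.default_rng(8)
        counts = rng.binomial(60, 0.003, size=500)
        df = error_distribution(list(counts), 60, 0.003)
        # full-support expectation sums to N; the table covers observed n
        total = 500 * 1.0
        assert df["expected_binomial_count"].sum() == pytest.approx(
            total, rel=1e-3
        )
        assert df["observed_count"].sum() == 500

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            error_distribution([1], 60, 1.5)
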