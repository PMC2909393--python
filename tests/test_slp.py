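import numpy as np
import pytest

from conftest import mutate_positions, random_seq
from slpotu.pwdist import pair_distance
from slpotu.seqio import dereplicate
from slpotu.simdata import ErrorModel, simulate_reads, simulate_templates
from slpotu.slp import (
    SLPClustering,
    SLPConfig,
    SLPPreclusterer,
    slp_pipeline,
    slp_precluster,
)


@pytest.fixture(scope="module")
def chained_trio(make_unique_module):
    """Template T (100 reads), V1 one diff from T (5), V2 one diff from V1
    and two from T (3): the canonical chaining fixture."""
    rng = np.random.default_rng(7)
    T = random_seq(rng, 60)
    V1 = mutate_positions(T, [10], rng)
    V2 = mutate_positions(V1, [40], rng)
    return (
        make_unique_module(T, 100, "t"),
        make_unique_module(V1, 5, "v"),
        make_unique_module(V2, 3, "w"),
    )


@pytest.fixture(scope="module")
def make_unique_module():
    from slpotu.seqio import UniqueSeq

    def _make(seq, count, prefix="r"):
        return UniqueSeq(sequence=seq, count=count,
                         member_ids=[f"{prefix}{i}" for i in range(count)])

    return _make


class TestPrecluster:
    def test_single_sequence_is_its_own_precluster(self, make_unique_module):
        u = make_unique_module("ACGTACGTACGT", 5)
        pcs = slp_precluster([u])
        assert len(pcs) == 1
        assert pcs[0].representative is u
        assert pcs[0].total_count == 5

    def test_chaining_beyond_width_through_intermediate(self, chained_trio):
        # V2 is 0.033 from T (beyond the 2% width) but chains via V1
        T, V1, V2 = chained_trio
        assert pair_distance(T.sequence, V2.sequence) == pytest.approx(2 / 60)
        pcs = slp_precluster([T, V1, V2])
        assert len(pcs) == 1
        assert pcs[0].representative is T
        assert pcs[0].total_count == 108
        assert len(pcs[0].members) == 3

    def test_two_templates_with_satellites_stay_apart(self, make_unique_module):
        rng = np.random.default_rng(13)
        A = random_seq(rng, 60)
        B = mutate_positions(A, rng.choice(60, size=4, replace=False), rng)
        assert pair_distance(A, B) >= 0.06
        sat_a = mutate_positions(A, [3], rng)
        sat_b = mutate_positions(B, [50], rng)
        uniques = sorted(
            [
                make_unique_module(A, 50, "a"),
                make_unique_module(B, 40, "b"),
                make_unique_module(sat_a, 4, "sa"),
                make_unique_module(sat_b, 3, "sb"),
            ],
            key=lambda u: (-u.count, u.sequence),
        )
        pcs = slp_precluster(uniques)
        assert len(pcs) == 2
        reps = {p.representative.sequence for p in pcs}
        assert reps == {A, B}
        assert sorted(p.total_count for p in pcs) == [43, 54]

    def test_two_templates_below_width_merge(self, make_unique_module):
        # known behavior: genuine templates closer than the precluster
        # width end up in one precluster (they would share a 3% OTU anyway)
        rng = np.random.default_rng(19)
        A = random_seq(rng, 60)
        B = mutate_positions(A, [30], rng)
        pcs = slp_precluster([
            make_unique_module(A, 50, "a"),
            make_unique_module(B, 45, "b"),
        ])
        assert len(pcs) == 1
        assert pcs[0].representative.sequence == A

    def test_unsorted_input_rejected(self, make_unique_module):
        a = make_unique_module("A" * 20, 1)
        b = make_unique_module("C" * 20, 9, "b")
        with pytest.raises(ValueError, match="sorted"):
            slp_precluster([a, b])

    def test_no_merge_rule_prefers_first_created_cluster(self, make_unique_module):
        # bridge is within the width of both seeds (which are > width
        # apart): it must join the first-created cluster, not merge them
        rng = np.random.default_rng(23)
        A = random_seq(rng, 120)
        B = mutate_positions(A, rng.choice(120, size=4, replace=False), rng)
        bridge_pos = [p for p in range(120) if A[p] != B[p]][:2]
        bridge = A
        for p in bridge_pos:
            bridge = bridge[:p] + B[p] + bridge[p + 1:]
        dA = pair_distance(A, bridge)
        dB = pair_distance(B, bridge)
        assert dA < 0.02 and dB < 0.02 and pair_distance(A, B) > 0.02
        uniques = sorted(
            [make_unique_module(A, 30, "a"), make_unique_module(B, 20, "b"),
             make_unique_module(bridge, 2, "x")],
            key=lambda u: (-u.count, u.sequence),
        )
        est = SLPPreclusterer().fit(uniques)
        assert len(est.preclusters_) == 2
        by_rep = {p.representative.sequence: p for p in est.preclusters_}
        assert len(by_rep[A].members) == 2  # bridge joined A's (first) cluster
        assert len(by_rep[B].members) == 1

    @pytest.mark.parametrize("x_count,expected", [(5, 1), (11, 2)])
    def test_small_cluster_rescue_single_pass(self, make_unique_module,
                                              x_count, expected):
        # X (0.033 from T) seeds its own cluster in pass 1 because the
        # linking variant Y (1 diff from both) is less abundant and joins
        # T's cluster only afterwards; pass 2 then absorbs X's cluster —
        # but only while it holds fewer than 10 reads
        rng = np.random.default_rng(29)
        T = random_seq(rng, 60)
        Y = mutate_positions(T, [15], rng)
        X = mutate_positions(Y, [45], rng)
        assert pair_distance(T, X) == pytest.approx(2 / 60)
        assert pair_distance(X, Y) == pytest.approx(1 / 60)
        uniques = sorted(
            [make_unique_module(T, 50, "t"),
             make_unique_module(X, x_count, "x"),
             make_unique_module(Y, 4, "y")],
            key=lambda u: (-u.count, u.sequence),
        )
        pcs = slp_precluster(uniques)
        assert len(pcs) == expected
        if expected == 1:
            assert pcs[0].representative.sequence == T
            assert pcs[0].total_count == 50 + x_count + 4

    def test_representative_has_maximal_count(self, noisy_uniques):
        est = SLPPreclusterer().fit(noisy_uniques)
        for p in est.preclusters_:
            assert p.representative in p.members
            top = max(m.count for m in p.members)
            assert p.representative.count == top
            ties = [m for m in p.members if m.count == top]
            assert p.representative.sequence == min(t.sequence for t in ties)

    def test_count_conservation_and_partition(self, noisy_uniques):
        est = SLPPreclusterer().fit(noisy_uniques)
        assert sum(p.total_count for p in est.preclusters_) == sum(
            u.count for u in noisy_uniques
        )
        assert sum(len(p.members) for p in est.preclusters_) == len(noisy_uniques)
        assert len(est.labels_) == len(noisy_uniques)

    def test_chain_property_within_preclusters(self, noisy_uniques):
        # every member connects to the representative by sub-width steps
        import networkx as nx

        est = SLPPreclusterer().fit(noisy_uniques)
        adj = est.distances_.neighbors()
        index_of = {id(u): i for i, u in enumerate(noisy_uniques)}
        checked = 0
        for p in est.preclusters_:
            if len(p.members) == 1:
                continue
            g = nx.Graph()
            idxs = [index_of[id(m)] for m in p.members]
            g.add_nodes_from(idxs)
            member_set = set(idxs)
            for i in idxs:
                for j, d in adj[i]:
                    if j in member_set and d < est.width:
                        g.add_edge(i, j)
            assert nx.is_connected(g)
            checked += 1
        assert checked > 0


class TestPipeline:
    def test_error_free_well_separated_templates(self):
        templates = simulate_templates(5, 60, 0.06, seed=31)
        reads, _ = simulate_reads(templates, n=500,
                                  error_model=ErrorModel(0, 0, 0, 0), seed=32)
        otus = slp_pipeline(dereplicate(reads))
        assert len(otus) == 5
        assert otus.total_count == 500

    def test_deterministic_across_runs(self, noisy_uniques):
        a = SLPClustering(mothur_rounding=True).fit(noisy_uniques)
        b = SLPClustering(mothur_rounding=True).fit(noisy_uniques)
        assert np.array_equal(a.labels_, b.labels_)
        assert [o.representative.sequence for o in a.otus_.otus] == [
            o.representative.sequence for o in b.otus_.otus
        ]

    def test_labels_follow_input_order(self, noisy_uniques):
        est = SLPClustering(mothur_rounding=True).fit(noisy_uniques)
        rev = list(reversed(noisy_uniques))
        est_rev = SLPClustering(mothur_rounding=True).fit(rev)
        # same partition regardless of presentation order
        part = {}
        for u, lab in zip(noisy_uniques, est.labels_):
            part.setdefault(int(lab), set()).add(u.sequence)
        part_rev = {}
        for u, lab in zip(rev, est_rev.labels_):
            part_rev.setdefault(int(lab), set()).add(u.sequence)
        assert sorted(map(frozenset, part.values()), key=sorted) == sorted(
            map(frozenset, part_rev.values()), key=sorted
        )

    def test_invalid_width_configuration_rejected(self):
        with pytest.raises(ValueError, match="precluster_width"):
            SLPConfig(precluster_width=0.03, final_width=0.03)
        from slpotu.seqio import UniqueSeq

        with pytest.raises(ValueError, match="precluster_width"):
            SLPClustering(precluster_width=0.05, final_width=0.03).fit(
                [UniqueSeq("ACGTACGT", 1, ["r0"])]
            )

    def test_no_high_abundance_mixing(self, noisy_uniques):
        # no OTU may contain two abundant sequences (count >= 10) farther
        # apart than the final width plus one rounding step
        est = SLPClustering(mothur_rounding=True).fit(noisy_uniques)
        for otu in est.otus_.otus:
            abundant = [m for m in otu.members if m.count >= 10]
            for i in range(len(abundant)):
                for j in range(i + 1, len(abundant)):
                    d = pair_distance(abundant[i].sequence, abundant[j].sequence)
                    assert d <= est.final_width + 0.01
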