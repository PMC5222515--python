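"""Network construction, degree statistics, and herb-role tiers."""

import numpy as np
import pytest

from herbnetpharm import (
    GeneSetCollection,
    HerbAggregate,
    InteractionScore,
    ValidationError,
    build_ct_network,
    build_tp_network,
    classify_roles,
    herb_aggregates,
    network_summary,
    node_degree,
)


def accepted(c, t):
    return InteractionScore(c, t, 0.9, 0.9, accepted=True)


class TestCtNetwork:
    def test_toy_construction_with_isolate(self, compound_factory):
        comps = [compound_factory(cid=c) for c in ("c1", "c2", "c3")]
        edges = [accepted("c1", "t1"), accepted("c2", "t1"), accepted("c2", "t2")]
        net, dropped = build_ct_network(comps, edges)
        assert len(net.left_nodes) == 2
        assert len(net.right_nodes) == 2
        assert len(net.edges) == 3
        assert dropped == ["c3"]
        assert node_degree(net, "t1") == 2
        assert node_degree(net, "c1") == 1

    def test_no_pairs_drops_everything(self, compound_factory):
        comps = [compound_factory(cid=f"c{i}") for i in range(4)]
        net, dropped = build_ct_network(comps, [])
        assert net.edges == set() and net.left_nodes == set()
        assert dropped == [f"c{i}" for i in range(4)]

    def test_unknown_compound_rejected(self, compound_factory):
        with pytest.raises(ValidationError, match="ghost"):
            build_ct_network([compound_factory(cid="c1")],
                             [accepted("ghost", "t1")])

    def test_duplicate_pairs_collapse_with_warning(self, compound_factory):
        comps = [compound_factory(cid="c1")]
        with pytest.warns(UserWarning, match="duplicate"):
            net, _ = build_ct_network(
                comps, [accepted("c1", "t1"), accepted("c1", "t1")]
            )
        assert len(net.edges) == 1

    def test_dropped_plus_surviving_partitions_candidates(self, compound_factory):
        rng = np.random.default_rng(5)
        comps = [compound_factory(cid=f"c{i}") for i in range(30)]
        pairs = [
            accepted(f"c{i}", f"t{j}")
            for i in range(30)
            for j in range(int(rng.integers(0, 4)))
        ]
        net, dropped = build_ct_network(comps, pairs)
        assert len(net.left_nodes) + len(dropped) == 30

    def test_unknown_node_lookup(self, toy_ct_network):
        with pytest.raises(KeyError):
            node_degree(toy_ct_network, "nope")


class TestHerbAggregates:
    def test_toy_aggregate(self, toy_ct_network):
        (agg,) = herb_aggregates(toy_ct_network)
        assert agg.herb_id == "A"
        assert agg.n_active_compounds == 2
        assert agg.total_degree == 3
        assert agg.mean_targets_per_compound == pytest.approx(1.5)

    def test_single_compound_mean_equals_degree(self, compound_factory):
        net, _ = build_ct_network(
            [compound_factory(cid="c1", herb="H")],
            [accepted("c1", "t1"), accepted("c1", "t2"), accepted("c1", "t3")],
        )
        (agg,) = herb_aggregates(net)
        assert agg.mean_targets_per_compound == 3.0

    def test_zero_compound_herb_reported(self, toy_ct_network):
        aggs = herb_aggregates(toy_ct_network, all_herbs=["A", "B"])
        by_id = {a.herb_id: a for a in aggs}
        assert by_id["B"].n_active_compounds == 0
        assert by_id["B"].mean_targets_per_compound == 0.0

    def test_missing_herb_metadata_rejected(self, toy_ct_network):
        del toy_ct_network.node_meta["c1"]
        with pytest.raises(ValidationError, match="c1"):
            herb_aggregates(toy_ct_network)


class TestClassifyRoles:
    def test_constructed_example(self):
        aggs = [
            HerbAggregate("A", 32, 384),
            HerbAggregate("B", 8, 58),
            HerbAggregate("C", 2, 13),
        ]
        roles = {r.herb_id: r.role for r in classify_roles(aggs,
                                                           chen_fraction=0.35)}
        assert roles == {"A": "jun", "B": "chen", "C": "zuo_shi"}

    def test_twenty_herbs_split_1_7_12(self):
        aggs = [HerbAggregate(f"h{i:02d}", 40 - i, 400 - 10 * i)
                for i in range(20)]
        roles = [r.role for r in classify_roles(aggs)]
        assert roles.count("jun") == 1
        assert roles.count("chen") == 7
        assert roles.count("zuo_shi") == 12

    def test_all_equal_ties_flagged_lexicographic(self):
        aggs = [HerbAggregate(h, 5, 30) for h in ("b", "a", "c")]
        roles = classify_roles(aggs, chen_fraction=0.35)
        assert [r.herb_id for r in roles] == ["a", "b", "c"]
        assert all(r.tied for r in roles)
        assert roles[0].role == "jun"

    def test_permutation_invariant(self):
        rng = np.random.default_rng(9)
        aggs = [HerbAggregate(f"h{i}", int(rng.integers(1, 40)),
                              int(rng.integers(1, 400))) for i in range(12)]
        base = {r.herb_id: (r.role, r.rank) for r in classify_roles(aggs)}
        for _ in range(5):
            rng.shuffle(aggs)
            assert {r.herb_id: (r.role, r.rank)
                    for r in classify_roles(aggs)} == base

    def test_single_herb_is_jun(self):
        (r,) = classify_roles([HerbAggregate("only", 3, 9)])
        assert r.role == "jun" and r.rank == 1

    def test_planted_tiers_recovered_95_percent(self):
        # 100 replicates of aggregate-level noise around the planted
        # 1 strong / 7 middle / 12 weak tier means at 1000 compounds/herb
        m = 1000
        tier_of = {f"h{i:02d}": ("jun" if i == 0 else
                                 "chen" if i <= 7 else "zuo_shi")
                   for i in range(20)}
        means = {"jun": 12.0, "chen": 7.24, "zuo_shi": 6.74}
        n_comp = {"jun": 400, "chen": 73, "zuo_shi": 73}
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(100):
            aggs = [
                HerbAggregate(
                    h,
                    n_comp[t],
                    int(rng.poisson(means[t] * m)),
                )
                for h, t in tier_of.items()
            ]
            got = {r.herb_id: r.role for r in classify_roles(aggs)}
            hits += got == tier_of
        assert hits >= 95


class TestTpNetwork:
    def test_toy_edges_and_multi_count(self):
        sets = GeneSetCollection(
            sets={"P1": frozenset({"t1", "t2"}), "P2": frozenset({"t2"})},
        )
        net, multi = build_tp_network(["t1", "t2", "t3"], sets)
        assert net.edges == {("t1", "P1"), ("t2", "P1"), ("t2", "P2")}
        assert "t3" not in net.left_nodes
        assert multi == 1

    def test_empty_collection(self):
        net, multi = build_tp_network(["t1"], GeneSetCollection())
        assert net.edges == set() and multi == 0

    def test_multi_pathway_count_on_33_targets(self, targets33):
        ids = [t.target_id for t in targets33]
        # 3 pathway-sized sets covering most targets more than once
        sets = GeneSetCollection(
            sets={
                "EGFR": frozenset(ids[:24]),
                "ESTROGEN": frozenset(ids[6:30]),
                "WNT": frozenset(ids[20:33] + ids[:5]),
            }
        )
        net, multi = build_tp_network(ids, sets)
        expected = sum(
            1 for t in ids
            if sum(t in s for s in sets.sets.values()) >= 2
        )
        assert multi == expected


class TestSummary:
    def test_toy_counts(self, toy_ct_network):
        s = network_summary(toy_ct_network)
        assert (s.n_nodes, s.n_edges, s.n_left, s.n_right) == (4, 3, 2, 2)
        assert s.mean_degree_left * s.n_left == pytest.approx(s.n_edges)

    def test_empty(self):
        from herbnetpharm import BipartiteNetwork

        s = network_summary(BipartiteNetwork(left_kind="a", right_kind="b"))
        assert (s.n_nodes, s.n_edges) == (0, 0)
        assert s.mean_degree_left == 0.0
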