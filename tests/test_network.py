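"""Replacement-network construction, refinement, ranking and CSV export."""

import itertools
import math
import random

import networkx as nx
import pytest

from rgroupnet.fragmentation import RGroup
from rgroupnet.network import (
    DEFAULT_REMOVE,
    build_network,
    rank_nodes,
    read_edge_list,
    refine_network,
    site_pairs,
    top_k_subnetwork,
    total_weight,
    write_edge_list,
)
from rgroupnet.series import SubstitutionSite

from conftest import edge_weights


def site(sid, idx, *smis):
    return SubstitutionSite(sid, idx, frozenset(RGroup(s, 1) for s in smis))


class TestSitePairs:
    def test_four_rgroups_yield_six_bidirectional_replacements(self):
        assert len(site_pairs(site("s", 1, "*F", "*Cl", "*Br", "*O"))) == 6

    def test_single_rgroup_yields_none(self):
        assert site_pairs(site("s", 1, "*F")) == []

    @pytest.mark.parametrize("k", [2, 3, 7])
    def test_counts_match_bruteforce_double_loop(self, k):
        smis = [f"*{'C' * i}O" for i in range(1, k + 1)]
        pairs = site_pairs(site("s", 1, *smis))
        brute = {
            tuple(sorted((a, b)))
            for i, a in enumerate(smis)
            for b in smis[i + 1:]
        }
        assert set(pairs) == brute
        assert len(pairs) == math.comb(k, 2)


class TestBuildNetwork:
    def test_repeated_pair_accumulates_weight_per_site(self):
        sites = [site(f"s{i}", 1, "*F", "*Cl") for i in range(3)]
        net = build_network(sites)
        assert edge_weights(net) == {("*Cl", "*F"): 3}

    def test_disjoint_sites_give_disjoint_edges(self):
        net = build_network([site("a", 1, "*F", "*Cl"), site("b", 1, "*Br", "*O")])
        assert net.number_of_nodes() == 4
        assert all(net.degree(n) == 1 for n in net)

    def test_singleton_site_contributes_isolated_node(self):
        net = build_network([site("a", 1, "*F", "*Cl"), site("b", 1, "*N")])
        assert "*N" in net and net.degree("*N") == 0

    def test_weight_conservation_on_random_sites(self):
        rng = random.Random(5)
        pool = [f"*{'C' * i}" for i in range(1, 9)]
        sites = [
            site(f"s{i}", 1, *rng.sample(pool, rng.randint(1, 6)))
            for i in range(40)
        ]
        net = build_network(sites)
        expected = sum(math.comb(len(s.rgroups), 2) for s in sites)
        assert total_weight(net) == expected
        assert sum(d for _, d in net.degree()) == 2 * net.number_of_edges()


class TestRefine:
    def test_removing_star_center_empties_network(self):
        sites = [site(f"s{i}", 1, "*C", f"*{'N' * (i + 1)}") for i in range(5)]
        net = build_network(sites)
        refined = refine_network(net, remove={"*C"}, drop_isolated=True)
        assert refined.number_of_nodes() == 0

    def test_removing_absent_node_is_noop(self):
        net = build_network([site("s", 1, "*F", "*Cl", "*Br")])
        refined = refine_network(net, remove={"*C"}, drop_isolated=False)
        assert edge_weights(refined) == edge_weights(net)

    def test_default_removal_set_is_hydrogen_methyl_phenyl(self):
        assert DEFAULT_REMOVE == {"*[H]", "*C", "*c1ccccc1"}

    def test_survivor_degrees_recomputed_from_scratch(self, two_site_library):
        from rgroupnet.pipeline import RunConfig, run_pipeline

        records, _ = two_site_library
        net = run_pipeline(records, RunConfig()).global_net
        refined = refine_network(net)
        for n in refined:
            expected = sum(1 for m in net.neighbors(n) if m not in DEFAULT_REMOVE)
            assert refined.degree(n) == expected
            assert refined.degree(n) <= net.degree(n)
        for a, b, d in refined.edges(data=True):
            assert d["weight"] == net[a][b]["weight"]


class TestRanking:
    def test_ties_break_by_ascending_smiles(self):
        net = nx.Graph()
        net.add_edge("A", "C", weight=1)
        net.add_edge("A", "D", weight=1)
        net.add_edge("A", "B", weight=1)
        net.add_edge("B", "C", weight=1)
        net.add_edge("B", "D", weight=1)
        # degrees: A=3, B=3, C=2, D=2
        assert rank_nodes(net) == ["A", "B", "C", "D"]

    def test_empty_network_ranks_empty(self):
        assert rank_nodes(nx.Graph()) == []


class TestTopK:
    def test_full_k_is_identity(self):
        net = build_network([site("s", 1, "*F", "*Cl", "*Br")])
        sub = top_k_subnetwork(net, net.number_of_nodes())
        assert edge_weights(sub) == edge_weights(net)

    def test_path_keeps_highest_degree_node(self):
        net = nx.Graph()
        net.add_edge("A", "B", weight=1)
        net.add_edge("B", "C", weight=1)
        sub = top_k_subnetwork(net, 1)
        assert set(sub.nodes) == {"B"} and sub.number_of_edges() == 0

    def test_induced_edges_equal_bruteforce_filter(self):
        rng = random.Random(9)
        net = nx.Graph()
        nodes = [f"n{i}" for i in range(12)]
        for a, b in itertools.combinations(nodes, 2):
            if rng.random() < 0.4:
                net.add_edge(a, b, weight=rng.randint(1, 5))
        keep = set(rank_nodes(net)[:5])
        sub = top_k_subnetwork(net, 5)
        brute = {
            tuple(sorted((a, b))): d["weight"]
            for a, b, d in net.edges(data=True)
            if a in keep and b in keep
        }
        assert edge_weights(sub) == brute
        assert sum(d for _, d in sub.degree()) == 2 * sub.number_of_edges()


class TestEdgeListCsv:
    def make_net(self):
        sites = [
            site("s1", 1, "*F", "*Cl", "*Br"),
            site("s2", 1, "*F", "*Cl"),
            site("s3", 1, "*O", "*N"),
        ]
        return build_network(sites)

    def test_round_trip_is_byte_identical(self, tmp_path):
        net = self.make_net()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_edge_list(net, p1)
        write_edge_list(read_edge_list(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_header_and_sort_order(self, tmp_path):
        p = tmp_path / "e.csv"
        write_edge_list(self.make_net(), p)
        lines = p.read_text().splitlines()
        assert lines[0] == "source,target,weight"
        weights = [int(l.rsplit(",", 1)[1]) for l in lines[1:]]
        assert weights == sorted(weights, reverse=True)

    def test_min_weight_filter(self, tmp_path):
        p = tmp_path / "e.csv"
        write_edge_list(self.make_net(), p, min_weight=2)
        lines = p.read_text().splitlines()[1:]
        assert all(int(l.rsplit(",", 1)[1]) >= 2 for l in lines)
        assert len(lines) == 1  # only the F-Cl edge reaches weight 2

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("from,to,w\na,b,1\n")
        with pytest.raises(ValueError, match="header"):
            read_edge_list(p)

    def test_self_edge_rejected(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("source,target,weight\na,a,1\n")
        with pytest.raises(ValueError, match="self-edge"):
            read_edge_list(p)
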