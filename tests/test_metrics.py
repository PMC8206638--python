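"""Topology metrics against independent brute-force oracles on small fixtures."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from megnet.metrics import (
    assortativity,
    clustering_coefficient,
    connection_frequency_stats,
    global_efficiency,
    identify_hubs,
    louvain_modules,
    rewire_preserving_degree,
    rich_club_analysis,
    rich_club_curve,
)
from megnet.network import Edge
from megnet.synthetic import generate_toy_graph

FIXTURES = ["complete4", "star5", "path3", "ring8", "club20", "two_cliques5"]


# ---------------------------------------------------------------- oracles
def oracle_clustering(g: nx.Graph) -> float:
    total = 0.0
    for n in g.nodes():
        nb = list(g.neighbors(n))
        d = len(nb)
        if d < 2:
            continue
        tri = sum(1 for a, b in itertools.combinations(nb, 2) if g.has_edge(a, b))
        total += 2 * tri / (d * (d - 1))
    return total / g.number_of_nodes()


def oracle_efficiency(g: nx.Graph) -> float:
    nodes = list(g.nodes())
    n = len(nodes)
    idx = {x: k for k, x in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges():
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):  # Floyd-Warshall
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return inv.sum() / (n * (n - 1))


def oracle_assortativity(g: nx.Graph) -> float:
    deg = dict(g.degree())
    xs, ys = [], []
    for u, v in g.edges():
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.std() == 0:
        return float("nan")
    return float(((xs - xs.mean()) * (ys - ys.mean())).sum() / (len(xs) * xs.std() * ys.std()))


def oracle_phi(g: nx.Graph):
    deg = dict(g.degree())
    out = {}
    for k in range(0, max(deg.values())):
        members = [n for n, d in deg.items() if d > k]
        if len(members) < 2:
            break
        e = sum(1 for a, b in itertools.combinations(members, 2) if g.has_edge(a, b))
        out[k] = 2 * e / (len(members) * (len(members) - 1))
    return out


# ---------------------------------------------------------------- clustering
class TestClustering:
    def test_complete_is_one(self, toy_graphs):
        assert clustering_coefficient(toy_graphs["complete4"]) == pytest.approx(1.0)

    def test_path_is_zero(self, toy_graphs):
        assert clustering_coefficient(toy_graphs["path3"]) == pytest.approx(0.0)

    @pytest.mark.parametrize("name", FIXTURES)
    def test_matches_triangle_oracle(self, toy_graphs, name):
        g = toy_graphs[name].to_networkx()
        assert clustering_coefficient(g) == pytest.approx(oracle_clustering(g))


class TestEfficiency:
    def test_complete_is_one(self, toy_graphs):
        assert global_efficiency(toy_graphs["complete4"]) == pytest.approx(1.0)

    def test_path3_closed_form(self, toy_graphs):
        assert global_efficiency(toy_graphs["path3"]) == pytest.approx(5 / 6)

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        assert global_efficiency(g) == 0.0

    @pytest.mark.parametrize("name", FIXTURES)
    def test_matches_floyd_warshall_oracle(self, toy_graphs, name):
        g = toy_graphs[name].to_networkx()
        assert global_efficiency(g) == pytest.approx(oracle_efficiency(g))


class TestAssortativity:
    def test_star_is_minus_one(self, toy_graphs):
        assert assortativity(toy_graphs["star5"]) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self, toy_graphs):
        assert math.isnan(assortativity(toy_graphs["ring8"]))

    @pytest.mark.parametrize("name", ["club20", "two_cliques5", "star5", "path3"])
    def test_matches_pearson_oracle(self, toy_graphs, name):
        g = toy_graphs[name].to_networkx()
        ours = assortativity(g)
        oracle = oracle_assortativity(g)
        if math.isnan(oracle):
            assert math.isnan(ours)
        else:
            assert ours == pytest.approx(oracle)


# ---------------------------------------------------------------- louvain
class TestLouvain:
    def test_two_cliques_found(self, toy_graphs):
        mean_n, mean_q = louvain_modules(toy_graphs["two_cliques5"], n_runs=100, seed=0)
        assert mean_n == pytest.approx(2.0, abs=0.1)  # exactly 2 in >=95% of runs
        assert mean_q > 0.3

    def test_single_clique_one_module(self, toy_graphs):
        mean_n, _ = louvain_modules(toy_graphs["complete4"], n_runs=50, seed=0)
        assert mean_n == pytest.approx(1.0)

    def test_edgeless_graph_all_singletons(self):
        g = nx.empty_graph(10)
        mean_n, q = louvain_modules(g, n_runs=5, seed=0)
        assert mean_n == 10.0 and q == 0.0

    def test_reproducible_across_calls(self, toy_graphs):
        a = louvain_modules(toy_graphs["club20"], n_runs=50, seed=3)
        b = louvain_modules(toy_graphs["club20"], n_runs=50, seed=3)
        assert a == b


# ---------------------------------------------------------------- rewiring
class TestRewiring:
    @pytest.mark.parametrize("name", FIXTURES)
    def test_degree_sequence_exactly_preserved(self, toy_graphs, name):
        g = toy_graphs[name].to_networkx()
        r = rewire_preserving_degree(g, seed=5)
        assert sorted(d for _, d in r.degree()) == sorted(d for _, d in g.degree())
        assert r.number_of_edges() == g.number_of_edges()

    def test_star_returned_unchanged(self, toy_graphs):
        g = toy_graphs["star5"].to_networkx()
        r = rewire_preserving_degree(g, seed=1)
        assert set(map(frozenset, r.edges())) == set(map(frozenset, g.edges()))

    def test_two_seeds_give_different_edge_sets(self):
        g = nx.gnm_random_graph(20, 60, seed=0)
        diffs = 0
        for s in range(20):
            a = set(map(frozenset, rewire_preserving_degree(g, seed=2 * s).edges()))
            b = set(map(frozenset, rewire_preserving_degree(g, seed=2 * s + 1).edges()))
            diffs += a != b
        assert diffs >= 19

    def test_stays_simple(self):
        g = nx.gnm_random_graph(15, 40, seed=2)
        r = rewire_preserving_degree(g, seed=3)
        assert all(u != v for u, v in r.edges())


# ---------------------------------------------------------------- rich club
class TestRichClub:
    @pytest.mark.parametrize("name", FIXTURES)
    def test_phi_curve_matches_enumeration_oracle(self, toy_graphs, name):
        g = toy_graphs[name].to_networkx()
        ks, phi = rich_club_curve(g)
        oracle = oracle_phi(g)
        assert dict(zip(ks.tolist(), phi.tolist())) == pytest.approx(oracle)

    def test_phi_at_zero_is_density_when_connected(self, toy_graphs):
        g = toy_graphs["club20"].to_networkx()
        ks, phi = rich_club_curve(g)
        assert phi[ks == 0][0] == pytest.approx(nx.density(g))

    def test_planted_club_recovered(self, toy_graphs):
        res = rich_club_analysis(toy_graphs["club20"], n_random=200, seed=0)
        assert res.members == [f"roi{k:02d}" for k in range(5)]
        assert res.n_nodes == 5
        assert res.min_degree == 4
        assert res.coefficient > 1.0

    def test_planted_club_recovery_stable_over_seeds(self, toy_graphs):
        hits = sum(
            rich_club_analysis(toy_graphs["club20"], n_random=100, seed=s).members
            == [f"roi{k:02d}" for k in range(5)]
            for s in range(20)
        )
        assert hits >= 19

    def test_complete_graph_normalizes_to_one(self, toy_graphs):
        res = rich_club_analysis(toy_graphs["complete4"], n_random=20, seed=0)
        assert np.allclose(res.phi, 1.0)
        assert res.coefficient == pytest.approx(1.0)

    def test_members_match_declared_level(self, toy_graphs):
        res = rich_club_analysis(toy_graphs["two_cliques5"], n_random=50, seed=1)
        g = toy_graphs["two_cliques5"].to_networkx()
        assert res.members == sorted(n for n, d in g.degree() if d > res.k_star)
        assert res.min_degree > res.k_star

    def test_no_club_definable_raises(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        with pytest.raises(ValueError):
            rich_club_curve(g)


# ---------------------------------------------------------------- hubs & bands
class TestHubs:
    def test_study_scale_four_hubs(self):
        g = generate_toy_graph("complete", n_nodes=41)
        assert len(identify_hubs(g)) == 4

    def test_small_network_one_hub(self):
        g = generate_toy_graph("ring", n_nodes=10)
        assert len(identify_hubs(g)) == 1

    def test_tie_break_by_label(self):
        g = nx.Graph()
        g.add_edges_from([("c", "x"), ("c", "y"), ("c", "z"),
                          ("a", "x"), ("a", "y"), ("a", "z"),
                          ("b", "x"), ("b", "y"), ("b", "z")])
        # a, b, c all degree 3; x, y, z degree 3 as well -> all tied, label order
        hubs = identify_hubs(g, fraction=0.4)  # floor(0.4*6) = 2
        assert hubs == ["a", "b"]

    def test_cardinality_rule_all_sizes(self):
        for n in range(1, 101):
            g = nx.path_graph(n) if n > 1 else nx.empty_graph(1)
            assert len(identify_hubs(g)) == max(1, math.floor(0.1 * n))


class TestConnectionFrequencyStats:
    def test_mean_and_band_assignment(self):
        edges = [Edge("a", "b", 2.0, 3.0), Edge("a", "c", 6.0, 3.0), Edge("b", "c", 10.0, 3.0)]
        mean_f, counts = connection_frequency_stats(edges)
        assert mean_f == pytest.approx(6.0)
        assert counts == {"delta": 1, "theta": 1, "alpha": 1, "beta": 0, "gamma": 0}

    def test_boundary_goes_to_upper_band(self):
        _, counts = connection_frequency_stats([4.0])
        assert counts["theta"] == 1 and counts["delta"] == 0

    def test_top_edge_included_in_gamma(self):
        _, counts = connection_frequency_stats([80.0])
        assert counts["gamma"] == 1

    def test_counts_partition_edges(self):
        rng = np.random.default_rng(0)
        freqs = rng.uniform(1, 80, size=57)
        _, counts = connection_frequency_stats(freqs)
        assert sum(counts.values()) == 57

    def test_empty_edge_set_flagged(self):
        mean_f, counts = connection_frequency_stats([])
        assert math.isnan(mean_f)
        assert all(v == 0 for v in counts.values())
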