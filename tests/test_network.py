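"""Network construction, topology, modules, Zi-Pi roles and random nulls."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pomnet.exceptions import InsufficientSamplesError
from pomnet.network import (AssociationMatrix, EcoNetwork, build_network,
                            classify_role, detect_modules, pearson_matrix,
                            random_null, role_summary, topology_stats, zi_pi)
from pomnet.otu_table import RelativeAbundanceTable


def _net_from_graph(g, threshold=0.9, total_otus=None):
    for _, _, d in g.edges(data=True):
        d.setdefault("weight", 1.0)
        d.setdefault("sign", 1)
    return EcoNetwork(g, threshold, total_otus or g.number_of_nodes())


def _brute_force_pearson(x, y):
    """Textbook Pearson r, written independently of numpy.corrcoef."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def _partitions(nodes):
    """All set partitions of ``nodes`` (Bell-number enumeration)."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _brute_force_max_modularity(g):
    best = -1.0
    for part in _partitions(sorted(g.nodes)):
        q = nx.community.modularity(g, [set(c) for c in part])
        best = max(best, q)
    return best


class TestPearsonMatrix:
    def test_duplicated_row_gives_r_one(self):
        rng = np.random.default_rng(0)
        base = rng.random(8)
        df = pd.DataFrame([base, base, rng.random(8)],
                          index=["A", "Acopy", "B"])
        df = df / df.sum(axis=0)
        m = pearson_matrix(RelativeAbundanceTable(df))
        i, j = m.otu_ids.index("A"), m.otu_ids.index("Acopy")
        assert m.values[i, j] == pytest.approx(1.0)

    def test_negated_row_gives_r_minus_one(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = 6.0 - x  # reflection around the mean
        df = pd.DataFrame([x, y], index=["A", "B"])
        df = df / df.sum(axis=0)
        m = pearson_matrix(RelativeAbundanceTable(df))
        assert m.values[0, 1] == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((5, 10)),
                          index=[f"O{i}" for i in range(5)])
        df = df / df.sum(axis=0)
        m = pearson_matrix(RelativeAbundanceTable(df))
        arr = df.to_numpy()
        for i in range(5):
            for j in range(i + 1, 5):
                assert m.values[i, j] == pytest.approx(
                    _brute_force_pearson(arr[i], arr[j]), abs=1e-12)

    def test_constant_rows_excluded(self):
        df = pd.DataFrame([[0.2] * 5, [0.3, 0.2, 0.4, 0.1, 0.3],
                           [0.5, 0.6, 0.4, 0.7, 0.5]],
                          index=["const", "A", "B"])
        df = df / df.sum(axis=0)
        # renormalization perturbs 'const'; construct directly instead
        vals = np.array([[0.2] * 5, [0.3, 0.2, 0.4, 0.1, 0.3]])
        vals = np.vstack([vals, 1 - vals.sum(axis=0)])
        df = pd.DataFrame(vals, index=["const", "A", "B"])
        m = pearson_matrix(RelativeAbundanceTable(df))
        assert "const" not in m.otu_ids

    def test_log10_transform_flag_preserves_monotone_structure(self):
        rng = np.random.default_rng(6)
        base = rng.random(10)
        df = pd.DataFrame([base, base * 2, rng.random(10)],
                          index=["A", "B", "C"])
        df = df / df.sum(axis=0)
        m = pearson_matrix(RelativeAbundanceTable(df), log10_pseudo=1e-6)
        assert m.values[0, 1] > 0.9  # proportional rows stay correlated
        with pytest.raises(ValueError, match="pseudo"):
            pearson_matrix(RelativeAbundanceTable(df), log10_pseudo=0.0)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["A", "B"])
        with pytest.raises(InsufficientSamplesError):
            pearson_matrix(RelativeAbundanceTable(df))


class TestBuildNetwork:
    def _matrix(self, entries, ids):
        n = len(ids)
        v = np.eye(n)
        for (i, j), r in entries.items():
            v[i, j] = v[j, i] = r
        return AssociationMatrix(v, ids, 10)

    def test_threshold_one_with_no_perfect_correlation(self):
        m = self._matrix({(0, 1): 0.99}, ["A", "B"])
        net = build_network(m, 1.0)
        assert net.n_links == 0 and net.total_otus == 2

    def test_signed_thresholding(self):
        m = self._matrix({(0, 1): 0.95, (0, 2): -0.96, (1, 2): 0.2},
                         ["A", "B", "C"])
        net = build_network(m, 0.9)
        assert net.n_nodes == 3 and net.n_links == 2
        stats = topology_stats(net)
        assert stats.positive_links == 1 and stats.negative_links == 1

    def test_isolated_otus_excluded_from_nodes(self):
        m = self._matrix({(0, 1): 0.95}, ["A", "B", "C", "D"])
        net = build_network(m, 0.9)
        assert net.total_otus == 4 and net.n_nodes == 2


def test_graphml_export_carries_node_attributes(tmp_path):
    net = _net_from_graph(
        nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3)))
    part = detect_modules(net)
    roles = zi_pi(net, part)
    path = tmp_path / "net.graphml"
    net.to_graphml(path, partition=part, roles=roles)
    back = nx.read_graphml(path)
    assert back.number_of_edges() == net.n_links
    some = list(back.nodes(data=True))[0][1]
    assert {"module", "zi", "pi", "role"} <= set(some)


class TestTopologyStats:
    def test_complete_graph_k4(self):
        stats = topology_stats(_net_from_graph(nx.complete_graph(4)))
        assert stats.avg_k == pytest.approx(3.0)
        assert stats.avg_cc == pytest.approx(1.0)
        assert stats.gd == pytest.approx(1.0)

    def test_path_p3(self):
        stats = topology_stats(_net_from_graph(nx.path_graph(3)))
        assert stats.avg_k == pytest.approx(4 / 3)
        assert stats.avg_cc == pytest.approx(0.0)
        assert stats.gd == pytest.approx(4 / 3)

    def test_avg_k_identity_from_printed_counts(self):
        """avgK = 2L/N for node/link counts of study-scale networks."""
        for n, l, expected in [(146, 347, 4.75), (105, 391, 7.45),
                               (99, 452, 9.13), (149, 389, 5.22),
                               (98, 229, 4.67), (92, 263, 5.72)]:
            g = nx.gnm_random_graph(n, l, seed=1)
            stats = topology_stats(_net_from_graph(g))
            assert round(stats.avg_k, 2) == expected

    def test_disconnected_pairs_excluded_from_gd(self):
        g = nx.disjoint_union(nx.path_graph(2), nx.path_graph(3))
        stats = topology_stats(_net_from_graph(g))
        assert stats.gd == pytest.approx((1 + (1 + 1 + 2) / 3 * 3) / 4)

    def test_sign_does_not_change_topology(self):
        g1 = nx.complete_graph(5)
        net_pos = _net_from_graph(g1.copy())
        g2 = nx.complete_graph(5)
        for _, _, d in g2.edges(data=True):
            d["sign"] = -1
            d["weight"] = -1.0
        net_neg = EcoNetwork(g2, 0.9, 5)
        s1, s2 = topology_stats(net_pos), topology_stats(net_neg)
        for f in ("avg_k", "avg_cc", "gd", "total_links", "modularity"):
            assert getattr(s1, f) == getattr(s2, f)
        assert s2.negative_links == s2.total_links


class TestDetectModules:
    def test_two_disjoint_cliques(self):
        net = _net_from_graph(
            nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4)))
        part = detect_modules(net)
        assert part.n_modules == 2
        assert part.modularity == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        part = detect_modules(_net_from_graph(nx.complete_graph(6)))
        assert part.n_modules == 1
        assert part.modularity == pytest.approx(0.0)

    def test_three_disjoint_triangles(self):
        net = _net_from_graph(
            nx.disjoint_union_all([nx.cycle_graph(3)] * 3))
        part = detect_modules(net)
        assert part.n_modules == 3
        assert part.modularity == pytest.approx(2 / 3)

    @pytest.mark.parametrize("maker", [
        lambda: nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4)),
        lambda: nx.cycle_graph(6),
        lambda: nx.barbell_graph(4, 1),
        lambda: nx.star_graph(6),
        lambda: nx.gnm_random_graph(8, 13, seed=5),
        lambda: nx.gnm_random_graph(9, 12, seed=7),
    ])
    def test_matches_exhaustive_partition_oracle(self, maker):
        """Greedy Q equals (or is within 0.05 of) the brute-force optimum."""
        g = maker()
        g.remove_nodes_from(list(nx.isolates(g)))
        part = detect_modules(_net_from_graph(g))
        best = _brute_force_max_modularity(g)
        assert part.modularity <= best + 1e-12
        assert part.modularity >= best - 0.05

    def test_deterministic_partition(self):
        g = nx.gnm_random_graph(12, 20, seed=3)
        nets = [_net_from_graph(g.copy()) for _ in range(2)]
        p1, p2 = (detect_modules(n) for n in nets)
        assert p1.module_of == p2.module_of


class TestZiPi:
    def test_all_links_inside_module_gives_pi_zero(self):
        net = _net_from_graph(nx.complete_graph(4))
        part = detect_modules(net)
        roles = zi_pi(net, part)
        assert (roles["pi"] == 0.0).all()

    def test_even_spread_over_four_modules(self):
        g = nx.star_graph(4)  # hub 0 + leaves 1..4
        net = _net_from_graph(g)
        from pomnet.network import ModulePartition
        part = ModulePartition({0: 0, 1: 1, 2: 2, 3: 3, 4: 0}, 4, 0.0)
        roles = zi_pi(net, part)
        assert roles.loc[0, "pi"] == pytest.approx(0.75)
        assert roles.loc[0, "role"] == "connector"

    def test_half_split_is_peripheral(self):
        g = nx.Graph([(0, 1), (0, 2)])
        net = _net_from_graph(g)
        from pomnet.network import ModulePartition
        part = ModulePartition({0: 0, 1: 0, 2: 1}, 2, 0.0)
        roles = zi_pi(net, part)
        assert roles.loc[0, "pi"] == pytest.approx(0.5)
        assert roles.loc[0, "role"] == "peripheral"  # 0.5 < 0.62

    def test_zi_standardized_within_modules(self):
        rng = np.random.default_rng(2)
        g = nx.gnm_random_graph(30, 80, seed=9)
        g.remove_nodes_from(list(nx.isolates(g)))
        net = _net_from_graph(g)
        part = detect_modules(net)
        roles = zi_pi(net, part)
        for mid, sub in roles.groupby("module"):
            kin_sd = sub["zi"].std(ddof=0)
            if len(sub) > 1 and sub["zi"].abs().sum() > 0:
                assert sub["zi"].mean() == pytest.approx(0.0, abs=1e-9)
                assert kin_sd == pytest.approx(1.0, abs=1e-9)

    def test_pi_bounded_by_module_count(self):
        g = nx.gnm_random_graph(25, 60, seed=4)
        g.remove_nodes_from(list(nx.isolates(g)))
        net = _net_from_graph(g)
        part = detect_modules(net)
        roles = zi_pi(net, part)
        assert (roles["pi"] <= 1 - 1 / part.n_modules + 1e-12).all()


class TestRoles:
    @pytest.mark.parametrize("zi,pi,role", [
        (3.0, 0.30, "module hub"),
        (1.0, 0.70, "connector"),
        (2.5, 0.62, "network hub"),   # both thresholds inclusive
        (2.49, 0.61, "peripheral"),
        (2.5, 0.61, "module hub"),
        (2.49, 0.62, "connector"),
    ])
    def test_quadrant_rule_with_boundaries(self, zi, pi, role):
        assert classify_role(zi, pi) == role

    def test_summary_counts_all_roles(self):
        df = pd.DataFrame({"role": ["module hub", "peripheral",
                                    "peripheral", "connector"]})
        s = role_summary(df)
        assert s["network hub"] == 0
        assert s["peripheral"] == 2


class TestRandomNull:
    def test_degree_sequence_preserved(self):
        g = nx.gnm_random_graph(20, 40, seed=0)
        g.remove_nodes_from(list(nx.isolates(g)))
        net = _net_from_graph(g)
        obs_degrees = sorted(d for _, d in g.degree())
        from pomnet.network import _double_edge_swap
        h = g.copy()
        rng = np.random.default_rng(1)
        accepted = _double_edge_swap(h, 50 * h.number_of_edges(), rng)
        assert accepted > 0
        assert sorted(d for _, d in h.degree()) == obs_degrees
        assert h.number_of_edges() == g.number_of_edges()

    def test_complete_graph_null_sd_zero(self):
        net = _net_from_graph(nx.complete_graph(5))
        null = random_null(net, n_rand=5, seed=0)
        assert null.null_sd["avg_cc"] == pytest.approx(0.0)
        assert null.null_mean["avg_cc"] == pytest.approx(1.0)

    def test_modular_network_q_exceeds_null(self):
        """Planted modular graphs sit far above their rewired nulls."""
        g = nx.disjoint_union_all([nx.complete_graph(8)] * 4)
        # sparsely connect the cliques so rewiring can mix them
        for a, b in [(0, 8), (8, 16), (16, 24), (24, 0)]:
            g.add_edge(a, b)
        net = _net_from_graph(g)
        null = random_null(net, n_rand=20, seed=3, swaps_per_link=20)
        gap = (null.observed["modularity"] - null.null_mean["modularity"])
        assert gap > 3 * null.null_sd["modularity"]
        assert null.p_values["modularity"] < 0.1
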