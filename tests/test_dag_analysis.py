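"""CPDAG conversion, separators/modules, partial correlation, centrality,
knockout response, and the length-two overlap test."""

import itertools

import networkx as nx
import numpy as np
import pytest

from latentdag import dag_analysis as da
from latentdag import network_io as nio
from latentdag import synthetic_data as sd
from latentdag.containers import DagNetwork, GeneNetwork, PerturbationDataset

from conftest import make_expression


# ---------------------------------------------------------------------------
# CPDAG


def all_dags(nodes):
    """Every DAG over the given nodes (exhaustive)."""
    pairs = list(itertools.combinations(nodes, 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (u, v), s in zip(pairs, states):
            if s == 1:
                edges.add((u, v))
            elif s == 2:
                edges.add((v, u))
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield frozenset(edges)


def skeleton_of(edges):
    return frozenset(frozenset(e) for e in edges)


def vstructs_of(edges, nodes):
    adj = {(u, v) for u, v in edges} | {(v, u) for u, v in edges}
    parents = {z: {u for u, v in edges if v == z} for z in nodes}
    out = set()
    for z in nodes:
        for x, y in itertools.combinations(sorted(parents[z]), 2):
            if (x, y) not in adj:
                out.add((x, y, z))
    return frozenset(out)


def compelled_by_enumeration(dag_edges, nodes):
    """Oracle: an edge is compelled iff every Markov-equivalent DAG (same
    skeleton + same v-structures) orients it the same way."""
    skel = skeleton_of(dag_edges)
    vs = vstructs_of(dag_edges, nodes)
    cls = [
        e
        for e in all_dags(nodes)
        if skeleton_of(e) == skel and vstructs_of(e, nodes) == vs
    ]
    compelled = set()
    for u, v in dag_edges:
        if all((u, v) in e for e in cls):
            compelled.add((u, v))
    return frozenset(compelled)


class TestToCpdag:
    def test_collider_stays_directed(self):
        dag = DagNetwork(gene_ids=("1", "2", "3"), edges={("1", "3"), ("2", "3")})
        cp = da.to_cpdag(dag)
        assert cp.directed_edges == frozenset({("1", "3"), ("2", "3")})
        assert cp.undirected_edges == frozenset()

    def test_chain_fully_undirected(self):
        dag = DagNetwork(gene_ids=("1", "2", "3"), edges={("1", "2"), ("2", "3")})
        cp = da.to_cpdag(dag)
        assert cp.directed_edges == frozenset()
        assert cp.undirected_edges == frozenset({("1", "2"), ("2", "3")})

    def test_single_edge_undirected(self):
        dag = DagNetwork(gene_ids=("1", "2"), edges={("1", "2")})
        cp = da.to_cpdag(dag)
        assert cp.undirected_edges == frozenset({("1", "2")})

    def test_matches_equivalence_class_oracle_up_to_4_nodes(self):
        nodes = ("a", "b", "c", "d")
        for edges in all_dags(nodes):
            dag = DagNetwork(gene_ids=nodes, edges=edges)
            cp = da.to_cpdag(dag)
            oracle = compelled_by_enumeration(edges, nodes)
            assert cp.directed_edges == oracle, f"failed on {sorted(edges)}"
            assert cp.skeleton_edges() == frozenset(
                (min(u, v), max(u, v)) for u, v in edges
            )


# ---------------------------------------------------------------------------
# Communities


class TestLeidenCommunities:
    def test_two_cliques_split(self):
        genes = tuple(f"g{i}" for i in range(10))
        edges = set()
        for grp in (genes[:5], genes[5:]):
            edges |= {tuple(sorted(p)) for p in itertools.combinations(grp, 2)}
        edges.add(("g0", "g5"))
        net = GeneNetwork(genes=genes, edges=frozenset(edges))
        comm = da.leiden_communities(net, seed=1)
        assert len(set(comm.values())) == 2
        assert len({comm[g] for g in genes[:5]}) == 1
        assert len({comm[g] for g in genes[5:]}) == 1

    def test_single_clique_one_community(self):
        genes = tuple(f"g{i}" for i in range(6))
        edges = frozenset(tuple(sorted(p)) for p in itertools.combinations(genes, 2))
        comm = da.leiden_communities(GeneNetwork(genes=genes, edges=edges), seed=1)
        assert len(set(comm.values())) == 1

    def test_isolated_nodes_own_communities(self):
        net = GeneNetwork(genes=("a", "b", "c"), edges=frozenset())
        comm = da.leiden_communities(net, seed=1)
        assert len(set(comm.values())) == 3


# ---------------------------------------------------------------------------
# Separators / modules


def path_network(n):
    genes = tuple(f"g{i:02d}" for i in range(n))
    edges = frozenset((genes[i], genes[i + 1]) for i in range(n - 1))
    return GeneNetwork(genes=genes, edges=edges)


class TestSeparators:
    def test_path15_center_only(self):
        net = path_network(15)
        seps = da.find_separators(net, min_component_size=7)
        assert [r.gene for r in seps] == ["g07"]
        assert sorted(len(c) for c in seps[0].components) == [7, 7]

    def test_star_center_not_separator(self):
        genes = ("hub",) + tuple(f"leaf{i}" for i in range(14))
        edges = frozenset(("hub", l) for l in genes[1:])
        net = GeneNetwork(genes=genes, edges=edges)
        assert da.find_separators(net, min_component_size=7) == []

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(10, 41))
            m = int(rng.integers(n - 1, 2 * n))
            g = nx.gnm_random_graph(n, min(m, n * (n - 1) // 2), seed=trial)
            genes = tuple(f"g{i}" for i in range(n))
            net = GeneNetwork(
                genes=genes,
                edges=frozenset((genes[a], genes[b]) for a, b in g.edges()),
            )
            found = {r.gene for r in da.find_separators(net, 3)}
            # brute force over every node of the main component
            gg = net.to_networkx()
            main = max(nx.connected_components(gg), key=len)
            sub = gg.subgraph(main)
            expect = set()
            for node in main:
                h = sub.copy()
                h.remove_node(node)
                comps = list(nx.connected_components(h))
                if len(comps) >= 2 and all(len(c) >= 3 for c in comps):
                    expect.add(node)
            assert found == expect

    def test_modules_from_path15(self):
        net = path_network(15)
        seps = da.find_separators(net, 7)
        mods = da.extract_modules(net, seps)
        assert len(mods) == 1
        assert len(mods[0].genes) == 7
        assert mods[0].separators == frozenset({"g07"})

    def test_no_separators_no_modules(self):
        genes = tuple("abc")
        net = GeneNetwork(
            genes=genes, edges=frozenset([("a", "b"), ("b", "c"), ("a", "c")])
        )
        assert da.extract_modules(net, da.find_separators(net, 1)) == []

    def test_module_plus_separator_reconnects(self):
        net = path_network(15)
        mods = da.extract_modules(net, da.find_separators(net, 7))
        g = net.to_networkx()
        keep = set(mods[0].genes) | set(mods[0].separators) | (
            set(net.genes) - set(mods[0].genes)
        )
        assert nx.is_connected(g.subgraph(keep))


# ---------------------------------------------------------------------------
# Partial correlation


class TestPartialCorrelation:
    def test_empty_conditioning_is_pearson(self, chain_expression):
        r = da.partial_correlation(chain_expression, "g1", "g2")
        expect = np.corrcoef(
            chain_expression.values[:, 0], chain_expression.values[:, 1]
        )[0, 1]
        assert r == pytest.approx(expect, abs=1e-12)

    def test_first_order_recursion_formula(self):
        # construct Gaussian data with known correlations via Cholesky
        R = np.array([[1.0, 0.5, 0.6], [0.5, 1.0, 0.7], [0.6, 0.7, 1.0]])
        L = np.linalg.cholesky(R)
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(200000, 3)) @ L.T
        X = make_expression(Z, ("x", "y", "z"))
        r = da.partial_correlation(X, "x", "y", ["z"])
        expect = (0.5 - 0.6 * 0.7) / np.sqrt((1 - 0.36) * (1 - 0.49))
        assert r == pytest.approx(expect, abs=0.01)

    def test_chain_conditional_independence(self):
        rng = np.random.default_rng(1)
        n = 5000
        x = rng.normal(size=n)
        z = 0.8 * x + 0.6 * rng.normal(size=n)
        y = 0.7 * z + rng.normal(size=n)
        X = make_expression(np.column_stack([x, z, y]), ("x", "z", "y"))
        assert abs(da.partial_correlation(X, "x", "y", ["z"])) < 0.05

    def test_matches_precision_matrix_formula(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(500, 6))
        X = make_expression(Z)
        genes = list(X.gene_ids)
        # oracle: partial correlation from the inverse covariance of the
        # involved columns
        cols = [0, 1, 2, 3]
        P = np.linalg.inv(np.cov(Z[:, cols], rowvar=False))
        expect = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        got = da.partial_correlation(X, genes[0], genes[1], [genes[2], genes[3]])
        assert got == pytest.approx(expect, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(6)
        Z = rng.normal(size=(300, 4))
        Z[:, 1] += 0.5 * Z[:, 0] + 0.3 * Z[:, 2]
        X = make_expression(Z, ("a", "b", "c", "d"))
        got = da.partial_correlation(X, "a", "b", ["c", "d"])
        df = pd.DataFrame(Z, columns=["a", "b", "c", "d"])
        ref = pg.partial_corr(df, x="a", y="b", covar=["c", "d"])["r"].iloc[0]
        assert got == pytest.approx(ref, abs=1e-9)

    def test_conditioning_gene_overlap_rejected(self, chain_expression):
        with pytest.raises(ValueError):
            da.partial_correlation(chain_expression, "g1", "g2", ["g1"])


class TestModuleIndependence:
    @pytest.fixture()
    def separator_sem(self):
        """Module {m1, m2} connects to the rest {o1, o2} only through s."""
        genes = ("m1", "m2", "s", "o1", "o2")
        W = np.zeros((5, 5))
        W[0, 1] = 0.8   # m1 -> m2
        W[0, 2] = 0.9   # m1 -> s
        W[2, 3] = 0.9   # s -> o1
        W[3, 4] = 0.8   # o1 -> o2
        gt = sd.GroundTruth(weights=W, gene_ids=genes, noise_sd=np.ones(5))
        return sd.simulate_expression(gt, 2000, seed=3)

    def test_partial_below_plain(self, separator_sem):
        rep = da.module_independence_report(
            separator_sem, ["m1", "m2"], ["s"], ["o1", "o2"]
        )
        assert rep.mean_abs_partial < rep.mean_abs_plain
        t, p = rep.paired_reduction_test()
        assert p < 0.01

    def test_single_pair(self, separator_sem):
        rep = da.module_independence_report(separator_sem, ["m1"], ["s"], ["o1"])
        assert len(rep.pairs) == 1

    def test_empty_separator_set_partial_equals_plain(self, separator_sem):
        rep = da.module_independence_report(
            separator_sem, ["m1", "m2"], [], ["o1", "o2"]
        )
        assert np.allclose(rep.plain_r, rep.partial_r)


# ---------------------------------------------------------------------------
# Centrality, shells


class TestBetweennessAndShells:
    def test_path3_middle(self):
        net = path_network(3)
        bt = da.betweenness(net, normalized=False)
        assert bt["g01"] == 1.0

    def test_complete_graph_zero(self):
        genes = tuple("abcd")
        edges = frozenset(tuple(sorted(p)) for p in itertools.combinations(genes, 2))
        bt = da.betweenness(GeneNetwork(genes=genes, edges=edges))
        assert all(v == 0.0 for v in bt.values())

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = int(rng.integers(5, 13))
            g = nx.gnm_random_graph(n, int(rng.integers(n, 2 * n)), seed=trial)
            genes = tuple(f"g{i}" for i in range(n))
            net = GeneNetwork(
                genes=genes,
                edges=frozenset((genes[a], genes[b]) for a, b in g.edges()),
            )
            got = da.betweenness(net)
            # oracle: enumerate all shortest paths per pair
            expect = {x: 0.0 for x in genes}
            gg = net.to_networkx()
            for s, t in itertools.combinations(genes, 2):
                try:
                    paths = list(nx.all_shortest_paths(gg, s, t))
                except nx.NetworkXNoPath:
                    continue
                for p in paths:
                    for mid in p[1:-1]:
                        expect[mid] += 1.0 / len(paths)
            for x in genes:
                assert got[x] == pytest.approx(expect[x], abs=1e-9)

    def test_star_shells(self):
        genes = ("hub", "l1", "l2", "far")
        edges = frozenset([("hub", "l1"), ("hub", "l2")])
        net = GeneNetwork(genes=genes, edges=edges)
        labels = da.neighbor_shells(net, seeds=["hub"])
        assert labels == {"hub": "seed", "l1": "shell1", "l2": "shell1", "far": "other"}

    def test_path_two_shells(self):
        net = path_network(5)
        labels = da.neighbor_shells(net, seeds=["g00"])
        assert labels["g01"] == "shell1"
        assert labels["g02"] == "shell2"
        assert labels["g03"] == "other"


# ---------------------------------------------------------------------------
# Knockout response


class TestKnockoutResponse:
    def make_pd(self, ctrl, means):
        return PerturbationDataset(
            gene_ids=("A", "B"), control=ctrl, condition_means=means
        )

    def test_zero_when_equal_to_control_mean(self, rng):
        ctrl = rng.normal(loc=2.0, size=(100, 2))
        means = {"B": np.array([ctrl[:, 0].mean(), 0.0])}
        pdset = self.make_pd(ctrl, means)
        assert da.knockout_response(pdset, "A", "B") == pytest.approx(0.0)

    def test_two_sd_above(self, rng):
        ctrl = rng.normal(size=(200, 2))
        mu = ctrl[:, 0].mean()
        s = ctrl[:, 0].std(ddof=1)
        pdset = self.make_pd(ctrl, {"B": np.array([mu + 2 * s, 0.0])})
        assert da.knockout_response(pdset, "A", "B") == pytest.approx(2.0)

    def test_chain_propagation(self, chain_truth):
        pdset = sd.simulate_perturbation_dataset(
            chain_truth, knockdown_shift=-5.0, seed=6
        )
        z = da.knockout_response(pdset, "g2", "g1")
        sd_a = pdset.control[:, 1].std(ddof=1)
        assert z == pytest.approx(-4.0 / sd_a, abs=0.25)

    def test_zero_sd_rejected(self):
        pdset = self.make_pd(
            np.column_stack([np.ones(10), np.arange(10.0)]),
            {"B": np.array([1.0, 0.0])},
        )
        with pytest.raises(ValueError):
            da.knockout_response(pdset, "A", "B")


# ---------------------------------------------------------------------------
# Length-two overlap test


class TestOverlapTest:
    def test_observed_single_path(self):
        base = GeneNetwork(genes=("a", "b", "c"), edges=frozenset([("a", "b")]))
        rep = GeneNetwork(genes=("a", "b", "c"), edges=frozenset([("b", "c")]))
        lat = GeneNetwork(genes=("a", "b", "c"), edges=frozenset([("a", "c")]))
        out = da.length_two_overlap_test(base, rep, lat, n_random=20, seed=0)
        assert out.observed == 1

    def test_empty_latentdag_zero_and_degenerate_null(self):
        base = GeneNetwork(genes=("a", "b", "c"), edges=frozenset([("a", "b")]))
        rep = GeneNetwork(genes=("a", "b", "c"), edges=frozenset([("b", "c")]))
        lat = GeneNetwork(genes=("a", "b", "c"), edges=frozenset())
        from latentdag.dag_analysis import _length_two_overlap_count
        from latentdag.network_io import combine_networks

        assert _length_two_overlap_count(combine_networks([base, rep]), lat) == 0
        # an all-zero null distribution is degenerate and must be reported
        with pytest.raises(ValueError, match="degenerate"):
            da.length_two_overlap_test(base, rep, lat, n_random=20, seed=0)

    def test_z_and_p_hand_formula(self):
        from scipy.stats import norm

        z = (10 - 4) / 2
        assert z == 3.0
        assert norm.sf(z) == pytest.approx(0.00135, abs=2e-5)

    def test_null_latentdag_rarely_significant(self):
        rng = np.random.default_rng(9)
        genes = tuple(f"g{i}" for i in range(40))
        base = nio.random_network(40, 60, seed=1, genes=genes)
        rep = nio.random_network(40, 60, seed=2, genes=genes)
        n_extreme = 0
        reps = 20
        for k in range(reps):
            lat = nio.random_network(40, 30, seed=100 + k, genes=genes)
            out = da.length_two_overlap_test(
                base, rep, lat, n_random=30, seed=int(rng.integers(2**31))
            )
            if abs(out.z) >= 3:
                n_extreme += 1
        assert n_extreme <= reps * 0.05 + 1


# ---------------------------------------------------------------------------
# Ranking


class TestRanking:
    def test_top_on_both_is_first(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(100, 5))
        vals[:, 2] = vals[:, 2] * 5 + 10
        X = make_expression(vals)
        assert da.rank_by_expression_and_variance(X)[0] == "g2"

    def test_identical_genes_id_ordered(self):
        v = np.random.default_rng(4).normal(size=(50, 1))
        X = make_expression(np.column_stack([v, v]), ("b", "a"))
        order = da.rank_by_expression_and_variance(X)
        assert order == ["a", "b"]

    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(80, 10)) * rng.uniform(0.5, 3, size=10)
        X = make_expression(vals)
        got = da.rank_by_expression_and_variance(X)
        from scipy.stats import rankdata

        mean_abs = np.abs(vals).mean(axis=0)
        var = vals.var(axis=0, ddof=1)
        rs = rankdata(-mean_abs) + rankdata(-var)
        expect = [g for _, g in sorted(zip(rs, X.gene_ids))]
        assert got == expect
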