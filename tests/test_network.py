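"""Interaction-network loading, density nulls and module detection."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from irescan import network as N
from irescan.synthetic import generate_planted_partition


def write_edges(tmp_path, rows):
    p = tmp_path / "edges.tsv"
    p.write_text(
        "node1\tnode2\tcombined_score\n"
        + "\n".join("\t".join(map(str, r)) for r in rows)
        + "\n"
    )
    return p


class TestLoadInteractions:
    def test_duplicate_edges_keep_max_score(self, tmp_path):
        g = N.load_interactions(
            write_edges(tmp_path, [("a", "b", 900), ("b", "a", 700)])
        )
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["combined_score"] == 900

    def test_self_loops_dropped(self, tmp_path):
        g = N.load_interactions(write_edges(tmp_path, [("a", "a", 999)]))
        assert g.number_of_edges() == 0

    def test_min_score_filter(self, tmp_path):
        g = N.load_interactions(
            write_edges(tmp_path, [("a", "b", 150), ("b", "c", 500)]),
            min_score=400,
        )
        assert list(g.edges()) == [("b", "c")]

    def test_missing_column_is_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("x\ty\n1\t2\n")
        with pytest.raises(ValueError, match="missing"):
            N.load_interactions(p)


class TestDensity:
    def test_triangle_is_complete(self):
        assert N.density(nx.complete_graph(3)) == 1.0

    def test_path_density(self):
        assert N.density(nx.path_graph(3)) == pytest.approx(2 / 3)

    def test_isolated_nodes(self):
        g = nx.empty_graph(10)
        assert N.density(g) == 0.0

    def test_too_small_is_error(self):
        with pytest.raises(ValueError):
            N.density(nx.empty_graph(1))


class TestNullDensity:
    def test_complete_graph_null_is_one(self):
        g = nx.complete_graph(20)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(20)})
        null = N.simulate_null_density(
            g, list(g.nodes()), m=5, reps=50,
            rng=np.random.default_rng(0), fit_boxcox=False,
        )
        assert np.all(null.densities == 1.0)

    def test_empty_graph_null_is_zero(self):
        g = nx.Graph()
        universe = [f"g{i}" for i in range(30)]
        null = N.simulate_null_density(
            g, universe, m=5, reps=50, rng=np.random.default_rng(0),
            fit_boxcox=False,
        )
        assert np.all(null.densities == 0.0)

    def test_er_graph_null_mean_matches_binomial_expectation(self):
        p_edge = 0.05
        g = nx.fast_gnp_random_graph(200, p_edge, seed=1)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes()})
        reps = 2000
        null = N.simulate_null_density(
            g, list(g.nodes()), m=50, reps=reps, rng=np.random.default_rng(2)
        )
        se = null.densities.std(ddof=1) / np.sqrt(reps)
        true_density = N.density(g)  # realized edge fraction of this graph
        assert abs(null.mean_density - true_density) < 3 * se + 1e-4

    def test_absent_genes_dilute_density(self):
        g = nx.complete_graph(10)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(10)})
        universe = list(g.nodes()) + [f"x{i}" for i in range(40)]
        null = N.simulate_null_density(
            g, universe, m=10, reps=300, rng=np.random.default_rng(3),
            fit_boxcox=False,
        )
        assert null.mean_density < 0.5

    def test_se_shrinks_with_replicates(self):
        g = nx.fast_gnp_random_graph(100, 0.1, seed=4)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes()})
        means = []
        for reps in (1000, 4000):
            boot = [
                N.simulate_null_density(
                    g, list(g.nodes()), m=20, reps=reps,
                    rng=np.random.default_rng(seed), fit_boxcox=False,
                ).mean_density
                for seed in range(8)
            ]
            means.append(np.std(boot))
        assert means[1] < means[0]


class TestBoxCox:
    def test_normal_samples_lambda_near_one(self):
        x = np.random.default_rng(0).normal(loc=20, scale=2, size=10_000)
        _, lmbda, _ = N.boxcox_transform(x)
        assert lmbda == pytest.approx(1.0, abs=0.3)

    def test_lognormal_samples_lambda_near_zero(self):
        x = np.exp(np.random.default_rng(1).normal(size=10_000))
        _, lmbda, _ = N.boxcox_transform(x)
        assert lmbda == pytest.approx(0.0, abs=0.15)

    def test_shift_makes_data_positive(self):
        x = np.concatenate([np.zeros(50), np.random.default_rng(2).uniform(size=50)])
        shift, _, transformed = N.boxcox_transform(x)
        assert shift > 0 and np.all(np.isfinite(transformed))

    def test_constant_samples_error(self):
        with pytest.raises(ValueError):
            N.boxcox_transform(np.ones(20))


class TestDensityPvalue:
    def _null(self, seed=0):
        g = nx.fast_gnp_random_graph(150, 0.08, seed=seed)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes()})
        return g, N.simulate_null_density(
            g, list(g.nodes()), m=25, reps=2000, rng=np.random.default_rng(seed)
        )

    def test_center_gives_half(self):
        _, null = self._null()
        med = float(np.median(null.densities))
        assert N.density_pvalue(med, null) == pytest.approx(0.5, abs=0.1)

    def test_far_tail_is_small(self):
        _, null = self._null()
        assert N.density_pvalue(null.densities.max() * 2 + 0.2, null) < 0.01

    def test_null_calibration_is_uniform(self):
        # p-values of draws from the null itself pass a KS test vs U(0,1)
        _, null = self._null(seed=5)
        rng = np.random.default_rng(6)
        draws = rng.choice(null.densities, size=500, replace=False)
        ps = np.array([N.density_pvalue(d, null) for d in draws])
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01


class TestLouvain:
    def test_two_cliques_joined_by_one_edge(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        part = N.louvain_modules(g, seed=0)
        assert part.n_modules == 2
        assert len({part.assignment[f"n{i}"] for i in range(6)}) == 1

    def test_single_clique_is_one_module(self):
        g = nx.relabel_nodes(nx.complete_graph(8), {i: f"n{i}" for i in range(8)})
        assert N.louvain_modules(g, seed=0).n_modules == 1

    def test_planted_partition_recovery(self):
        g, truth = generate_planted_partition([20] * 5, p_in=0.3, p_out=0.02, seed=7)
        part = N.louvain_modules(g, seed=7)
        nodes = sorted(g.nodes())
        ari = adjusted_rand_score(
            [truth[n] for n in nodes], [part.assignment[n] for n in nodes]
        )
        assert ari >= 0.8

    def test_modularity_beats_trivial_partition(self):
        g, _ = generate_planted_partition([15] * 3, p_in=0.4, p_out=0.05, seed=8)
        part = N.louvain_modules(g, seed=8)
        trivial = nx.community.modularity(g, [set(g.nodes())])
        assert part.modularity >= trivial


class TestModuleReport:
    def test_star_degrees(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        part = N.louvain_modules(g, seed=0)
        _, degrees = N.module_report(
            g, part, list(g.nodes()), null_reps=50, rng=np.random.default_rng(0)
        )
        by_gene = degrees.set_index("gene_id")["degree"]
        assert by_gene["n0"] == 5 and (by_gene.drop("n0") == 1).all()

    def test_triangle_module_density_one(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e")])
        part = N.ModulePartition(
            assignment={"a": 1, "b": 1, "c": 1, "d": 2, "e": 2},
            modularity=0.0, seed=None,
        )
        modules, _ = N.module_report(
            g, part, list("abcde") + [f"x{i}" for i in range(20)],
            null_reps=100, rng=np.random.default_rng(1),
        )
        assert modules.set_index("module").loc[1, "density"] == 1.0

    def test_singleton_module_flagged_excluded(self):
        g = nx.Graph([("a", "b")])
        g.add_node("c")
        part = N.ModulePartition(
            assignment={"a": 1, "b": 1, "c": 2}, modularity=0.0, seed=None
        )
        modules, _ = N.module_report(
            g, part, ["a", "b", "c"] + [f"x{i}" for i in range(10)],
            null_reps=50, rng=np.random.default_rng(2),
        )
        row = modules.set_index("module").loc[2]
        assert bool(row["excluded"]) and np.isnan(row["density"])
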