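import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.sparse.csgraph import floyd_warshall

from rhizonet.network import (CoreTaxaResult, EdgeRule, build_network,
                              core_taxa, networks_per_scope,
                              prevalence_filter, spearman_matrix, topology)
from rhizonet.tables_io import CountTable, StudyDesign, ValidationError


def _design(treatments, reps):
    rows, idx = [], []
    for t in treatments:
        for r in range(1, reps + 1):
            rows.append((t, r))
            idx.append(f"{t}_r{r}")
    return StudyDesign(pd.DataFrame(rows, columns=["treatment", "replicate"],
                                    index=idx), tuple(treatments))


class TestEdgeRule:
    @pytest.mark.parametrize("kwargs", [
        {"min_abs_r": 0.0}, {"min_abs_r": 1.0}, {"max_p": 0.0},
        {"prevalence": 0.0}, {"prevalence": 1.5}, {"scope": "everywhere"},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            EdgeRule(**kwargs)


class TestPrevalenceFilter:
    def _table(self, presence_counts, n_samples=6):
        rows = {}
        for name, k in presence_counts.items():
            rows[name] = [1] * k + [0] * (n_samples - k)
        counts = pd.DataFrame(rows).T
        counts.columns = [f"control_r{i + 1}" for i in range(n_samples)]
        lineages = pd.Series({n: f"p__X;g__{n}" for n in rows})
        return CountTable(counts, lineages)

    def test_strictly_more_than_threshold(self):
        table = self._table({"keep5": 5, "drop4": 4, "zero": 0})
        design = _design(["control"], 6)
        retained = prevalence_filter(table, design, EdgeRule())
        assert retained["control"] == ["keep5"]  # 5/6 > 0.8, 4/6 not

    def test_boundary_is_exclusive(self):
        # exactly 80% present must be dropped (strict "more than")
        table = self._table({"exact": 8, "above": 9}, n_samples=10)
        design = _design(["control"], 10)
        retained = prevalence_filter(table, design, EdgeRule())
        assert retained["control"] == ["above"]


class TestSpearmanMatrix:
    def test_perfect_monotone(self):
        df = pd.DataFrame([[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1],
                           [2, 4, 6, 8, 10, 12]],
                          index=["up", "down", "up2"], dtype=float)
        rho, p = spearman_matrix(df)
        assert rho.loc["up", "up2"] == pytest.approx(1.0)
        assert rho.loc["up", "down"] == pytest.approx(-1.0)
        assert p.loc["up", "up2"] < 1e-6

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 9)
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            df = pd.DataFrame([x, y], index=["x", "y"])
            rho, _ = spearman_matrix(df)
            oracle = stats.pearsonr(stats.rankdata(x),
                                    stats.rankdata(y)).statistic
            assert rho.loc["x", "y"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_reported_missing(self):
        df = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]],
                          index=["const", "x"], dtype=float)
        rho, p = spearman_matrix(df)
        assert np.isnan(rho.loc["const", "x"])
        assert np.isnan(p.loc["const", "x"])

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        n = 5
        x = rng.random(n)
        y = rng.random(n)
        df = pd.DataFrame([x, y], index=["x", "y"])
        rho, p = spearman_matrix(df, method="exact")
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(stats.pearsonr(rx, ry).statistic)
        null = [abs(stats.pearsonr(rx[list(pm)], ry).statistic)
                for pm in itertools.permutations(range(n))]
        expected = np.mean(np.array(null) >= obs - 1e-12)
        assert p.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_edge_set_rank_invariance(self, default_study):
        # strictly monotone per-genus transform must not change the network
        from rhizonet.community import relative_abundance
        props = relative_abundance(default_study.counts)
        sub = props.iloc[:15, :12]
        rho1, p1 = spearman_matrix(sub)
        rho2, p2 = spearman_matrix(np.exp(5 * sub))
        g1 = build_network(rho1, p1, EdgeRule())
        g2 = build_network(rho2, p2, EdgeRule())
        assert set(g1.edges) == set(g2.edges)


class TestBuildNetwork:
    def _mats(self, rho_val, p_val):
        idx = pd.Index(["a", "b"])
        rho = pd.DataFrame([[1.0, rho_val], [rho_val, 1.0]],
                           index=idx, columns=idx)
        p = pd.DataFrame([[np.nan, p_val], [p_val, np.nan]],
                         index=idx, columns=idx)
        return rho, p

    def test_boundary_rho_excluded(self):
        g = build_network(*self._mats(0.6, 0.001), EdgeRule())
        assert g.number_of_edges() == 0

    def test_strong_significant_pair_included_with_sign(self):
        g = build_network(*self._mats(0.95, 0.001), EdgeRule())
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["sign"] == "+"

    def test_negative_edge_sign(self):
        g = build_network(*self._mats(-0.95, 0.001), EdgeRule())
        assert g["a"]["b"]["sign"] == "-"

    def test_isolated_nodes_dropped_by_default(self):
        idx = pd.Index(["a", "b", "c"])
        rho = pd.DataFrame(np.eye(3), index=idx, columns=idx)
        rho.loc["a", "b"] = rho.loc["b", "a"] = 0.9
        p = pd.DataFrame(0.001, index=idx, columns=idx)
        g = build_network(rho, p, EdgeRule())
        assert set(g.nodes) == {"a", "b"}
        g_keep = build_network(rho, p, EdgeRule(), drop_isolated=False)
        assert set(g_keep.nodes) == {"a", "b", "c"}


class TestTopology:
    @pytest.mark.parametrize("n,e,expected", [
        (41, 76, 3.707), (44, 99, 4.500), (31, 61, 3.935),
        (40, 106, 5.30), (31, 121, 7.806), (71, 178, 5.014)])
    def test_average_degree_identity(self, n, e, expected):
        g = nx.gnm_random_graph(n, e, seed=42)
        rep = topology(g, seed=0)
        assert round(rep.average_degree, 3) == pytest.approx(expected,
                                                             abs=5e-3)

    def test_triangle_closed_form(self):
        rep = topology(nx.cycle_graph(3))
        assert rep.average_degree == 2.0
        assert rep.average_clustering == 1.0
        assert rep.average_path_length == 1.0
        assert rep.diameter == 1.0
        assert rep.modularity == pytest.approx(0.0, abs=1e-12)

    def test_empty_graph_metrics_undefined(self):
        rep = topology(nx.Graph())
        assert rep.nodes == 0 and rep.edges == 0
        assert np.isnan(rep.average_path_length) and np.isnan(rep.diameter)

    def test_path_metrics_match_floyd_warshall(self):
        rng = np.random.default_rng(0)
        for trial in range(40):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.7),
                                    seed=int(rng.integers(1 << 30)))
            rep = topology(g, seed=0)
            d = floyd_warshall(nx.to_scipy_sparse_array(g, weight=None),
                               unweighted=True)
            finite = d[np.isfinite(d) & (d > 0)]
            if finite.size == 0:
                assert np.isnan(rep.average_path_length)
            else:
                assert rep.average_path_length == pytest.approx(finite.mean(),
                                                                abs=1e-12)
                assert rep.diameter == pytest.approx(finite.max(), abs=0)

    def test_modularity_bounded_by_exhaustive_optimum(self):
        def best_partition_modularity(g):
            nodes = list(g.nodes)
            best = -1.0
            # enumerate set partitions (restricted growth strings)
            def grow(i, labels, kmax):
                nonlocal best
                if i == len(nodes):
                    comms = {}
                    for node, lab in zip(nodes, labels):
                        comms.setdefault(lab, set()).add(node)
                    q = nx.community.modularity(g, list(comms.values()))
                    best = max(best, q)
                    return
                for lab in range(kmax + 1):
                    grow(i + 1, labels + [lab], max(kmax, lab + 1))
            grow(1, [0], 1)
            return best

        rng = np.random.default_rng(1)
        for trial in range(6):
            n = int(rng.integers(5, 8))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            rep = topology(g, seed=0)
            assert rep.modularity <= best_partition_modularity(g) + 1e-9

    def test_one_community_partition_has_zero_modularity(self):
        g = nx.gnm_random_graph(10, 20, seed=3)
        q = nx.community.modularity(g, [set(g.nodes)])
        assert q == pytest.approx(0.0, abs=1e-12)


class TestCoreTaxa:
    def test_star_center_is_unique_core(self):
        res = core_taxa(nx.star_graph(5), q=0.9)
        assert res.core == [0]

    def test_path_middle_core_at_median_quantile(self):
        g = nx.path_graph(5)
        res = core_taxa(g, q=0.5)
        assert 2 in res.core
        # BFS closeness oracle for the middle node
        assert res.table.loc[2, "closeness"] == pytest.approx(4 / 6)

    def test_core_nested_in_quantile(self):
        g = nx.gnm_random_graph(30, 60, seed=5)
        strict = set(core_taxa(g, q=1.0).core)
        loose = set(core_taxa(g, q=0.9).core)
        assert strict <= loose

    def test_empty_graph_empty_result(self):
        res = core_taxa(nx.Graph())
        assert res.table.empty and res.core == []

    def test_deterministic(self, default_study):
        nets = networks_per_scope(default_study.counts, default_study.design,
                                  EdgeRule())
        g = nets["control"]
        a = core_taxa(g, q=0.9).table
        b = core_taxa(g, q=0.9).table
        pd.testing.assert_frame_equal(a, b)


def test_networks_per_scope_produces_six_treatment_networks(default_study):
    nets = networks_per_scope(default_study.counts, default_study.design,
                              EdgeRule())
    assert set(nets) == set(default_study.design.treatments)
    for g in nets.values():
        assert not any(True for _ in nx.selfloop_edges(g))
        for _, _, d in g.edges(data=True):
            assert abs(d["rho"]) > 0.6 and d["p"] < 0.05
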