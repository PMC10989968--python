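import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micronar.conet import (bh_adjust, spearman_all_pairs, call_edges,
                            extract_island_subnetworks, load_edge_list,
                            write_edge_list)
from micronar.tables_io import OtuTable, SampleMetadata


def corr_of(matrix, **kw):
    return spearman_all_pairs(np.asarray(matrix, dtype=float), **kw)


class TestSpearman:
    def test_closed_form_example(self):
        # d = (1,1,1,1) wait: ranks differ by (1,-1,1,-1); sum d^2 = 4
        x = np.array([[1, 2], [2, 1], [3, 4], [4, 3]], dtype=float)
        res = corr_of(x)
        assert res.rho[0, 1] == pytest.approx(1 - 6 * 4 / (4 * 15), abs=1e-12)
        assert res.rho[0, 1] == pytest.approx(0.6)

    def test_monotone_map_gives_one(self):
        x = np.linspace(0, 1, 10)
        mat = np.column_stack([x, np.exp(3 * x)])
        assert corr_of(mat).rho[0, 1] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mat = rng.normal(size=(10, 2))
            res = corr_of(mat)
            rx = stats.rankdata(mat[:, 0])
            ry = stats.rankdata(mat[:, 1])
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert res.rho[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_pvalues_match_scipy(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(25, 6))
        res = corr_of(mat)
        ref_r, ref_p = stats.spearmanr(mat)
        assert res.rho == pytest.approx(ref_r, abs=1e-12)
        assert res.pval == pytest.approx(ref_p, abs=1e-9)

    def test_zero_variance_otu_never_edges(self, caplog):
        mat = np.column_stack([np.arange(8.0), np.full(8, 3.0),
                               np.arange(8.0) ** 2])
        with caplog.at_level("WARNING"):
            res = corr_of(mat)
        assert np.isnan(res.rho[0, 1]) and np.isnan(res.rho[1, 2])
        assert "zero-variance" in caplog.text
        g = call_edges(res, rho_min=0.0, alpha=1.0)
        assert "OTU1" not in g.nodes
        assert g.has_edge("OTU0", "OTU2")

    def test_exact_permutation_pvalue(self):
        from itertools import permutations
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(6, 3))
        res = corr_of(mat, pvalue_method="exact")
        # oracle: enumerate all permutations of one margin
        for i in range(3):
            for j in range(i + 1, 3):
                obs = abs(stats.spearmanr(mat[:, i], mat[:, j]).statistic)
                y = mat[:, j]
                hits = sum(
                    abs(stats.spearmanr(mat[:, i], y[list(p)]).statistic)
                    >= obs - 1e-12
                    for p in permutations(range(6)))
                assert res.pval[i, j] == pytest.approx(hits / 720, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            corr_of(np.zeros((3, 2)))


class TestBhAdjust:
    def test_hand_executed_step_up(self):
        # largest k with p(k) <= k*alpha/m is k=4 -> all rejected at 0.05
        q = bh_adjust(np.array([0.01, 0.02, 0.04, 0.05]))
        assert (q <= 0.05).all()
        assert q == pytest.approx([0.04, 0.04, 0.05, 0.05])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 60)))
            mine = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_qval_at_least_pval(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestCallEdges:
    def test_permissive_thresholds_give_complete_graph(self):
        rng = np.random.default_rng(2)
        res = corr_of(rng.normal(size=(12, 5)))
        g = call_edges(res, rho_min=0.0, alpha=1.0)
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 10

    def test_impossible_threshold_gives_empty(self):
        rng = np.random.default_rng(2)
        res = corr_of(rng.normal(size=(12, 5)))
        g = call_edges(res, rho_min=1.01, alpha=0.05)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 0

    def test_toy_table_matches_pair_enumeration(self):
        # 5 OTUs engineered so a subset of pairs passes the thresholds;
        # compare against brute force over all 10 pairs
        rng = np.random.default_rng(3)
        latent = rng.normal(size=30)
        mat = np.column_stack([
            latent + 0.05 * rng.normal(size=30),
            latent + 0.05 * rng.normal(size=30),
            -latent + 0.05 * rng.normal(size=30),
            rng.normal(size=30),
            rng.normal(size=30),
        ])
        res = corr_of(mat)
        g = call_edges(res, rho_min=0.8, alpha=0.05)
        expected = set()
        iu = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        pvals = np.array([stats.spearmanr(mat[:, i], mat[:, j]).pvalue
                          for i, j in iu])
        from statsmodels.stats.multitest import multipletests
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for (i, j), q in zip(iu, qvals):
            r = stats.spearmanr(mat[:, i], mat[:, j]).statistic
            if abs(r) >= 0.8 and q < 0.05:
                expected.add((f"OTU{i}", f"OTU{j}"))
        assert {tuple(sorted(e)) for e in g.edges} == expected
        assert {tuple(sorted(e)) for e in g.edges} == {
            ("OTU0", "OTU1"), ("OTU0", "OTU2"), ("OTU1", "OTU2")}

    def test_edge_calling_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        res = corr_of(rng.normal(size=(15, 8)))
        loose = {tuple(sorted(e))
                 for e in call_edges(res, rho_min=0.2, alpha=0.5).edges}
        tighter_rho = {tuple(sorted(e))
                       for e in call_edges(res, rho_min=0.4, alpha=0.5).edges}
        tighter_alpha = {tuple(sorted(e))
                         for e in call_edges(res, rho_min=0.2, alpha=0.1).edges}
        assert tighter_rho <= loose
        assert tighter_alpha <= loose

    def test_signed_rho_preserved(self):
        mat = np.column_stack([np.arange(10.0), -np.arange(10.0)])
        g = call_edges(corr_of(mat), rho_min=0.9, alpha=0.05)
        assert g.edges["OTU0", "OTU1"]["rho"] == pytest.approx(-1.0)


def _toy_island_setup():
    # meta-network is a triangle A-B-C
    meta_net = nx.Graph()
    meta_net.add_edge("A", "B", rho=0.9, qval=0.001)
    meta_net.add_edge("B", "C", rho=0.8, qval=0.001)
    meta_net.add_edge("A", "C", rho=0.7, qval=0.001)
    counts = np.array([
        [5, 3, 2, 1],   # island big: everything
        [4, 2, 0, 0],   # island small: only A, B
    ])
    table = OtuTable(["s1", "s2"], ["A", "B", "C", "D"], counts)
    meta = SampleMetadata(pd.DataFrame([
        {"sample_id": "s1", "island_id": "big", "area_m2": 1e4},
        {"sample_id": "s2", "island_id": "small", "area_m2": 1e2},
    ]))
    return meta_net, table, meta


class TestIslandSubnetworks:
    def test_full_island_equals_meta_network(self):
        meta_net, table, meta = _toy_island_setup()
        subs = extract_island_subnetworks(meta_net, table, meta)
        big = next(s for s in subs if s.island_id == "big")
        assert set(big.graph.edges) == set(meta_net.edges)
        assert big.area_m2 == 1e4

    def test_partial_island_induces_single_edge(self):
        meta_net, table, meta = _toy_island_setup()
        subs = extract_island_subnetworks(meta_net, table, meta)
        small = next(s for s in subs if s.island_id == "small")
        assert set(small.graph.nodes) == {"A", "B"}
        assert small.graph.number_of_edges() == 1

    def test_isolated_present_node_excluded(self):
        meta_net = nx.Graph()
        meta_net.add_edge("A", "B", rho=0.9, qval=0.001)
        meta_net.add_edge("C", "D", rho=0.9, qval=0.001)
        counts = np.array([[1, 1, 1, 0]])  # C present but D absent -> C isolated
        table = OtuTable(["s1"], ["A", "B", "C", "D"], counts)
        meta = SampleMetadata(pd.DataFrame(
            [{"sample_id": "s1", "island_id": "I", "area_m2": 1.0}]))
        subs = extract_island_subnetworks(meta_net, table, meta)
        assert set(subs[0].graph.nodes) == {"A", "B"}

    def test_subnetworks_sorted_by_area_and_bounded(self):
        meta_net, table, meta = _toy_island_setup()
        subs = extract_island_subnetworks(meta_net, table, meta)
        assert [s.island_id for s in subs] == ["small", "big"]
        for s in subs:
            assert s.graph.number_of_edges() <= meta_net.number_of_edges()

    def test_unknown_meta_node_rejected(self):
        meta_net, table, meta = _toy_island_setup()
        meta_net.add_edge("A", "ZZZ", rho=0.9, qval=0.01)
        with pytest.raises(ValueError, match="absent from the table"):
            extract_island_subnetworks(meta_net, table, meta)


def test_graphml_round_trip(tmp_path):
    from micronar.conet import write_graphml
    g = nx.Graph()
    g.add_edge("x", "y", rho=0.75, qval=0.01)
    p = tmp_path / "net.graphml"
    write_graphml(g, p)
    back = nx.read_graphml(p)
    assert set(back.edges) == {("x", "y")}
    assert back.edges["x", "y"]["rho"] == pytest.approx(0.75)


def test_edge_list_round_trip(tmp_path):
    g = nx.Graph()
    g.add_edge("x", "y", rho=0.75)
    g.add_edge("y", "z", rho=-0.62)
    p = tmp_path / "edges.tsv"
    write_edge_list(g, p)
    back = load_edge_list(p)
    assert set(back.edges) == set(g.edges)
    assert back.edges["y", "z"]["rho"] == pytest.approx(-0.62)
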