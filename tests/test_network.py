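"""Spearman networks, merging, degree ranking and export."""

import numpy as np
import pandas as pd
import networkx as nx
import pytest

import xhyb
from xhyb import ValidationError
from xhyb.network import import_graphml


def expr_from(array, ids=None, cols=None):
    arr = np.asarray(array, float)
    ids = ids or [f"S{i}" for i in range(arr.shape[0])]
    cols = cols or [f"c{j}" for j in range(arr.shape[1])]
    return xhyb.ExpressionMatrix(
        pd.DataFrame(arr, index=pd.Index(ids, name="probe_set_id"), columns=cols)
    )


def rank_formula_spearman(x, y):
    """Pearson correlation of average ranks, written out directly."""
    def avg_rank(v):
        v = np.asarray(v, float)
        out = np.empty(len(v))
        for i, val in enumerate(v):
            less = (v < val).sum()
            equal = (v == val).sum()
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = avg_rank(x), avg_rank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return (rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum())


def test_spearman_monotone_antitone_and_ties():
    e = expr_from([[1, 2, 3], [3, 5, 9], [9, 5, 3], [1, 2, 2]])
    r = xhyb.spearman_matrix(e)
    assert r.loc["S0", "S1"] == pytest.approx(1.0)
    assert r.loc["S0", "S2"] == pytest.approx(-1.0)

    x = [1.0, 2.0, 2.0, 3.0]
    y = [1.0, 3.0, 3.0, 5.0]
    e2 = expr_from([x, y], cols=list("abcd"))
    r2 = xhyb.spearman_matrix(e2)
    assert r2.loc["S0", "S1"] == pytest.approx(rank_formula_spearman(x, y))


def test_spearman_constant_row_never_an_edge():
    e = expr_from([[1, 2, 3], [5, 5, 5], [2, 4, 6]])
    r = xhyb.spearman_matrix(e)
    assert np.isnan(r.loc["S1", "S0"]) and np.isnan(r.loc["S1", "S2"])
    g = xhyb.build_network(r, threshold=0.5)
    assert g.degree("S1") == 0


def test_spearman_needs_three_samples():
    with pytest.raises(ValidationError):
        xhyb.spearman_matrix(expr_from([[1, 2], [2, 1]]))


def test_perfect_triangle_and_degrees():
    e = expr_from([[1, 2, 3, 4], [2, 3, 5, 9], [0, 1, 2, 3]])
    g = xhyb.build_network(xhyb.spearman_matrix(e), threshold=0.9)
    assert g.number_of_edges() == 3
    assert sorted(dict(g.degree).values()) == [2, 2, 2]


def test_absolute_mode_links_anticorrelated_nodes():
    e = expr_from([[1, 2, 3, 4], [9, 7, 4, 1]])
    corr = xhyb.spearman_matrix(e)
    g_abs = xhyb.build_network(corr, threshold=0.9, mode="absolute")
    g_pos = xhyb.build_network(corr, threshold=0.9, mode="positive")
    assert g_abs.has_edge("S0", "S1")
    assert g_abs.edges["S0", "S1"]["sign"] == -1
    assert not g_pos.has_edge("S0", "S1")


def test_threshold_monotonicity_never_adds_edges():
    rng = np.random.default_rng(11)
    corr_src = expr_from(rng.normal(size=(15, 8)))
    corr = xhyb.spearman_matrix(corr_src)
    prev = None
    for thr in (0.3, 0.5, 0.7, 0.9, 1.0):
        edges = set(map(frozenset, xhyb.build_network(corr, thr).edges))
        if prev is not None:
            assert edges <= prev
        prev = edges
    # threshold 1.0 on noisy data: almost surely empty
    assert len(set(xhyb.build_network(corr, 1.0).edges)) == 0


def test_planted_modules_recovered_at_low_noise():
    layout = xhyb.simulate_layout(200, 11, seed=61)
    truth = xhyb.simulate_truth(
        layout, 10, 0, n_modules=3, module_size=10, seed=62
    )
    sheet = xhyb.simulate_sample_sheet()
    rna = xhyb.simulate_rna(layout, truth, sheet, noise_sd=0.1, seed=63)
    active = sheet.active()
    cols = list(active.loc[active["genotype"] == "DipC", "sample_id"])
    gdna_like = pd.Series(1e9, index=layout.probe_ids)
    mask = xhyb.select_probe_pairs(gdna_like, layout, 0.0, genotype="DipC")
    expr = xhyb.rma_summarize(
        xhyb.ProbeIntensityMatrix(rna.values[cols]), mask, layout
    )
    members = {m: truth.module_members(m) for m in range(3)}
    nodes = sorted(set().union(*members.values()))
    sub = xhyb.ExpressionMatrix(expr.values.loc[nodes])
    net = xhyb.build_network(xhyb.spearman_matrix(sub), threshold=0.9)
    within, between = [], []
    for m, ids in members.items():
        k = len(ids)
        possible = k * (k - 1) / 2
        got = sum(net.has_edge(a, b) for i, a in enumerate(ids) for b in ids[i + 1:])
        within.append(got / possible)
    for m1 in range(3):
        for m2 in range(m1 + 1, 3):
            cross = sum(
                net.has_edge(a, b) for a in members[m1] for b in members[m2]
            )
            between.append(cross / (len(members[m1]) * len(members[m2])))
    assert min(within) >= 0.8
    assert max(between) <= 0.05


def test_merge_disjoint_additive_and_identical_idempotent():
    g1 = nx.Graph()
    g1.add_edge("a", "b", rho=0.95, sign=1)
    nx.set_node_attributes(g1, "A", "genotype_origin")
    g2 = nx.Graph()
    g2.add_edge("c", "d", rho=-0.92, sign=-1)
    nx.set_node_attributes(g2, "B", "genotype_origin")
    merged = xhyb.merge_networks(g1, g2)
    assert merged.number_of_nodes() == 4 and merged.number_of_edges() == 2
    assert merged.nodes["a"]["genotype_origin"] == "A"

    same = xhyb.merge_networks(g1, g1)
    assert set(same.edges) == set(g1.edges)
    assert same.nodes["a"]["genotype_origin"] == "A"


def test_merge_shared_node_origin_both_and_conflict_recorded():
    g1 = nx.Graph()
    g1.add_node("x", genotype_origin="A", direction="up")
    g1.add_node("y", genotype_origin="A")
    g2 = nx.Graph()
    g2.add_node("x", genotype_origin="B", direction="down")
    g2.add_node("z", genotype_origin="B")
    merged = xhyb.merge_networks(g1, g2)
    assert merged.nodes["x"]["genotype_origin"] == "both"
    assert merged.nodes["x"]["direction"] == "conflict"
    assert merged.nodes["y"]["genotype_origin"] == "A"
    assert merged.nodes["z"]["genotype_origin"] == "B"


def test_degree_table_path_and_handshake():
    g = nx.path_graph(["a", "b", "c"])
    table = xhyb.degree_table(g, tf_only=False).set_index("probe_set_id")
    assert table.loc["a", "degree_whole"] == 1
    assert table.loc["b", "degree_whole"] == 2
    assert table.loc["c", "degree_whole"] == 1
    assert table["degree_whole"].sum() == 2 * g.number_of_edges()


def test_degree_table_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(12)
    for trial in range(5):
        g = nx.gnp_random_graph(200, 0.03, seed=int(rng.integers(1e6)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        sub_nodes = set(list(g.nodes)[:80])
        table = xhyb.degree_table(g, sub_nodes, tf_only=False).set_index(
            "probe_set_id"
        )
        edges = list(g.edges)
        for node in g.nodes:
            brute_whole = sum(node in e for e in edges)
            brute_sub = sum(
                node in e and e[0] in sub_nodes and e[1] in sub_nodes
                for e in edges
            )
            if node not in sub_nodes:
                brute_sub = 0
            assert table.loc[node, "degree_whole"] == brute_whole
            assert table.loc[node, "degree_drought"] == brute_sub
        assert (table["degree_drought"] <= table["degree_whole"]).all()
        # sorted descending by whole-network degree
        assert (np.diff(table["degree_whole"].to_numpy()) <= 0).all()


def test_degree_table_subnetwork_nodes_must_exist():
    g = nx.path_graph(["a", "b"])
    with pytest.raises(ValidationError):
        xhyb.degree_table(g, {"zz"}, tf_only=False)


def test_degree_table_tf_filter():
    g = nx.path_graph(["a", "b", "c"])
    nx.set_node_attributes(g, {"a": True, "b": False, "c": False}, "is_tf")
    table = xhyb.degree_table(g, tf_only=True)
    assert list(table["probe_set_id"]) == ["a"]


def test_sif_export_triangle_and_empty(tmp_path):
    g = nx.complete_graph(["a", "b", "c"])
    path = tmp_path / "net.sif"
    xhyb.export_network(g, "sif", path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 3
    assert all(line.split("\t")[1] == "co" for line in lines)

    empty = nx.Graph()
    epath = tmp_path / "empty.sif"
    xhyb.export_network(empty, "sif", epath)
    assert epath.read_text() == ""


def test_graphml_round_trip_preserves_structure_and_attrs(tmp_path):
    g = nx.Graph()
    g.add_node("a", genotype_origin="A", direction="up", is_tf=True, name="WRKY")
    g.add_node("b", genotype_origin="both", direction="down", is_tf=False, name="x")
    g.add_edge("a", "b", rho=0.93, sign=1)
    path = tmp_path / "net.graphml"
    xhyb.export_network(g, "graphml", path)
    back = import_graphml(path)
    assert set(back.nodes) == {"a", "b"}
    assert back.nodes["a"]["is_tf"] is True
    assert back.nodes["a"]["name"] == "WRKY"
    assert back.edges["a", "b"]["rho"] == pytest.approx(0.93)
    assert back.edges["a", "b"]["sign"] == 1
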