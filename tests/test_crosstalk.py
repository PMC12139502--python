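"""Crosstalk networks: BFS path lengths, Mann-Whitney statistic, builder filters."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardatlas import path_length_test, receptor_tf_path_lengths, build_crosstalk_network
from cardatlas.crosstalk import (
    CrosstalkError,
    _u_statistic,
    graph_from_edges,
    paths_to_frame,
)
from cardatlas.io import GeneSetCollection


def chain_graph(*nodes):
    g = nx.Graph()
    nx.add_path(g, nodes)
    return g


# ---------------------------------------------------------------------------
# shortest-path lengths
# ---------------------------------------------------------------------------

def test_path_lengths_examples():
    g = chain_graph("R", "a", "b", "TF")
    tab, summary = receptor_tf_path_lengths(g, ["R"], ["TF"])
    assert tab.length.tolist() == [3]
    adj, _ = receptor_tf_path_lengths(chain_graph("R", "TF"), ["R"], ["TF"])
    assert adj.length.tolist() == [1]
    same, _ = receptor_tf_path_lengths(chain_graph("R", "x"), ["R"], ["R"])
    assert same.length.tolist() == [0] and bool(same.identical.iloc[0])


def test_path_lengths_unreachable_counted():
    g = nx.Graph()
    g.add_edge("R", "a")
    g.add_node("TF")
    tab, summary = receptor_tf_path_lengths(g, ["R"], ["TF"])
    assert len(tab) == 0
    assert summary["n_unreachable"] == 1


def _floyd_warshall(g):
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for a, b in g.edges:
        dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return nodes, dist


def test_bfs_lengths_match_floyd_warshall_oracle():
    rng = np.random.default_rng(17)
    for _ in range(20):
        n = int(rng.integers(5, 50))
        g = nx.gnp_random_graph(n, 0.12, seed=int(rng.integers(1 << 30)))
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        nodes, dist = _floyd_warshall(g)
        idx = {v: i for i, v in enumerate(nodes)}
        receptors = nodes[: max(1, n // 4)]
        tfs = nodes[-max(1, n // 4):]
        tab, _ = receptor_tf_path_lengths(g, receptors, tfs)
        got = {(r.receptor, r.tf): r.length for r in tab.itertuples(index=False)}
        for r in receptors:
            for t in tfs:
                d = dist[idx[r], idx[t]]
                if np.isinf(d):
                    assert (r, t) not in got
                else:
                    assert got[(r, t)] == int(d)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mw_exact_spec_example():
    t = path_length_test([1, 2], [3, 4])
    assert t.u_statistic == 0
    assert t.p_value == pytest.approx(1 / 6)
    assert t.method == "exact"


def test_mw_identical_samples_not_significant():
    t = path_length_test([1, 2, 3], [1, 2, 3])
    assert t.p_value >= 0.5


def test_mw_empty_sample_errors():
    with pytest.raises(CrosstalkError):
        path_length_test([], [1])


def _rank_sum_enumeration(x, y):
    """Oracle: permutation tail of the rank-sum statistic (midranks)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        hits += ranks[list(comb)].sum() <= w_obs + 1e-9
        total += 1
    return hits / total


def test_mw_exact_matches_permutation_enumeration_all_small_splits():
    """Exact p equals full rank-sum enumeration for every split with n+m <= 12."""
    rng = np.random.default_rng(31)
    for total in range(2, 13):
        for n in range(1, total):
            m = total - n
            x = rng.integers(0, 5, size=n).astype(float)  # ties on purpose
            y = rng.integers(0, 5, size=m).astype(float)
            t = path_length_test(x, y)
            assert t.method == "exact"
            assert t.p_value == pytest.approx(_rank_sum_enumeration(x, y), abs=1e-12), (n, m)


def test_mw_matches_scipy_on_tie_free_data():
    rng = np.random.default_rng(4)
    x = rng.normal(size=5)
    y = rng.normal(1.0, size=6)
    t = path_length_test(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="less", method="exact")
    assert t.u_statistic == pytest.approx(ref.statistic)
    assert t.p_value == pytest.approx(ref.pvalue, abs=1e-12)
    xb = rng.normal(size=30)
    yb = rng.normal(0.5, size=40)
    tb = path_length_test(xb, yb)
    refb = stats.mannwhitneyu(xb, yb, alternative="less", method="asymptotic")
    assert tb.p_value == pytest.approx(refb.pvalue, rel=1e-9)


def test_u_statistic_tie_handling():
    assert _u_statistic(np.array([1.0, 2.0]), np.array([2.0, 3.0])) == 0.5


# ---------------------------------------------------------------------------
# network builder
# ---------------------------------------------------------------------------

def _builder_inputs():
    # chain L - R - a - TF, plus padding genes for a workable ORA universe
    edges = pd.DataFrame({"a": ["R", "a"], "b": ["a", "TF"]})
    graph = graph_from_edges(edges)
    lr = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
    ligand_calls = pd.DataFrame(
        {"feature": ["L"], "group": ["CF"], "rule": ["enriched_ligand"],
         "statistic": [2.0], "threshold": [1.5], "passed": [True]}
    )
    pathway_sets = GeneSetCollection({"PW": frozenset({"R", "a", "TF"})})
    universe = {"R", "a", "TF"} | {f"pad{i}" for i in range(12)}
    tftg = pd.DataFrame({"tf": ["TF", "TF"], "target": ["tg1", "tg2"]})
    return dict(
        ligand_calls=ligand_calls,
        receptor_detection={"CM": {"R"}},
        lr_pairs=lr,
        graph=graph,
        cts_tfs={"TF"},
        tftg=tftg,
        pathway_sets=pathway_sets,
        universe=universe,
        target_celltype="CM",
    )


def test_builder_assembles_expected_path():
    paths = build_crosstalk_network(**_builder_inputs())
    assert len(paths) == 1
    p = paths[0]
    assert p.path_nodes == ("R", "a", "TF")
    assert p.length == 2
    assert p.tgs == {"tg1", "tg2"}
    assert p.enriched_pathways[0][0] == "PW"
    frame = paths_to_frame(paths)
    assert frame.loc[0, "path"] == "R|a|TF"


def test_builder_filters():
    # (i) ligand not enriched anywhere
    args = _builder_inputs()
    args["ligand_calls"] = args["ligand_calls"].assign(passed=[False])
    assert build_crosstalk_network(**args) == []
    # ligand enriched only in the target cell-type itself does not count
    args = _builder_inputs()
    args["ligand_calls"] = args["ligand_calls"].assign(group=["CM"])
    assert build_crosstalk_network(**args) == []
    # (ii) receptor not detected in the target proteome
    args = _builder_inputs()
    args["receptor_detection"] = {"CM": set()}
    assert build_crosstalk_network(**args) == []
    # (iii) no enriched pathway on the branch
    args = _builder_inputs()
    args["pathway_sets"] = GeneSetCollection({"PW": frozenset({"pad1", "pad2"})})
    assert build_crosstalk_network(**args) == []
    # unreachable TF emits nothing
    args = _builder_inputs()
    args["graph"].add_node("TF2")
    args["cts_tfs"] = {"TF2"}
    assert build_crosstalk_network(**args) == []


def test_builder_monotone_in_ligand_calls():
    """Shrinking the enriched-ligand set never adds paths."""
    args = _builder_inputs()
    lc = pd.concat(
        [args["ligand_calls"],
         pd.DataFrame({"feature": ["L2"], "group": ["EC"], "rule": ["enriched_ligand"],
                       "statistic": [2.0], "threshold": [1.5], "passed": [True]})],
        ignore_index=True,
    )
    args["lr_pairs"] = pd.DataFrame({"ligand": ["L", "L2"], "receptor": ["R", "R"]})
    args["ligand_calls"] = lc
    full = {(p.ligand, p.tf) for p in build_crosstalk_network(**args)}
    args["ligand_calls"] = lc.assign(passed=[True, False])
    shrunk = {(p.ligand, p.tf) for p in build_crosstalk_network(**args)}
    assert shrunk <= full


def test_builder_skips_receptor_absent_from_graph(caplog):
    args = _builder_inputs()
    args["lr_pairs"] = pd.DataFrame({"ligand": ["L"], "receptor": ["Rghost"]})
    args["receptor_detection"] = {"CM": {"Rghost"}}
    with caplog.at_level("WARNING"):
        assert build_crosstalk_network(**args) == []
    assert "absent from the pathway graph" in caplog.text


def test_graph_from_edges_rejects_self_loop():
    with pytest.raises(CrosstalkError):
        graph_from_edges(pd.DataFrame({"a": ["x"], "b": ["x"]}))
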