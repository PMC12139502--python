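"""Ligand -> receptor -> TF -> target-gene crosstalk networks.

The builder walks a hierarchical signalling model of cell-cell communication:
a ligand enriched in a source cell-type binds a receptor detected in the
target cell-type's proteome; from the receptor, signal propagates through an
(undirected) pathway graph to transcription factors, each of which drags in
its target genes. A receptor->TF route is kept only when the nodes of its
shortest path are significantly enriched for at least one named pathway
(hypergeometric p < 0.05 against the detected-proteome universe).

The headline statistic compares unweighted shortest-path lengths from
receptors to *cell-type-specific* TFs against lengths to *all* detected TFs
with a one-sided Mann-Whitney U test (alternative: specific paths shorter).
The p-value is exact — full permutation enumeration, ties included — when the
two samples hold at most 12 values combined, and a tie- and continuity-
corrected normal approximation otherwise; the method used is recorded.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ora_table
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "CrosstalkPath",
    "PathLengthTest",
    "receptor_tf_path_lengths",
    "path_length_test",
    "build_crosstalk_network",
    "graph_from_edges",
]

EXACT_LIMIT = 12  # combined sample size up to which the MW p is enumerated exactly


class CrosstalkError(ValueError):
    pass


def graph_from_edges(edges: pd.DataFrame, directed: bool = False) -> nx.Graph:
    """Build a simple pathway graph from a (a, b[, pathway]) edge list.

    Self-loops are rejected; duplicate edges collapse silently (simple graph).
    """
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    cols = list(edges.columns)
    for row in edges.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            raise CrosstalkError(f"self-loop on node {a!r}")
        attrs = {"pathway": str(row[2])} if len(cols) > 2 and pd.notna(row[2]) else {}
        g.add_edge(a, b, **attrs)
    return g


# ---------------------------------------------------------------------------
# shortest-path lengths
# ---------------------------------------------------------------------------

def receptor_tf_path_lengths(
    graph: nx.Graph, receptors, tfs
) -> tuple[pd.DataFrame, dict]:
    """BFS shortest-path edge counts for every (receptor, TF) pair.

    Unreachable pairs (and endpoints absent from the graph) are omitted from
    the table and counted in the summary. A receptor that is itself a TF gets
    length 0 and is flagged.
    """
    receptors = sorted(set(receptors))
    tfs = sorted(set(tfs))
    rows = []
    unreachable = 0
    missing = 0
    for r in receptors:
        if r not in graph:
            missing += len(tfs)
            continue
        dist = nx.single_source_shortest_path_length(graph, r)
        for t in tfs:
            if t not in graph:
                missing += 1
            elif t in dist:
                rows.append({"receptor": r, "tf": t, "length": dist[t], "identical": r == t})
            else:
                unreachable += 1
    table = pd.DataFrame(rows, columns=["receptor", "tf", "length", "identical"])
    summary = {
        "n_pairs": len(table),
        "n_unreachable": unreachable,
        "n_missing_endpoint": missing,
    }
    return table, summary


# ---------------------------------------------------------------------------
# one-sided Mann-Whitney U (specific < all)
# ---------------------------------------------------------------------------

@dataclass
class PathLengthTest:
    lengths_specific: list[float]
    lengths_all: list[float]
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"
    n: int = field(init=False)
    m: int = field(init=False)

    def __post_init__(self) -> None:
        self.n = len(self.lengths_specific)
        self.m = len(self.lengths_all)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{x_i > y_j} + 0.5 #{x_i == y_j} (small U means 'x smaller')."""
    xs = np.sort(x)
    less = np.searchsorted(xs, y, side="left")  # per y: how many x strictly below
    leq = np.searchsorted(xs, y, side="right")
    greater = x.size - leq
    return float(np.sum(greater) + 0.5 * np.sum(leq - less))


def _exact_p(pooled: np.ndarray, n: int, u_obs: float) -> float:
    """P(U <= u_obs) over all C(n+m, n) assignments of the pooled values."""
    idx = range(len(pooled))
    count = 0
    total = 0
    for comb in itertools.combinations(idx, n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        count += u <= u_obs + 1e-12
        total += 1
    return count / total


def path_length_test(lengths_specific, lengths_all) -> PathLengthTest:
    """One-sided Mann-Whitney U: are the specific path lengths shorter?

    Exact permutation p when n + m <= 12; otherwise a normal approximation
    with tie correction and continuity correction. The 'all' sample may
    contain the specific sample (the conventional specific-vs-all reading);
    shared observations only make the test conservative.
    """
    x = np.asarray(list(lengths_specific), dtype=float)
    y = np.asarray(list(lengths_all), dtype=float)
    if x.size == 0 or y.size == 0:
        raise CrosstalkError("both samples must be non-empty")
    u = _u_statistic(x, y)
    n, m = x.size, y.size
    if n + m <= EXACT_LIMIT:
        p = _exact_p(np.concatenate([x, y]), n, u)
        method = "exact"
    else:
        pooled = np.concatenate([x, y])
        N = n + m
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (N * (N - 1))
        var = n * m / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            p = 1.0  # all values identical: no evidence of a shift
        else:
            z = (u - n * m / 2.0 + 0.5) / math.sqrt(var)
            p = float(stats.norm.cdf(z))
        method = "normal-approximation"
    return PathLengthTest(
        lengths_specific=list(x),
        lengths_all=list(y),
        u_statistic=u,
        p_value=float(p),
        method=method,
    )


# ---------------------------------------------------------------------------
# network builder
# ---------------------------------------------------------------------------

@dataclass
class CrosstalkPath:
    ligand: str
    receptor: str
    source_celltype: str
    target_celltype: str
    tf: str
    path_nodes: tuple[str, ...]
    length: int
    tgs: frozenset[str]
    enriched_pathways: tuple[tuple[str, float], ...]


def _lexicographic_shortest_path(graph: nx.Graph, source: str, target: str) -> list[str] | None:
    """BFS shortest path, ties resolved by lexicographic node order."""
    if source not in graph or target not in graph:
        return None
    if source == target:
        return [source]
    parent = {source: None}
    frontier = [source]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in sorted(graph.neighbors(node)):
                if nb not in parent:
                    parent[nb] = node
                    if nb == target:
                        path = [nb]
                        while parent[path[-1]] is not None:
                            path.append(parent[path[-1]])
                        return path[::-1]
                    nxt.append(nb)
        frontier = nxt
    return None


def build_crosstalk_network(
    ligand_calls: pd.DataFrame,
    receptor_detection: dict[str, frozenset[str] | set[str]],
    lr_pairs: pd.DataFrame,
    graph: nx.Graph,
    cts_tfs,
    tftg: pd.DataFrame,
    pathway_sets: GeneSetCollection,
    universe,
    target_celltype: str,
    alpha: float = 0.05,
) -> list[CrosstalkPath]:
    """Assemble ligand->receptor->TF->TG paths into the target cell-type.

    Retains a (ligand, receptor) pair when the ligand passed the enriched-
    ligand rule in some cell-type other than the target and the receptor is
    detected in the target cell-type's proteome. For each retained pair and
    each TF in ``cts_tfs`` reachable from the receptor, the receptor->TF
    shortest-path node set is tested against ``pathway_sets`` (universe =
    detected proteome) and the path is kept when at least one pathway reaches
    p < alpha. Target genes are attached from the TF->TG map. Receptors absent
    from the graph are skipped with a logged warning.
    """
    enriched = ligand_calls[(ligand_calls["rule"] == "enriched_ligand") & ligand_calls["passed"]]
    ligand_sources: dict[str, set[str]] = {}
    for row in enriched.itertuples(index=False):
        ligand_sources.setdefault(str(row.feature), set()).add(str(row.group))

    detected = frozenset(receptor_detection.get(target_celltype, frozenset()))
    tg_map: dict[str, set[str]] = {}
    for row in tftg.itertuples(index=False):
        tg_map.setdefault(str(row[0]), set()).add(str(row[1]))

    cts_tfs = sorted(set(cts_tfs))
    universe = frozenset(universe)
    paths: list[CrosstalkPath] = []
    for row in lr_pairs.itertuples(index=False):
        ligand, receptor = str(row[0]), str(row[1])
        sources = {c for c in ligand_sources.get(ligand, set()) if c != target_celltype}
        if not sources:
            continue  # filter (i): ligand not enriched in a non-target cell-type
        if receptor not in detected:
            continue  # filter (ii): receptor not detected in the target proteome
        if receptor not in graph:
            logger.warning("receptor %s absent from the pathway graph; pair skipped", receptor)
            continue
        dist = nx.single_source_shortest_path_length(graph, receptor)
        for tf in cts_tfs:
            if tf not in dist:
                continue  # unreachable
            nodes = _lexicographic_shortest_path(graph, receptor, tf)
            assert nodes is not None and len(nodes) - 1 == dist[tf]
            ora = ora_table(frozenset(nodes), pathway_sets, universe)
            hits = ora[ora["p_value"] < alpha]
            if not len(hits):
                continue  # filter (iii): no significantly enriched pathway on the branch
            for source in sorted(sources):
                paths.append(
                    CrosstalkPath(
                        ligand=ligand,
                        receptor=receptor,
                        source_celltype=source,
                        target_celltype=target_celltype,
                        tf=tf,
                        path_nodes=tuple(nodes),
                        length=len(nodes) - 1,
                        tgs=frozenset(tg_map.get(tf, set())),
                        enriched_pathways=tuple(
                            (str(r.set), float(r.p_value)) for r in hits.itertuples(index=False)
                        ),
                    )
                )
    return paths


def paths_to_frame(paths: list[CrosstalkPath]) -> pd.DataFrame:
    rows = [
        {
            "ligand": p.ligand,
            "receptor": p.receptor,
            "source_celltype": p.source_celltype,
            "target_celltype": p.target_celltype,
            "tf": p.tf,
            "length": p.length,
            "path": "|".join(p.path_nodes),
            "n_tgs": len(p.tgs),
            "tgs": ";".join(sorted(p.tgs)),
            "top_pathway": p.enriched_pathways[0][0] if p.enriched_pathways else "",
            "top_pathway_p": p.enriched_pathways[0][1] if p.enriched_pathways else float("nan"),
        }
        for p in paths
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ligand", "receptor", "source_celltype", "target_celltype", "tf",
            "length", "path", "n_tgs", "tgs", "top_pathway", "top_pathway_p",
        ],
    )


def write_sif(paths: list[CrosstalkPath], path) -> None:
    """Export the network in Cytoscape SIF (node relation node) format."""
    lines = set()
    for p in paths:
        lines.add(f"{p.ligand}\tligand_receptor\t{p.receptor}")
        for a, b in zip(p.path_nodes, p.path_nodes[1:]):
            lines.add(f"{a}\tpathway\t{b}")
        for tg in sorted(p.tgs):
            lines.add(f"{p.tf}\ttf_tg\t{tg}")
    with open(path, "w") as fh:
        fh.write("".join(f"{line}\n" for line in sorted(lines)))


def write_graphml(paths: list[CrosstalkPath], path) -> None:
    g = nx.DiGraph()
    for p in paths:
        g.add_node(p.ligand, role="ligand", celltype=p.source_celltype)
        g.add_node(p.receptor, role="receptor", celltype=p.target_celltype)
        g.add_node(p.tf, role="tf")
        g.add_edge(p.ligand, p.receptor, relation="ligand_receptor")
        for a, b in zip(p.path_nodes, p.path_nodes[1:]):
            g.add_edge(a, b, relation="pathway")
        for tg in sorted(p.tgs):
            g.add_node(tg, role="tg")
            g.add_edge(p.tf, tg, relation="tf_tg")
    nx.write_graphml(g, path)
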