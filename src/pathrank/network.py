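"""Pathway interaction subnetworks and significance-weighted betweenness.

For each significant gene set the induced subgraph of a STRING-style
interactome is extracted.  Every edge is scored by the logarithm (base 10)
of the geometric mean of the BH-adjusted p-values of its two endpoint
genes:

    log_gm_score = (log10 p_u + log10 p_v) / 2

Shortest-path algorithms need positive weights, and this log score is
non-positive, so the traversal cost defaults to the geometric mean itself,
``sqrt(p_u * p_v)`` — strictly positive and order-isomorphic to the log
score, so minimum-cost paths preferentially run through significant genes.
An additive alternative ("shifted_log": the log score shifted to be
positive) is available; the literal log score is always kept as an edge
annotation.

Node and edge betweenness are computed by Brandes-style single-source
shortest-path accumulation with fractional counting over all minimum-cost
paths (relative tie tolerance 1e-9 for floating-point path costs), at two
scopes: once on the full cost-weighted interactome ("global", the node
width of the published network figures) and once within each pathway
subnetwork ("pathway", the node height).
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .diffexp import P_FLOOR
from .preprocess import DomainError, InputError

logger = logging.getLogger("pathrank.network")

DEFAULT_SCORE_CUTOFF = 400  # STRING medium confidence
COST_TRANSFORMS = ("gm", "shifted_log")
SHIFTED_LOG_EPS = 1e-6
TIE_REL_TOL = 1e-9


@dataclass
class PathwayNetwork:
    """Induced pathway subgraph with node/edge annotations.

    Node attributes: logfc, p_adj, rank, betweenness_pathway,
    betweenness_global.  Edge attributes: combined_score, log_gm_score,
    cost, betweenness_edge.
    """

    parent_set: str
    graph: nx.Graph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


# ---------------------------------------------------------------------------
# Interactome loading and subnetwork extraction
# ---------------------------------------------------------------------------

def load_interactome(
    path: str | Path,
    score_cutoff: int = DEFAULT_SCORE_CUTOFF,
    case_insensitive: bool = False,
) -> nx.Graph:
    """Read a STRING-style TSV (node1, node2, combined_score) into a simple
    undirected graph, keeping edges with score >= cutoff.

    Self-loops are dropped with a warning; duplicate edges keep the maximum
    score.  Identifiers are matched case-sensitively unless
    ``case_insensitive`` (then uppercased).
    """
    graph = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise InputError(f"{path}: empty interactome file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            u, v, raw_score = fields[0], fields[1], fields[2]
            try:
                score = int(raw_score)
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer score {raw_score!r}") from exc
            if case_insensitive:
                u, v = u.upper(), v.upper()
            if u == v:
                logger.warning("%s:%d: self-loop on %s dropped", path, lineno, u)
                continue
            if score < score_cutoff:
                continue
            if graph.has_edge(u, v):
                old = graph.edges[u, v]["combined_score"]
                logger.warning(
                    "%s:%d: duplicate edge %s-%s, keeping max score", path, lineno, u, v
                )
                score = max(score, old)
            graph.add_edge(u, v, combined_score=score)
    return graph


def extract_subnetwork(
    interactome: nx.Graph, members: set[str] | frozenset[str], parent_set: str = ""
) -> PathwayNetwork:
    """Induced subgraph on the pathway members present in the interactome.

    Members isolated after induction are kept as degree-0 nodes; an empty
    intersection yields an empty network (logged).
    """
    if not members:
        raise InputError("empty member list")
    present = set(members) & set(interactome.nodes)
    if not present:
        logger.info("pathway %s: no members in interactome", parent_set or "<unnamed>")
    sub = nx.Graph()
    sub.add_nodes_from(sorted(present))
    for u, v, data in interactome.subgraph(present).edges(data=True):
        sub.add_edge(u, v, **data)
    return PathwayNetwork(parent_set=parent_set, graph=sub)


# ---------------------------------------------------------------------------
# Edge costs
# ---------------------------------------------------------------------------

def edge_cost(
    p_u: float,
    p_v: float,
    transform: str = "gm",
    min_log_gm: float | None = None,
    eps: float = SHIFTED_LOG_EPS,
) -> tuple[float, float]:
    """(log10 geometric-mean score, positive traversal cost) for one edge.

    ``transform="gm"`` gives cost sqrt(p_u * p_v); ``"shifted_log"`` gives
    the log score shifted above zero by the network-wide minimum (which the
    caller must supply) plus ``eps``.
    """
    for p in (p_u, p_v):
        if not (0.0 < p <= 1.0):
            raise DomainError(f"p-value {p} outside (0, 1]")
    log_gm = (math.log10(p_u) + math.log10(p_v)) / 2.0
    if transform == "gm":
        cost = math.sqrt(p_u * p_v)
    elif transform == "shifted_log":
        if min_log_gm is None:
            raise InputError("shifted_log transform needs the network-wide minimum log score")
        cost = log_gm - min_log_gm + eps
    else:
        raise InputError(f"unknown cost transform {transform!r}; choose from {COST_TRANSFORMS}")
    return log_gm, cost


def assign_costs(
    graph: nx.Graph, de: pd.DataFrame, transform: str = "gm"
) -> nx.Graph:
    """Annotate every edge in place with log_gm_score and cost.

    Genes absent from the DE table get p_adj = 1 (maximal cost, logged), so
    unmeasured genes never attract shortest paths.  Nodes are annotated with
    their p_adj, logfc and significance rank where available.
    """
    if transform not in COST_TRANSFORMS:
        raise InputError(f"unknown cost transform {transform!r}")
    p_of: dict[str, float] = {}
    missing = 0
    for node in graph.nodes:
        if node in de.index:
            p = float(de.at[node, "p_adj"])
            graph.nodes[node]["logfc"] = float(de.at[node, "logfc"])
            graph.nodes[node]["rank"] = int(de.at[node, "rank"])
        else:
            p = 1.0
            missing += 1
        p_of[node] = max(p, P_FLOOR)
        graph.nodes[node]["p_adj"] = p_of[node]
    if missing:
        logger.info("%d interactome genes missing from DE table: p_adj set to 1", missing)

    log_scores = {
        (u, v): (math.log10(p_of[u]) + math.log10(p_of[v])) / 2.0
        for u, v in graph.edges
    }
    min_log = min(log_scores.values(), default=0.0)
    for (u, v), log_gm in log_scores.items():
        _, cost = edge_cost(p_of[u], p_of[v], transform, min_log_gm=min_log)
        graph.edges[u, v]["log_gm_score"] = log_gm
        graph.edges[u, v]["cost"] = cost
    return graph


# ---------------------------------------------------------------------------
# Weighted betweenness (Brandes accumulation with tie tolerance)
# ---------------------------------------------------------------------------

def weighted_betweenness(
    graph: nx.Graph, weight: str = "cost", rel_tol: float = TIE_REL_TOL
) -> tuple[dict, dict]:
    """Node and edge betweenness under minimum-total-cost paths.

    For every unordered node pair all minimum-cost paths are counted
    fractionally; endpoints are excluded from their own pairs; disconnected
    pairs contribute nothing.  Path-cost ties are detected with relative
    tolerance ``rel_tol`` to absorb floating-point summation error.
    Unnormalized counts are returned (a star center over k leaves scores
    C(k, 2)).
    """
    for u, v, data in graph.edges(data=True):
        w = data.get(weight, 1.0)
        if not (w > 0):
            raise DomainError(f"edge {u}-{v} has non-positive cost {w}")

    node_bt = {v: 0.0 for v in graph.nodes}
    edge_bt = {tuple(sorted((u, v))): 0.0 for u, v in graph.edges}
    counter = itertools.count()

    for source in graph.nodes:
        # Dijkstra with fractional path counting
        dist: dict = {}
        sigma = {source: 1.0}
        preds: dict = {source: []}
        settled_order = []
        settled = set()
        heap = [(0.0, next(counter), source)]
        tentative = {source: 0.0}
        while heap:
            d, _, u = heapq.heappop(heap)
            if u in settled:
                continue
            settled.add(u)
            dist[u] = d
            settled_order.append(u)
            for v, data in graph.adj[u].items():
                if v in settled:
                    continue
                nd = d + data.get(weight, 1.0)
                tol = rel_tol * max(1.0, abs(nd))
                old = tentative.get(v)
                if old is None or nd < old - tol:
                    tentative[v] = nd
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (nd, next(counter), v))
                elif abs(nd - old) <= tol:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        # Brandes back-propagation of pair dependencies
        delta = {v: 0.0 for v in settled_order}
        for w_node in reversed(settled_order):
            for v in preds[w_node]:
                c = sigma[v] / sigma[w_node] * (1.0 + delta[w_node])
                edge_bt[tuple(sorted((v, w_node)))] += c
                delta[v] += c
            if w_node != source:
                node_bt[w_node] += delta[w_node]

    # each unordered pair was counted from both endpoints
    for k in node_bt:
        node_bt[k] /= 2.0
    for k in edge_bt:
        edge_bt[k] /= 2.0
    return node_bt, edge_bt


# ---------------------------------------------------------------------------
# Dual-scope annotation and ranking
# ---------------------------------------------------------------------------

def dual_scope_annotate(
    interactome: nx.Graph,
    pathway_networks: list[PathwayNetwork],
    de: pd.DataFrame,
    transform: str = "gm",
) -> list[PathwayNetwork]:
    """Attach global- and pathway-scope betweenness to every pathway node.

    Costs on both scopes derive from the same DE table.  Global betweenness
    is computed once on the full cost-weighted interactome; pathway
    betweenness on each induced subnetwork.
    """
    assign_costs(interactome, de, transform)
    global_node_bt, _ = weighted_betweenness(interactome)
    nx.set_node_attributes(interactome, global_node_bt, "betweenness_global")
    for pn in pathway_networks:
        assign_costs(pn.graph, de, transform)
        node_bt, edge_bt = weighted_betweenness(pn.graph)
        for node in pn.graph.nodes:
            pn.graph.nodes[node]["betweenness_pathway"] = node_bt[node]
            pn.graph.nodes[node]["betweenness_global"] = global_node_bt.get(node, 0.0)
        for u, v in pn.graph.edges:
            pn.graph.edges[u, v]["betweenness_edge"] = edge_bt[tuple(sorted((u, v)))]
    return pathway_networks


def rank_by_betweenness(network: PathwayNetwork) -> list[str]:
    """Pathway nodes by descending within-pathway betweenness.

    Ties break by ascending adjusted p-value, then gene id.
    """
    def key(node):
        data = network.graph.nodes[node]
        return (-data.get("betweenness_pathway", 0.0), data.get("p_adj", 1.0), node)

    return sorted(network.graph.nodes, key=key)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

NODE_EXPORT_COLUMNS = [
    "gene", "logfc", "p_adj", "rank", "betweenness_global", "betweenness_pathway"
]
EDGE_EXPORT_COLUMNS = [
    "node1", "node2", "combined_score", "log_gm_score", "cost", "betweenness_edge"
]


def global_betweenness_table(interactome: nx.Graph) -> pd.DataFrame:
    """All interactome nodes by descending cost-weighted betweenness."""
    rows = [
        {
            "gene": node,
            "p_adj": data.get("p_adj", 1.0),
            "betweenness_global": data.get("betweenness_global", 0.0),
        }
        for node, data in interactome.nodes(data=True)
    ]
    out = pd.DataFrame(rows, columns=["gene", "p_adj", "betweenness_global"])
    return out.sort_values(
        ["betweenness_global", "p_adj", "gene"],
        ascending=[False, True, True], kind="mergesort",
    ).reset_index(drop=True)


def node_attribute_table(network: PathwayNetwork) -> pd.DataFrame:
    """Per-node figure-encoding fields: fill = logfc, width = global
    betweenness, height = pathway betweenness, label = significance rank."""
    rows = []
    for node in rank_by_betweenness(network):
        data = network.graph.nodes[node]
        rows.append(
            {
                "gene": node,
                "logfc": data.get("logfc", float("nan")),
                "p_adj": data.get("p_adj", 1.0),
                "rank": data.get("rank", -1),
                "betweenness_global": data.get("betweenness_global", 0.0),
                "betweenness_pathway": data.get("betweenness_pathway", 0.0),
            }
        )
    return pd.DataFrame(rows, columns=NODE_EXPORT_COLUMNS)


def edge_attribute_table(network: PathwayNetwork) -> pd.DataFrame:
    """Per-edge figure-encoding fields (thickness = combined_score)."""
    rows = []
    for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
        data = network.graph.edges[u, v]
        rows.append(
            {
                "node1": u,
                "node2": v,
                "combined_score": data.get("combined_score", 0),
                "log_gm_score": data.get("log_gm_score", 0.0),
                "cost": data.get("cost", 1.0),
                "betweenness_edge": data.get("betweenness_edge", 0.0),
            }
        )
    return pd.DataFrame(rows, columns=EDGE_EXPORT_COLUMNS)


def export_network(network: PathwayNetwork, out_dir: str | Path, stem: str) -> None:
    """Write GraphML plus node/edge attribute TSVs for one pathway."""
    out_dir = Path(out_dir)
    graph = network.graph.copy()
    graph.graph["parent_set"] = network.parent_set
    nx.write_graphml(graph, out_dir / f"{stem}.graphml")
    node_attribute_table(network).to_csv(
        out_dir / f"{stem}.nodes.tsv", sep="\t", index=False, float_format="%.10g"
    )
    edge_attribute_table(network).to_csv(
        out_dir / f"{stem}.edges.tsv", sep="\t", index=False, float_format="%.10g"
    )
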