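"""Shared fixtures: matrix builders and independent brute-force oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pathrank.preprocess import CONTROL, TREATED, ExpressionMatrix


def build_matrix(
    values, row_ids=None, n_treated=None, sample_ids=None
) -> ExpressionMatrix:
    """ExpressionMatrix from a 2-D array; first ``n_treated`` columns are
    the treated arm (default: half)."""
    arr = np.asarray(values, dtype=float)
    n_rows, n_cols = arr.shape
    if n_treated is None:
        n_treated = n_cols // 2
    if row_ids is None:
        row_ids = [f"g{i + 1}" for i in range(n_rows)]
    if sample_ids is None:
        sample_ids = [f"T{i + 1}" for i in range(n_treated)] + [
            f"C{i + 1}" for i in range(n_cols - n_treated)
        ]
    group_of = {
        s: (TREATED if i < n_treated else CONTROL) for i, s in enumerate(sample_ids)
    }
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=row_ids, columns=sample_ids),
        group_of=group_of,
    )


@pytest.fixture
def matrix_builder():
    return build_matrix


# ---------------------------------------------------------------------------
# Independent oracles (kept free of any pathrank internals)
# ---------------------------------------------------------------------------

def brute_force_betweenness(graph: nx.Graph, weight: str = "cost", tol: float = 1e-9):
    """Node and edge betweenness by exhaustive enumeration of all simple
    paths between every node pair, fractional over the minimum-cost ties."""
    node_bt = {v: 0.0 for v in graph.nodes}
    edge_bt = {tuple(sorted(e)): 0.0 for e in graph.edges}
    for s, t in itertools.combinations(list(graph.nodes), 2):
        if not nx.has_path(graph, s, t):
            continue
        paths = list(nx.all_simple_paths(graph, s, t))
        costs = [
            sum(graph.edges[u, v].get(weight, 1.0) for u, v in zip(p, p[1:]))
            for p in paths
        ]
        cmin = min(costs)
        best = [
            p
            for p, c in zip(paths, costs)
            if c <= cmin + tol * max(1.0, abs(cmin))
        ]
        k = len(best)
        for p in best:
            for v in p[1:-1]:
                node_bt[v] += 1.0 / k
            for u, v in zip(p, p[1:]):
                edge_bt[tuple(sorted((u, v)))] += 1.0 / k
    return node_bt, edge_bt


def exact_ranksum_pvalue(n_universe: int, member_ranks) -> float:
    """P(rank sum <= observed) by full enumeration of C(n, m) placements."""
    member_ranks = sorted(member_ranks)
    m = len(member_ranks)
    observed = sum(member_ranks)
    total = 0
    at_most = 0
    for comb in itertools.combinations(range(1, n_universe + 1), m):
        total += 1
        if sum(comb) <= observed:
            at_most += 1
    return at_most / total


@pytest.fixture
def betweenness_oracle():
    return brute_force_betweenness


@pytest.fixture
def ranksum_oracle():
    return exact_ranksum_pvalue
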