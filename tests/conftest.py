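"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
subpathway mining is validated against exhaustive subset enumeration, and
the hypergeometric tail against exact rational arithmetic.
"""

from __future__ import annotations

import random
from collections import deque
from fractions import Fraction
from itertools import combinations
from math import comb

import pytest

from drsn.pathway_io import PathwayGraph


def make_pathway(pathway_id, edges, isolated=(), genes=None, name="test"):
    """PathwayGraph from an edge list; one gene per node unless overridden."""
    nodes = {n for e in edges for n in e} | set(isolated)
    node_genes = {
        n: frozenset(genes[n]) if genes and n in genes else frozenset({f"g_{n}"})
        for n in nodes
    }
    norm_edges = {tuple(sorted(e)) for e in edges}
    return PathwayGraph(
        pathway_id=pathway_id, name=name, nodes=nodes, edges=norm_edges,
        node_genes=node_genes,
    ).validate()


def bfs_distances(nodes, edges, source):
    """Plain BFS distances, independent of networkx."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_force_subpathways(g: PathwayGraph, k: int, min_size: int):
    """All maximal node subsets with pairwise distance <= k, by enumeration.

    Exponential: only for graphs with <= ~12 nodes.
    """
    nodes = sorted(g.nodes)
    dist = {n: bfs_distances(g.nodes, g.edges, n) for n in nodes}

    def ok(subset):
        return all(
            b in dist[a] and dist[a][b] <= k for a, b in combinations(subset, 2)
        )

    candidates = [
        frozenset(c)
        for size in range(min_size, len(nodes) + 1)
        for c in combinations(nodes, size)
        if ok(c)
    ]
    return sorted(
        (c for c in candidates
         if not any(c < other for other in candidates)),
        key=sorted,
    )


def exact_hypergeom_tail(r, n, m, N) -> Fraction:
    """P(X >= r) for X ~ Hypergeom(N, m, n), exact rational arithmetic."""
    total = Fraction(0)
    for x in range(r, min(n, m) + 1):
        if n - x <= N - m:
            total += Fraction(comb(m, x) * comb(N - m, n - x), comb(N, n))
    return total


def random_pathway(rng: random.Random, max_nodes=12, pathway_id="path:RND"):
    """Random (possibly disconnected) pathway graph for oracle comparisons."""
    n = rng.randint(2, max_nodes)
    nodes = [f"N{i:02d}" for i in range(n)]
    p_edge = rng.uniform(0.1, 0.5)
    edges = {
        (a, b)
        for a, b in combinations(nodes, 2)
        if rng.random() < p_edge
    }
    return make_pathway(pathway_id, edges, isolated=nodes)


@pytest.fixture
def path_graph_5():
    """Path A-B-C-D-E."""
    return make_pathway(
        "path:00001", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")]
    )


@pytest.fixture
def triangle():
    return make_pathway("path:00002", [("A", "B"), ("B", "C"), ("A", "C")])
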