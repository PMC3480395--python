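"""Mining of local pathway regions ("subpathways") by the distance-k clique method.

A subpathway of a pathway graph is a maximal set of nodes whose pairwise
shortest-path distance in the pathway is at most ``k``. These are exactly
the maximal cliques of the distance-k power graph, enumerated here with
networkx's pivoting Bron-Kerbosch implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from drsn.errors import ValidationError
from drsn.pathway_io import PathwayGraph

__all__ = [
    "Subpathway",
    "distance_power_graph",
    "mine_subpathways",
    "mine_all",
    "write_catalog",
    "read_catalog",
]


@dataclass(frozen=True)
class Subpathway:
    """A maximal distance-bounded node set of one pathway, with its genes."""

    subpathway_id: str
    pathway_id: str
    nodes: frozenset[str]
    genes: frozenset[str]


def _as_nx(g: PathwayGraph) -> nx.Graph:
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    out.add_edges_from(g.edges)
    return out


def distance_power_graph(g: PathwayGraph | nx.Graph, k: int) -> nx.Graph:
    """Graph over the same nodes with u~v iff 0 < dist(u, v) <= k.

    Nodes in different components of the input are never adjacent. For
    ``k == 1`` the result equals the input graph.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    base = _as_nx(g) if isinstance(g, PathwayGraph) else g
    power = nx.Graph()
    power.add_nodes_from(base.nodes)
    for source in base.nodes:
        reachable = nx.single_source_shortest_path_length(base, source, cutoff=k)
        for target, dist in reachable.items():
            if 0 < dist and source < target:
                power.add_edge(source, target)
    return power


def mine_subpathways(g: PathwayGraph, k: int = 3, min_size: int = 2) -> list[Subpathway]:
    """All maximal distance-<=k node sets of *g* with at least *min_size* nodes.

    Enumeration order is deterministic: ascending by the sorted node tuple.
    Identifiers are ``<pathway_id>_<n>`` with n assigned 1-based in that
    order.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    g.validate()
    power = distance_power_graph(g, k)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(power) if len(c) >= min_size]
    cliques.sort()
    out = []
    for n, clique in enumerate(cliques, start=1):
        genes: set[str] = set()
        for node in clique:
            genes |= g.node_genes[node]
        out.append(
            Subpathway(
                subpathway_id=f"{g.pathway_id}_{n}",
                pathway_id=g.pathway_id,
                nodes=frozenset(clique),
                genes=frozenset(genes),
            )
        )
    return out


def mine_all(
    pathways: Sequence[PathwayGraph], k: int = 3, min_size: int = 2
) -> dict[str, Subpathway]:
    """Mine every pathway and merge the results into one id-keyed catalog."""
    seen: set[str] = set()
    catalog: dict[str, Subpathway] = {}
    for g in pathways:
        if g.pathway_id in seen:
            raise ValidationError(f"duplicate pathway_id {g.pathway_id!r}")
        seen.add(g.pathway_id)
        for sp in mine_subpathways(g, k=k, min_size=min_size):
            catalog[sp.subpathway_id] = sp
    return catalog


def write_catalog(catalog: dict[str, Subpathway], path) -> None:
    lines = ["subpathway_id\tpathway_id\tnodes\tgenes"]
    for sid in sorted(catalog):
        sp = catalog[sid]
        lines.append(
            f"{sp.subpathway_id}\t{sp.pathway_id}"
            f"\t{';'.join(sorted(sp.nodes))}\t{';'.join(sorted(sp.genes))}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def read_catalog(path) -> dict[str, Subpathway]:
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "subpathway_id\tpathway_id\tnodes\tgenes":
        raise ValidationError(f"{path}: not a subpathway catalog TSV")
    catalog: dict[str, Subpathway] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        sid, pid, nodes, genes = line.split("\t")
        catalog[sid] = Subpathway(
            subpathway_id=sid,
            pathway_id=pid,
            nodes=frozenset(n for n in nodes.split(";") if n),
            genes=frozenset(g for g in genes.split(";") if g),
        )
    return catalog
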