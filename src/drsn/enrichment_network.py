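"""Hypergeometric enrichment, bipartite network assembly and null-model analysis.

Each drug's affected-gene set is tested against each subpathway's gene set
with an upper-tail hypergeometric test; significant pairs (p < alpha) become
edges of a bipartite drug-subpathway network. The module also provides the
network's descriptive statistics, a log-log power-law fit of its degree
distributions, and a degree-preserving shuffle of the underlying drug-gene
associations for empirical null comparison.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import linregress

from drsn.errors import ValidationError
from drsn.expression_degs import DrugGeneSet
from drsn.pathway_io import GeneUniverse
from drsn.subpathway_mining import Subpathway

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "DRSN",
    "hypergeometric_pvalue",
    "build_drsn",
    "network_stats",
    "powerlaw_fit",
    "randomize_drug_gene",
    "null_network_comparison",
    "read_drsn_edges",
    "write_drsn_edges",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Audit record for one drug-subpathway hypergeometric test."""

    drug_id: str
    subpathway_id: str
    overlap: int
    drug_genes_in_background: int
    subpathway_genes_in_background: int
    background_size: int
    p_value: float


@dataclass
class DRSN:
    """Bipartite drug-subpathway network; only degree >= 1 nodes are kept."""

    drug_nodes: set[str]
    subpathway_nodes: set[str]
    edges: dict[tuple[str, str], float]  # (drug_id, subpathway_id) -> p_value
    alpha: float = 0.01

    def drug_neighbors(self) -> dict[str, frozenset[str]]:
        """Map drug -> set of linked subpathways."""
        acc: dict[str, set[str]] = {d: set() for d in self.drug_nodes}
        for (d, s) in self.edges:
            acc[d].add(s)
        return {d: frozenset(v) for d, v in acc.items()}

    def subpathway_neighbors(self) -> dict[str, frozenset[str]]:
        """Map subpathway -> set of linked drugs."""
        acc: dict[str, set[str]] = {s: set() for s in self.subpathway_nodes}
        for (d, s) in self.edges:
            acc[s].add(d)
        return {s: frozenset(v) for s, v in acc.items()}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.drug_nodes, bipartite="drug")
        g.add_nodes_from(self.subpathway_nodes, bipartite="subpathway")
        for (d, s), p in self.edges.items():
            g.add_edge(d, s, p_value=p)
        return g


def _logsumexp(values: list[float]) -> float:
    top = max(values)
    return top + math.log(sum(math.exp(v - top) for v in values))


def hypergeometric_pvalue(overlap: int, drug_n: int, subpath_m: int, background_N: int) -> float:
    """Upper-tail probability P(X >= overlap), X ~ Hypergeom(N, m, n).

    Exact term-by-term summation in log space (log-gamma binomials combined
    with log-sum-exp), stable for the count ranges arising here.
    """
    r, n, m, N = overlap, drug_n, subpath_m, background_N
    if not (0 <= r <= min(n, m) <= max(n, m) <= N):
        raise ValidationError(
            f"inconsistent hypergeometric counts: r={r}, n={n}, m={m}, N={N}"
        )
    if r == 0:
        return 1.0

    def log_binom(a: int, b: int) -> float:
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    log_denom = log_binom(N, n)
    log_terms = []
    for x in range(r, min(n, m) + 1):
        if n - x > N - m:
            continue
        log_terms.append(log_binom(m, x) + log_binom(N - m, n - x) - log_denom)
    if not log_terms:
        return 0.0
    return min(1.0, math.exp(_logsumexp(log_terms)))


def build_drsn(
    drug_sets: Sequence[DrugGeneSet],
    catalog: Mapping[str, Subpathway],
    background: GeneUniverse,
    alpha: float = 0.01,
) -> tuple[DRSN, list[EnrichmentResult]]:
    """Test every drug against every subpathway and keep significant links.

    Drug and subpathway gene sets are intersected with *background* before
    testing; drugs disjoint from the background are skipped with a warning.
    An edge exists iff its p-value is strictly below *alpha*. All tested
    results are returned for audit.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    bg = background.as_set()
    N = len(bg)
    sub_genes = {
        sid: sp.genes & bg for sid, sp in sorted(catalog.items())
    }
    results: list[EnrichmentResult] = []
    edges: dict[tuple[str, str], float] = {}
    for ds in sorted(drug_sets, key=lambda d: d.drug_id):
        dg = ds.genes & bg
        if not dg:
            logger.warning(
                "drug %s: no genes in the background universe; skipped", ds.drug_id
            )
            continue
        for sid, sg in sub_genes.items():
            if not sg:
                continue
            r = len(dg & sg)
            p = hypergeometric_pvalue(r, len(dg), len(sg), N)
            results.append(
                EnrichmentResult(
                    drug_id=ds.drug_id,
                    subpathway_id=sid,
                    overlap=r,
                    drug_genes_in_background=len(dg),
                    subpathway_genes_in_background=len(sg),
                    background_size=N,
                    p_value=p,
                )
            )
            if p < alpha:
                edges[(ds.drug_id, sid)] = p
    net = DRSN(
        drug_nodes={d for d, _ in edges},
        subpathway_nodes={s for _, s in edges},
        edges=edges,
        alpha=alpha,
    )
    return net, results


def network_stats(net: DRSN) -> dict:
    """Descriptive statistics of the bipartite network (undirected)."""
    g = net.to_graph()
    drug_deg = {d: g.degree(d) for d in net.drug_nodes}
    sub_deg = {s: g.degree(s) for s in net.subpathway_nodes}
    giant = max((len(c) for c in nx.connected_components(g)), default=0)
    return {
        "n_drugs": len(net.drug_nodes),
        "n_subpathways": len(net.subpathway_nodes),
        "n_nodes": len(net.drug_nodes) + len(net.subpathway_nodes),
        "n_edges": len(net.edges),
        "giant_component": giant,
        "drug_degrees": dict(sorted(drug_deg.items())),
        "subpathway_degrees": dict(sorted(sub_deg.items())),
        "max_drug_degree": max(drug_deg.values(), default=0),
        "min_drug_degree": min(drug_deg.values(), default=0),
        "max_subpathway_degree": max(sub_deg.values(), default=0),
        "min_subpathway_degree": min(sub_deg.values(), default=0),
    }


def powerlaw_fit(degree_sequence: Sequence[int]) -> dict:
    """Least-squares line through (log10 k, log10 P(k)) over observed degrees.

    P(k) is the fraction of nodes with degree k. Requires at least three
    distinct positive degree values.
    """
    degrees = [d for d in degree_sequence if d > 0]
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        raise ValidationError(
            f"power-law fit needs >= 3 distinct degrees, got {len(values)}"
        )
    pk = counts / len(degrees)
    fit = linregress(np.log10(values), np.log10(pk))
    return {"slope": float(fit.slope), "r_squared": float(fit.rvalue**2)}


def randomize_drug_gene(
    assoc: Iterable[tuple[str, str]],
    n_swaps: int | None = None,
    seed: int | random.Random = 0,
) -> set[tuple[str, str]]:
    """Degree-preserving shuffle of a bipartite drug-gene edge set.

    One swap picks two edges (d1, g1), (d2, g2) and replaces them with
    (d1, g2), (d2, g1) when neither replacement already exists, leaving
    every drug's and every gene's degree unchanged. ``n_swaps`` defaults to
    10x the edge count (standard edge-swap MCMC mixing heuristic).
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    edges = sorted(set(assoc))
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    if n_swaps < 0:
        raise ValueError(f"n_swaps must be >= 0, got {n_swaps}")
    if len(edges) < 2:
        return set(edges)
    present = set(edges)
    for _ in range(n_swaps):
        i, j = rng.randrange(len(edges)), rng.randrange(len(edges))
        if i == j:
            continue
        d1, g1 = edges[i]
        d2, g2 = edges[j]
        if g1 == g2 or d1 == d2:
            continue
        e1, e2 = (d1, g2), (d2, g1)
        if e1 in present or e2 in present:
            continue
        present.discard((d1, g1))
        present.discard((d2, g2))
        present.add(e1)
        present.add(e2)
        edges[i], edges[j] = e1, e2
    return present


def _avg_degree(net: DRSN) -> tuple[float, float]:
    n_d, n_s = len(net.drug_nodes), len(net.subpathway_nodes)
    e = len(net.edges)
    return (e / n_d if n_d else 0.0, e / n_s if n_s else 0.0)


def null_network_comparison(
    drug_sets: Sequence[DrugGeneSet],
    catalog: Mapping[str, Subpathway],
    background: GeneUniverse,
    alpha: float = 0.01,
    n_random: int = 1000,
    seed: int = 0,
    n_swaps: int | None = None,
) -> dict:
    """Compare the observed network against degree-preserving random rewires.

    Each replicate shuffles the drug-gene associations (drug and gene
    degrees fixed), re-runs the full enrichment, and rebuilds the network.
    Empirical p-values use the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_random)``; raw exceedance counts
    are reported alongside.
    """
    if n_random < 1:
        raise ValueError(f"n_random must be >= 1, got {n_random}")
    observed_net, _ = build_drsn(drug_sets, catalog, background, alpha)
    obs = {
        "n_edges": len(observed_net.edges),
        "avg_drug_degree": _avg_degree(observed_net)[0],
        "avg_subpathway_degree": _avg_degree(observed_net)[1],
    }
    assoc = {(ds.drug_id, g) for ds in drug_sets for g in ds.genes}
    rng = random.Random(seed)
    null_values: dict[str, list[float]] = {k: [] for k in obs}
    for _ in range(n_random):
        shuffled = randomize_drug_gene(assoc, n_swaps=n_swaps, seed=rng)
        by_drug: dict[str, set[str]] = {ds.drug_id: set() for ds in drug_sets}
        for d, g in shuffled:
            by_drug[d].add(g)
        null_sets = [
            DrugGeneSet(drug_id=d, genes=frozenset(gs)) for d, gs in by_drug.items()
        ]
        null_net, _ = build_drsn(null_sets, catalog, background, alpha)
        null_values["n_edges"].append(len(null_net.edges))
        avg_d, avg_s = _avg_degree(null_net)
        null_values["avg_drug_degree"].append(avg_d)
        null_values["avg_subpathway_degree"].append(avg_s)
    report = {"observed": obs, "null_mean": {}, "exceedances": {}, "empirical_p": {}}
    for key, nulls in null_values.items():
        exceed = sum(1 for v in nulls if v >= obs[key])
        report["null_mean"][key] = float(np.mean(nulls))
        report["exceedances"][key] = exceed
        report["empirical_p"][key] = (1 + exceed) / (1 + n_random)
    return report


# ---------------------------------------------------------------------------
# edge-table I/O (also used to ingest externally published association tables)


def write_drsn_edges(net: DRSN, path) -> None:
    lines = ["drug_id\tsubpathway_id\tp_value"]
    for (d, s), p in sorted(net.edges.items()):
        lines.append(f"{d}\t{s}\t{p:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_drsn_edges(path, alpha: float = 0.01) -> DRSN:
    """Read a drug/subpathway/p-value edge TSV into a network.

    Accepts 2-column (no p-value) or 3-column rows; a header line whose
    third field is not numeric is skipped. Duplicate rows collapse to one
    edge.
    """
    edges: dict[tuple[str, str], float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValidationError(f"{path}:{lineno}: expected >= 2 fields")
        drug, sub = fields[0].strip(), fields[1].strip()
        if lineno == 1 and drug.lower() in ("drug_id", "drug", "drug_name"):
            continue  # header
        p = math.nan
        if len(fields) >= 3 and fields[2].strip():
            try:
                p = float(fields[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ValidationError(f"{path}:{lineno}: bad p-value {fields[2]!r}")
        edges[(drug, sub)] = p
    return DRSN(
        drug_nodes={d for d, _ in edges},
        subpathway_nodes={s for _, s in edges},
        edges=edges,
        alpha=alpha,
    )
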