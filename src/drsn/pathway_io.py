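"""Readers and writers for pathway graphs, expression matrices and association tables.

All formats are plain text (TSV, or a small KGML-like XML dialect for
pathways) so that inputs can be versioned and diffed. Readers normalize
node/row order so that repeated reads — and reads of row-permuted files —
produce identical in-memory values.

Formats
-------
Pathway edgelist TSV
    ``#<pathway_id>\t<name>`` header line, then ``NODE\t<id>\t<g1;g2;...>``
    and ``EDGE\t<id_a>\t<id_b>`` rows.
KGML subset XML
    ``<pathway name=.. title=..>`` with ``<entry id=.. type="enzyme|gene"
    name="g1 g2 ...">`` children and ``<relation entry1=.. entry2=..>``
    (or ``<reaction .../>`` with the same two attributes) connectivity.
    All connectivity is collapsed to undirected edges.
Expression matrix TSV
    Genes in rows (first column the gene id), samples in columns; a separate
    annotation TSV with columns instance_id, drug_id, treatment_column,
    control_column pairs each treatment sample with its control.
Association TSVs
    Two-column key/value files, one row per pair; the tissue-label file has
    three columns: gene_id, label in {HKG, TEG}, semicolon tissue list
    (empty for HKG).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from drsn.errors import ParseError, ValidationError

__all__ = [
    "PathwayGraph",
    "GeneUniverse",
    "TissueLabel",
    "AssociationTables",
    "read_pathway",
    "write_pathway",
    "read_expression_instances",
    "write_expression_instances",
    "read_associations",
    "write_associations",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PathwayGraph:
    """Undirected enzyme/gene graph for one metabolic pathway.

    Every node carries a non-empty set of gene annotations; the graph may be
    disconnected. Edges are stored as sorted 2-tuples of node ids.
    """

    pathway_id: str
    name: str
    nodes: set[str]
    edges: set[tuple[str, str]]
    node_genes: dict[str, frozenset[str]]

    def validate(self) -> "PathwayGraph":
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"{self.pathway_id}: self-loop on node {a!r}")
            for n in (a, b):
                if n not in self.nodes:
                    raise ValidationError(
                        f"{self.pathway_id}: edge ({a!r}, {b!r}) references unknown node {n!r}"
                    )
        missing = self.nodes - set(self.node_genes)
        if missing:
            raise ValidationError(
                f"{self.pathway_id}: nodes without gene annotation: {sorted(missing)}"
            )
        for n, genes in self.node_genes.items():
            if not genes:
                raise ValidationError(f"{self.pathway_id}: node {n!r} has an empty gene set")
        return self

    def gene_set(self) -> frozenset[str]:
        """Union of gene annotations over all nodes."""
        out: set[str] = set()
        for genes in self.node_genes.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered, duplicate-free collection of gene identifiers."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("gene universe is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene universe contains duplicate identifiers")
        if any(not g for g in self.genes):
            raise ValidationError("gene universe contains an empty identifier")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class TissueLabel:
    """Expression-breadth label for one gene: HKG (all tissues) or TEG."""

    kind: str  # "HKG" | "TEG"
    tissues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("HKG", "TEG"):
            raise ValidationError(f"unknown tissue label kind {self.kind!r}")
        if self.kind == "TEG" and not self.tissues:
            raise ValidationError("TEG label requires at least one tissue")
        if self.kind == "HKG" and self.tissues:
            raise ValidationError("HKG label must not carry tissues")


@dataclass
class AssociationTables:
    """Drug/disease annotation maps; maps may be partial (absent keys)."""

    drug_class: dict[str, str] = field(default_factory=dict)
    drug_indication: dict[str, frozenset[str]] = field(default_factory=dict)
    drug_side_effects: dict[str, frozenset[str]] = field(default_factory=dict)
    drug_targets: dict[str, frozenset[str]] = field(default_factory=dict)
    disease_subpathways: dict[str, frozenset[str]] = field(default_factory=dict)
    disease_class: dict[str, str] = field(default_factory=dict)
    tissue_labels: dict[str, TissueLabel] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pathway graphs


def _sorted_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _parse_gene_field(raw: str, where: str) -> frozenset[str]:
    genes = frozenset(g for g in raw.split(";") if g)
    if not genes:
        raise ParseError(f"{where}: empty gene annotation")
    return genes


def _read_pathway_edgelist(path: Path) -> PathwayGraph:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ParseError(f"{path}:1: expected '#<pathway_id>\\t<name>' header")
    header = lines[0][1:].split("\t")
    if len(header) != 2:
        raise ParseError(f"{path}:1: header must have exactly two tab-separated fields")
    pathway_id, name = header
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    node_genes: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind == "NODE":
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: NODE rows need 3 fields")
            _, node_id, gene_field = fields
            if node_id in nodes:
                raise ParseError(f"{path}:{lineno}: duplicate node {node_id!r}")
            nodes.add(node_id)
            node_genes[node_id] = _parse_gene_field(gene_field, f"{path}:{lineno}")
        elif kind == "EDGE":
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: EDGE rows need 3 fields")
            _, a, b = fields
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-loop on {a!r}")
            edges.add(_sorted_edge(a, b))
        else:
            raise ParseError(f"{path}:{lineno}: unknown row kind {kind!r}")
    return PathwayGraph(pathway_id, name, nodes, edges, node_genes).validate()


def _read_pathway_kgml(path: Path) -> PathwayGraph:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "pathway":
        raise ParseError(f"{path}: root element must be <pathway>, got <{root.tag}>")
    pathway_id = root.get("name", "")
    name = root.get("title", "")
    if not pathway_id:
        raise ParseError(f"{path}: <pathway> lacks a 'name' attribute")
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    node_genes: dict[str, frozenset[str]] = {}
    for entry in root.iter("entry"):
        if entry.get("type") not in ("enzyme", "gene"):
            continue  # maps/compounds/orthologs are out of scope
        node_id = entry.get("id")
        if node_id is None:
            raise ParseError(f"{path}: <entry> lacks an 'id' attribute")
        genes = frozenset(g for g in (entry.get("name") or "").split() if g)
        if not genes:
            raise ParseError(f"{path}: entry {node_id!r} has no gene annotation")
        nodes.add(node_id)
        node_genes[node_id] = genes
    for tag in ("relation", "reaction"):
        for rel in root.iter(tag):
            a, b = rel.get("entry1"), rel.get("entry2")
            if a is None or b is None:
                raise ParseError(f"{path}: <{tag}> lacks entry1/entry2 attributes")
            if a == b:
                continue
            edges.add(_sorted_edge(a, b))
    return PathwayGraph(pathway_id, name, nodes, edges, node_genes).validate()


def read_pathway(path: str | Path, format: str = "edgelist-tsv") -> PathwayGraph:
    """Read one pathway graph from *path* in the given dialect.

    Parameters
    ----------
    path
        File to read.
    format
        Either ``"edgelist-tsv"`` or ``"kgml-subset"``.
    """
    path = Path(path)
    if format == "edgelist-tsv":
        return _read_pathway_edgelist(path)
    if format == "kgml-subset":
        return _read_pathway_kgml(path)
    raise ValueError(f"unknown pathway format {format!r}")


def write_pathway(g: PathwayGraph, path: str | Path) -> None:
    """Write *g* in the edgelist TSV dialect (lexicographically normalized)."""
    g.validate()
    lines = [f"#{g.pathway_id}\t{g.name}"]
    for n in sorted(g.nodes):
        lines.append(f"NODE\t{n}\t{';'.join(sorted(g.node_genes[n]))}")
    for a, b in sorted(g.edges):
        lines.append(f"EDGE\t{a}\t{b}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# expression instances


def read_expression_instances(
    matrix_path: str | Path, annotation_path: str | Path
) -> list["ExpressionInstance"]:
    """Read paired treatment/control expression instances.

    The matrix holds genes in rows and samples in columns; the annotation
    table names, for every instance, the treatment and control columns and
    the perturbing drug. Instances share one gene universe in matrix row
    order.
    """
    from drsn.expression_degs import ExpressionInstance  # avoid import cycle

    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValidationError(f"{matrix_path}: duplicate gene rows {dupes}")
    ann = pd.read_csv(
        annotation_path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
    )
    required = ["instance_id", "drug_id", "treatment_column", "control_column"]
    missing_cols = [c for c in required if c not in ann.columns]
    if missing_cols:
        raise ParseError(f"{annotation_path}: missing columns {missing_cols}")
    genes = GeneUniverse(tuple(str(g) for g in matrix.index))
    instances: list[ExpressionInstance] = []
    for row in ann.itertuples(index=False):
        for col in (row.treatment_column, row.control_column):
            if col not in matrix.columns:
                raise ValidationError(
                    f"{annotation_path}: instance {row.instance_id!r} references "
                    f"column {col!r} absent from the expression matrix"
                )
        treatment = matrix[row.treatment_column].to_numpy(dtype=float)
        control = matrix[row.control_column].to_numpy(dtype=float)
        instances.append(
            ExpressionInstance(
                instance_id=row.instance_id,
                drug_id=row.drug_id,
                genes=genes,
                treatment=treatment,
                control=control,
            )
        )
    return instances


def write_expression_instances(
    instances: Sequence["ExpressionInstance"],
    matrix_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write instances back to the matrix + annotation TSV pair."""
    if not instances:
        Path(matrix_path).write_text("gene_id\n")
        Path(annotation_path).write_text(
            "instance_id\tdrug_id\ttreatment_column\tcontrol_column\n"
        )
        return
    genes = instances[0].genes
    cols: dict[str, np.ndarray] = {}
    ann_rows = []
    for inst in instances:
        if inst.genes is not genes and inst.genes != genes:
            raise ValidationError("instances do not share one gene universe")
        t_col = f"{inst.instance_id}.T"
        c_col = f"{inst.instance_id}.C"
        cols[t_col] = inst.treatment
        cols[c_col] = inst.control
        ann_rows.append((inst.instance_id, inst.drug_id, t_col, c_col))
    frame = pd.DataFrame(cols, index=pd.Index(genes.genes, name="gene_id"))
    frame.to_csv(matrix_path, sep="\t", float_format="%.6f")
    ann = pd.DataFrame(
        ann_rows, columns=["instance_id", "drug_id", "treatment_column", "control_column"]
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# association tables

_SET_VALUED = {
    "drug_indication": "drug_indication.tsv",
    "drug_side_effects": "drug_side_effects.tsv",
    "drug_targets": "drug_targets.tsv",
    "disease_subpathways": "disease_subpathways.tsv",
}
_SINGLE_VALUED = {
    "drug_class": "drug_class.tsv",
    "disease_class": "disease_class.tsv",
}
_TISSUE_FILE = "tissue_labels.tsv"


def _read_pairs(path: Path) -> list[tuple[str, str]]:
    pairs = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
        pairs.append((fields[0], fields[1]))
    return pairs


def read_associations(directory: str | Path) -> AssociationTables:
    """Read every association TSV present in *directory*.

    Missing files yield empty maps. Single-valued maps (class labels) raise
    on conflicting duplicate rows.
    """
    directory = Path(directory)
    tables = AssociationTables()
    for attr, fname in _SET_VALUED.items():
        path = directory / fname
        if not path.exists():
            continue
        acc: dict[str, set[str]] = {}
        for key, value in _read_pairs(path):
            acc.setdefault(key, set()).add(value)
        setattr(tables, attr, {k: frozenset(v) for k, v in acc.items()})
    for attr, fname in _SINGLE_VALUED.items():
        path = directory / fname
        if not path.exists():
            continue
        out: dict[str, str] = {}
        for key, value in _read_pairs(path):
            if key in out and out[key] != value:
                raise ValidationError(
                    f"{path}: conflicting rows for {key!r}: {out[key]!r} vs {value!r}"
                )
            out[key] = value
        setattr(tables, attr, out)
    tissue_path = directory / _TISSUE_FILE
    if tissue_path.exists():
        labels: dict[str, TissueLabel] = {}
        for lineno, line in enumerate(tissue_path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{tissue_path}:{lineno}: expected 3 fields")
            gene, kind, tissue_field = fields
            tissues = frozenset(t for t in tissue_field.split(";") if t)
            if kind == "TEG" and not tissues:
                raise ValidationError(
                    f"{tissue_path}:{lineno}: TEG {gene!r} has an empty tissue field"
                )
            labels[gene] = TissueLabel(kind=kind, tissues=tissues)
        tables.tissue_labels = labels
    return tables


def write_associations(tables: AssociationTables, directory: str | Path) -> None:
    """Write every non-empty map of *tables* into *directory* (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _SET_VALUED.items():
        mapping: Mapping[str, Iterable[str]] = getattr(tables, attr)
        if not mapping:
            continue
        lines = [
            f"{key}\t{value}"
            for key in sorted(mapping)
            for value in sorted(mapping[key])
        ]
        (directory / fname).write_text("\n".join(lines) + "\n")
    for attr, fname in _SINGLE_VALUED.items():
        mapping2: Mapping[str, str] = getattr(tables, attr)
        if not mapping2:
            continue
        lines = [f"{key}\t{mapping2[key]}" for key in sorted(mapping2)]
        (directory / fname).write_text("\n".join(lines) + "\n")
    if tables.tissue_labels:
        lines = [
            f"{gene}\t{label.kind}\t{';'.join(sorted(label.tissues))}"
            for gene, label in sorted(tables.tissue_labels.items())
        ]
        (directory / _TISSUE_FILE).write_text("\n".join(lines) + "\n")
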