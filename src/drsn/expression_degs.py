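"""Fold-change DEG calling per instance and per-drug merging of affected genes.

A gene is differentially expressed in an instance when the absolute log2
ratio of treatment over control intensity exceeds the threshold (strict
inequality). Per-drug affected-gene sets are the union of the per-instance
DEG sets over all instances of that drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from drsn.errors import ValidationError
from drsn.pathway_io import GeneUniverse

__all__ = [
    "ExpressionInstance",
    "DrugGeneSet",
    "call_degs",
    "merge_drug_genes",
    "write_drug_gene_sets",
    "read_drug_gene_sets",
]


@dataclass
class ExpressionInstance:
    """One paired treatment/control expression experiment for one drug."""

    instance_id: str
    drug_id: str
    genes: GeneUniverse
    treatment: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        self.treatment = np.asarray(self.treatment, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        n = len(self.genes)
        if self.treatment.shape != (n,) or self.control.shape != (n,):
            raise ValidationError(
                f"instance {self.instance_id!r}: vector lengths "
                f"{self.treatment.shape}/{self.control.shape} do not match "
                f"{n} genes"
            )
        if (self.treatment < 0).any() or (self.control < 0).any():
            raise ValidationError(f"instance {self.instance_id!r}: negative intensities")


@dataclass(frozen=True)
class DrugGeneSet:
    """Merged set of genes affected by one drug across its instances."""

    drug_id: str
    genes: frozenset[str]


def call_degs(
    inst: ExpressionInstance,
    log2_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> frozenset[str]:
    """Genes with ``|log2((t + c0) / (c + c0))| > log2_threshold``.

    ``c0`` is the pseudocount guarding zero intensities; with ``c0 == 0``
    any zero intensity raises, instructing the caller to supply a positive
    pseudocount. Both up- and down-regulation count.
    """
    if log2_threshold <= 0:
        raise ValueError(f"log2_threshold must be > 0, got {log2_threshold}")
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if pseudocount == 0 and ((inst.control == 0).any() or (inst.treatment == 0).any()):
        raise ValidationError(
            f"instance {inst.instance_id!r} has zero intensities; "
            "use a positive pseudocount"
        )
    ratio = np.log2(inst.treatment + pseudocount) - np.log2(inst.control + pseudocount)
    mask = np.abs(ratio) > log2_threshold
    return frozenset(g for g, m in zip(inst.genes.genes, mask) if m)


def merge_drug_genes(
    instances: Sequence[ExpressionInstance],
    log2_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> list[DrugGeneSet]:
    """One DrugGeneSet per distinct drug, genes unioned over its instances.

    Drugs whose union is empty are retained (filtered downstream). Output
    order follows first appearance of each drug in *instances*.
    """
    order: list[str] = []
    merged: dict[str, set[str]] = {}
    for inst in instances:
        if inst.drug_id not in merged:
            merged[inst.drug_id] = set()
            order.append(inst.drug_id)
        merged[inst.drug_id] |= call_degs(inst, log2_threshold, pseudocount)
    return [DrugGeneSet(drug_id=d, genes=frozenset(merged[d])) for d in order]


def write_drug_gene_sets(drug_sets: Sequence[DrugGeneSet], path) -> None:
    lines = ["drug_id\tgenes"]
    for ds in sorted(drug_sets, key=lambda d: d.drug_id):
        lines.append(f"{ds.drug_id}\t{';'.join(sorted(ds.genes))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_drug_gene_sets(path) -> list[DrugGeneSet]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "drug_id\tgenes":
        raise ValidationError(f"{path}: not a drug gene-set TSV")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        drug_id, genes = (line.split("\t") + [""])[:2]
        out.append(
            DrugGeneSet(drug_id=drug_id, genes=frozenset(g for g in genes.split(";") if g))
        )
    return out
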