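"""Drug-disease association scoring through shared subpathways.

A drug (via its linked subpathways) and a disease (via its associated
subpathways) are scored by the fold enrichment ratio FER = O/E, where O is
the observed overlap of the two subpathway sets and E the overlap expected
from the sets' sizes relative to their class-pair union. Class-level
association scores average FER over all drug/disease pairs of a class pair;
pair-level overlaps are additionally tested with an upper-tail
hypergeometric test against the full mined-subpathway population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from drsn.errors import ValidationError
from drsn.enrichment_network import DRSN, hypergeometric_pvalue
from drsn.pathway_io import AssociationTables

__all__ = ["ClassAssociationMatrix", "fer", "overlap_significance", "association_scores"]


@dataclass
class ClassAssociationMatrix:
    """Drug-class x disease-class association scores plus per-pair results."""

    drug_classes: list[str]
    disease_classes: list[str]
    scores: pd.DataFrame  # index = drug classes, columns = disease classes
    pair_results: list[tuple[str, str, float, float]] = field(default_factory=list)
    # pair_results rows: (drug_id, disease_id, FER, overlap_p)

    def significant_pairs(self, threshold: float = 0.01) -> list[tuple[str, str, float, float]]:
        return [row for row in self.pair_results if row[3] < threshold]


def fer(drug_subpaths: frozenset[str] | set[str],
        disease_subpaths: frozenset[str] | set[str],
        union_size: int) -> float:
    """Fold enrichment ratio O/E of two subpathway sets.

    O is the observed overlap; E = |A| * |B| / union_size is the overlap
    expected if both sets were drawn independently from the union. Returns
    0.0 when the sets are disjoint.
    """
    if union_size <= 0:
        raise ValidationError(f"union_size must be positive, got {union_size}")
    if union_size < max(len(drug_subpaths), len(disease_subpaths)):
        raise ValidationError(
            f"union_size {union_size} smaller than a set "
            f"({len(drug_subpaths)}, {len(disease_subpaths)})"
        )
    if not drug_subpaths or not disease_subpaths:
        raise ValidationError("both subpathway sets must be non-empty")
    observed = len(set(drug_subpaths) & set(disease_subpaths))
    if observed == 0:
        return 0.0
    expected = len(drug_subpaths) * len(disease_subpaths) / union_size
    return observed / expected


def overlap_significance(
    drug_subpaths: frozenset[str] | set[str],
    disease_subpaths: frozenset[str] | set[str],
    population: int,
) -> float:
    """Upper-tail hypergeometric p of the overlap of two subpathway sets.

    *population* is the number of all mined subpathways at the chosen k.
    """
    a, b = set(drug_subpaths), set(disease_subpaths)
    if population < len(a | b):
        raise ValidationError(
            f"population {population} smaller than the union size {len(a | b)}"
        )
    return hypergeometric_pvalue(len(a & b), len(a), len(b), population)


def association_scores(
    drsn: DRSN,
    tables: AssociationTables,
    population: int | None = None,
) -> ClassAssociationMatrix:
    """Association score matrix between drug classes and disease classes.

    AS(i, j) = (1 / (N_i * N_j)) * sum over drugs s in class i, diseases t
    in class j of FER(s, t), where each FER's union size is the number of
    distinct subpathways linked to class i's drugs or class j's diseases.
    Classes with no member carrying subpathways are absent from the matrix
    (not reported as zero). Pair-level overlaps are tested against
    *population* (default: all subpathways seen across the network and the
    disease table).
    """
    drug_sp = {
        d: sps for d, sps in drsn.drug_neighbors().items() if sps and d in tables.drug_class
    }
    disease_sp = {
        t: sps
        for t, sps in tables.disease_subpathways.items()
        if sps and t in tables.disease_class
    }
    if population is None:
        all_sp = set()
        for sps in drug_sp.values():
            all_sp |= sps
        for sps in disease_sp.values():
            all_sp |= sps
        population = len(all_sp)
    by_drug_class: dict[str, list[str]] = {}
    for d in sorted(drug_sp):
        by_drug_class.setdefault(tables.drug_class[d], []).append(d)
    by_disease_class: dict[str, list[str]] = {}
    for t in sorted(disease_sp):
        by_disease_class.setdefault(tables.disease_class[t], []).append(t)
    drug_classes = sorted(by_drug_class)
    disease_classes = sorted(by_disease_class)
    if not drug_classes or not disease_classes:
        raise ValidationError("no scorable drug or disease classes")
    scores = pd.DataFrame(0.0, index=drug_classes, columns=disease_classes)
    pair_results: list[tuple[str, str, float, float]] = []
    for ci in drug_classes:
        drugs = by_drug_class[ci]
        class_drug_union = set()
        for d in drugs:
            class_drug_union |= drug_sp[d]
        for cj in disease_classes:
            diseases = by_disease_class[cj]
            union = set(class_drug_union)
            for t in diseases:
                union |= disease_sp[t]
            union_size = len(union)
            total = 0.0
            for d in drugs:
                for t in diseases:
                    value = fer(drug_sp[d], disease_sp[t], union_size)
                    total += value
                    p = overlap_significance(drug_sp[d], disease_sp[t], population)
                    pair_results.append((d, t, value, p))
            scores.loc[ci, cj] = total / (len(drugs) * len(diseases))
    return ClassAssociationMatrix(
        drug_classes=drug_classes,
        disease_classes=disease_classes,
        scores=scores,
        pair_results=pair_results,
    )
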