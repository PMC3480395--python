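"""Tissue-specificity analysis of therapeutic vs non-therapeutic subpathways.

A network subpathway is therapeutic when some linked drug's therapeutic
targets intersect that drug's own affected genes within the subpathway;
otherwise non-therapeutic. Per-subpathway profiles record the drug-affected
gene set, its housekeeping (HKG) / tissue-specific (TEG) composition, and
the tissue-homogeneity coefficient: the maximum fraction of affected TEGs
expressed in a single tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from drsn.errors import ValidationError
from drsn.enrichment_network import DRSN
from drsn.expression_degs import DrugGeneSet
from drsn.pathway_io import TissueLabel
from drsn.subpathway_mining import Subpathway

__all__ = [
    "SubpathwayTissueProfile",
    "classify_subpathways",
    "th_coefficient",
    "build_tissue_profiles",
    "degree_comparison",
    "composition_ratios",
    "tissue_th_sums",
    "th_class_comparison",
]

THERAPEUTIC = "therapeutic"
NON_THERAPEUTIC = "non_therapeutic"


@dataclass
class SubpathwayTissueProfile:
    """Tissue composition of the drug-affected genes of one subpathway."""

    subpathway_id: str
    klass: str  # THERAPEUTIC | NON_THERAPEUTIC
    affected_genes: frozenset[str]
    teg_ratio: float
    hkg_ratio: float
    th: float
    top_tissue: str | None

    def __post_init__(self) -> None:
        if self.klass not in (THERAPEUTIC, NON_THERAPEUTIC):
            raise ValidationError(f"unknown subpathway class {self.klass!r}")
        if self.teg_ratio + self.hkg_ratio > 1 + 1e-12:
            raise ValidationError("teg_ratio + hkg_ratio must be <= 1")
        if not (0 <= self.th <= 1):
            raise ValidationError("th must lie in [0, 1]")
        if (self.top_tissue is not None) != (self.th > 0):
            raise ValidationError("top_tissue must be set iff th > 0")


def classify_subpathways(
    net: DRSN,
    drug_sets: Sequence[DrugGeneSet],
    drug_targets: Mapping[str, frozenset[str]],
    catalog: Mapping[str, Subpathway],
    drug_specific: bool = True,
) -> dict[str, str]:
    """Partition the network's subpathways into therapeutic / non-therapeutic.

    With ``drug_specific=True`` (default) a subpathway is therapeutic iff
    some linked drug's own targets appear among that drug's affected genes
    inside the subpathway. The flag set to False relaxes this: any linked
    drug's target inside the union of affected genes counts.
    """
    genes_by_drug = {ds.drug_id: ds.genes for ds in drug_sets}
    sub_neighbors = net.subpathway_neighbors()
    classes: dict[str, str] = {}
    for sid in sorted(net.subpathway_nodes):
        if sid not in catalog:
            raise ValidationError(f"subpathway {sid!r} missing from catalog")
        sp_genes = catalog[sid].genes
        therapeutic = False
        if drug_specific:
            for d in sub_neighbors[sid]:
                affected_here = genes_by_drug.get(d, frozenset()) & sp_genes
                if affected_here & drug_targets.get(d, frozenset()):
                    therapeutic = True
                    break
        else:
            affected_union: set[str] = set()
            targets_union: set[str] = set()
            for d in sub_neighbors[sid]:
                affected_union |= genes_by_drug.get(d, frozenset()) & sp_genes
                targets_union |= drug_targets.get(d, frozenset())
            therapeutic = bool(affected_union & targets_union)
        classes[sid] = THERAPEUTIC if therapeutic else NON_THERAPEUTIC
    return classes


def th_coefficient(
    affected_tegs: frozenset[str] | set[str],
    tissue_labels: Mapping[str, TissueLabel],
) -> tuple[float, str | None]:
    """Tissue-homogeneity coefficient of a set of tissue-specific genes.

    ``th = max_j |{g expressed in tissue j}| / |affected_tegs|``; 0 with no
    TEGs. Ties between tissues break lexicographically for determinism.
    """
    if not affected_tegs:
        return 0.0, None
    per_tissue: dict[str, int] = {}
    for g in affected_tegs:
        label = tissue_labels.get(g)
        if label is None or label.kind != "TEG":
            raise ValidationError(f"gene {g!r} is not an annotated TEG")
        if not label.tissues:
            raise ValidationError(f"TEG {g!r} lacks tissue annotation")
        for tissue in label.tissues:
            per_tissue[tissue] = per_tissue.get(tissue, 0) + 1
    top_tissue = max(sorted(per_tissue), key=lambda t: per_tissue[t])
    return per_tissue[top_tissue] / len(affected_tegs), top_tissue


def build_tissue_profiles(
    net: DRSN,
    drug_sets: Sequence[DrugGeneSet],
    catalog: Mapping[str, Subpathway],
    classes: Mapping[str, str],
    tissue_labels: Mapping[str, TissueLabel],
) -> list[SubpathwayTissueProfile]:
    """Per-subpathway profiles over the union of linked drugs' affected genes.

    Subpathways with zero affected genes are excluded (they carry no ratio
    information).
    """
    genes_by_drug = {ds.drug_id: ds.genes for ds in drug_sets}
    sub_neighbors = net.subpathway_neighbors()
    profiles = []
    for sid in sorted(net.subpathway_nodes):
        sp_genes = catalog[sid].genes
        affected: set[str] = set()
        for d in sub_neighbors[sid]:
            affected |= genes_by_drug.get(d, frozenset()) & sp_genes
        if not affected:
            continue
        tegs = {
            g for g in affected
            if g in tissue_labels and tissue_labels[g].kind == "TEG"
        }
        hkgs = {
            g for g in affected
            if g in tissue_labels and tissue_labels[g].kind == "HKG"
        }
        th, top = th_coefficient(tegs, tissue_labels)
        profiles.append(
            SubpathwayTissueProfile(
                subpathway_id=sid,
                klass=classes[sid],
                affected_genes=frozenset(affected),
                teg_ratio=len(tegs) / len(affected),
                hkg_ratio=len(hkgs) / len(affected),
                th=th,
                top_tissue=top,
            )
        )
    return profiles


def _split_by_class(values: Mapping[str, float], classes: Mapping[str, str]):
    ther = [v for k, v in values.items() if classes[k] == THERAPEUTIC]
    non = [v for k, v in values.items() if classes[k] == NON_THERAPEUTIC]
    return ther, non


def degree_comparison(net: DRSN, classes: Mapping[str, str]) -> dict:
    """Rank-sum comparison of subpathway degrees: therapeutic vs the rest.

    One-sided ("therapeutic greater") against non-therapeutic subpathways
    and against all subpathways.
    """
    degrees = {s: len(v) for s, v in net.subpathway_neighbors().items()}
    ther, non = _split_by_class(degrees, classes)
    if not ther or not non:
        raise ValidationError("both subpathway classes must be non-empty")
    stat, p = mannwhitneyu(ther, non, alternative="greater")
    _, p_all = mannwhitneyu(ther, list(degrees.values()), alternative="greater")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "p_value_vs_all": float(p_all),
        "medians": {
            THERAPEUTIC: float(np.median(ther)),
            NON_THERAPEUTIC: float(np.median(non)),
        },
    }


def composition_ratios(
    profiles: Sequence[SubpathwayTissueProfile],
) -> dict:
    """Class-wise comparison of TEG and HKG fractions of affected genes.

    TEG ratios: one-sided rank-sum (therapeutic greater). HKG ratios:
    two-sided (no directional claim).
    """
    teg = {p.subpathway_id: p.teg_ratio for p in profiles}
    hkg = {p.subpathway_id: p.hkg_ratio for p in profiles}
    classes = {p.subpathway_id: p.klass for p in profiles}
    teg_t, teg_n = _split_by_class(teg, classes)
    hkg_t, hkg_n = _split_by_class(hkg, classes)
    if not teg_t or not teg_n:
        raise ValidationError("both subpathway classes must be non-empty")
    _, teg_p = mannwhitneyu(teg_t, teg_n, alternative="greater")
    _, hkg_p = mannwhitneyu(hkg_t, hkg_n, alternative="two-sided")
    return {
        "teg_ratio": {s: r for s, r in sorted(teg.items())},
        "hkg_ratio": {s: r for s, r in sorted(hkg.items())},
        "teg_means": {
            THERAPEUTIC: float(np.mean(teg_t)),
            NON_THERAPEUTIC: float(np.mean(teg_n)),
        },
        "hkg_means": {
            THERAPEUTIC: float(np.mean(hkg_t)),
            NON_THERAPEUTIC: float(np.mean(hkg_n)),
        },
        "teg_p_value": float(teg_p),
        "hkg_p_value": float(hkg_p),
    }


def tissue_th_sums(
    profiles: Sequence[SubpathwayTissueProfile],
) -> dict[str, dict[str, float]]:
    """Per-class, per-tissue sums of TH over profiles topping in that tissue."""
    sums: dict[str, dict[str, float]] = {THERAPEUTIC: {}, NON_THERAPEUTIC: {}}
    for p in profiles:
        if p.th == 0 or p.top_tissue is None:
            continue
        bucket = sums[p.klass]
        bucket[p.top_tissue] = bucket.get(p.top_tissue, 0.0) + p.th
    return sums


def th_class_comparison(profiles: Sequence[SubpathwayTissueProfile]) -> dict:
    """One-sided rank-sum of TH coefficients, therapeutic greater."""
    ther = [p.th for p in profiles if p.klass == THERAPEUTIC]
    non = [p.th for p in profiles if p.klass == NON_THERAPEUTIC]
    if not ther or not non:
        raise ValidationError("both subpathway classes must be non-empty")
    stat, p = mannwhitneyu(ther, non, alternative="greater")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "medians": {
            THERAPEUTIC: float(np.median(ther)),
            NON_THERAPEUTIC: float(np.median(non)),
        },
    }
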