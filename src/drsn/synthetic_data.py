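"""Synthetic input generator with controllable planted structure.

Every input the pipeline consumes can be generated here: random pathway
graphs, paired treatment/control expression instances with planted
perturbations concentrated on known subpathways, and annotation tables in
which side-effect sharing, drug-class/disease-class subpathway blocks and
tissue labels carry tunable signal. Ground truth (which subpathways each
drug perturbs, and which disease class is aligned with which drug class) is
emitted as a first-class artifact so downstream recovery tests never
reverse-engineer the generator.

Determinism: the whole chain is reproducible from ``cfg.seed``; each stage
derives an independent child generator from the seed so stages can be rerun
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from drsn.errors import ValidationError
from drsn.expression_degs import ExpressionInstance
from drsn.pathway_io import (
    AssociationTables,
    GeneUniverse,
    PathwayGraph,
    TissueLabel,
    write_associations,
    write_expression_instances,
    write_pathway,
)
from drsn.subpathway_mining import Subpathway, mine_all, write_catalog

__all__ = [
    "SimulationConfig",
    "generate_pathways",
    "generate_expression",
    "generate_annotations",
    "aligned_drug_class",
    "write_simulation",
]

# background (off-target) perturbations use a fixed magnitude so that the
# false-positive rate stays defined even when the planted effect is zero
_BACKGROUND_LOG2_EFFECT = 2.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_pathways: int = 10
    pathway_size_range: tuple[int, int] = (8, 14)
    edge_density: float = 0.15
    genes_per_node_range: tuple[int, int] = (1, 3)
    n_drugs: int = 30
    instances_per_drug_range: tuple[int, int] = (1, 3)
    n_target_subpathways_per_drug: int = 2
    planted_log2_effect: float = 2.0
    noise_sd: float = 0.3
    background_deg_rate: float = 0.01
    n_diseases: int = 12
    n_drug_classes: int = 3
    n_disease_classes: int = 3
    class_subpathway_overlap: float = 0.8
    side_effect_vocabulary_size: int = 40
    side_effect_sharing_prob: float = 0.3
    baseline_prob: float = 0.05
    indication_vocabulary_size: int = 15
    fraction_hkg: float = 0.2
    fraction_teg: float = 0.2
    n_tissues: int = 8
    therapeutic_target_rate: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "edge_density",
            "class_subpathway_overlap",
            "side_effect_sharing_prob",
            "baseline_prob",
            "fraction_hkg",
            "fraction_teg",
            "therapeutic_target_rate",
            "background_deg_rate",
        ):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        if self.fraction_hkg + self.fraction_teg > 1:
            raise ValidationError("fraction_hkg + fraction_teg must be <= 1")
        for name in ("pathway_size_range", "genes_per_node_range", "instances_per_drug_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValidationError(f"{name} must be a non-degenerate range, got {(lo, hi)}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent child generator for one generation stage."""
        return np.random.default_rng([self.seed, stage])


def generate_pathways(cfg: SimulationConfig) -> list[PathwayGraph]:
    """Random connected pathway graphs with disjoint per-node gene sets.

    Each graph is a uniform random recursive tree plus extra edges added
    with probability ``edge_density`` per remaining node pair; density 0
    therefore yields exactly n - 1 edges.
    """
    rng = cfg.rng(1)
    pathways = []
    gene_counter = 0
    for p in range(cfg.n_pathways):
        pid = f"path:SIM{p + 1:02d}"
        n = int(rng.integers(cfg.pathway_size_range[0], cfg.pathway_size_range[1] + 1))
        nodes = [f"E{i + 1:02d}" for i in range(n)]
        edges: set[tuple[str, str]] = set()
        for i in range(1, n):
            j = int(rng.integers(0, i))
            a, b = nodes[j], nodes[i]
            edges.add((a, b) if a <= b else (b, a))
        for i in range(n):
            for j in range(i + 1, n):
                pair = (nodes[i], nodes[j])
                if pair not in edges and rng.random() < cfg.edge_density:
                    edges.add(pair)
        node_genes = {}
        for node in nodes:
            count = int(
                rng.integers(cfg.genes_per_node_range[0], cfg.genes_per_node_range[1] + 1)
            )
            node_genes[node] = frozenset(
                f"G{gene_counter + i + 1:05d}" for i in range(count)
            )
            gene_counter += count
        pathways.append(
            PathwayGraph(
                pathway_id=pid,
                name=f"simulated pathway {p + 1}",
                nodes=set(nodes),
                edges=edges,
                node_genes=node_genes,
            ).validate()
        )
    return pathways


def _universe(pathways: Sequence[PathwayGraph]) -> GeneUniverse:
    genes: set[str] = set()
    for g in pathways:
        genes |= g.gene_set()
    return GeneUniverse(tuple(sorted(genes)))


def generate_expression(
    cfg: SimulationConfig,
    pathways: Sequence[PathwayGraph],
    mined_catalog: Mapping[str, Subpathway],
) -> tuple[list[ExpressionInstance], dict[str, frozenset[str]]]:
    """Instances with planted perturbations, plus the planted-link ground truth.

    Per drug, ``n_target_subpathways_per_drug`` catalog subpathways are
    chosen; their gene union is multiplied by ``2**planted_log2_effect`` in
    every treatment profile. Baselines are log-normal (mean ~7 on the log2
    scale); treatment and control each carry independent multiplicative
    log-normal noise of sd ``noise_sd`` (log2 scale). A
    ``background_deg_rate`` fraction of off-target genes is additionally
    perturbed at a fixed +-2 log2 magnitude.
    """
    if not mined_catalog:
        raise ValidationError("mined catalog is empty; nothing to plant on")
    rng = cfg.rng(2)
    universe = _universe(pathways)
    gene_index = {g: i for i, g in enumerate(universe.genes)}
    sub_ids = sorted(mined_catalog)
    instances: list[ExpressionInstance] = []
    planted: dict[str, frozenset[str]] = {}
    n_genes = len(universe)
    for d in range(cfg.n_drugs):
        drug_id = f"D{d + 1:03d}"
        n_targets = min(cfg.n_target_subpathways_per_drug, len(sub_ids))
        chosen = sorted(rng.choice(len(sub_ids), size=n_targets, replace=False).tolist())
        target_ids = frozenset(sub_ids[i] for i in chosen)
        planted[drug_id] = target_ids
        target_gene_rows = sorted(
            {gene_index[g] for sid in target_ids for g in mined_catalog[sid].genes}
        )
        n_inst = int(
            rng.integers(cfg.instances_per_drug_range[0], cfg.instances_per_drug_range[1] + 1)
        )
        for i in range(n_inst):
            baseline = np.exp2(rng.normal(7.0, 1.0, size=n_genes))
            control = baseline * np.exp2(rng.normal(0.0, cfg.noise_sd, size=n_genes))
            log2_shift = rng.normal(0.0, cfg.noise_sd, size=n_genes)
            log2_shift[target_gene_rows] += cfg.planted_log2_effect
            background = rng.random(n_genes) < cfg.background_deg_rate
            background[target_gene_rows] = False
            signs = rng.choice([-1.0, 1.0], size=n_genes)
            log2_shift[background] += signs[background] * _BACKGROUND_LOG2_EFFECT
            treatment = baseline * np.exp2(log2_shift)
            instances.append(
                ExpressionInstance(
                    instance_id=f"{drug_id}.I{i + 1:02d}",
                    drug_id=drug_id,
                    genes=universe,
                    treatment=treatment,
                    control=control,
                )
            )
    return instances, planted


def aligned_drug_class(disease_class: str, cfg: SimulationConfig) -> str:
    """Drug class whose planted subpathways seed the given disease class."""
    j = int(disease_class.removeprefix("TC"))
    i = (j - 1) % cfg.n_drug_classes + 1
    return f"DC{i}"


def generate_annotations(
    cfg: SimulationConfig,
    ground_truth: Mapping[str, frozenset[str]],
    catalog: Mapping[str, Subpathway],
) -> AssociationTables:
    """Annotation tables whose signal strength is controlled by the config.

    Side-effect terms anchor on random subpathways: drugs planted on a
    term's anchor carry the term with ``side_effect_sharing_prob``, all
    drugs with ``baseline_prob``; equal probabilities therefore yield a
    no-signal null. Disease classes draw their diseases' subpathways from
    the subpathway block planted for the aligned drug class (see
    :func:`aligned_drug_class`) with probability
    ``class_subpathway_overlap``. Indications are class-level vocabulary
    chunks, assigned independently of the network.
    """
    rng = cfg.rng(3)
    drugs = sorted(ground_truth)
    sub_ids = sorted(catalog)
    tables = AssociationTables()

    # drug classes: uniform random, independent of the planted links
    classes = [f"DC{i + 1}" for i in range(cfg.n_drug_classes)]
    tables.drug_class = {
        d: classes[int(rng.integers(0, cfg.n_drug_classes))] for d in drugs
    }

    # indications: each class owns a chunk of the vocabulary
    vocab = [f"IND{i + 1:03d}" for i in range(cfg.indication_vocabulary_size)]
    chunk = max(1, len(vocab) // cfg.n_drug_classes)
    class_terms = {
        c: vocab[i * chunk : (i + 1) * chunk] or [vocab[-1]]
        for i, c in enumerate(classes)
    }
    indication: dict[str, frozenset[str]] = {}
    for d in drugs:
        terms = {t for t in class_terms[tables.drug_class[d]] if rng.random() < 0.8}
        if rng.random() < 0.2:
            terms.add(vocab[int(rng.integers(0, len(vocab)))])
        if terms:
            indication[d] = frozenset(terms)
    tables.drug_indication = indication

    # side effects anchored on subpathways
    side_effects: dict[str, set[str]] = {d: set() for d in drugs}
    for t in range(cfg.side_effect_vocabulary_size):
        term = f"SE{t + 1:03d}"
        anchor = sub_ids[int(rng.integers(0, len(sub_ids)))]
        for d in drugs:
            prob = (
                cfg.side_effect_sharing_prob
                if anchor in ground_truth[d]
                else cfg.baseline_prob
            )
            if rng.random() < prob:
                side_effects[d].add(term)
    tables.drug_side_effects = {
        d: frozenset(v) for d, v in side_effects.items() if v
    }

    # therapeutic targets sampled from each drug's planted genes
    targets: dict[str, frozenset[str]] = {}
    for d in drugs:
        candidates = sorted({g for sid in ground_truth[d] for g in catalog[sid].genes})
        picked = {
            candidates[int(rng.integers(0, len(candidates)))]
            for _ in range(cfg.n_target_subpathways_per_drug)
            if candidates and rng.random() < cfg.therapeutic_target_rate
        }
        if picked:
            targets[d] = frozenset(picked)
    tables.drug_targets = targets

    # diseases: classes aligned to drug-class planted blocks
    disease_classes = [f"TC{j + 1}" for j in range(cfg.n_disease_classes)]
    blocks: dict[str, list[str]] = {}
    for tc in disease_classes:
        dc = aligned_drug_class(tc, cfg)
        block = sorted(
            {
                sid
                for d in drugs
                if tables.drug_class[d] == dc
                for sid in ground_truth[d]
            }
        )
        blocks[tc] = block
    disease_sp: dict[str, frozenset[str]] = {}
    disease_class: dict[str, str] = {}
    for j in range(cfg.n_diseases):
        disease_id = f"T{j + 1:03d}"
        tc = disease_classes[j % cfg.n_disease_classes]
        disease_class[disease_id] = tc
        size = int(rng.integers(2, 6))
        chosen: set[str] = set()
        for _ in range(size):
            block = blocks[tc]
            if block and rng.random() < cfg.class_subpathway_overlap:
                chosen.add(block[int(rng.integers(0, len(block)))])
            else:
                chosen.add(sub_ids[int(rng.integers(0, len(sub_ids)))])
        disease_sp[disease_id] = frozenset(chosen)
    tables.disease_subpathways = disease_sp
    tables.disease_class = disease_class

    # tissue labels over the full gene universe
    genes = sorted({g for sp in catalog.values() for g in sp.genes})
    tissues = [f"T{j + 1:02d}" for j in range(cfg.n_tissues)]
    labels: dict[str, TissueLabel] = {}
    for g in genes:
        u = rng.random()
        if u < cfg.fraction_hkg:
            labels[g] = TissueLabel(kind="HKG")
        elif u < cfg.fraction_hkg + cfg.fraction_teg:
            tissue = tissues[int(rng.integers(0, cfg.n_tissues))]
            labels[g] = TissueLabel(kind="TEG", tissues=frozenset({tissue}))
    tables.tissue_labels = labels
    return tables


def write_ground_truth(planted: Mapping[str, frozenset[str]], path) -> None:
    lines = ["drug_id\tplanted_subpathways"]
    for d in sorted(planted):
        lines.append(f"{d}\t{';'.join(sorted(planted[d]))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path) -> dict[str, frozenset[str]]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "drug_id\tplanted_subpathways":
        raise ValidationError(f"{path}: not a ground-truth TSV")
    out = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        drug, sps = (line.split("\t") + [""])[:2]
        out[drug] = frozenset(s for s in sps.split(";") if s)
    return out


def write_simulation(
    cfg: SimulationConfig, outdir, k: int = 3, min_size: int = 2
) -> dict:
    """Generate and write a complete input directory.

    Layout: ``pathways/<id>.tsv``, ``expression_matrix.tsv``,
    ``instance_annotation.tsv``, ``associations/*.tsv``,
    ``subpathway_catalog.tsv`` and ``ground_truth_planted.tsv``.
    """
    outdir = Path(outdir)
    (outdir / "pathways").mkdir(parents=True, exist_ok=True)
    pathways = generate_pathways(cfg)
    for g in pathways:
        write_pathway(g, outdir / "pathways" / (g.pathway_id.replace(":", "_") + ".tsv"))
    catalog = mine_all(pathways, k=k, min_size=min_size)
    instances, planted = generate_expression(cfg, pathways, catalog)
    write_expression_instances(
        instances, outdir / "expression_matrix.tsv", outdir / "instance_annotation.tsv"
    )
    tables = generate_annotations(cfg, planted, catalog)
    write_associations(tables, outdir / "associations")
    write_catalog(catalog, outdir / "subpathway_catalog.tsv")
    write_ground_truth(planted, outdir / "ground_truth_planted.tsv")
    return {
        "n_pathways": len(pathways),
        "n_subpathways": len(catalog),
        "n_instances": len(instances),
        "n_drugs": cfg.n_drugs,
    }
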