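import random

import pytest

from drsn.errors import ValidationError
from drsn.enrichment_network import DRSN
from drsn.expression_degs import DrugGeneSet
from drsn.pathway_io import TissueLabel
from drsn.subpathway_mining import Subpathway
from drsn.tissue_specificity import (
    NON_THERAPEUTIC,
    THERAPEUTIC,
    SubpathwayTissueProfile,
    build_tissue_profiles,
    classify_subpathways,
    composition_ratios,
    degree_comparison,
    th_class_comparison,
    th_coefficient,
    tissue_th_sums,
)


def make_net(links):
    edges = {(d, s): 0.001 for d, subs in links.items() for s in subs}
    return DRSN(
        drug_nodes=set(links),
        subpathway_nodes={s for subs in links.values() for s in subs},
        edges=edges,
    )


def make_catalog(gene_map):
    return {
        sid: Subpathway(
            subpathway_id=sid,
            pathway_id=sid.rsplit("_", 1)[0],
            nodes=frozenset({f"n{i}" for i in range(len(genes))}),
            genes=frozenset(genes),
        )
        for sid, genes in gene_map.items()
    }


class TestClassify:
    def test_target_inside_subpathway(self):
        net = make_net({"D1": ["S1"]})
        catalog = make_catalog({"S1": {"G1", "G5"}})
        drug_sets = [DrugGeneSet("D1", frozenset({"G1", "G2"}))]
        classes = classify_subpathways(net, drug_sets, {"D1": frozenset({"G1"})}, catalog)
        assert classes == {"S1": THERAPEUTIC}

    def test_target_outside_subpathway(self):
        net = make_net({"D1": ["S1"]})
        catalog = make_catalog({"S1": {"G5"}})
        drug_sets = [DrugGeneSet("D1", frozenset({"G1", "G5"}))]
        classes = classify_subpathways(net, drug_sets, {"D1": frozenset({"G1"})}, catalog)
        assert classes == {"S1": NON_THERAPEUTIC}

    def test_drug_without_targets(self):
        net = make_net({"D1": ["S1"]})
        catalog = make_catalog({"S1": {"G1"}})
        drug_sets = [DrugGeneSet("D1", frozenset({"G1"}))]
        classes = classify_subpathways(net, drug_sets, {}, catalog)
        assert classes == {"S1": NON_THERAPEUTIC}

    def test_drug_specific_vs_global(self):
        # D2's target is in the subpathway but only via D1's affected genes
        net = make_net({"D1": ["S1"], "D2": ["S1"]})
        catalog = make_catalog({"S1": {"G1", "G2"}})
        drug_sets = [
            DrugGeneSet("D1", frozenset({"G1"})),
            DrugGeneSet("D2", frozenset({"G2"})),
        ]
        targets = {"D2": frozenset({"G1"})}
        strict = classify_subpathways(net, drug_sets, targets, catalog)
        assert strict == {"S1": NON_THERAPEUTIC}
        relaxed = classify_subpathways(
            net, drug_sets, targets, catalog, drug_specific=False
        )
        assert relaxed == {"S1": THERAPEUTIC}

    def test_monotone_in_targets(self):
        rng = random.Random(6)
        genes = [f"G{i}" for i in range(30)]
        catalog = make_catalog(
            {f"S{i}": set(rng.sample(genes, 6)) for i in range(5)}
        )
        links = {f"D{i}": rng.sample(sorted(catalog), 2) for i in range(6)}
        net = make_net(links)
        drug_sets = [
            DrugGeneSet(d, frozenset(rng.sample(genes, 10))) for d in sorted(links)
        ]
        targets = {"D0": frozenset({genes[0]})}
        before = classify_subpathways(net, drug_sets, targets, catalog)
        more = dict(targets)
        more["D1"] = frozenset(rng.sample(genes, 3))
        after = classify_subpathways(net, drug_sets, more, catalog)
        for sid in before:
            if before[sid] == THERAPEUTIC:
                assert after[sid] == THERAPEUTIC

    def test_missing_catalog_entry(self):
        net = make_net({"D1": ["S1"]})
        with pytest.raises(ValidationError):
            classify_subpathways(net, [], {}, {})


LABELS = {
    "G_liv1": TissueLabel("TEG", frozenset({"liver"})),
    "G_liv2": TissueLabel("TEG", frozenset({"liver"})),
    "G_kid": TissueLabel("TEG", frozenset({"kidney"})),
    "G_lung": TissueLabel("TEG", frozenset({"lung"})),
    "G_hkg": TissueLabel("HKG"),
}


class TestThCoefficient:
    def test_all_one_tissue(self):
        th, top = th_coefficient({"G_liv1", "G_liv2"}, LABELS)
        assert th == 1.0 and top == "liver"

    def test_no_tegs(self):
        th, top = th_coefficient(frozenset(), LABELS)
        assert th == 0.0 and top is None

    def test_half_liver(self):
        th, top = th_coefficient({"G_liv1", "G_liv2", "G_kid", "G_lung"}, LABELS)
        assert th == pytest.approx(0.5)
        assert top == "liver"

    def test_tie_breaks_lexicographically(self):
        th, top = th_coefficient({"G_kid", "G_lung"}, LABELS)
        assert th == pytest.approx(0.5)
        assert top == "kidney"

    def test_non_teg_rejected(self):
        with pytest.raises(ValidationError):
            th_coefficient({"G_hkg"}, LABELS)
        with pytest.raises(ValidationError):
            th_coefficient({"G_unknown"}, LABELS)

    def test_matches_brute_force(self):
        rng = random.Random(1)
        tissues = [f"t{i}" for i in range(5)]
        for _ in range(30):
            labels = {
                f"G{i}": TissueLabel(
                    "TEG",
                    frozenset(rng.sample(tissues, rng.randint(1, 3))),
                )
                for i in range(rng.randint(1, 10))
            }
            tegs = set(labels)
            th, top = th_coefficient(tegs, labels)
            counts = {
                t: sum(1 for g in tegs if t in labels[g].tissues) for t in tissues
            }
            best = max(counts.values())
            assert th == pytest.approx(best / len(tegs))
            assert counts[top] == best
            assert top == min(t for t, c in counts.items() if c == best)

    def test_multi_tissue_teg_counts_everywhere(self):
        labels = {"G1": TissueLabel("TEG", frozenset({"liver", "kidney"}))}
        th, top = th_coefficient({"G1"}, labels)
        assert th == 1.0 and top == "kidney"  # lexicographic tie break


class TestProfilesAndComparisons:
    def _profiles(self):
        return [
            SubpathwayTissueProfile("S1", THERAPEUTIC, frozenset({"a"}), 0.5, 0.25, 0.8, "liver"),
            SubpathwayTissueProfile("S2", THERAPEUTIC, frozenset({"b"}), 0.4, 0.2, 0.6, "liver"),
            SubpathwayTissueProfile("S3", NON_THERAPEUTIC, frozenset({"c"}), 0.1, 0.3, 0.5, "lung"),
            SubpathwayTissueProfile("S4", NON_THERAPEUTIC, frozenset({"d"}), 0.0, 0.2, 0.0, None),
        ]

    def test_build_profiles_counting(self):
        net = make_net({"D1": ["S1"], "D2": ["S1"]})
        catalog = make_catalog({"S1": {"G_liv1", "G_kid", "G_hkg", "G_other"}})
        drug_sets = [
            DrugGeneSet("D1", frozenset({"G_liv1", "G_hkg"})),
            DrugGeneSet("D2", frozenset({"G_kid", "G_other"})),
        ]
        (profile,) = build_tissue_profiles(
            net, drug_sets, catalog, {"S1": THERAPEUTIC}, LABELS
        )
        assert profile.affected_genes == {"G_liv1", "G_kid", "G_hkg", "G_other"}
        assert profile.teg_ratio == pytest.approx(0.5)
        assert profile.hkg_ratio == pytest.approx(0.25)
        assert profile.th == pytest.approx(0.5)
        assert profile.top_tissue == "kidney"

    def test_zero_affected_excluded(self):
        net = make_net({"D1": ["S1"]})
        catalog = make_catalog({"S1": {"G_x"}})
        drug_sets = [DrugGeneSet("D1", frozenset({"G_y"}))]
        assert build_tissue_profiles(net, drug_sets, catalog, {"S1": THERAPEUTIC}, LABELS) == []

    def test_degree_separation(self):
        hi = [f"S_hi{j}" for j in range(4)]
        links = {f"D{i}": hi for i in range(10)}
        for j in range(4):
            links[f"E{j}"] = [f"S_lo{j}"]
        net = make_net(links)
        classes = {s: THERAPEUTIC for s in hi}
        classes.update({f"S_lo{j}": NON_THERAPEUTIC for j in range(4)})
        report = degree_comparison(net, classes)
        assert report["medians"][THERAPEUTIC] > report["medians"][NON_THERAPEUTIC]
        assert report["p_value"] < 0.05

    def test_degree_identity_distribution(self):
        links = {"D1": ["S1", "S2"], "D2": ["S1", "S2"]}
        net = make_net(links)
        classes = {"S1": THERAPEUTIC, "S2": NON_THERAPEUTIC}
        report = degree_comparison(net, classes)
        assert report["p_value"] > 0.4

    def test_degree_empty_class_rejected(self):
        net = make_net({"D1": ["S1"]})
        with pytest.raises(ValidationError):
            degree_comparison(net, {"S1": THERAPEUTIC})

    def test_composition_ratios(self):
        report = composition_ratios(self._profiles())
        assert report["teg_means"][THERAPEUTIC] == pytest.approx(0.45)
        assert report["teg_means"][NON_THERAPEUTIC] == pytest.approx(0.05)
        assert 0 < report["teg_p_value"] <= 1
        assert 0 < report["hkg_p_value"] <= 1

    def test_th_sums_additivity(self):
        sums = tissue_th_sums(self._profiles())
        assert sums[THERAPEUTIC]["liver"] == pytest.approx(1.4)
        assert sums[NON_THERAPEUTIC]["lung"] == pytest.approx(0.5)
        # zero-TH profile contributes nowhere
        assert sum(sums[NON_THERAPEUTIC].values()) == pytest.approx(0.5)

    def test_th_sums_conservation(self):
        profiles = self._profiles()
        sums = tissue_th_sums(profiles)
        for klass in (THERAPEUTIC, NON_THERAPEUTIC):
            assert sum(sums[klass].values()) == pytest.approx(
                sum(p.th for p in profiles if p.klass == klass)
            )

    def test_th_class_comparison(self):
        report = th_class_comparison(self._profiles())
        assert report["medians"][THERAPEUTIC] == pytest.approx(0.7)
        assert 0 < report["p_value"] <= 1

    def test_profile_invariants(self):
        with pytest.raises(ValidationError):
            SubpathwayTissueProfile("S", THERAPEUTIC, frozenset(), 0.8, 0.5, 0.1, "x")
        with pytest.raises(ValidationError):
            SubpathwayTissueProfile("S", THERAPEUTIC, frozenset(), 0.1, 0.1, 0.0, "x")
        with pytest.raises(ValidationError):
            SubpathwayTissueProfile("S", "bogus", frozenset(), 0.1, 0.1, 0.5, "x")
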