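"""Drug-pair statistics: shared indications, side effects and subpathway trends.

Two drugs are "connected" when they link to at least one common subpathway
in the bipartite network. The module tests whether connected pairs share
indications more often than random pairs (permutation test with strict
exceedance counting), whether they share more side-effect terms than the
background of all annotated pairs (one-sided rank-sum), and whether sharing
more subpathways implies sharing more side effects (OLS on binned means).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import linregress, mannwhitneyu

from drsn.errors import ValidationError
from drsn.enrichment_network import DRSN

__all__ = [
    "DrugPairRecord",
    "connected_drug_pairs",
    "strict_exceedance_pvalue",
    "shared_indication_test",
    "shared_side_effect_comparison",
    "shared_subpathway_trend",
]


@dataclass(frozen=True)
class DrugPairRecord:
    """One unordered connected drug pair with its sharing counts."""

    drug_a: str
    drug_b: str
    shared_subpathways: int
    shared_indications: int = 0
    shared_side_effects: int = 0

    def __post_init__(self) -> None:
        if not self.drug_a < self.drug_b:
            raise ValidationError(
                f"pair must be canonically ordered, got ({self.drug_a!r}, {self.drug_b!r})"
            )
        if min(self.shared_subpathways, self.shared_indications, self.shared_side_effects) < 0:
            raise ValidationError("sharing counts must be >= 0")


def _shared(mapping: Mapping[str, frozenset[str]] | None, a: str, b: str) -> int:
    if mapping is None:
        return 0
    return len(mapping.get(a, frozenset()) & mapping.get(b, frozenset()))


def connected_drug_pairs(
    net: DRSN,
    restrict_to: set[str] | None = None,
    drug_indication: Mapping[str, frozenset[str]] | None = None,
    drug_side_effects: Mapping[str, frozenset[str]] | None = None,
) -> list[DrugPairRecord]:
    """All unordered drug pairs sharing >= 1 subpathway neighbor.

    ``restrict_to`` limits pairs to drugs with annotation records (e.g. the
    subset present in a side-effect resource). Optional annotation maps fill
    the sharing counts of the returned records.
    """
    neighbors = net.drug_neighbors()
    drugs = sorted(neighbors)
    if restrict_to is not None:
        drugs = [d for d in drugs if d in restrict_to]
    out = []
    for a, b in combinations(drugs, 2):
        shared_sp = len(neighbors[a] & neighbors[b])
        if shared_sp == 0:
            continue
        out.append(
            DrugPairRecord(
                drug_a=a,
                drug_b=b,
                shared_subpathways=shared_sp,
                shared_indications=_shared(drug_indication, a, b),
                shared_side_effects=_shared(drug_side_effects, a, b),
            )
        )
    return out


def strict_exceedance_pvalue(observed: float, null_values: Sequence[float]) -> float:
    """Fraction of null replicate values strictly greater than *observed*."""
    if not null_values:
        raise ValidationError("empty null sample")
    return sum(1 for v in null_values if v > observed) / len(null_values)


def _count_sharing_pairs(
    pairs: Sequence[tuple[str, str]], mapping: Mapping[str, frozenset[str]]
) -> int:
    return sum(
        1
        for a, b in pairs
        if mapping.get(a, frozenset()) & mapping.get(b, frozenset())
    )


def shared_indication_test(
    pairs: Sequence[DrugPairRecord],
    drug_indication: Mapping[str, frozenset[str]],
    universe: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test: do connected pairs share indications more than chance?

    ``observed_count`` is the number of connected pairs sharing >= 1
    indication. Each permutation draws the same number of distinct unordered
    pairs uniformly from *universe*; the empirical p-value is the fraction
    of permutations whose sharing count strictly exceeds the observed one.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    universe_sorted = sorted(universe)
    if len(universe_sorted) < 2:
        raise ValidationError("universe must contain >= 2 drugs")
    n_pairs = len(pairs)
    max_pairs = len(universe_sorted) * (len(universe_sorted) - 1) // 2
    if n_pairs > max_pairs:
        raise ValidationError(
            f"cannot draw {n_pairs} distinct pairs from {len(universe_sorted)} drugs"
        )
    observed = _count_sharing_pairs(
        [(p.drug_a, p.drug_b) for p in pairs], drug_indication
    )
    rng = random.Random(seed)
    null_counts = []
    for _ in range(n_perm):
        drawn: set[tuple[str, str]] = set()
        while len(drawn) < n_pairs:
            a, b = rng.sample(universe_sorted, 2)
            drawn.add((a, b) if a < b else (b, a))
        null_counts.append(_count_sharing_pairs(sorted(drawn), drug_indication))
    exceedances = sum(1 for c in null_counts if c > observed)
    return {
        "observed_count": observed,
        "null_mean": float(np.mean(null_counts)),
        "exceedances": exceedances,
        "empirical_p": exceedances / n_perm,
        "n_perm": n_perm,
    }


def shared_side_effect_comparison(
    pairs: Sequence[DrugPairRecord],
    drug_side_effects: Mapping[str, frozenset[str]],
    all_drugs: set[str],
) -> dict:
    """Connected pairs vs all annotated pairs: shared side-effect counts.

    Compares the per-pair shared-term counts of connected pairs against
    those of every unordered pair of annotated drugs with a one-sided
    (greater) Wilcoxon rank-sum test.
    """
    annotated = sorted(d for d in all_drugs if d in drug_side_effects)
    if len(annotated) < 2:
        raise ValidationError("need >= 2 annotated drugs for the background")
    connected = [
        _shared(drug_side_effects, p.drug_a, p.drug_b)
        for p in pairs
        if p.drug_a in drug_side_effects and p.drug_b in drug_side_effects
    ]
    background = [
        _shared(drug_side_effects, a, b) for a, b in combinations(annotated, 2)
    ]
    if not connected or not background:
        raise ValidationError("either pair sample is empty")
    stat, p = mannwhitneyu(connected, background, alternative="greater")
    return {
        "connected_counts": connected,
        "background_counts": background,
        "statistic": float(stat),
        "p_value": float(p),
        "connected_mean": float(np.mean(connected)),
        "background_mean": float(np.mean(background)),
    }


def shared_subpathway_trend(
    pairs: Sequence[DrugPairRecord], binned: bool = True
) -> dict:
    """Does sharing more subpathways imply sharing more side effects?

    Pairs are binned by their exact shared-subpathway count; the mean
    shared-side-effect count per bin is regressed on the bin value by OLS.
    ``binned=False`` fits the raw pairs instead.
    """
    if binned:
        bins: dict[int, list[int]] = {}
        for p in pairs:
            bins.setdefault(p.shared_subpathways, []).append(p.shared_side_effects)
        if len(bins) < 3:
            raise ValidationError(
                f"trend regression needs >= 3 distinct shared-subpathway values, got {len(bins)}"
            )
        xs = sorted(bins)
        ys = [float(np.mean(bins[x])) for x in xs]
        bin_means = dict(zip(xs, ys))
    else:
        if len({p.shared_subpathways for p in pairs}) < 3:
            raise ValidationError("trend regression needs >= 3 distinct x values")
        xs = [p.shared_subpathways for p in pairs]
        ys = [float(p.shared_side_effects) for p in pairs]
        bin_means = {}
    fit = linregress(xs, ys)
    slope_p = float(fit.pvalue) if not math.isnan(fit.pvalue) else 1.0
    return {
        "bin_means": bin_means,
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "slope_p": slope_p,
    }
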