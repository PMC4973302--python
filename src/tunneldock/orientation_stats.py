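"""Orientation-preference frequency analysis.

The analysis set is the subset of classified poses that protrude through
portal 1 only and realise at least one potential hydrogen bond. Within the
top decile by clash score (smallest integer cutoff c such that at least 10%
of the set scores fewer than c clashes -- ties at the cutoff are all-in),
poses are counted by ring orientation, and the two counts are compared
against equal expected frequencies with a chi-squared goodness-of-fit test
(df = 1, no continuity correction). The fold ratio is reported at one
decimal; full precision is retained internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .classify import ClassifiedScore, PortalDefinition, classify_ensemble
from .ensemble import PoseSet
from .scoring import ProteinScorer, score_ensemble
from .structures import ConformerModel, ProteinStructure, assign_polar_roles, select_model

__all__ = [
    "OrientationSummary",
    "filter_analysis_set",
    "top_decile",
    "orientation_preference",
    "preference_from_counts",
    "robustness_battery",
    "partition_checks",
    "REFERENCE_STUDY_COUNTS",
]

#: Published accounting of the lutein-StARD3 docking ensemble, used as example
#: inputs for the frequency analysis: total ensemble size, the two portal
#: sets, the two (equal) orientation sets, the filtered analysis set, and the
#: top-decile orientation split with its clash cutoff and winner scores.
REFERENCE_STUDY_COUNTS: dict[str, int] = {
    "total": 27324,
    "two_portals": 14256,
    "one_portal": 13068,
    "epsilon_toward_portal1": 13662,
    "epsilon_toward_portal2": 13662,
    "analysis_set": 8469,
    "top_group": 836,
    "top_epsilon_in": 620,
    "top_beta_in": 216,
    "clash_cutoff": 23,
    "winner_clashes": 14,
    "winner_hbonds": 2,
}


@dataclass
class OrientationSummary:
    """Counts, fold ratio and chi-squared result for one analysis run."""

    n_filtered: int
    clash_cutoff: int
    n_top: int
    n_epsilon_in: int
    n_beta_in: int
    fold_ratio: float
    chi2: float
    p_value: float
    protein_label: str = ""

    def __post_init__(self) -> None:
        if self.n_epsilon_in + self.n_beta_in != self.n_top:
            raise ValueError("orientation counts must sum to the top-group size")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")

    @property
    def fold_ratio_display(self) -> str:
        if math.isinf(self.fold_ratio):
            return "inf"
        return f"{self.fold_ratio:.1f}"

    def to_json(self) -> dict:
        return {
            "n_filtered": self.n_filtered,
            "clash_cutoff": self.clash_cutoff,
            "n_top": self.n_top,
            "n_epsilon_in": self.n_epsilon_in,
            "n_beta_in": self.n_beta_in,
            "fold_ratio": None if math.isinf(self.fold_ratio) else self.fold_ratio,
            "fold_ratio_display": self.fold_ratio_display,
            "chi2": self.chi2,
            "p_value": self.p_value,
            "protein_label": self.protein_label,
        }


def filter_analysis_set(
    records: Sequence[ClassifiedScore],
    portal_class: str = "one_portal",
    min_hbonds: int = 1,
) -> list[ClassifiedScore]:
    """Poses of the stated portal class with at least ``min_hbonds`` H-bonds,
    in input order. An empty result is allowed."""
    return [
        r
        for r in records
        if r.portal_class == portal_class and r.hbonds >= min_hbonds
    ]


def top_decile(
    subset: Sequence[ClassifiedScore],
    fraction: float = 0.1,
) -> tuple[int, list[ClassifiedScore]]:
    """Integer clash cutoff and the records strictly below it.

    The cutoff is the smallest integer c such that at least ``fraction`` of
    the subset scores fewer than c clashes; all ties at the cutoff are
    included, so the group may exceed the nominal fraction.
    """
    if not subset:
        raise ValueError("empty analysis subset")
    clashes = np.array([r.clashes for r in subset])
    k = max(1, math.ceil(fraction * len(subset)))
    kth = int(np.partition(clashes, k - 1)[k - 1])
    cutoff = kth + 1
    top = [r for r in subset if r.clashes < cutoff]
    return cutoff, top


def preference_from_counts(
    n_epsilon_in: int,
    n_beta_in: int,
    n_filtered: int | None = None,
    clash_cutoff: int = 0,
    protein_label: str = "",
) -> OrientationSummary:
    """Chi-squared goodness-of-fit of two orientation counts vs 50/50.

    With a zero count in one class the fold ratio is infinite; the statistic
    is still computed.
    """
    n_top = n_epsilon_in + n_beta_in
    if n_top == 0:
        raise ValueError("no classified poses to analyze")
    if n_beta_in > 0:
        fold = n_epsilon_in / n_beta_in
    else:
        fold = math.inf
    chi2, p = stats.chisquare([n_epsilon_in, n_beta_in])
    return OrientationSummary(
        n_filtered=n_top if n_filtered is None else n_filtered,
        clash_cutoff=clash_cutoff,
        n_top=n_top,
        n_epsilon_in=n_epsilon_in,
        n_beta_in=n_beta_in,
        fold_ratio=float(fold),
        chi2=float(chi2),
        p_value=float(max(p, np.nextafter(0, 1))),
        protein_label=protein_label,
    )


def orientation_preference(
    top: Sequence[ClassifiedScore],
    n_filtered: int | None = None,
    clash_cutoff: int = 0,
    protein_label: str = "",
) -> OrientationSummary:
    n_eps = sum(1 for r in top if r.orientation_class == "epsilon_in")
    n_beta = sum(1 for r in top if r.orientation_class == "beta_in")
    return preference_from_counts(
        n_eps, n_beta, n_filtered=n_filtered, clash_cutoff=clash_cutoff,
        protein_label=protein_label,
    )


def analyze(
    classified: Sequence[ClassifiedScore],
    portal_class: str = "one_portal",
    min_hbonds: int = 1,
    fraction: float = 0.1,
    protein_label: str = "",
) -> OrientationSummary:
    """Filter, take the top decile, and summarize orientation preference."""
    subset = filter_analysis_set(classified, portal_class, min_hbonds)
    if not subset:
        raise ValueError("empty analysis set after filtering")
    cutoff, top = top_decile(subset, fraction)
    return orientation_preference(
        top, n_filtered=len(subset), clash_cutoff=cutoff, protein_label=protein_label
    )


def robustness_battery(
    ps: PoseSet,
    protein: ProteinStructure,
    variants: Sequence[tuple[str, ConformerModel]],
    portals: tuple[PortalDefinition, PortalDefinition],
    baseline: Sequence[ClassifiedScore] | None = None,
    portal_class: str = "one_portal",
    min_hbonds: int = 1,
    fraction: float = 0.1,
    **scorer_kwargs,
) -> list[tuple[str, OrientationSummary, float]]:
    """Re-score and re-analyze the pose set under protein-model perturbations.

    Returns, per variant, its label, the orientation summary, and the mean
    clash shift (variant minus baseline, averaged over all poses). The pose
    set itself is never altered.
    """
    def run(prot: ProteinStructure, label: str):
        scorer = ProteinScorer(assign_polar_roles(prot), label=label, **scorer_kwargs)
        records = score_ensemble(ps, prot, scorer=scorer)
        classified = classify_ensemble(ps, records, portals)
        return records, classified

    if baseline is None:
        base_records, baseline = run(protein, protein.id)
    base_clashes = np.array([r.clashes for r in baseline])

    out = []
    for label, model in variants:
        variant_protein = select_model(protein, model)
        records, classified = run(variant_protein, label)
        shift = float(
            np.mean(np.array([r.clashes for r in records]) - base_clashes)
        )
        summary = analyze(
            classified, portal_class, min_hbonds, fraction, protein_label=label
        )
        out.append((label, summary, shift))
    return out


def partition_checks(counts: Mapping[str, int]) -> dict[str, bool]:
    """Arithmetic consistency of an ensemble accounting record.

    Checks that the top-decile orientation counts sum to the top group, the
    portal sets partition the ensemble, and the orientation sets split it in
    half.
    """
    return {
        "top_counts_sum": counts["top_epsilon_in"] + counts["top_beta_in"]
        == counts["top_group"],
        "portal_partition": counts["two_portals"] + counts["one_portal"]
        == counts["total"],
        "orientation_halves": counts["epsilon_toward_portal1"]
        == counts["epsilon_toward_portal2"]
        and counts["epsilon_toward_portal1"] * 2 == counts["total"],
    }
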