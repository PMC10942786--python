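"""Pattern taxonomy for dichotomized expression splits.

Maps each gene's best-scoring bipartition of the eight autonomic cell
groups (four ganglia plus four pelvic clusters) onto seven named
expression patterns, reflecting which division of the autonomic nervous
system the expressing side resembles:

I    all sympathetic ganglia + pelvic clusters   (sympathetic-and-pelvic)
II   parasympathetic only                        (parasympathetic-not-pelvic)
III  all sympathetic ganglia only                (sympathetic-not-pelvic)
IV   parasympathetic + some pelvic clusters      (parasympathetic-and-some-pelvic)
V    parasympathetic + the cholinergic clusters  (cholinergic)
VI   all sympathetic + the noradrenergic cluster (noradrenergic)
VII  pelvic clusters in a class by themselves    (pelvic-specific)

Splits that cut across the sympathetic ganglia, or mix divisions in any
other way, are labeled "other" and carry no information about a
sympathetic or parasympathetic identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .screen import Bipartition, GeneSplitScore

__all__ = [
    "PATTERN_ORDER",
    "PATTERN_CATEGORY",
    "GroupRoleMap",
    "PatternAssignment",
    "default_role_map",
    "classify_split",
    "tally_patterns",
    "order_for_heatmap",
]

PATTERN_ORDER = ("I", "II", "III", "IV", "V", "VI", "VII", "other")

PATTERN_CATEGORY = {
    "I": "sympathetic-and-pelvic",
    "II": "parasympathetic-not-pelvic",
    "III": "sympathetic-not-pelvic",
    "IV": "parasympathetic-and-some-pelvic",
    "V": "cholinergic",
    "VI": "noradrenergic",
    "VII": "pelvic-specific",
    "other": "other",
}

VALID_ROLES = ("sympathetic", "parasympathetic", "pelvic_cluster")


@dataclass(frozen=True)
class GroupRoleMap:
    """Role of each cell group plus the neurotransmitter partition of the
    pelvic clusters (cholinergic vs noradrenergic)."""

    roles: Mapping[str, str]
    cholinergic_pelvic: frozenset = frozenset({"P1", "P2", "P4"})
    noradrenergic_pelvic: frozenset = frozenset({"P3"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "roles", dict(self.roles))
        object.__setattr__(self, "cholinergic_pelvic", frozenset(self.cholinergic_pelvic))
        object.__setattr__(self, "noradrenergic_pelvic", frozenset(self.noradrenergic_pelvic))
        for g, r in self.roles.items():
            if r not in VALID_ROLES:
                raise ValueError(f"unknown role {r!r} for group {g!r}")
        pelvic = self.pelvic
        chol, nora = self.cholinergic_pelvic, self.noradrenergic_pelvic
        if not (chol | nora) <= pelvic:
            raise ValueError("cholinergic/noradrenergic sets must be pelvic clusters")
        if chol & nora:
            raise ValueError("cholinergic and noradrenergic sets overlap")

    def _of(self, role: str) -> frozenset:
        return frozenset(g for g, r in self.roles.items() if r == role)

    @property
    def sympathetic(self) -> frozenset:
        return self._of("sympathetic")

    @property
    def parasympathetic(self) -> frozenset:
        return self._of("parasympathetic")

    @property
    def pelvic(self) -> frozenset:
        return self._of("pelvic_cluster")


def default_role_map() -> GroupRoleMap:
    """The eight default groups: stellate, coeliac and lumbar sympathetic
    chains, the sphenopalatine parasympathetic ganglion, and pelvic
    clusters P1-P4 (P1, P2, P4 cholinergic; P3 noradrenergic)."""
    return GroupRoleMap(
        roles={
            "sphenopalatine": "parasympathetic",
            "stellate": "sympathetic",
            "coeliac": "sympathetic",
            "lumbar": "sympathetic",
            "P1": "pelvic_cluster",
            "P2": "pelvic_cluster",
            "P3": "pelvic_cluster",
            "P4": "pelvic_cluster",
        }
    )


@dataclass(frozen=True)
class PatternAssignment:
    gene: str
    pattern: str
    category: str = field(default="")
    split: Bipartition | None = None
    score: float = float("nan")

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_ORDER:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not self.category:
            object.__setattr__(self, "category", PATTERN_CATEGORY[self.pattern])


def classify_split(
    split: Bipartition,
    roles: GroupRoleMap,
    require_all_pelvic: bool = False,
) -> str:
    """Assign a pattern label (I-VII or "other") to an ordered split.

    Exact-set patterns (VII, V, VI, II, III) are tested before the
    subset patterns (I, IV) so that every split receives exactly one
    label.  With ``require_all_pelvic`` pattern I demands all pelvic
    clusters on the sympathetic side rather than any nonempty subset.
    """
    s1 = frozenset(split.subset_1)
    s2 = frozenset(split.subset_2)
    unknown = (s1 | s2) - set(roles.roles)
    if unknown:
        raise ValueError(f"unknown groups in split: {sorted(unknown)}")

    sym, para, pel = roles.sympathetic, roles.parasympathetic, roles.pelvic
    s1_sym, s1_para, s1_pel = s1 & sym, s1 & para, s1 & pel
    s2_pel = s2 & pel

    # VII: all or some pelvic clusters in a class by themselves, by
    # expression (subset_1 pelvic-only) or by absence (subset_2 pelvic-only)
    if s1 and s1 <= pel:
        return "VII"
    if s2 and s2 <= pel:
        return "VII"
    # V / VI: the two neurotransmitter synexpression patterns (exact sets)
    if s1 == para | roles.cholinergic_pelvic and roles.cholinergic_pelvic:
        return "V"
    if s1 == sym | roles.noradrenergic_pelvic and roles.noradrenergic_pelvic:
        return "VI"
    # II / III: one division alone, no pelvic involvement
    if s1 == para:
        return "II"
    if s1 == sym:
        return "III"
    # I: all sympathetic ganglia plus pelvic clusters, no parasympathetic
    if s1_sym == sym and not s1_para and s1_pel:
        if not require_all_pelvic or s1_pel == pel:
            return "I"
        return "other"
    # IV: parasympathetic plus a pelvic subset other than the cholinergic set
    if s1_para == para and para and not s1_sym and s1_pel:
        return "IV"
    return "other"


def classify_assignment(
    gene: str,
    split: Bipartition,
    roles: GroupRoleMap,
    score: float = float("nan"),
    require_all_pelvic: bool = False,
) -> PatternAssignment:
    label = classify_split(split, roles, require_all_pelvic=require_all_pelvic)
    return PatternAssignment(gene, label, split=split, score=score)


def tally_patterns(assignments: Iterable[PatternAssignment]) -> dict:
    """Count assignments per pattern and per consolidated category,
    including the aggregate counts used when reading the taxonomy
    (I+II argue against a parasympathetic pelvic identity, III+IV
    against a sympathetic one, V+VI track neurotransmitter phenotype)."""
    assignments = list(assignments)
    by_pattern = {p: 0 for p in PATTERN_ORDER}
    for a in assignments:
        by_pattern[a.pattern] += 1
    by_category = {PATTERN_CATEGORY[p]: n for p, n in by_pattern.items()}
    return {
        "n_genes": len(assignments),
        "by_pattern": by_pattern,
        "by_category": by_category,
        "consolidated": {
            "against_parasympathetic (I+II)": by_pattern["I"] + by_pattern["II"],
            "against_sympathetic (III+IV)": by_pattern["III"] + by_pattern["IV"],
            "neurotransmitter (V+VI)": by_pattern["V"] + by_pattern["VI"],
            "pelvic_specific (VII)": by_pattern["VII"],
            "other": by_pattern["other"],
        },
    }


def order_for_heatmap(
    assignments: Sequence[PatternAssignment],
) -> tuple[list[PatternAssignment], dict[str, tuple[int, int]]]:
    """Order genes in contiguous pattern blocks I..VII then "other",
    score-descending within each block (heatmap row order).

    Returns the ordered assignments and, per pattern present, its
    half-open [start, stop) row range.
    """
    rank = {p: i for i, p in enumerate(PATTERN_ORDER)}

    def key(a: PatternAssignment):
        s = a.score if a.score == a.score else float("-inf")  # NaN last
        return (rank[a.pattern], -s, a.gene)

    ordered = sorted(assignments, key=key)
    blocks: dict[str, tuple[int, int]] = {}
    if not ordered:
        return [], blocks
    start = 0
    for i, a in enumerate(ordered + [None]):  # type: ignore[list-item]
        if a is None or (i > start and a.pattern != ordered[start].pattern):
            blocks[ordered[start].pattern] = (start, i)
            start = i
        if a is None:
            break
    return ordered, blocks


def write_patterns_tsv(assignments: Sequence[PatternAssignment], path) -> pd.DataFrame:
    rows = [
        {
            "gene": a.gene,
            "pattern": a.pattern,
            "category": a.category,
            "subset_1": ";".join(a.split.subset_1) if a.split else "",
            "score": "-inf" if a.score == float("-inf") else a.score,
        }
        for a in assignments
    ]
    df = pd.DataFrame(rows, columns=["gene", "pattern", "category", "subset_1", "score"])
    df.to_csv(path, sep="\t", index=False)
    return df


def write_tally_json(tally: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(tally, fh, indent=2, sort_keys=True)
        fh.write("\n")
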