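"""Ig-class co-expression and cross-class VDJ-pattern sharing.

Under classical class-switch recombination (CSR) a B cell that expresses two
heavy-chain classes (say IgM and IgG) carries the *same* rearranged VDJ on
both transcripts — only the constant region differs.  This module counts Ig
classes per cell, labels two-class combinations (IgM+IgD, IgM+IgG, IgG+IgA,
other), and tests, per cell, whether classes co-expressed in that cell share
any identical recombination pattern.  A sharing fraction of 1 is the
classical-CSR expectation; a sharing fraction near 0 means each class carries
its own distinct rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .repertoire_core import CellProfile

__all__ = [
    "ClassCombination",
    "CrossClassReport",
    "class_count_category",
    "class_pair_label",
    "cross_class_sharing",
    "sharing_summary",
]

PAIR_LABELS = ("IgM_IgD", "IgM_IgG", "IgG_IgA", "other_pair")

_NAMED_PAIRS = {
    frozenset({"IGHM", "IGHD"}): "IgM_IgD",
    frozenset({"IGHM", "IGHG"}): "IgM_IgG",
    frozenset({"IGHG", "IGHA"}): "IgG_IgA",
}


@dataclass(frozen=True)
class ClassCombination:
    """A labelled set of co-expressed Ig classes."""

    label: str  # single | IgM_IgD | IgM_IgG | IgG_IgA | other_pair | three_or_more
    classes: frozenset


@dataclass
class CrossClassReport:
    """Pairwise pattern-sharing report for one multi-class cell.

    ``class_pairs`` holds one entry per unordered class pair
    ``(class_a, class_b, shared, a_only, b_only, shares_any)`` with
    ``class_a < class_b`` lexicographically.
    """

    barcode: str
    class_pairs: list

    @property
    def shares_any(self) -> bool:
        """True if any class pair in this cell shares at least one pattern."""
        return any(p[5] for p in self.class_pairs)


def class_count_category(profile: CellProfile):
    """Bin the number of Ig classes: "one" / "two" / "three" (>=3 -> "three").

    Returns None for cells without any classed IGH contig — such cells are
    excluded from class-count denominators rather than raising.
    """
    n = len(profile.c_classes)
    if n == 0:
        return None
    return ("one", "two")[n - 1] if n <= 2 else "three"


def class_pair_label(profile: CellProfile) -> ClassCombination:
    """Label a two-class cell's combination; requires exactly two classes."""
    if len(profile.c_classes) != 2:
        raise ValueError(
            f"class_pair_label requires exactly 2 classes, got {sorted(profile.c_classes)}"
        )
    classes = frozenset(profile.c_classes)
    return ClassCombination(_NAMED_PAIRS.get(classes, "other_pair"), classes)


def combination_label(profile: CellProfile) -> ClassCombination:
    """Full combination label: single / named pair / other_pair / three_or_more."""
    n = len(profile.c_classes)
    classes = frozenset(profile.c_classes)
    if n == 1:
        return ClassCombination("single", classes)
    if n == 2:
        return class_pair_label(profile)
    return ClassCombination("three_or_more", classes)


def cross_class_sharing(profile: CellProfile) -> CrossClassReport:
    """Pairwise pattern intersections between co-expressed classes of one cell.

    Uses ``per_class_patterns`` as built by repertoire_core under the active
    key mode — the same key that defines pattern multiplicity, so the sharing
    statistic is commensurable with the multiplicity statistic.  Classes with
    no full-length assembled pattern contribute an empty set (and thus cannot
    share).
    """
    pairs = []
    for a, b in combinations(sorted(profile.c_classes), 2):
        pa = profile.per_class_patterns.get(a, frozenset())
        pb = profile.per_class_patterns.get(b, frozenset())
        shared = frozenset(pa & pb)
        pairs.append((a, b, shared, frozenset(pa - pb), frozenset(pb - pa),
                      bool(shared)))
    return CrossClassReport(barcode=profile.barcode, class_pairs=pairs)


def sharing_summary(profiles, group_by=()) -> pd.DataFrame:
    """Per-group class-count composition, pair composition and sharing fraction.

    Emitted metrics:

    * ``class_count`` — one/two/three composition over cells with >=1 classed
      IGH contig (categories partition the denominator);
    * ``class_pair`` — IgM_IgD / IgM_IgG / IgG_IgA / other_pair composition
      among two-class cells;
    * ``cross_class_sharing`` — fraction of multi-class (>=2 classes) cells in
      which at least one class pair shares an identical pattern.

    Same output schema as :func:`repertoire_core.summarize_cohort`.
    """
    from .repertoire_core import _group_label  # shared grouping convention

    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    groups: dict = {}
    for prof in profiles:
        groups.setdefault(_group_label(prof, group_by), []).append(prof)

    rows = []
    for label in sorted(groups):
        members = groups[label]
        gname = "/".join(label)

        cats = [c for c in (class_count_category(p) for p in members) if c]
        denom = len(cats)
        for cat in ("one", "two", "three"):
            rows.append((gname, "class_count", cat, sum(c == cat for c in cats), denom))

        two_class = [p for p in members if len(p.c_classes) == 2]
        for lab in PAIR_LABELS:
            num = sum(class_pair_label(p).label == lab for p in two_class)
            rows.append((gname, "class_pair", lab, num, len(two_class)))

        multi = [p for p in members if len(p.c_classes) >= 2]
        num_shared = sum(cross_class_sharing(p).shares_any for p in multi)
        rows.append((gname, "cross_class_sharing", "shares_any", num_shared, len(multi)))

    out = pd.DataFrame(
        rows, columns=["group", "metric", "category", "numerator", "denominator"]
    )
    out["proportion"] = out["numerator"] / out["denominator"].where(
        out["denominator"] > 0
    )
    return out
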