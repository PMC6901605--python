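"""Per-cell V(D)J recombination-pattern counting and cohort summaries.

The central statistic: for each cell barcode, how many *distinct* heavy-chain
(V_H-D-J_H) and light-chain (V_K-J_K, V_L-J_L) recombination patterns are
observed among its assembled contigs.  Under strict allelic exclusion every
B cell carries exactly one productive heavy and one productive light
rearrangement, so multiplicities above one — and kappa/lambda co-expression —
quantify departures from the one-cell-one-antibody rule (or, on real data,
artifact load from doublets and ambient transcripts).

A *pattern* is keyed by the germline gene calls, optionally together with the
CDR3 sequence (``PatternKey``).  The nucleotide-level key (default) is the
most conservative distinctness claim: two contigs count as one pattern only
if V, D, J and the CDR3 nt sequence all agree.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .contig_io import ContigTable

__all__ = [
    "PatternKey",
    "QCFlags",
    "DEFAULT_QC",
    "V_SEGMENT_QC",
    "RecombinationPattern",
    "CellProfile",
    "collapse_c_class",
    "qc_filter",
    "build_cell_profiles",
    "multiplicity_category",
    "light_chain_usage",
    "v_segment_multiplicity",
    "summarize_cohort",
]

IG_CLASSES = ("IGHM", "IGHD", "IGHG", "IGHA", "IGHE")


class PatternKey(str, enum.Enum):
    """Which fields define the identity of a recombination pattern."""

    gene_only = "gene_only"          # (v, d, j)
    gene_cdr3nt = "gene_cdr3nt"      # (v, d, j, cdr3_nt)
    gene_cdr3aa = "gene_cdr3aa"      # (v, d, j, cdr3_aa)


@dataclass(frozen=True)
class QCFlags:
    """Which contig QC flags must hold for a contig to enter the analysis."""

    is_cell: bool = True
    high_confidence: bool = True
    productive: bool = True
    full_length: bool = True
    min_umis: int = 1


#: Default preset for pattern counting: cell-associated, high-confidence,
#: productive, fully assembled contigs.
DEFAULT_QC = QCFlags()

#: Preset for V-segment-level counting: drops the full-length requirement so
#: transcripts whose D/J ends failed to assemble still contribute their V gene.
V_SEGMENT_QC = QCFlags(full_length=False)


@dataclass(frozen=True)
class RecombinationPattern:
    """Identity of one rearrangement under the active key mode.

    ``cdr3`` is None in gene_only mode; equality is field-wise on
    allele-stripped gene names.
    """

    locus: str
    v_gene: str
    d_gene: object  # str or None (always None for light chains)
    j_gene: str
    cdr3: object = None

    def __post_init__(self):
        # order=True needs comparable fields; map None below any string
        object.__setattr__(self, "_sort_key", (
            self.locus, self.v_gene, self.d_gene or "", self.j_gene, self.cdr3 or ""))


@dataclass
class CellProfile:
    """Per-barcode aggregation of patterns, V genes and Ig classes."""

    barcode: str
    patterns_by_locus: dict = field(default_factory=dict)
    v_genes_by_locus: dict = field(default_factory=dict)
    c_classes: set = field(default_factory=set)
    per_class_patterns: dict = field(default_factory=dict)
    subset: str = "unassigned"
    donor: object = None

    def patterns(self, locus: str) -> frozenset:
        return self.patterns_by_locus.get(locus, frozenset())

    def sorted_patterns(self, locus: str) -> list:
        """Patterns in deterministic lexicographic (v, d, j, cdr3) order."""
        return sorted(self.patterns(locus), key=lambda p: p._sort_key)


def collapse_c_class(c_call) -> object:
    """Collapse a heavy-chain constant gene to class level (IGHG1..4 -> IGHG)."""
    if c_call is None or (isinstance(c_call, float) and pd.isna(c_call)):
        return None
    for cls in IG_CLASSES:
        if str(c_call).startswith(cls):
            return cls
    return None


def qc_filter(table: ContigTable, flags: QCFlags = DEFAULT_QC) -> ContigTable:
    """Return a new table keeping only contigs that pass all enabled flags."""
    df = table.df
    mask = df["umis"] >= flags.min_umis
    for name in ("is_cell", "high_confidence", "productive", "full_length"):
        if getattr(flags, name):
            mask &= df[name]
    return ContigTable(
        df=df.loc[mask].reset_index(drop=True),
        dialect=table.dialect,
        source=table.source,
        dropped=list(table.dropped),
    )


def _pattern_from_row(row, key_mode: PatternKey):
    if row.v_call is None or row.j_call is None:
        return None
    if key_mode is PatternKey.gene_cdr3nt:
        cdr3 = row.cdr3_nt
    elif key_mode is PatternKey.gene_cdr3aa:
        cdr3 = row.cdr3_aa
    else:
        cdr3 = None
    return RecombinationPattern(
        locus=row.locus, v_gene=row.v_call, d_gene=row.d_call,
        j_gene=row.j_call, cdr3=cdr3,
    )


def build_cell_profiles(
    table: ContigTable,
    key_mode: PatternKey = PatternKey.gene_cdr3nt,
    donor=None,
) -> dict:
    """Aggregate a (QC-filtered) contig table into one CellProfile per barcode.

    A contig contributes a pattern to ``patterns_by_locus`` when both its V
    and J calls are present (D is optional — heavy-chain contigs with an
    unresolved D still define a pattern with ``d_gene=None``).  Every contig
    with a V call contributes to ``v_genes_by_locus`` regardless of assembly
    completeness.  Heavy-chain patterns are additionally binned per Ig class
    in ``per_class_patterns``; contigs without a C call count toward
    ``patterns_by_locus`` but not toward any class.

    Returns an insertion-ordered dict barcode -> CellProfile.
    """
    profiles: dict = {}
    for row in table.df.itertuples(index=False):
        prof = profiles.get(row.barcode)
        if prof is None:
            prof = profiles[row.barcode] = CellProfile(barcode=row.barcode, donor=donor)
        pattern = _pattern_from_row(row, key_mode)
        if pattern is not None:
            prof.patterns_by_locus.setdefault(row.locus, set()).add(pattern)
        if row.v_call is not None:
            prof.v_genes_by_locus.setdefault(row.locus, set()).add(row.v_call)
        if row.locus == "IGH":
            cls = collapse_c_class(row.c_call)
            if cls is not None:
                prof.c_classes.add(cls)
                if pattern is not None:
                    prof.per_class_patterns.setdefault(cls, set()).add(pattern)
    for prof in profiles.values():
        prof.patterns_by_locus = {
            k: frozenset(v) for k, v in prof.patterns_by_locus.items()
        }
        prof.v_genes_by_locus = {
            k: frozenset(v) for k, v in prof.v_genes_by_locus.items()
        }
        prof.per_class_patterns = {
            k: frozenset(v) for k, v in prof.per_class_patterns.items()
        }
    return profiles


def multiplicity_category(profile: CellProfile, locus: str) -> str:
    """Bin the number of distinct patterns at a locus: zero/one/two/three_or_more."""
    n = len(profile.patterns(locus))
    if n == 0:
        return "zero"
    if n == 1:
        return "one"
    if n == 2:
        return "two"
    return "three_or_more"


def light_chain_usage(profile: CellProfile) -> str:
    """kappa_only / lambda_only / both / none from light-locus pattern sets."""
    has_k = bool(profile.patterns("IGK"))
    has_l = bool(profile.patterns("IGL"))
    if has_k and has_l:
        return "both"
    if has_k:
        return "kappa_only"
    if has_l:
        return "lambda_only"
    return "none"


def v_segment_multiplicity(profile: CellProfile, locus: str) -> int:
    """Number of distinct (allele-stripped) V genes seen at a locus."""
    return len(profile.v_genes_by_locus.get(locus, ()))


# ---------------------------------------------------------------------------
# Cohort summaries


_MULTIPLICITY_CATEGORIES = ("one", "two", "three_or_more")
_USAGE_CATEGORIES = ("kappa_only", "lambda_only", "both")


def _group_label(profile: CellProfile, group_by) -> tuple:
    parts = []
    for key in group_by:
        if key == "donor":
            parts.append(str(profile.donor))
        elif key == "subset":
            parts.append(profile.subset)
        else:
            raise ValueError(f"unknown group key {key!r}")
    return tuple(parts) if parts else ("all",)


def summarize_cohort(
    profiles,
    group_by=(),
    metrics=("igh_multiplicity", "igk_multiplicity", "igl_multiplicity",
             "light_chain_usage"),
) -> pd.DataFrame:
    """Build a per-group proportion table with explicit numerators/denominators.

    Denominator conventions (per-metric, matching how per-donor n's are
    reported for locus-stratified figures):

    * ``{igh,igk,igl}_multiplicity`` — cells with >=1 pattern at that locus;
      categories one / two / three_or_more partition the denominator.
    * ``light_chain_usage`` — cells with >=1 light-chain pattern; categories
      kappa_only / lambda_only / both partition the denominator.
    * ``multi_{igh,igk,igl}_v`` — numerator = cells with >=2 distinct V genes
      at the locus, denominator = cells with >=1 V gene there (V-segment
      preset tables).
    * ``multi_{igh,igk,igl}_pattern`` — numerator = cells with >=2 patterns,
      denominator = cells with >=1 pattern.

    Returns a DataFrame with columns
    ``group, metric, category, numerator, denominator, proportion`` sorted
    lexicographically; ``proportion`` is NA when the denominator is 0.
    """
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    if not profiles:
        raise ValueError("summarize_cohort needs at least one profile")

    groups: dict = {}
    for prof in profiles:
        groups.setdefault(_group_label(prof, group_by), []).append(prof)

    rows = []
    locus_of = {"igh": "IGH", "igk": "IGK", "igl": "IGL"}
    for label in sorted(groups):
        members = groups[label]
        gname = "/".join(label)
        for metric in metrics:
            if metric.endswith("_multiplicity"):
                locus = locus_of[metric.split("_")[0]]
                cats = [
                    multiplicity_category(p, locus)
                    for p in members
                    if p.patterns(locus)
                ]
                denom = len(cats)
                for cat in _MULTIPLICITY_CATEGORIES:
                    num = sum(c == cat for c in cats)
                    rows.append((gname, metric, cat, num, denom))
            elif metric == "light_chain_usage":
                cats = [
                    light_chain_usage(p)
                    for p in members
                    if p.patterns("IGK") or p.patterns("IGL")
                ]
                denom = len(cats)
                for cat in _USAGE_CATEGORIES:
                    num = sum(c == cat for c in cats)
                    rows.append((gname, metric, cat, num, denom))
            elif metric.startswith("multi_") and metric.endswith("_v"):
                locus = locus_of[metric.split("_")[1]]
                counts = [
                    v_segment_multiplicity(p, locus)
                    for p in members
                    if v_segment_multiplicity(p, locus) >= 1
                ]
                rows.append(
                    (gname, metric, "ge2", sum(c >= 2 for c in counts), len(counts))
                )
            elif metric.startswith("multi_") and metric.endswith("_pattern"):
                locus = locus_of[metric.split("_")[1]]
                counts = [len(p.patterns(locus)) for p in members if p.patterns(locus)]
                rows.append(
                    (gname, metric, "ge2", sum(c >= 2 for c in counts), len(counts))
                )
            else:
                raise ValueError(f"unknown metric {metric!r}")

    out = pd.DataFrame(
        rows, columns=["group", "metric", "category", "numerator", "denominator"]
    )
    out["proportion"] = out["numerator"] / out["denominator"].where(
        out["denominator"] > 0
    )
    return out.sort_values(["group", "metric", "category"], kind="stable").reset_index(
        drop=True
    )
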