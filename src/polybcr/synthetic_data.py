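"""Truth-tracked synthetic single-cell V(D)J data generator.

Generates per-cell contig annotation tables, a paired marker-gene expression
matrix and a ground-truth table with the statistical structure the analysis
pipeline assumes:

* per-locus distributions of the number of distinct recombination patterns
  per cell (1, 2 or 3), configurable per B-cell subset;
* kappa/lambda co-expression rates per subset;
* per-subset Ig-class-count distributions and class-pair composition (naive
  pairs favour IgM+IgD, memory pairs favour IgG+IgA, IgM+IgG occurs in both);
* a ``cross_class_share_rate`` interpolating between the classical
  class-switch expectation (all classes of a cell carry one common VDJ
  pattern; rate 1) and fully class-private patterns (rate 0);
* doublet and ambient-contamination artifact injectors with recorded
  provenance, for sensitivity analyses of apparent multi-pattern rates.

Default rates are mid-range values of the per-donor percentages observed in
healthy peripheral-blood CD19+ cohorts profiled with the 10x 5'/V(D)J assay
(two-pattern heavy chains ~7%% of cells, kappa/lambda co-expression ~20-28%%
in naive cells, plasma cells ~1%% of the cohort, GEX/VDJ barcode overlap
~94%%); artifact rates default to 0 so the generator's native structure is
exactly the configured one.

A cell whose class count exceeds its drawn pattern count carries the surplus
classes on partially assembled contigs (``full_length=False``, no J call):
the class is observable but contributes no countable pattern.  This mirrors
real 5' V(D)J libraries, where many constant-region-bearing transcripts fail
to assemble into an intact V-D-J contig, and keeps the configured pattern
and class-count distributions simultaneously recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contig_io import SCHEMA_COLUMNS, ContigTable
from .gex_link import ExpressionMatrix

__all__ = [
    "SimConfig",
    "GermlineRegistry",
    "TruthTable",
    "build_registry",
    "simulate_cells",
    "inject_doublets",
    "inject_ambient",
    "simulate_amplicons",
    "write_sim_outputs",
]

_NUCS = np.array(list("ACGT"))

OTHER_PAIRS = [
    frozenset(p)
    for p in (
        ("IGHM", "IGHA"), ("IGHM", "IGHE"), ("IGHD", "IGHG"), ("IGHD", "IGHA"),
        ("IGHD", "IGHE"), ("IGHG", "IGHE"), ("IGHA", "IGHE"),
    )
]

_PAIR_SETS = {
    "IgM_IgD": frozenset({"IGHM", "IGHD"}),
    "IgM_IgG": frozenset({"IGHM", "IGHG"}),
    "IgG_IgA": frozenset({"IGHG", "IGHA"}),
}


def _check_dist(name, probs):
    probs = np.asarray(probs, dtype=float)
    if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name}: probabilities must lie in [0,1] and sum to 1")
    return probs


@dataclass
class SimConfig:
    """Study conditions for the generator.  All rates are probabilities.

    ``pattern_count_dist[locus][subset]`` is ``(P(1), P(2), P(3))`` for the
    number of distinct patterns a cell carries at that locus (given the locus
    is detected in that cell at all).
    """

    n_cells: int = 4000
    seed: int = 0

    subset_mix: dict = field(
        default_factory=lambda: {"naive": 0.52, "memory": 0.47, "plasma": 0.01}
    )

    pattern_count_dist: dict = field(
        default_factory=lambda: {
            "IGH": {"naive": (0.935, 0.062, 0.003), "memory": (0.912, 0.084, 0.004),
                    "plasma": (0.994, 0.005, 0.001)},
            "IGK": {"naive": (0.868, 0.128, 0.004), "memory": (0.883, 0.113, 0.004),
                    "plasma": (0.989, 0.010, 0.001)},
            "IGL": {"naive": (0.782, 0.213, 0.005), "memory": (0.848, 0.147, 0.005),
                    "plasma": (0.989, 0.010, 0.001)},
        }
    )

    kappa_lambda_coexpression_rate: dict = field(
        default_factory=lambda: {"naive": 0.28, "memory": 0.12, "plasma": 0.20}
    )
    #: P(kappa | exactly one light-chain type), reflecting the ~60/40 human
    #: kappa/lambda usage bias.
    kappa_fraction: float = 0.60
    #: fraction of cells with at least one assembled heavy-chain pattern
    #: (per-donor heavy-chain n's are a few percent below the light-chain n's).
    igh_detection_rate: float = 0.94

    class_count_dist: dict = field(
        default_factory=lambda: {"naive": (0.75, 0.22, 0.03),
                                 "memory": (0.60, 0.36, 0.04),
                                 "plasma": (0.90, 0.09, 0.01)}
    )
    pair_composition: dict = field(
        default_factory=lambda: {
            "naive": {"IgM_IgD": 0.66, "IgM_IgG": 0.17, "IgG_IgA": 0.03,
                      "other_pair": 0.14},
            "memory": {"IgM_IgD": 0.05, "IgM_IgG": 0.28, "IgG_IgA": 0.37,
                       "other_pair": 0.30},
            "plasma": {"IgM_IgD": 0.10, "IgM_IgG": 0.30, "IgG_IgA": 0.40,
                       "other_pair": 0.20},
        }
    )
    single_class_dist: dict = field(
        default_factory=lambda: {
            "naive": {"IGHM": 0.75, "IGHD": 0.20, "IGHG": 0.04, "IGHA": 0.01},
            "memory": {"IGHM": 0.15, "IGHG": 0.55, "IGHA": 0.28, "IGHE": 0.02},
            "plasma": {"IGHG": 0.60, "IGHA": 0.35, "IGHM": 0.05},
        }
    )

    cross_class_share_rate: float = 0.0
    doublet_rate: float = 0.0
    ambient_rate: float = 0.0

    #: fraction of V(D)J cell barcodes also captured in the 5' GEX library.
    gex_detection_rate: float = 0.9434
    #: separation (in noise SDs) between positive and negative marker means.
    marker_separation: float = 5.0
    #: probability a truly negative marker shows a small non-zero value
    #: (ambient leakage); otherwise negative markers read exactly 0.
    negative_leak_rate: float = 0.005

    registry_sizes: dict = field(
        default_factory=lambda: {"IGH": (20, 10, 6), "IGK": (15, 0, 5),
                                 "IGL": (15, 0, 5)}
    )

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        _check_dist("subset_mix", list(self.subset_mix.values()))
        for locus, per_subset in self.pattern_count_dist.items():
            for subset, probs in per_subset.items():
                _check_dist(f"pattern_count_dist[{locus}][{subset}]", probs)
        for subset, probs in self.class_count_dist.items():
            _check_dist(f"class_count_dist[{subset}]", probs)
        for subset, comp in self.pair_composition.items():
            _check_dist(f"pair_composition[{subset}]", list(comp.values()))
        for subset, comp in self.single_class_dist.items():
            _check_dist(f"single_class_dist[{subset}]", list(comp.values()))
        for name in ("cross_class_share_rate", "ambient_rate",
                     "gex_detection_rate", "kappa_fraction",
                     "igh_detection_rate", "negative_leak_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        for subset, v in self.kappa_lambda_coexpression_rate.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError("kappa_lambda_coexpression_rate must lie in [0,1]")
        if not 0.0 <= self.doublet_rate <= 0.5:
            raise ValueError("doublet_rate must lie in [0, 0.5]")
        for locus, (nv, nd, nj) in self.registry_sizes.items():
            if nv < 1 or nj < 1 or nd < 0:
                raise ValueError(f"registry_sizes[{locus}]: need n_V>=1, n_J>=1, n_D>=0")
            if locus in ("IGK", "IGL") and nd != 0:
                raise ValueError(f"{locus} must have an empty D pool")


@dataclass
class GermlineRegistry:
    """Named synthetic germline V/D/J segment pools with nucleotide sequences."""

    segments: dict  # locus -> {"V": {name: seq}, "D": {...}, "J": {...}}

    def pool(self, locus: str, kind: str) -> dict:
        return self.segments[locus][kind]

    def names(self, locus: str, kind: str) -> list:
        return list(self.segments[locus][kind])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for locus, pools in self.segments.items():
                for kind, pool in pools.items():
                    for name, seq in pool.items():
                        fh.write(f">{name}\n{seq}\n")

    @classmethod
    def from_fasta(cls, path) -> "GermlineRegistry":
        """Load a registry from FASTA; names must start with
        {IGH,IGK,IGL}{V,D,J} (IMGT naming convention)."""
        from Bio import SeqIO

        segments: dict = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            name = rec.id
            locus, kind = name[:3], name[3]
            if locus not in ("IGH", "IGK", "IGL") or kind not in "VDJ":
                raise ValueError(f"cannot infer locus/segment type from {name!r}")
            segments.setdefault(locus, {"V": {}, "D": {}, "J": {}})[kind][name] = str(
                rec.seq
            ).upper()
        return cls(segments=segments)


_SEG_LEN = {"V": 300, "D": 20, "J": 50}


def build_registry(config: SimConfig, seed=None) -> GermlineRegistry:
    """Reproducible synthetic germline pools (V 300 nt, D 20 nt, J 50 nt)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    segments = {}
    for locus, (nv, nd, nj) in config.registry_sizes.items():
        pools = {}
        for kind, n in zip("VDJ", (nv, nd, nj)):
            pool = {}
            for i in range(n):
                name = f"{locus}{kind}{i % 7 + 1}-S{i + 1}"
                pool[name] = "".join(rng.choice(_NUCS, size=_SEG_LEN[kind]))
            pools[kind] = pool
        segments[locus] = pools
    return GermlineRegistry(segments=segments)


@dataclass
class TruthTable:
    """Ground truth per emitted barcode.

    Columns: subset, provenance (native/doublet/ambient_contaminated),
    constituents (';'-joined source cell barcodes for doublets), per-locus
    pattern serializations ('v|d|j|cdr3' joined by ';'), classes,
    shares_cross_class, n_ambient_contigs.
    """

    df: pd.DataFrame

    def pattern_count(self, barcode: str, locus: str) -> int:
        s = self.df.loc[barcode, f"{locus.lower()}_patterns"]
        return 0 if not s else len(set(s.split(";")))


def _serialize_patterns(patterns) -> str:
    return ";".join(
        sorted("|".join("" if f is None else f for f in p) for p in patterns)
    )


class _CellDraw:
    """Workspace for one simulated cell (native, pre-artifact)."""

    __slots__ = ("barcode", "subset", "patterns", "classes", "shares", "light_usage")


def _draw_junction(rng, registry, locus, v_name, d_name, j_name) -> str:
    """In-frame CDR3 nt: V 3' flank + N1 (+ D) + N2 + J 5' flank.

    N-region lengths are uniform on 0-6, with the second adjusted so the
    total length is a multiple of 3 (an in-frame, productive junction).
    """
    v_part = registry.pool(locus, "V")[v_name][-6:]
    d_part = registry.pool(locus, "D")[d_name] if d_name else ""
    j_part = registry.pool(locus, "J")[j_name][:6]
    n1 = int(rng.integers(0, 7))
    fixed = len(v_part) + n1 + len(d_part) + len(j_part)
    choices = [n2 for n2 in range(7) if (fixed + n2) % 3 == 0]
    n2 = int(rng.choice(choices))
    ns = "".join(rng.choice(_NUCS, size=n1 + n2))
    return v_part + ns[:n1] + d_part + ns[n1:] + j_part


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


def _draw_patterns(rng, registry, locus, k) -> list:
    """k distinct (v, d, j, cdr3_nt) tuples at a locus."""
    v_names = registry.names(locus, "V")
    d_names = registry.names(locus, "D")
    j_names = registry.names(locus, "J")
    out = []
    seen = set()
    while len(out) < k:
        v = v_names[rng.integers(len(v_names))]
        d = d_names[rng.integers(len(d_names))] if d_names else None
        j = j_names[rng.integers(len(j_names))]
        cdr3 = _draw_junction(rng, registry, locus, v, d, j)
        key = (v, d, j, cdr3)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def _draw_class_set(rng, config, subset) -> frozenset:
    n = 1 + rng.choice(3, p=_check_dist("class_count", config.class_count_dist[subset]))
    if n == 1:
        comp = config.single_class_dist[subset]
        return frozenset({rng.choice(list(comp), p=_check_dist("s", list(comp.values())))})
    if n == 2:
        comp = config.pair_composition[subset]
        label = rng.choice(list(comp), p=_check_dist("p", list(comp.values())))
        if label == "other_pair":
            return OTHER_PAIRS[rng.integers(len(OTHER_PAIRS))]
        return _PAIR_SETS[label]
    # three classes: a named pair plus one extra class
    comp = config.pair_composition[subset]
    label = rng.choice(list(comp), p=_check_dist("p", list(comp.values())))
    base = (OTHER_PAIRS[rng.integers(len(OTHER_PAIRS))]
            if label == "other_pair" else _PAIR_SETS[label])
    rest = [c for c in ("IGHM", "IGHD", "IGHG", "IGHA", "IGHE") if c not in base]
    return base | {rest[rng.integers(len(rest))]}


def simulate_cells(config: SimConfig, registry: GermlineRegistry = None, seed=None):
    """Draw a cohort of native cells.

    Returns ``(ContigTable, ExpressionMatrix, TruthTable)``.  Artifacts are
    not injected here; apply :func:`inject_doublets` / :func:`inject_ambient`
    explicitly.  Fully deterministic given (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if registry is None:
        registry = build_registry(config, seed=rng.integers(2**31))

    subsets = list(config.subset_mix)
    subset_probs = _check_dist("subset_mix", list(config.subset_mix.values()))

    contig_rows = []
    truth_rows = []
    contig_serial = 0

    def add_contig(barcode, locus, v, d, j, c_call, cdr3_nt, full_length, umis=None):
        nonlocal contig_serial
        contig_serial += 1
        cdr3_aa = _translate(cdr3_nt) if cdr3_nt else None
        contig_rows.append({
            "barcode": barcode,
            "contig_id": f"{barcode}_contig_{contig_serial}",
            "locus": locus,
            "v_call": v, "d_call": d, "j_call": j, "c_call": c_call,
            "cdr3_aa": cdr3_aa, "cdr3_nt": cdr3_nt,
            "productive": True, "full_length": full_length,
            "high_confidence": True, "is_cell": True,
            "umis": int(2 + rng.poisson(20)) if umis is None else umis,
            "reads": int(50 + rng.poisson(500)),
        })

    for i in range(config.n_cells):
        barcode = f"CELL{i:06d}-1"
        subset = subsets[rng.choice(len(subsets), p=subset_probs)]

        patterns = {"IGH": [], "IGK": [], "IGL": []}
        classes = frozenset()
        shares = False

        # heavy chain
        if rng.random() < config.igh_detection_rate:
            k = 1 + rng.choice(3, p=np.asarray(
                config.pattern_count_dist["IGH"][subset], dtype=float))
            patterns["IGH"] = _draw_patterns(rng, registry, "IGH", k)
            classes = _draw_class_set(rng, config, subset)
            class_list = sorted(classes)
            shares = (len(class_list) >= 2
                      and rng.random() < config.cross_class_share_rate)
            if shares:
                # every class carries the first pattern; surplus patterns are
                # attached to random classes
                v, d, j, cdr3 = patterns["IGH"][0]
                for cls in class_list:
                    add_contig(barcode, "IGH", v, d, j, cls, cdr3, True)
                for v, d, j, cdr3 in patterns["IGH"][1:]:
                    cls = class_list[rng.integers(len(class_list))]
                    add_contig(barcode, "IGH", v, d, j, cls, cdr3, True)
            else:
                # class-private patterns: the k patterns are dealt out over
                # the first min(c, k) classes; surplus classes ride on
                # partially assembled (class-only) contigs
                owners = [class_list[min(idx, len(class_list) - 1)]
                          for idx in range(k)]
                rng.shuffle(owners)
                for (v, d, j, cdr3), cls in zip(patterns["IGH"], owners):
                    add_contig(barcode, "IGH", v, d, j, cls, cdr3, True)
                v_names = registry.names("IGH", "V")
                for cls in class_list[min(len(class_list), k):]:
                    v = v_names[rng.integers(len(v_names))]
                    add_contig(barcode, "IGH", v, None, None, cls, None, False)

        # light chains
        if rng.random() < config.kappa_lambda_coexpression_rate[subset]:
            light_loci, usage = ["IGK", "IGL"], "both"
        elif rng.random() < config.kappa_fraction:
            light_loci, usage = ["IGK"], "kappa_only"
        else:
            light_loci, usage = ["IGL"], "lambda_only"
        for locus in light_loci:
            k = 1 + rng.choice(3, p=np.asarray(
                config.pattern_count_dist[locus][subset], dtype=float))
            patterns[locus] = _draw_patterns(rng, registry, locus, k)
            c_call = "IGKC" if locus == "IGK" else "IGLC"
            for v, d, j, cdr3 in patterns[locus]:
                add_contig(barcode, locus, v, d, j, c_call, cdr3, True)

        truth_rows.append({
            "barcode": barcode,
            "subset": subset,
            "provenance": "native",
            "constituents": barcode,
            "igh_patterns": _serialize_patterns(patterns["IGH"]),
            "igk_patterns": _serialize_patterns(patterns["IGK"]),
            "igl_patterns": _serialize_patterns(patterns["IGL"]),
            "classes": ";".join(sorted(classes)),
            "light_usage": usage,
            "shares_cross_class": shares,
            "n_ambient_contigs": 0,
        })

    contig_df = pd.DataFrame(contig_rows, columns=SCHEMA_COLUMNS)
    table = ContigTable(df=contig_df, dialect="tenx_csv", source="simulated")
    truth = TruthTable(df=pd.DataFrame(truth_rows).set_index("barcode", drop=False))

    matrix = _simulate_markers(rng, config, truth)
    return table, matrix, truth


def _simulate_markers(rng, config: SimConfig, truth: TruthTable) -> ExpressionMatrix:
    """Per-subset marker expression for the GEX-captured barcode subset.

    Positive markers ~ N(separation, 1) floored at a small positive value;
    negative markers read exactly 0 except for rare ambient leakage
    (dropout-dominated zeros, as in log-normalized scRNA data); CD38 has a
    moderate baseline in all B cells and sits ``separation`` SDs higher in
    plasma cells.
    """
    sep = config.marker_separation
    captured = [
        bc for bc in truth.df["barcode"]
        if rng.random() < config.gex_detection_rate
    ]
    pos_by_subset = {
        "naive": {"CD19", "IGHM", "IGHD"},
        "memory": {"CD19", "CD27"},
        "plasma": {"CD19", "CD27"},
    }
    genes = ["CD19", "CD27", "CD38", "IGHM", "IGHD"]
    values = np.zeros((len(captured), len(genes)))
    subset_of = truth.df["subset"]
    cd38_base = 1.5
    for r, bc in enumerate(captured):
        subset = subset_of[bc]
        positives = pos_by_subset[subset]
        for c, gene in enumerate(genes):
            if gene == "CD38":
                mean = cd38_base + (sep if subset == "plasma" else 0.0)
                values[r, c] = max(0.0, rng.normal(mean, 1.0))
            elif gene in positives:
                values[r, c] = max(0.05, rng.normal(sep, 1.0))
            elif rng.random() < config.negative_leak_rate:
                values[r, c] = rng.uniform(0.2, 1.0)
    return ExpressionMatrix(pd.DataFrame(values, index=captured, columns=genes))


# ---------------------------------------------------------------------------
# Artifact injectors


def inject_doublets(table: ContigTable, truth: TruthTable, rate: float, seed: int):
    """Merge random disjoint cell pairs under one barcode.

    ``rate`` is the target fraction of *emitted* barcodes that are doublets:
    with N input cells, d = round(rate*N/(1+rate)) pairs are merged, leaving
    N-d barcodes of which d are doublets.  For a fixed seed the merged pair
    set at a lower rate is a prefix of (nested in) the set at a higher rate,
    so apparent multi-pattern rates are monotone in ``rate`` by construction.

    Returns a new ``(ContigTable, TruthTable)``; inputs are not modified.
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError("doublet rate must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    barcodes = list(truth.df["barcode"])
    order = [barcodes[i] for i in rng.permutation(len(barcodes))]
    n = len(barcodes)
    d = int(round(rate * n / (1.0 + rate)))

    df = table.df.copy()
    tdf = truth.df.copy()
    for p in range(d):
        keep, merge = order[2 * p], order[2 * p + 1]
        df.loc[df["barcode"] == merge, "barcode"] = keep
        for col in ("igh_patterns", "igk_patterns", "igl_patterns", "classes"):
            parts = set(filter(None, tdf.loc[keep, col].split(";"))) | set(
                filter(None, tdf.loc[merge, col].split(";"))
            )
            tdf.loc[keep, col] = ";".join(sorted(parts))
        tdf.loc[keep, "provenance"] = "doublet"
        tdf.loc[keep, "constituents"] = f"{keep};{merge}"
        tdf = tdf.drop(index=merge)
    new_table = ContigTable(df=df.reset_index(drop=True), dialect=table.dialect,
                            source=table.source, dropped=list(table.dropped))
    return new_table, TruthTable(df=tdf)


def inject_ambient(table: ContigTable, truth: TruthTable, rate: float, seed: int):
    """Append, per cell with probability ``rate``, one stray contig copied
    from a random other cell's pool, at UMI count 1 (ambient transcripts are
    low-support, so a UMI floor of 2 removes them).

    Returns a new ``(ContigTable, TruthTable)``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("ambient rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    df = table.df
    tdf = truth.df.copy()
    barcodes = list(tdf["barcode"])
    # all randomness drawn up front so that, for a fixed seed, the set of
    # contaminated cells at a lower rate is a subset of the set at a higher
    # rate — apparent multi-pattern rates are then monotone in `rate`
    u = rng.random(len(barcodes))
    picks = rng.random(len(barcodes))
    new_rows = []
    for ci, bc in enumerate(barcodes):
        if u[ci] >= rate:
            continue
        donor_pool = df.index[df["barcode"] != bc]
        if len(donor_pool) == 0:
            continue
        src = df.loc[donor_pool[int(picks[ci] * len(donor_pool))]].copy()
        src["barcode"] = bc
        src["contig_id"] = f"{bc}_ambient_{len(new_rows) + 1}"
        src["umis"] = 1
        new_rows.append(src)
        if tdf.loc[bc, "provenance"] == "native":
            tdf.loc[bc, "provenance"] = "ambient_contaminated"
        tdf.loc[bc, "n_ambient_contigs"] += 1
    out = df if not new_rows else pd.concat(
        [df, pd.DataFrame(new_rows)], ignore_index=True
    )
    new_table = ContigTable(df=out.reset_index(drop=True), dialect=table.dialect,
                            source=table.source, dropped=list(table.dropped))
    return new_table, TruthTable(df=tdf)


# ---------------------------------------------------------------------------
# Sanger amplicon simulation


def simulate_amplicons(
    registry: GermlineRegistry,
    pattern_counts,
    locus: str = "IGH",
    reads_per_pattern: int = 2,
    mutation_rate: float = 0.0,
    seed: int = 0,
):
    """Synthesize Sanger-style amplicon reads for cells with known pattern counts.

    Parameters
    ----------
    pattern_counts : sequence of int
        One entry per cell: the number of distinct recombination patterns
        that cell carries.  Each pattern yields ``reads_per_pattern`` reads
        (full V + N/D junction + full J), optionally with random
        substitutions at ``mutation_rate`` per base.

    Returns
    -------
    (reads, truth) where reads is a list of ``(cell_id, read_id, sequence)``
    tuples and truth a DataFrame with the source segments per read.
    """
    rng = np.random.default_rng(seed)
    reads = []
    truth_rows = []
    for ci, k in enumerate(pattern_counts):
        cell_id = f"SC{ci:04d}"
        pats = _draw_patterns(rng, registry, locus, int(k))
        for pi, (v, d, j, _cdr3) in enumerate(pats):
            n1 = int(rng.integers(0, 7))
            n2 = int(rng.integers(0, 7))
            insert = ("".join(rng.choice(_NUCS, size=n1))
                      + (registry.pool(locus, "D")[d] if d else "")
                      + "".join(rng.choice(_NUCS, size=n2)))
            template = registry.pool(locus, "V")[v] + insert + registry.pool(
                locus, "J")[j]
            for ri in range(reads_per_pattern):
                seq = _mutate(rng, template, mutation_rate)
                read_id = f"{cell_id}_p{pi}_r{ri}"
                reads.append((cell_id, read_id, seq))
                truth_rows.append({
                    "cell_id": cell_id, "read_id": read_id, "locus": locus,
                    "v_call": v, "d_call": d, "j_call": j, "pattern_index": pi,
                })
    return reads, pd.DataFrame(truth_rows)


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        alt = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alt[rng.integers(3)]
    return "".join(arr)


def write_sim_outputs(out_dir, table: ContigTable, matrix: ExpressionMatrix,
                      truth: TruthTable) -> None:
    """Write a simulation as 10x-dialect CSV + MTX triplet dir + truth TSV."""
    from .contig_io import write_contig_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_contig_table(table, out_dir / "filtered_contig_annotations.csv", "tenx_csv")
    matrix.to_mtx_dir(out_dir / "matrix")
    truth.df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
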