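"""Germline V/D/J assignment for Sanger amplicon reads.

Single-cell validation arm: amplicons of the rearranged variable region are
assigned to germline segments by best-identity local alignment against a
registry of named V/D/J sequences, then reads are collapsed to the unique
recombination patterns of each cell (the same dedup semantics used for 10x
contigs), and segment-usage spectra are tabulated.

Alignment is plain Smith-Waterman-style local alignment (match +1, mismatch
-1, gap -2 by default) via Bio.Align.PairwiseAligner — a desk-scale
equivalent of a BLAST best-hit search against a germline database.  The
junction (the read region between the end of the V alignment and the start
of the J alignment) stands in for the CDR3 in nucleotide-level pattern keys;
the D segment is searched only inside that window and reported only when its
alignment spans at least ``min_d_length`` read bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align, SeqIO

from .repertoire_core import PatternKey, RecombinationPattern
from .synthetic_data import GermlineRegistry

__all__ = [
    "SangerRead",
    "AlignParams",
    "PatternCall",
    "assign_germline",
    "assign_all",
    "collapse_unique_patterns",
    "segment_usage_spectrum",
    "read_sanger_fasta",
    "calls_to_frame",
]


@dataclass(frozen=True)
class SangerRead:
    """One Sanger read: a sequenced amplicon clone from one sorted cell."""

    cell_id: str
    read_id: str
    sequence: str
    locus_hint: str = "unknown"  # IGH / IGK / IGL / unknown (from primer set)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty read sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"read contains non-ACGTN characters: {sorted(bad)}")


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    min_identity: float = 80.0  # percent, for V and J acceptance
    min_coverage: float = 0.5   # min fraction of the germline segment aligned
    min_d_length: int = 8       # min read bases a D alignment must cover
    tie_mode: str = "strict"    # strict -> ambiguous; lenient -> smallest name


@dataclass
class PatternCall:
    """Germline assignment for one read."""

    cell_id: str
    read_id: str
    locus: str
    v_call: object = None
    d_call: object = None
    j_call: object = None
    v_identity: float = 0.0
    j_identity: float = 0.0
    junction: object = None
    status: str = "assigned"  # assigned | no_V | no_J | ambiguous

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap
    aligner.extend_gap_score = params.gap
    return aligner


def _best_hits(aligner, read_seq: str, pool: dict):
    """Names achieving the maximal local-alignment score against the read."""
    best_score, best_names = None, []
    for name in sorted(pool):
        score = aligner.score(read_seq, pool[name])
        if best_score is None or score > best_score:
            best_score, best_names = score, [name]
        elif score == best_score:
            best_names.append(name)
    return best_score, best_names


def _align_details(aligner, read_seq: str, segment: str):
    """(identity_percent, read_start, read_end, read_span, segment_coverage)
    of the best local alignment of ``segment`` against ``read_seq``."""
    aln = aligner.align(read_seq, segment)[0]
    counts = aln.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / ncols if ncols else 0.0
    target_ranges = aln.aligned[0]
    start = int(target_ranges[0][0])
    end = int(target_ranges[-1][1])
    seg_span = sum(int(e) - int(s) for s, e in aln.aligned[1])
    coverage = seg_span / len(segment) if segment else 0.0
    return identity, start, end, end - start, coverage


def assign_germline(
    read: SangerRead,
    registry: GermlineRegistry,
    params: AlignParams = AlignParams(),
) -> PatternCall:
    """Assign the best-matching germline V, (D,) and J to one read.

    V and J are each assigned by highest local-alignment score over their
    pool and accepted only at >= ``min_identity`` percent identity; equal
    best scores yield status ``ambiguous`` in strict mode or the
    lexicographically smallest name in lenient mode.  The D segment is
    searched inside the inter-V-J window only.  When ``locus_hint`` is
    unknown, the locus whose V pool scores highest is used.
    """
    aligner = _aligner(params)
    seq = read.sequence.upper()

    if read.locus_hint in registry.segments:
        locus = read.locus_hint
        v_score, v_names = _best_hits(aligner, seq, registry.pool(locus, "V"))
    else:
        locus, v_score, v_names = None, None, []
        for cand in registry.segments:
            score, names = _best_hits(aligner, seq, registry.pool(cand, "V"))
            if v_score is None or score > v_score:
                locus, v_score, v_names = cand, score, names
    call = PatternCall(cell_id=read.cell_id, read_id=read.read_id, locus=locus or "unknown")
    if not v_names:
        call.status = "no_V"
        return call
    v_name = min(v_names)
    v_identity, _v_start, v_end, _span, v_cov = _align_details(
        aligner, seq, registry.pool(locus, "V")[v_name]
    )
    if v_identity < params.min_identity or v_cov < params.min_coverage:
        call.status = "no_V"
        return call
    if len(v_names) > 1 and params.tie_mode == "strict":
        call.status = "ambiguous"
        return call
    call.v_call, call.v_identity = v_name, v_identity

    # J is sought downstream of the V alignment
    tail = seq[v_end:]
    j_pool = registry.pool(locus, "J")
    if not tail or not j_pool:
        call.status = "no_J"
        return call
    j_score, j_names = _best_hits(aligner, tail, j_pool)
    j_name = min(j_names)
    j_identity, j_start_rel, _j_end, _span, j_cov = _align_details(
        aligner, tail, j_pool[j_name]
    )
    if j_identity < params.min_identity or j_cov < params.min_coverage:
        call.status = "no_J"
        return call
    if len(j_names) > 1 and params.tie_mode == "strict":
        call.status = "ambiguous"
        return call
    call.j_call, call.j_identity = j_name, j_identity

    junction = tail[:j_start_rel]
    call.junction = junction

    d_pool = registry.pool(locus, "D")
    if d_pool and junction:
        d_score, d_names = _best_hits(aligner, junction, d_pool)
        d_name = min(d_names)
        _ident, _s, _e, span, _cov = _align_details(aligner, junction, d_pool[d_name])
        if span >= params.min_d_length:
            call.d_call = d_name
    return call


def assign_all(reads, registry, params: AlignParams = AlignParams()) -> list:
    return [assign_germline(r, registry, params) for r in reads]


def collapse_unique_patterns(
    calls, key_mode: PatternKey = PatternKey.gene_cdr3nt
) -> dict:
    """Collapse assigned reads to unique patterns per cell.

    Same dedup semantics as contig-based profiling: a pattern is the tuple of
    gene calls, plus the junction sequence in nucleotide-key mode (or its
    translation in amino-acid mode, when in frame).  Unassigned reads are
    skipped.  Returns dict cell_id -> frozenset of RecombinationPattern.
    """
    from Bio.Seq import Seq

    per_cell: dict = {}
    for call in calls:
        if not call.assigned:
            continue
        if key_mode is PatternKey.gene_only:
            cdr3 = None
        elif key_mode is PatternKey.gene_cdr3aa:
            j = call.junction or ""
            cdr3 = str(Seq(j).translate()) if j and len(j) % 3 == 0 else None
        else:
            cdr3 = call.junction
        pattern = RecombinationPattern(
            locus=call.locus, v_gene=call.v_call, d_gene=call.d_call,
            j_gene=call.j_call, cdr3=cdr3,
        )
        per_cell.setdefault(call.cell_id, set()).add(pattern)
    return {cell: frozenset(p) for cell, p in per_cell.items()}


def segment_usage_spectrum(
    patterns_by_cell: dict, registry: GermlineRegistry, locus: str = "IGH"
) -> pd.DataFrame:
    """Count germline segment usage over all patterns of all cells.

    Every registry entry appears, including zero-count segments.  Frequencies
    are normalized within each pool (V, D, J) over the patterns that carry a
    call for that pool, so they sum to 1 per pool (or are all NA for an
    unused pool).
    """
    counts = {kind: {name: 0 for name in registry.names(locus, kind)}
              for kind in "VDJ"}
    for patterns in patterns_by_cell.values():
        for p in patterns:
            if p.locus != locus:
                continue
            counts["V"][p.v_gene] += 1
            if p.d_gene is not None:
                counts["D"][p.d_gene] += 1
            counts["J"][p.j_gene] += 1
    rows = []
    for kind in "VDJ":
        total = sum(counts[kind].values())
        for name in sorted(counts[kind]):
            c = counts[kind][name]
            rows.append((kind, name, c, c / total if total else float("nan")))
    return pd.DataFrame(rows, columns=["pool", "segment", "count", "frequency"])


def read_sanger_fasta(path) -> list:
    """Read amplicons from FASTA.

    Header convention: ``>cell_id|read_id[|locus_hint]``; a header without
    ``|`` is treated as both cell and read id with an unknown locus.
    """
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        cell = parts[0]
        read_id = parts[1] if len(parts) > 1 else rec.id
        hint = parts[2] if len(parts) > 2 else "unknown"
        reads.append(SangerRead(cell, read_id, str(rec.seq).upper(), hint))
    return reads


def calls_to_frame(calls) -> pd.DataFrame:
    """PatternCalls as a TSV-ready DataFrame (one row per read)."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in calls],
            "read_id": [c.read_id for c in calls],
            "locus": [c.locus for c in calls],
            "v_call": [c.v_call for c in calls],
            "d_call": [c.d_call for c in calls],
            "j_call": [c.j_call for c in calls],
            "v_identity": [round(c.v_identity, 2) for c in calls],
            "j_identity": [round(c.j_identity, 2) for c in calls],
            "junction": [c.junction for c in calls],
            "status": [c.status for c in calls],
        }
    )
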