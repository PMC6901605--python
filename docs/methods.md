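# Methods

## The statistic

The unit of analysis is the *recombination pattern*: the identity of one
V(D)J rearrangement observed as an assembled single-cell contig.  Three key
modes define pattern identity (`PatternKey`):

| mode | key | use |
|---|---|---|
| `gene_only` | (V, D, J) gene calls | merges somatic-hypermutation variants of one clone |
| `gene_cdr3aa` | (V, D, J, CDR3 aa) | intermediate |
| `gene_cdr3nt` | (V, D, J, CDR3 nt) | default; the most conservative distinctness claim |

Gene calls are compared at gene level: multi-gene calls keep the first
listed gene and allele suffixes (`*01`) are stripped on input.  By
construction, pattern counts are monotone in key coarseness
(`gene_only` ≤ `gene_cdr3aa` ≤ `gene_cdr3nt` per cell), which the suite
asserts as a property.

Per cell, the pipeline reports the number of distinct patterns per locus
binned as one / two / three-or-more, light-chain usage (κ only / λ only /
both), V-segment multiplicity, Ig class counts, and pairwise pattern
sharing between co-expressed classes.  Cohort summaries always carry
explicit numerators and denominators; proportions are exact ratios.

### Denominators

Per-locus denominators are the cells with at least one pattern at that
locus; the light-chain-usage denominator is cells with at least one light
pattern.  This is why per-locus *n*'s differ within one cohort.  Both
conventions are configurable in `summarize_cohort`.

### QC presets

The default preset keeps contigs with
`is_cell ∧ high_confidence ∧ productive ∧ full_length` — the semantics of a
filtered Cell Ranger annotation table.  The `v_segment` preset drops the
full-length requirement so partially assembled transcripts still contribute
their V gene (and their C gene, for class counting: many constant-bearing
transcripts never assemble into an intact V-D-J, so class-count analyses are
run on `v_segment`-filtered profiles).  A UMI floor (`min_umis`) is
available but off by default; it exists to probe ambient-RNA sensitivity,
since ambient transcripts are low-support.

## Marker-rule subset classification

Instead of a clustering pipeline, subsets are assigned by explicit
predicates over a normalized expression matrix, evaluated in priority order
(each cell gets exactly one label):

1. **plasma**: CD19⁺ and CD38 ≥ high-cutoff;
2. **naive**: CD19⁺, CD27⁻, IGHM⁺, IGHD⁺;
3. **memory**: CD19⁺, CD27⁺;
4. otherwise **unassigned**.

"Positive" means expression strictly above `positive_cutoff` (default 0,
i.e. any non-zero normalized value — appropriate for log-normalized scRNA
data where a silent gene reads 0).  The CD38-high cutoff defaults to a
robust outlier rule — median + 3×1.4826×MAD of CD38 among CD19⁺ cells —
because plasma cells are a rare (~1%) very-high tail of the CD38
distribution; a fixed-percentile mode is also provided, but note that a
percentile cutoff labels a fixed fraction of cells CD38-high regardless of
how many plasma cells are actually present, which is the wrong behaviour
when the plasma fraction is far from `100 - percentile`.  CD10, which some
sorting schemes use, is deliberately not part of the default rules (surface
gates and transcriptome annotations disagree on it); it can be added via a
custom `MarkerRuleSet`.

## The simulator

`synthetic_data.simulate_cells` draws, per cell: a subset from
`subset_mix`; a per-locus pattern count k ∈ {1,2,3} from
`pattern_count_dist[locus][subset]`; κ/λ co-expression from a per-subset
rate (otherwise a single light-chain type, κ with probability
`kappa_fraction`); an Ig class set from per-subset class-count and
pair-composition distributions (naive pairs favour IgM+IgD, memory pairs
IgG+IgA, IgM+IgG occurs in both).  Each pattern is a random (V, D, J) draw
from a synthetic germline registry plus an in-frame junction
(V 3′ hexamer + N₁ + D + N₂ + J 5′ hexamer, N lengths uniform 0–6 with the
second adjusted to keep the length a multiple of 3).  Junctions are random
enough that nucleotide-level keys are effectively always distinct; somatic
hypermutation and clonal lineages are *not* modelled.

With probability `cross_class_share_rate` a multi-class cell's classes all
carry one common pattern (classical CSR); otherwise patterns are dealt out
disjointly over classes, and classes in excess of the drawn pattern count
ride on partially assembled contigs (`full_length=False`, no J call) —
class visible, no countable pattern.  This reflects how class counts can
exceed full-length pattern counts in real 5′ V(D)J libraries and keeps the
configured pattern-count and class-count distributions simultaneously
recoverable; the suite checks recovery of the configured rates within 3
binomial standard errors at n = 4000 over 5 seeds.

Marker expression: positive markers ~ N(separation, 1) floored at a small
positive value; negative markers read exactly 0 except for rare leakage
(probability `negative_leak_rate`, default 0.005) — a dropout-dominated
model of log-normalized counts; CD38 has a moderate baseline (mean 1.5) in
all B cells and sits `marker_separation` (default 5) SDs higher in plasma
cells.  With these defaults the marker rules recover ≥ 99% of true labels;
degrading the separation degrades recovery smoothly.

Default rates are mid-range values of the per-donor percentages reported
for healthy peripheral-blood CD19⁺ cohorts: heavy-chain two-pattern rate
~6–8% (naive below memory), κ two-pattern ~11–13%, λ ~15–21%, κ/λ
co-expression 28%/12%/20% for naive/memory/plasma, subset mix
0.52/0.47/0.01, GEX capture of V(D)J barcodes 94.34%.  Plasma cells are
modelled as nearly always single-pattern.  Artifact rates default to 0.

### Artifact models

*Doublets* (`inject_doublets`): random disjoint cell pairs merged under one
barcode; `rate` is the fraction of emitted barcodes that are doublets
(d = round(rate·N/(1+rate)) merges).  For a fixed seed the merge set at a
lower rate is nested in that at a higher rate, making apparent
multi-pattern rates monotone in the rate by construction, not just in
expectation.  Doublets are subset-unbiased.

*Ambient contamination* (`inject_ambient`): per cell with probability
`rate`, one contig copied from another cell at UMI count 1.  All
randomness is pre-drawn so contaminated-cell sets are likewise nested
across rates.  Because native contigs have ≥ 2 UMIs, a `min_umis=2` floor
removes every contaminant and restores native estimates exactly — the
suite asserts this recovery.

Truth tables record, per emitted barcode, the subset, true per-locus
pattern sets, class set, provenance (native / doublet /
ambient_contaminated) and doublet constituents, so every pipeline estimate
can be checked against ground truth.

### What passing tests do and do not show

The generator produces idealized data: perfect QC flags, no
mispriming/chimeras, no shared clones between cells, no SHM, no
subset-biased doublets, dropout-style marker noise.  Passing recovery tests
therefore demonstrates the *pipeline's* correctness under its stated
assumptions, not that real-data multi-pattern rates are artifact-free — the
artifact injectors exist precisely to quantify how doublet and ambient
rates inflate apparent multiplicity.

## Sanger arm

Amplicon reads are assigned to germline segments by local alignment
(match +1, mismatch −1, gap −2; all configurable) against a named registry,
taking the best-scoring pool member — a desk-scale equivalent of a BLAST
best-hit search.  Acceptance requires ≥ 80% identity over the alignment and
≥ 50% coverage of the germline segment (the coverage floor rejects short
spurious local hits from unrelated sequence).  Equal best scores yield
status `ambiguous` in strict mode or the lexicographically smallest name in
lenient mode.  The junction is the read region between the V-alignment end
and the J-alignment start and stands in for the CDR3 in nucleotide keys;
D is searched only inside that window and reported only when its alignment
spans ≥ 8 read bases.  Reads collapse to unique patterns per cell with the
same dedup semantics as contig profiles (asserted by a cross-module
agreement test).  With ≤ 5% random substitutions, ≥ 95% of reads still
recover their source V and J.

## Numerical and design choices

- **Pattern key default** is `gene_cdr3nt`; published per-cell examples
  display gene calls together with CDR3 sequences, and the nt key is the
  strictest.  The mode is a flag because reasonable analyses differ here.
- **Ordering/ties**: pattern sets are emitted sorted lexicographically by
  (V, D, J, CDR3); summaries sort by (group, metric, category).  Identical
  input and configuration give byte-identical outputs.
- **AIRR junction vs CDR3**: AIRR `junction` includes the conserved
  flanking codons; CDR3 is the junction minus first/last codon.  10x
  `cdr3_nt` is already the CDR3.  AIRR output writes the optional `cdr3`
  fields so round trips are exact.
- **Degenerate inputs**: empty tables round-trip as header-only files;
  groups with zero denominator get a null proportion rather than an error;
  cells without a classed heavy contig are excluded from class-count
  denominators.
- **Problem sizes**: tests and the acceptance script use cohorts of a few
  hundred to 4000 cells and a few hundred amplicon reads — large enough
  that 3-SE binomial checks are meaningful for rates of a few percent,
  small enough to run comfortably on one CPU.

## Known limitations

- No clonal lineage, SHM or phylogeny modelling; no paired-chain clonotype
  networks.
- Subclass resolution (IGHG1–4, IGHA1–2) is collapsed to class level.
- The simulator's germline registry is synthetic; a user FASTA can be
  loaded but no curated germline database ships with the package.
- Doublet detection from expression profiles is out of scope; the doublet
  model here is generative only.
- Heavy-chain contigs lacking a C call contribute patterns but are
  invisible to all class-level statistics.
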