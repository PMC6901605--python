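# polybcr

Single-cell B-cell receptor (BCR) repertoire analysis focused on one
question: **how many distinct antibodies does one B cell transcribe?**

Classical immunology expects exactly one: allelic exclusion permits a single
productive V\_H-D-J\_H rearrangement per cell, isotypic exclusion a single
light-chain type (κ *or* λ), and class-switch recombination (CSR) replaces
only the heavy-chain constant region while preserving the rearranged VDJ.
10x-style single-cell V(D)J enrichment data make these rules directly
testable: every assembled contig carries a cell barcode, germline V/D/J/C
gene calls and a CDR3 sequence.  `polybcr` turns a contig annotation table
into per-cell multiplicity statistics:

- the number of **distinct recombination patterns** per cell and locus
  (IGH, IGK, IGL), where a pattern is keyed by the germline gene calls
  optionally plus the CDR3 (nucleotide-level by default: contigs count as
  one pattern only if V, D, J *and* CDR3 nt agree);
- **κ/λ co-expression** (isotypic inclusion) per cell;
- per-cell **Ig class counts** (IgM/IgD/IgG/IgA/IgE from the C gene) and,
  for multi-class cells, whether co-expressed classes **share an identical
  VDJ pattern** (the classical-CSR expectation) or carry private ones;
- **V-segment multiplicity** from partially assembled transcripts that
  still carry a V gene call;
- B-cell **subset stratification** (naive / memory / plasma) by explicit
  marker rules (CD19, CD27, CD38, IGHM, IGHD) over a paired 5′ GEX matrix,
  linked by exact barcode match.

Because public raw data are not required for development or testing, the
package ships a **truth-tracked simulator** (`polybcr.synthetic_data`) that
generates contig tables, marker matrices and ground truth with configurable
per-locus multiplicity rates, κ/λ co-expression, class-count composition,
cross-class sharing, plus **doublet** and **ambient-contamination**
injectors for sensitivity analyses — and a **Sanger arm**
(`polybcr.sanger_analysis`) that assigns germline segments to amplicon reads
by best-identity local alignment and collapses reads to unique patterns per
cell.

## Worked example

```python
from polybcr import (
    SimConfig, simulate_cells, qc_filter, build_cell_profiles,
    summarize_cohort, classify_subsets, join_profiles, DEFAULT_QC,
)

config = SimConfig(n_cells=4000)
contigs, markers, truth = simulate_cells(config, seed=7)

profiles = build_cell_profiles(qc_filter(contigs, DEFAULT_QC))
profiles = join_profiles(profiles, classify_subsets(markers))

summary = summarize_cohort(
    profiles,
    metrics=("igh_multiplicity", "light_chain_usage"),
)
print(summary.to_string(index=False))
```

prints

```
group            metric      category  numerator  denominator  proportion
  all  igh_multiplicity           one       3497         3740    0.935027
  all  igh_multiplicity three_or_more         12         3740    0.003209
  all  igh_multiplicity           two        231         3740    0.061765
  all light_chain_usage          both        834         4000    0.208500
  all light_chain_usage    kappa_only       1914         4000    0.478500
  all light_chain_usage   lambda_only       1252         4000    0.313000
```

Read this as: of the 3740 cells with at least one assembled heavy-chain
pattern, 93.5% carry exactly one V\_H-D-J\_H pattern, 6.2% carry two and
0.3% carry three or more (the generator's defaults place the two-pattern
rate near the mid-range observed in healthy peripheral-blood B cells); 20.9%
of light-chain-positive cells co-express κ and λ patterns.  Denominators are
per metric: cells with no pattern at a locus are excluded from that locus's
denominator, which is why heavy- and light-chain *n*'s differ.

A shell interface mirrors the library:

```bash
polybcr simulate --seed 7 --out-dir sim/
polybcr profile  --contigs sim/filtered_contig_annotations.csv --out-summary summary.tsv
polybcr isotype  --contigs sim/filtered_contig_annotations.csv --out isotype.tsv
polybcr annotate --matrix sim/matrix --contigs sim/filtered_contig_annotations.csv --out labelled.tsv
polybcr convert  --in sim/filtered_contig_annotations.csv --from tenx --to airr --out contigs.airr.tsv
polybcr sanger   --reads reads.fa --germline germline.fa --out-patterns patterns.tsv
```

## Layout

| module | contents |
|---|---|
| `polybcr.contig_io` | 10x CSV / AIRR TSV contig tables, one normalized schema, round-trip I/O |
| `polybcr.repertoire_core` | QC presets, pattern keys, per-cell profiles, multiplicity & usage statistics, cohort summaries |
| `polybcr.isotype_analysis` | Ig-class counts, pair labels, cross-class VDJ sharing |
| `polybcr.gex_link` | barcode overlap, marker-rule subset classification, profile joining |
| `polybcr.synthetic_data` | simulator, germline registry, doublet/ambient injectors, amplicon synthesis |
| `polybcr.sanger_analysis` | local-alignment germline assignment, pattern collapsing, segment-usage spectra |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
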