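"""Per-cell pattern dedup, multiplicity binning and cohort summaries."""

import numpy as np
import pytest

from polybcr.repertoire_core import (
    DEFAULT_QC,
    V_SEGMENT_QC,
    CellProfile,
    PatternKey,
    RecombinationPattern,
    build_cell_profiles,
    light_chain_usage,
    multiplicity_category,
    qc_filter,
    summarize_cohort,
    v_segment_multiplicity,
)

from conftest import make_contig, random_contig_table, table_from_rows


def brute_force_patterns(table, barcode, locus, key_mode):
    """Independent nested-loop dedup over raw rows (the oracle)."""
    seen = []
    for row in table.df.itertuples(index=False):
        if row.barcode != barcode or row.locus != locus:
            continue
        if row.v_call is None or row.j_call is None:
            continue
        cdr3 = {"gene_only": None, "gene_cdr3nt": row.cdr3_nt,
                "gene_cdr3aa": row.cdr3_aa}[key_mode.value]
        key = (row.v_call, row.d_call, row.j_call, cdr3)
        if not any(key == s for s in seen):
            seen.append(key)
    return len(seen)


class TestQCFilter:
    def test_default_preset_drops_nonproductive(self):
        rows = [make_contig("BC1-1", "c1", productive=True),
                make_contig("BC1-1", "c2", productive=False)]
        out = qc_filter(table_from_rows(rows), DEFAULT_QC)
        assert len(out) == 1 and out.df.iloc[0]["contig_id"] == "c1"

    def test_v_segment_preset_keeps_partial_contigs(self):
        partial = make_contig("BC1-1", "c1", full_length=False, j_call=None,
                              cdr3_nt=None, cdr3_aa=None)
        table = table_from_rows([partial])
        assert len(qc_filter(table, DEFAULT_QC)) == 0
        assert len(qc_filter(table, V_SEGMENT_QC)) == 1

    def test_all_pass_is_identity(self):
        table = table_from_rows([make_contig("BC1-1", "c1"),
                                 make_contig("BC2-1", "c2")])
        out = qc_filter(table, DEFAULT_QC)
        assert out.df.equals(table.df)


class TestBuildProfiles:
    def test_identical_contigs_collapse_to_one_pattern(self):
        rows = [make_contig("BC1-1", "c1"), make_contig("BC1-1", "c2")]
        profiles = build_cell_profiles(table_from_rows(rows))
        assert len(profiles["BC1-1"].patterns("IGH")) == 1

    def test_three_distinct_heavy_patterns_in_one_cell(self):
        # one cell carrying three distinct gene/CDR3 combinations
        rows = [
            make_contig("BC1-1", "c1", v_call="IGHV1-69", cdr3_nt="GCTAGCGCT"),
            make_contig("BC1-1", "c2", v_call="IGHV3-23", cdr3_nt="GCTAGCAAA"),
            make_contig("BC1-1", "c3", v_call="IGHV4-34", cdr3_nt="GCTAGCTTT"),
        ]
        profiles = build_cell_profiles(table_from_rows(rows))
        assert len(profiles["BC1-1"].patterns("IGH")) == 3

    def test_contig_without_c_call_not_in_per_class_patterns(self):
        rows = [make_contig("BC1-1", "c1", c_call=None)]
        prof = build_cell_profiles(table_from_rows(rows))["BC1-1"]
        assert len(prof.patterns("IGH")) == 1
        assert prof.per_class_patterns == {}
        assert prof.c_classes == set()

    @pytest.mark.parametrize("key_mode", list(PatternKey))
    @pytest.mark.parametrize("seed", range(20))
    def test_dedup_matches_brute_force_oracle(self, seed, key_mode):
        rng = np.random.default_rng(seed)
        table = random_contig_table(rng, int(rng.integers(10, 200)))
        profiles = build_cell_profiles(table, key_mode)
        for bc, prof in profiles.items():
            for locus in ("IGH", "IGK", "IGL"):
                assert len(prof.patterns(locus)) == brute_force_patterns(
                    table, bc, locus, key_mode
                )

    @pytest.mark.parametrize("seed", range(5))
    def test_key_coarseness_monotonicity(self, seed):
        rng = np.random.default_rng(100 + seed)
        table = random_contig_table(rng, 120)
        by_mode = {m: build_cell_profiles(table, m) for m in PatternKey}
        for bc in by_mode[PatternKey.gene_only]:
            for locus in ("IGH", "IGK", "IGL"):
                n_gene = len(by_mode[PatternKey.gene_only][bc].patterns(locus))
                n_aa = len(by_mode[PatternKey.gene_cdr3aa][bc].patterns(locus))
                n_nt = len(by_mode[PatternKey.gene_cdr3nt][bc].patterns(locus))
                assert n_gene <= n_aa <= n_nt


class TestCategories:
    def test_multiplicity_bins(self):
        prof = CellProfile(barcode="x")
        assert multiplicity_category(prof, "IGH") == "zero"
        pats = [RecombinationPattern("IGH", f"V{i}", None, "J1") for i in range(7)]
        prof.patterns_by_locus = {"IGH": frozenset(pats[:1])}
        assert multiplicity_category(prof, "IGH") == "one"
        prof.patterns_by_locus = {"IGH": frozenset(pats[:2])}
        assert multiplicity_category(prof, "IGH") == "two"
        # a cell with more than seven patterns still lands in the top bin
        prof.patterns_by_locus = {"IGH": frozenset(pats)}
        assert multiplicity_category(prof, "IGH") == "three_or_more"

    def test_light_chain_usage(self):
        p = RecombinationPattern("IGK", "IGKV1", None, "IGKJ1")
        q = RecombinationPattern("IGL", "IGLV1", None, "IGLJ1")
        cases = [
            ({"IGK": frozenset({p})}, "kappa_only"),
            ({"IGL": frozenset({q})}, "lambda_only"),
            ({"IGK": frozenset({p}), "IGL": frozenset({q})}, "both"),
            ({}, "none"),
        ]
        for patterns, expected in cases:
            assert light_chain_usage(CellProfile("x", patterns_by_locus=patterns)) == expected

    def test_v_segment_multiplicity_counts_distinct_genes(self):
        rows = [
            make_contig("BC1-1", "c1", v_call="IGHV1-69", full_length=False,
                        j_call=None, cdr3_nt=None, cdr3_aa=None),
            make_contig("BC1-1", "c2", v_call="IGHV3-23"),
        ]
        table = qc_filter(table_from_rows(rows), V_SEGMENT_QC)
        prof = build_cell_profiles(table)["BC1-1"]
        assert v_segment_multiplicity(prof, "IGH") == 2
        assert v_segment_multiplicity(prof, "IGK") == 0
        # full-length patterns can never exceed the V-segment count
        assert v_segment_multiplicity(prof, "IGH") >= len(
            {p.v_gene for p in prof.patterns("IGH")}
        )


def _profiles_with_counts(counts, locus="IGH"):
    """Cells with prescribed per-cell pattern counts at one locus."""
    profiles = []
    for i, k in enumerate(counts):
        pats = frozenset(
            RecombinationPattern(locus, f"V{j}", None, "J1", f"CDR{j}")
            for j in range(k)
        )
        profiles.append(CellProfile(f"BC{i}", patterns_by_locus={locus: pats} if k else {}))
    return profiles


class TestSummarize:
    def test_partition_and_proportions_sum_to_one(self):
        profiles = _profiles_with_counts([0, 1, 1, 2, 3, 5, 1, 2])
        out = summarize_cohort(profiles, metrics=("igh_multiplicity",))
        assert (out["denominator"] == 7).all()  # zero-pattern cell excluded
        assert out["numerator"].sum() == 7
        assert abs(out["proportion"].sum() - 1.0) < 1e-12

    def test_multi_v_proportion_printed_ratio(self):
        # 5803 cells of which 2886 carry >=2 heavy-chain V genes -> 49.73%
        profiles = []
        for i in range(5803):
            n_v = 2 if i < 2886 else 1
            genes = frozenset(f"IGHV{j}" for j in range(n_v))
            profiles.append(CellProfile(f"BC{i}", v_genes_by_locus={"IGH": genes}))
        out = summarize_cohort(profiles, metrics=("multi_igh_v",))
        assert out.loc[0, "numerator"] == 2886
        assert out.loc[0, "denominator"] == 5803
        assert round(100 * out.loc[0, "proportion"], 2) == 49.73

    def test_multi_pattern_ratio_small_cohort(self):
        # 41 cells, 31 with two or more patterns -> 75.61%
        profiles = _profiles_with_counts([1] * 10 + [2] * 22 + [8] * 9)
        out = summarize_cohort(profiles, metrics=("multi_igh_pattern",))
        assert round(100 * out.loc[0, "proportion"], 2) == 75.61

    def test_empty_group_has_null_proportion(self):
        profiles = _profiles_with_counts([0])
        out = summarize_cohort(profiles, metrics=("igh_multiplicity",))
        assert (out["denominator"] == 0).all()
        assert out["proportion"].isna().all()

    def test_single_cell_single_pattern(self):
        out = summarize_cohort(_profiles_with_counts([1]),
                               metrics=("igh_multiplicity",))
        one = out[out.category == "one"].iloc[0]
        assert one["proportion"] == 1.0

    def test_determinism_byte_identical(self):
        rng = np.random.default_rng(3)
        table = random_contig_table(rng, 150)
        outs = []
        for _ in range(2):
            profiles = build_cell_profiles(qc_filter(table, DEFAULT_QC))
            outs.append(summarize_cohort(profiles).to_csv(index=False))
        assert outs[0] == outs[1]

    def test_group_by_subset(self):
        profiles = _profiles_with_counts([1, 2, 1, 1])
        for p, s in zip(profiles, ["naive", "naive", "memory", "memory"]):
            p.subset = s
        out = summarize_cohort(profiles, group_by=("subset",),
                               metrics=("igh_multiplicity",))
        naive_two = out[(out.group == "naive") & (out.category == "two")].iloc[0]
        assert naive_two["numerator"] == 1 and naive_two["denominator"] == 2
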