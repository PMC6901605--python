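"""Generator determinism, configured-rate recovery and artifact models."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from polybcr.contig_io import normalize_gene_call, read_contig_table, write_contig_table
from polybcr.repertoire_core import (
    DEFAULT_QC,
    build_cell_profiles,
    light_chain_usage,
    qc_filter,
)
from polybcr.synthetic_data import (
    SimConfig,
    build_registry,
    inject_ambient,
    inject_doublets,
    simulate_cells,
)


def multi_pattern_fraction(table, locus="IGH", qc=DEFAULT_QC):
    profiles = build_cell_profiles(qc_filter(table, qc))
    counts = [len(p.patterns(locus)) for p in profiles.values() if p.patterns(locus)]
    return sum(c >= 2 for c in counts) / len(counts)


class TestRegistry:
    def test_same_seed_identical_registries(self):
        config = SimConfig()
        r1, r2 = build_registry(config, seed=5), build_registry(config, seed=5)
        assert r1.segments == r2.segments

    def test_pool_sizes_and_lengths(self, registry):
        assert len(registry.names("IGH", "V")) == 20
        assert len(registry.names("IGK", "D")) == 0
        assert all(len(s) == 300 for s in registry.pool("IGH", "V").values())
        assert all(len(s) == 20 for s in registry.pool("IGH", "D").values())
        assert all(len(s) == 50 for s in registry.pool("IGH", "J").values())

    def test_single_v_pool_forces_shared_gene(self):
        config = SimConfig(
            n_cells=30,
            registry_sizes={"IGH": (1, 2, 2), "IGK": (1, 0, 1), "IGL": (1, 0, 1)},
        )
        table, _, _ = simulate_cells(config, seed=3)
        igh_vs = set(table.df.loc[table.df.locus == "IGH", "v_call"].dropna())
        assert igh_vs == {"IGHV1-S1"}

    def test_names_survive_gene_call_normalization(self, registry):
        for locus in ("IGH", "IGK", "IGL"):
            for kind in "VDJ":
                for name in registry.names(locus, kind):
                    assert normalize_gene_call(name) == name

    def test_fasta_round_trip(self, registry, tmp_path):
        from polybcr.synthetic_data import GermlineRegistry

        registry.to_fasta(tmp_path / "germ.fa")
        back = GermlineRegistry.from_fasta(tmp_path / "germ.fa")
        assert back.segments == registry.segments


class TestSimulateCells:
    def test_full_determinism(self):
        config = SimConfig(n_cells=150)
        a = simulate_cells(config, seed=9)
        b = simulate_cells(config, seed=9)
        pd.testing.assert_frame_equal(a[0].df, b[0].df)
        pd.testing.assert_frame_equal(a[1].values, b[1].values)
        pd.testing.assert_frame_equal(a[2].df, b[2].df)

    def test_degenerate_single_pattern_config(self):
        dist = {"naive": (1.0, 0.0, 0.0), "memory": (1.0, 0.0, 0.0),
                "plasma": (1.0, 0.0, 0.0)}
        config = SimConfig(
            n_cells=300,
            pattern_count_dist={"IGH": dist, "IGK": dist, "IGL": dist},
        )
        table, _, _ = simulate_cells(config, seed=1)
        assert multi_pattern_fraction(table, "IGH") == 0.0

    def test_kappa_lambda_rate_within_binomial_ci(self):
        rate = 0.25
        config = SimConfig(
            n_cells=2500,
            kappa_lambda_coexpression_rate={"naive": rate, "memory": rate,
                                            "plasma": rate},
        )
        table, _, _ = simulate_cells(config, seed=17)
        profiles = build_cell_profiles(qc_filter(table, DEFAULT_QC))
        usable = [p for p in profiles.values()
                  if p.patterns("IGK") or p.patterns("IGL")]
        frac = sum(light_chain_usage(p) == "both" for p in usable) / len(usable)
        se = np.sqrt(rate * (1 - rate) / len(usable))
        assert abs(frac - rate) <= 3 * se

    def test_truth_matches_pipeline_counts(self, small_sim):
        _, table, _, truth = small_sim
        profiles = build_cell_profiles(qc_filter(table, DEFAULT_QC))
        for bc, prof in profiles.items():
            for locus in ("IGH", "IGK", "IGL"):
                assert len(prof.patterns(locus)) == truth.pattern_count(bc, locus)

    def test_emitted_table_is_valid_and_round_trips(self, small_sim, tmp_path):
        _, table, _, _ = small_sim
        table.validate()
        for dialect in ("tenx_csv", "airr_tsv"):
            path = tmp_path / f"sim.{dialect}"
            write_contig_table(table, path, dialect)
            back = read_contig_table(path, dialect)
            pd.testing.assert_frame_equal(back.df, table.df)

    def test_config_validation_rejects_bad_distributions(self):
        with pytest.raises(ValueError):
            SimConfig(subset_mix={"naive": 0.9, "memory": 0.9, "plasma": 0.1}).validate()
        with pytest.raises(ValueError):
            SimConfig(doublet_rate=0.7).validate()
        with pytest.raises(ValueError):
            SimConfig(registry_sizes={"IGH": (0, 1, 1), "IGK": (1, 0, 1),
                                      "IGL": (1, 0, 1)}).validate()


@pytest.fixture(scope="module")
def native():
    """Cohort where every cell carries exactly one pattern per locus."""
    dist = {"naive": (1.0, 0.0, 0.0), "memory": (1.0, 0.0, 0.0),
            "plasma": (1.0, 0.0, 0.0)}
    config = SimConfig(
        n_cells=800,
        pattern_count_dist={"IGH": dist, "IGK": dist, "IGL": dist},
    )
    return simulate_cells(config, seed=23)


class TestDoublets:
    def test_zero_rate_is_identity(self, native):
        table, _, truth = native
        t2, tr2 = inject_doublets(table, truth, 0.0, seed=1)
        pd.testing.assert_frame_equal(t2.df, table.df)
        pd.testing.assert_frame_equal(tr2.df, truth.df)

    def test_apparent_multiplicity_monotone_in_rate(self, native):
        table, _, truth = native
        fracs = []
        for rate in (0.0, 0.05, 0.1, 0.2):
            t2, _ = inject_doublets(table, truth, rate, seed=31)
            fracs.append(multi_pattern_fraction(t2, "IGH"))
        assert fracs[0] == 0.0  # native cells are all single-pattern here
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > 0.0

    def test_doublet_rate_arithmetic(self, native):
        # expected apparent two-pattern fraction from pairing arithmetic:
        # d/(N-d) of emitted barcodes are merged pairs; a merged pair shows
        # >=2 heavy patterns unless both constituents drew the same pattern
        # (negligible for a 20x10x6 registry with random junctions)
        table, _, truth = native
        rate = 0.1
        t2, tr2 = inject_doublets(table, truth, rate, seed=31)
        n = len(truth.df)
        d = int(round(rate * n / (1 + rate)))
        assert len(tr2.df) == n - d
        assert (tr2.df["provenance"] == "doublet").sum() == d
        observed = multi_pattern_fraction(t2, "IGH")
        # doublets missing a heavy chain in one constituent stay single-pattern,
        # so the apparent fraction is slightly below d/(N-d)
        assert 0.5 * d / (n - d) <= observed <= d / (n - d) + 1e-9

    def test_merged_pattern_set_is_union_of_constituents(self, native):
        table, _, truth = native
        t2, tr2 = inject_doublets(table, truth, 0.2, seed=31)
        doublets = tr2.df[tr2.df["provenance"] == "doublet"]
        row = doublets.iloc[0]
        a, b = row["constituents"].split(";")
        union = set(filter(None, truth.df.loc[a, "igh_patterns"].split(";"))) | set(
            filter(None, truth.df.loc[b, "igh_patterns"].split(";"))
        )
        assert set(filter(None, row["igh_patterns"].split(";"))) == union


class TestAmbient:
    def test_zero_rate_is_identity(self, small_sim):
        _, table, _, truth = small_sim
        t2, tr2 = inject_ambient(table, truth, 0.0, seed=1)
        pd.testing.assert_frame_equal(t2.df, table.df)

    def test_umi_floor_removes_contamination(self, small_sim):
        _, table, _, truth = small_sim
        native_frac = multi_pattern_fraction(table, "IGH")
        t2, _ = inject_ambient(table, truth, 1.0, seed=3)
        contaminated = multi_pattern_fraction(t2, "IGH")
        floored = multi_pattern_fraction(
            t2, "IGH", qc=dataclasses.replace(DEFAULT_QC, min_umis=2)
        )
        assert contaminated > native_frac
        assert floored == native_frac

    def test_contaminant_comes_from_another_cell(self, small_sim):
        _, table, _, truth = small_sim
        t2, tr2 = inject_ambient(table, truth, 0.3, seed=5)
        added = t2.df.iloc[len(table.df):]
        assert (added["umis"] == 1).all()
        df = table.df.fillna({"v_call": "-", "cdr3_nt": "-"})
        for row in added.itertuples(index=False):
            # an identical contig exists under some other barcode
            src = df[
                (df["v_call"] == (row.v_call or "-"))
                & (df["cdr3_nt"] == (row.cdr3_nt or "-"))
                & (df["barcode"] != row.barcode)
            ]
            assert len(src) >= 1

    def test_provenance_recorded(self, small_sim):
        _, table, _, truth = small_sim
        _, tr2 = inject_ambient(table, truth, 0.5, seed=7)
        contaminated = tr2.df[tr2.df["n_ambient_contigs"] > 0]
        assert (contaminated["provenance"] == "ambient_contaminated").all()
        assert len(contaminated) > 0
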