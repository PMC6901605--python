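"""Shared fixtures: tiny contig tables and random-table generators."""

import numpy as np
import pandas as pd
import pytest

from polybcr.contig_io import SCHEMA_COLUMNS, ContigTable


def make_contig(
    barcode,
    contig_id,
    locus="IGH",
    v_call="IGHV1-S1",
    d_call="IGHD1-S1",
    j_call="IGHJ1-S1",
    c_call="IGHM",
    cdr3_nt="GCTAGCGCT",
    cdr3_aa="ASA",
    productive=True,
    full_length=True,
    high_confidence=True,
    is_cell=True,
    umis=5,
    reads=100,
):
    if locus != "IGH":
        d_call = None
    return {
        "barcode": barcode, "contig_id": contig_id, "locus": locus,
        "v_call": v_call, "d_call": d_call, "j_call": j_call, "c_call": c_call,
        "cdr3_aa": cdr3_aa, "cdr3_nt": cdr3_nt, "productive": productive,
        "full_length": full_length, "high_confidence": high_confidence,
        "is_cell": is_cell, "umis": umis, "reads": reads,
    }


def table_from_rows(rows) -> ContigTable:
    return ContigTable(df=pd.DataFrame(rows, columns=SCHEMA_COLUMNS))


_NT = np.array(list("ACGT"))


def random_contig_table(rng: np.random.Generator, n_rows: int) -> ContigTable:
    """A random (valid) contig table with heavy barcode collisions so per-cell
    dedup actually has something to do."""
    loci = ["IGH", "IGK", "IGL"]
    rows = []
    n_barcodes = max(1, n_rows // 4)
    for i in range(n_rows):
        locus = loci[rng.integers(3)]
        v = f"{locus}V{rng.integers(1, 4)}"
        j = f"{locus}J{rng.integers(1, 3)}"
        d = f"IGHD{rng.integers(1, 3)}" if locus == "IGH" and rng.random() < 0.8 else None
        has_cdr3 = rng.random() < 0.9
        cdr3_nt = "".join(rng.choice(_NT, size=3 * int(rng.integers(2, 5)))) if has_cdr3 else None
        c_call = None
        if locus == "IGH" and rng.random() < 0.8:
            c_call = ["IGHM", "IGHD", "IGHG", "IGHA", "IGHE"][rng.integers(5)]
        elif locus != "IGH":
            c_call = "IGKC" if locus == "IGK" else "IGLC"
        rows.append(make_contig(
            barcode=f"BC{rng.integers(n_barcodes):04d}-1",
            contig_id=f"contig_{i}",
            locus=locus, v_call=v, d_call=d, j_call=j, c_call=c_call,
            cdr3_nt=cdr3_nt, cdr3_aa=None,
            productive=bool(rng.random() < 0.9),
            full_length=bool(rng.random() < 0.85),
            high_confidence=bool(rng.random() < 0.95),
            is_cell=True,
            umis=int(rng.integers(1, 40)),
            reads=int(rng.integers(10, 1000)),
        ))
    return table_from_rows(rows)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated cohort reused by several test modules."""
    from polybcr.synthetic_data import SimConfig, simulate_cells

    config = SimConfig(n_cells=600)
    table, matrix, truth = simulate_cells(config, seed=42)
    return config, table, matrix, truth


@pytest.fixture(scope="session")
def registry():
    from polybcr.synthetic_data import SimConfig, build_registry

    return build_registry(SimConfig(), seed=7)
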