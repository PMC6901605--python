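"""Reading, validation and writing of single-cell V(D)J contig annotation tables.

Two dialects are supported and normalized onto one internal schema:

* the 10x Genomics ``filtered_contig_annotations.csv`` dialect
  (columns ``barcode, is_cell, contig_id, high_confidence, length, chain,
  v_gene, d_gene, j_gene, c_gene, full_length, productive, cdr3, cdr3_nt,
  reads, umis, raw_clonotype_id``), and
* the AIRR Rearrangement TSV dialect
  (``cell_id, locus, v_call, d_call, j_call, c_call, junction, junction_aa,
  productive, ...``).

The internal schema is a pandas DataFrame with one row per assembled contig
(one V(D)J transcript observed in one cell barcode) and the columns listed in
:data:`SCHEMA_COLUMNS`.  Gene calls are normalized to gene level: of a
multi-gene call like ``"IGHV1-69*01,IGHV1-69*02"`` only the first listed gene
is kept and the ``*NN`` allele suffix is stripped, because gene-level identity
is the granularity at which recombination patterns are compared downstream.

AIRR ``junction`` includes the conserved flanking C and W/F codons; the
internal ``cdr3_nt``/``cdr3_aa`` fields hold the CDR3 proper (junction minus
the first and last codon).  10x ``cdr3_nt`` is taken to be the CDR3 already.
When writing AIRR output the optional AIRR ``cdr3``/``cdr3_aa`` columns are
emitted so that a round trip reproduces the normalized fields exactly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "BCR_LOCI",
    "SCHEMA_COLUMNS",
    "ContigTable",
    "ContigFormatError",
    "normalize_gene_call",
    "read_contig_table",
    "write_contig_table",
]

BCR_LOCI = ("IGH", "IGK", "IGL")

#: Columns of the normalized internal schema, in canonical order.
SCHEMA_COLUMNS = [
    "barcode",
    "contig_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "cdr3_aa",
    "cdr3_nt",
    "productive",
    "full_length",
    "high_confidence",
    "is_cell",
    "umis",
    "reads",
]

TENX_COLUMNS = [
    "barcode",
    "is_cell",
    "contig_id",
    "high_confidence",
    "length",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "full_length",
    "productive",
    "cdr3",
    "cdr3_nt",
    "reads",
    "umis",
    "raw_clonotype_id",
]

AIRR_COLUMNS = [
    "sequence_id",
    "cell_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "junction",
    "junction_aa",
    "cdr3",
    "cdr3_aa",
    "productive",
    "complete_vdj",
    "high_confidence",
    "is_cell",
    "duplicate_count",
    "consensus_count",
]

_REQUIRED = {
    "tenx_csv": ["barcode", "contig_id", "chain", "v_gene", "j_gene", "productive"],
    "airr_tsv": ["cell_id", "locus", "v_call", "j_call", "productive"],
}

_ALLELE_RE = re.compile(r"\*\d+.*$")


class ContigFormatError(ValueError):
    """Raised when an input file does not match the declared dialect."""


@dataclass
class ContigTable:
    """A normalized collection of V(D)J contigs.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per contig, columns :data:`SCHEMA_COLUMNS`.  String columns
        use ``None``/NA for missing values; flag columns are plain bools.
    dialect : str
        ``"tenx_csv"`` or ``"airr_tsv"`` — the dialect the table was read
        from (or the native dialect of a constructed table).
    source : str
        Provenance label (file path or generator tag).
    dropped : list of str
        One message per input row dropped during normalization, so that
        ``rows_in == len(df) + len(dropped)``.
    """

    df: pd.DataFrame
    dialect: str = "tenx_csv"
    source: str = ""
    dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in SCHEMA_COLUMNS if c not in self.df.columns]
        if missing:
            raise ContigFormatError(f"contig table missing columns: {missing}")
        self.df = self.df.loc[:, SCHEMA_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def barcodes(self) -> set:
        return set(self.df["barcode"])

    def validate(self) -> None:
        """Check the internal-schema invariants; raise ``ValueError`` on breach."""
        df = self.df
        if df["barcode"].isna().any() or (df["barcode"] == "").any():
            raise ValueError("empty barcode")
        if df["contig_id"].duplicated().any():
            dup = df.loc[df["contig_id"].duplicated(), "contig_id"].iloc[0]
            raise ValueError(f"duplicate contig_id: {dup!r}")
        bad_locus = ~df["locus"].isin(BCR_LOCI)
        if bad_locus.any():
            raise ValueError(f"unknown locus: {df.loc[bad_locus, 'locus'].iloc[0]!r}")
        light = df["locus"].isin(("IGK", "IGL"))
        if df.loc[light, "d_call"].notna().any():
            raise ValueError("light-chain contig carries a d_call")
        both = df["cdr3_nt"].notna() & df["cdr3_aa"].notna()
        if (df.loc[both, "cdr3_nt"].str.len() % 3 != 0).any():
            raise ValueError("cdr3_nt length not divisible by 3 alongside cdr3_aa")
        if (df["umis"] < 0).any() or (df["reads"] < 0).any():
            raise ValueError("negative umis/reads")


def normalize_gene_call(value) -> object:
    """Normalize a germline gene call to gene level.

    Keeps only the first gene of a comma-separated multi-gene call and strips
    any ``*NN`` allele suffix.  Empty strings, ``"None"`` and NA become None.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s in ("", "None", "nan", "NA"):
        return None
    first = s.split(",")[0].strip()
    return _ALLELE_RE.sub("", first)


def _parse_tenx_bool(value) -> bool:
    # 10x emits "True"/"False"/"None"; "None" (not called) maps to False.
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    return str(value).strip().lower() == "true"


def _opt_str(value) -> object:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return None if s in ("", "None", "nan") else s


def _trim_junction(junction, step: int = 3) -> object:
    """CDR3 = junction minus the conserved first and last codon (nt) or residue (aa)."""
    if junction is None:
        return None
    return junction[step:-step] if len(junction) >= 2 * step else None


def _check_header(columns, dialect: str, path) -> None:
    missing = [c for c in _REQUIRED[dialect] if c not in columns]
    if missing:
        raise ContigFormatError(
            f"{path}: not a valid {dialect} file, missing column(s) {missing}"
        )


def read_contig_table(path, dialect: str = "tenx_csv") -> ContigTable:
    """Read a contig annotation file and normalize it onto the internal schema.

    Parameters
    ----------
    path : path-like
        CSV (10x dialect) or TSV (AIRR dialect) file.
    dialect : {"tenx_csv", "airr_tsv"}

    Returns
    -------
    ContigTable
        Rows with a chain/locus outside {IGH, IGK, IGL} (e.g. TCR chains in a
        mixed enrichment) are dropped with a warning and recorded in
        ``table.dropped``.
    """
    path = Path(path)
    if dialect not in _REQUIRED:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "tenx_csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw = raw.replace({"": None})
    _check_header(raw.columns, dialect, path)

    records = []
    dropped = []
    for i, row in enumerate(raw.itertuples(index=False)):
        row = dict(zip(raw.columns, row))
        if dialect == "tenx_csv":
            rec = _normalize_tenx_row(row, i)
        else:
            rec = _normalize_airr_row(row, i)
        if isinstance(rec, str):
            dropped.append(rec)
        else:
            records.append(rec)
    for msg in dropped:
        warnings.warn(f"{path.name}: dropped row — {msg}", stacklevel=2)

    df = pd.DataFrame(records, columns=SCHEMA_COLUMNS)
    if len(df):
        df["umis"] = df["umis"].astype(int)
        df["reads"] = df["reads"].astype(int)
    else:
        df = df.astype({"umis": int, "reads": int})
    table = ContigTable(df=df, dialect=dialect, source=str(path), dropped=dropped)
    table.validate()
    return table


def _normalize_tenx_row(row: dict, i: int):
    chain = (row.get("chain") or "").strip()
    if chain not in BCR_LOCI:
        return f"row {i}: unknown chain {chain!r}"
    d_call = normalize_gene_call(row.get("d_gene")) if chain == "IGH" else None
    return {
        "barcode": row["barcode"],
        "contig_id": row.get("contig_id") or f"{row['barcode']}_contig_{i}",
        "locus": chain,
        "v_call": normalize_gene_call(row.get("v_gene")),
        "d_call": d_call,
        "j_call": normalize_gene_call(row.get("j_gene")),
        "c_call": normalize_gene_call(row.get("c_gene")),
        "cdr3_aa": _opt_str(row.get("cdr3")),
        "cdr3_nt": _opt_str(row.get("cdr3_nt")),
        "productive": _parse_tenx_bool(row.get("productive")),
        "full_length": _parse_tenx_bool(row.get("full_length")),
        "high_confidence": _parse_tenx_bool(row.get("high_confidence")),
        "is_cell": _parse_tenx_bool(row.get("is_cell")),
        "umis": int(row.get("umis") or 0),
        "reads": int(row.get("reads") or 0),
    }


def _normalize_airr_row(row: dict, i: int):
    locus = (row.get("locus") or "").strip()
    if locus not in BCR_LOCI:
        return f"row {i}: unknown locus {locus!r}"
    cdr3_nt = _opt_str(row.get("cdr3")) or _trim_junction(_opt_str(row.get("junction")))
    cdr3_aa = _opt_str(row.get("cdr3_aa")) or _trim_junction(
        _opt_str(row.get("junction_aa")), step=1
    )
    d_call = normalize_gene_call(row.get("d_call")) if locus == "IGH" else None

    def flag(name, default):
        v = row.get(name)
        if v is None:
            return default
        return str(v).strip().upper() in ("T", "TRUE")

    return {
        "barcode": row["cell_id"],
        "contig_id": row.get("sequence_id") or f"{row['cell_id']}_seq_{i}",
        "locus": locus,
        "v_call": normalize_gene_call(row.get("v_call")),
        "d_call": d_call,
        "j_call": normalize_gene_call(row.get("j_call")),
        "c_call": normalize_gene_call(row.get("c_call")),
        "cdr3_aa": cdr3_aa,
        "cdr3_nt": cdr3_nt,
        "productive": flag("productive", False),
        "full_length": flag("complete_vdj", True),
        "high_confidence": flag("high_confidence", True),
        "is_cell": flag("is_cell", True),
        "umis": int(row.get("duplicate_count") or 0),
        "reads": int(row.get("consensus_count") or 0),
    }


def write_contig_table(table: ContigTable, path, dialect: str = "tenx_csv") -> None:
    """Write a ContigTable to disk in the requested dialect (UTF-8).

    Round trip guarantee: reading the written file reproduces every field of
    the normalized schema.  In the 10x dialect, missing gene calls and CDR3s
    are written as the literal ``"None"`` and booleans as ``"True"/"False"``,
    matching Cell Ranger output.
    """
    path = Path(path)
    df = table.df
    if dialect == "tenx_csv":
        out = pd.DataFrame(
            {
                "barcode": df["barcode"],
                "is_cell": df["is_cell"].map({True: "True", False: "False"}),
                "contig_id": df["contig_id"],
                "high_confidence": df["high_confidence"].map(
                    {True: "True", False: "False"}
                ),
                "length": 0,
                "chain": df["locus"],
                "v_gene": df["v_call"].fillna("None"),
                "d_gene": df["d_call"].fillna("None"),
                "j_gene": df["j_call"].fillna("None"),
                "c_gene": df["c_call"].fillna("None"),
                "full_length": df["full_length"].map({True: "True", False: "False"}),
                "productive": df["productive"].map({True: "True", False: "False"}),
                "cdr3": df["cdr3_aa"].fillna("None"),
                "cdr3_nt": df["cdr3_nt"].fillna("None"),
                "reads": df["reads"],
                "umis": df["umis"],
                "raw_clonotype_id": "None",
            }
        )
        out.to_csv(path, index=False)
    elif dialect == "airr_tsv":
        tf = {True: "T", False: "F"}
        out = pd.DataFrame(
            {
                "sequence_id": df["contig_id"],
                "cell_id": df["barcode"],
                "locus": df["locus"],
                "v_call": df["v_call"],
                "d_call": df["d_call"],
                "j_call": df["j_call"],
                "c_call": df["c_call"],
                "junction": None,
                "junction_aa": None,
                "cdr3": df["cdr3_nt"],
                "cdr3_aa": df["cdr3_aa"],
                "productive": df["productive"].map(tf),
                "complete_vdj": df["full_length"].map(tf),
                "high_confidence": df["high_confidence"].map(tf),
                "is_cell": df["is_cell"].map(tf),
                "duplicate_count": df["umis"],
                "consensus_count": df["reads"],
            }
        )
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
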