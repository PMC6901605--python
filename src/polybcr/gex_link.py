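"""Linking V(D)J barcodes to 5' gene-expression barcodes and B-cell subsets.

The V(D)J enrichment library and the 5' GEX library of one 10x run share cell
barcodes, so repertoire profiles can be joined to expression-derived cell
annotations by exact barcode match.  Subset labels (naive / memory / plasma)
are assigned with explicit marker rules over a normalized expression matrix
rather than a clustering pipeline:

* plasma:  CD19+ and CD38 above a "very high" cutoff;
* naive:   CD19+, CD27-, IGHM+ and IGHD+;
* memory:  CD19+ and CD27+ (and not plasma);

evaluated in priority order plasma -> naive -> memory -> unassigned, so every
cell gets exactly one label.  "Positive" means expression strictly above
``positive_cutoff`` (default 0: any non-zero normalized expression).  The
CD38-high cutoff defaults to a robust outlier rule, median + 3 scaled MADs of
CD38 among CD19+ cells, because plasma cells are a rare (~1%) CD38-very-high
tail; a plain percentile mode is available for users who prefer to fix the
expected plasma abundance instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .repertoire_core import CellProfile

__all__ = [
    "ExpressionMatrix",
    "MarkerRuleSet",
    "OverlapStats",
    "barcode_overlap",
    "classify_subsets",
    "join_profiles",
    "labels_from_pairs",
]

DEFAULT_MARKERS = ("CD19", "CD27", "CD38", "IGHM", "IGHD")


@dataclass
class ExpressionMatrix:
    """A cells x genes matrix of non-negative normalized expression values."""

    values: pd.DataFrame  # index = barcodes, columns = genes

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate barcodes in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate genes in expression matrix")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("expression values must be finite and non-negative")

    @property
    def barcodes(self) -> list:
        return list(self.values.index)

    @property
    def genes(self) -> list:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Dense TSV, first column barcode, remaining columns genes."""
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    @classmethod
    def from_mtx_dir(cls, directory) -> "ExpressionMatrix":
        """10x-style triplet directory: matrix.mtx (genes x cells),
        barcodes.tsv, features.tsv (gene name in 2nd column if present)."""
        from scipy.io import mmread

        directory = Path(directory)
        mat = mmread(directory / "matrix.mtx").toarray()
        barcodes = pd.read_csv(
            directory / "barcodes.tsv", sep="\t", header=None
        )[0].tolist()
        feats = pd.read_csv(directory / "features.tsv", sep="\t", header=None)
        genes = feats[1 if feats.shape[1] > 1 else 0].tolist()
        return cls(pd.DataFrame(mat.T, index=barcodes, columns=genes))

    def to_mtx_dir(self, directory) -> None:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(str(directory / "matrix.mtx"), csr_matrix(self.values.to_numpy().T))
        pd.Series(self.barcodes).to_csv(
            directory / "barcodes.tsv", sep="\t", index=False, header=False
        )
        pd.DataFrame({"id": self.genes, "name": self.genes}).to_csv(
            directory / "features.tsv", sep="\t", index=False, header=False
        )


@dataclass(frozen=True)
class MarkerRuleSet:
    """Thresholded marker predicates for subset assignment.

    cd38_high_cutoff=None resolves at classification time from the matrix
    according to ``cd38_cutoff_mode``:

    * ``"mad"`` (default): median + 3 * 1.4826 * MAD of CD38 among CD19+ cells
      (a standard robust outlier threshold — plasma cells are the CD38
      outlier tail);
    * ``"percentile"``: the ``cd38_percentile``-th percentile of CD38 among
      CD19+ cells.
    """

    positive_cutoff: float = 0.0
    cd38_high_cutoff: object = None
    cd38_cutoff_mode: str = "mad"
    cd38_percentile: float = 90.0
    required_genes: tuple = DEFAULT_MARKERS

    def resolve_cd38_cutoff(self, matrix: ExpressionMatrix) -> float:
        if self.cd38_high_cutoff is not None:
            return float(self.cd38_high_cutoff)
        cd19_pos = matrix.values["CD19"] > self.positive_cutoff
        cd38 = matrix.values.loc[cd19_pos, "CD38"].to_numpy()
        if cd38.size == 0:
            return np.inf
        if self.cd38_cutoff_mode == "percentile":
            return float(np.percentile(cd38, self.cd38_percentile))
        med = np.median(cd38)
        mad = np.median(np.abs(cd38 - med))
        return float(med + 3.0 * 1.4826 * mad)


@dataclass(frozen=True)
class OverlapStats:
    """Barcode overlap between the V(D)J and GEX libraries of one sample."""

    n_vdj: int
    n_gex: int
    n_overlap: int

    @property
    def fraction_of_vdj(self) -> float:
        return self.n_overlap / self.n_vdj

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction_of_vdj


def barcode_overlap(vdj_barcodes, gex_barcodes) -> OverlapStats:
    """Exact-string barcode intersection, reported relative to the V(D)J set."""
    vdj = set(vdj_barcodes)
    gex = set(gex_barcodes)
    if not vdj:
        raise ValueError("V(D)J barcode set is empty")
    return OverlapStats(n_vdj=len(vdj), n_gex=len(gex), n_overlap=len(vdj & gex))


def classify_subsets(matrix: ExpressionMatrix, rules: MarkerRuleSet = MarkerRuleSet()) -> dict:
    """Assign exactly one subset label per barcode by marker rules.

    Returns an ordered dict barcode -> label in
    {"naive", "memory", "plasma", "unassigned"}.
    Raises ``KeyError`` naming the first required marker gene missing from the
    matrix.
    """
    for gene in rules.required_genes:
        if gene not in matrix.values.columns:
            raise KeyError(f"required marker gene missing from matrix: {gene!r}")

    cut = rules.positive_cutoff
    cd38_high = rules.resolve_cd38_cutoff(matrix)
    v = matrix.values
    cd19 = v["CD19"].to_numpy() > cut
    cd27 = v["CD27"].to_numpy() > cut
    cd38 = v["CD38"].to_numpy()
    ighm = v["IGHM"].to_numpy() > cut
    ighd = v["IGHD"].to_numpy() > cut

    labels = {}
    for i, bc in enumerate(matrix.barcodes):
        if cd19[i] and cd38[i] >= cd38_high:
            labels[bc] = "plasma"
        elif cd19[i] and not cd27[i] and ighm[i] and ighd[i]:
            labels[bc] = "naive"
        elif cd19[i] and cd27[i]:
            labels[bc] = "memory"
        else:
            labels[bc] = "unassigned"
    return labels


def labels_from_pairs(pairs) -> dict:
    """Build a barcode -> label map, rejecting duplicate barcode entries."""
    labels: dict = {}
    for bc, lab in pairs:
        if bc in labels:
            raise ValueError(f"duplicate label entry for barcode {bc!r}")
        labels[bc] = lab
    return labels


def join_profiles(profiles, labels: dict):
    """Attach subset labels to profiles (left join on the V(D)J side).

    Profiles whose barcode has no label keep subset="unassigned".  Returns a
    new container of the same kind (dict or list) with updated profiles.
    """
    def relabel(p: CellProfile) -> CellProfile:
        return replace(p, subset=labels.get(p.barcode, "unassigned"))

    if isinstance(profiles, dict):
        return {bc: relabel(p) for bc, p in profiles.items()}
    return [relabel(p) for p in profiles]
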