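"""Reading and writing expression matrices, sample labels, gene lists and result tables.

All statistics downstream are rank- or threshold-based within each dataset,
so no normalization or log transform is applied on read: RPKM/FPKM/TPM-like
non-negative abundances are stored exactly as given.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CompositionError,
    DuplicateIdentifierError,
    FormatError,
    LabelError,
    MissingGeneError,
    ValueRangeError,
)

logger = logging.getLogger(__name__)

GCT_VERSION_TAG = "#1.2"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """A gene-by-sample grid of non-negative normalized abundances.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers, order preserved.
    sample_ids : sequence of str
        Unique column identifiers, order preserved.
    values : array-like of shape (n_genes, n_samples)
        Finite, non-negative abundances (RPKM/FPKM/TPM-like; the unit is
        immaterial because every downstream statistic uses within-dataset
        ranks only).
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> None:
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        _check_unique(gene_ids, "gene")
        _check_unique(sample_ids, "sample")
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape != (len(gene_ids), len(sample_ids)):
            raise FormatError(
                f"values shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise ValueRangeError("expression values must be finite")
        if np.any(values < 0):
            raise ValueRangeError("expression values must be non-negative")
        self.gene_ids: list[str] = gene_ids
        self.sample_ids: list[str] = sample_ids
        self.values: np.ndarray = values
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def row(self, gene_id: str) -> np.ndarray:
        """Per-sample values of one gene, in matrix sample order."""
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise MissingGeneError(f"gene {gene_id!r} not in matrix") from None

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


@dataclass
class CaseControlStudy:
    """An expression matrix with a disjoint case/control sample partition.

    ``case_sample_ids`` are the diseased samples (S_D) and
    ``control_sample_ids`` the healthy controls (S_c).
    """

    matrix: ExpressionMatrix
    case_sample_ids: list[str]
    control_sample_ids: list[str]

    def __post_init__(self) -> None:
        cases, controls = set(self.case_sample_ids), set(self.control_sample_ids)
        if not cases or not controls:
            raise CompositionError("both case and control arms must be non-empty")
        if cases & controls:
            raise LabelError(f"samples in both arms: {sorted(cases & controls)}")
        known = set(self.matrix.sample_ids)
        stray = (cases | controls) - known
        if stray:
            raise LabelError(f"labelled samples absent from matrix: {sorted(stray)}")

    def case_values(self, gene_id: str) -> np.ndarray:
        return self.matrix.row(gene_id)[self.matrix.sample_indices(self.case_sample_ids)]

    def control_values(self, gene_id: str) -> np.ndarray:
        return self.matrix.row(gene_id)[self.matrix.sample_indices(self.control_sample_ids)]


@dataclass
class GeneList:
    """An ordered list of unique gene identifiers, optionally with loci.

    Intervals, when present, follow the BED convention: 0-based, half-open.
    """

    gene_ids: list[str]
    intervals: Optional[dict[str, tuple[str, int, int]]] = None  # gene -> (chrom, start, end)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.gene_ids, "gene")
        if self.intervals:
            for g, (chrom, start, end) in self.intervals.items():
                if not start < end:
                    raise FormatError(f"gene {g}: interval start {start} not < end {end}")

    def __iter__(self):
        return iter(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for x in ids:
            if x in seen:
                dupes.append(x)
            seen.add(x)
        raise DuplicateIdentifierError(f"duplicate {kind} identifiers: {sorted(set(dupes))}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_gct(path: str | Path) -> ExpressionMatrix:
    """Read a GCT 1.2 expression matrix.

    The first line must be the ``#1.2`` version tag and the second the
    declared ``<rows>\\t<columns>`` counts. The Description column is
    discarded: the pipeline operates on identifiers only.
    """
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != GCT_VERSION_TAG:
            raise FormatError(f"{path}: first line {version!r} is not the GCT 1.2 tag")
        dims = fh.readline().strip().split("\t")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: malformed GCT dimensions line") from None
        # read as strings and convert through numpy so that GCT and TSV
        # readers parse floats identically (exact strtod round-trip)
        df = pd.read_csv(fh, sep="\t", header=0, dtype=str)
    if df.shape[1] != n_cols + 2:
        raise FormatError(
            f"{path}: declared {n_cols} samples but found {df.shape[1] - 2} columns"
        )
    if df.shape[0] != n_rows:
        raise FormatError(f"{path}: declared {n_rows} rows but found {df.shape[0]}")
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    sample_ids = [str(c) for c in df.columns[2:]]
    values = _numeric_block(df.iloc[:, 2:], path)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def read_tsv_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a plain TSV matrix: first row sample ids, first column gene ids.

    A fully blank row means the gene was not measured and is dropped with a
    warning; a partially blank or non-numeric cell is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.isna().all(axis=None) and df.shape[1] == 0:
        raise FormatError(f"{path}: empty matrix")
    blank = df.isna() | (df.apply(lambda col: col.str.strip() == "") if df.size else df.isna())
    all_blank = blank.all(axis=1)
    if all_blank.any():
        dropped = [str(g) for g in df.index[all_blank]]
        logger.warning("%s: dropping %d fully blank gene row(s): %s", path, len(dropped), dropped)
        df = df.loc[~all_blank]
        blank = blank.loc[~all_blank]
    if blank.any(axis=None):
        bad = [str(g) for g in df.index[blank.any(axis=1)]]
        raise ValueRangeError(f"{path}: blank cells in partially measured rows: {bad}")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(c) for c in df.columns]
    values = _numeric_block(df, path)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def _numeric_block(df: pd.DataFrame, path: Path) -> np.ndarray:
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueRangeError(f"{path}: non-numeric expression value ({exc})") from None
    if df.shape[0] and not np.all(np.isfinite(values)):
        raise ValueRangeError(f"{path}: non-finite expression value")
    if df.shape[0] and np.any(values < 0):
        raise ValueRangeError(f"{path}: negative expression value")
    return values


def read_case_control(matrix_path: str | Path, labels_path: str | Path) -> CaseControlStudy:
    """Read a case-control matrix plus a two-column sample/label TSV.

    Labels must be ``case`` or ``control``; samples absent from the label
    file are excluded with a warning.
    """
    matrix = read_tsv_matrix(matrix_path)
    labels: dict[str, str] = {}
    with open(labels_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{labels_path}:{line_no}: expected 2 columns")
            sample, label = parts[0].strip(), parts[1].strip().lower()
            if line_no == 1 and label not in {"case", "control"}:
                continue  # header line
            if label not in {"case", "control"}:
                raise LabelError(f"{labels_path}:{line_no}: unknown label {label!r}")
            if sample in labels and labels[sample] != label:
                raise LabelError(f"sample {sample!r} labelled both case and control")
            labels[sample] = label
    unlabelled = [s for s in matrix.sample_ids if s not in labels]
    if unlabelled:
        logger.warning("excluding %d unlabelled sample(s): %s", len(unlabelled), unlabelled)
        keep = [s for s in matrix.sample_ids if s in labels]
        idx = matrix.sample_indices(keep)
        matrix = ExpressionMatrix(matrix.gene_ids, keep, matrix.values[:, idx])
    cases = [s for s in matrix.sample_ids if labels[s] == "case"]
    controls = [s for s in matrix.sample_ids if labels[s] == "control"]
    if not cases or not controls:
        raise CompositionError(
            f"study needs both arms; got {len(cases)} cases, {len(controls)} controls"
        )
    return CaseControlStudy(matrix, cases, controls)


def read_gene_list(path: str | Path) -> GeneList:
    """Read a gene list: one id per line, or BED-like 4+ column TSV.

    BED intervals are interpreted as 0-based half-open ``[start, end)``.
    """
    path = Path(path)
    gene_ids: list[str] = []
    intervals: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) >= 4:
                chrom, start, end, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
                gene_ids.append(gene)
                intervals[gene] = (chrom, start, end)
            else:
                gene_ids.append(parts[0].strip())
    return GeneList(gene_ids, intervals or None)


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an ExpressionMatrix as GCT 1.2 (Description column set to NA)."""
    with open(path, "w") as fh:
        fh.write(GCT_VERSION_TAG + "\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\tNA\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_tsv_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an ExpressionMatrix as a plain TSV (genes x samples)."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Result-table writer
# ---------------------------------------------------------------------------

#: float fields rendered in scientific notation with 6 significant digits
_SCI_FMT = "{:.6e}"


def write_records(records: Sequence[object], path: str | Path,
                  columns: Optional[Sequence[str]] = None) -> None:
    """Write a homogeneous sequence of result dataclasses as a TSV table.

    One header line, one row per record in input order. Real-valued fields
    are rendered in scientific notation with six significant digits so that
    a round-trip read reproduces them to the printed precision; integers and
    booleans round-trip bit-exactly.
    """
    path = Path(path)
    if records:
        if columns is None:
            columns = [f.name for f in dataclasses.fields(records[0])]
        rows = []
        for rec in records:
            d = dataclasses.asdict(rec)
            rows.append([_render(d[c]) for c in columns])
    else:
        if columns is None:
            raise ValueError("columns required to write an empty record table")
        rows = []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _render(value: object) -> str:
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return "True" if value else "False"
    if value is None:
        return "NA"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if math.isnan(value):
            return "NA"
        return _SCI_FMT.format(float(value))
    return str(value)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_records` back into a DataFrame."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
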