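"""Domain types, delimited-text readers/writers, and sample alignment.

Matrices are stored as dense :class:`numpy.ndarray` values plus ordered id
lists.  File formats are plain delimited text: CSV for matrices (one header
row of ids, one id column) and TSV for edge tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneExpressionMatrix",
    "DrugSensitivityTable",
    "DependencyScreenMatrix",
    "AlignedDataset",
    "Edge",
    "EdgeList",
    "read_matrix",
    "write_matrix",
    "read_sensitivity_table",
    "write_sensitivity_table",
    "read_edge_table",
    "write_edge_table",
    "align_samples",
    "top_variance_genes",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class _IdMatrix:
    """A real matrix with ordered, unique row and column ids."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    _row_kind = "row"
    _col_kind = "column"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = [str(i) for i in self.row_ids]
        self.col_ids = [str(i) for i in self.col_ids]
        if self.values.ndim != 2:
            raise ValueError("matrix values must be 2-dimensional")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} {self._row_kind} ids x "
                f"{len(self.col_ids)} {self._col_kind} ids"
            )
        _check_unique(self.row_ids, self._row_kind)
        _check_unique(self.col_ids, self._col_kind)

    # -- lookup helpers ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, row_id: str) -> int:
        try:
            return self.row_ids.index(row_id)
        except ValueError:
            raise KeyError(f"unknown {self._row_kind} id: {row_id!r}") from None

    def col_index(self, col_id: str) -> int:
        try:
            return self.col_ids.index(col_id)
        except ValueError:
            raise KeyError(f"unknown {self._col_kind} id: {col_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def _subset_cols(self, col_ids: Sequence[str]):
        idx = [self.col_index(c) for c in col_ids]
        return type(self)(self.values[:, idx], list(self.row_ids), list(col_ids))

    def _subset_rows(self, row_ids: Sequence[str]):
        idx = [self.row_index(r) for r in row_ids]
        return type(self)(self.values[idx, :], list(row_ids), list(self.col_ids))


@dataclass
class GeneExpressionMatrix(_IdMatrix):
    """Expression values, genes in rows and samples in columns."""

    _row_kind = "gene"
    _col_kind = "sample"

    @property
    def gene_ids(self) -> list[str]:
        return self.row_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.col_ids

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self.row_index(gene_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GeneExpressionMatrix":
        return self._subset_cols(sample_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "GeneExpressionMatrix":
        return self._subset_rows(gene_ids)


@dataclass
class DependencyScreenMatrix(_IdMatrix):
    """Knockout dependency scores, genes in rows and samples in columns."""

    _row_kind = "gene"
    _col_kind = "sample"

    @property
    def gene_ids(self) -> list[str]:
        return self.row_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.col_ids

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self.row_index(gene_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "DependencyScreenMatrix":
        return self._subset_cols(sample_ids)


@dataclass
class DrugSensitivityTable(_IdMatrix):
    """Continuous drug-response scores, samples in rows and drugs in columns."""

    _row_kind = "sample"
    _col_kind = "drug"

    @property
    def sample_ids(self) -> list[str]:
        return self.row_ids

    @property
    def drug_ids(self) -> list[str]:
        return self.col_ids

    def drug_column(self, drug_id: str) -> np.ndarray:
        return self.values[:, self.col_index(drug_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "DrugSensitivityTable":
        return self._subset_rows(sample_ids)


@dataclass
class AlignedDataset:
    """Expression, sensitivity and dependency tables on one shared sample order.

    ``regulator_ids`` are the candidate regulators (columns of the design
    matrix); ``target_ids`` are the genes whose expression is modelled.
    """

    expression: GeneExpressionMatrix
    sensitivity: DrugSensitivityTable
    dependency: DependencyScreenMatrix
    regulator_ids: list[str] = field(default_factory=list)
    target_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        s = self.expression.sample_ids
        if self.sensitivity.sample_ids != s or self.dependency.sample_ids != s:
            raise ValueError("sample ids of the three tables must be identical and identically ordered")
        genes = set(self.expression.gene_ids)
        for rid in self.regulator_ids:
            if rid not in genes:
                raise ValueError(f"regulator id {rid!r} not in expression gene ids")
        for tid in self.target_ids:
            if tid not in genes:
                raise ValueError(f"target id {tid!r} not in expression gene ids")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def regulator_matrix(self) -> np.ndarray:
        """Samples x regulators design matrix."""
        idx = [self.expression.row_index(r) for r in self.regulator_ids]
        return self.expression.values[idx, :].T

    def target_vector(self, target_id: str) -> np.ndarray:
        return self.expression.gene_row(target_id)


class Edge(NamedTuple):
    target: str
    regulator: str
    weight: float
    sample: str | None = None


@dataclass
class EdgeList:
    """Directed regulator -> target edges, optionally tagged with a sample id."""

    edges: list[Edge]

    def __post_init__(self) -> None:
        keys = set()
        clean = []
        for e in self.edges:
            e = Edge(str(e[0]), str(e[1]), float(e[2]), None if e[3] is None else str(e[3]))
            if not np.isfinite(e.weight):
                raise ValueError(f"non-finite weight for edge {e.target!r} <- {e.regulator!r}")
            key = (e.target, e.regulator, e.sample)
            if key in keys:
                raise ValueError(f"duplicate edge record: {key}")
            keys.add(key)
            clean.append(e)
        self.edges = clean

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return {(e.target, e.regulator) for e in self.edges}


# ---------------------------------------------------------------------------
# Matrix IO
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"no data rows/columns in {path}")
    # unparsable cells become NaN (missing)
    return df.apply(pd.to_numeric, errors="coerce")


def read_matrix(
    path: str | Path,
    orientation: str = "rows-are-genes",
    matrix_type: str = "expression",
    delimiter: str = ",",
) -> GeneExpressionMatrix | DependencyScreenMatrix:
    """Read a genes x samples matrix from delimited text.

    ``orientation`` says what the file rows are; the returned matrix always
    has genes in rows.  ``matrix_type`` picks the returned class
    (``"expression"`` or ``"dependency"``).
    """
    if orientation not in ("rows-are-genes", "rows-are-samples"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = _read_table(path, delimiter)
    if orientation == "rows-are-samples":
        df = df.T
    cls = {"expression": GeneExpressionMatrix, "dependency": DependencyScreenMatrix}
    try:
        klass = cls[matrix_type]
    except KeyError:
        raise ValueError(f"unknown matrix_type: {matrix_type!r}") from None
    return klass(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def write_matrix(matrix: _IdMatrix, path: str | Path, delimiter: str = ",") -> None:
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="id")


def read_sensitivity_table(path: str | Path, delimiter: str = ",") -> DrugSensitivityTable:
    """Read a samples x drugs sensitivity table (rows are samples)."""
    df = _read_table(path, delimiter)
    return DrugSensitivityTable(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def write_sensitivity_table(table: DrugSensitivityTable, path: str | Path, delimiter: str = ",") -> None:
    table.to_frame().to_csv(path, sep=delimiter, index_label="id")


# ---------------------------------------------------------------------------
# Edge table IO
# ---------------------------------------------------------------------------

_EDGE_HEADER = ["target", "regulator", "weight", "sample"]


def write_edge_table(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for e in edges:
            fh.write(f"{e.target}\t{e.regulator}\t{e.weight!r}\t{'' if e.sample is None else e.sample}\n")


def read_edge_table(path: str | Path) -> EdgeList:
    records: list[Edge] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != _EDGE_HEADER[:3]:
            raise ValueError(f"{path}: unexpected edge-table header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{lineno}: expected 3 or 4 fields, got {len(parts)}")
            try:
                weight = float(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {parts[2]!r}") from None
            sample = parts[3] if len(parts) == 4 and parts[3] != "" else None
            records.append(Edge(parts[0], parts[1], weight, sample))
    return EdgeList(records)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_samples(
    expr: GeneExpressionMatrix,
    ds: DrugSensitivityTable,
    dep: DependencyScreenMatrix,
    drug_ids: Sequence[str],
    regulator_ids: Sequence[str] | None = None,
    target_ids: Sequence[str] | None = None,
) -> AlignedDataset:
    """Restrict the three tables to their common samples.

    A sample is kept only if it appears in all three tables and has a finite
    sensitivity value for every drug in ``drug_ids``.  The retained samples
    are ordered lexicographically so downstream stages are deterministic.
    """
    if not expr.sample_ids or not ds.sample_ids or not dep.sample_ids:
        raise ValueError("all inputs must have at least one sample")
    common = set(expr.sample_ids) & set(ds.sample_ids) & set(dep.sample_ids)
    kept = []
    for s in sorted(common):
        row = ds.values[ds.row_index(s)]
        vals = [row[ds.col_index(d)] for d in drug_ids]
        if all(np.isfinite(v) for v in vals):
            kept.append(s)
    if not kept:
        raise ValueError("no samples shared by all inputs with complete sensitivity values")
    dropped = len(common) - len(kept)
    if dropped:
        logger.info("align_samples: dropped %d samples with missing sensitivity", dropped)

    expr_a = expr.subset_samples(kept)
    dep_a = dep.subset_samples(kept)
    ds_a = ds.subset_samples(kept)
    if not np.all(np.isfinite(expr_a.values)):
        raise ValueError("expression matrix has missing values for retained samples")
    if not np.all(np.isfinite(dep_a.values)):
        raise ValueError("dependency matrix has missing values for retained samples")

    regulator_ids = list(regulator_ids) if regulator_ids is not None else list(expr.gene_ids)
    target_ids = list(target_ids) if target_ids is not None else list(expr.gene_ids)
    return AlignedDataset(expr_a, ds_a, dep_a, regulator_ids, target_ids)


def top_variance_genes(expr: GeneExpressionMatrix, k: int) -> list[str]:
    """The ``k`` genes with the highest expression variance (ties by id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    var = expr.values.var(axis=1)
    order = sorted(range(len(expr.gene_ids)), key=lambda i: (-var[i], expr.gene_ids[i]))
    return [expr.gene_ids[i] for i in order[:k]]
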