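"""Target selection, regulatory-effect tensors, labels and classifier features.

The regulatory effect of regulator j on target l in sample a is the fitted
coefficient times the regulator's expression in that sample; flattening the
per-sample L x J effect matrices row-major gives the classifier features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import (
    AlignedDataset,
    DependencyScreenMatrix,
    DrugSensitivityTable,
    GeneExpressionMatrix,
)
from .network_profiler import NetworkStack

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryEffectTensor",
    "SensitivityLabels",
    "FeatureMatrix",
    "SENSITIVE",
    "RESISTANT",
    "INTERMEDIATE",
    "dependency_correlation_filter",
    "compute_regulatory_effects",
    "label_sensitivity",
    "classify_by_percentiles",
    "build_feature_matrix",
]

SENSITIVE = "sensitive"
RESISTANT = "resistant"
INTERMEDIATE = "intermediate"


@dataclass
class RegulatoryEffectTensor:
    """RE[sample, target, regulator] = beta_hat * regulator expression."""

    values: np.ndarray  # n x L x J
    sample_ids: list[str]
    target_ids: list[str]
    regulator_ids: list[str]
    modulator_drug: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.sample_ids), len(self.target_ids), len(self.regulator_ids))
        if self.values.shape != expected:
            raise ValueError(f"tensor shape {self.values.shape} != {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite regulatory effect")

    def subset_samples(self, sample_ids: Sequence[str]) -> "RegulatoryEffectTensor":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return RegulatoryEffectTensor(self.values[idx], list(sample_ids),
                                      list(self.target_ids), list(self.regulator_ids),
                                      self.modulator_drug)


@dataclass
class SensitivityLabels:
    """Three-way labels from the P10/P90 percentiles of a drug's scores."""

    labels: list[str]
    sample_ids: list[str]
    p10_value: float
    p90_value: float
    response_drug: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels and sample_ids must have equal length")
        bad = set(self.labels) - {SENSITIVE, RESISTANT, INTERMEDIATE}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    def label_of(self, sample_id: str) -> str:
        return self.labels[self.sample_ids.index(sample_id)]

    def samples_with(self, label: str) -> list[str]:
        return [s for s, lab in zip(self.sample_ids, self.labels) if lab == label]

    @property
    def n_sensitive(self) -> int:
        return self.labels.count(SENSITIVE)

    @property
    def n_resistant(self) -> int:
        return self.labels.count(RESISTANT)


@dataclass
class FeatureMatrix:
    """Flattened regulatory-effect rows for the classifiable samples.

    Columns are (target, regulator) pairs in target-major order; labels are
    binary with sensitive = 1 and resistant = 0.
    """

    values: np.ndarray  # rows x (L*J or restricted)
    sample_ids: list[str]
    columns: list[tuple[str, str]]
    labels: np.ndarray  # int {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.sample_ids), len(self.columns)):
            raise ValueError("feature matrix shape inconsistent with ids")
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels length inconsistent")
        self.columns = [(str(t), str(r)) for t, r in self.columns]

    @property
    def column_map(self) -> dict[tuple[str, str], int]:
        return {c: i for i, c in enumerate(self.columns)}

    def column(self, target: str, regulator: str) -> np.ndarray:
        return self.values[:, self.column_map[(target, regulator)]]

    def drop_column(self, target: str, regulator: str) -> "FeatureMatrix":
        key = (target, regulator)
        cmap = self.column_map
        if key not in cmap:
            raise KeyError(f"unknown feature column {key}")
        i = cmap[key]
        keep = [j for j in range(len(self.columns)) if j != i]
        return FeatureMatrix(self.values[:, keep], list(self.sample_ids),
                             [self.columns[j] for j in keep], self.labels.copy())


def save_feature_matrix(fm: FeatureMatrix, out_dir) -> None:
    """Persist as CSV (rows: samples; first column: label) plus a column map."""
    import json
    from pathlib import Path

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [f"{t}|{r}" for t, r in fm.columns]
    df = pd.DataFrame(fm.values, index=fm.sample_ids, columns=cols)
    df.insert(0, "label", fm.labels)
    df.to_csv(out / "features.csv", index_label="sample")
    (out / "column_map.json").write_text(
        json.dumps({f"{t}|{r}": i for i, (t, r) in enumerate(fm.columns)}, indent=1))


def load_feature_matrix(in_dir) -> FeatureMatrix:
    from pathlib import Path

    import pandas as pd

    df = pd.read_csv(Path(in_dir) / "features.csv", index_col=0)
    labels = df.pop("label").to_numpy(dtype=int)
    columns = [tuple(c.split("|", 1)) for c in df.columns]
    return FeatureMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index], columns, labels)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def dependency_correlation_filter(
    dep: DependencyScreenMatrix,
    ds: DrugSensitivityTable,
    drug: str,
    top_fraction: float = 0.01,
    signed: bool = False,
) -> list[str]:
    """Genes whose dependency profile correlates most with a drug's scores.

    Pearson correlation per gene against the drug's sensitivity column;
    genes are ranked by |r| (or by signed r when ``signed``) and the top
    ``ceil(top_fraction * n_genes)`` returned, ties broken by gene id.
    Zero-variance gene rows get correlation 0 with a warning.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if dep.sample_ids != ds.sample_ids:
        raise ValueError("dependency and sensitivity tables must share sample order")
    n = len(dep.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation ranking")
    y = ds.drug_column(drug)
    y_c = y - y.mean()
    y_ss = float(y_c @ y_c)
    D = dep.values
    D_c = D - D.mean(axis=1, keepdims=True)
    row_ss = (D_c * D_c).sum(axis=1)
    degenerate = (row_ss <= 0) | (y_ss <= 0)
    if degenerate.any():
        logger.warning("dependency_correlation_filter: %d zero-variance rows scored 0",
                       int(degenerate.sum()))
    denom = np.sqrt(np.where(degenerate, 1.0, row_ss * y_ss))
    r = np.where(degenerate, 0.0, (D_c @ y_c) / denom)
    score = r if signed else np.abs(r)
    k = math.ceil(top_fraction * len(dep.gene_ids))
    order = sorted(range(len(dep.gene_ids)), key=lambda i: (-score[i], dep.gene_ids[i]))
    return [dep.gene_ids[i] for i in order[:k]]


def compute_regulatory_effects(
    stack: NetworkStack,
    expr: GeneExpressionMatrix,
    scale: str = "raw",
) -> RegulatoryEffectTensor:
    """Elementwise product of coefficients and regulator expression.

    The stack's coefficients are reported on the raw expression scale, so
    ``scale="raw"`` (the default) is the consistent pairing;
    ``scale="standardized"`` z-scores each regulator's expression across
    samples first.
    """
    if scale not in ("raw", "standardized"):
        raise ValueError(f"unknown scale: {scale!r}")
    for s in stack.sample_ids:
        if s not in expr.sample_ids:
            raise KeyError(f"stack sample {s!r} missing from expression matrix")
    reg_idx = []
    for r in stack.regulator_ids:
        reg_idx.append(expr.row_index(r))  # raises KeyError naming the id
    col_idx = [expr.col_index(s) for s in stack.sample_ids]
    x = expr.values[np.ix_(reg_idx, col_idx)].T  # n x J
    if scale == "standardized":
        sd = x.std(axis=0)
        x = np.divide(x - x.mean(axis=0), sd, out=np.zeros_like(x), where=sd > 0)
    re = stack.coefficients * x[:, None, :]
    return RegulatoryEffectTensor(re, list(stack.sample_ids), list(stack.target_ids),
                                  list(stack.regulator_ids), stack.modulator_drug)


def classify_by_percentiles(values: np.ndarray, p_low: float = 10.0,
                            p_high: float = 90.0) -> tuple[list[str], float, float]:
    """Strict-inequality three-way split at the two empirical percentiles.

    Percentiles use the linear-interpolation convention (numpy default), so
    e.g. the 10th percentile of 1..100 is 10.9.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 samples for percentile labeling")
    lo = float(np.percentile(values, p_low))
    hi = float(np.percentile(values, p_high))
    labels = [SENSITIVE if v < lo else RESISTANT if v > hi else INTERMEDIATE
              for v in values]
    return labels, lo, hi


def label_sensitivity(ds: DrugSensitivityTable, drug: str, p_low: float = 10.0,
                      p_high: float = 90.0) -> SensitivityLabels:
    """Label samples sensitive (< P10), resistant (> P90) or intermediate."""
    values = ds.drug_column(drug)
    labels, lo, hi = classify_by_percentiles(values, p_low, p_high)
    out = SensitivityLabels(labels, list(ds.sample_ids), lo, hi, drug)
    logger.info("label_sensitivity(%s): %d sensitive, %d resistant, %d intermediate",
                drug, out.n_sensitive, out.n_resistant,
                len(labels) - out.n_sensitive - out.n_resistant)
    return out


def build_feature_matrix(tensor: RegulatoryEffectTensor,
                         labels: SensitivityLabels) -> FeatureMatrix:
    """Drop intermediate samples and flatten each L x J effect matrix."""
    if set(tensor.sample_ids) != set(labels.sample_ids):
        raise ValueError("tensor and labels must cover the same samples")
    keep, y = [], []
    for i, s in enumerate(tensor.sample_ids):
        lab = labels.label_of(s)
        if lab == SENSITIVE:
            keep.append(i)
            y.append(1)
        elif lab == RESISTANT:
            keep.append(i)
            y.append(0)
    y = np.asarray(y, dtype=int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 sensitive and 2 resistant samples")
    n, L, J = tensor.values.shape
    flat = tensor.values[keep].reshape(len(keep), L * J)
    columns = [(t, r) for t in tensor.target_ids for r in tensor.regulator_ids]
    return FeatureMatrix(flat, [tensor.sample_ids[i] for i in keep], columns, y)
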