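"""Ablation-based edge importance with a pooled two-sample t-test.

Each candidate feature column (a target-regulator edge) is removed in turn,
the repeated-CV accuracy distribution is recomputed without it, and the
shift relative to the full model is tested with a pooled two-sample t-test.
Edges with p-values below the threshold are the crucial interactions; the
sign records whether removing the edge hurt (+) or helped (-) accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .feature_builder import FeatureMatrix
from .predictor import ClassifierConfig, CVResult, repeated_stratified_cv

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeImportance",
    "CrucialEdgeSet",
    "ablate_feature",
    "pooled_t_test",
    "pn_sign",
    "run_xprediction",
    "benjamini_hochberg",
    "write_importance_table",
    "read_importance_table",
]


@dataclass
class EdgeImportance:
    target: str
    regulator: str
    mean_acc_full: float
    mean_acc_ablated: float
    sd_full: float
    sd_ablated: float
    n_full: int
    n_ablated: int
    t_statistic: float
    p_value: float
    pn_sign: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.pn_sign not in ("+", "-"):
            raise ValueError("pn_sign must be '+' or '-'")
        expected = "+" if self.mean_acc_full - self.mean_acc_ablated > 0 else "-"
        if self.pn_sign != expected:
            raise ValueError("pn_sign inconsistent with the accuracy difference")


@dataclass
class CrucialEdgeSet:
    modulator_drug: str
    response_drug: str
    edges: list[EdgeImportance]
    alpha: float = 0.01

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.p_value >= self.alpha:
                raise ValueError("edge with p >= alpha in crucial set")

    def pairs(self) -> set[tuple[str, str]]:
        return {(e.target, e.regulator) for e in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


def ablate_feature(features: FeatureMatrix, target: str, regulator: str) -> FeatureMatrix:
    """The feature matrix with one (target, regulator) column removed."""
    return features.drop_column(target, regulator)


def pooled_t_test(acc_full: Sequence[float], acc_ablated: Sequence[float]) -> tuple[float, float]:
    """Two-sided pooled two-sample t-test on two accuracy samples.

    T = (mean1 - mean2) / (s_p * sqrt(1/N1 + 1/N2)) with the pooled standard
    deviation s_p^2 = ((N1-1) s1^2 + (N2-1) s2^2) / (N1 + N2 - 2), and p from
    the Student t distribution with N1 + N2 - 2 degrees of freedom.
    """
    a = np.asarray(acc_full, dtype=float)
    b = np.asarray(acc_ablated, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples must have at least 2 observations")
    diff = float(a.mean() - b.mean())
    s1 = float(a.var(ddof=1))
    s2 = float(b.var(ddof=1))
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if sp2 <= 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; p-value set to 0")
        return float(np.sign(diff)) * np.inf, 0.0
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df=n1 + n2 - 2))
    return float(t), min(p, 1.0)


def pn_sign(mean_full: float, mean_ablated: float) -> str:
    """'+' when removing the edge lowers accuracy, '-' otherwise."""
    if not (np.isfinite(mean_full) and np.isfinite(mean_ablated)):
        raise ValueError("means must be finite")
    if mean_full > mean_ablated:
        return "+"
    if mean_full == mean_ablated:
        warnings.warn("exact tie in mean accuracies; sign set to '-'")
    return "-"


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; raw thresholding is the default)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def _ablated_seed(base_seed: int, edge_index: int) -> int:
    # fresh, deterministic fold seeds per edge, independent of the full run
    return (base_seed * 1_000_003 + (edge_index + 1) * 7_919) % (2**31 - 1)


def run_xprediction(
    features: FeatureMatrix,
    config: ClassifierConfig,
    k: int = 10,
    n_it: int = 50,
    n_it_ablated: int | None = None,
    candidate_edges: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.01,
    base_seed: int = 0,
    adjust: str | None = None,
    full_result: CVResult | None = None,
) -> tuple[list[EdgeImportance], CrucialEdgeSet]:
    """Score every candidate edge by ablation and threshold at ``alpha``.

    The full model's repeated CV runs once (or is supplied precomputed via
    ``full_result``); each candidate edge then gets its own repeated CV on
    the ablated matrix with fresh fold seeds, followed by the pooled t-test.
    Results are sorted by p-value, ties broken by (target, regulator).
    """
    if n_it_ablated is None:
        n_it_ablated = n_it
    if candidate_edges is None:
        candidate_edges = [c for i, c in enumerate(features.columns)
                           if np.any(features.values[:, i] != 0.0)]
    candidate_edges = [(str(t), str(r)) for t, r in candidate_edges]
    if not candidate_edges:
        raise ValueError("empty candidate edge set")
    cmap = features.column_map
    for e in candidate_edges:
        if e not in cmap:
            raise KeyError(f"candidate edge {e} not in the feature columns")
    if adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment: {adjust!r}")

    if full_result is None:
        full_result = repeated_stratified_cv(features, config, k=k,
                                             n_iterations=n_it, base_seed=base_seed)
    acc_full = np.asarray(full_result.iteration_accuracies)

    records: list[EdgeImportance] = []
    for idx, (t_id, r_id) in enumerate(candidate_edges):
        ablated = ablate_feature(features, t_id, r_id)
        res = repeated_stratified_cv(ablated, config, k=k, n_iterations=n_it_ablated,
                                     base_seed=_ablated_seed(base_seed, cmap[(t_id, r_id)]))
        acc_abl = np.asarray(res.iteration_accuracies)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_stat, p = pooled_t_test(acc_full, acc_abl)
            sign = pn_sign(float(acc_full.mean()), float(acc_abl.mean()))
        records.append(EdgeImportance(
            target=t_id, regulator=r_id,
            mean_acc_full=float(acc_full.mean()), mean_acc_ablated=float(acc_abl.mean()),
            sd_full=float(acc_full.std(ddof=1)), sd_ablated=float(acc_abl.std(ddof=1)),
            n_full=len(acc_full), n_ablated=len(acc_abl),
            t_statistic=t_stat, p_value=p, pn_sign=sign,
        ))

    if adjust == "bh":
        adj = benjamini_hochberg([r.p_value for r in records])
        for r, q in zip(records, adj):
            r.p_value = float(q)
    records.sort(key=lambda r: (r.p_value, r.target, r.regulator))
    crucial = CrucialEdgeSet(modulator_drug="", response_drug="",
                             edges=[r for r in records if r.p_value < alpha], alpha=alpha)
    logger.info("run_xprediction: %d of %d candidate edges crucial at alpha=%g",
                len(crucial), len(records), alpha)
    return records, crucial


# ---------------------------------------------------------------------------
# Importance table IO (TSV mirroring the published table layout)
# ---------------------------------------------------------------------------

_IMP_HEADER = ["target", "regulator", "acc_full", "acc_ablated", "T", "p_value", "PN"]


def write_importance_table(records: Sequence[EdgeImportance], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_IMP_HEADER) + "\n")
        for r in records:
            fh.write(f"{r.target}\t{r.regulator}\t{r.mean_acc_full!r}\t"
                     f"{r.mean_acc_ablated!r}\t{r.t_statistic!r}\t{r.p_value!r}\t{r.pn_sign}\n")


def read_importance_table(path: str | Path) -> list[EdgeImportance]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _IMP_HEADER:
            raise ValueError(f"{path}: unexpected importance header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 fields")
            out.append(EdgeImportance(
                target=parts[0], regulator=parts[1],
                mean_acc_full=float(parts[2]), mean_acc_ablated=float(parts[3]),
                sd_full=0.0, sd_ablated=0.0, n_full=0, n_ablated=0,
                t_statistic=float(parts[4]), p_value=float(parts[5]), pn_sign=parts[6],
            ))
    return out
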