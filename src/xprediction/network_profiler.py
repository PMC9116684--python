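"""Per-sample network estimation by kernel-weighted elastic-net regression.

For every anchor sample the other samples are weighted by a Gaussian kernel
on the distance between their modulator values (a drug-sensitivity score),
and a weighted elastic net is fitted to predict each target gene from the
candidate regulators.  The coefficient rows, one per (anchor, target), form
a stack of per-sample networks.

The solver is cyclic coordinate descent on the penalized weighted
least-squares objective

    (1/2) sum_i w_i (y_i - x_i' b)^2
        + lam * (mixing * ||b||_1 + (1 - mixing)/2 * ||b||_2^2)

using precomputed Gram/covariance statistics, warm starts along a
descending lambda path, and an explicit per-sweep check that the objective
never increases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from .core_io import AlignedDataset, Edge, EdgeList

logger = logging.getLogger(__name__)

__all__ = [
    "KernelWeights",
    "PenaltyConfig",
    "NetworkStack",
    "ConvergenceError",
    "gaussian_kernel",
    "kernel_weights",
    "fit_weighted_elastic_net",
    "lambda_max",
    "select_bandwidth",
    "estimate_sample_network",
    "estimate_all_networks",
    "default_bandwidth_grid",
]

ZERO_TOL = 1e-12  # coefficients below this magnitude are stored as absent


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------

def gaussian_kernel(m_i: float, m_alpha: float, b: float) -> float:
    """exp(-(m_i - m_alpha)^2 / b); equals 1 at zero distance."""
    if b <= 0:
        raise ValueError("bandwidth must be positive")
    d = np.asarray(m_i, dtype=float) - np.asarray(m_alpha, dtype=float)
    out = np.exp(-(d * d) / b)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class KernelWeights:
    """Per-sample kernel weights anchored at one sample."""

    weights: np.ndarray
    anchor_sample: str
    bandwidth: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("kernel weights must lie in (0, 1]")


def kernel_weights(modulator: np.ndarray, anchor_index: int, bandwidth: float,
                   anchor_sample: str = "") -> KernelWeights:
    m = np.asarray(modulator, dtype=float)
    w = gaussian_kernel(m, m[anchor_index], bandwidth)
    return KernelWeights(np.asarray(w, dtype=float), anchor_sample or str(anchor_index), bandwidth)


# ---------------------------------------------------------------------------
# Penalty configuration
# ---------------------------------------------------------------------------

@dataclass
class PenaltyConfig:
    """Elastic-net penalty: strength, L1 fraction, and how lambda is chosen.

    ``selection="fixed"`` uses ``lam`` directly; ``selection="grid_cv"``
    picks lambda by weighted K-fold cross-validation over a log-spaced grid
    from lambda_max down ``lambda_min_ratio`` decades, applying either the
    CV-minimum rule or the one-standard-error rule.
    """

    lam: float | None = None
    mixing: float = 0.5
    selection: str = "fixed"
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 5
    cv_seed: int = 0
    cv_rule: str = "1se"
    cv_se_factor: float = 1.0
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")
        if self.selection not in ("fixed", "grid_cv"):
            raise ValueError(f"unknown selection mode: {self.selection!r}")
        if self.selection == "fixed":
            if self.lam is None:
                raise ValueError("fixed selection requires lam")
            if self.lam < 0:
                raise ValueError("lam must be nonnegative")
        if self.cv_rule not in ("min", "1se"):
            raise ValueError(f"unknown cv_rule: {self.cv_rule!r}")


# ---------------------------------------------------------------------------
# Coordinate descent core
# ---------------------------------------------------------------------------

def _objective_gram(G: np.ndarray, c: np.ndarray, yy: float, b: np.ndarray,
                    lam: float, mixing: float) -> float:
    quad = 0.5 * yy - c @ b + 0.5 * b @ G @ b
    pen = lam * (mixing * np.abs(b).sum() + 0.5 * (1.0 - mixing) * (b @ b))
    return float(quad + pen)


def _cd_core(G, c, yy, lam, mixing, beta, tol, max_iter):
    """Cyclic coordinate descent on the Gram form of the objective.

    Returns (beta, status): 0 converged, 1 max_iter exceeded, 2 objective
    increased between sweeps (a solver bug; must never happen).
    """
    p = c.shape[0]
    l1 = lam * mixing
    l2 = lam * (1.0 - mixing)
    Gb = G @ beta
    obj = 0.5 * yy - c @ beta + 0.5 * beta @ Gb \
        + lam * (mixing * np.abs(beta).sum() + 0.5 * (1.0 - mixing) * (beta @ beta))
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            denom = G[j, j] + l2
            if denom <= 0.0:
                # degenerate column (zero weighted variance): coefficient stays 0
                if beta[j] != 0.0:
                    Gb -= G[:, j] * beta[j]
                    beta[j] = 0.0
                continue
            rho = c[j] - (Gb[j] - G[j, j] * beta[j])
            if rho > l1:
                new = (rho - l1) / denom
            elif rho < -l1:
                new = (rho + l1) / denom
            else:
                new = 0.0
            delta = new - beta[j]
            if delta != 0.0:
                Gb += G[:, j] * delta
                beta[j] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        new_obj = 0.5 * yy - c @ beta + 0.5 * beta @ (G @ beta) \
            + lam * (mixing * np.abs(beta).sum() + 0.5 * (1.0 - mixing) * (beta @ beta))
        if new_obj > obj + 1e-9 * max(1.0, abs(obj)):
            return beta, 2
        obj = new_obj
        if max_delta < tol:
            return beta, 0
    return beta, 1


try:  # the numba JIT gives a ~50x speedup on the inner loops; optional
    from numba import njit

    _cd_core = njit(cache=True)(_cd_core)
except ImportError:  # pragma: no cover
    pass


def _cd_gram(G: np.ndarray, c: np.ndarray, yy: float, lam: float, mixing: float,
             beta0: np.ndarray, tol: float, max_iter: int, context: str = "") -> np.ndarray:
    beta, status = _cd_core(np.ascontiguousarray(G), np.ascontiguousarray(c),
                            float(yy), float(lam), float(mixing),
                            beta0.copy(), float(tol), int(max_iter))
    if status == 2:
        raise AssertionError(f"objective increased during coordinate descent {context}")
    if status == 1:
        raise ConvergenceError(f"coordinate descent did not converge in {max_iter} sweeps {context}")
    return beta


def lambda_max(X: np.ndarray, y: np.ndarray, w: np.ndarray, mixing: float) -> float:
    """Smallest lambda at which the elastic-net solution is identically zero."""
    grad = np.abs(X.T @ (w * y)).max() if X.size else 0.0
    if mixing <= 0:
        raise ValueError("lambda_max undefined for pure ridge (mixing = 0)")
    return float(grad) / mixing


def _as_weight_array(w, n: int) -> np.ndarray:
    arr = w.weights if isinstance(w, KernelWeights) else np.asarray(w, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"weights have shape {arr.shape}, expected ({n},)")
    if np.any(arr < 0):
        raise ValueError("weights must be nonnegative")
    if arr.sum() <= 0:
        raise ValueError("all-zero kernel weights")
    return arr


def _lambda_path(lmax: float, penalty: PenaltyConfig) -> np.ndarray:
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, lmax * penalty.lambda_min_ratio, penalty.n_lambdas)


def _fit_path(G, c, yy, path, penalty: PenaltyConfig, context: str = "") -> np.ndarray:
    """Warm-started solutions along a descending lambda path (len(path) x p)."""
    p = len(c)
    out = np.empty((len(path), p))
    beta = np.zeros(p)
    for i, lam in enumerate(path):
        beta = _cd_gram(G, c, yy, lam, penalty.mixing, beta, penalty.tol,
                        penalty.max_iter, context)
        out[i] = beta
    return out


def _gram(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    Xw = X * w[:, None]
    return Xw.T @ X, X.T @ (w * y), float(w @ (y * y))


def _cv_select_lambda(X, y, w, penalty: PenaltyConfig, context: str = "") -> float:
    """Weighted K-fold CV over the lambda path; returns the chosen lambda."""
    n = len(y)
    lmax = lambda_max(X, y, w, penalty.mixing) if penalty.mixing > 0 else \
        np.abs(X.T @ (w * y)).max()
    path = _lambda_path(lmax, penalty)
    k = min(penalty.cv_folds, n)
    rng = np.random.default_rng(penalty.cv_seed)
    fold_of = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(fold_of)
    errs = np.zeros((k, len(path)))
    valid = np.zeros(k, dtype=bool)
    for f in range(k):
        tr = fold_of != f
        va = ~tr
        w_va = w[va]
        if w_va.sum() <= 0 or w[tr].sum() <= 0:
            continue
        G, c, yy = _gram(X[tr], y[tr], w[tr])
        betas = _fit_path(G, c, yy, path, penalty, context)
        resid = y[va][None, :] - betas @ X[va].T
        errs[f] = (resid * resid * w_va[None, :]).sum(axis=1) / w_va.sum()
        valid[f] = True
    if not valid.any():
        return float(path[0])
    errs = errs[valid]
    mean = errs.mean(axis=0)
    i_min = int(np.argmin(mean))
    if penalty.cv_rule == "min" or errs.shape[0] < 2:
        return float(path[i_min])
    se = errs.std(axis=0, ddof=1) / np.sqrt(errs.shape[0])
    threshold = mean[i_min] + penalty.cv_se_factor * se[i_min]
    # path is descending, so the first index within one SE is the largest lambda
    i_1se = int(np.nonzero(mean <= threshold)[0][0])
    return float(path[i_1se])


def fit_weighted_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    w: KernelWeights | np.ndarray,
    penalty: PenaltyConfig,
    context: str = "",
) -> np.ndarray:
    """Solve the weighted elastic net; returns the coefficient vector.

    ``X`` and ``y`` are used as given (standardize beforehand if needed).
    With ``selection="grid_cv"`` lambda is chosen by weighted K-fold CV
    first, then the model is refitted on all samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n x p and y length n")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    w_arr = _as_weight_array(w, n)
    if penalty.selection == "grid_cv":
        lam = _cv_select_lambda(X, y, w_arr, penalty, context)
    else:
        lam = float(penalty.lam)
    G, c, yy = _gram(X, y, w_arr)
    lmax = np.abs(c).max() / penalty.mixing if penalty.mixing > 0 else lam
    # warm start along a short descending path for stability at small lambda
    if 0 < lam < lmax:
        path = np.geomspace(lmax, lam, 8)
    else:
        path = np.array([lam])
    beta = _fit_path(G, c, yy, path, penalty, context)[-1]
    return beta


# ---------------------------------------------------------------------------
# Local fits with per-anchor weighted standardization
# ---------------------------------------------------------------------------

def _weighted_standardize(X, y, w):
    """Weighted z-scoring of the columns of X and of y.

    Returns standardized arrays plus the means/scales needed to map the
    coefficients back to the original scale.  Columns with zero weighted
    variance are mapped to all-zero columns (their coefficients are 0).
    """
    wn = w / w.sum()
    mu_x = wn @ X
    Xc = X - mu_x
    var_x = wn @ (Xc * Xc)
    sd_x = np.sqrt(var_x)
    mu_y = float(wn @ y)
    yc = y - mu_y
    sd_y = float(np.sqrt(wn @ (yc * yc)))
    Xs = np.divide(Xc, sd_x, out=np.zeros_like(Xc), where=sd_x > 0)
    ys = yc / sd_y if sd_y > 0 else np.zeros_like(yc)
    return Xs, ys, wn, mu_x, sd_x, mu_y, sd_y


def _local_fit(X, y, w, penalty: PenaltyConfig, context: str = ""):
    """Standardized weighted elastic-net fit; coefficients on the raw scale.

    Returns ``(beta_raw, mu_x, mu_y)`` so predictions at an anchor are
    ``mu_y + (x - mu_x) @ beta_raw`` (the intercept is absorbed by the
    weighted centering).
    """
    Xs, ys, wn, mu_x, sd_x, mu_y, sd_y = _weighted_standardize(X, y, w)
    if sd_y == 0:
        return np.zeros(X.shape[1]), mu_x, mu_y
    beta_std = fit_weighted_elastic_net(Xs, ys, wn, penalty, context)
    beta = np.divide(beta_std * sd_y, sd_x, out=np.zeros_like(beta_std), where=sd_x > 0)
    beta[np.abs(beta) < ZERO_TOL] = 0.0
    return beta, mu_x, mu_y


# ---------------------------------------------------------------------------
# Bandwidth selection
# ---------------------------------------------------------------------------

def default_bandwidth_grid(modulator: np.ndarray) -> list[float]:
    v = float(np.var(np.asarray(modulator, dtype=float)))
    if v <= 0:
        v = 1.0
    return [f * v for f in (0.25, 0.5, 1.0, 2.0, 4.0)]


def select_bandwidth(
    modulator: np.ndarray,
    candidates: Sequence[float],
    X: np.ndarray,
    y: np.ndarray,
    penalty: PenaltyConfig,
    max_anchors: int | None = None,
    seed: int = 0,
) -> float:
    """Pick the bandwidth minimizing leave-one-out local prediction error.

    For each candidate and each anchor, the local model is fitted with the
    anchor held out and used to predict the anchor's response; the candidate
    with the smallest mean squared error wins, ties going to the smallest
    candidate.  CV-based lambda selection would be prohibitive inside the
    LOO loop, so each local fit uses a fixed lambda at 5% of its lambda_max.
    """
    candidates = sorted(float(b) for b in candidates)
    if not candidates:
        raise ValueError("empty bandwidth candidate list")
    if any(b <= 0 for b in candidates):
        raise ValueError("bandwidth candidates must be positive")
    if len(candidates) == 1:
        return candidates[0]
    m = np.asarray(modulator, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(m)
    anchors = np.arange(n)
    if max_anchors is not None and max_anchors < n:
        anchors = np.sort(np.random.default_rng(seed).choice(n, size=max_anchors, replace=False))

    errors = []
    for b in candidates:
        sq = 0.0
        for a in anchors:
            w = gaussian_kernel(m, m[a], b)
            w = np.asarray(w, dtype=float)
            w[a] = 0.0  # leave the anchor out
            if w.sum() <= 0:
                sq += float(y[a] ** 2)
                continue
            keep = w > 0
            Xs, ys, wn, mu_x, sd_x, mu_y, sd_y = _weighted_standardize(X[keep], y[keep], w[keep])
            if sd_y == 0:
                pred = mu_y
            else:
                lmax = lambda_max(Xs, ys, wn, max(penalty.mixing, 1e-8))
                local = replace(penalty, selection="fixed", lam=0.05 * lmax)
                beta_std = fit_weighted_elastic_net(Xs, ys, wn, local)
                beta = np.divide(beta_std * sd_y, sd_x, out=np.zeros_like(beta_std), where=sd_x > 0)
                pred = mu_y + float((X[a] - mu_x) @ beta)
            sq += float((y[a] - pred) ** 2)
        errors.append(sq / len(anchors))
    best = int(np.argmin(errors))  # argmin takes the first (smallest) candidate on ties
    return candidates[best]


# ---------------------------------------------------------------------------
# Network stack
# ---------------------------------------------------------------------------

@dataclass
class NetworkStack:
    """Coefficients beta[sample, target, regulator] for all per-sample fits."""

    coefficients: np.ndarray  # n x L x J, exact zeros mean absent edges
    sample_ids: list[str]
    target_ids: list[str]
    regulator_ids: list[str]
    bandwidths: dict[str, float] = field(default_factory=dict)
    modulator_drug: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expected = (len(self.sample_ids), len(self.target_ids), len(self.regulator_ids))
        if self.coefficients.shape != expected:
            raise ValueError(f"coefficient shape {self.coefficients.shape} != {expected}")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficient in network stack")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape

    def sample_network(self, sample_id: str) -> np.ndarray:
        return self.coefficients[self.sample_ids.index(sample_id)]

    def to_edge_list(self, tol: float = ZERO_TOL) -> EdgeList:
        edges = []
        for a, s in enumerate(self.sample_ids):
            for l, t in enumerate(self.target_ids):
                for j, r in enumerate(self.regulator_ids):
                    v = self.coefficients[a, l, j]
                    if abs(v) > tol:
                        edges.append(Edge(t, r, float(v), s))
        return EdgeList(edges)


def save_network_stack(stack: NetworkStack, out_dir) -> None:
    """Write a stack as a sparse edge table plus a JSON manifest."""
    import json
    from pathlib import Path

    from .core_io import write_edge_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_table(stack.to_edge_list(), out / "networks.tsv")
    manifest = {
        "sample_ids": stack.sample_ids,
        "target_ids": stack.target_ids,
        "regulator_ids": stack.regulator_ids,
        "bandwidths": stack.bandwidths,
        "modulator_drug": stack.modulator_drug,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_network_stack(in_dir) -> NetworkStack:
    import json
    from pathlib import Path

    from .core_io import read_edge_table

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    samples = manifest["sample_ids"]
    targets = manifest["target_ids"]
    regs = manifest["regulator_ids"]
    coef = np.zeros((len(samples), len(targets), len(regs)))
    s_pos = {s: i for i, s in enumerate(samples)}
    t_pos = {t: i for i, t in enumerate(targets)}
    r_pos = {r: i for i, r in enumerate(regs)}
    for e in read_edge_table(src / "networks.tsv"):
        if e.sample is None:
            raise ValueError("stack edge table rows must carry a sample id")
        coef[s_pos[e.sample], t_pos[e.target], r_pos[e.regulator]] = e.weight
    return NetworkStack(coef, samples, targets, regs,
                        manifest.get("bandwidths", {}), manifest.get("modulator_drug", ""))


def _target_design(dataset: AlignedDataset, target_id: str):
    """Design matrix excluding the target itself from its regulators."""
    regs = [r for r in dataset.regulator_ids if r != target_id]
    idx = [dataset.expression.row_index(r) for r in regs]
    X = dataset.expression.values[idx, :].T
    y = dataset.expression.gene_row(target_id)
    return X, y, regs


def _expand_row(beta: np.ndarray, regs: list[str], all_regs: list[str]) -> np.ndarray:
    if len(regs) == len(all_regs):
        return beta
    out = np.zeros(len(all_regs))
    pos = {r: i for i, r in enumerate(all_regs)}
    for b, r in zip(beta, regs):
        out[pos[r]] = b
    return out


def estimate_sample_network(
    dataset: AlignedDataset,
    modulator_drug: str,
    target_id: str,
    anchor_sample: str,
    penalty: PenaltyConfig,
    bandwidth: float,
) -> np.ndarray:
    """Coefficient row over ``dataset.regulator_ids`` for one (anchor, target)."""
    m = dataset.sensitivity.drug_column(modulator_drug)
    a = dataset.sample_ids.index(anchor_sample)
    X, y, regs = _target_design(dataset, target_id)
    w = kernel_weights(m, a, bandwidth, anchor_sample)
    beta, _, _ = _local_fit(X, y, w.weights, penalty,
                            context=f"(target={target_id}, anchor={anchor_sample})")
    return _expand_row(beta, regs, dataset.regulator_ids)


def _estimate_target(dataset, modulator_drug, target_id, penalty, bandwidth,
                     bandwidth_candidates, bandwidth_max_anchors):
    m = dataset.sensitivity.drug_column(modulator_drug)
    X, y, regs = _target_design(dataset, target_id)
    if bandwidth is None:
        cands = bandwidth_candidates or default_bandwidth_grid(m)
        b = select_bandwidth(m, cands, X, y, penalty, max_anchors=bandwidth_max_anchors)
    else:
        b = float(bandwidth)
    n = dataset.n_samples
    rows = np.empty((n, len(dataset.regulator_ids)))
    cache: dict[float, np.ndarray] = {}
    for a in range(n):
        key = round(float(m[a]), 15)
        if key in cache:
            rows[a] = cache[key]  # equal modulator values give identical fits
            continue
        w = kernel_weights(m, a, b, dataset.sample_ids[a])
        beta, _, _ = _local_fit(
            X, y, w.weights, penalty,
            context=f"(target={target_id}, anchor={dataset.sample_ids[a]})")
        rows[a] = _expand_row(beta, regs, dataset.regulator_ids)
        cache[key] = rows[a]
    return b, rows


def estimate_all_networks(
    dataset: AlignedDataset,
    modulator_drug: str,
    targets: Sequence[str] | None = None,
    penalty: PenaltyConfig | None = None,
    bandwidth: float | dict[str, float] | None = None,
    bandwidth_candidates: Sequence[float] | None = None,
    bandwidth_max_anchors: int | None = None,
    n_jobs: int = 1,
) -> NetworkStack:
    """Estimate the full stack of per-sample networks.

    ``bandwidth`` may be a single value, a per-target mapping, or ``None``
    to select per-target bandwidths by leave-one-out error.  Results are
    assembled by index so the output is identical for any ``n_jobs``.
    """
    targets = list(targets) if targets is not None else list(dataset.target_ids)
    if not targets:
        raise ValueError("empty target list")
    penalty = penalty or PenaltyConfig(selection="grid_cv")

    def bw_for(t):
        if bandwidth is None:
            return None
        if isinstance(bandwidth, dict):
            return bandwidth[t]
        return float(bandwidth)

    results = Parallel(n_jobs=n_jobs)(
        delayed(_estimate_target)(
            dataset, modulator_drug, t, penalty, bw_for(t),
            bandwidth_candidates, bandwidth_max_anchors)
        for t in targets
    )
    n, J = dataset.n_samples, len(dataset.regulator_ids)
    coef = np.zeros((n, len(targets), J))
    bandwidths = {}
    for l, (t, (b, rows)) in enumerate(zip(targets, results)):
        coef[:, l, :] = rows
        bandwidths[t] = b
    return NetworkStack(coef, list(dataset.sample_ids), targets,
                        list(dataset.regulator_ids), bandwidths, modulator_drug)
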