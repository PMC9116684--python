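"""Synthetic datasets matching the varying-coefficient generative model.

Each sample carries a continuous modulator value; regulator expression is
i.i.d. standard normal; target expression is the linear combination of
regulators with coefficients that are smooth functions of the modulator,
plus Gaussian noise.  Dependency scores for a planted gene subset track the
modulator so the correlation filter can recover them.  Full ground truth is
returned for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .core_io import (
    AlignedDataset,
    DependencyScreenMatrix,
    DrugSensitivityTable,
    GeneExpressionMatrix,
)
from .feature_builder import FeatureMatrix, classify_by_percentiles

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "simulate_labels",
    "simulate_feature_matrix",
    "PROFILES",
    "MODULATOR_DRUG",
]

PROFILES = ("constant", "increasing", "sensitive_only", "resistant_only")
MODULATOR_DRUG = "drug_mod"


@dataclass
class SimulationConfig:
    n_samples: int = 100
    n_regulators: int = 10
    n_targets: int = 3
    edge_density: float = 0.2
    noise_sd: float = 0.5
    n_crucial_edges: int = 0
    coefficient_profile: str | Sequence[str] = "constant"
    modulator_distribution: str = "normal"
    seed: int = 0
    dependency_strength: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_regulators, self.n_targets) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.modulator_distribution not in ("normal", "uniform"):
            raise ValueError(f"unknown modulator distribution: {self.modulator_distribution!r}")
        profiles = self._profile_list()
        for p in profiles:
            if p not in PROFILES:
                raise ValueError(f"unknown coefficient profile: {p!r}")
        n_edges = self.n_edges
        if self.n_crucial_edges < 0 or self.n_crucial_edges > n_edges:
            raise ValueError("n_crucial_edges must lie in [0, number of true edges]")

    def _profile_list(self) -> list[str]:
        if isinstance(self.coefficient_profile, str):
            return [self.coefficient_profile]
        return list(self.coefficient_profile)

    @property
    def n_edges(self) -> int:
        return max(1, round(self.edge_density * self.n_targets * self.n_regulators))


@dataclass
class GroundTruth:
    """True coefficient functions, planted edges and labels of a simulation."""

    modulator: np.ndarray
    modulator_grid: np.ndarray
    beta_functions: dict[tuple[int, int], np.ndarray]  # (l, j) -> values on grid
    beta_at_samples: np.ndarray  # n x L x J
    support: set[tuple[int, int]]
    crucial_edges: set[tuple[int, int]]
    true_labels: list[str]
    planted_dependency_genes: list[str]
    edge_profiles: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.crucial_edges <= self.support:
            raise ValueError("crucial edges must lie inside the sparse support")


def _profile_fn(profile: str, amplitude: float, m_stats: dict[str, float]) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth (logistic-ramp) coefficient functions of the modulator."""
    p10, p90 = m_stats["p10"], m_stats["p90"]
    med, sd = m_stats["median"], m_stats["sd"]
    tau = 0.15 * sd if sd > 0 else 0.15
    if profile == "constant":
        return lambda m: amplitude * np.ones_like(np.asarray(m, dtype=float))
    if profile == "increasing":
        return lambda m: amplitude * expit((np.asarray(m, dtype=float) - med) / (0.5 * sd if sd > 0 else 0.5))
    if profile == "sensitive_only":
        # full strength below P10, tapering smoothly to 0 above it
        return lambda m: amplitude * expit((p10 - np.asarray(m, dtype=float)) / tau)
    if profile == "resistant_only":
        return lambda m: amplitude * expit((np.asarray(m, dtype=float) - p90) / tau)
    raise ValueError(f"unknown profile: {profile!r}")


def simulate_dataset(config: SimulationConfig) -> tuple[AlignedDataset, GroundTruth]:
    """Generate an aligned dataset plus ground truth, deterministically.

    Gene ids are ``R0001..`` for regulators and ``T0001..`` for targets; the
    single drug column is :data:`MODULATOR_DRUG` holding the modulator.  The
    dependency matrix covers regulators and targets; the target genes are
    the planted modulator-correlated subset.
    """
    n, J, L = config.n_samples, config.n_regulators, config.n_targets
    root = np.random.default_rng(config.seed)
    rng_m, rng_x, rng_e, rng_edges, rng_dep = root.spawn(5)

    if config.modulator_distribution == "uniform":
        m = rng_m.uniform(-np.sqrt(3), np.sqrt(3), size=n)
    else:
        m = rng_m.standard_normal(n)
    m_stats = {
        "p10": float(np.percentile(m, 10)),
        "p90": float(np.percentile(m, 90)),
        "median": float(np.median(m)),
        "sd": float(m.std()),
    }

    X = rng_x.standard_normal((n, J))

    # sparse support and per-edge profiles/amplitudes
    all_pairs = [(l, j) for l in range(L) for j in range(J)]
    n_edges = config.n_edges
    chosen = rng_edges.choice(len(all_pairs), size=n_edges, replace=False)
    support = [all_pairs[i] for i in sorted(chosen)]
    profiles = config._profile_list()
    amplitudes = rng_edges.uniform(0.75, 1.5, size=n_edges) * rng_edges.choice([-1.0, 1.0], size=n_edges)

    grid = np.linspace(m.min(), m.max(), 101)
    beta_at_samples = np.zeros((n, L, J))
    beta_functions: dict[tuple[int, int], np.ndarray] = {}
    edge_profiles: dict[tuple[int, int], str] = {}
    # modulator-varying edges come first so crucial edges are label-driving
    varying = [p for p in PROFILES if p != "constant"]
    for k, (l, j) in enumerate(support):
        if config.n_crucial_edges and k < config.n_crucial_edges:
            prof = profiles[k % len(profiles)]
            if prof == "constant" and len(profiles) == 1:
                prof = "sensitive_only"
            elif prof == "constant":
                prof = next((p for p in profiles if p != "constant"), "sensitive_only")
            if prof not in varying:
                prof = "sensitive_only"
        else:
            prof = profiles[k % len(profiles)]
        fn = _profile_fn(prof, float(amplitudes[k]), m_stats)
        beta_at_samples[:, l, j] = fn(m)
        beta_functions[(l, j)] = fn(grid)
        edge_profiles[(l, j)] = prof

    noise = rng_e.standard_normal((n, L)) * config.noise_sd
    Y = np.einsum("nj,nlj->nl", X, beta_at_samples) + noise

    regulator_ids = [f"R{j + 1:04d}" for j in range(J)]
    target_ids = [f"T{l + 1:04d}" for l in range(L)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = regulator_ids + target_ids
    expr_values = np.vstack([X.T, Y.T])
    expression = GeneExpressionMatrix(expr_values, gene_ids, sample_ids)

    sensitivity = DrugSensitivityTable(m[:, None], sample_ids, [MODULATOR_DRUG])

    dep = rng_dep.standard_normal((len(gene_ids), n))
    planted = list(target_ids)
    for g in planted:
        dep[gene_ids.index(g)] += config.dependency_strength * m
    dependency = DependencyScreenMatrix(dep, gene_ids, sample_ids)

    dataset = AlignedDataset(expression, sensitivity, dependency, regulator_ids, target_ids)
    labels, _, _ = classify_by_percentiles(m) if n >= 10 else (["intermediate"] * n, 0.0, 0.0)
    truth = GroundTruth(
        modulator=m,
        modulator_grid=grid,
        beta_functions=beta_functions,
        beta_at_samples=beta_at_samples,
        support=set(support),
        crucial_edges=set(support[: config.n_crucial_edges]),
        true_labels=labels,
        planted_dependency_genes=planted,
        edge_profiles=edge_profiles,
    )
    return dataset, truth


def simulate_labels(modulator: np.ndarray, p_low: float = 10.0, p_high: float = 90.0) -> list[str]:
    """Percentile labels for a simulated modulator (same rule as real data)."""
    labels, _, _ = classify_by_percentiles(np.asarray(modulator, dtype=float), p_low, p_high)
    return labels


def simulate_feature_matrix(
    n_samples: int,
    n_edges: int,
    n_informative: int,
    effect: float = 1.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, list[tuple[str, str]]]:
    """A balanced binary feature matrix with planted label-driving columns.

    The first ``n_informative`` columns have a mean shift of ``effect``
    between the classes; the rest are pure noise.  Returns the matrix and
    the list of informative (target, regulator) column keys.
    """
    if n_informative > n_edges:
        raise ValueError("n_informative cannot exceed n_edges")
    rng = np.random.default_rng(seed)
    y = np.zeros(n_samples, dtype=int)
    y[: n_samples // 2] = 1
    perm = rng.permutation(n_samples)
    y = y[perm]
    values = rng.standard_normal((n_samples, n_edges)) * noise_sd
    informative_idx = rng.choice(n_edges, size=n_informative, replace=False)
    for i in informative_idx:
        values[:, i] += effect * y
    columns = [(f"T{k + 1:04d}", f"R{k + 1:04d}") for k in range(n_edges)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    fm = FeatureMatrix(values, sample_ids, columns, y)
    return fm, [columns[i] for i in sorted(informative_idx)]


def ground_truth_to_json(truth: GroundTruth, path: str | Path) -> None:
    """Serialize the ground truth to JSON (edges keyed ``"l,j"``)."""
    payload = {
        "modulator": truth.modulator.tolist(),
        "modulator_grid": truth.modulator_grid.tolist(),
        "beta_functions": {f"{l},{j}": v.tolist() for (l, j), v in truth.beta_functions.items()},
        "support": sorted(truth.support),
        "crucial_edges": sorted(truth.crucial_edges),
        "true_labels": truth.true_labels,
        "planted_dependency_genes": truth.planted_dependency_genes,
        "edge_profiles": {f"{l},{j}": p for (l, j), p in truth.edge_profiles.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))
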