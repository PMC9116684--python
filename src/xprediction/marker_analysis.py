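"""Set operations on network stacks and importance results.

Covers edges present in every sample's network, drug-drug similarity by
shared crucial edges, class-exclusive (sensitive / resistant) marker edges,
and a tabular export of regulatory effects for heatmap plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import Edge, EdgeList
from .feature_builder import RESISTANT, SENSITIVE, RegulatoryEffectTensor, SensitivityLabels
from .network_profiler import NetworkStack
from .xprediction_explain import CrucialEdgeSet

__all__ = [
    "DrugNetwork",
    "MarkerSet",
    "pan_cancer_edges",
    "drug_similarity_network",
    "sensitivity_specific_markers",
    "export_regulatory_effect_table",
]


@dataclass
class DrugNetwork:
    """Undirected drug-drug graph weighted by shared crucial-edge counts."""

    nodes: list[str]
    edges: list[tuple[str, str, int]]  # (drug_a, drug_b, n_common), a < b

    def __post_init__(self) -> None:
        clean = []
        for a, b, n in self.edges:
            if n < 1:
                raise ValueError("drug-network edges need at least one shared interaction")
            a, b = sorted((a, b))
            clean.append((a, b, int(n)))
        self.edges = sorted(set(clean))

    def weight(self, drug_a: str, drug_b: str) -> int:
        a, b = sorted((drug_a, drug_b))
        for x, y, n in self.edges:
            if (x, y) == (a, b):
                return n
        return 0


@dataclass
class MarkerSet:
    """Edges present only in sensitive or only in resistant samples."""

    drug: str
    sensitive_markers: list[tuple[str, str]]
    resistant_markers: list[tuple[str, str]]
    tol: float = 1e-12

    def __post_init__(self) -> None:
        overlap = set(self.sensitive_markers) & set(self.resistant_markers)
        if overlap:
            raise ValueError(f"markers in both classes: {sorted(overlap)}")
        self.sensitive_markers = sorted(set(self.sensitive_markers))
        self.resistant_markers = sorted(set(self.resistant_markers))


def pan_cancer_edges(stack: NetworkStack, tol: float = 1e-12) -> EdgeList:
    """Edges whose coefficient exceeds ``tol`` in magnitude in every sample.

    The reported weight is the minimum absolute coefficient across samples
    (the edge's weakest presence).
    """
    if stack.coefficients.shape[0] == 0:
        raise ValueError("empty network stack")
    absC = np.abs(stack.coefficients)
    present = (absC > tol).all(axis=0)  # L x J
    min_abs = absC.min(axis=0)
    edges = []
    for l, t in enumerate(stack.target_ids):
        for j, r in enumerate(stack.regulator_ids):
            if present[l, j]:
                edges.append(Edge(t, r, float(min_abs[l, j])))
    return EdgeList(edges)


def drug_similarity_network(crucial_sets: Mapping[str, CrucialEdgeSet]) -> DrugNetwork:
    """Connect two drugs iff their crucial edge sets intersect."""
    drugs = sorted(crucial_sets)
    if len(drugs) < 2:
        raise ValueError("need at least 2 drugs")
    pairs = {d: crucial_sets[d].pairs() for d in drugs}
    edges = []
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            n = len(pairs[a] & pairs[b])
            if n >= 1:
                edges.append((a, b, n))
    return DrugNetwork(drugs, edges)


def sensitivity_specific_markers(
    tensor: RegulatoryEffectTensor,
    labels: SensitivityLabels,
    edges: Sequence[tuple[str, str]] | None = None,
    tol: float = 1e-12,
    drug: str = "",
) -> MarkerSet:
    """Classify edges whose regulatory effect exists in only one class.

    An edge is a sensitive marker when |RE| > tol for at least one sensitive
    sample and |RE| <= tol for every resistant sample; resistant markers are
    symmetric.  Only sensitive/resistant samples participate.
    """
    sens = [s for s in labels.samples_with(SENSITIVE) if s in tensor.sample_ids]
    res = [s for s in labels.samples_with(RESISTANT) if s in tensor.sample_ids]
    if not sens or not res:
        raise ValueError("need at least one sensitive and one resistant sample")
    s_idx = [tensor.sample_ids.index(s) for s in sens]
    r_idx = [tensor.sample_ids.index(s) for s in res]
    if edges is None:
        edges = [(t, r) for t in tensor.target_ids for r in tensor.regulator_ids]
    sensitive_markers, resistant_markers = [], []
    for t_id, r_id in edges:
        l = tensor.target_ids.index(t_id)
        j = tensor.regulator_ids.index(r_id)
        col = np.abs(tensor.values[:, l, j])
        in_sens = bool((col[s_idx] > tol).any())
        in_res = bool((col[r_idx] > tol).any())
        if in_sens and not in_res:
            sensitive_markers.append((t_id, r_id))
        elif in_res and not in_sens:
            resistant_markers.append((t_id, r_id))
    return MarkerSet(drug or labels.response_drug, sensitive_markers, resistant_markers, tol)


def export_regulatory_effect_table(
    tensor: RegulatoryEffectTensor,
    labels: SensitivityLabels,
    edges: Sequence[tuple[str, str]],
    path: str | Path,
) -> None:
    """Samples x edges TSV of regulatory effects with a label column.

    One row per tensor sample, one column per requested edge (written as
    ``regulator>target``), suitable for external heatmap tools.
    """
    edges = [(str(t), str(r)) for t, r in edges]
    with open(path, "w") as fh:
        header = ["sample", "label"] + [f"{r}>{t}" for t, r in edges]
        fh.write("\t".join(header) + "\n")
        if not edges:
            return
        for i, s in enumerate(tensor.sample_ids):
            row = [s, labels.label_of(s)]
            for t_id, r_id in edges:
                l = tensor.target_ids.index(t_id)
                j = tensor.regulator_ids.index(r_id)
                row.append(repr(float(tensor.values[i, l, j])))
            fh.write("\t".join(row) + "\n")
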