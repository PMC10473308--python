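"""Scoring inferred networks against ground truth, plus network summaries.

Monte-Carlo benchmarking reports three rates pooled over replicates: TPR
(fraction of true directed edges declared), TNR (fraction of false ordered
pairs left undeclared), and the ground-truth rate (fraction of replicates
whose entire inferred adjacency equals the generating network). The
edge-set Jaccard similarity, per-subnetwork degree profiles, and directed
shortest-path distributions mirror the summaries used for comparing
inferred brain networks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .inference import CausalNetwork
from .simulate import GroundTruthNetwork

__all__ = [
    "EvaluationReport",
    "confusion_rates",
    "network_similarity",
    "degree_profiles",
    "shortest_path_distribution",
]


@dataclass
class EvaluationReport:
    """Pooled Monte-Carlo accuracy rates, all in percent."""

    tpr: float
    tnr: float
    ground_truth_rate: float
    per_edge_accuracy: dict[tuple[str, str], float]
    n_reps: int

    def __post_init__(self) -> None:
        for rate in (self.tpr, self.tnr, self.ground_truth_rate):
            if not 0.0 <= rate <= 100.0:
                raise ValueError("rates must lie in [0, 100]")


def confusion_rates(
    inferred: list[CausalNetwork], truth: GroundTruthNetwork
) -> EvaluationReport:
    """TPR / TNR / ground-truth rate of an ensemble of inferred networks.

    Per-edge accuracy is the detection rate for true edges and the rejection
    rate for false ordered pairs, enabling per-edge accuracy bars.
    """
    if not inferred:
        raise ValueError("need at least one inferred network")
    names = truth.names
    true_adj = truth.adjacency
    n = len(names)
    off_diag = ~np.eye(n, dtype=bool)
    n_true = int(true_adj.sum())
    n_false = int((off_diag & ~true_adj).sum())

    tp = 0
    tn = 0
    exact = 0
    correct = np.zeros((n, n), dtype=int)
    for net in inferred:
        if tuple(net.names) != tuple(names):
            raise ValueError("node-set mismatch between inferred network and truth")
        adj = net.adjacency
        tp += int((adj & true_adj).sum())
        tn += int((~adj & ~true_adj & off_diag).sum())
        correct += (adj == true_adj) & off_diag
        exact += int(np.array_equal(adj, true_adj))

    reps = len(inferred)
    per_edge = {
        (names[i], names[j]): 100.0 * correct[i, j] / reps
        for i in range(n)
        for j in range(n)
        if i != j
    }
    return EvaluationReport(
        tpr=100.0 * tp / (n_true * reps) if n_true else 100.0,
        tnr=100.0 * tn / (n_false * reps) if n_false else 100.0,
        ground_truth_rate=100.0 * exact / reps,
        per_edge_accuracy=per_edge,
        n_reps=reps,
    )


def network_similarity(a: CausalNetwork, b: CausalNetwork) -> float:
    """Edge-set Jaccard similarity |A ∩ B| / |A ∪ B| of two binary networks.

    Defined as 1 when both edge sets are empty (identical networks).
    """
    if tuple(a.names) != tuple(b.names):
        raise ValueError("networks are over different node sets")
    ea, eb = a.edges, b.edges
    union = ea | eb
    if not union:
        return 1.0
    return len(ea & eb) / len(union)


def degree_profiles(
    net: CausalNetwork, partition: dict[str, str]
) -> dict[str, dict[str, list[int]]]:
    """Per-subnetwork multisets of node in-degrees and out-degrees.

    In-degree counts edges into a node; out-degree counts edges out of it.
    ``partition`` maps every node to a subnetwork label.
    """
    missing = set(net.names) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover nodes {sorted(missing)}")
    in_deg = net.adjacency.sum(axis=0)
    out_deg = net.adjacency.sum(axis=1)
    profiles: dict[str, dict[str, list[int]]] = {}
    for i, name in enumerate(net.names):
        label = partition[name]
        entry = profiles.setdefault(label, {"in": [], "out": []})
        entry["in"].append(int(in_deg[i]))
        entry["out"].append(int(out_deg[i]))
    return profiles


def shortest_path_distribution(net: CausalNetwork) -> dict:
    """Directed shortest-path lengths over all ordered reachable pairs.

    Returns ``{"lengths": Counter, "unreachable": int}`` where the counter
    maps path length (>= 1) to the number of ordered pairs attaining it.
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.names)
    g.add_edges_from(net.edges)
    lengths: Counter = Counter()
    reachable = 0
    for _, targets in nx.all_pairs_shortest_path_length(g):
        for dist in targets.values():
            if dist >= 1:
                lengths[dist] += 1
                reachable += 1
    n = len(net.names)
    return {"lengths": lengths, "unreachable": n * (n - 1) - reachable}
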