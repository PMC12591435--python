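"""Network-recovery and clustering performance metrics.

All edge-level counts are over unordered off-diagonal pairs (the strict
upper triangle of symmetric, hollow adjacency matrices).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from numpy.typing import NDArray
from sklearn.metrics import normalized_mutual_info_score

__all__ = [
    "ConfusionCounts",
    "confusion",
    "scores",
    "average_clustering_coefficient",
    "cluster_labels",
    "nmi",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total_pairs(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_adj(adj: NDArray) -> NDArray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return adj


def confusion(adj_hat: NDArray, adj_true: NDArray) -> ConfusionCounts:
    """Edge confusion counts over upper-triangle pairs."""
    adj_hat = _check_adj(adj_hat)
    adj_true = _check_adj(adj_true)
    if adj_hat.shape != adj_true.shape:
        raise ValueError("shape mismatch between estimate and truth")
    iu = np.triu_indices(adj_hat.shape[0], 1)
    e_hat = adj_hat[iu].astype(bool)
    e_true = adj_true[iu].astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(e_hat & e_true)),
        fp=int(np.sum(e_hat & ~e_true)),
        fn=int(np.sum(~e_hat & e_true)),
        tn=int(np.sum(~e_hat & ~e_true)),
    )


def scores(counts: ConfusionCounts) -> dict[str, float]:
    """MCC, F1, FDR and TPR with explicit degenerate-case conventions.

    FDR = 0 when nothing is declared; F1 = 0 when there is nothing to
    recover and nothing declared; MCC = 0 when any confusion marginal is
    empty (the correlation is undefined there).
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    fdr = fp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    tpr = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return {"mcc": float(mcc), "f1": float(f1), "fdr": float(fdr), "tpr": float(tpr)}


def average_clustering_coefficient(adj: NDArray) -> float:
    """Mean local clustering coefficient; degree-<2 nodes contribute 0."""
    adj = _check_adj(adj)
    return float(nx.average_clustering(nx.from_numpy_array(adj)))


def cluster_labels(adj: NDArray, method: str = "modularity") -> NDArray[np.int_]:
    """Node partition of a graph: connected components or greedy modularity.

    Modularity (default) is robust to the occasional spurious bridge edge
    that would merge otherwise separate components.
    """
    adj = _check_adj(adj)
    g = nx.from_numpy_array(adj)
    p = adj.shape[0]
    labels = np.empty(p, dtype=int)
    if method == "components":
        groups = nx.connected_components(g)
    elif method == "modularity":
        if g.number_of_edges() == 0:
            groups = ({v} for v in g.nodes)
        else:
            groups = nx.community.greedy_modularity_communities(g)
    else:
        raise ValueError(f"method must be 'components' or 'modularity', got {method!r}")
    for lab, nodes in enumerate(groups):
        labels[list(nodes)] = lab
    return labels


def nmi(labels_a: NDArray, labels_b: NDArray) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return float(normalized_mutual_info_score(labels_a, labels_b,
                                              average_method="arithmetic"))
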