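"""Ground-truth network generators and Gaussian data simulation.

Two network topologies (scale-free attachment trees and five disconnected
Erdos-Renyi clusters) crossed with two partial-correlation weighting
schemes:

* ``fixed``  -- every edge carries the same raw weight v; the diagonal is
  inflated past the most negative eigenvalue so the matrix is positive
  definite. Emulates generators that set all partial correlations to a
  common p-dependent value.
* ``random`` -- the precision matrix is drawn from a G-Wishart(b=3, I)
  distribution restricted to the graph, via the upper-Cholesky
  construction: free diagonal entries are chi distributed, free edge
  entries standard normal, and non-edge entries completed so the precision
  has exact zeros off the support. Emulates generators that sample partial
  correlations freely on (-1, 1), yielding a mix of strong and nearly
  invisible edges. The construction is exact for forests (trees with a
  perfect elimination ordering); for the cyclic cluster graphs, where the
  completion is numerically unstable, random edge weights uniform on
  (-1, 1) with a strictly diagonally dominant diagonal are used instead.

In both schemes the covariance is rescaled to unit diagonal (a correlation
matrix), so downstream standardization assumptions hold, and the precision
support equals the adjacency exactly.

Also provides the rank-based nonparanormal transform used to Gaussianize
real data before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numpy.typing import NDArray
from scipy import linalg, stats

__all__ = [
    "TrueNetwork",
    "generate_scale_free",
    "generate_cluster",
    "sample_mvn",
    "nonparanormal_transform",
    "CLUSTER_DENSITY_FIXED",
    "CLUSTER_DENSITY_RANDOM",
]

Matrix = NDArray[np.float64]

# Within-cluster edge probabilities, calibrated so the mean clustering
# coefficient of the true five-cluster networks at p=100 is ~0.303 (fixed
# weights) and ~0.195 (random weights).
CLUSTER_DENSITY_FIXED = 0.305
CLUSTER_DENSITY_RANDOM = 0.206


@dataclass
class TrueNetwork:
    adjacency: NDArray[np.int_]
    omega_true: Matrix
    sigma_true: Matrix
    cluster_labels: NDArray[np.int_] | None
    generator: dict


def _elimination_ordering(adj: NDArray[np.int_]) -> NDArray[np.int_]:
    """Children-before-parents ordering per connected component.

    For a forest this is a perfect elimination ordering (each vertex has at
    most one later neighbor, its parent), which makes the G-Wishart
    Cholesky construction exact; for other graphs it is only a heuristic.
    """
    g = nx.from_numpy_array(adj)
    order: list[int] = []
    for comp in nx.connected_components(g):
        root = min(comp)
        bfs = [root] + [v for _, v in nx.bfs_edges(g, root)]
        order.extend(reversed(bfs))
    return np.asarray(order)


def _gwishart_precision(adj: NDArray[np.int_], rng: np.random.Generator,
                        b: float = 3.0) -> Matrix:
    """Draw a precision matrix with support ``adj`` from G-Wishart(b, I).

    Upper-Cholesky construction K = Psi' Psi in a perfect elimination
    ordering: psi_ii^2 ~ chi2(b + #later neighbors), edge entries psi_ij ~
    N(0, 1), and non-edge entries completed as
    psi_ij = -(sum_k<i psi_ki psi_kj) / psi_ii, which forces K_ij = 0
    exactly off the support.
    """
    p = adj.shape[0]
    order = _elimination_ordering(adj)
    A = adj[np.ix_(order, order)]
    psi = np.zeros((p, p))
    for i in range(p):
        later = np.flatnonzero(A[i, i + 1:])
        psi[i, i] = np.sqrt(rng.chisquare(b + len(later)))
        for j in range(i + 1, p):
            if A[i, j]:
                psi[i, j] = rng.standard_normal()
            elif i > 0:
                psi[i, j] = -(psi[:i, i] @ psi[:i, j]) / psi[i, i]
    K = psi.T @ psi
    inv_order = np.argsort(order)
    K = K[np.ix_(inv_order, inv_order)]
    K[(adj == 0) & ~np.eye(p, dtype=bool)] = 0.0  # clear completion round-off
    return (K + K.T) / 2.0


def _weights_to_matrices(
    adj: NDArray[np.int_],
    weights: str,
    rng: np.random.Generator,
    v: float = 0.3,
    u: float = 0.1,
) -> tuple[Matrix, Matrix]:
    """Turn an adjacency pattern into (omega_true, sigma_true).

    The raw precision is built per the weighting scheme, inverted, and the
    inverse rescaled to a correlation matrix; omega_true is the inverse of
    that correlation matrix, which preserves the support pattern exactly
    (the rescaling is a congruence by a positive diagonal matrix).
    """
    p = adj.shape[0]
    if weights == "fixed":
        raw = v * adj.astype(float)
        lam_min = linalg.eigvalsh(raw, check_finite=False)[0]
        raw[np.diag_indices(p)] = abs(lam_min) + 0.1 + u
    elif weights == "random":
        n_edges = int(adj.sum()) // 2
        n_comps = nx.number_connected_components(nx.from_numpy_array(adj))
        if n_edges == p - n_comps:  # forest: exact G-Wishart draw
            raw = _gwishart_precision(adj, rng)
        else:
            w = rng.uniform(-1.0, 1.0, size=(p, p))
            w = np.triu(w, 1)
            raw = (w + w.T) * adj
            raw[np.diag_indices(p)] = np.abs(raw).sum(axis=1) + 0.1
    else:
        raise ValueError(f"weights must be 'fixed' or 'random', got {weights!r}")
    sigma_raw = linalg.inv(raw, check_finite=False)
    d = np.sqrt(np.diag(sigma_raw))
    sigma = sigma_raw / np.outer(d, d)
    sigma = (sigma + sigma.T) / 2.0
    # inv(sigma) = diag(d) @ raw @ diag(d): support preserved exactly
    omega = raw * np.outer(d, d)
    omega = (omega + omega.T) / 2.0
    return omega, sigma


def generate_scale_free(p: int, weights: str = "fixed", seed: int = 0) -> TrueNetwork:
    """Preferential-attachment tree (one edge per new node, p-1 edges)."""
    if p < 3:
        raise ValueError("need p >= 3")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(p, 1, seed=int(rng.integers(2**31 - 1)))
    adj = nx.to_numpy_array(g, dtype=int)
    omega, sigma = _weights_to_matrices(adj, weights, rng)
    return TrueNetwork(
        adjacency=adj,
        omega_true=omega,
        sigma_true=sigma,
        cluster_labels=None,
        generator={"structure": "scale_free", "weights": weights, "p": p, "seed": seed},
    )


def generate_cluster(
    p: int,
    n_clusters: int = 5,
    weights: str = "fixed",
    density: float | None = None,
    seed: int = 0,
) -> TrueNetwork:
    """Five (by default) disconnected Erdos-Renyi clusters of near-equal size.

    No edges cross cluster boundaries, so the true graph has exactly
    ``n_clusters`` connected components (up to isolated vertices inside
    sparse clusters). Default densities are calibrated per weighting scheme
    to the reference clustering-coefficient levels.
    """
    if density is None:
        density = CLUSTER_DENSITY_FIXED if weights == "fixed" else CLUSTER_DENSITY_RANDOM
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")
    rng = np.random.default_rng(seed)
    sizes = [p // n_clusters + (1 if i < p % n_clusters else 0) for i in range(n_clusters)]
    labels = np.repeat(np.arange(n_clusters), sizes)
    adj = np.zeros((p, p), dtype=int)
    start = 0
    for s in sizes:
        block = (rng.random((s, s)) < density).astype(int)
        block = np.triu(block, 1)
        block = block + block.T
        adj[start : start + s, start : start + s] = block
        start += s
    omega, sigma = _weights_to_matrices(adj, weights, rng)
    return TrueNetwork(
        adjacency=adj,
        omega_true=omega,
        sigma_true=sigma,
        cluster_labels=labels,
        generator={
            "structure": "cluster",
            "weights": weights,
            "p": p,
            "n_clusters": n_clusters,
            "density": density,
            "seed": seed,
        },
    )


def sample_mvn(net: TrueNetwork, n: int, seed: int = 0) -> Matrix:
    """Draw n i.i.d. zero-mean Gaussian samples with covariance sigma_true."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = linalg.cholesky(net.sigma_true, lower=True, check_finite=False)
    return rng.standard_normal((n, net.sigma_true.shape[0])) @ L.T


def nonparanormal_transform(Y: Matrix) -> Matrix:
    """Rank-based Gaussianization (shrunken-ECDF variant).

    Per column: ranks are converted to a truncated empirical CDF (clipped
    at delta_n = 1 / (4 n^{1/4} sqrt(pi log n)) from both ends), mapped
    through standard-normal quantiles, and rescaled to unit variance.
    Monotone within each column, so rank order is preserved.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    for j in range(p):
        if len(np.unique(Y[:, j])) < 3:
            warnings.warn(f"column {j} has fewer than 3 distinct values; "
                          "rank-based transform is unreliable")
    delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
    ranks = stats.rankdata(Y, axis=0, method="average")
    ecdf = np.clip(ranks / n, delta, 1.0 - delta)
    X = stats.norm.ppf(ecdf)
    return X / X.std(axis=0)
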