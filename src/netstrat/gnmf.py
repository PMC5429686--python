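"""Graph-regularized nonnegative matrix factorization (GNMF).

Factorizes a nonnegative data matrix A (genes x patients) as A ~ U V^T with
U (genes x k) and V (patients x k) nonnegative, minimizing

    || A - U V^T ||_F^2  +  lambda * Tr(V^T L V),

where L = D - S is the unnormalized Laplacian of a patient affinity graph S.
The Laplacian term pulls the low-dimensional representations (rows of V) of
neighboring patients together, so cluster structure respects the geometry of
the smoothed profiles. Optimization uses the standard multiplicative
updates, which keep the factors nonnegative and never increase the
objective:

    U <- U * (A V) / (U V^T V)
    V <- V * (A^T U + lambda S V) / (V U^T U + lambda D V)

Cluster labels are the argmax over each patient's row of V.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError, DataError

__all__ = ["GNMFConfig", "GNMFResult", "AffinityGraph", "build_affinity",
           "gnmf_factorize", "assign_clusters"]

_EPS = 1e-12  # denominator floor; does not move fixed points


@dataclass(frozen=True)
class GNMFConfig:
    k: int = 3
    lam: float = 150.0
    knn_p: int = 5
    max_updates: int = 500
    objective_tol: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if self.lam < 0:
            raise ConfigurationError("lambda must be >= 0")
        if self.knn_p < 1:
            raise ConfigurationError("knn_p must be >= 1")


@dataclass
class AffinityGraph:
    """0/1 kNN affinity over patients with its degree matrix and Laplacian."""

    adjacency: np.ndarray

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.degrees) - self.adjacency


@dataclass
class GNMFResult:
    U: np.ndarray
    V: np.ndarray
    objective_trace: list[float]
    labels: np.ndarray  # 1-based cluster index per patient

    @property
    def k(self) -> int:
        return self.V.shape[1]


def build_affinity(A: np.ndarray, knn_p: int = 5) -> AffinityGraph:
    """Symmetrized k-nearest-neighbor graph over the columns (patients) of A.

    Each patient links to every patient whose Euclidean distance is at most
    its knn_p-th smallest (ties included, so identical columns link to all),
    and the graph is symmetrized by union.
    """
    n = A.shape[1]
    if n < knn_p + 1:
        raise ConfigurationError(f"need at least knn_p+1={knn_p + 1} patients, have {n}")
    G = A.T @ A
    sq = np.diag(G)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * G, 0.0)
    np.fill_diagonal(d2, np.inf)
    kth = np.partition(d2, knn_p - 1, axis=1)[:, knn_p - 1]
    adj = (d2 <= kth[:, None] + 1e-12).astype(float)
    adj = np.maximum(adj, adj.T)  # union symmetrization
    np.fill_diagonal(adj, 0.0)
    return AffinityGraph(adjacency=adj)


def _objective(A, U, V, lam, L) -> float:
    resid = A - U @ V.T
    obj = float(np.sum(resid * resid))
    if lam > 0:
        obj += lam * float(np.trace(V.T @ L @ V))
    return obj


def gnmf_factorize(A: np.ndarray, graph: AffinityGraph,
                   config: GNMFConfig = GNMFConfig()) -> GNMFResult:
    """Run multiplicative updates from a seeded uniform(0,1) initialization.

    Stops when the relative objective change drops below
    ``config.objective_tol`` or after ``config.max_updates`` sweeps.
    Deterministic given config and seed.
    """
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise DataError("GNMF input matrix has negative entries")
    n_genes, n_patients = A.shape
    if graph.adjacency.shape != (n_patients, n_patients):
        raise ConfigurationError("affinity graph size does not match patient count")
    rng = np.random.default_rng(config.seed)
    k, lam = config.k, config.lam
    U = rng.random((n_genes, k))
    V = rng.random((n_patients, k))
    S = graph.adjacency
    D = graph.degrees
    L = graph.laplacian

    trace = [_objective(A, U, V, lam, L)]
    for _ in range(config.max_updates):
        U *= (A @ V) / np.maximum(U @ (V.T @ V), _EPS)
        num = A.T @ U
        den = V @ (U.T @ U)
        if lam > 0:
            num = num + lam * (S @ V)
            den = den + lam * (D[:, None] * V)
        V *= num / np.maximum(den, _EPS)
        obj = _objective(A, U, V, lam, L)
        prev = trace[-1]
        trace.append(obj)
        if prev > 0 and abs(prev - obj) / prev < config.objective_tol:
            break
    return GNMFResult(U=U, V=V, objective_trace=trace, labels=assign_clusters(V))


def assign_clusters(V: np.ndarray) -> np.ndarray:
    """1-based argmax cluster per row of V; ties and all-zero rows go to cluster 1."""
    V = np.asarray(V)
    if V.ndim != 2 or V.shape[1] < 1:
        raise DataError("V must be a 2-D matrix with at least one column")
    if (V < 0).any():
        raise DataError("V must be nonnegative")
    zero_rows = ~V.any(axis=1)
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} all-zero rows assigned to cluster 1")
    return V.argmax(axis=1) + 1
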