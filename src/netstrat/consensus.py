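"""Consensus clustering, cophenetic model selection, silhouette core samples.

Because the factorization is initialized at random, a single run's labels
are not trustworthy. The consensus matrix records, for every patient pair,
the fraction of random restarts that co-cluster them; final labels come from
cutting the average-linkage dendrogram of the consensus distance
(1 - consensus) at k, so they are a deterministic function of the consensus
matrix. The cophenetic correlation between that dendrogram's distances and
the consensus distances measures the stability of each k; the k with the
largest coefficient is kept (ties to the smaller k). Silhouette widths on
the consensus distance flag patients with strong subtype membership; the
core set keeps those with width strictly above the threshold (default 0.20).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .errors import ConfigurationError, DataError
from .gnmf import AffinityGraph, GNMFConfig, GNMFResult, gnmf_factorize

__all__ = ["ConsensusResult", "SilhouetteReport", "consensus_cluster",
           "cophenetic_coefficient", "select_k", "silhouette_widths"]


@dataclass
class ConsensusResult:
    k: int
    consensus: np.ndarray
    labels: np.ndarray  # 1-based
    cophenetic: float
    n_runs: int


@dataclass
class SilhouetteReport:
    widths: np.ndarray
    core_mask: np.ndarray
    threshold: float

    @property
    def core_indices(self) -> np.ndarray:
        return np.flatnonzero(self.core_mask)


def _consensus_linkage(consensus: np.ndarray):
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    # average linkage on the condensed consensus distance
    return sch.linkage(squareform(D, checks=False), method="average"), D


def _cut_labels(consensus: np.ndarray, k: int) -> np.ndarray:
    Z, _ = _consensus_linkage(consensus)
    return sch.fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(A: np.ndarray, graph: AffinityGraph, k_range=range(2, 10),
                      n_runs: int = 100, base_seed: int = 0,
                      config: GNMFConfig = GNMFConfig()) -> dict[int, ConsensusResult]:
    """Per-k consensus over ``n_runs`` random GNMF initializations.

    Run ``r`` of a given k uses seed ``base_seed + r``. A run that raises is
    retried once with a shifted seed and then excluded; more than 10%
    exclusions abort.
    """
    if n_runs < 2:
        raise ConfigurationError("n_runs must be >= 2")
    n_patients = A.shape[1]
    results: dict[int, ConsensusResult] = {}
    for k in k_range:
        counts = np.zeros((n_patients, n_patients))
        used = 0
        for run in range(n_runs):
            res = _one_run(A, graph, config, k, base_seed + run)
            if res is None:
                res = _one_run(A, graph, config, k, base_seed + n_runs + run)
            if res is None:
                warnings.warn(f"k={k}: run {run} excluded after retry")
                continue
            same = res.labels[:, None] == res.labels[None, :]
            counts += same
            used += 1
        if used < 0.9 * n_runs:
            raise DataError(f"k={k}: more than 10% of consensus runs failed")
        consensus = counts / used
        np.fill_diagonal(consensus, 1.0)
        labels = _cut_labels(consensus, k)
        coph, _ = cophenetic_coefficient(consensus, return_flag=True)
        results[k] = ConsensusResult(k=k, consensus=consensus, labels=labels,
                                     cophenetic=coph, n_runs=used)
    return results


def _one_run(A, graph, config: GNMFConfig, k: int, seed: int) -> GNMFResult | None:
    try:
        cfg = GNMFConfig(k=k, lam=config.lam, knn_p=config.knn_p,
                         max_updates=config.max_updates,
                         objective_tol=config.objective_tol, seed=seed)
        return gnmf_factorize(A, graph, cfg)
    except Exception:
        return None


def cophenetic_coefficient(consensus: np.ndarray, return_flag: bool = False):
    """Correlation between consensus distances and dendrogram cophenetic distances.

    A constant off-diagonal distance makes the correlation undefined; the
    dendrogram then reproduces the distances exactly, so 1.0 is returned
    with the degenerate flag set.
    """
    n = consensus.shape[0]
    if n < 3:
        raise ConfigurationError("need at least 3 patients")
    Z, D = _consensus_linkage(consensus)
    d_obs = squareform(D, checks=False)
    d_coph = sch.cophenet(Z)
    degenerate = np.ptp(d_obs) == 0 or np.ptp(d_coph) == 0
    if degenerate:
        # all merges at one height: distances reproduced exactly
        coef = 1.0 if np.allclose(d_obs, d_coph) else 0.0
    elif np.array_equal(d_obs, d_coph):
        coef = 1.0  # dendrogram reproduces the distances perfectly
    else:
        coef = float(pearsonr(d_obs, d_coph).statistic)
    return (coef, degenerate) if return_flag else coef


def select_k(results: dict[int, ConsensusResult]):
    """k with the largest cophenetic coefficient; ties go to the smaller k.

    Returns ``(k_star, table)`` with the full (k, coefficient) table for
    reporting.
    """
    if len(results) < 2:
        raise ConfigurationError("need at least two candidate k values")
    table = {k: results[k].cophenetic for k in sorted(results)}
    k_star = max(table, key=lambda k: (table[k], -k))
    return k_star, table


def silhouette_widths(consensus: np.ndarray, labels, threshold: float = 0.20) -> SilhouetteReport:
    """Silhouette on the consensus distance d = 1 - consensus.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    the rest of i's cluster and b(i) the smallest mean distance to another
    cluster; members of singleton clusters get s = 0. Core samples have
    width strictly greater than ``threshold``.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DataError("silhouette undefined for a single cluster")
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    n = D.shape[0]
    widths = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            widths[i] = 0.0
            continue
        a = D[i, own].sum() / (own.sum() - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return SilhouetteReport(widths=widths, core_mask=widths > threshold, threshold=threshold)
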