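"""Random walk with restart over the interaction network.

Each patient's sparse binary mutation vector seeds a restarting random walk,

    p[t+1] = (1 - r) W p[t] + r p[0],

with W the column-normalized adjacency and r the restart probability. The
steady state p[inf] spreads each mutation's influence into its network
neighborhood, so patients mutated in different but interacting genes end up
with similar smoothed profiles. Iteration stops when the L1 change between
successive vectors falls below the tolerance (default 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, ConvergenceError, DataError
from .mutation_io import MutationMatrix
from .ppi import PPINetwork

__all__ = ["PropagationConfig", "SmoothedMatrix", "seed_vector", "rwr_steady_state",
           "smooth_cohort"]

# above this node count the iteration uses sparse matrix products
_DENSE_LIMIT = 5000


@dataclass(frozen=True)
class PropagationConfig:
    restart_prob: float = 0.75
    tolerance: float = 1e-6
    max_iterations: int = 10000
    strict: bool = False  # error (rather than drop) patients with no in-network mutation

    def __post_init__(self):
        if not (0.0 <= self.restart_prob <= 1.0):
            raise ConfigurationError("restart_prob must lie in [0, 1]")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")


@dataclass
class SmoothedMatrix:
    """Steady-state propagation scores, patients x network genes."""

    patients: list[str]
    genes: list[str]
    values: np.ndarray
    iterations: list[int] | None = None
    dropped_patients: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.genes)


def seed_vector(patient_row: np.ndarray, gene_names, network: PPINetwork) -> np.ndarray:
    """Uniform distribution over the patient's mutated in-network genes.

    Raises :class:`DataError` when no mutated gene maps to the network (the
    cohort driver decides whether that is fatal or a drop).
    """
    idx = network.node_index()
    p0 = np.zeros(network.n_nodes)
    hits = [idx[g] for g, v in zip(gene_names, patient_row) if v and g in idx]
    if not hits:
        raise DataError("patient has no mutated gene in the network")
    p0[hits] = 1.0 / len(hits)
    return p0


def rwr_steady_state(p0: np.ndarray, W, config: PropagationConfig = PropagationConfig()):
    """Iterate the restart recurrence from p0 until the L1 change < tolerance.

    Returns ``(p_inf, n_iterations)``. With r = 1 the map is the identity on
    p0 and returns after a single step.
    """
    P, n_it = _iterate(p0[None, :], W, config)
    return P[0], n_it


def _iterate(P0: np.ndarray, W, config: PropagationConfig):
    """Batched iteration: each row of P0 is one walk. Returns (P_inf, iters)."""
    r = config.restart_prob
    if sp.issparse(W):
        Wt = W.T.tocsr() if W.shape[0] > _DENSE_LIMIT else np.asarray(W.todense()).T
    else:
        Wt = np.asarray(W).T
    P = P0.copy()
    for t in range(1, config.max_iterations + 1):
        P_next = (1.0 - r) * (P @ Wt) + r * P0
        delta = np.abs(P_next - P).sum(axis=1).max()
        P = P_next
        if delta < config.tolerance:
            return P, t
    raise ConvergenceError(
        f"no convergence after {config.max_iterations} iterations (residual {delta:.3e})",
        residual=float(delta))


def smooth_cohort(matrix: MutationMatrix, network: PPINetwork,
                  config: PropagationConfig = PropagationConfig()) -> SmoothedMatrix:
    """Steady-state smoothed profile for every patient with an in-network mutation.

    Patients whose entire mutated set lies outside the network have no
    defined seed distribution; they are dropped with a record (or raise,
    under ``config.strict``).
    """
    idx = network.node_index()
    col_map = np.array([idx.get(g, -1) for g in matrix.genes])
    kept_rows, dropped = [], []
    P0 = []
    for i, patient in enumerate(matrix.patients):
        row = matrix.values[i]
        hits = col_map[(row > 0) & (col_map >= 0)]
        if hits.size == 0:
            if config.strict:
                raise DataError(f"patient {patient} has no mutated gene in the network")
            dropped.append(patient)
            continue
        p0 = np.zeros(network.n_nodes)
        p0[hits] = 1.0 / hits.size
        P0.append(p0)
        kept_rows.append(patient)
    if not P0:
        raise DataError("no patient has an in-network mutation")
    W = network.normalized_adjacency()
    P_inf, n_it = _iterate(np.asarray(P0), W, config)
    return SmoothedMatrix(patients=kept_rows, genes=list(network.nodes), values=P_inf,
                          iterations=[n_it] * len(kept_rows), dropped_patients=dropped)
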