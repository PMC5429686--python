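"""Scored protein-protein interaction networks.

Loads STRING-style edge lists, applies the high-confidence score threshold
(strictly greater than 0.7 by default, on the 0-1 scale), and exposes the
column-normalized adjacency matrix W used by the random-walk propagation:
W[i, j] = A[i, j] / sum_i A[i, j], so each non-isolated column of W sums to 1
and repeated multiplication conserves probability mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DataError, FormatError

__all__ = ["PPINetwork", "read_string_edges", "column_normalize", "intersect_with_network"]


@dataclass
class PPINetwork:
    """Undirected scored gene graph with cached adjacency matrices.

    Parameters
    ----------
    graph:
        Undirected simple :class:`networkx.Graph`; every edge carries a
        ``score`` attribute in (0, 1].
    score_threshold:
        The confidence threshold the retained edges survived (metadata).
    """

    graph: nx.Graph
    score_threshold: float = 0.7
    _nodes: list[str] = field(init=False, repr=False)

    def __post_init__(self):
        self._nodes = sorted(self.graph.nodes)

    @property
    def nodes(self) -> list[str]:
        """Node gene symbols in a fixed (sorted) order."""
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self._nodes)}

    def adjacency(self, binarize: bool = False) -> sp.csr_matrix:
        """Symmetric weighted adjacency in :attr:`nodes` order."""
        A = nx.to_scipy_sparse_array(self.graph, nodelist=self._nodes, weight="score", format="csr")
        if binarize:
            A = (A > 0).astype(float)
        return sp.csr_matrix(A)

    def normalized_adjacency(self, binarize: bool = False) -> sp.csr_matrix:
        """Column-normalized adjacency W (isolated-node columns stay zero)."""
        return column_normalize(self.adjacency(binarize=binarize))

    def summary(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_components": nx.number_connected_components(self.graph),
            "score_threshold": self.score_threshold,
        }


def read_string_edges(path, score_threshold: float = 0.7, binarize: bool = False) -> PPINetwork:
    """Load a 3-column scored edge list and keep edges with score strictly above threshold.

    Scores on the STRING 0-1000 integer convention (any value > 1 in the file)
    are divided by 1000 before thresholding. Duplicate and reversed pairs are
    merged keeping the maximum score; self-loops are dropped.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty edge list: {path}")
    if df.shape[1] < 3:
        raise FormatError(f"expected 3 columns (gene_a, gene_b, score) in {path}")
    df = df.iloc[:, :3]
    df.columns = ["gene_a", "gene_b", "score"]
    # optional header row: detect a non-numeric score in the first line
    first = df.iloc[0]["score"]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        line = int(scores.isna().idxmax()) + 1
        raise FormatError(f"non-numeric score at data line {line} of {path}")
    df["score"] = scores.astype(float)
    if (df["score"] > 1).any():
        df["score"] = df["score"] / 1000.0
    df = df[df["gene_a"].astype(str) != df["gene_b"].astype(str)]
    df = df[df["score"] > score_threshold]
    if df.empty:
        raise DataError(f"no edges survive score > {score_threshold} in {path}")
    g = nx.Graph()
    for a, b, s in df.itertuples(index=False):
        a, b = str(a), str(b)
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], s)
        else:
            g.add_edge(a, b, score=1.0 if binarize else s)
    return PPINetwork(graph=g, score_threshold=score_threshold)


def column_normalize(adjacency) -> sp.csr_matrix:
    """Divide every column by its sum; all-zero columns are left untouched.

    Accepts a dense array or sparse matrix; returns CSR. Raises
    :class:`DataError` on negative entries.
    """
    A = sp.csr_matrix(adjacency, dtype=float)
    if (A.data < 0).any():
        raise DataError("adjacency has negative entries")
    colsum = np.asarray(A.sum(axis=0)).ravel()
    scale = np.ones_like(colsum)
    nz = colsum > 0
    scale[nz] = 1.0 / colsum[nz]
    return sp.csr_matrix(A @ sp.diags(scale))


def intersect_with_network(matrix, network: PPINetwork):
    """Restrict a mutation matrix to genes present in the network.

    Returns ``(restricted_matrix, report)`` where the report lists dropped
    genes and flags patients whose entire mutated gene set fell outside the
    network (they have no propagation seed).
    """
    node_set = set(network.nodes)
    kept = [g for g in matrix.genes if g in node_set]
    dropped = [g for g in matrix.genes if g not in node_set]
    restricted = matrix.restrict_genes(kept)
    burdens = restricted.values.sum(axis=1)
    flagged = [p for p, b in zip(restricted.patients, burdens) if b == 0]
    report = {
        "n_dropped_genes": len(dropped),
        "dropped_genes": dropped,
        "patients_without_network_mutations": flagged,
    }
    return restricted, report
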