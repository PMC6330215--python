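"""Cognitive-system summaries of subgraphs.

A subgraph (one basis column folded back to an N x N symmetric matrix V)
is coarse-grained over an a-priori partition of the N nodes into labeled
systems: within-system connectivity

    R_s = sum_{i,j in P_s} V_ij / |P_s|^2

(both edge orientations counted; the zero diagonal contributes nothing,
so a complete system of size n saturates at 1 - 1/n), and between-system
connectivity

    I_st = sum_{i in P_s, j in P_t} V_ij / (|P_s| |P_t|).

Locality is measured by the skewness of the off-diagonal entries of the
system matrix, and per-system importance by a label-permutation test on
the column sums of the full symmetric system matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SystemPartition", "SystemMatrix", "fold_subgraph",
           "system_matrix", "locality_skewness", "significant_systems"]


@dataclass
class SystemPartition:
    """Node-to-system assignment with a fixed system order."""

    labels: list                      # ordered system names
    node_to_system: np.ndarray        # (N,) int index into labels

    def __post_init__(self):
        self.node_to_system = np.asarray(self.node_to_system, dtype=int)
        if self.node_to_system.min(initial=0) < 0 or (
                self.node_to_system.max(initial=-1) >= len(self.labels)):
            raise ValueError("node system index out of range")
        if np.any(self.sizes < 1):
            raise ValueError("every system must contain at least one node")

    @property
    def n_nodes(self) -> int:
        return self.node_to_system.size

    @property
    def n_systems(self) -> int:
        return len(self.labels)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.node_to_system, minlength=len(self.labels))

    def indicator(self) -> np.ndarray:
        """(N, m) one-hot system membership matrix."""
        B = np.zeros((self.n_nodes, self.n_systems))
        B[np.arange(self.n_nodes), self.node_to_system] = 1.0
        return B

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "SystemPartition":
        """From a (node_id, system) table; system order is first appearance."""
        df = df.sort_values("node_id") if "node_id" in df else df
        labels = list(pd.unique(df["system"]))
        idx = {lab: i for i, lab in enumerate(labels)}
        return cls(labels=labels,
                   node_to_system=df["system"].map(idx).to_numpy())

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node_id": np.arange(self.n_nodes),
            "system": [self.labels[i] for i in self.node_to_system],
        })


@dataclass
class SystemMatrix:
    """m x m symmetric summary: diagonal R_s, off-diagonal I_st."""

    values: np.ndarray
    labels: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def fold_subgraph(w_column: np.ndarray, n_nodes: int | None = None) -> np.ndarray:
    """Fold an E-vector back to the N x N symmetric zero-diagonal matrix.

    Rows follow the fixed lexicographic (i < j) edge order.
    """
    w = np.asarray(w_column, dtype=float).ravel()
    E = w.size
    if n_nodes is None:
        n_nodes = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
    if n_nodes * (n_nodes - 1) // 2 != E:
        raise ValueError(f"length {E} is not a triangular number")
    V = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    V[iu] = w
    V[(iu[1], iu[0])] = w
    return V


def system_matrix(V: np.ndarray, partition: SystemPartition) -> SystemMatrix:
    """Within/between-system connectivity summary of one subgraph."""
    V = np.asarray(V, dtype=float)
    n = partition.n_nodes
    if V.shape != (n, n):
        raise ValueError(f"V has shape {V.shape}; partition labels {n} nodes")
    if not np.allclose(V, V.T):
        raise ValueError("V must be symmetric")
    B = partition.indicator()
    sums = B.T @ V @ B
    sizes = partition.sizes.astype(float)
    return SystemMatrix(values=sums / np.outer(sizes, sizes),
                        labels=list(partition.labels))


def locality_skewness(M: SystemMatrix) -> float:
    """Sample skewness of the off-diagonal upper-triangle system entries.

    High skewness marks a localized subgraph (a few dominant system pairs);
    low skewness marks a distributed one.  Zero-variance input returns 0.
    """
    vals = M.values[np.triu_indices(M.values.shape[0], k=1)]
    if vals.size < 3:
        raise ValueError("need at least 3 systems")
    if np.ptp(vals) == 0 or np.std(vals) == 0:
        return 0.0
    return float(stats.skew(vals, bias=True))


def significant_systems(V: np.ndarray, partition: SystemPartition,
                        n_perm: int = 1000, alpha: float = 0.05,
                        seed: int | None = None) -> pd.DataFrame:
    """Label-permutation test of per-system expression in a subgraph.

    The statistic for system s is the column sum of the full symmetric
    system matrix (its within term plus all between terms).  The null
    permutes the node-to-system labels uniformly (system sizes preserved);
    a system is flagged when its observed statistic exceeds the one-sided
    ``1 - alpha`` percentile of its null (uncorrected across systems).

    Returns a table with columns system, statistic, null_p95, pvalue,
    significant.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if partition.n_systems < 2:
        raise ValueError("need at least 2 systems")
    rng = np.random.default_rng(seed)
    sizes = partition.sizes.astype(float)
    denom = np.outer(sizes, sizes)
    observed = (system_matrix(V, partition).values).sum(axis=0)

    B = partition.indicator()
    null = np.empty((n_perm, partition.n_systems))
    for p in range(n_perm):
        perm = rng.permutation(partition.n_nodes)
        Bp = B[perm]
        null[p] = ((Bp.T @ V @ Bp) / denom).sum(axis=0)
    cutoff = np.percentile(null, 100 * (1 - alpha), axis=0)
    pvals = (1 + (null >= observed).sum(axis=0)) / (n_perm + 1)
    return pd.DataFrame({
        "system": partition.labels,
        "statistic": observed,
        "null_p95": cutoff,
        "pvalue": pvals,
        "significant": observed > cutoff,
    })
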