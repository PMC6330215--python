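"""From region time series to the nonnegative cohort matrix X.

Pipeline steps: sliding windows, band-averaged wavelet coherence per
window (a multilayer network, one N x N layer per window), per-layer mean
normalization, unfolding of the upper triangle to an edges x windows
matrix, across-subject motion regression with clipping at zero, and
concatenation of all subjects into X (edges x windows*subjects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .coherence import CoherenceConfig, cwt_morlet, smooth_spectrum

__all__ = [
    "MultilayerNetwork", "EdgeTimeMatrix", "CohortMatrix",
    "sliding_windows", "build_multilayer", "normalize_layers",
    "unfold", "fold", "edge_index_pairs", "regress_motion", "concatenate",
    "CoherenceNetworks",
]


def sliding_windows(n_samples: int, window_len: int,
                    overlap_frac: float) -> list[tuple[int, int]]:
    """Half-open sample ranges of overlapping sliding windows.

    The step is ``round(window_len * (1 - overlap_frac))`` samples;
    trailing samples that do not fill a complete window are dropped.
    With 120 samples, 20-sample windows and 90% overlap this yields the
    canonical 51 windows.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if n_samples < window_len:
        raise ValueError(
            f"need at least window_len={window_len} samples, got {n_samples}")
    step = int(round(window_len * (1.0 - overlap_frac)))
    if step < 1:
        raise ValueError("overlap too large: window step rounds to zero")
    n_win = (n_samples - window_len) // step + 1
    return [(i * step, i * step + window_len) for i in range(n_win)]


def edge_index_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """Fixed lexicographic (i < j) edge ordering used throughout."""
    iu = np.triu_indices(n_nodes, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


@dataclass
class MultilayerNetwork:
    """One subject's stack of windowed coherence networks.

    values : (N, N, T) array, each layer symmetric with zero diagonal.
    node_ids : node labels.
    window_ranges : (start, stop) sample indices of each window.
    degenerate_nodes : indices of constant (zero-power) input series whose
        edges are defined as 0.
    """

    values: np.ndarray
    node_ids: list = field(default_factory=list)
    window_ranges: list = field(default_factory=list)
    degenerate_nodes: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]


@dataclass
class EdgeTimeMatrix:
    """Unfolded connectivity: one row per unique edge, one column per window."""

    values: np.ndarray               # (E, T)
    edge_index: list                 # ordered (i, j) pairs, i < j
    node_ids: list = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]


@dataclass
class CohortMatrix:
    """Concatenated nonnegative cohort matrix X = [C_1 ... C_S]."""

    values: np.ndarray               # (E, T*S)
    column_map: pd.DataFrame         # columns: column, subject, window
    subject_order: list
    edge_index: list = field(default_factory=list)

    def subject_block(self, subject) -> np.ndarray:
        cols = self.column_map.loc[self.column_map["subject"] == subject,
                                   "column"].to_numpy()
        if cols.size == 0:
            raise KeyError(f"unknown subject {subject!r}")
        return self.values[:, cols]


def _pair_coherence_block(W_all, s_col, sxx, pairs, cfg):
    """Smoothed coherence for a block of node pairs; (P, n_scales, n)."""
    cross = W_all[pairs[:, 0]] * np.conj(W_all[pairs[:, 1]]) / s_col
    # smoothing acts on (scales, ..., time); move scale axis first
    sxy = smooth_spectrum(np.moveaxis(cross, 1, 0), cfg)
    sxy = np.moveaxis(sxy, 0, 1)
    denom = sxx[pairs[:, 0]] * sxx[pairs[:, 1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(denom > 0, np.abs(sxy) ** 2 / denom, 0.0)
    return np.clip(coh, 0.0, 1.0)


def build_multilayer(series: np.ndarray, cfg: CoherenceConfig,
                     node_ids=None, pair_block: int = 512) -> MultilayerNetwork:
    """Windowed, band-averaged coherence network from regions x samples data.

    ``A[i, j, l]`` is the mean of the pairwise coherence map over the
    in-band scales and the samples of window ``l``.  Constant input series
    are flagged degenerate and contribute zero edges.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 2:
        raise ValueError("series must be (n_regions >= 2, n_samples)")
    n_nodes, n_samples = series.shape
    if node_ids is None:
        node_ids = list(range(n_nodes))
    windows = sliding_windows(n_samples, cfg.window_len, cfg.overlap_frac)
    band = cfg.band_mask()
    scales = cfg.scales()
    s_col = scales[None, :, None]

    degenerate = [i for i in range(n_nodes) if np.ptp(series[i]) == 0]
    W_all = np.stack([cwt_morlet(x, cfg) for x in series])      # (N, ns, n)
    power = np.abs(W_all) ** 2 / s_col
    sxx = np.moveaxis(smooth_spectrum(np.moveaxis(power, 1, 0), cfg), 0, 1)
    for i in degenerate:
        sxx[i] = 0.0

    iu = np.column_stack(np.triu_indices(n_nodes, k=1))
    A = np.zeros((n_nodes, n_nodes, len(windows)))
    starts = np.array([w[0] for w in windows])
    stops = np.array([w[1] for w in windows])
    for lo in range(0, iu.shape[0], pair_block):
        pairs = iu[lo:lo + pair_block]
        coh = _pair_coherence_block(W_all, s_col, sxx, pairs, cfg)
        band_coh = coh[:, band, :].mean(axis=1)                 # (P, n)
        csum = np.concatenate([np.zeros((band_coh.shape[0], 1)),
                               np.cumsum(band_coh, axis=1)], axis=1)
        win_means = (csum[:, stops] - csum[:, starts]) / (stops - starts)
        A[pairs[:, 0], pairs[:, 1], :] = win_means
        A[pairs[:, 1], pairs[:, 0], :] = win_means
    return MultilayerNetwork(values=A, node_ids=list(node_ids),
                             window_ranges=windows,
                             degenerate_nodes=degenerate)


def normalize_layers(ml: MultilayerNetwork) -> MultilayerNetwork:
    """Divide each layer by its mean upper-triangle edge weight.

    The diagonal is structurally zero and excluded from the mean; after
    normalization each layer's upper-triangle mean is exactly 1.  A layer
    with nonpositive mean is an error (it carries no scale to divide by).
    """
    A = ml.values
    iu = np.triu_indices(A.shape[0], k=1)
    means = A[iu[0], iu[1], :].mean(axis=0)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(f"layer(s) {bad.tolist()} have nonpositive mean; "
                         "cannot normalize")
    return MultilayerNetwork(values=A / means[None, None, :],
                             node_ids=ml.node_ids,
                             window_ranges=ml.window_ranges,
                             degenerate_nodes=ml.degenerate_nodes)


def unfold(ml: MultilayerNetwork, atol: float = 1e-10) -> EdgeTimeMatrix:
    """Upper-triangle unfolding to edges x windows, lexicographic (i<j) rows."""
    A = ml.values
    if not np.allclose(A, np.transpose(A, (1, 0, 2)), atol=atol):
        raise ValueError("layers are not symmetric within tolerance")
    iu = np.triu_indices(A.shape[0], k=1)
    return EdgeTimeMatrix(values=A[iu[0], iu[1], :],
                          edge_index=edge_index_pairs(A.shape[0]),
                          node_ids=ml.node_ids)


def fold(etm: EdgeTimeMatrix) -> MultilayerNetwork:
    """Inverse of :func:`unfold` (zero diagonal, symmetric layers)."""
    E, T = etm.values.shape
    n = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
    if n * (n - 1) // 2 != E:
        raise ValueError(f"{E} rows is not a triangular number")
    A = np.zeros((n, n, T))
    iu = np.triu_indices(n, k=1)
    A[iu[0], iu[1], :] = etm.values
    A[iu[1], iu[0], :] = etm.values
    return MultilayerNetwork(values=A, node_ids=etm.node_ids)


def regress_motion(edge_matrices: list, motion) -> list:
    """Remove the across-subject motion trend from every (edge, window) cell.

    For each cell an ordinary least-squares fit of value on the per-subject
    motion scalar is computed across subjects; the slope component
    ``b * (motion - mean(motion))`` is subtracted, so the fitted value at
    the cohort's mean motion (intercept plus slope at the mean) is
    retained and the nonnegative scale survives.  Centering matters: it
    keeps the cell's level, and it prevents the slope-estimation error --
    which enters each subject's series multiplied by the motion regressor
    -- from growing monotonically with motion, which would leak a spurious
    motion dependence into nonlinear summaries such as the histogram
    entropy.  Any resulting negative value is set to zero.  With zero
    motion variance the regression is skipped (identity transform) with a
    warning.
    """
    import warnings

    motion = np.asarray(motion, dtype=float)
    if len(edge_matrices) < 3:
        raise ValueError("need at least 3 subjects for motion regression")
    if len(edge_matrices) != motion.size:
        raise ValueError("one motion scalar per subject required")
    if not np.isfinite(motion).all():
        raise ValueError("motion must be finite")
    get = lambda c: c.values if isinstance(c, EdgeTimeMatrix) else np.asarray(c)
    V = np.stack([get(c) for c in edge_matrices])   # (S, E, T)
    m = motion - motion.mean()
    var = float(m @ m)
    if var == 0:
        warnings.warn("motion has zero variance; regression skipped")
        return list(edge_matrices)
    slope = np.tensordot(m, V - V.mean(axis=0), axes=(0, 0)) / var  # (E, T)
    out = np.maximum(V - m[:, None, None] * slope[None], 0.0)
    result = []
    for i, c in enumerate(edge_matrices):
        if isinstance(c, EdgeTimeMatrix):
            result.append(EdgeTimeMatrix(values=out[i], edge_index=c.edge_index,
                                         node_ids=c.node_ids))
        else:
            result.append(out[i])
    return result


def concatenate(edge_matrices: list, subject_ids=None) -> CohortMatrix:
    """Concatenate per-subject edge-time matrices into the cohort matrix X."""
    if not edge_matrices:
        raise ValueError("no subjects to concatenate")
    if subject_ids is None:
        subject_ids = list(range(len(edge_matrices)))
    get = lambda c: c.values if isinstance(c, EdgeTimeMatrix) else np.asarray(c)
    first = get(edge_matrices[0])
    blocks, rows = [], []
    for sid, c in zip(subject_ids, edge_matrices):
        v = get(c)
        if v.shape != first.shape:
            raise ValueError(f"subject {sid!r} has shape {v.shape}, "
                             f"expected {first.shape}")
        if (v < 0).any():
            raise ValueError(f"subject {sid!r} has negative entries")
        blocks.append(v)
        rows.extend((sid, w) for w in range(v.shape[1]))
    values = np.concatenate(blocks, axis=1)
    column_map = pd.DataFrame(rows, columns=["subject", "window"])
    column_map.insert(0, "column", np.arange(values.shape[1]))
    edge_index = (edge_matrices[0].edge_index
                  if isinstance(edge_matrices[0], EdgeTimeMatrix)
                  else edge_index_pairs(
                      int(round((1 + np.sqrt(1 + 8 * first.shape[0])) / 2))))
    return CohortMatrix(values=values, column_map=column_map,
                        subject_order=list(subject_ids),
                        edge_index=edge_index)


class CoherenceNetworks(TransformerMixin, BaseEstimator):
    """Transformer from per-subject region time series to cohort matrix X.

    Stateless (``fit`` records nothing but the input spec); ``transform``
    takes a list of (n_regions, n_samples) arrays and returns a
    :class:`CohortMatrix`.  Motion regression is applied when a ``motion``
    vector is supplied at transform time.
    """

    def __init__(self, config: CoherenceConfig | None = None,
                 normalize: bool = True):
        self.config = config
        self.normalize = normalize

    def fit(self, X, y=None):
        self.config_ = self.config or CoherenceConfig()
        return self

    def transform(self, X, motion=None, subject_ids=None) -> CohortMatrix:
        if not hasattr(self, "config_"):
            self.fit(X)
        edges = []
        for series in X:
            ml = build_multilayer(series, self.config_)
            if self.normalize:
                ml = normalize_layers(ml)
            edges.append(unfold(ml))
        if motion is not None:
            edges = regress_motion(edges, motion)
        return concatenate(edges, subject_ids=subject_ids)
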