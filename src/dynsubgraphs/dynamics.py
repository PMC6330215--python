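"""Energy, entropy and group statistics of subgraph expression.

For one subject and subgraph, the expression series S_1..S_L (one
nonnegative coefficient per time window) is summarized by

* energy        sum_n S_n^2                 (overall expression magnitude)
* entropy       -sum_i P_i log P_i          (histogram estimator, natural
                log, 10 equal-width bins over the series' own [min, max];
                a proxy for switching/transience)
* mean |dS|     mean absolute first difference (alternative transience).

Standardization divides each (subject, subgraph) series by its own mean,
so that between-subject comparisons are of relative rather than absolute
expression.  Group comparisons use the Wilcoxon rank-sum z with tie
correction; permutation nulls are provided for the energy-entropy
correlation (element shuffle) and the age-residualized behavior
association.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "energy", "entropy", "mean_abs_derivative", "entropy_rows",
    "standardize", "summarize_dynamics", "energy_entropy_relation",
    "shuffle_null_correlation", "group_compare", "motion_check",
    "behavior_association",
]


def energy(series: np.ndarray) -> float:
    """Signal energy: the sum of squared expression coefficients."""
    s = np.asarray(series, dtype=float)
    return float(np.sum(s * s))


def entropy(series: np.ndarray, n_bins: int = 10) -> float:
    """Histogram entropy over equal-width bins spanning [min, max].

    Natural log; empty bins contribute nothing.  A constant series has a
    degenerate range and returns 0 (the limiting value).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise ValueError("series must have length >= 2")
    lo, hi = s.min(), s.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(s, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / s.size
    return float(-(p * np.log(p)).sum())


def entropy_rows(V: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Vectorized histogram entropy of each row of a 2-D array."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    V = np.asarray(V, dtype=float)
    n, L = V.shape
    lo = V.min(axis=1)
    hi = V.max(axis=1)
    span = hi - lo
    ok = span > 0
    t = (V - lo[:, None]) / np.where(ok, span, 1.0)[:, None]
    idx = np.minimum((t * n_bins).astype(int), n_bins - 1)
    flat = (np.arange(n)[:, None] * n_bins + idx).ravel()
    counts = np.bincount(flat, minlength=n * n_bins).reshape(n, n_bins)
    P = counts / L
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    out = -terms.sum(axis=1)
    out[~ok] = 0.0
    return out


def mean_abs_derivative(series: np.ndarray) -> float:
    """Mean absolute first difference of the expression series."""
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise ValueError("series must have length >= 2")
    return float(np.mean(np.abs(np.diff(s))))


def _series_by_subject(H: np.ndarray, column_map: pd.DataFrame):
    """Yield (subject, (k, T_s) coefficient block) in subject order."""
    for subject, grp in column_map.groupby("subject", sort=False):
        yield subject, H[:, grp["column"].to_numpy()]


def standardize(H: np.ndarray, column_map: pd.DataFrame):
    """Divide each (subject, subgraph) series by its mean.

    Returns ``(H_std, missing)`` where ``missing`` is a boolean
    (n_subjects, k) mask marking zero-mean series that were left in place
    rather than divided (their standardized statistics are undefined).
    """
    H = np.asarray(H, dtype=float)
    H_std = H.copy()
    subjects = list(pd.unique(column_map["subject"]))
    missing = np.zeros((len(subjects), H.shape[0]), dtype=bool)
    for s_idx, (subject, grp) in enumerate(column_map.groupby("subject",
                                                              sort=False)):
        cols = grp["column"].to_numpy()
        means = H[:, cols].mean(axis=1)
        zero = means == 0
        missing[s_idx] = zero
        safe = np.where(zero, 1.0, means)
        H_std[:, cols] = H[:, cols] / safe[:, None]
    return H_std, missing


def summarize_dynamics(H: np.ndarray, column_map: pd.DataFrame,
                       group_labels=None, motion=None,
                       n_bins: int = 10) -> pd.DataFrame:
    """Per-(subject, subgraph) dynamics table.

    Columns: subject, subgraph, energy, entropy, mean_abs_derivative,
    standardized_energy, standardized_entropy, plus group and motion when
    supplied (one value per subject, in subject order).
    """
    H = np.asarray(H, dtype=float)
    H_std, missing = standardize(H, column_map)
    rows = []
    subjects = list(pd.unique(column_map["subject"]))
    std_blocks = dict(_series_by_subject(H_std, column_map))
    for s_idx, (subject, block) in enumerate(_series_by_subject(H, column_map)):
        block_std = std_blocks[subject]
        ent = entropy_rows(block, n_bins=n_bins)
        ent_std = entropy_rows(block_std, n_bins=n_bins)
        for g in range(H.shape[0]):
            rows.append({
                "subject": subject,
                "subgraph": g,
                "energy": float(np.sum(block[g] ** 2)),
                "entropy": float(ent[g]),
                "mean_abs_derivative": float(np.mean(np.abs(np.diff(block[g])))),
                "standardized_energy": (np.nan if missing[s_idx, g]
                                        else float(np.sum(block_std[g] ** 2))),
                "standardized_entropy": (np.nan if missing[s_idx, g]
                                         else float(ent_std[g])),
            })
    out = pd.DataFrame(rows)
    if group_labels is not None:
        gmap = dict(zip(subjects, group_labels))
        out["group"] = out["subject"].map(gmap)
    if motion is not None:
        mmap = dict(zip(subjects, np.asarray(motion, dtype=float)))
        out["motion"] = out["subject"].map(mmap)
    return out


def energy_entropy_relation(summary: pd.DataFrame):
    """Pearson r of log mean energy vs mean entropy across subgraphs.

    Energies and entropies are first averaged across subjects within each
    subgraph; the correlation is computed over the resulting k points.
    """
    per = summary.groupby("subgraph")[["energy", "entropy"]].mean()
    if len(per) < 3:
        raise ValueError("need at least 3 subgraphs")
    if (per["energy"] <= 0).any():
        raise ValueError("all mean energies must be positive")
    x = np.log(per["energy"].to_numpy())
    y = per["entropy"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in energy or entropy across subgraphs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _subject_column_index(column_map: pd.DataFrame):
    """(S, T) column-index array when all subjects share a window count,
    else None (ragged cohorts fall back to a per-subject loop)."""
    groups = [grp["column"].to_numpy()
              for _, grp in column_map.groupby("subject", sort=False)]
    if len({g.size for g in groups}) == 1:
        return np.stack(groups)
    return None


def _relation_from_H(H: np.ndarray, column_map: pd.DataFrame,
                     n_bins: int, idx: np.ndarray | None = None) -> float:
    """Energy-entropy correlation recomputed directly from a coefficient
    matrix (fast path used inside the permutation null)."""
    k = H.shape[0]
    if idx is None:
        idx = _subject_column_index(column_map)
    if idx is not None:
        blocks = H[:, idx]                       # (k, S, T)
        e = (blocks ** 2).sum(axis=2).mean(axis=1)
        S, T = idx.shape
        h = entropy_rows(blocks.reshape(k * S, T),
                         n_bins=n_bins).reshape(k, S).mean(axis=1)
    else:
        energies, entropies = [], []
        for _, block in _series_by_subject(H, column_map):
            energies.append((block ** 2).sum(axis=1))
            entropies.append(entropy_rows(block, n_bins=n_bins))
        e = np.mean(energies, axis=0)
        h = np.mean(entropies, axis=0)
    if (e <= 0).any() or np.ptp(np.log(e)) == 0 or np.ptp(h) == 0:
        raise ValueError("degenerate energy or entropy; correlation undefined")
    return float(stats.pearsonr(np.log(e), h)[0])


def shuffle_null_correlation(H: np.ndarray, column_map: pd.DataFrame,
                             n_perm: int = 1000, seed: int | None = None,
                             n_bins: int = 10) -> dict:
    """Element-shuffle permutation null for the energy-entropy correlation.

    Every permutation shuffles all entries of H jointly across rows and
    columns (shape preserved) and recomputes the per-subgraph correlation
    of log mean energy with mean entropy.  The p value counts permuted
    |r| at least as large as observed, with add-one smoothing.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    H = np.asarray(H, dtype=float)
    rng = np.random.default_rng(seed)
    idx = _subject_column_index(column_map)
    observed = _relation_from_H(H, column_map, n_bins, idx=idx)
    flat = H.ravel()
    count = 0
    null = np.empty(n_perm)
    for i in range(n_perm):
        Hp = rng.permutation(flat).reshape(H.shape)
        try:
            r = _relation_from_H(Hp, column_map, n_bins, idx=idx)
        except ValueError:
            r = 0.0
        null[i] = r
        count += abs(r) >= abs(observed)
    return {"observed_r": observed,
            "pvalue": (1 + count) / (n_perm + 1),
            "n_perm": n_perm,
            "null": null}


def group_compare(values, group_labels, group_order=None, exact: bool = False):
    """Two-sided Wilcoxon rank-sum comparison of two groups.

    Returns ``(z, p)``.  z uses the tie-corrected normal approximation with
    continuity correction and is negative when the second-listed group has
    the larger ranks.  With ``exact=True`` (small samples, no large-sample
    approximation wanted) the p value comes from the exact rank-sum
    distribution instead; z is still reported from the normal form.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    if group_order is None:
        group_order = list(pd.unique(group_labels))
    if len(group_order) != 2:
        raise ValueError("exactly two groups required")
    x = values[group_labels == group_order[0]]
    y = values[group_labels == group_order[1]]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    w1 = ranks[:n1].sum()
    expected = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
                if n > 1 else 0.0)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    diff = w1 - expected
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    if exact:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue)
    else:
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return float(z), p


def motion_check(summary: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-subject energy and entropy with motion.

    Metrics are averaged over subgraphs within each subject first; returns
    a table with columns metric, r, pvalue.
    """
    if "motion" not in summary:
        raise ValueError("summary has no motion column")
    per = summary.groupby("subject")[["energy", "entropy", "motion"]].mean()
    if len(per) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(per["motion"].to_numpy()) == 0:
        raise ValueError("motion has zero variance")
    rows = []
    for metric in ("energy", "entropy"):
        vals = per[metric].to_numpy()
        if np.ptp(vals) == 0:
            raise ValueError(f"{metric} has zero variance")
        r, p = stats.pearsonr(vals, per["motion"].to_numpy())
        rows.append({"metric": metric, "r": float(r), "pvalue": float(p)})
    return pd.DataFrame(rows)


def behavior_association(flexibility, behavior, age, n_perm: int = 1000,
                         seed: int | None = None):
    """Age-residualized association between flexibility and behavior.

    Both variables are residualized on age by OLS (with intercept); the
    statistic is the Pearson correlation of the residuals, and the null is
    built by permuting the residualized behavior across subjects.  Returns
    ``(partial_r, pvalue)``.
    """
    flexibility = np.asarray(flexibility, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    age = np.asarray(age, dtype=float)
    if flexibility.size < 10:
        raise ValueError("need at least 10 subjects")
    design = np.column_stack([np.ones_like(age), age])
    res_f = flexibility - design @ np.linalg.lstsq(design, flexibility,
                                                   rcond=None)[0]
    res_b = behavior - design @ np.linalg.lstsq(design, behavior,
                                                rcond=None)[0]
    if np.ptp(res_f) == 0 or np.ptp(res_b) == 0:
        raise ValueError("zero residual variance")
    r_obs = float(stats.pearsonr(res_f, res_b)[0])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = stats.pearsonr(res_f, rng.permutation(res_b))[0]
        count += abs(r) >= abs(r_obs)
    return r_obs, (1 + count) / (n_perm + 1)
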