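"""Agreement metrics for partitions and ordinal predictions.

The Jaccard (Tanimoto) index compares two partitions of the same points by
pair co-membership; the polychoric correlation estimates the latent-normal
correlation underlying an ordinal contingency table (its 2x2 special case
is the tetrachoric correlation).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import multivariate_normal, norm

__all__ = ["jaccard_index", "polychoric_corr"]


def jaccard_index(truth_labels: Sequence, predicted_labels: Sequence) -> float:
    """Pair co-membership Jaccard index between two partitions.

    tau = |pairs together in both| / |pairs together in either|; it is
    invariant to relabeling of either partition and lies in [0, 1]
    (1 on identical partitions, 0 when no co-clustered pair is shared).
    """
    t = np.asarray(truth_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if len(t) < 2:
        raise ValueError("need at least 2 points to form pairs")
    from sklearn.metrics.cluster import pair_confusion_matrix

    c = pair_confusion_matrix(t, p).astype(float)
    both, t_only, p_only = c[1, 1], c[1, 0], c[0, 1]
    union = both + t_only + p_only
    if union == 0:  # all singleton pairs in both partitions
        return 0.0
    return float(both / union)


def _table_loglik(rho: float, table: np.ndarray, tx: np.ndarray, ty: np.ndarray) -> float:
    """Log-likelihood of an ordinal table under a latent bivariate normal."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    bvn = multivariate_normal(mean=[0.0, 0.0], cov=cov)
    # cell probability = rectangle probability of the latent normal
    cx = np.concatenate(([-np.inf], tx, [np.inf]))
    cy = np.concatenate(([-np.inf], ty, [np.inf]))

    def F(a: float, b: float) -> float:
        if np.isinf(a) and a < 0 or np.isinf(b) and b < 0:
            return 0.0
        if np.isinf(a) and np.isinf(b):
            return 1.0
        if np.isinf(a):
            return float(norm.cdf(b))
        if np.isinf(b):
            return float(norm.cdf(a))
        return float(bvn.cdf([a, b]))

    ll = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            pij = (F(cx[i + 1], cy[j + 1]) - F(cx[i], cy[j + 1])
                   - F(cx[i + 1], cy[j]) + F(cx[i], cy[j]))
            ll += table[i, j] * np.log(max(pij, 1e-12))
    return ll


def polychoric_corr(x: Sequence, y: Sequence) -> float:
    """Two-step maximum-likelihood polychoric correlation.

    Thresholds are fixed from the marginal cumulative proportions
    (normal quantiles), then the latent correlation maximizes the table
    likelihood.  Empty contingency cells receive a +0.5 continuity
    correction.  Returns nan (with a warning) when either variable is
    constant.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    xl, xi = np.unique(x, return_inverse=True)
    yl, yi = np.unique(y, return_inverse=True)
    if len(xl) < 2 or len(yl) < 2:
        warnings.warn("polychoric correlation undefined for a constant variable")
        return float("nan")
    table = np.zeros((len(xl), len(yl)), float)
    for a, b in zip(xi, yi):
        table[a, b] += 1
    if (table == 0).any():
        table = table + 0.5
    n = table.sum()
    tx = norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / n)
    ty = norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / n)
    res = optimize.minimize_scalar(
        lambda r: -_table_loglik(r, table, tx, ty),
        bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": 1e-5})
    return float(res.x)
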