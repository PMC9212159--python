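"""Reference dependence measures: Pearson's r, Kendall's tau-b, and the
sample distance correlation (dCor).

Pearson and Kendall delegate to scipy.stats. Distance correlation is the
biased V-statistic estimator built from double-centered pairwise-distance
matrices: dCor = dCov / sqrt(dVar_x * dVar_y), which lies in [0, 1] and
equals 0 in population exactly under independence.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["pearson", "kendall_tau", "distance_correlation"]


def _check_pair(x, y, min_len=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("expected two 1-D arrays of equal length")
    if x.size < min_len:
        raise ValueError(f"need at least {min_len} observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs contain non-finite values")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation, in [-1, 1]. Errors on constant input."""
    x, y = _check_pair(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: Pearson correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def kendall_tau(x, y) -> float:
    """Kendall's tau-b (tie-corrected), in [-1, 1]. Errors on all-tied input."""
    x, y = _check_pair(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("all-tied input: Kendall tau undefined")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def distance_correlation(x, y) -> float:
    """Sample distance correlation (biased V-statistic), in [0, 1].

    Double-centers the absolute-difference matrices of each series and
    combines them as dCov^2 = mean(A * B), dVar^2 = mean(A * A);
    dCor = sqrt(dCov^2 / sqrt(dVar_x^2 * dVar_y^2)). dcor(x, x) = 1 for any
    non-constant x; the value is invariant to shifts and positive rescaling.
    """
    x, y = _check_pair(x, y)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        raise ValueError("zero distance variance: constant input")
    dcov2 = (A * B).mean()
    val = np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y))
    return float(np.clip(val, 0.0, 1.0))
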