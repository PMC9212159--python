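"""Significance machinery for correlation estimates.

Two tests are used throughout:

* the plug-in t-test for a single correlation value m computed from T
  observations: t = m sqrt(T-2) / sqrt(1 - m^2), df = T - 2. This is exact
  for Pearson's r under bivariate normality and is applied, by convention,
  to every measure here (including Kendall's tau and dCor) — it is the rule
  that reproduces the per-value p-values in the simulation tables;
* the one-sample t-test across replicate values of a measure, df = R - 1,
  two-sided, for replicate-averaged estimates.

The Bonferroni-style per-replicate significance threshold defaults to
5e-4 (0.05 / 100 replicates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .kernels import KernelSpec, TimeSeriesPair, kernelized_correlation

__all__ = [
    "ReplicateSummary",
    "ScreenResult",
    "plugin_correlation_test",
    "per_replicate_significant",
    "replicate_ttest",
    "average_kc_over_replicates",
    "self_correlation_screen",
    "dcor_permutation_test",
    "BONFERRONI_THRESHOLD",
]

#: 0.05 family-wise level split over the 100 simulation replicates
BONFERRONI_THRESHOLD = 5e-4


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean, standard error and one-sample t-test over replicate values."""

    values: tuple
    mean: float
    se: float
    p_value: float
    df: int
    degenerate: bool = False

    @property
    def n_replicates(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the condition self-correlation screen for one variable."""

    name: str
    self_correlation: float
    se: float
    p_value: float
    flagged: bool


def plugin_correlation_test(
    m: float,
    T: int,
    alternative: Literal["one_sided", "two_sided"] = "one_sided",
) -> float:
    """P-value for a correlation value m on T observations via the plug-in t.

    t = m sqrt(T-2) / sqrt(1-m^2) referred to Student's t with df = T - 2.
    One-sided means the upper tail (H1: positive dependence), so m = 0 gives
    p = 0.5 and m < 0 gives p > 0.5. |m| = 1 gives p = 0.
    """
    if abs(m) > 1:
        raise ValueError(f"correlation value out of [-1, 1]: {m}")
    if T < 3:
        raise ValueError(f"plug-in test needs T >= 3, got {T}")
    df = T - 2
    if abs(m) == 1.0:
        t = np.inf * np.sign(m)
    else:
        t = m * np.sqrt(df) / np.sqrt(1.0 - m * m)
    if alternative == "one_sided":
        return float(stats.t.sf(t, df))
    if alternative == "two_sided":
        return float(2.0 * stats.t.sf(abs(t), df))
    raise ValueError(f"unknown alternative {alternative!r}")


def per_replicate_significant(
    m: float, T: int, threshold: float = BONFERRONI_THRESHOLD
) -> bool:
    """Whether a single replicate's value clears the corrected threshold."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return plugin_correlation_test(m, T, "one_sided") < threshold


def replicate_ttest(values: Sequence[float]) -> ReplicateSummary:
    """One-sample t-test of replicate measure values against 0.

    Two-sided, df = R - 1, se = sd / sqrt(R). Identical replicate values
    give se = 0; the p-value is then reported as 0.0 with a degeneracy
    warning rather than NaN.
    """
    vals = tuple(float(v) for v in values)
    R = len(vals)
    if R < 2:
        raise ValueError(f"need at least 2 replicate values, got {R}")
    arr = np.asarray(vals)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / np.sqrt(R))
    df = R - 1
    if se == 0.0:
        warnings.warn(
            "identical replicate values: standard error is 0, p-value "
            "degenerate (reported as 0)",
            RuntimeWarning,
            stacklevel=2,
        )
        return ReplicateSummary(vals, mean, 0.0, 0.0, df, degenerate=True)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ReplicateSummary(vals, mean, se, p, df)


def average_kc_over_replicates(
    reps: Sequence[TimeSeriesPair], spec: KernelSpec | None = None
) -> ReplicateSummary:
    """K_c per replicate, then the one-sample t-test across replicates."""
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates")
    T = reps[0].T
    if any(r.T != T for r in reps):
        raise ValueError("replicates must share the same number of time points")
    values = [kernelized_correlation(r, spec) for r in reps]
    return replicate_ttest(values)


def self_correlation_screen(
    name: str,
    condition_a: Sequence[np.ndarray],
    condition_b: Sequence[np.ndarray],
    spec: KernelSpec | None = None,
    value_threshold: float = 0.95,
    p_threshold: float = 0.001,
) -> ScreenResult:
    """Screen one variable for condition-invariance via its self-correlation.

    Pairs the variable's series in condition A with its series in condition B
    (replicate by replicate), computes K_c per replicate and averages. A
    variable whose mean self-correlation exceeds ``value_threshold`` with
    p below ``p_threshold`` behaves identically in both conditions and is
    flagged as uninformative for a condition-contrast analysis.
    """
    if len(condition_a) != len(condition_b) or len(condition_a) < 2:
        raise ValueError("need matched replicate lists with R >= 2")
    pairs = [TimeSeriesPair(a, b) for a, b in zip(condition_a, condition_b)]
    summary = average_kc_over_replicates(pairs, spec)
    flagged = bool(summary.mean > value_threshold and summary.p_value < p_threshold)
    return ScreenResult(name, summary.mean, summary.se, summary.p_value, flagged)


def dcor_permutation_test(
    x, y, n_perm: int = 999, rng: np.random.Generator | int | None = None
) -> float:
    """Permutation p-value for distance correlation (non-default alternative
    to the plug-in rule)."""
    from .baselines import distance_correlation

    rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    observed = distance_correlation(x, y)
    hits = 1  # the observed statistic counts
    for _ in range(n_perm):
        if distance_correlation(x, rng.permutation(y)) >= observed:
            hits += 1
    return hits / (n_perm + 1)
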