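"""Model/Results interface for pairwise nonlinear correlation analysis.

`PairCorrelation` is built from one pair of series, or from R >= 2 replicate
pairs, plus a kernel specification; `fit()` computes the kernelized
correlation together with the requested baseline measures and their
significance, returning a `PairCorrelationResults` with a `summary()` table.
Gamma training (for complementary-patterned pairs) is a fit option.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import baselines
from .gammatrain import GammaTrainResult, train_gamma
from .inference import (ReplicateSummary, plugin_correlation_test,
                        replicate_ttest)
from .kernels import KernelSpec, TimeSeriesPair, kernelized_correlation

__all__ = ["PairCorrelation", "PairCorrelationResults"]

_BASELINES = {
    "pearson": baselines.pearson,
    "kendall": baselines.kendall_tau,
    "dcor": baselines.distance_correlation,
}


class PairCorrelation:
    """Nonlinear correlation model for a pair of aligned series.

    Parameters
    ----------
    replicates : sequence of TimeSeriesPair
        One or more replicate observations of the same pair of variables.
    spec : KernelSpec, optional
        Kernel used for K_c; defaults to RBF with gamma = 0.5, standardized.
    baselines : sequence of {"pearson", "kendall", "dcor"}
        Classical measures computed alongside K_c.
    names : (str, str), optional
        Labels for the two variables (used in the summary).
    """

    def __init__(self, replicates: Sequence[TimeSeriesPair],
                 spec: KernelSpec | None = None,
                 baselines: Sequence[str] = ("pearson", "kendall", "dcor"),
                 names: tuple[str, str] = ("x", "y")):
        reps = list(replicates)
        if not reps:
            raise ValueError("need at least one replicate pair")
        T = reps[0].T
        if any(r.T != T for r in reps):
            raise ValueError("replicates must share the same T")
        unknown = set(baselines) - set(_BASELINES)
        if unknown:
            raise ValueError(f"unknown baseline measures {sorted(unknown)}")
        self.replicates = reps
        self.spec = spec or KernelSpec()
        self.baselines = tuple(baselines)
        self.names = names

    @classmethod
    def from_pair(cls, x, y, times=None, **kwargs) -> "PairCorrelation":
        return cls([TimeSeriesPair(x, y, times=times)], **kwargs)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, var_a: str, var_b: str,
                       replicate_col: str | None = None,
                       **kwargs) -> "PairCorrelation":
        """Build from a long-format frame with one column per variable and an
        optional replicate column; rows must be in time order."""
        if replicate_col is None:
            groups = [data]
        else:
            groups = [g for _, g in data.groupby(replicate_col, sort=True)]
        reps = [TimeSeriesPair(g[var_a].to_numpy(float),
                               g[var_b].to_numpy(float)) for g in groups]
        return cls(reps, names=(var_a, var_b), **kwargs)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def fit(self, train: bool = False, grid=None,
            flat_tolerance: float = 8e-5) -> "PairCorrelationResults":
        """Estimate K_c (optionally with replicate-trained gamma) and the
        baseline measures, with p-values.

        With one replicate every measure is tested by the one-sided plug-in
        t-test on T observations; with R >= 2 each measure is computed per
        replicate and tested by the across-replicate one-sample t-test.
        """
        spec = self.spec
        gamma_train: GammaTrainResult | None = None
        if train:
            if spec.family != "rbf":
                raise ValueError("gamma training applies to the RBF kernel")
            if self.n_replicates < 2:
                raise ValueError("gamma training needs R >= 2 replicates")
            gamma_train = train_gamma(self.replicates, grid=grid,
                                      flat_tolerance=flat_tolerance,
                                      standardize=spec.standardize)
            spec = KernelSpec(family="rbf", gamma=gamma_train.gamma_star,
                              standardize=spec.standardize)

        def estimate(fn):
            vals = [fn(r) for r in self.replicates]
            if len(vals) == 1:
                p = plugin_correlation_test(vals[0], self.replicates[0].T)
                return ReplicateSummary(tuple(vals), vals[0], np.nan, p, 0)
            return replicate_ttest(vals)

        estimates = {spec.label: estimate(
            lambda r: kernelized_correlation(r, spec))}
        for name in self.baselines:
            fn = _BASELINES[name]
            estimates[name] = estimate(lambda r, fn=fn: fn(r.x, r.y))
        return PairCorrelationResults(self, spec, estimates, gamma_train)


class PairCorrelationResults:
    """Estimates, uncertainties and tests from a fitted PairCorrelation."""

    def __init__(self, model: PairCorrelation, spec: KernelSpec,
                 estimates: dict[str, ReplicateSummary],
                 gamma_train: GammaTrainResult | None = None):
        self.model = model
        self.spec = spec
        self.estimates = estimates
        self.gamma_train = gamma_train
        kc_label = spec.label
        self.kc = estimates[kc_label].mean
        self.kc_pvalue = estimates[kc_label].p_value

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"measure": name, "value": s.mean, "se": s.se, "p_value": s.p_value}
            for name, s in self.estimates.items()
        ]
        return pd.DataFrame(rows).set_index("measure")

    def summary(self) -> str:
        a, b = self.model.names
        lines = [
            "Pairwise nonlinear correlation",
            "=" * 58,
            f"pair:       {a} - {b}",
            f"T:          {self.model.replicates[0].T} time points, "
            f"R = {self.model.n_replicates} replicate(s)",
            f"kernel:     {self.spec.label}"
            + (" [trained]" if self.gamma_train is not None else ""),
            f"standardize: {self.spec.standardize}",
            "-" * 58,
            f"{'measure':<22}{'value':>9}{'se':>9}{'p_value':>11}",
        ]
        for name, s in self.estimates.items():
            se = f"{s.se:.4f}" if np.isfinite(s.se) else "--"
            lines.append(f"{name:<22}{s.mean:>9.4f}{se:>9}{s.p_value:>11.4g}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"<PairCorrelationResults kc={self.kc:.4f} p={self.kc_pvalue:.3g}>"
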