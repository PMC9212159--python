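"""Expression-table I/O, the all-pairs correlation engine, and synthetic
fixture datasets.

Tables are delimited text (TSV/CSV) with variables in rows: the first column
holds identifiers and the remaining columns hold time points. Replicates are
either separate files or contiguous column blocks in one file; the layout is
always declared, never guessed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .gammatrain import train_gamma
from .inference import plugin_correlation_test, replicate_ttest
from .kernels import KernelSpec, TimeSeriesPair, kernelized_correlation

__all__ = [
    "ExpressionDataset",
    "read_expression_table",
    "write_expression_table",
    "all_pairs_kc",
    "make_fixtures",
]

logger = logging.getLogger("kercor")


@dataclass
class ExpressionDataset:
    """n variables x T time points x R replicates of expression values.

    ``conditions`` optionally tags each replicate (e.g. "Th0" / "Th17") so
    that replicates from different experimental conditions can be separated.
    """

    variables: list[str]
    times: list
    values: np.ndarray  # (n, T, R)
    conditions: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a (n, T, R) array")
        n, T, R = self.values.shape
        if len(self.variables) != n:
            raise ValueError("variable count does not match values")
        if len(self.times) != T:
            raise ValueError("time count does not match values")
        if T < 3:
            raise ValueError(f"need T >= 3 time points, got {T}")
        if len(set(self.variables)) != n:
            raise ValueError("duplicate variable identifiers")
        if not np.isfinite(self.values).all():
            raise ValueError("dataset contains missing/non-finite values")
        if self.conditions is not None and len(self.conditions) != R:
            raise ValueError("conditions must tag every replicate")

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def series(self, variable: str, replicate: int = 0) -> np.ndarray:
        return self.values[self.variables.index(variable), :, replicate]

    def replicate_pairs(self, var_a: str, var_b: str,
                        replicates: Sequence[int] | None = None) -> list[TimeSeriesPair]:
        reps = range(self.n_replicates) if replicates is None else replicates
        return [TimeSeriesPair(self.series(var_a, r), self.series(var_b, r),
                               times=self.times) for r in reps]

    def subset_condition(self, condition: str) -> "ExpressionDataset":
        if self.conditions is None:
            raise ValueError("dataset has no condition tags")
        idx = [i for i, c in enumerate(self.conditions) if c == condition]
        if not idx:
            raise ValueError(f"no replicates tagged {condition!r}")
        return ExpressionDataset(self.variables, list(self.times),
                                 self.values[:, :, idx],
                                 [condition] * len(idx))


def _parse_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate identifiers {dups}")
    for col in df.columns:
        bad = df[col].isna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            row = df.index[coerced.isna().argmax()]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    return df.astype(float)


def read_expression_table(
    path: str | Path | Sequence[str | Path],
    sep: str | None = None,
    n_replicates: int = 1,
    layout: Literal["single", "replicate_blocks", "per_file"] = "single",
    conditions: Sequence[str] | None = None,
) -> ExpressionDataset:
    """Load an expression dataset from delimited text.

    Layouts
    -------
    ``single``
        One file, columns are the T time points, R = 1.
    ``replicate_blocks``
        One file, columns are R contiguous blocks of T time points each
        (replicate-major); ``n_replicates`` must be declared.
    ``per_file``
        A list of paths, one file per replicate, identical row/column sets.

    Any missing value, non-numeric cell, or duplicate identifier is a hard
    error naming the offending location.
    """
    def load(p):
        p = Path(p)
        use_sep = sep if sep is not None else ("," if p.suffix.lower() == ".csv" else "\t")
        df = pd.read_csv(p, sep=use_sep, index_col=0,
                         float_precision="round_trip")
        return _parse_frame(df, p)

    if layout == "per_file":
        if isinstance(path, (str, Path)):
            raise ValueError("per_file layout expects a list of paths")
        frames = [load(p) for p in path]
        first = frames[0]
        for f in frames[1:]:
            if not (f.index.equals(first.index) and f.columns.equals(first.columns)):
                raise ValueError("replicate files disagree on variables or time points")
        values = np.stack([f.to_numpy() for f in frames], axis=2)
        variables = list(first.index.astype(str))
        times = list(first.columns)
    else:
        df = load(path)
        variables = list(df.index.astype(str))
        if layout == "single":
            values = df.to_numpy()[:, :, None]
            times = list(df.columns)
        elif layout == "replicate_blocks":
            if n_replicates < 1 or df.shape[1] % n_replicates:
                raise ValueError(
                    f"{path}: {df.shape[1]} columns not divisible into "
                    f"{n_replicates} replicate blocks")
            T = df.shape[1] // n_replicates
            arr = df.to_numpy().reshape(len(variables), n_replicates, T)
            values = np.moveaxis(arr, 1, 2)  # (n, T, R)
            times = [str(c) for c in df.columns[:T]]
        else:
            raise ValueError(f"unknown layout {layout!r}")
    return ExpressionDataset(variables, times, values,
                             list(conditions) if conditions else None)


def write_expression_table(
    dataset: ExpressionDataset, path: str | Path, sep: str = "\t"
) -> None:
    """Write a dataset back to delimited text (replicate blocks if R > 1)."""
    n, T, R = dataset.values.shape
    cols, blocks = [], []
    for r in range(R):
        tag = f"_r{r + 1}" if R > 1 else ""
        cols.extend(f"{t}{tag}" for t in dataset.times)
        blocks.append(dataset.values[:, :, r])
    df = pd.DataFrame(np.hstack(blocks), index=dataset.variables, columns=cols)
    df.index.name = "id"
    # shortest round-trippable decimal representation, so read(write(ds)) is
    # bit-identical
    df.to_csv(path, sep=sep, float_format=lambda v: repr(float(v)))


def all_pairs_kc(
    dataset: ExpressionDataset,
    spec: KernelSpec | None = None,
    adjust: Literal["bonferroni", "bh", "none"] = "bonferroni",
    train: bool = False,
) -> pd.DataFrame:
    """K_c for all n(n-1)/2 unordered variable pairs.

    With a single replicate the p-value is the one-sided plug-in t-test on
    T observations; with R >= 2 replicates K_c is computed per replicate and
    the across-replicate one-sample t-test (two-sided) is used. ``train=True``
    replaces the spec's gamma with the replicate-trained value per pair
    (RBF, R >= 2 only). Pairs involving a constant variable are kept in the
    output with NaN value and a warning, and the run continues.
    """
    if dataset.n_variables < 2:
        raise ValueError("need at least 2 variables")
    spec = spec or KernelSpec()
    rows = []
    for va, vb in combinations(dataset.variables, 2):
        pairs = dataset.replicate_pairs(va, vb)
        gamma_used = spec.gamma
        try:
            use_spec = spec
            if train and spec.family == "rbf" and len(pairs) >= 2:
                gamma_used = train_gamma(pairs, standardize=spec.standardize).gamma_star
                use_spec = KernelSpec(family="rbf", gamma=gamma_used,
                                      standardize=spec.standardize)
            if len(pairs) == 1:
                value = kernelized_correlation(pairs[0], use_spec)
                p = plugin_correlation_test(value, pairs[0].T)
            else:
                summ = replicate_ttest(
                    [kernelized_correlation(pr, use_spec) for pr in pairs])
                value, p = summ.mean, summ.p_value
            rows.append((va, vb, use_spec.label, value, p, gamma_used))
        except ValueError as err:
            warnings.warn(f"pair ({va}, {vb}) failed: {err}", RuntimeWarning,
                          stacklevel=2)
            rows.append((va, vb, spec.label, np.nan, np.nan, gamma_used))
        logger.debug("pair %s-%s done", va, vb)
    table = pd.DataFrame(
        rows, columns=["variable_a", "variable_b", "measure", "value",
                       "p_value", "gamma_used"])
    ok = table["p_value"].notna()
    adjusted = np.full(len(table), np.nan)
    if adjust == "none":
        adjusted[ok.to_numpy()] = table.loc[ok, "p_value"]
    else:
        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[adjust]
        if ok.any():
            adjusted[ok.to_numpy()] = multipletests(
                table.loc[ok, "p_value"].to_numpy(), method=method)[1]
    table["p_adjusted"] = adjusted
    logger.info("all-pairs run: %d pairs, %d failed", len(table), int((~ok).sum()))
    return table[["variable_a", "variable_b", "measure", "value", "p_value",
                  "p_adjusted", "gamma_used"]]


# --------------------------------------------------------------------------
# synthetic fixtures


def _sinusoid(t, phase, amplitude=1.0, offset=0.0, period=None):
    period = period or (t[-1] - t[0])
    return amplitude * np.sin(2 * np.pi * (t - phase) / period) + offset


def make_fixtures(kind: str, seed: int = 0) -> ExpressionDataset:
    """Synthetic datasets emulating the shapes of the study's inputs.

    ``th17_like``
        8 variables x 5 time points (0, 12, 24, 48, 72 h) x 3 replicates in
        each of two conditions (Th0-like, Th17-like): an anchor gene, genes
        similar or complementary to it in the second condition only, and two
        condition-invariant genes (identical profiles in both conditions, so
        the self-correlation screen should flag them).
    ``yeast_alpha_like``
        4 variables x 18 time points with two-cycle periodic structure:
        two in-phase genes, one anti-phase gene, one quarter-phase gene.
        The two cycles (t = 1-9 and 10-18) can serve as replicates.
    ``worked_example``
        A synthetic T = 3 pair whose RBF (gamma = 0.5) Gram matrix is
        [[1, 0, 0], [0, 1, 0.988], [0, 0.988, 1]] to three decimals.
    """
    rng = np.random.default_rng(seed)
    if kind == "th17_like":
        t = np.array([0.0, 12.0, 24.0, 48.0, 72.0])
        ramp = t / t[-1]
        anchor = 5 * ramp**2  # accelerating induction, IL17A-like
        profiles_th17 = {
            "ANCHOR": anchor,
            "SIM1": 4 * ramp**2 + 0.5,          # similar pattern
            "SIM2": 5 * np.sin(np.pi * ramp / 2),
            "SIM3": 3 * ramp,
            "COMP1": 5 * (1 - ramp) ** 2,        # complementary pattern
            "COMP2": 4 - 3.5 * ramp,
            "INV1": 2 + np.sin(2 * np.pi * ramp),  # condition-invariant
            "INV2": 1 + ramp * (1 - ramp) * 4,
        }
        flat = 1.0 + 0.2 * ramp
        values = np.empty((8, 5, 6))
        conditions = ["Th0"] * 3 + ["Th17"] * 3
        for i, (name, prof) in enumerate(profiles_th17.items()):
            base_th0 = prof if name.startswith("INV") else flat * prof.mean() / flat.mean()
            for r in range(3):
                values[i, :, r] = base_th0 + 0.05 * prof.std() * rng.standard_normal(5)
                values[i, :, r + 3] = prof + 0.05 * prof.std() * rng.standard_normal(5)
        return ExpressionDataset(list(profiles_th17), list(t), values, conditions)
    if kind == "yeast_alpha_like":
        t = np.arange(0.0, 126.0, 7.0)  # 18 points, two 63-min cycles
        profiles = {
            "CYCA": _sinusoid(t, 0.0, period=63.0),
            "CYCB": _sinusoid(t, 5.0, amplitude=0.8, period=63.0),
            "ANTI": _sinusoid(t, 31.5, amplitude=1.2, period=63.0),
            "QRTR": _sinusoid(t, 15.75, period=63.0),
        }
        values = np.empty((4, 18, 1))
        for i, prof in enumerate(profiles.values()):
            values[i, :, 0] = prof + 0.05 * rng.standard_normal(18)
        return ExpressionDataset(list(profiles), list(t), values)
    if kind == "worked_example":
        # u1 far from u2 and u3; ||u2 - u3||^2 chosen so that
        # exp(-0.5 * ||u2 - u3||^2) = 0.988 exactly
        delta = np.sqrt(-np.log(0.988))  # per-coordinate offset of u3 from u2
        x = np.array([5.0, 0.0, delta])
        y = np.array([-5.0, 0.0, delta])
        return ExpressionDataset(["GX", "GY"], [1, 2, 3],
                                 np.stack([x, y])[:, :, None])
    raise ValueError(f"unknown fixture kind {kind!r}")
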