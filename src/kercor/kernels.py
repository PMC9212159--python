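"""Kernels on paired observations and the kernelized correlation coefficient.

The kernelized correlation K_c of two aligned series x, y of length T is
computed in five steps:

1. optionally z-score each series across time points;
2. form the planar observations u_i = (x_i, y_i);
3. build the T x T Gram matrix K_ij = k(u_i, u_j) for a polynomial or
   Gaussian (RBF) kernel;
4. double-center it, Kc = H K H with H = I - (1/T) 11';
5. plug the kernelized vectors Kc x and Kc y into Pearson's r.

Because H annihilates constant vectors, K_c inherits location invariance from
the centering and, for the RBF kernel, flips sign when one series is negated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "KernelSpec",
    "TimeSeriesPair",
    "KernelizedPair",
    "standardize",
    "polynomial_kernel",
    "rbf_kernel",
    "pair_kernel_matrix",
    "double_center",
    "kernelize",
    "kernelized_correlation",
]

#: variance below this in a kernelized vector is treated as degenerate
_DEGENERATE_VAR = 1e-14


@dataclass(frozen=True)
class TimeSeriesPair:
    """Two aligned numeric series observed at the same T >= 3 time points.

    Time labels are metadata only: the measure uses the order of the
    observations, never their spacing.
    """

    x: np.ndarray
    y: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 3:
            raise ValueError(f"need T >= 3 time points, got T={x.size}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("series contain non-finite values")
        times = self.times
        if times is None:
            times = np.arange(x.size)
        else:
            times = np.asarray(times)
            if times.shape != x.shape:
                raise ValueError("times must match the series length")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "times", times)

    @property
    def T(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters used to build the Gram matrix.

    Parameters
    ----------
    family : {"rbf", "polynomial"}
        Kernel family. The RBF (Gaussian) kernel is
        ``k(u, v) = exp(-gamma * ||u - v||^2)``; the polynomial kernel is
        ``k(u, v) = (1 + <u, v>)^d``.
    gamma : float, optional
        Inverse kernel width, > 0. RBF only. Default 0.5, the rule-of-thumb
        width for similar-patterned (positively correlated) pairs;
        complementary-patterned pairs should use a replicate-trained value.
    degree : int, optional
        Polynomial degree, >= 2. Polynomial only.
    standardize : bool
        Whether each series is z-scored across time points before the Gram
        matrix is built (step 1). Default True.
    """

    family: Literal["rbf", "polynomial"] = "rbf"
    gamma: float | None = None
    degree: int | None = None
    standardize: bool = True

    def __post_init__(self):
        if self.family == "rbf":
            if self.degree is not None:
                raise ValueError("degree is a polynomial-kernel parameter")
            gamma = 0.5 if self.gamma is None else float(self.gamma)
            if not gamma > 0:
                raise ValueError(f"gamma must be > 0, got {gamma}")
            object.__setattr__(self, "gamma", gamma)
        elif self.family == "polynomial":
            if self.gamma is not None:
                raise ValueError("gamma is an RBF-kernel parameter")
            degree = 2 if self.degree is None else int(self.degree)
            if degree < 2:
                raise ValueError(f"degree must be >= 2, got {degree}")
            object.__setattr__(self, "degree", degree)
        else:
            raise ValueError(f"unknown kernel family {self.family!r}")

    @property
    def label(self) -> str:
        if self.family == "rbf":
            return f"K_c-RBF(gamma={self.gamma:g})"
        return f"K_c-poly{self.degree}"


@dataclass(frozen=True)
class KernelizedPair:
    """Gram matrix, its double-centered form, and the kernelized vectors."""

    u: np.ndarray  # (T, 2) planar observations after optional z-scoring
    K: np.ndarray  # (T, T) Gram matrix
    Kc: np.ndarray  # (T, T) double-centered Gram matrix
    xk: np.ndarray  # Kc @ x
    yk: np.ndarray  # Kc @ y


def standardize(series: Sequence[float] | np.ndarray) -> np.ndarray:
    """Z-score a series: subtract the mean, divide by the sample sd (T-1).

    Raises
    ------
    ValueError
        If the series is constant (zero sample variance), which would make
        the z-score undefined.
    """
    v = np.asarray(series, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("standardize expects a 1-D series with T >= 3")
    sd = v.std(ddof=1)
    if not sd > 0:
        raise ValueError("constant series: zero variance, cannot standardize")
    return (v - v.mean()) / sd


def polynomial_kernel(u, v, degree: int) -> float:
    """Polynomial kernel (1 + <u, v>)^degree on points in the plane."""
    if degree < 2:
        raise ValueError(f"degree must be >= 2, got {degree}")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return float((1.0 + u @ v) ** degree)


def rbf_kernel(u, v, gamma: float) -> float:
    """Gaussian (RBF) kernel exp(-gamma * ||u - v||^2); in (0, 1].

    Underflows cleanly to 0.0 for very distant points.
    """
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    d = np.asarray(u, dtype=float) - np.asarray(v, dtype=float)
    return float(np.exp(-gamma * (d @ d)))


def _prepared_series(pair: TimeSeriesPair, spec: KernelSpec):
    if spec.standardize:
        return standardize(pair.x), standardize(pair.y)
    return pair.x.copy(), pair.y.copy()


def _gram(u: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.family == "rbf":
        sq = ((u[:, None, :] - u[None, :, :]) ** 2).sum(axis=-1)
        K = np.exp(-spec.gamma * sq)
    else:
        K = (1.0 + u @ u.T) ** spec.degree
    # enforce exact symmetry against floating-point asymmetry
    return (K + K.T) / 2.0


def pair_kernel_matrix(pair: TimeSeriesPair, spec: KernelSpec) -> KernelizedPair:
    """Build the Gram matrix of the planar observations u_i = (x_i, y_i).

    Returns a :class:`KernelizedPair` with only ``u`` and ``K`` meaningful;
    use :func:`kernelize` for the centered matrix and kernelized vectors.
    """
    xs, ys = _prepared_series(pair, spec)
    u = np.column_stack([xs, ys])
    K = _gram(u, spec)
    T = pair.T
    return KernelizedPair(u=u, K=K, Kc=np.full((T, T), np.nan), xk=np.full(T, np.nan), yk=np.full(T, np.nan))


def double_center(K: np.ndarray) -> np.ndarray:
    """Double-center a square matrix: Kc = H K H with H = I - (1/T) 11'.

    Every row and column of the result sums to zero. Implemented via the
    equivalent entrywise form K_ij - rowmean_i - colmean_j + grandmean,
    which is O(T^2) instead of two matrix products.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"double_center expects a square matrix, got shape {K.shape}")
    row = K.mean(axis=1, keepdims=True)
    col = K.mean(axis=0, keepdims=True)
    return K - row - col + K.mean()


def kernelize(pair: TimeSeriesPair, spec: KernelSpec) -> KernelizedPair:
    """Run steps 1-5's data part: Gram matrix, centering, kernelized vectors."""
    xs, ys = _prepared_series(pair, spec)
    u = np.column_stack([xs, ys])
    K = _gram(u, spec)
    Kc = double_center(K)
    return KernelizedPair(u=u, K=K, Kc=Kc, xk=Kc @ xs, yk=Kc @ ys)


def kernelized_correlation(
    pair: TimeSeriesPair,
    spec: KernelSpec | None = None,
    base: Literal["pearson"] = "pearson",
) -> float:
    """The kernelized correlation coefficient K_c of a pair of series.

    Pearson's r of the kernelized vectors Kc x and Kc y. Values lie in
    [-1, 1]; positive (negative) values indicate a similar (complementary)
    temporal pattern, including nonlinear ones.

    Parameters
    ----------
    pair : TimeSeriesPair
    spec : KernelSpec, optional
        Defaults to the RBF kernel with gamma = 0.5 and standardization on.
    base : {"pearson"}
        The plug-in correlation applied to the kernelized vectors. Only
        Pearson is implemented; the argument exists for extension.

    Raises
    ------
    ValueError
        If either kernelized vector is (numerically) constant, e.g. when the
        kernel collapses all observations to the same point.
    """
    if base != "pearson":
        raise NotImplementedError(f"base correlation {base!r} not implemented")
    if spec is None:
        spec = KernelSpec()
    kp = kernelize(pair, spec)
    vx = kp.xk.var()
    vy = kp.yk.var()
    if vx < _DEGENERATE_VAR or vy < _DEGENERATE_VAR:
        raise ValueError(
            "degenerate kernelization: a kernelized vector is numerically "
            f"constant (var(xk)={vx:.3g}, var(yk)={vy:.3g})"
        )
    xc = kp.xk - kp.xk.mean()
    yc = kp.yk - kp.yk.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return float(np.clip(r, -1.0, 1.0))
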