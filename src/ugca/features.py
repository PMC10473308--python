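"""Lagged design matrices and their nonlinear expansions.

The nonlinear modeling procedure approximates an unknown coupling function
by a truncated Taylor-style decomposition: the design for a target variable
concatenates (a) plain lagged copies of every predictor, (b) elementwise
powers 2..s of each lag column (the high-order term), and (c) instantaneous
products of the target's and each other predictor's lag-1 columns (the
cross-term). With s=1 and cross-terms off this reduces exactly to the linear
vector-autoregressive design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import TimeSeriesPanel

__all__ = [
    "NonlinearSpec",
    "DesignMatrix",
    "build_lag_matrix",
    "expand_polynomial",
    "build_cross_terms",
    "assemble_design",
]


@dataclass(frozen=True)
class NonlinearSpec:
    """Degrees of freedom of the model family.

    max_lag : scan ceiling for the time-lag of every predictor block.
    poly_order : polynomial order s; each lag column contributes powers 1..s.
    include_cross : append lag-1 x lag-1 cross products between the target
        and each other predictor.
    cross_all_lags : also append matched-lag products up to the block lag
        (off by default; the default cross-term is lag-1 only).
    """

    max_lag: int = 5
    poly_order: int = 2
    include_cross: bool = True
    cross_all_lags: bool = False

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")

    @property
    def is_linear(self) -> bool:
        return self.poly_order == 1 and not self.include_cross


LINEAR_SPEC = NonlinearSpec(poly_order=1, include_cross=False)


@dataclass
class DesignMatrix:
    """A response vector, its regressor matrix, and per-column provenance.

    Column tags are tuples: ``("lin", var, lag)``, ``("pow", var, lag, p)``
    with p >= 2, or ``("cross", target, var, lag)``.
    """

    response: np.ndarray
    regressors: np.ndarray
    column_tags: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2 or self.regressors.shape[0] != len(self.response):
            raise ValueError("regressors must be m x k with m matching the response")
        if len(self.column_tags) != self.regressors.shape[1]:
            raise ValueError("one tag per regressor column required")
        if self.m <= self.k:
            raise ValueError(
                f"under-determined design: m={self.m} <= k={self.k}"
            )

    @property
    def m(self) -> int:
        return len(self.response)

    @property
    def k(self) -> int:
        return self.regressors.shape[1]

    @property
    def max_lag(self) -> int:
        return max((tag[2] if tag[0] != "cross" else tag[3] for tag in self.column_tags), default=0)


def build_lag_matrix(series: np.ndarray, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Response/regressor split of a univariate autoregression.

    Row t of the result pairs observation t with its ``lag`` predecessors:
    column ell holds the series shifted back by ell, for ell = 1..lag.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    n = len(series)
    if lag >= n:
        raise ValueError(f"lag {lag} >= series length {n}")
    response = series[lag:]
    columns = np.column_stack([series[lag - ell : n - ell] for ell in range(1, lag + 1)])
    return response, columns


def expand_polynomial(
    lag_columns: np.ndarray, poly_order: int
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Powers 1..s of each lag column, lag-major then power.

    Returns the expanded matrix and ``(lag, power)`` tags (lags numbered
    1..L in column order of the input).
    """
    if poly_order < 1:
        raise ValueError("poly_order must be >= 1")
    lag_columns = np.atleast_2d(np.asarray(lag_columns, dtype=float))
    if lag_columns.shape[1] == 0:
        return lag_columns.copy(), []
    blocks, tags = [], []
    for ell in range(lag_columns.shape[1]):
        col = lag_columns[:, ell]
        for p in range(1, poly_order + 1):
            blocks.append(col**p)
            tags.append((ell + 1, p))
    return np.column_stack(blocks), tags


def build_cross_terms(
    lag_columns_x: np.ndarray,
    lag_columns_y: np.ndarray,
    all_lags: bool = False,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Instantaneous products of matching lag columns of two variables.

    By default only the lag-1 x lag-1 product is emitted; with
    ``all_lags=True`` every matched lag up to the shorter block is included.
    Tags are ``(lag, lag)`` pairs.
    """
    x = np.atleast_2d(np.asarray(lag_columns_x, dtype=float))
    y = np.atleast_2d(np.asarray(lag_columns_y, dtype=float))
    if x.shape[1] == 0 or y.shape[1] == 0:
        raise ValueError("both inputs must have at least one lag column")
    if x.shape[0] != y.shape[0]:
        raise ValueError("row-count mismatch between lag blocks")
    n_lags = min(x.shape[1], y.shape[1]) if all_lags else 1
    cols = np.column_stack([x[:, ell] * y[:, ell] for ell in range(n_lags)])
    tags = [(ell + 1, ell + 1) for ell in range(n_lags)]
    return cols, tags


def assemble_design(
    target: str,
    predictors: list[str],
    panel: TimeSeriesPanel,
    spec: NonlinearSpec,
    lags: int | dict[str, int],
    align_lag: int | None = None,
) -> DesignMatrix:
    """Full design for predicting ``target`` from the given predictor set.

    ``lags`` is either one shared lag for every predictor block or a
    per-predictor mapping. ``align_lag`` fixes the number of leading rows
    dropped (so that competing models for one target share the exact same
    response window); it defaults to the largest lag used and must be at
    least that.

    Column order: all linear lag columns (target's own history first, then
    the remaining predictors in the given order), then powers 2..s of each
    lag column in the same order, then the cross columns between the target
    and each non-target predictor.
    """
    if target not in panel.names:
        raise KeyError(f"target {target!r} not in panel")
    order = [target] + [p for p in predictors if p != target]
    for p in order:
        if p not in panel.names:
            raise KeyError(f"predictor {p!r} not in panel")
    lag_of = {p: (lags if isinstance(lags, int) else lags[p]) for p in order}
    for p, ell in lag_of.items():
        if not 1 <= ell <= spec.max_lag:
            raise ValueError(f"lag {ell} for {p!r} outside 1..{spec.max_lag}")
    drop = max(lag_of.values()) if align_lag is None else align_lag
    if drop < max(lag_of.values()):
        raise ValueError("align_lag must be >= the largest lag used")
    n = panel.n_time
    if drop >= n:
        raise ValueError("alignment lag exceeds series length")

    response = panel.series(target)[drop:]
    lin_cols, lin_tags = [], []
    for p in order:
        x = panel.series(p)
        for ell in range(1, lag_of[p] + 1):
            lin_cols.append(x[drop - ell : n - ell])
            lin_tags.append(("lin", p, ell))
    pow_cols, pow_tags = [], []
    if spec.poly_order >= 2:
        for col, (_, p, ell) in zip(lin_cols, lin_tags):
            for pw in range(2, spec.poly_order + 1):
                pow_cols.append(col**pw)
                pow_tags.append(("pow", p, ell, pw))
    cross_cols, cross_tags = [], []
    if spec.include_cross:
        xt = panel.series(target)
        for p in order[1:]:
            xp = panel.series(p)
            n_cross = min(lag_of[target], lag_of[p]) if spec.cross_all_lags else 1
            for ell in range(1, n_cross + 1):
                cross_cols.append(
                    xt[drop - ell : n - ell] * xp[drop - ell : n - ell]
                )
                cross_tags.append(("cross", target, p, ell))

    regressors = np.column_stack(lin_cols + pow_cols + cross_cols)
    tags = lin_tags + pow_tags + cross_tags
    if len(response) <= regressors.shape[1]:
        raise ValueError(
            f"under-determined model for target {target!r}: "
            f"m={len(response)} <= k={regressors.shape[1]} at lags={lag_of}, "
            f"s={spec.poly_order}"
        )
    return DesignMatrix(response=response, regressors=regressors, column_tags=tags)
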