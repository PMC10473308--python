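"""Conventional two-stage conditional Granger causality analysis.

The baseline against which the description-length approach is compared:
(1) select each model's lag order by an information criterion (BIC by
default, AIC selectable), then (2) decide each directed effect with a
nested-model F-test at a user-chosen confidence level. The same nonlinear
design construction (polynomial powers and lag-1 cross-terms) is used as in
the uGCA modules, so the comparison isolates the decision machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .features import NonlinearSpec
from .inference import CausalNetwork, PanelCache, _fast_fit
from .simulate import TimeSeriesPanel

__all__ = [
    "FTestResult",
    "select_order_ic",
    "gca_conditional_test",
    "infer_network_gca",
]


@dataclass(frozen=True)
class FTestResult:
    """Outcome of one conditional nested-model F-test.

    ``gc_index`` is the log residual-variance ratio ln(var eps_restricted /
    var eps_unrestricted); the effect is declared iff ``p_value < alpha``.
    """

    statistic: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float
    gc_index: float

    @property
    def declared(self) -> bool:
        return self.p_value < self.alpha


def _ic_value(rss: float, m: int, k: int, criterion: str) -> float:
    nll_core = m * np.log(max(rss, 1e-300) / m)
    if criterion == "bic":
        return nll_core + k * np.log(m)
    if criterion == "aic":
        return nll_core + 2.0 * k
    raise ValueError(f"unknown criterion {criterion!r}")


def select_order_ic(
    target: str,
    predictors: list[str],
    panel: TimeSeriesPanel,
    spec: NonlinearSpec = NonlinearSpec(),
    criterion: str = "bic",
    _cache: PanelCache | None = None,
    min_lag: int = 1,
) -> int:
    """Information-criterion lag order for (target | own + predictors).

    Scans the shared lag 1..max_lag (or ``min_lag``..max_lag) and returns the
    argmin of the criterion; ties break toward the smaller lag.
    """
    cache = _cache if _cache is not None else PanelCache(panel, spec)
    others = [p for p in predictors if p != target]
    best = None
    for ell in range(min_lag, spec.max_lag + 1):
        y, V = cache.design(target, others, ell)
        if V.shape[0] <= V.shape[1]:
            continue
        fit = _fast_fit(y, V)
        value = _ic_value(fit.rss, fit.m, fit.k, criterion)
        if best is None or value < best[0]:
            best = (value, ell)
    if best is None:
        raise ValueError(f"no admissible lag for target {target!r}")
    return best[1]


def gca_conditional_test(
    target: str,
    source: str,
    conditioning: set[str],
    panel: TimeSeriesPanel,
    spec: NonlinearSpec = NonlinearSpec(),
    alpha: float = 0.05,
    criterion: str = "bic",
    _cache: PanelCache | None = None,
) -> FTestResult:
    """Conditional GCA F-test of source -> target given the conditioning set.

    Restricted model: target's own history plus the conditioning set;
    unrestricted: the same plus the source. Both orders are selected by the
    information criterion; when the freely selected unrestricted order would
    break nesting (fewer regressors than the restricted model), it is
    re-selected over lags >= the restricted order so the F-test's nesting
    assumption holds. Both models are fitted on the common response window.
    """
    cache = _cache if _cache is not None else PanelCache(panel, spec)
    cond = sorted(set(conditioning) - {target, source})
    lag_r = select_order_ic(target, cond, panel, spec, criterion, _cache=cache)
    lag_u = select_order_ic(target, cond + [source], panel, spec, criterion, _cache=cache)
    if lag_u < lag_r:
        lag_u = select_order_ic(
            target, cond + [source], panel, spec, criterion, _cache=cache, min_lag=lag_r
        )
    y, V_r = cache.design(target, cond, lag_r)
    _, V_u = cache.design(target, cond + [source], lag_u)
    fit_r = _fast_fit(y, V_r)
    fit_u = _fast_fit(y, V_u)
    q = fit_u.k - fit_r.k
    if q <= 0:
        raise ValueError(
            f"unrestricted model is not a superset (k_u={fit_u.k} <= k_r={fit_r.k})"
        )
    df_den = fit_u.m - fit_u.k
    rss_u = max(fit_u.rss, 1e-300)
    statistic = ((fit_r.rss - fit_u.rss) / q) / (rss_u / df_den)
    statistic = max(statistic, 0.0)
    p_value = float(stats.f.sf(statistic, q, df_den))
    return FTestResult(
        statistic=float(statistic),
        df_num=q,
        df_den=df_den,
        p_value=p_value,
        alpha=alpha,
        gc_index=float(np.log(max(fit_r.rss, 1e-300) / rss_u)),
    )


def infer_network_gca(
    panel: TimeSeriesPanel,
    spec: NonlinearSpec = NonlinearSpec(),
    alpha: float = 0.05,
    criterion: str = "bic",
) -> CausalNetwork:
    """Whole-network conditional GCA.

    Each ordered pair (source, target) is tested conditioning on all
    remaining nodes; an edge is drawn iff the F-test declares it at alpha.
    """
    cache = PanelCache(panel, spec)
    names = list(panel.names)
    idx = {n: i for i, n in enumerate(names)}
    adj = np.zeros((len(names), len(names)), dtype=bool)
    scores = np.full((len(names), len(names)), np.nan)
    for target in names:
        for source in names:
            if source == target:
                continue
            cond = set(names) - {source, target}
            res = gca_conditional_test(
                target, source, cond, panel, spec, alpha, criterion, _cache=cache
            )
            if res.declared:
                adj[idx[source], idx[target]] = True
                scores[idx[source], idx[target]] = res.gc_index
    return CausalNetwork(
        adjacency=adj,
        names=tuple(names),
        scores=scores,
        method=f"gca-{criterion}-a{alpha}",
        spec={
            "max_lag": spec.max_lag,
            "poly_order": spec.poly_order,
            "include_cross": spec.include_cross,
            "alpha": alpha,
        },
    )
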