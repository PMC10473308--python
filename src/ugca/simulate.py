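"""Synthetic coupled dynamical systems for benchmarking causal discovery.

Provides the three-node system (a linear vector-autoregressive backbone plus
variants augmented with squared-lag terms or instantaneous cross-terms), a
six-node system mixing Gaussian-modulated autoregression, tanh couplings and
pairwise product terms, and a generic user-specified recursion simulator.
All generators draw i.i.d. zero-mean Gaussian innovations, discard a burn-in
segment, and are bit-reproducible given (seed, config).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "SimulationConfig",
    "TimeSeriesPanel",
    "GroundTruthNetwork",
    "DivergenceError",
    "simulate_three_node",
    "simulate_six_node",
    "simulate_custom",
    "three_node_ground_truth",
    "six_node_ground_truth",
    "check_stationarity",
    "generate_ensemble",
]

#: any trajectory value beyond this magnitude is treated as divergent
DIVERGENCE_BOUND = 1e6
#: capped number of fresh sub-seeds tried when a trajectory diverges
MAX_RETRIES = 20


class DivergenceError(RuntimeError):
    """Raised when a simulated trajectory keeps diverging after capped retries."""


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one synthetic ensemble.

    Parameters
    ----------
    n_time : int
        Number of post-burn-in samples per series (>= 50).
    noise_variance : float
        Variance of each innovation term (> 0).
    seed : int
        Master seed; all sub-streams derive from it deterministically.
    burn_in : int
        Initial samples discarded to wash out the initial condition.
    n_reps : int
        Number of independent replicates when generating an ensemble.
    """

    n_time: int
    noise_variance: float
    seed: int
    burn_in: int = 200
    n_reps: int = 1

    def __post_init__(self) -> None:
        if self.n_time < 50:
            raise ValueError(f"n_time must be >= 50, got {self.n_time}")
        if self.noise_variance <= 0:
            raise ValueError("noise_variance must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class TimeSeriesPanel:
    """A finite multivariate time series: rows are time points, columns variables."""

    values: np.ndarray
    names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (time x variables)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel contains non-finite values")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("one name per column required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("variable names must be unique")
        if self.values.shape[0] <= self.values.shape[1]:
            raise ValueError("need more time points than variables")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def series(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Boolean directed adjacency; entry (i, j) true iff variable i drives j."""

    adjacency: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (len(self.names), len(self.names)):
            raise ValueError("adjacency must be square over the node names")
        if adj.diagonal().any():
            raise ValueError("self-loops are excluded")
        object.__setattr__(self, "adjacency", adj)

    @property
    def edges(self) -> set[tuple[str, str]]:
        idx = np.argwhere(self.adjacency)
        return {(self.names[i], self.names[j]) for i, j in idx}


# ---------------------------------------------------------------------------
# Term-based recursion engine
# ---------------------------------------------------------------------------
# A model is a mapping {variable: [term, ...]}; each term is a dict with
#   coef       : float
#   sources    : list of variable names
#   lags       : list of positive ints, same length as sources
#   transform  : identity | square | power | product | tanh | gauss_mod
#   power      : int exponent (transform == "power" only)
# identity/square/power/tanh/gauss_mod take a single (source, lag);
# product multiplies the lagged values of all listed (source, lag) pairs.

_SINGLE_TRANSFORMS = {
    "identity": lambda v: v,
    "square": lambda v: v * v,
    "tanh": math.tanh,
    "gauss_mod": lambda v: v * math.exp(-v * v),
}


def _validate_model_spec(model_spec: dict) -> None:
    names = set(model_spec)
    for var, terms in model_spec.items():
        for term in terms:
            missing = {"coef", "sources", "lags", "transform"} - set(term)
            if missing:
                raise ValueError(f"term for {var!r} missing fields {sorted(missing)}")
            if len(term["sources"]) != len(term["lags"]):
                raise ValueError(f"term for {var!r}: sources/lags length mismatch")
            for src in term["sources"]:
                if src not in names:
                    raise ValueError(f"term for {var!r} references unknown variable {src!r}")
            for lag in term["lags"]:
                if not (isinstance(lag, (int, np.integer)) and lag >= 1):
                    raise ValueError(f"term for {var!r}: lags must be positive integers")
            tr = term["transform"]
            if tr not in _SINGLE_TRANSFORMS and tr not in ("power", "product"):
                raise ValueError(f"unknown transform {tr!r}")
            if tr == "power" and "power" not in term:
                raise ValueError("power transform requires a 'power' field")
            if tr != "product" and len(term["sources"]) != 1:
                raise ValueError(f"transform {tr!r} takes exactly one source")


def _term_value(term: dict, hist: np.ndarray, cols: dict[str, int], t: int) -> float:
    tr = term["transform"]
    if tr == "product":
        out = 1.0
        for src, lag in zip(term["sources"], term["lags"]):
            out *= hist[t - lag, cols[src]]
        return term["coef"] * out
    v = hist[t - term["lags"][0], cols[term["sources"][0]]]
    if tr == "power":
        return term["coef"] * v ** term["power"]
    return term["coef"] * _SINGLE_TRANSFORMS[tr](v)


def _model_max_lag(model_spec: dict) -> int:
    lags = [lag for terms in model_spec.values() for term in terms for lag in term["lags"]]
    return max(lags, default=1)


def _run_recursion(
    model_spec: dict, config: SimulationConfig, spawn_key: tuple[int, ...]
) -> TimeSeriesPanel:
    """Simulate once; retry with fresh sub-seeds on divergence, capped."""
    names = list(model_spec)
    cols = {name: i for i, name in enumerate(names)}
    p = _model_max_lag(model_spec)
    total = config.n_time + config.burn_in + p
    sd = math.sqrt(config.noise_variance)

    for attempt in range(MAX_RETRIES + 1):
        ss = np.random.SeedSequence(config.seed, spawn_key=tuple(spawn_key) + (attempt,))
        rng = np.random.default_rng(ss)
        hist = np.empty((total, len(names)))
        hist[:p] = rng.normal(0.0, sd, size=(p, len(names)))
        eps = rng.normal(0.0, sd, size=(total - p, len(names)))
        diverged = False
        for t in range(p, total):
            for j, name in enumerate(names):
                acc = eps[t - p, j]
                for term in model_spec[name]:
                    acc += _term_value(term, hist, cols, t)
                hist[t, j] = acc
            if np.max(np.abs(hist[t])) > DIVERGENCE_BOUND:
                diverged = True
                break
        if not diverged:
            return TimeSeriesPanel(
                values=hist[p + config.burn_in :].copy(),
                names=names,
                meta={
                    "seed": config.seed,
                    "spawn_key": tuple(spawn_key),
                    "retries": attempt,
                    "noise_variance": config.noise_variance,
                },
            )
    raise DivergenceError(
        f"trajectory diverged in all {MAX_RETRIES + 1} attempts (spawn_key={spawn_key})"
    )


def _spec_ground_truth(model_spec: dict) -> GroundTruthNetwork:
    names = list(model_spec)
    idx = {n: i for i, n in enumerate(names)}
    adj = np.zeros((len(names), len(names)), dtype=bool)
    for var, terms in model_spec.items():
        for term in terms:
            for src in term["sources"]:
                if src != var:
                    adj[idx[src], idx[var]] = True
    return GroundTruthNetwork(adjacency=adj, names=tuple(names))


# ---------------------------------------------------------------------------
# Three-node system
# ---------------------------------------------------------------------------

def _lin(coef: float, src: str, lag: int = 1) -> dict:
    return {"coef": coef, "sources": [src], "lags": [lag], "transform": "identity"}


def _sq(coef: float, src: str, lag: int = 1) -> dict:
    return {"coef": coef, "sources": [src], "lags": [lag], "transform": "square"}


def _prod(coef: float, srcs: list[str], lags: list[int]) -> dict:
    return {"coef": coef, "sources": srcs, "lags": lags, "transform": "product"}


def _three_node_spec(variant: str) -> dict:
    # shared linear backbone
    spec = {
        "X1": [_lin(0.35, "X1"), _lin(0.34, "X2")],
        "X2": [_lin(0.39, "X2"), _lin(-0.36, "X1")],
        "X3": [_lin(-0.37, "X3"), _lin(0.34, "X1"), _lin(0.35, "X2")],
    }
    if variant == "linear":
        return spec
    if variant == "high_order":
        spec["X1"] += [_sq(-0.14, "X1"), _sq(-0.14, "X2")]
        spec["X2"] += [_sq(-0.24, "X1"), _sq(0.24, "X2")]
        spec["X3"] += [_sq(0.22, "X3"), _sq(-0.21, "X1"), _sq(-0.20, "X2")]
        return spec
    if variant == "cross":
        spec["X1"] += [_prod(-0.14, ["X1", "X2"], [1, 1])]
        spec["X2"] += [_prod(-0.24, ["X1", "X2"], [1, 1])]
        spec["X3"] += [_prod(0.21, ["X1", "X3"], [1, 1]), _prod(-0.20, ["X2", "X3"], [1, 1])]
        return spec
    raise ValueError(f"unknown three-node variant {variant!r}")


def three_node_ground_truth() -> GroundTruthNetwork:
    """True edge set of every three-node variant: {1→2, 2→1, 1→3, 2→3}."""
    return _spec_ground_truth(_three_node_spec("linear"))


def simulate_three_node(
    config: SimulationConfig,
    variant: str = "linear",
    spawn_key: tuple[int, ...] = (0,),
) -> TimeSeriesPanel:
    """Simulate the three-node coupled system.

    ``variant`` selects the plain linear backbone (``"linear"``), the variant
    augmented with squared-lag terms (``"high_order"``), or the variant
    augmented with instantaneous lag-1 cross products (``"cross"``).
    """
    panel = _run_recursion(_three_node_spec(variant), config, spawn_key)
    panel.meta["system"] = f"three_node_{variant}"
    return panel


# ---------------------------------------------------------------------------
# Six-node system
# ---------------------------------------------------------------------------

def _gauss(coef: float, src: str, lag: int = 1) -> dict:
    return {"coef": coef, "sources": [src], "lags": [lag], "transform": "gauss_mod"}


def _tanh(coef: float, src: str, lag: int = 1) -> dict:
    return {"coef": coef, "sources": [src], "lags": [lag], "transform": "tanh"}


def _six_node_spec() -> dict:
    return {
        "Y1": [_gauss(0.85, "Y1"), _lin(-0.34, "Y1", 2), _lin(0.35, "Y2", 2)],
        "Y2": [_gauss(0.96, "Y2"), _lin(-0.34, "Y2", 2), _lin(0.86, "Y1")],
        "Y3": [_lin(0.82, "Y3"), _lin(-0.36, "Y3", 2), _lin(0.81, "Y1"), _lin(-0.32, "Y1", 2)],
        "Y4": [_gauss(0.88, "Y4"), _lin(0.32, "Y4", 2), _tanh(0.89, "Y2"), _tanh(-0.84, "Y5")],
        "Y5": [
            _gauss(0.82, "Y5"),
            _lin(-0.59, "Y5", 2),
            _prod(-0.48, ["Y2", "Y4"], [1, 1]),
            _prod(0.43, ["Y2", "Y5"], [1, 1]),
            _prod(0.45, ["Y4", "Y5"], [1, 1]),
        ],
        "Y6": [
            _gauss(0.85, "Y6"),
            _lin(0.26, "Y6", 2),
            _lin(0.82, "Y3"),
            _lin(-0.55, "Y5"),
            _prod(0.22, ["Y3", "Y5"], [1, 1]),
        ],
    }


def six_node_ground_truth() -> GroundTruthNetwork:
    """True edge set of the six-node system (9 of the 30 ordered pairs)."""
    return _spec_ground_truth(_six_node_spec())


def simulate_six_node(
    config: SimulationConfig, spawn_key: tuple[int, ...] = (0,)
) -> TimeSeriesPanel:
    """Simulate the six-node system (Gaussian-modulated AR self-terms,
    tanh couplings, and pairwise lag-1 product terms)."""
    panel = _run_recursion(_six_node_spec(), config, spawn_key)
    panel.meta["system"] = "six_node"
    return panel


def simulate_custom(
    model_spec: dict, config: SimulationConfig, spawn_key: tuple[int, ...] = (0,)
) -> tuple[TimeSeriesPanel, GroundTruthNetwork]:
    """Simulate a user-specified recursion.

    ``model_spec`` maps each variable name to a list of additive terms; see
    the term grammar documented at the top of this module. Returns the panel
    together with the ground-truth network derived from term dependencies.
    """
    _validate_model_spec(model_spec)
    panel = _run_recursion(model_spec, config, spawn_key)
    panel.meta["system"] = "custom"
    return panel, _spec_ground_truth(model_spec)


# ---------------------------------------------------------------------------
# Stationarity screening and ensembles
# ---------------------------------------------------------------------------

def check_stationarity(
    panel: TimeSeriesPanel, alpha: float = 0.05, max_lag: int | None = 10
) -> dict:
    """Augmented Dickey-Fuller screen, one unit-root test per series.

    A series passes when the unit-root null is rejected at ``alpha``;
    constant (zero-variance) series are flagged degenerate and fail.
    Returns ``{"passes": bool, "series": {name: {...}}}``.
    """
    report: dict = {"series": {}}
    all_pass = True
    for name in panel.names:
        x = panel.series(name)
        if len(x) < 30:
            raise ValueError("each series must have length >= 30")
        if np.ptp(x) == 0.0:
            report["series"][name] = {"pvalue": 1.0, "reject": False, "degenerate": True}
            all_pass = False
            continue
        maxlag = min(max_lag, len(x) // 2 - 2) if max_lag is not None else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, pvalue = adfuller(x, maxlag=maxlag, autolag="AIC")[:2]
        reject = bool(pvalue < alpha)
        report["series"][name] = {
            "statistic": float(stat),
            "pvalue": float(pvalue),
            "reject": reject,
            "degenerate": False,
        }
        all_pass = all_pass and reject
    report["passes"] = all_pass
    return report


def generate_ensemble(
    generator,
    config: SimulationConfig,
    alpha: float = 0.05,
    max_screen_retries: int = 20,
) -> tuple[list[TimeSeriesPanel], int]:
    """Generate ``config.n_reps`` independent, stationarity-screened panels.

    ``generator`` is a callable ``(config, spawn_key) -> TimeSeriesPanel``
    (e.g. ``simulate_six_node`` or ``functools.partial``-bound variants).
    Panels failing the ADF screen are regenerated with fresh sub-seeds; the
    total regeneration count is returned alongside the panels. Sub-seeds
    derive from (master seed, replicate index, attempt), so the ensemble is
    reproducible under partial re-runs.
    """
    panels: list[TimeSeriesPanel] = []
    regenerated = 0
    for rep in range(config.n_reps):
        for attempt in range(max_screen_retries + 1):
            panel = generator(config, spawn_key=(rep, attempt))
            if check_stationarity(panel, alpha=alpha)["passes"]:
                panels.append(panel)
                break
            regenerated += 1
        else:
            raise RuntimeError(
                f"replicate {rep}: stationarity screen failed "
                f"{max_screen_retries + 1} times"
            )
    return panels, regenerated
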