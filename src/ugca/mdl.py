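"""Least-squares fitting and description-length (MDL) model scoring.

Two coding schemes are provided. The two-part code splits the length into a
Gaussian negative log-likelihood at the MLE noise variance plus an explicit
parameter-literal term at precision delta (optimal delta = 1/n; parameters
with |xi|/delta < 1 are free to encode). The normalized maximum likelihood
(NML) code replaces the parameter literal with the parametric complexity of
the regression family, obtained from the Fisher-information integral over
the ball beta' S beta <= R:

    L_NML = (m/2) ln(2 pi tau) + RSS/(2 tau)
          + (k/2) ln(m/2) - ln Gamma(k/2) + (k/2) ln(R_hat / tau0) - 2 ln k

with tau = tau0 = RSS/m and R_hat = beta' V'V beta / m at the MLE, so the
likelihood part reduces to (m/2) ln(2 pi RSS/m) + m/2. All lengths are in
nats; only differences between models of the same target on the same
response window are meaningful.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .features import DesignMatrix

__all__ = [
    "RegressionFit",
    "CodeLength",
    "fit_lsq",
    "length_two_part",
    "length_nml",
    "select_model",
]

#: relative RSS floor, applied as eps = RSS_FLOOR * m * var(response)
RSS_FLOOR = 1e-12


@dataclass
class RegressionFit:
    """Least-squares solution plus the quantities the code lengths need.

    ``r_hat`` is the per-sample fitted signal energy beta' V'V beta / m;
    ``tau_hat`` the MLE noise variance RSS/m; ``gram`` the k x k matrix V'V
    (optional, not needed by the code lengths themselves).
    """

    beta_hat: np.ndarray
    rss: float
    m: int
    k: int
    r_hat: float
    response_var: float
    gram: np.ndarray | None = None
    rank: int | None = None

    @property
    def tau_hat(self) -> float:
        return self.rss / self.m


@dataclass(frozen=True)
class CodeLength:
    """A description length in nats, tagged with its coding scheme.

    Lengths are comparable only across models of the same target fitted on
    the same response window (identical m).
    """

    nats: float
    scheme: str
    model_id: dict = field(default_factory=dict)


def _lstsq_stats(y: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, float, float, int]:
    beta, _, rank, _ = np.linalg.lstsq(V, y, rcond=None)
    fitted = V @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    r_hat = float(fitted @ fitted) / len(y)
    return beta, rss, r_hat, int(rank)


def fit_lsq(design: DesignMatrix, compute_gram: bool = True) -> RegressionFit:
    """Least-squares fit of a design matrix.

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning. Residuals are orthogonal to every regressor column up to
    numerical tolerance.
    """
    y, V = design.response, design.regressors
    beta, rss, r_hat, rank = _lstsq_stats(y, V)
    if rank < design.k:
        warnings.warn(
            f"rank-deficient design (rank {rank} < k {design.k}); "
            "using the minimum-norm solution",
            stacklevel=2,
        )
    return RegressionFit(
        beta_hat=beta,
        rss=rss,
        m=design.m,
        k=design.k,
        r_hat=r_hat,
        response_var=float(np.var(y)),
        gram=V.T @ V if compute_gram else None,
        rank=rank,
    )


def _effective_rss(fit: RegressionFit) -> float:
    """RSS clamped away from zero so exact fits don't yield -inf lengths."""
    eps = RSS_FLOOR * fit.m * fit.response_var
    rss = max(fit.rss, eps)
    if rss <= 0.0:
        raise ValueError("degenerate likelihood: RSS and response variance are zero")
    return rss


def _gaussian_nll(rss: float, m: int) -> float:
    # (m/2) ln(2 pi tau) + RSS / (2 tau) at tau = RSS/m
    return 0.5 * m * math.log(2.0 * math.pi * rss / m) + 0.5 * m


def length_two_part(
    fit: RegressionFit,
    n: int | None = None,
    delta: float | None = None,
    model_id: dict | None = None,
) -> CodeLength:
    """Two-part code length: Gaussian NLL plus the parameter literal.

    The parameter vector is xi = (tau_hat, beta_1 .. beta_k); each component
    with |xi_i| / delta >= 1 costs ln(|xi_i|/delta) nats, plus ln(k+1) for
    the model dimension. ``delta`` defaults to 1/n with n = m.
    """
    if n is None:
        n = fit.m
    if delta is None:
        delta = 1.0 / n
    rss = _effective_rss(fit)
    xi = np.concatenate(([rss / fit.m], fit.beta_hat))
    ratios = np.abs(xi) / delta
    param_bits = float(np.sum(np.log(ratios[ratios >= 1.0])))
    nats = _gaussian_nll(rss, fit.m) + param_bits + math.log(fit.k + 1)
    return CodeLength(nats=nats, scheme="two_part", model_id=model_id or {})


def length_nml(fit: RegressionFit, model_id: dict | None = None) -> CodeLength:
    """NML code length with the Fisher-information parametric complexity."""
    if fit.k < 1:
        raise ValueError("NML length requires k >= 1")
    rss = _effective_rss(fit)
    if fit.r_hat <= 0.0:
        raise ValueError("NML length requires positive fitted energy R_hat")
    tau0 = rss / fit.m
    nats = (
        _gaussian_nll(rss, fit.m)
        + 0.5 * fit.k * math.log(fit.m / 2.0)
        - float(gammaln(fit.k / 2.0))
        + 0.5 * fit.k * math.log(fit.r_hat / tau0)
        - 2.0 * math.log(fit.k)
    )
    return CodeLength(nats=nats, scheme="nml", model_id=model_id or {})


def code_length(
    fit: RegressionFit, scheme: str, model_id: dict | None = None
) -> CodeLength:
    """Dispatch to the requested coding scheme ('nml' or 'two_part')."""
    if scheme == "nml":
        return length_nml(fit, model_id=model_id)
    if scheme == "two_part":
        return length_two_part(fit, model_id=model_id)
    raise ValueError(f"unknown coding scheme {scheme!r}")


def select_model(
    candidates: list[DesignMatrix], scheme: str = "nml"
) -> tuple[RegressionFit, CodeLength]:
    """Shortest-description-length model among the candidates.

    All candidates must share the target and response window (equal m); ties
    break toward smaller k, then smaller maximum lag.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    ms = {c.m for c in candidates}
    if len(ms) > 1:
        raise ValueError(
            f"candidates fit on different response windows (m values {sorted(ms)}); "
            "lengths are incomparable"
        )
    best = None
    for design in candidates:
        fit = fit_lsq(design, compute_gram=False)
        cl = code_length(
            fit, scheme, model_id={"k": design.k, "max_lag": design.max_lag}
        )
        key = (cl.nats, design.k, design.max_lag)
        if best is None or key < best[0]:
            best = (key, fit, cl)
    return best[1], best[2]
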