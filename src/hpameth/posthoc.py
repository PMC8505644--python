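"""Interaction models: does hypersexual disorder modify the methylation signal?

Two model families probe disease-state dependence of the association between
a CpG's methylation and DST non-suppression:

* linear:   M ~ a + b + a:b             (methylation as outcome)
* logistic: outcome ~ M + b + M:b       (non-suppression as outcome)

The logistic fit is plain IRLS with explicit separation diagnostics — at
n = 93 with two binary predictors, quasi-separation is a real possibility
and must surface as an error rather than a silently diverging coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["InteractionFit", "SeparationError", "interaction_linear", "interaction_logistic"]

_TERMS = ("intercept", "main_a", "main_b", "interaction")


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


@dataclass
class InteractionFit:
    model: str  # "linear" | "logistic"
    coef: pd.Series
    se: pd.Series
    p: pd.Series
    n: int
    converged: bool = True
    n_iter: int = 0
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coef, "se": self.se, "p": self.p})


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    levels = np.unique(v)
    if not np.isin(levels, [0.0, 1.0]).all() or levels.size != 2:
        raise ValueError(f"{name} must be 0/1 with both levels present")
    return v


def interaction_linear(cg, a, b) -> InteractionFit:
    """OLS of methylation on two binary factors and their product.

    All four design cells must be non-empty, otherwise the interaction term
    is not identifiable.
    """
    cg = np.asarray(cg, dtype=float)
    a = _check_binary(a, "a")
    b = _check_binary(b, "b")
    for va in (0, 1):
        for vb in (0, 1):
            if not np.any((a == va) & (b == vb)):
                raise ValueError(f"empty design cell a={va}, b={vb}: interaction inestimable")
    X = np.column_stack([np.ones(cg.size), a, b, a * b])
    coef, _, rank, _ = np.linalg.lstsq(X, cg, rcond=None)
    resid = cg - X @ coef
    df = cg.size - 4
    if df < 1:
        raise ValueError("not enough samples for a 4-parameter model")
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    p = 2 * stats.t.sf(np.abs(t), df)
    idx = pd.Index(_TERMS)
    return InteractionFit("linear", pd.Series(coef, idx), pd.Series(se, idx), pd.Series(p, idx), cg.size)


def interaction_logistic(
    outcome, cg, b, max_iter: int = 50, tol: float = 1e-10
) -> InteractionFit:
    """Logistic regression of a binary outcome on methylation, a binary
    moderator and their product, fitted by IRLS with Wald p-values.

    Raises :class:`SeparationError` when the coefficient norm diverges or
    all fitted probabilities saturate at 0/1, the IRLS signature of
    (quasi-)complete separation.
    """
    y = _check_binary(outcome, "outcome")
    cg = np.asarray(cg, dtype=float)
    b = _check_binary(b, "b")
    X = np.column_stack([np.ones(y.size), cg, b, cg * b])
    beta = np.zeros(4)
    deviance = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        if np.all(w < 1e-10):
            raise SeparationError("all fitted probabilities saturated at 0 or 1")
        z = eta + (y - mu) / np.maximum(w, 1e-10)
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError as err:
            raise SeparationError("singular weighted design during IRLS") from err
        if np.linalg.norm(beta) > 1e3:
            raise SeparationError("diverging coefficients: complete or quasi-separation")
        with np.errstate(divide="ignore"):
            ll = np.where(y == 1, np.log(mu), np.log1p(-mu))
        dev_new = -2 * np.sum(ll)
        if abs(deviance - dev_new) < tol * (abs(dev_new) + 0.1):
            deviance = dev_new
            break
        deviance = dev_new
    else:
        raise SeparationError(f"IRLS did not converge in {max_iter} iterations")
    if deviance < 1e-6:
        # zero deviance means every observation is classified perfectly
        raise SeparationError("deviance collapsed to zero: complete separation")
    eta = np.clip(X @ beta, -30, 30)
    mu = 1 / (1 + np.exp(-eta))
    w = mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    idx = pd.Index(_TERMS)
    return InteractionFit(
        "logistic",
        pd.Series(beta, idx),
        pd.Series(se, idx),
        pd.Series(p, idx),
        y.size,
        converged=True,
        n_iter=n_iter,
        extra={"deviance": float(deviance)},
    )
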