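"""Small numerical helpers shared across modules.

The logistic solver here is a lean IRLS used inside bootstrap loops where
statsmodels' overhead would dominate; model-facing code (summaries, CIs)
still goes through statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


def expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def logit_irls(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
    ridge: float = 1e-9,
) -> np.ndarray:
    """Weighted logistic regression coefficients via IRLS.

    A tiny ridge keeps the normal equations solvable; fits whose linear
    predictor diverges (separation) raise :class:`SeparationError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w0 = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        wls = w0 * mu * (1.0 - mu)
        grad = X.T @ (w0 * (y - mu)) - ridge * beta
        H = (X.T * wls) @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as err:  # pragma: no cover - ridge guards this
            raise SeparationError("singular Hessian in logistic fit") from err
        # dampen exploding steps
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    if np.max(np.abs(X @ beta)) > 30.0 and np.max(np.abs(beta)) > 50.0:
        raise SeparationError("diverging coefficients suggest separation")
    return beta


def logit_predict(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return expit(np.asarray(X, dtype=float) @ beta)


def add_intercept(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.c_[np.ones(len(X)), X]


def profile_ci_logit(result, name: str, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood CI for one coefficient of a statsmodels Logit fit.

    The coefficient is fixed via an offset, the remaining coefficients are
    re-optimized, and endpoints solve the deviance equation.  Falls back to
    the Wald interval when the profile root-finding fails.
    """
    import statsmodels.api as sm

    model = result.model
    names = list(result.params.index)
    j = names.index(name)
    X = np.asarray(model.exog, dtype=float)
    y = np.asarray(model.endog, dtype=float)
    bhat = np.asarray(result.params)
    llf = result.llf
    crit = stats.chi2.ppf(level, 1) / 2.0

    keep = [i for i in range(X.shape[1]) if i != j]
    Xk = X[:, keep]
    xj = X[:, j]

    def profile_ll(bj: float) -> float:
        res = sm.GLM(y, Xk, family=sm.families.Binomial(), offset=bj * xj).fit()
        return float(res.llf)

    def g(bj: float) -> float:
        return llf - profile_ll(bj) - crit

    se = float(result.bse.iloc[j])
    wald = (bhat[j] - stats.norm.ppf(0.5 + level / 2) * se,
            bhat[j] + stats.norm.ppf(0.5 + level / 2) * se)
    bounds = []
    for direction, wald_end in ((-1, wald[0]), (1, wald[1])):
        lo = bhat[j]
        hi = bhat[j] + direction * se
        try:
            for _ in range(40):
                if g(hi) > 0:
                    break
                lo, hi = hi, hi + direction * se
            else:
                raise RuntimeError("no bracket")
            a, b = sorted((lo, hi))
            bounds.append(float(optimize.brentq(g, a, b, xtol=1e-8)))
        except Exception:
            bounds.append(float(wald_end))
    return min(bounds), max(bounds)


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2)
    return estimate - z * se, estimate + z * se
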