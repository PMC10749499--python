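"""Logistic regression core shared by the burden and two-hit tests.

Both tests fit the same model: a binary group label (case/control, or
LOH/no-LOH) regressed on a per-sample carrier indicator plus optional
principal-component covariates, by maximum likelihood. The carrier
coefficient is the natural-log odds ratio; its Wald two-sided p-value is the
test statistic.

When the design contains only the intercept and the binary carrier
indicator, observations are collapsed onto the (at most four) distinct
covariate patterns with frequency weights before fitting — the MLE is
unchanged and the fit cost becomes independent of sample size.

Perfect separation (a zero cell in the 2x2 table, or a diverging fit) is
flagged; the reported estimate then comes from a Jeffreys-prior (Firth)
penalized refit, which is always finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

_LN2 = np.log(2.0)
#: |coef| beyond which an unpenalized logistic fit is treated as diverging.
_DIVERGENCE_BOUND = 15.0


@dataclass
class LogitFit:
    """Carrier-coefficient summary of one logistic fit."""

    coef: float  # natural-log odds ratio of the carrier indicator
    se: float
    p_value: float
    converged: bool
    separation: bool
    penalized: bool

    @property
    def log2_or(self) -> float:
        return self.coef / _LN2


def _as_design(carrier: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(carrier, dtype=float), carrier.astype(float)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    return np.column_stack(cols)


def firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, bool]:
    """Jeffreys-prior penalized logistic regression (Firth's bias reduction).

    Newton iterations on the penalized score U*(b) = X'(y - p + h (1/2 - p))
    where h is the diagonal of the logistic hat matrix. Returns coefficients,
    their standard errors from the penalized information, and a convergence
    flag. Estimates are finite even under complete separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X, info_inv, X * w[:, None])
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = (X.T * w) @ X
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se, converged


def fit_carrier_logit(
    y: np.ndarray,
    carrier: np.ndarray,
    covariates: np.ndarray | None = None,
    penalize_on_separation: bool = True,
) -> LogitFit:
    """ML logistic regression of a binary outcome on a carrier indicator.

    ``y`` is the 0/1 group label, ``carrier`` the 0/1 carrier indicator,
    ``covariates`` an optional n x k array (PC scores). Returns the carrier
    coefficient on the natural-log scale with its Wald two-sided p-value.
    """
    y = np.asarray(y, dtype=float)
    carrier = np.asarray(carrier, dtype=float)
    if y.shape != carrier.shape:
        raise ValueError("y and carrier must have equal length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")

    freq_weights = None
    if covariates is None:
        # Collapse to the four (y, carrier) cells; identical MLE.
        cells = np.bincount((2 * y + carrier).astype(int), minlength=4)
        keep = cells > 0
        y_fit = np.array([0.0, 0.0, 1.0, 1.0])[keep]
        carrier_fit = np.array([0.0, 1.0, 0.0, 1.0])[keep]
        freq_weights = cells[keep].astype(float)
        X = _as_design(carrier_fit, None)
        # Separation: a zero cell in the 2x2 table.
        separation_hint = bool((cells == 0).any())
    else:
        y_fit = y
        X = _as_design(carrier, covariates)
        separation_hint = False

    coef = se = np.nan
    p_value = np.nan
    converged = False
    separation = separation_hint
    if not separation_hint:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.GLM(y_fit, X, family=sm.families.Binomial(), freq_weights=freq_weights)
                res = model.fit(maxiter=100, tol=1e-10)
                coef = float(res.params[1])
                se = float(res.bse[1])
                p_value = float(res.pvalues[1])
                converged = bool(res.converged)
            except Exception:
                converged = False
        if not converged or not np.isfinite(coef) or abs(coef) > _DIVERGENCE_BOUND:
            separation = True

    penalized = False
    if separation and penalize_on_separation:
        if freq_weights is not None:
            # Expand weighted rows for the penalized fit (cells are tiny).
            y_pen = np.repeat(y_fit, freq_weights.astype(int))
            X_pen = np.repeat(X, freq_weights.astype(int), axis=0)
        else:
            y_pen, X_pen = y_fit, X
        beta, bse, conv = firth_logit(X_pen, y_pen)
        coef, se = float(beta[1]), float(bse[1])
        z = coef / se if se > 0 else np.nan
        from scipy.stats import norm

        p_value = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
        converged = conv
        penalized = True

    return LogitFit(
        coef=coef,
        se=se,
        p_value=p_value,
        converged=converged,
        separation=separation,
        penalized=penalized,
    )
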