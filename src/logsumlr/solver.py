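"""Coordinate-descent solver for penalized (logistic) regression.

The logistic loss is handled by iteratively reweighted least squares
(IRLS): at the current coefficients the loss is replaced by the weighted
quadratic in the working response

    Z_i = eta_i + (y_i - f(eta_i)) / W_i ,   W_i = f(eta_i) (1 - f(eta_i)) ,

with ``f`` the logistic function, and the penalized weighted
least-squares problem is solved by cyclic coordinate descent with the
closed-form thresholding operators of :mod:`logsumlr.penalties`.

The loss is normalized by the fixed sample size (objective
``(1/n) NLL + P(beta)``), columns are standardized by default, and the
per-coordinate curvature ``v_j = sum_i (W_i/n) x_ij^2`` is handled by
solving ``min 1/2 v_j (b - w_j/v_j)^2 + P(b)``, i.e. the thresholding
operators are applied to ``w_j / v_j`` with penalty levels divided by
``v_j``.  Each IRLS step backtracks toward the previous iterate if the
re-linearization overshoots, so the objective trace is nonincreasing.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.special import expit, logit

from ._cd import cd_sweep_kernel
from .penalties import Penalty, PenaltyConfig, penalty_value

__all__ = [
    "SolverSettings",
    "CoefficientFit",
    "working_response",
    "cd_sweep",
    "fit_penalized_logistic",
    "fit_penalized_linear",
]

_KIND_CODE = {k: i for i, k in enumerate(Penalty)}


@dataclasses.dataclass(frozen=True)
class SolverSettings:
    """Convergence and preprocessing knobs.

    tol: maximum absolute coefficient change declaring convergence.
    max_outer: IRLS re-weighting steps; max_inner: CD sweeps per step.
    weight_floor: lower clamp on the IRLS weights, preventing working
    responses from blowing up at saturated probabilities.
    """

    tol: float = 1e-4
    max_outer: int = 50
    max_inner: int = 100
    weight_floor: float = 1e-5
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_outer < 1 or self.max_inner < 1:
            raise ValueError("max_outer and max_inner must be >= 1")
        if not self.weight_floor > 0:
            raise ValueError("weight_floor must be positive")


@dataclasses.dataclass
class CoefficientFit:
    """Fitted intercept and coefficients (on the original feature scale)."""

    beta0: float
    beta: np.ndarray
    n_iter_outer: int
    converged: bool
    objective_trace: np.ndarray
    penalty: PenaltyConfig


def working_response(fitted, y, weight_floor: float = 1e-5):
    """IRLS working response and weights at the current linear predictor.

    Returns ``(Z, W)`` with ``W = max(f(1-f), weight_floor)`` and
    ``Z = fitted + (y - f)/W`` (division uses the clamped weight).
    """
    fitted = np.asarray(fitted, dtype=float)
    if not np.all(np.isfinite(fitted)):
        raise FloatingPointError("non-finite linear predictor in IRLS step")
    y = np.asarray(y, dtype=float)
    f = expit(fitted)
    W = np.maximum(f * (1.0 - f), weight_floor)
    Z = fitted + (y - f) / W
    return Z, W


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant column(s); their coefficients are forced to 0",
            stacklevel=3,
        )
    sd_safe = np.where(constant, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd_safe


def cd_sweep(X, Z, W, beta, beta0, cfg: PenaltyConfig, update_intercept: bool = True):
    """One cyclic coordinate sweep of the penalized weighted LS problem.

    ``W`` must already be on the loss scale the penalty refers to (the
    logistic solver passes IRLS weights divided by n).  Returns
    ``(beta, beta0, max_abs_change)``; ``beta`` is modified in place.
    """
    X = np.asfortranarray(np.asarray(X, dtype=float))
    Z = np.asarray(Z, dtype=float)
    wts = np.asarray(W, dtype=float)
    beta = np.asarray(beta, dtype=float)
    vj = wts @ (X * X)
    r = Z - beta0 - X @ beta
    p1, p2, p3 = cfg.effective()
    beta0, maxd = cd_sweep_kernel(
        X, r, wts, beta, float(beta0), vj, _KIND_CODE[cfg.kind], p1, p2, p3, update_intercept
    )
    return beta, beta0, maxd


def _prepare(X, settings: SolverSettings):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if settings.standardize:
        Xs, mu, sd = _standardize(X)
    else:
        Xs, mu, sd = X.copy(), np.zeros(X.shape[1]), np.ones(X.shape[1])
    return np.asfortranarray(Xs), mu, sd


def _init_coefs(p, mu, sd, beta_init, beta0_init):
    if beta_init is None:
        return np.zeros(p), 0.0 if beta0_init is None else float(beta0_init)
    beta_init = np.asarray(beta_init, dtype=float)
    beta = beta_init * sd
    beta0 = (0.0 if beta0_init is None else float(beta0_init)) + float(beta_init @ mu)
    return beta, beta0


def _to_original_scale(beta, beta0, mu, sd):
    b = beta / sd
    return float(beta0 - b @ mu), b


def fit_penalized_logistic(
    X,
    y,
    cfg: PenaltyConfig,
    settings: SolverSettings = SolverSettings(),
    beta_init=None,
    beta0_init=None,
) -> CoefficientFit:
    """Fit a penalized logistic regression by IRLS + coordinate descent.

    Deterministic given inputs.  On non-convergence the fit is returned
    with ``converged=False`` and a warning.
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("y must be coded 0/1")
    if classes.size < 2:
        raise ValueError("y contains a single class; cannot fit a classifier")
    Xs, mu, sd = _prepare(X, settings)
    n, p = Xs.shape
    if n != y.size:
        raise ValueError("X and y have different numbers of samples")
    beta, beta0 = _init_coefs(p, mu, sd, beta_init, beta0_init)
    if beta_init is None and beta0_init is None:
        beta0 = float(logit(np.clip(y.mean(), 1e-12, 1 - 1e-12)))
    kind = _KIND_CODE[cfg.kind]
    p1, p2, p3 = cfg.effective()

    def objective(eta_, beta_):
        nll = float(np.sum(np.logaddexp(0.0, eta_) - y * eta_))
        return nll / n + penalty_value(beta_, cfg)

    trace = []
    converged = False
    n_outer = 0
    obj_prev = objective(beta0 + Xs @ beta, beta)
    for outer in range(settings.max_outer):
        n_outer = outer + 1
        eta = beta0 + Xs @ beta
        Z, W = working_response(eta, y, settings.weight_floor)
        wts = W / n  # fixed 1/n loss scale; penalty level is comparable across iterations
        vj = wts @ (Xs * Xs)
        r = Z - eta
        beta_prev = beta.copy()
        beta0_prev = beta0
        for _ in range(settings.max_inner):
            beta0, maxd = cd_sweep_kernel(
                Xs, r, wts, beta, beta0, vj, kind, p1, p2, p3, True
            )
            if maxd < settings.tol:
                break
        # IRLS is not a descent method once weights saturate; backtrack
        # toward the previous iterate until the true objective decreases.
        obj = objective(beta0 + Xs @ beta, beta)
        stalled = False
        for halving in range(31):
            if obj <= obj_prev + 1e-12:
                break
            if halving == 30:
                beta, beta0, obj = beta_prev.copy(), beta0_prev, obj_prev
                stalled = True
                break
            beta = 0.5 * (beta + beta_prev)
            beta0 = 0.5 * (beta0 + beta0_prev)
            obj = objective(beta0 + Xs @ beta, beta)
        trace.append(obj)
        outer_change = max(
            float(np.max(np.abs(beta - beta_prev))) if p else 0.0,
            abs(beta0 - beta0_prev),
        )
        obj_prev = obj
        if stalled or outer_change < settings.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"IRLS did not converge in {settings.max_outer} outer iterations",
            stacklevel=2,
        )
    beta0_orig, beta_orig = _to_original_scale(beta, beta0, mu, sd)
    return CoefficientFit(
        beta0=beta0_orig,
        beta=beta_orig,
        n_iter_outer=n_outer,
        converged=converged,
        objective_trace=np.asarray(trace),
        penalty=cfg,
    )


def fit_penalized_linear(
    X,
    y,
    cfg: PenaltyConfig,
    settings: SolverSettings = SolverSettings(),
    beta_init=None,
) -> CoefficientFit:
    """Penalized least squares (Gaussian loss, unit weights) by CD."""
    y = np.asarray(y, dtype=float)
    Xs, mu, sd = _prepare(X, settings)
    n, p = Xs.shape
    if n != y.size:
        raise ValueError("X and y have different numbers of samples")
    beta, beta0 = _init_coefs(p, mu, sd, beta_init, None)
    if beta_init is None:
        beta0 = float(y.mean())
    kind = _KIND_CODE[cfg.kind]
    p1, p2, p3 = cfg.effective()
    wts = np.full(n, 1.0 / n)
    vj = wts @ (Xs * Xs)
    r = y - beta0 - Xs @ beta
    trace = []
    converged = False
    n_sweeps = 0
    for _ in range(settings.max_outer * settings.max_inner):
        beta0, maxd = cd_sweep_kernel(Xs, r, wts, beta, beta0, vj, kind, p1, p2, p3, True)
        n_sweeps += 1
        trace.append(0.5 * float(wts @ r**2) + penalty_value(beta, cfg))
        if maxd < settings.tol:
            converged = True
            break
    if not converged:
        warnings.warn("coordinate descent did not converge", stacklevel=2)
    beta0_orig, beta_orig = _to_original_scale(beta, beta0, mu, sd)
    return CoefficientFit(
        beta0=beta0_orig,
        beta=beta_orig,
        n_iter_outer=n_sweeps,
        converged=converged,
        objective_trace=np.asarray(trace),
        penalty=cfg,
    )
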