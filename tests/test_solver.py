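"""IRLS + coordinate-descent solver against closed forms and grid oracles."""

import warnings

import numpy as np
import pytest
from scipy.special import expit, logit

from logsumlr.penalties import Penalty, PenaltyConfig, penalty_terms, threshold
from logsumlr._cd import _thresh_scalar
from logsumlr.estimator import lambda_max
from logsumlr.solver import (
    SolverSettings,
    cd_sweep,
    fit_penalized_linear,
    fit_penalized_logistic,
    working_response,
)

_KIND_CODE = {k: i for i, k in enumerate(Penalty)}


def test_working_response_at_null():
    Z, W = working_response(np.zeros(4), np.array([1, 0, 1, 0]))
    assert np.allclose(W, 0.25)
    assert np.allclose(Z, [2, -2, 2, -2])


def test_working_response_clamps_saturated_weights():
    Z, W = working_response(np.array([20.0]), np.array([1.0]), weight_floor=1e-5)
    assert W[0] >= 1e-5
    assert np.isfinite(Z[0])


def test_working_response_example():
    eta = logit(0.8)
    Z, W = working_response(np.array([eta]), np.array([1.0]))
    assert Z[0] == pytest.approx(eta + 0.2 / 0.16)


def test_working_response_rejects_nonfinite():
    with pytest.raises(FloatingPointError):
        working_response(np.array([np.inf]), np.array([1.0]))


def test_kernel_matches_public_operators(rng):
    """The numba scalar dispatch must agree exactly with the reference
    operators for every penalty and random curvature."""
    cfgs = [
        PenaltyConfig(Penalty.L1, lam=0.7),
        PenaltyConfig(Penalty.EN, lam=1.1, a=0.3),
        PenaltyConfig(Penalty.SCAD, lam=0.6, scad_a=3.7),
        PenaltyConfig(Penalty.MCP, lam=0.6, gamma=2.5),
        PenaltyConfig(Penalty.HALF, lam=0.8),
        PenaltyConfig(Penalty.HLR, lam=0.8, a=0.6),
        PenaltyConfig(Penalty.LOGSUM, lam=0.9, eps=0.05),
        PenaltyConfig(Penalty.LOGSUM_L2, lam=0.9, lam1=0.7, lam2=0.3, eps=0.01),
    ]
    for cfg in cfgs:
        p1, p2, p3 = cfg.effective()
        for _ in range(200):
            u = float(rng.uniform(-8, 8))
            v = float(rng.uniform(0.5, 2.0))
            got = _thresh_scalar(u, v, _KIND_CODE[cfg.kind], p1, p2, p3)
            try:
                want = threshold(u, cfg, scale=v)
            except ValueError:
                continue
            assert got == pytest.approx(want, abs=1e-12)


def test_orthonormal_single_feature_reduces_to_operator(rng):
    n = 50
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()  # unit variance so v = 1 under 1/n weights
    z = rng.standard_normal(n)
    lam = 0.3
    fit = fit_penalized_linear(
        x[:, None], z, PenaltyConfig(Penalty.L1, lam=lam),
        SolverSettings(standardize=False, tol=1e-10),
    )
    w = float(np.mean(x * (z - z.mean())))
    assert fit.beta[0] == pytest.approx(threshold(w, PenaltyConfig(Penalty.L1, lam=lam)), abs=1e-8)


def test_all_zero_column_gets_zero_coefficient(rng):
    X = rng.standard_normal((30, 3))
    X[:, 1] = 0.0
    z = rng.standard_normal(30)
    beta = np.zeros(3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_penalized_linear(X, z, PenaltyConfig(Penalty.L1, lam=0.01))
    assert fit.beta[1] == 0.0


@pytest.mark.parametrize(
    "cfg",
    [
        PenaltyConfig(Penalty.L1, lam=0.15),
        PenaltyConfig(Penalty.EN, lam=0.2, a=0.5),
        PenaltyConfig(Penalty.LOGSUM_L2, lam=0.08, lam1=0.5, lam2=0.5, eps=0.01),
    ],
    ids=["L1", "EN", "LOGSUM_L2"],
)
def test_linear_cd_fixed_point_matches_2d_grid(rng, cfg):
    """p=2, n=20: the CD fixed point minimizes the penalized least-squares
    objective, checked against an exhaustive 2-D grid with refinement."""
    X = rng.standard_normal((20, 2))
    y = 1.5 * X[:, 0] - 0.5 * X[:, 1] + 0.3 * rng.standard_normal(20)
    fit = fit_penalized_linear(X, y, cfg, SolverSettings(tol=1e-12, standardize=False))

    yc = y - y.mean()
    Xc = X - X.mean(axis=0)

    def objective(b1, b2):
        r = yc - Xc[:, 0] * b1 - Xc[:, 1] * b2
        return 0.5 * np.mean(r**2) + float(penalty_terms(np.array([b1, b2]), cfg).sum())

    def _pen(b):
        return float(penalty_terms(np.asarray(b), cfg).sum())

    # coarse vectorized grid, then fine grid around the coarse argmin
    g = np.arange(-3.0, 3.0, 0.01)
    B1, B2 = np.meshgrid(g, g, indexing="ij")
    R = yc[None, None, :] - np.multiply.outer(B1, Xc[:, 0]) - np.multiply.outer(B2, Xc[:, 1])
    P = penalty_terms(B1.ravel(), cfg).reshape(B1.shape) + penalty_terms(
        B2.ravel(), cfg
    ).reshape(B2.shape)
    obj = 0.5 * np.mean(R**2, axis=-1) + P
    i, j = np.unravel_index(np.argmin(obj), obj.shape)
    b1, b2 = g[i], g[j]
    for step in (1e-3, 1e-4, 1e-5, 1e-6):
        gg1 = b1 + np.arange(-10, 11) * step
        gg2 = b2 + np.arange(-10, 11) * step
        vals = np.array([[objective(a, b) for b in gg2] for a in gg1])
        ii, jj = np.unravel_index(np.argmin(vals), vals.shape)
        b1, b2 = gg1[ii], gg2[jj]
    assert fit.beta == pytest.approx([b1, b2], abs=1e-4)


def test_logistic_matches_smooth_ridge_optimum(rng):
    """EN with a=0 is a smooth objective; compare against scipy BFGS."""
    from scipy.optimize import minimize

    X = rng.standard_normal((40, 3))
    eta = X[:, 0] - 0.5 * X[:, 2]
    y = (rng.random(40) < expit(eta)).astype(float)
    cfg = PenaltyConfig(Penalty.EN, lam=0.1, a=0.0)
    fit = fit_penalized_logistic(X, y, cfg, SolverSettings(tol=1e-10, standardize=False))

    def obj(theta):
        e = theta[0] + X @ theta[1:]
        return np.mean(np.logaddexp(0, e) - y * e) + 0.05 * 0.1 * 10 * np.sum(theta[1:] ** 2)

    # 1/n NLL + lam*(1-a)/2 * ||b||^2 with lam=0.1, a=0
    def obj2(theta):
        e = theta[0] + X @ theta[1:]
        return np.mean(np.logaddexp(0, e) - y * e) + 0.5 * 0.1 * np.sum(theta[1:] ** 2)

    res = minimize(obj2, np.zeros(4), method="BFGS", options={"gtol": 1e-12})
    assert fit.beta0 == pytest.approx(res.x[0], abs=1e-5)
    assert fit.beta == pytest.approx(res.x[1:], abs=1e-5)


@pytest.mark.parametrize("kind", list(Penalty), ids=[k.value for k in Penalty])
def test_null_model_threshold(separable_toy, kind):
    """Above lambda_max (asserted at 10x the null score) the fit is the
    null model: zero coefficients, intercept at the label log-odds."""
    X, y = separable_toy.X, separable_toy.y
    lam = 10.0 * lambda_max(X, y, Penalty.L1)
    kw = {}
    if kind is Penalty.LOGSUM:
        kw["eps"] = 0.5 * np.sqrt(lam)
    cfg = PenaltyConfig(kind, lam=lam, **kw)
    fit = fit_penalized_logistic(X, y, cfg)
    assert np.all(fit.beta == 0.0)
    assert fit.beta0 == pytest.approx(float(logit(y.mean())), abs=1e-3)


def test_separable_toy_perfect_training_accuracy(separable_toy):
    fit = fit_penalized_logistic(
        separable_toy.X, separable_toy.y, PenaltyConfig(Penalty.L1, lam=1e-3)
    )
    pred = (expit(fit.beta0 + separable_toy.X @ fit.beta) >= 0.5).astype(int)
    assert np.mean(pred == separable_toy.y) == 1.0


def test_scale_equivariance(noisy_toy):
    cfg = PenaltyConfig(Penalty.EN, lam=0.05, a=0.5)
    fit1 = fit_penalized_logistic(noisy_toy.X, noisy_toy.y, cfg)
    X2 = noisy_toy.X.copy()
    X2[:, 0] *= 10.0
    fit2 = fit_penalized_logistic(X2, noisy_toy.y, cfg)
    eta1 = fit1.beta0 + noisy_toy.X @ fit1.beta
    eta2 = fit2.beta0 + X2 @ fit2.beta
    assert np.allclose(eta1, eta2, atol=1e-8)
    assert fit2.beta[0] == pytest.approx(fit1.beta[0] / 10.0, abs=1e-10)


def test_determinism(noisy_toy):
    cfg = PenaltyConfig(Penalty.LOGSUM_L2, lam=0.05, lam1=0.5, lam2=0.5, eps=0.01)
    f1 = fit_penalized_logistic(noisy_toy.X, noisy_toy.y, cfg)
    f2 = fit_penalized_logistic(noisy_toy.X, noisy_toy.y, cfg)
    assert f1.beta0 == f2.beta0
    assert np.array_equal(f1.beta, f2.beta)


@pytest.mark.parametrize(
    "cfg",
    [PenaltyConfig(Penalty.L1, lam=0.05), PenaltyConfig(Penalty.EN, lam=0.05, a=0.5)],
    ids=["L1", "EN"],
)
def test_monotone_descent_convex(noisy_toy, cfg):
    fit = fit_penalized_logistic(noisy_toy.X, noisy_toy.y, cfg)
    assert np.all(np.diff(fit.objective_trace) <= 1e-8)


def test_fixed_point_stable_under_one_sweep(noisy_toy):
    settings = SolverSettings(tol=1e-8)
    cfg = PenaltyConfig(Penalty.EN, lam=0.1, a=0.5)
    fit = fit_penalized_logistic(noisy_toy.X, noisy_toy.y, cfg, settings)
    assert fit.converged
    # rebuild the working problem at the fitted point and sweep once
    mu, sd = noisy_toy.X.mean(axis=0), noisy_toy.X.std(axis=0)
    Xs = (noisy_toy.X - mu) / sd
    beta = fit.beta * sd
    beta0 = fit.beta0 + float(fit.beta @ mu)
    Z, W = working_response(beta0 + Xs @ beta, noisy_toy.y, settings.weight_floor)
    _, _, maxd = cd_sweep(Xs, Z, W / len(Z), beta.copy(), beta0, cfg)
    assert maxd <= 10 * settings.tol


def test_warm_start_idempotent_at_fixed_point(noisy_toy):
    settings = SolverSettings(tol=1e-8)
    cfg = PenaltyConfig(Penalty.L1, lam=0.05)
    f1 = fit_penalized_logistic(noisy_toy.X, noisy_toy.y, cfg, settings)
    f2 = fit_penalized_logistic(
        noisy_toy.X, noisy_toy.y, cfg, settings, beta_init=f1.beta, beta0_init=f1.beta0
    )
    assert f2.beta == pytest.approx(f1.beta, abs=1e-6)
    assert f2.beta0 == pytest.approx(f1.beta0, abs=1e-6)


def test_single_class_rejected(rng):
    X = rng.standard_normal((10, 2))
    with pytest.raises(ValueError, match="single class"):
        fit_penalized_logistic(X, np.ones(10), PenaltyConfig(Penalty.L1, lam=0.1))


def test_noiseless_linear_recovery(rng):
    X = rng.standard_normal((50, 4))
    y = X[:, 0].copy()
    fit = fit_penalized_linear(X, y, PenaltyConfig(Penalty.L1, lam=1e-6),
                               SolverSettings(tol=1e-10))
    assert fit.beta == pytest.approx([1.0, 0, 0, 0], abs=1e-4)
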