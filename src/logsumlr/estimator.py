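"""User-facing penalized logistic regression: fit, predict, CV tuning.

The positive class is label 1 (the case / "Class 2" group); sensitivity
and specificity elsewhere in the package follow that convention.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .penalties import Penalty, PenaltyConfig, logsum_l2_zero_band
from .solver import CoefficientFit, SolverSettings, fit_penalized_logistic, working_response

__all__ = [
    "LabeledDataset",
    "CVResult",
    "fit",
    "predict_proba",
    "classify",
    "select_support",
    "cross_validate",
    "default_grid",
    "lambda_max",
    "read_dataset",
    "write_dataset",
    "write_fit",
    "read_fit",
]


@dataclasses.dataclass
class LabeledDataset:
    """Feature matrix with binary labels and optional simulation truth."""

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]
    true_beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on the number of samples")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if not np.all(np.isin(self.y, (0, 1))):
            raise ValueError("y must be coded 0/1")
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != self.X.shape[1]:
            raise ValueError("feature_ids length must match the number of columns")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if self.true_beta is not None:
            self.true_beta = np.asarray(self.true_beta, dtype=float)
            if self.true_beta.size != self.X.shape[1]:
                raise ValueError("true_beta length must match the number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], self.feature_ids, self.true_beta)


@dataclasses.dataclass
class CVResult:
    grid: list[PenaltyConfig]
    fold_accuracy: np.ndarray  # (len(grid), k)
    mean_accuracy: np.ndarray
    best: PenaltyConfig
    k: int
    seed: int


def fit(
    data: LabeledDataset,
    cfg: PenaltyConfig,
    settings: SolverSettings = SolverSettings(),
    beta_init=None,
    beta0_init=None,
) -> CoefficientFit:
    """Fit the penalized logistic model on a labeled dataset."""
    return fit_penalized_logistic(
        data.X, data.y, cfg, settings, beta_init=beta_init, beta0_init=beta0_init
    )


def predict_proba(fit_: CoefficientFit, X) -> np.ndarray:
    """P(y = 1 | x) = logistic(beta0 + X beta)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != fit_.beta.size:
        raise ValueError(
            f"X has {X.shape[-1] if X.ndim == 2 else '?'} columns, fit expects {fit_.beta.size}"
        )
    return expit(fit_.beta0 + X @ fit_.beta)


def classify(fit_: CoefficientFit, X, cut: float = 0.5) -> np.ndarray:
    """Label 1 where the predicted probability is >= ``cut`` (closed rule)."""
    if not 0.0 < cut < 1.0:
        raise ValueError("cut must lie strictly inside (0, 1)")
    return (predict_proba(fit_, X) >= cut).astype(int)


def select_support(fit_: CoefficientFit, tol: float = 0.0) -> np.ndarray:
    """Sorted 0-based indices of features with ``|beta_j| > tol``."""
    return np.flatnonzero(np.abs(fit_.beta) > tol)


def _null_scores(X, y, settings: SolverSettings):
    """|w_j| and curvatures v_j at the null model, on the solver's scale."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if settings.standardize:
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xs = (X - X.mean(axis=0)) / sd
    else:
        Xs = X
    pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    eta = np.full(y.size, math.log(pbar / (1 - pbar)))
    Z, W = working_response(eta, y, settings.weight_floor)
    wts = W / y.size  # matches the solver's 1/n loss scale
    wj = np.abs((wts * (Z - eta)) @ Xs)
    vj = wts @ (Xs * Xs)
    vj = np.where(vj <= 0, 1.0, vj)
    return np.maximum(wj, 1e-10), vj


def lambda_max(
    X, y, kind: Penalty | str, *, a: float = 0.5, lam1: float = 0.5, eps: float = 0.01,
    settings: SolverSettings = SolverSettings(),
) -> float:
    """Smallest penalty level that zeroes every coefficient at the null model.

    Uses the per-coordinate zero band of the requested operator applied to
    the scaled problem ``(w_j / v_j, lam / v_j)``; for LOGSUM_L2 the band
    is nonlinear in lam and is solved by vectorized bisection.
    """
    kind = Penalty(kind)
    wj, vj = _null_scores(X, y, settings)
    if kind in (Penalty.L1, Penalty.SCAD, Penalty.MCP):
        return float(wj.max())
    if kind is Penalty.EN:
        return float(wj.max()) / max(a, 1e-3)
    if kind is Penalty.HALF:
        # |w|/v <= (3/2)(lam/v)^(2/3)  <=>  lam >= (2|w|/3)^(3/2)/sqrt(v)
        return float(np.max((2.0 * wj / 3.0) ** 1.5 / np.sqrt(vj)))
    if kind is Penalty.HLR:
        return float(np.max((2.0 * wj / 3.0) ** 1.5 / np.sqrt(vj))) / max(a, 1e-3)
    if kind is Penalty.LOGSUM:
        # |w|/v <= 2*sqrt(lam/v) - eps
        return float(np.max(vj * (wj / vj + eps) ** 2 / 4.0))
    lam2 = 1.0 - lam1

    def short(lam):
        band = 2.0 * np.sqrt((lam * lam1 / vj) * (1.0 + 2.0 * lam * lam2 / vj)) - (
            1.0 + 2.0 * lam * lam2 / vj
        ) * eps
        return band - wj / vj

    lo, hi = 1e-10, 1.0
    while np.any(short(hi) < 0) and hi < 1e8:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.any(short(mid) < 0):
            lo = mid
        else:
            hi = mid
    return hi


def _lambda_path(lmax: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def default_grid(
    kind: Penalty | str,
    X,
    y,
    *,
    n_lambda: int = 30,
    lam_min_ratio: float = 0.01,
    a_values: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    lam1_values: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    eps_values: Sequence[float] = (1e-3, 1e-2, 1e-1),
    settings: SolverSettings = SolverSettings(),
) -> list[PenaltyConfig]:
    """Tuning grid: a decreasing log-spaced lambda path per parameter family.

    EN/HLR cross the path with the mixing weight ``a``; LOGSUM crosses it
    with ``eps`` (kept only where ``eps < sqrt(lam)``); LOGSUM_L2 crosses
    it with ``lam1`` (``lam2 = 1 - lam1``) and ``eps`` (kept only where the
    zero band stays positive).
    """
    kind = Penalty(kind)
    grid: list[PenaltyConfig] = []
    if kind in (Penalty.L1, Penalty.SCAD, Penalty.MCP, Penalty.HALF):
        lmax = lambda_max(X, y, kind, settings=settings)
        for lam in _lambda_path(lmax, n_lambda, lam_min_ratio):
            grid.append(PenaltyConfig(kind, lam=lam))
    elif kind in (Penalty.EN, Penalty.HLR):
        for a in a_values:
            lmax = lambda_max(X, y, kind, a=a, settings=settings)
            for lam in _lambda_path(lmax, n_lambda, lam_min_ratio):
                grid.append(PenaltyConfig(kind, lam=lam, a=a))
    elif kind is Penalty.LOGSUM:
        for eps in eps_values:
            lmax = lambda_max(X, y, kind, eps=eps, settings=settings)
            for lam in _lambda_path(lmax, n_lambda, lam_min_ratio):
                if eps < math.sqrt(lam):
                    grid.append(PenaltyConfig(kind, lam=lam, eps=eps))
    else:
        for lam1 in lam1_values:
            for eps in eps_values:
                lmax = lambda_max(X, y, kind, lam1=lam1, eps=eps, settings=settings)
                for lam in _lambda_path(lmax, n_lambda, lam_min_ratio):
                    if logsum_l2_zero_band(lam * lam1, lam * (1 - lam1), eps) > 0:
                        grid.append(
                            PenaltyConfig(kind, lam=lam, lam1=lam1, lam2=1.0 - lam1, eps=eps)
                        )
    return grid


def _family_key(cfg: PenaltyConfig):
    return (cfg.kind.value, cfg.a, cfg.scad_a, cfg.gamma, cfg.lam1, cfg.lam2, cfg.eps)


def _fit_path(X, y, configs, settings):
    """Fit a decreasing-lambda family with warm starts; yields fits in input order."""
    order = np.argsort([-c.lam for c in configs], kind="stable")
    fits: dict[int, CoefficientFit] = {}
    beta_init = None
    beta0_init = None
    for idx in order:
        f = fit_penalized_logistic(
            X, y, configs[idx], settings, beta_init=beta_init, beta0_init=beta0_init
        )
        fits[int(idx)] = f
        beta_init, beta0_init = f.beta, f.beta0
    return [fits[i] for i in range(len(configs))]


def cross_validate(
    data: LabeledDataset,
    grid: Sequence[PenaltyConfig],
    k: int = 10,
    seed: int = 0,
    settings: SolverSettings = SolverSettings(),
) -> CVResult:
    """Stratified k-fold CV over a penalty grid, scored by held-out accuracy.

    ``best`` attains the maximum mean accuracy; ties break toward the
    sparser model (larger ``lam``, then larger ``lam1``).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid is empty")
    if k < 2 or k > data.n:
        raise ValueError("need 2 <= k <= n folds")
    counts = np.bincount(data.y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"cannot stratify {k} folds: minority class has only {counts.min()} samples"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    acc = np.zeros((len(grid), k))
    families: dict[tuple, list[int]] = {}
    for i, cfg in enumerate(grid):
        families.setdefault(_family_key(cfg), []).append(i)
    for fold, (tr, va) in enumerate(skf.split(data.X, data.y)):
        Xtr, ytr = data.X[tr], data.y[tr]
        Xva, yva = data.X[va], data.y[va]
        for idxs in families.values():
            fits = _fit_path(Xtr, ytr, [grid[i] for i in idxs], settings)
            for i, f in zip(idxs, fits):
                pred = (expit(f.beta0 + Xva @ f.beta) >= 0.5).astype(int)
                acc[i, fold] = float(np.mean(pred == yva))
    mean_acc = acc.mean(axis=1)
    ranked = sorted(
        range(len(grid)),
        key=lambda i: (mean_acc[i], grid[i].lam, grid[i].lam1),
    )
    best = grid[ranked[-1]]
    return CVResult(
        grid=grid, fold_accuracy=acc, mean_accuracy=mean_acc, best=best, k=k, seed=seed
    )


# ---------------------------------------------------------------------------
# delimited-text IO

def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def write_dataset(path, data: LabeledDataset) -> None:
    """Samples x features table with a leading sample column and a
    trailing 0/1 ``label`` column."""
    df = pd.DataFrame(data.X, columns=data.feature_ids)
    df.insert(0, "sample", [f"S{i + 1}" for i in range(data.n)])
    df["label"] = data.y
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_dataset(path, label_col: str = "label") -> LabeledDataset:
    df = pd.read_csv(path, sep=_sep_for(path))
    if label_col not in df.columns:
        raise ValueError(f"no '{label_col}' column in {path}")
    y = df[label_col].to_numpy()
    feats = df.drop(columns=[label_col])
    feats = feats.drop(columns=[feats.columns[0]])  # sample-ID column
    X = feats.to_numpy(dtype=float)
    return LabeledDataset(X, y, list(feats.columns))


def write_fit(path, fit_: CoefficientFit, feature_ids: Sequence[str], seed=None) -> None:
    """Flat key-value coefficient file with a run-metadata header."""
    cfg = fit_.penalty
    lines = [
        f"# penalty: {cfg.kind.value}",
        f"# lam: {float(cfg.lam)!r}",
        f"# a: {float(cfg.a)!r}",
        f"# scad_a: {float(cfg.scad_a)!r}",
        f"# gamma: {float(cfg.gamma)!r}",
        f"# lam1: {float(cfg.lam1)!r}",
        f"# lam2: {float(cfg.lam2)!r}",
        f"# eps: {float(cfg.eps)!r}",
        f"# seed: {seed!r}",
        f"# converged: {fit_.converged}",
        f"# n_iter_outer: {fit_.n_iter_outer}",
        f"(intercept)\t{float(fit_.beta0)!r}",
    ]
    for fid, b in zip(feature_ids, fit_.beta):
        lines.append(f"{fid}\t{float(b)!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_fit(path) -> tuple[CoefficientFit, list[str]]:
    meta: dict[str, str] = {}
    ids: list[str] = []
    coefs: list[float] = []
    beta0 = 0.0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition(": ")
                meta[key] = val
            elif line:
                fid, _, val = line.partition("\t")
                if fid == "(intercept)":
                    beta0 = float(val)
                else:
                    ids.append(fid)
                    coefs.append(float(val))
    cfg = PenaltyConfig(
        kind=meta["penalty"],
        lam=float(meta["lam"]),
        a=float(meta["a"]),
        scad_a=float(meta["scad_a"]),
        gamma=float(meta["gamma"]),
        lam1=float(meta["lam1"]),
        lam2=float(meta["lam2"]),
        eps=float(meta["eps"]),
    )
    fit_ = CoefficientFit(
        beta0=beta0,
        beta=np.asarray(coefs),
        n_iter_outer=int(meta.get("n_iter_outer", 0)),
        converged=meta.get("converged") == "True",
        objective_trace=np.empty(0),
        penalty=cfg,
    )
    return fit_, ids
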