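"""Univariate thresholding operators for sparse penalized regression.

Each operator solves (or approximately solves) the one-dimensional problem

    min_beta  1/2 (beta - w)^2 + P(beta)

that arises per coordinate in a coordinate-descent sweep under an
orthonormal design.  Eight penalties are supported:

========== ===============================================================
``L1``        lasso, ``lam * |b|``
``EN``        elastic net, ``lam * (a*|b| + (1-a)/2 * b^2)``
``SCAD``      smoothly clipped absolute deviation (shape ``scad_a > 2``)
``MCP``       minimax concave penalty (shape ``gamma > 1``)
``HALF``      L_{1/2}, ``lam * |b|^(1/2)``
``HLR``       L_{1/2} + ridge mix, ``lam * (a*|b|^(1/2) + (1-a)/2 * b^2)``
``LOGSUM``    log-sum, ``lam * log(|b| + eps)`` (an L0 surrogate)
``LOGSUM_L2`` log-sum + ridge, ``l1 * log(|b| + eps) + l2 * b^2``
========== ===============================================================

The LogSum + L2 operator is the model this package exists for: the log-sum
term drives aggressive, nearly unbiased sparsity while the ridge term
spreads weight over groups of correlated features.  Its closed form
follows from the stationarity condition

    (1 + 2*l2) * b - |w| + l1 / (b + eps) = 0 ,

a quadratic in ``b`` whose larger root is taken when the zero band
``|w| <= 2*sqrt(l1*(1 + 2*l2)) - (1 + 2*l2)*eps`` is exceeded.

A brute-force grid + local-refinement oracle (:func:`oracle_minimize`)
over the same univariate objective is provided as the independent test
reference for every operator.
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np
from scipy import optimize

__all__ = [
    "Penalty",
    "PenaltyConfig",
    "soft_threshold",
    "en_threshold",
    "scad_threshold",
    "mcp_threshold",
    "half_threshold",
    "hlr_threshold",
    "logsum_threshold",
    "logsum_l2_threshold",
    "logsum_l2_zero_band",
    "univariate_objective",
    "oracle_minimize",
    "threshold",
]


class Penalty(str, enum.Enum):
    L1 = "L1"
    EN = "EN"
    SCAD = "SCAD"
    MCP = "MCP"
    HALF = "HALF"
    HLR = "HLR"
    LOGSUM = "LOGSUM"
    LOGSUM_L2 = "LOGSUM_L2"


@dataclasses.dataclass(frozen=True)
class PenaltyConfig:
    """Penalty choice plus its parameters.

    ``lam`` is the overall penalty level.  Only the fields relevant to
    ``kind`` are consulted; the rest keep their defaults.  For
    ``LOGSUM_L2`` the model parameterization is
    ``lam * (lam1*log(|b|+eps) + lam2*b^2)`` with ``lam1 + lam2 = 1``,
    i.e. ``lam1`` balances sparsity against the grouping ridge while
    ``lam`` sets the overall strength; the effective operator weights are
    ``lam*lam1`` and ``lam*lam2``.
    """

    kind: Penalty
    lam: float = 1.0
    a: float = 0.5          # EN / HLR mixing weight on the sparse term
    scad_a: float = 3.7     # SCAD shape
    gamma: float = 3.0      # MCP shape
    lam1: float = 0.5       # LOGSUM_L2 log-sum weight
    lam2: float = 0.5       # LOGSUM_L2 ridge weight
    eps: float = 0.01       # LOGSUM / LOGSUM_L2 smoothing constant

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", Penalty(self.kind))
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError(f"lam must be positive and finite, got {self.lam}")
        k = self.kind
        if k in (Penalty.EN, Penalty.HLR) and not 0.0 <= self.a <= 1.0:
            raise ValueError(f"mixing weight a must lie in [0, 1], got {self.a}")
        if k is Penalty.SCAD and not self.scad_a > 2.0:
            raise ValueError(f"SCAD shape must exceed 2, got {self.scad_a}")
        if k is Penalty.MCP and not self.gamma > 1.0:
            raise ValueError(f"MCP gamma must exceed 1, got {self.gamma}")
        if k is Penalty.LOGSUM:
            if not 0.0 < self.eps < math.sqrt(self.lam):
                raise ValueError(
                    f"LOGSUM requires 0 < eps < sqrt(lam); got eps={self.eps}, lam={self.lam}"
                )
        if k is Penalty.LOGSUM_L2:
            if self.lam1 < 0 or self.lam2 < 0:
                raise ValueError("lam1 and lam2 must be nonnegative")
            if abs(self.lam1 + self.lam2 - 1.0) > 1e-12:
                raise ValueError(
                    f"LOGSUM_L2 requires lam1 + lam2 = 1, got {self.lam1} + {self.lam2}"
                )
            if self.eps <= 0:
                raise ValueError("eps must be positive")
            band = logsum_l2_zero_band(self.lam * self.lam1, self.lam * self.lam2, self.eps)
            if band <= 0:
                raise ValueError(
                    "degenerate LOGSUM_L2 configuration: zero-band threshold "
                    f"2*sqrt(l1*(1+2*l2)) - (1+2*l2)*eps = {band:.3g} <= 0; "
                    "decrease eps or increase lam*lam1"
                )

    def effective(self) -> tuple[float, float, float]:
        """Operator parameters ``(p1, p2, p3)`` on the solver's scale."""
        k = self.kind
        if k is Penalty.L1:
            return self.lam, 0.0, 0.0
        if k is Penalty.EN or k is Penalty.HLR:
            return self.lam, self.a, 0.0
        if k is Penalty.SCAD:
            return self.lam, self.scad_a, 0.0
        if k is Penalty.MCP:
            return self.lam, self.gamma, 0.0
        if k is Penalty.HALF:
            return self.lam, 0.0, 0.0
        if k is Penalty.LOGSUM:
            return self.lam, 0.0, self.eps
        return self.lam * self.lam1, self.lam * self.lam2, self.eps


def _check_w(w: float) -> float:
    w = float(w)
    if not np.isfinite(w):
        raise ValueError(f"w must be finite, got {w}")
    return w


def soft_threshold(w: float, lam: float) -> float:
    """Soft thresholding: ``sign(w) * max(|w| - lam, 0)``.

    The closed upper rule applies: ``|w| == lam`` maps to 0.
    """
    w = _check_w(w)
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be positive and finite, got {lam}")
    return math.copysign(max(abs(w) - lam, 0.0), w)


def en_threshold(w: float, lam: float, a: float) -> float:
    """Elastic-net operator: soft threshold at ``lam*a`` then ridge shrink."""
    w = _check_w(w)
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be positive and finite, got {lam}")
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"a must lie in [0, 1], got {a}")
    z = math.copysign(max(abs(w) - lam * a, 0.0), w)
    return z / (1.0 + lam * (1.0 - a))


def scad_threshold(w: float, lam: float, scad_a: float) -> float:
    """SCAD operator: soft below 2*lam, blended to the identity above a*lam."""
    w = _check_w(w)
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be positive and finite, got {lam}")
    if not scad_a > 2.0:
        raise ValueError(f"scad_a must exceed 2, got {scad_a}")
    aw = abs(w)
    if aw <= 2.0 * lam:
        return math.copysign(max(aw - lam, 0.0), w)
    if aw <= scad_a * lam:
        return math.copysign(((scad_a - 1.0) * aw - scad_a * lam) / (scad_a - 2.0), w)
    return w


def mcp_threshold(w: float, lam: float, gamma: float) -> float:
    """MCP operator: rescaled soft threshold below gamma*lam, identity above."""
    w = _check_w(w)
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be positive and finite, got {lam}")
    if not gamma > 1.0:
        raise ValueError(f"gamma must exceed 1, got {gamma}")
    aw = abs(w)
    if aw <= gamma * lam:
        return math.copysign(max(aw - lam, 0.0) / (1.0 - 1.0 / gamma), w)
    return w


def _half_core(w: float, lam: float) -> float:
    # lam == 0 degenerates to the identity (no penalty).
    if lam == 0.0:
        return w
    aw = abs(w)
    # |w| <= 3*(lam/4)^(2/3): no real stationary point; 0 is the minimizer
    if aw <= 3.0 * (lam / 4.0) ** (2.0 / 3.0):
        return 0.0
    phi = math.acos((lam / 4.0) * (aw / 3.0) ** -1.5)
    beta = (2.0 / 3.0) * w * (1.0 + math.cos(2.0 * (math.pi - phi) / 3.0))
    # The cosine root is a stationary point; keep it only when it beats 0,
    # so the returned value is the global minimizer.
    if 0.5 * (beta - w) ** 2 + lam * math.sqrt(abs(beta)) < 0.5 * w * w:
        return beta
    return 0.0


def half_threshold(w: float, lam: float) -> float:
    """L_{1/2} (half) thresholding operator.

    The nonzero branch is the cosine closed form
    ``(2/3) * w * (1 + cos(2*(pi - phi)/3))`` with
    ``phi = arccos((lam/4) * (|w|/3)^(-3/2))`` (the constant consistent
    with the ``1/2 (b - w)^2`` loss convention), returned only when its
    objective value beats 0, so the output is the global minimizer of
    ``1/2 (b - w)^2 + lam * |b|^(1/2)``.  The effective zero band is
    ``|w| <= (3/2) * lam^(2/3)``.
    """
    w = _check_w(w)
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be positive and finite, got {lam}")
    return _half_core(w, lam)


def hlr_threshold(w: float, lam: float, a: float) -> float:
    """L_{1/2} + ridge operator: half threshold at ``lam*a``, ridge shrink."""
    w = _check_w(w)
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be positive and finite, got {lam}")
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"a must lie in [0, 1], got {a}")
    return _half_core(w, lam * a) / (1.0 + lam * (1.0 - a))


def logsum_threshold(w: float, lam: float, eps: float) -> float:
    """Log-sum thresholding operator.

    With ``c1 = |w| - eps`` and ``c2 = c1^2 - 4*(lam - |w|*eps)`` the
    nonzero branch is ``sign(w) * (c1 + sqrt(c2)) / 2`` (the larger root
    of the stationarity quadratic), returned when ``c2 > 0``; otherwise 0.
    Requires ``0 < eps < sqrt(lam)`` so that the zero band
    ``|w| <= 2*sqrt(lam) - eps`` is nonempty.
    """
    w = _check_w(w)
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be positive and finite, got {lam}")
    if not 0.0 < eps < math.sqrt(lam):
        raise ValueError(f"requires 0 < eps < sqrt(lam); got eps={eps}, lam={lam}")
    aw = abs(w)
    c1 = aw - eps
    c2 = c1 * c1 - 4.0 * (lam - aw * eps)
    if c2 > 0.0:
        beta = 0.5 * (c1 + math.sqrt(c2))
        if beta > 0.0:
            return math.copysign(beta, w)
    return 0.0


def logsum_l2_zero_band(lam1: float, lam2: float, eps: float) -> float:
    """Zero-band threshold ``2*sqrt(lam1*(1+2*lam2)) - (1+2*lam2)*eps``."""
    d = 1.0 + 2.0 * lam2
    return 2.0 * math.sqrt(lam1 * d) - d * eps


def logsum_l2_threshold(w: float, lam1: float, lam2: float, eps: float) -> float:
    """LogSum + L2 thresholding operator.

    Solves ``min 1/2 (b - w)^2 + lam1*log(|b|+eps) + lam2*b^2``: zero when
    ``|w|`` is at or below the zero band of :func:`logsum_l2_zero_band`,
    otherwise the larger root of the stationarity quadratic

        (1+2*lam2)*b^2 - (|w| - (1+2*lam2)*eps)*b - |w|*eps + lam1 = 0 .

    ``lam1``/``lam2`` are the effective weights on the solver scale; the
    model-level convention ``lam1 + lam2 = 1`` lives in
    :class:`PenaltyConfig`.
    """
    w = _check_w(w)
    if lam1 < 0 or lam2 < 0:
        raise ValueError("lam1 and lam2 must be nonnegative")
    if eps <= 0:
        raise ValueError("eps must be positive")
    band = logsum_l2_zero_band(lam1, lam2, eps)
    if band <= 0.0:
        raise ValueError(
            f"zero-band threshold {band:.3g} <= 0: requires "
            f"eps < 2*sqrt(lam1/(1+2*lam2)) = {2.0 * math.sqrt(lam1 / (1.0 + 2.0 * lam2)):.3g}"
        )
    aw = abs(w)
    if aw <= band:
        return 0.0
    d = 1.0 + 2.0 * lam2
    disc = (aw + d * eps) ** 2 - 4.0 * lam1 * d
    beta = ((aw - d * eps) + math.sqrt(disc)) / (2.0 * d)
    return math.copysign(beta, w)


def penalty_terms(beta, cfg: PenaltyConfig) -> np.ndarray:
    """Elementwise penalty ``P(beta_j)`` under ``cfg``."""
    b = np.abs(np.atleast_1d(np.asarray(beta, dtype=float)))
    k = cfg.kind
    if k is Penalty.L1:
        val = cfg.lam * b
    elif k is Penalty.EN:
        val = cfg.lam * (cfg.a * b + 0.5 * (1.0 - cfg.a) * b**2)
    elif k is Penalty.SCAD:
        lam, a = cfg.lam, cfg.scad_a
        val = np.where(
            b <= lam,
            lam * b,
            np.where(
                b <= a * lam,
                (2.0 * a * lam * b - b**2 - lam**2) / (2.0 * (a - 1.0)),
                lam**2 * (a + 1.0) / 2.0,
            ),
        )
    elif k is Penalty.MCP:
        lam, g = cfg.lam, cfg.gamma
        val = np.where(b <= g * lam, lam * b - b**2 / (2.0 * g), 0.5 * g * lam**2)
    elif k is Penalty.HALF:
        val = cfg.lam * np.sqrt(b)
    elif k is Penalty.HLR:
        val = cfg.lam * (cfg.a * np.sqrt(b) + 0.5 * (1.0 - cfg.a) * b**2)
    elif k is Penalty.LOGSUM:
        val = cfg.lam * np.log(b + cfg.eps)
    else:
        l1, l2 = cfg.lam * cfg.lam1, cfg.lam * cfg.lam2
        val = l1 * np.log(b + cfg.eps) + l2 * b**2
    return np.asarray(val, dtype=float)


def penalty_value(beta, cfg: PenaltyConfig) -> float:
    """Penalty ``P(beta)`` (summed over entries) under ``cfg``."""
    return float(np.sum(penalty_terms(beta, cfg)))


def univariate_objective(beta: float, w: float, cfg: PenaltyConfig) -> float:
    """``1/2 (beta - w)^2 + P(beta)`` for the configured penalty."""
    beta = float(beta)
    w = _check_w(w)
    return 0.5 * (beta - w) ** 2 + penalty_value(beta, cfg)


def oracle_minimize(
    w: float,
    cfg: PenaltyConfig,
    lo: float | None = None,
    hi: float | None = None,
    n_grid: int = 20001,
) -> float:
    """Brute-force minimizer of the univariate objective (test reference).

    Dense grid over ``[lo, hi]`` followed by bounded local refinement
    around the best grid point; 0 is always a candidate and wins ties.
    Independent of the closed-form operators.
    """
    w = _check_w(w)
    if lo is None or hi is None:
        span = max(2.0 * abs(w), 1.0)
        lo = -span if lo is None else lo
        hi = span if hi is None else hi
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    grid = np.linspace(lo, hi, int(n_grid))
    vals = np.array([univariate_objective(b, w, cfg) for b in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: univariate_objective(t, w, cfg),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-12},
    )
    best, best_val = float(res.x), float(res.fun)
    if vals[i] < best_val:
        best, best_val = float(grid[i]), float(vals[i])
    zero_val = univariate_objective(0.0, w, cfg)
    if zero_val <= best_val + 1e-15:
        return 0.0
    return best


def threshold(w: float, cfg: PenaltyConfig, scale: float = 1.0) -> float:
    """Apply the configured operator to the scaled problem
    ``min 1/2 * scale * (b - w)^2 + P(b)``.

    Equivalent to dividing the penalty level by ``scale`` (the
    per-coordinate curvature ``v_j`` in a coordinate-descent sweep).
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    p1, p2, p3 = cfg.effective()
    k = cfg.kind
    if k is Penalty.L1:
        return soft_threshold(w, p1 / scale)
    if k is Penalty.EN:
        return en_threshold(w, p1 / scale, p2)
    if k is Penalty.SCAD:
        return scad_threshold(w, p1 / scale, p2)
    if k is Penalty.MCP:
        return mcp_threshold(w, p1 / scale, p2)
    if k is Penalty.HALF:
        return half_threshold(w, p1 / scale)
    if k is Penalty.HLR:
        return hlr_threshold(w, p1 / scale, p2)
    if k is Penalty.LOGSUM:
        return logsum_threshold(w, p1 / scale, p3)
    return logsum_l2_threshold(w, p1 / scale, p2 / scale, p3)
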