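"""Regularized S-map: time-varying interaction sign and strength.

The S-map fits, at every prediction time, a locally weighted linear model in
the reconstructed state space; its slope coefficients approximate entries of
the time-varying Jacobian, i.e. interaction strengths.  Library weights fall
off exponentially with state-space distance at rate ``theta`` (theta = 0 is
a global linear fit), and a ridge penalty ``lambda`` (intercept unpenalized)
stabilizes the local solve on short, noisy series.  The sign and strength of
a detected edge X -> Y come from the time-averaged coefficient of X at lag
-1 in the model for Y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .abundance import CommunityTimeSeries
from .edm import DelayBlock, make_block, standardize
from .uic import UICResult

__all__ = [
    "SMapConfig",
    "SMapCoefficients",
    "smap_local_fit",
    "smap_coefficients",
    "tune_smap",
    "edge_strength",
    "quantify_network",
]

DEFAULT_THETA_GRID = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
DEFAULT_LAMBDA_GRID = (0.0, 0.01, 0.1, 1.0)


@dataclass(frozen=True)
class SMapConfig:
    """Hyperparameter grids and predictor layout for edge quantification."""

    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID

    def __post_init__(self):
        if not self.theta_grid or not self.lambda_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if any(t < 0 for t in self.theta_grid) or any(l < 0 for l in self.lambda_grid):
            raise ValueError("theta and lambda values must be nonnegative")


@dataclass(frozen=True)
class SMapCoefficients:
    """Per-time S-map coefficients for one edge plus the summary statistics.

    ``trajectory`` holds the cause-coordinate coefficient at each valid
    prediction time; ``strength`` is its arithmetic mean, ``sign`` the sign
    of that mean (0 when the mean is exactly zero, flagged indeterminate).
    """

    cause: str
    effect: str
    trajectory: np.ndarray
    strength: float
    sign: int
    theta: float
    lam: float
    indeterminate: bool

    def __post_init__(self):
        if len(self.trajectory) == 0:
            raise ValueError("empty coefficient trajectory")


def _weights(d: np.ndarray, theta: float) -> np.ndarray:
    dbar = d.mean()
    if dbar == 0:
        raise ValueError("all library rows identical (mean distance 0)")
    return np.exp(-theta * d / dbar)


def _solve_weighted_ridge(z: np.ndarray, y: np.ndarray, w: np.ndarray,
                          lam: float) -> np.ndarray:
    """Minimize sum_k w_k (y_k - b0 - b.z_k)^2 + lam*||b||^2.

    Returns (b, b0) concatenated as [slopes..., intercept]; the intercept is
    unpenalized.
    """
    n, p = z.shape
    design = np.hstack([z, np.ones((n, 1))])
    sw = np.sqrt(w)
    a = design * sw[:, None]
    rhs = a.T @ (y * sw)
    gram = a.T @ a
    penalty = np.diag(np.r_[np.full(p, lam), 0.0])
    return np.linalg.solve(gram + penalty, rhs)


def smap_local_fit(block: DelayBlock, target_row: int, theta: float,
                   lam: float) -> np.ndarray:
    """Locally weighted ridge fit at one valid row of a delay block.

    ``target_row`` indexes the valid rows.  Library = all other valid rows;
    weights ``w_k = exp(-theta * d_k / dbar)`` with ``d_k`` the Euclidean
    distance from library row k to the target row and ``dbar`` the mean such
    distance.  Returns ``[slope_1, ..., slope_p, intercept]`` ordered as
    ``block.coords``.
    """
    xv, yv, _ = block.valid_rows()
    n = len(xv)
    if not (0 <= target_row < n):
        raise IndexError("target_row out of range of valid rows")
    lib = np.arange(n) != target_row
    d = np.linalg.norm(xv[lib] - xv[target_row], axis=1)
    w = _weights(d, theta)
    return _solve_weighted_ridge(xv[lib], yv[lib], w, lam)


def smap_coefficients(block: DelayBlock, theta: float,
                      lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and LOO predictions at every valid row.

    Returns ``(coeffs, predictions)`` where ``coeffs`` has one row
    ``[slopes..., intercept]`` per valid row.
    """
    xv, yv, _ = block.valid_rows()
    n, p = xv.shape
    coeffs = np.empty((n, p + 1))
    preds = np.empty(n)
    for i in range(n):
        coeffs[i] = smap_local_fit(block, i, theta, lam)
        preds[i] = coeffs[i, :p] @ xv[i] + coeffs[i, p]
    return coeffs, preds


def tune_smap(block: DelayBlock,
              theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
              lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
              ) -> tuple[float, float]:
    """Select (theta, lambda) minimizing leave-one-out forecast MSE.

    Ties break toward smaller theta, then smaller lambda, independent of
    grid ordering.
    """
    thetas = sorted(set(float(t) for t in theta_grid))
    lams = sorted(set(float(l) for l in lambda_grid))
    if not thetas or not lams:
        raise ValueError("hyperparameter grids must be nonempty")
    _, yv, _ = block.valid_rows()
    best = None
    for theta in thetas:
        for lam in lams:
            _, preds = smap_coefficients(block, theta, lam)
            mse = float(np.mean((preds - yv) ** 2))
            if best is None or mse < best[0]:
                best = (mse, theta, lam)
    return best[1], best[2]


def _edge_block(ts, cause: str, effect: str, e_used: int,
                standardized: bool) -> DelayBlock:
    xs = _series(ts, cause, standardized)
    ys = _series(ts, effect, standardized)
    series = {"cause": xs, "effect": ys}
    coordinates = [("effect", -l) for l in range(1, e_used + 1)] + [("cause", -1)]
    return make_block(series, coordinates, ("effect", 0))


def _series(ts, genus, standardized):
    if isinstance(ts, CommunityTimeSeries):
        s = ts.series(genus)
    else:
        s = {r: np.asarray(v, float) for r, v in ts[genus].items()}
    return s if standardized else standardize(s)


def edge_strength(ts, cause: str, effect: str, e_used: int,
                  config: SMapConfig = SMapConfig(),
                  uic_results: Sequence[UICResult] | None = None,
                  standardized: bool = False) -> SMapCoefficients:
    """Sign and strength of the edge cause -> effect.

    The model forecasts the effect at time t from its own delay coordinates
    (lags -1..-E, E from the causality test) plus the cause at lag -1; the
    edge strength is the mean over prediction times of the cause
    coefficient (standardized units), and the sign is the sign of that
    mean.  A mean of exactly zero is flagged indeterminate.  When
    ``uic_results`` is given, the edge must appear in its significant set.
    """
    if uic_results is not None:
        sig = {(r.cause, r.effect) for r in uic_results if r.significant}
        if (cause, effect) not in sig:
            raise ValueError(f"edge {cause}->{effect} is not in the "
                             "significant causal set")
    block = _edge_block(ts, cause, effect, e_used, standardized)
    theta, lam = tune_smap(block, config.theta_grid, config.lambda_grid)
    coeffs, _ = smap_coefficients(block, theta, lam)
    traj = coeffs[:, e_used]  # the cause coordinate follows the E effect lags
    strength = float(traj.mean())
    sign = int(np.sign(strength))
    return SMapCoefficients(cause=cause, effect=effect, trajectory=traj,
                            strength=strength, sign=sign, theta=theta,
                            lam=lam, indeterminate=(sign == 0))


def quantify_network(ts, uic_results: Sequence[UICResult],
                     config: SMapConfig = SMapConfig(),
                     standardized: bool = False) -> list[SMapCoefficients]:
    """S-map sign/strength for every significant causal edge.

    Indeterminate edges (mean coefficient exactly zero) are excluded from
    the returned signed set, matching their exclusion from signed network
    summaries.
    """
    out = []
    for r in uic_results:
        if not r.significant:
            continue
        res = edge_strength(ts, r.cause, r.effect, r.e_used, config=config,
                            standardized=standardized)
        if not res.indeterminate:
            out.append(res)
    return out
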