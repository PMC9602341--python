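"""Empirical dynamic modeling core: delay embedding and simplex projection.

A :class:`DelayBlock` holds the lag-coordinate matrix built from replicated
series.  Rows that would need values before a replicate's start or after its
end are masked invalid, so no embedding vector ever mixes time points from
different replicates.  :func:`simplex_forecast` is leave-one-out
nearest-neighbor forecasting with exponentially distance-decaying weights;
its skill over a grid of embedding dimensions drives
:func:`select_embedding`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DelayBlock",
    "ForecastSkill",
    "standardize",
    "make_block",
    "simplex_forecast",
    "forecast_skill",
    "select_embedding",
]


@dataclass(frozen=True)
class DelayBlock:
    """Lag-coordinate state-space matrix with replicate-aware validity mask.

    ``coords`` is the ordered list of (variable, lag) pairs defining the
    columns of ``x``; ``y`` is the prediction target (``target_var`` at lag
    ``tp`` relative to each row's time).  ``valid`` marks rows whose every
    coordinate and target lie inside one replicate.  ``replicate`` and
    ``time`` label rows for exclusion rules.
    """

    coords: tuple[tuple[str, int], ...]
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    replicate: np.ndarray
    time: np.ndarray
    target: tuple[str, int]

    def __post_init__(self):
        n = len(self.x)
        if not (len(self.y) == len(self.valid) == len(self.replicate)
                == len(self.time) == n):
            raise ValueError("row attributes must have equal length")

    @property
    def n_coords(self) -> int:
        return len(self.coords)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_rows(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, y, time) restricted to valid rows."""
        v = self.valid
        return self.x[v], self.y[v], self.time[v]


@dataclass(frozen=True)
class ForecastSkill:
    """Out-of-sample skill: Pearson rho, mean squared error, #points."""

    rho: float
    mse: float
    n_pred: int

    def __post_init__(self):
        if self.n_pred < 1:
            raise ValueError("n_pred must be >= 1")
        if self.mse < 0:
            raise ValueError("mse must be nonnegative")


def standardize(series: Mapping[object, np.ndarray]) -> dict:
    """Z-score per-replicate series jointly over all replicates.

    Mean and (population) standard deviation are computed over the
    concatenation of the replicates of one condition, so replicates stay on
    a common scale.  A constant series cannot be standardized.
    """
    arrays = {rep: np.asarray(v, dtype=float) for rep, v in series.items()}
    pooled = np.concatenate(list(arrays.values()))
    mu = pooled.mean()
    sd = pooled.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant series")
    return {rep: (v - mu) / sd for rep, v in arrays.items()}


def make_block(series: Mapping[str, Mapping[object, np.ndarray]],
               coords: Sequence[tuple[str, int]],
               target: tuple[str, int]) -> DelayBlock:
    """Assemble a delay block from replicated series.

    ``series`` maps variable name -> {replicate -> 1-D array}; all variables
    must share the replicate structure.  ``coords`` are (variable, lag)
    pairs (lags <= 0 look into the past); ``target`` is (variable, tp) with
    tp the prediction lag (tp=+1 forecasts one step ahead, tp=-1 maps to one
    step in the past).  The row at (replicate, t) is valid iff every
    requested lag and the target index fall inside that replicate.
    """
    coords = tuple((str(v), int(l)) for v, l in coords)
    tvar, tp = target
    variables = set(v for v, _ in coords) | {tvar}
    reps = None
    for v in variables:
        if v not in series:
            raise KeyError(f"variable {v!r} missing from series set")
        r = list(series[v].keys())
        if reps is None:
            reps = r
        elif r != reps:
            raise ValueError("all variables must share the replicate structure")
    xs, ys, valids, rep_lab, times = [], [], [], [], []
    for rep in reps:
        lengths = {len(series[v][rep]) for v in variables}
        if len(lengths) != 1:
            raise ValueError(f"unequal series lengths in replicate {rep!r}")
        n = lengths.pop()
        xmat = np.full((n, len(coords)), np.nan)
        yvec = np.full(n, np.nan)
        ok = np.ones(n, dtype=bool)
        t_idx = np.arange(n)
        for c, (v, lag) in enumerate(coords):
            src = t_idx + lag
            inside = (src >= 0) & (src < n)
            ok &= inside
            xmat[inside, c] = np.asarray(series[v][rep], dtype=float)[src[inside]]
        src = t_idx + tp
        inside = (src >= 0) & (src < n)
        ok &= inside
        yvec[inside] = np.asarray(series[tvar][rep], dtype=float)[src[inside]]
        xs.append(xmat)
        ys.append(yvec)
        valids.append(ok)
        rep_lab.extend([rep] * n)
        times.append(t_idx.astype(float))
    return DelayBlock(
        coords=coords,
        x=np.vstack(xs),
        y=np.concatenate(ys),
        valid=np.concatenate(valids),
        replicate=np.asarray(rep_lab, dtype=object),
        time=np.concatenate(times),
        target=(str(tvar), int(tp)),
    )


def _neighbor_distances(x: np.ndarray, times: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distances with self and same-time rows excluded.

    Rows sharing a time index (the row itself and its same-time copies in
    other replicates) are set to +inf so they can never be neighbors:
    replicate copies of the same moment would leak the answer.
    """
    d = cdist(x, x)
    same_time = times[:, None] == times[None, :]
    d[same_time] = np.inf
    return d


def simplex_forecast(block: DelayBlock, k: int | None = None) -> np.ndarray:
    """Leave-one-out simplex projection over the valid rows of a block.

    For each valid row the ``k`` nearest valid neighbors (Euclidean metric,
    excluding the row itself and same-time rows from other replicates) vote
    with weights ``w_j = exp(-d_j / d_min)`` where ``d_min`` is the distance
    to the nearest neighbor; the prediction is the weighted mean of the
    neighbors' targets.  If ``d_min = 0``, equal weights over the
    zero-distance neighbors only.  Distance ties break by row index.

    Returns an array aligned with ``block`` rows; invalid rows are NaN.
    ``k`` defaults to n_coords + 1 (the standard E+1 simplex).
    """
    if k is None:
        k = block.n_coords + 1
    xv, yv, tv = block.valid_rows()
    n = len(xv)
    if n == 0:
        raise ValueError("block has no valid rows")
    d = _neighbor_distances(xv, tv)
    preds = np.full(len(block.x), np.nan)
    valid_idx = np.flatnonzero(block.valid)
    for i in range(n):
        di = d[i]
        finite = np.isfinite(di)
        if finite.sum() < k:
            rep, t = block.replicate[valid_idx[i]], block.time[valid_idx[i]]
            raise ValueError(
                f"fewer than k={k} valid neighbors for row "
                f"(replicate={rep!r}, t={t:g})")
        order = np.argsort(di, kind="stable")[:k]
        d_min = di[order[0]]
        if d_min == 0:
            zero = finite & (di == 0)
            preds[valid_idx[i]] = yv[zero].mean()
        else:
            w = np.exp(-di[order] / d_min)
            preds[valid_idx[i]] = float(w @ yv[order] / w.sum())
    return preds


def forecast_skill(predictions: np.ndarray,
                   observations: np.ndarray) -> ForecastSkill:
    """Pearson rho and MSE over the points where a prediction exists."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    ok = np.isfinite(p) & np.isfinite(o)
    if ok.sum() < 1:
        raise ValueError("no predicted points")
    p, o = p[ok], o[ok]
    mse = float(np.mean((p - o) ** 2))
    if p.std() == 0 or o.std() == 0:
        rho = float("nan")
    else:
        rho = float(np.corrcoef(p, o)[0, 1])
    return ForecastSkill(rho=rho, mse=mse, n_pred=int(ok.sum()))


def select_embedding(series: Mapping[object, np.ndarray],
                     e_grid: Iterable[int] = range(1, 11),
                     tp: int = 1) -> int:
    """Embedding dimension maximizing leave-one-out simplex skill.

    Builds univariate blocks with lags 0..-(E-1) for each E in the grid,
    forecasts the series at lag ``tp``, and returns the E with the highest
    Pearson rho (ties toward smaller E).  Dimensions that leave too few
    valid rows for E+1 neighbors are skipped.
    """
    e_grid = sorted(set(int(e) for e in e_grid))
    if not e_grid:
        raise ValueError("E grid must be nonempty")
    if min(e_grid) < 1:
        raise ValueError("embedding dimensions must be >= 1")
    best_e, best_rho = None, -np.inf
    var = {"x": {rep: np.asarray(v, dtype=float) for rep, v in series.items()}}
    for e in e_grid:
        coordinates = [("x", -l) for l in range(e)]
        block = make_block(var, coordinates, ("x", tp))
        try:
            preds = simplex_forecast(block)
        except ValueError:
            continue  # not enough neighbors at this dimension
        skill = forecast_skill(preds, block.y)
        rho = -np.inf if np.isnan(skill.rho) else skill.rho
        if rho > best_rho:
            best_e, best_rho = e, rho
    if best_e is None:
        raise ValueError("no embedding dimension in the grid is feasible "
                         "for series of this length")
    return best_e
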