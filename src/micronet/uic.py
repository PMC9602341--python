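"""Directed causality screening between genera (UIC-style test).

The test for an edge X -> Y (X causes Y) follows the cross-mapping logic of
convergent cross mapping: if X forces Y, the effect's trajectory encodes the
cause, so a delay embedding of Y can recover X at the causal lag.  Two
leave-one-out simplex models forecast the cause at lag ``tp`` (default -1,
one 0.5-day step into the past):

* full model    — effect coordinates at lags 0, -1, ..., -(E-1),
                  i.e. including the candidate coordinate Y_t
* reduced model — effect coordinates at lags -1, ..., -E only

Each model's embedding dimension is chosen automatically by its own
cross-map skill over the dimension grid, evaluated on a common set of
prediction rows, so the comparison is between the best model with the
time-t information and the best model without it.  The statistic is the
information-flow proxy ``te = ln MSE_reduced - ln MSE_full``; positive te
means the candidate coordinate improves the forecast of the lagged cause.
Significance comes from bootstrap resampling of the pointwise prediction
errors, with a circular-shift surrogate test available as a cross-check.
Pairs whose existence cannot be statistically established are treated as
non-interacting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .abundance import CommunityTimeSeries
from .edm import make_block, simplex_forecast, standardize

__all__ = [
    "UICResult",
    "uic_statistic",
    "bootstrap_p",
    "surrogate_p",
    "test_pair",
    "scan_all_pairs",
]

#: Default embedding-dimension grid for the pair test; sized for triplicate
#: ~29-point replicates (deeper lags sacrifice too many prediction rows).
DEFAULT_E_GRID = tuple(range(1, 6))


@dataclass(frozen=True)
class UICResult:
    """Outcome of one directed pair test (cause -> effect at lag tp)."""

    cause: str
    effect: str
    tp: int
    e_used: int
    te: float
    p_value: float
    n_pred: int
    significant: bool

    def __post_init__(self):
        if not (0 <= self.p_value <= 1):
            raise ValueError("p_value must lie in [0, 1]")


def uic_statistic(errors_full: np.ndarray,
                  errors_reduced: np.ndarray) -> float:
    """Log MSE ratio te = ln(MSE_reduced) - ln(MSE_full).

    Both vectors must hold pointwise prediction errors for the same targets;
    te > 0 iff the candidate coordinate improves the forecast.
    """
    ef = np.asarray(errors_full, dtype=float)
    er = np.asarray(errors_reduced, dtype=float)
    if ef.shape != er.shape:
        raise ValueError("error vectors must have the same length")
    if len(ef) < 8:
        raise ValueError("need at least 8 prediction points")
    mse_f = float(np.mean(ef ** 2))
    mse_r = float(np.mean(er ** 2))
    if mse_f == 0 or mse_r == 0:
        raise ValueError("zero MSE: degenerate deterministic fit")
    return float(np.log(mse_r) - np.log(mse_f))


def bootstrap_p(errors_full: np.ndarray, errors_reduced: np.ndarray,
                b: int = 2000, seed: int | None = None) -> float:
    """One-sided bootstrap p-value for te > 0.

    Prediction-target indices are resampled with replacement ``b`` times;
    p = (1 + #{te* <= 0}) / (b + 1).
    """
    ef = np.asarray(errors_full, dtype=float) ** 2
    er = np.asarray(errors_reduced, dtype=float) ** 2
    if ef.shape != er.shape:
        raise ValueError("error vectors must have the same length")
    if b < 1:
        raise ValueError("number of bootstrap resamples must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(ef)
    idx = rng.integers(0, n, size=(b, n))
    mse_f = ef[idx].mean(axis=1)
    mse_r = er[idx].mean(axis=1)
    # te* <= 0  <=>  MSE_reduced <= MSE_full (log is monotone; avoids log(0))
    n_nonpos = int(np.sum(mse_r <= mse_f))
    return (1 + n_nonpos) / (b + 1)


def _pair_blocks(cause: Mapping[object, np.ndarray],
                 effect: Mapping[object, np.ndarray],
                 e: int, tp: int,
                 effect_lag0: Mapping[object, np.ndarray] | None = None):
    """Full/reduced delay blocks for one directed pair at dimension ``e``.

    ``effect_lag0`` substitutes the series used for the lag-0 candidate
    coordinate (surrogate testing); the lagged coordinates always come from
    the original effect series.
    """
    series = {"cause": dict(cause), "effect": dict(effect)}
    lag0_var = "effect"
    if effect_lag0 is not None:
        series["effect_surr"] = dict(effect_lag0)
        lag0_var = "effect_surr"
    full_coords = [(lag0_var, 0)] + [("effect", -l) for l in range(1, e)]
    red_coords = [("effect", -l) for l in range(1, e + 1)]
    target = ("cause", tp)
    return (make_block(series, full_coords, target),
            make_block(series, red_coords, target))


def _pair_errors(cause, effect, e_grid, tp, effect_lag0=None,
                 fixed_dims: tuple[int, int] | None = None):
    """Best full-model and reduced-model errors over a common row set.

    For every dimension in the grid both models are forecast leave-one-out;
    errors are aligned on the rows valid at the deepest dimension, and each
    model keeps its best dimension by MSE (ties toward smaller E).  Returns
    ``(te, errors_full, errors_reduced, e_full, e_reduced)``.  When
    ``fixed_dims`` is given the dimension search is skipped (surrogates).
    """
    e_grid = sorted(set(int(e) for e in e_grid))
    if not e_grid or min(e_grid) < 1:
        raise ValueError("embedding grid must be nonempty with E >= 1")
    e_max = max(e_grid)
    # Common prediction rows: those valid for the deepest lag in the grid.
    fb_max, rb_max = _pair_blocks(cause, effect, e_max, tp, effect_lag0)
    common = fb_max.valid & rb_max.valid
    if common.sum() < 8:
        raise ValueError("too few joint prediction points for the pair test")
    best_f = best_r = None
    dims = e_grid if fixed_dims is None else sorted(set(fixed_dims))
    for e in dims:
        full, red = _pair_blocks(cause, effect, e, tp, effect_lag0)
        pf = simplex_forecast(full)
        pr = simplex_forecast(red)
        ef = full.y[common] - pf[common]
        er = red.y[common] - pr[common]
        if np.all(np.isfinite(ef)):
            mf = float(np.mean(ef ** 2))
            if (fixed_dims is None or e == fixed_dims[0]) and \
                    (best_f is None or mf < best_f[0]):
                best_f = (mf, e, ef)
        if np.all(np.isfinite(er)):
            mr = float(np.mean(er ** 2))
            if (fixed_dims is None or e == fixed_dims[1]) and \
                    (best_r is None or mr < best_r[0]):
                best_r = (mr, e, er)
    if best_f is None or best_r is None:
        raise ValueError("no feasible embedding dimension for the pair test")
    te = uic_statistic(best_f[2], best_r[2])
    return te, best_f[2], best_r[2], best_f[1], best_r[1]


def test_pair(ts: CommunityTimeSeries | Mapping[str, Mapping[object, np.ndarray]],
              cause: str, effect: str, tp: int = -1, alpha: float = 0.05,
              e_grid: Iterable[int] = DEFAULT_E_GRID, b: int = 2000,
              seed: int | None = None,
              standardized: bool = False) -> UICResult:
    """Test the directed interaction cause -> effect at lag ``tp``.

    ``ts`` is either a :class:`CommunityTimeSeries` or a mapping
    genus -> {replicate -> series}.  Series are z-scored over the pooled
    replicates unless ``standardized`` is set.  ``e_used`` reports the full
    model's automatically selected embedding dimension.
    """
    if cause == effect:
        raise ValueError("self-pairs are not tested")
    xs = _get_series(ts, cause, standardized)
    ys = _get_series(ts, effect, standardized)
    min_len = min(len(v) for v in ys.values())
    grid = [e for e in e_grid if e + 2 <= min_len]
    if not grid:
        raise ValueError("series too short for any embedding in the grid")
    te, e_f, e_r, dim_f, _ = _pair_errors(xs, ys, grid, tp)
    p = bootstrap_p(e_f, e_r, b=b, seed=seed)
    return UICResult(cause=cause, effect=effect, tp=tp, e_used=dim_f, te=te,
                     p_value=p, n_pred=len(e_f),
                     significant=bool(p < alpha and te > 0))


def surrogate_p(cause: Mapping[object, np.ndarray],
                effect: Mapping[object, np.ndarray],
                n_surrogates: int = 100, seed: int | None = None,
                tp: int = -1, e_grid: Iterable[int] = DEFAULT_E_GRID,
                standardized: bool = False) -> float:
    """Circular-shift surrogate p-value for the pair test.

    The candidate lag-0 coordinate is replaced by circular shifts of the
    effect series (shift >= E, applied within each replicate), destroying
    the time-locked alignment while preserving marginal structure; the
    model dimensions stay fixed at the observed fit.
    p = (1 + #{te_surr >= te_obs}) / (n_surrogates + 1).
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    xs = {r: np.asarray(v, float) for r, v in cause.items()}
    ys = {r: np.asarray(v, float) for r, v in effect.items()}
    if not standardized:
        xs, ys = standardize(xs), standardize(ys)
    te_obs, _, _, dim_f, dim_r = _pair_errors(xs, ys, e_grid, tp)
    rng = np.random.default_rng(seed)
    n_ge = 0
    e_min_shift = max(dim_f, dim_r)
    for _ in range(n_surrogates):
        shifted = {}
        for rep, v in ys.items():
            lo, hi = e_min_shift, len(v) - e_min_shift
            if hi <= lo:
                raise ValueError("series too short for shift >= E surrogates")
            shifted[rep] = np.roll(v, int(rng.integers(lo, hi)))
        te_s, *_ = _pair_errors(xs, ys, e_grid, tp, effect_lag0=shifted,
                                fixed_dims=(dim_f, dim_r))
        if te_s >= te_obs:
            n_ge += 1
    return (1 + n_ge) / (n_surrogates + 1)


def _get_series(ts, genus, standardized):
    if isinstance(ts, CommunityTimeSeries):
        s = ts.series(genus)
    else:
        s = {r: np.asarray(v, float) for r, v in ts[genus].items()}
    return s if standardized else standardize(s)


def scan_all_pairs(ts: CommunityTimeSeries | Mapping[str, Mapping[object, np.ndarray]],
                   alpha: float = 0.05, tp: int = -1,
                   e_grid: Iterable[int] = DEFAULT_E_GRID, b: int = 2000,
                   seed: int | None = 0, bh_correct: bool = False,
                   return_all: bool = False) -> list[UICResult]:
    """Test every ordered genus pair; return the significant edge set.

    Pairs whose test is not significant contribute no edge ("no interaction
    unless statistically determined").  Every pair test uses the same
    bootstrap seed derived from ``seed``: resampling then depends only on a
    pair's data, which makes the edge decisions invariant to relabeling or
    reordering the genera.  ``bh_correct`` applies Benjamini-Hochberg across
    all ordered pairs before thresholding (off by default).
    """
    if isinstance(ts, CommunityTimeSeries):
        genera = ts.genera
        raw = {g: ts.series(g) for g in genera}
    else:
        genera = list(ts.keys())
        raw = {g: ts[g] for g in genera}
    std = {g: standardize(raw[g]) for g in genera}
    pairs = [(x, y) for x in genera for y in genera if x != y]
    boot_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    results = []
    for (x, y) in pairs:
        results.append(test_pair(std, x, y, tp=tp, alpha=alpha, e_grid=e_grid,
                                 b=b, seed=boot_seed, standardized=True))
    if bh_correct and results:
        results = _apply_bh(results, alpha)
    if return_all:
        return results
    return [r for r in results if r.significant]


def _apply_bh(results: Sequence[UICResult], alpha: float) -> list[UICResult]:
    """Benjamini-Hochberg step-up over all tested pairs."""
    from dataclasses import replace

    m = len(results)
    order = np.argsort([r.p_value for r in results], kind="stable")
    max_k = 0
    for rank, idx in enumerate(order, start=1):
        if results[idx].p_value <= rank * alpha / m:
            max_k = rank
    passed = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order, start=1):
        passed[idx] = rank <= max_k
    return [replace(r, significant=bool(passed[i] and r.te > 0))
            for i, r in enumerate(results)]
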