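"""Absolute-abundance assembly and community-level diagnostics.

Absolute genus abundances are computed as N_i(t) = N_T(t) * P_i(t): the
qPCR-measured total (spike-in corrected for extraction efficiency) times the
amplicon relative abundance.  The day-0 sample of each replicate is removed
before network inference, and genera absent at more than ``max_absent`` of
the pooled remaining time points are dropped.  Bray-Curtis dissimilarity
from the starting composition quantifies how strongly a condition perturbs
the community (the stress diagnostic).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityTimeSeries",
    "estimate_extraction_efficiency",
    "absolute_abundance",
    "assemble",
    "drop_day0",
    "prevalence_filter",
    "bray_curtis",
    "dissimilarity_trajectory",
]


@dataclass(frozen=True)
class CommunityTimeSeries:
    """Replicate-tagged genus x time absolute-abundance matrix.

    ``abundance`` is a wide frame indexed by (replicate, time_days) with one
    column per genus, holding copies/mL.  ``day0_removed`` and
    ``filter_applied`` are provenance flags set by :func:`drop_day0` and
    :func:`prevalence_filter`.
    """

    abundance: pd.DataFrame
    day0_removed: bool = False
    filter_applied: bool = False

    def __post_init__(self):
        ab = self.abundance
        if not isinstance(ab.index, pd.MultiIndex) or ab.index.names != ["replicate", "time_days"]:
            raise ValueError("abundance must be indexed by (replicate, time_days)")
        if (ab.values < 0).any():
            raise ValueError("abundances must be nonnegative")
        for rep in self.replicates:
            t = ab.loc[rep].index.to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"time not strictly increasing in replicate {rep!r}")

    @property
    def replicates(self) -> list:
        return list(self.abundance.index.get_level_values("replicate").unique())

    @property
    def genera(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_timepoints_total(self) -> int:
        return len(self.abundance)

    def replicate_frame(self, rep) -> pd.DataFrame:
        """Time x genus frame for one replicate."""
        return self.abundance.loc[rep]

    def series(self, genus: str) -> dict:
        """Per-replicate 1-D abundance arrays for one genus."""
        return {rep: self.abundance.loc[rep, genus].to_numpy()
                for rep in self.replicates}

    def to_tidy(self) -> pd.DataFrame:
        tidy = (self.abundance.stack().rename("abundance").reset_index())
        tidy.columns = ["replicate", "time_days", "genus", "abundance"]
        return tidy


def estimate_extraction_efficiency(residual_copies: float,
                                   spiked_copies: float) -> float:
    """DNA extraction efficiency from the residual internal standard.

    Efficiency = residual / spiked, clipped to (0, 1] with a warning when
    the measured residual exceeds the spiked amount.
    """
    if spiked_copies <= 0:
        raise ValueError("spiked_copies must be positive")
    if residual_copies <= 0:
        raise ValueError("residual spike-in copies must be positive: "
                         "cannot estimate extraction efficiency")
    eff = residual_copies / spiked_copies
    if eff > 1:
        warnings.warn(f"extraction efficiency estimate {eff:.3f} > 1; "
                      "clipping to 1.0", stacklevel=2)
        eff = 1.0
    return eff


def absolute_abundance(total: float, proportions: Sequence[float],
                       atol: float = 1e-6) -> np.ndarray:
    """Per-genus absolute abundance N_i = N_T * P_i for one sample."""
    p = np.asarray(proportions, dtype=float)
    if total < 0:
        raise ValueError("total abundance must be nonnegative")
    if abs(p.sum() - 1.0) > atol:
        raise ValueError(f"proportions must sum to 1 (got {p.sum():.6g})")
    return total * p


def assemble(tidy: pd.DataFrame) -> CommunityTimeSeries:
    """Build a CommunityTimeSeries from the tidy observation table.

    Expects columns replicate, time_days, genus, proportion,
    total_copies_per_ml (the dialect written by the synthetic generator).
    Flagged (all-zero) samples are dropped with a warning.
    """
    df = tidy.copy()
    if "flagged" in df.columns and df["flagged"].any():
        n_bad = df.loc[df["flagged"], ["replicate", "time_days"]].drop_duplicates()
        warnings.warn(f"dropping {len(n_bad)} flagged (all-zero) samples",
                      stacklevel=2)
        df = df[~df["flagged"]]
    wide_p = df.pivot_table(index=["replicate", "time_days"], columns="genus",
                            values="proportion", sort=True)
    totals = (df.groupby(["replicate", "time_days"], sort=True)
              ["total_copies_per_ml"].first())
    bad = (wide_p.sum(axis=1) - 1.0).abs() > 1e-6
    if bad.any():
        raise ValueError(f"proportions do not sum to 1 in {int(bad.sum())} samples")
    ab = wide_p.mul(totals, axis=0)
    ab.index.names = ["replicate", "time_days"]
    ab.columns.name = None
    return CommunityTimeSeries(abundance=ab)


def drop_day0(ts: CommunityTimeSeries) -> CommunityTimeSeries:
    """Remove the day-0 sample of every replicate (initial transient)."""
    if ts.day0_removed:
        raise ValueError("day-0 samples were already removed")
    times = ts.abundance.index.get_level_values("time_days")
    keep = times > 0
    if keep.all():
        raise ValueError("no day-0 (time 0) samples present to remove")
    return replace(ts, abundance=ts.abundance[keep], day0_removed=True)


def prevalence_filter(ts: CommunityTimeSeries,
                      max_absent: int = 40) -> CommunityTimeSeries:
    """Drop genera absent (zero abundance) at more than ``max_absent`` of the
    pooled time points across replicates.

    Absence means exactly zero estimated absolute abundance (zero reads);
    a genus is kept iff its absence count is <= max_absent.
    """
    absent = (ts.abundance == 0).sum(axis=0)
    keep = absent[absent <= max_absent].index
    removed = [g for g in ts.genera if g not in set(keep)]
    if removed:
        logger.info("prevalence filter removed %d genera: %s",
                    len(removed), ", ".join(map(str, removed)))
    return replace(ts, abundance=ts.abundance[list(keep)], filter_applied=True)


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(x, y))


def dissimilarity_trajectory(ts: CommunityTimeSeries,
                             reference: Sequence[float]) -> pd.Series:
    """Bray-Curtis dissimilarity of every sample from a reference composition.

    ``reference`` is the day-0 genus abundance vector aligned with
    ``ts.genera`` (raw abundances, no scaling).  Returns one value per
    (replicate, time_days).
    """
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (len(ts.genera),):
        raise ValueError("reference length must match the genus set")
    vals = [bray_curtis(row, ref) for row in ts.abundance.to_numpy()]
    return pd.Series(vals, index=ts.abundance.index, name="bray_curtis")
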