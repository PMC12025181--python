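"""Functional-group succession rate (SR).

SR between two sampling occasions a < b is the total absolute change
in functional-group relative biomass per day,

    SR = sum_i |f_ib - f_ia| / (b - a),

with f the relative-biomass vector over the union of groups present at
either time (absent groups contribute 0) and b - a in calendar days
between the actual sampling dates. Because each f sums to 1, the sum of
absolute differences is at most 2, so 0 <= SR <= 2/(b - a); SR = 0 for
an unchanged community and the maximum is reached under complete
turnover. SR depends only on relative biomass, so uniform scaling of
biomass leaves it unchanged.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .functional_groups import BiomassMatrix
from .io_core import ValidationError

logger = logging.getLogger("phytofg")

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class Interval:
    a: _dt.date
    b: _dt.date
    delta_days: float
    sr: float


@dataclass
class SuccessionSeries:
    """Time-ordered relative-biomass profiles at one site with interval SRs."""

    site_id: str
    timepoints: list[_dt.date]
    profiles: np.ndarray  # timepoint x group, rows sum to 1
    groups: list[str]
    intervals: list[Interval]


def succession_rate(fa: np.ndarray, fb: np.ndarray, delta_days: float) -> float:
    """SR per day between two relative-biomass vectors.

    Both vectors must be over the same group ordering and sum to 1
    (tolerance 1e-9); ``delta_days`` must be positive.
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if fa.shape != fb.shape:
        raise ValidationError("relative-biomass vectors differ in length")
    if not delta_days > 0:
        raise ValidationError(f"delta_days must be > 0, got {delta_days}")
    for label, f in (("fa", fa), ("fb", fb)):
        if np.any(f < -_NORM_TOL):
            raise ValidationError(f"{label} has negative entries")
        if abs(f.sum() - 1.0) > _NORM_TOL:
            raise ValidationError(
                f"{label} is not normalized (sums to {f.sum():.12g})")
    return float(np.abs(fb - fa).sum() / delta_days)


def series_sr(bm: BiomassMatrix, site_id: str) -> SuccessionSeries:
    """Consecutive-pair SR series for one site.

    Samples at the site are ordered by date; each adjacent pair yields
    one interval with delta in calendar days. Samples with zero total
    biomass (undefined relative biomass) are dropped with a warning.
    """
    idx = [i for i, (s, _) in enumerate(bm.samples) if s == site_id]
    if not idx:
        raise ValidationError(f"no samples for site {site_id!r}")
    idx.sort(key=lambda i: bm.samples[i][1])
    keep, dropped = [], []
    for i in idx:
        if np.isnan(bm.relative[i]).any():
            dropped.append(bm.samples[i])
        else:
            keep.append(i)
    if dropped:
        logger.warning("site %s: dropping %d zero-biomass sample(s): %s",
                       site_id, len(dropped), dropped)
    if len(keep) < 2:
        raise ValidationError(
            f"site {site_id!r} has {len(keep)} usable timepoint(s); need >= 2")
    dates = [bm.samples[i][1] for i in keep]
    if len(set(dates)) != len(dates):
        raise ValidationError(f"duplicate sampling dates at site {site_id!r}")
    profiles = bm.relative[keep]
    intervals = []
    for r in range(1, len(keep)):
        delta = (dates[r] - dates[r - 1]).days
        sr = succession_rate(profiles[r - 1], profiles[r], delta)
        intervals.append(Interval(a=dates[r - 1], b=dates[r],
                                  delta_days=float(delta), sr=sr))
    return SuccessionSeries(site_id=site_id, timepoints=dates,
                            profiles=profiles, groups=list(bm.groups),
                            intervals=intervals)


def all_series_sr(bm: BiomassMatrix) -> list[SuccessionSeries]:
    """One SuccessionSeries per site in the biomass matrix."""
    return [series_sr(bm, s) for s in sorted({s for s, _ in bm.samples})]


def aggregate_sr(series: list[SuccessionSeries],
                 by: str = "site") -> pd.DataFrame:
    """Mean interval SR grouped by month, year or site.

    An interval is attributed to the calendar month/year of its
    endpoint ``b``. Returns columns ``group_key``, ``mean_SR_per_day``
    (also 3-decimal rounded as ``mean_SR_3dp``) and ``n_intervals``.
    """
    if by not in ("month", "year", "site"):
        raise ValidationError(f"unknown aggregation key {by!r}")
    if not series:
        raise ValidationError("no succession series given")
    rows = []
    for s in series:
        for iv in s.intervals:
            if by == "month":
                key = f"{iv.b.year:04d}-{iv.b.month:02d}"
            elif by == "year":
                key = iv.b.year
            else:
                key = s.site_id
            rows.append((key, iv.sr))
    df = pd.DataFrame(rows, columns=["group_key", "sr"])
    out = (df.groupby("group_key", sort=True)["sr"]
             .agg(mean_SR_per_day="mean", n_intervals="size")
             .reset_index())
    out["mean_SR_3dp"] = out["mean_SR_per_day"].round(3)
    return out
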