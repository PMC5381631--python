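"""Per-cohort acceleration and adjacent-cohort slope-ratio statistics.

The *acceleration* of cancer incidence is the slope of log incidence
against log age.  Under a simple multistage model with k rate-limiting
steps the hazard is proportional to age^(k-1), so the acceleration is
k - 1 and a power-law cohort plots as a straight line in log-log space.

For each adjacent pair of 5-year cohorts we re-fit both slopes using only
the age bands observed in *both* cohorts (so the comparison is never
confounded by differing age support), take log2 of the recent:prior slope
ratio, and summarise the ratios by their mean, the standard error of that
mean, and the mean:SE ratio.  The mean of the log2 ratios is the log2 of
the geometric mean of the slope ratios — the multiplicative tendency of
the acceleration to change across cohorts.  A negative value means the
more recent cohorts' incidence rises less steeply with age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import AgeBand, CohortTable

__all__ = [
    "SlopeEstimate",
    "PairRatio",
    "AccelSummary",
    "AccelCurve",
    "loglog_slope",
    "common_bands",
    "pair_ratio",
    "all_pair_ratios",
    "summarize",
    "pointwise_acceleration",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope of log rate on log representative age for one cohort."""

    cohort_start: int
    bands_used: tuple[AgeBand, ...]
    slope: float
    intercept: float

    @property
    def n_points(self) -> int:
        return len(self.bands_used)


@dataclass(frozen=True)
class PairRatio:
    """Adjacent-cohort acceleration ratio on common age bands.

    ``log2_ratio`` is log2(slope_recent / slope_prior); NaN when fewer
    than two common usable bands exist or either slope is non-positive.
    """

    recent_cohort: int
    prior_cohort: int
    common_bands: tuple[AgeBand, ...]
    slope_recent: float
    slope_prior: float
    log2_ratio: float

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.log2_ratio)


@dataclass(frozen=True)
class AccelSummary:
    """Mean, SE and mean:SE of the non-missing adjacent-cohort log2 ratios."""

    ratios: tuple[PairRatio, ...]
    mean: float
    se: float
    z: float

    @property
    def n(self) -> int:
        return sum(not r.is_missing for r in self.ratios)


@dataclass(frozen=True)
class AccelCurve:
    """Pointwise (finite-difference) acceleration along one cohort's ages."""

    cohort_start: int
    points: tuple[tuple[float, float], ...]  # (age, acceleration)


# ---------------------------------------------------------------------------
# slope estimation
# ---------------------------------------------------------------------------


def loglog_slope(
    bands: list[AgeBand],
    rates,
    cohort_start: int = 0,
) -> SlopeEstimate | None:
    """OLS slope of log(rate) on log(representative age).

    Bands with zero, negative or missing rates are excluded (their log is
    undefined) with a logged warning; if fewer than two usable points
    remain, returns None.  The slope is invariant to the log base (both
    axes are transformed identically) and to rescaling all rates.
    """
    rates = np.asarray(rates, dtype=float)
    if len(bands) != rates.size:
        raise ValueError("bands and rates must have equal length")
    usable = np.isfinite(rates) & (rates > 0)
    if not np.all(usable):
        dropped = [b.label for b, u in zip(bands, usable) if not u]
        logger.warning(
            "cohort %s: excluding %d band(s) with zero/missing rate: %s",
            cohort_start, len(dropped), ", ".join(dropped),
        )
    if usable.sum() < 2:
        return None
    kept = [b for b, u in zip(bands, usable) if u]
    x = np.log([b.representative_age for b in kept])
    y = np.log(rates[usable])
    fit = stats.linregress(x, y)
    return SlopeEstimate(
        cohort_start=cohort_start,
        bands_used=tuple(kept),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def common_bands(table: CohortTable, a: int, b: int) -> list[AgeBand]:
    """Age bands with a finite, positive rate in both cohorts ``a`` and
    ``b`` of the same table, sorted ascending."""
    row_a, row_b = table.row(a), table.row(b)
    keep = np.isfinite(row_a) & (row_a > 0) & np.isfinite(row_b) & (row_b > 0)
    return [band for band, k in zip(table.bands, keep) if k]


def pair_ratio(table: CohortTable, recent: int) -> PairRatio:
    """log2 ratio of the recent cohort's slope to the adjacent prior
    cohort's slope, both fitted on their common age bands only."""
    prior = recent - 5
    if prior not in table.cohort_starts:
        raise ValueError(f"prior cohort {prior} absent from table")
    shared = common_bands(table, recent, prior)
    idx = [table.bands.index(b) for b in shared]
    fit_r = loglog_slope(shared, table.row(recent)[idx], recent) if len(shared) >= 2 else None
    fit_p = loglog_slope(shared, table.row(prior)[idx], prior) if len(shared) >= 2 else None
    s_r = fit_r.slope if fit_r else np.nan
    s_p = fit_p.slope if fit_p else np.nan
    if np.isfinite(s_r) and np.isfinite(s_p) and s_r > 0 and s_p > 0:
        ratio = float(np.log2(s_r / s_p))
    else:
        ratio = np.nan
    return PairRatio(
        recent_cohort=recent,
        prior_cohort=prior,
        common_bands=tuple(shared),
        slope_recent=s_r,
        slope_prior=s_p,
        log2_ratio=ratio,
    )


def all_pair_ratios(table: CohortTable) -> list[PairRatio]:
    """Pair ratios for every adjacent cohort pair of the table, oldest first."""
    return [pair_ratio(table, c) for c in table.cohort_starts[1:]]


def summarize(ratios: list[PairRatio]) -> AccelSummary:
    """Mean of the non-missing log2 ratios, its standard error (sample
    standard deviation over sqrt(n)) and the mean:SE ratio."""
    vals = np.array([r.log2_ratio for r in ratios if not r.is_missing])
    if vals.size < 2:
        raise ValueError("need at least 2 usable ratios to summarize")
    if np.all(vals == vals[0]):
        raise ValueError("zero standard error: all usable ratios are equal")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size))
    if se == 0:
        raise ValueError("zero standard error")
    return AccelSummary(ratios=tuple(ratios), mean=mean, se=se, z=mean / se)


def pointwise_acceleration(table: CohortTable, cohort_start: int) -> AccelCurve:
    """Finite-difference acceleration curve for one cohort.

    For each adjacent pair of usable bands the acceleration is
    dlog(rate)/dlog(age), attached to the geometric-mean age of the pair.
    For an exact power law c * age^m every point equals m.
    """
    row = table.row(cohort_start)
    keep = np.isfinite(row) & (row > 0)
    ages = np.array([b.representative_age for b in table.bands])[keep]
    rates = row[keep]
    if ages.size < 2:
        raise ValueError(f"cohort {cohort_start}: need at least 2 usable cells")
    accel = np.diff(np.log(rates)) / np.diff(np.log(ages))
    mid_ages = np.sqrt(ages[:-1] * ages[1:])
    return AccelCurve(
        cohort_start=cohort_start,
        points=tuple(zip(mid_ages.tolist(), accel.tolist())),
    )
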