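"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check:
``grid_refine_slope`` minimises the least-squares objective by bracketed
grid refinement instead of the normal equations, and
``two_point_slope`` is the closed form for n = 2.
"""

from __future__ import annotations

import io

import numpy as np
import pytest
from hypothesis import settings

import cohortaccel as ca

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

GB_YEARS = range(1975, 2015)

#: the 16 printed adjacent-cohort log2 ratios for GB males (recent cohort
#: 1900-04 ... 1975-79), plus the printed summary row
PRINTED_GB_RATIOS = [
    0.03, 0.01, -0.07, -0.03, -0.04, -0.05, -0.02, -0.02,
    -0.07, -0.06, -0.07, -0.09, -0.12, -0.02, -0.20, -0.28,
]
PRINTED_GB_SUMMARY = {"mean": -0.07, "se": 0.02, "z": -3.54}


@pytest.fixture(scope="session")
def table1() -> ca.CohortTable:
    return ca.load_table1()


@pytest.fixture(scope="session")
def gb_spec() -> ca.CohortSpec:
    return ca.CohortSpec(1895, 1975, min_age=25)


@pytest.fixture()
def embedded_registry(table1, gb_spec) -> ca.PeriodAgeRateTable:
    """A period x age table whose Lexis diagonals carry the cohort-table
    values unchanged, so extraction must reproduce the cohort table."""
    years = list(GB_YEARS)
    bands = list(table1.bands)
    rate = np.full((len(years), len(bands)), np.nan)
    for i, y in enumerate(years):
        for j, band in enumerate(bands):
            c = ca.cohort_for(y, band, gb_spec)
            if c is not None:
                v = table1.cell(c, band)
                if np.isfinite(v):
                    rate[i, j] = v
    return ca.PeriodAgeRateTable(years=years, bands=bands, rate=rate)


def grid_refine_slope(ages, rates, lo=-60.0, hi=60.0, iters=40) -> float:
    """Brute-force least-squares slope in log-log space.

    For a candidate slope m the optimal intercept is mean(y - m x); the
    slope is found by repeatedly refining a 41-point grid around the
    minimum of the residual sum of squares.
    """
    x = np.log(np.asarray(ages, dtype=float))
    y = np.log(np.asarray(rates, dtype=float))

    def sse(m: float) -> float:
        b = float(np.mean(y - m * x))
        return float(np.sum((y - m * x - b) ** 2))

    for _ in range(iters):
        grid = np.linspace(lo, hi, 41)
        i = int(np.argmin([sse(m) for m in grid]))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
    return 0.5 * (lo + hi)


def two_point_slope(a1, r1, a2, r2) -> float:
    return float(np.log(r2 / r1) / np.log(a2 / a1))


def make_ratios(values) -> list[ca.PairRatio]:
    """Wrap bare log2 values as PairRatio records for summarize()."""
    out = []
    for i, v in enumerate(values):
        c = 1900 + 5 * i
        out.append(
            ca.PairRatio(
                recent_cohort=c,
                prior_cohort=c - 5,
                common_bands=(),
                slope_recent=np.nan,
                slope_prior=np.nan,
                log2_ratio=float(v) if v is not None else np.nan,
            )
        )
    return out


def csv_table(text: str):
    """A file-like CSV source from an inline string."""
    return io.StringIO(text.strip() + "\n")
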