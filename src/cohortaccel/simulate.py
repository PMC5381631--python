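"""Multistage-carcinogenesis registry simulator with known ground truth.

Generates period x age incidence tables from a cohort-varying power-law
hazard with Poisson count noise.  Under the classical multistage model,
a cancer requiring k rate-limiting steps has incidence approximately

    I(t) = A * t^(k-1)

at age t, so the log-log age-incidence slope (the acceleration) is
exactly k - 1.  Letting k and A vary across birth cohorts scripts the
scenario of interest — rising baseline incidence with falling
acceleration, the pattern produced in other cancers by knocking out
protective mechanisms — while keeping the true acceleration of every
cohort known in closed form, so the whole extraction-and-regression
pipeline can be checked against ground truth.

Counts are drawn per (year, band) cell as Poisson with mean
``expected_rate * person_years / 100000``; each cell's hazard is
evaluated at the band's representative (midpoint) age for the cell's
assigned cohort, matching how the estimator treats bands so that
estimator error is isolated from band-discretisation error.  An exact
within-band integration mode is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .acceleration import AccelSummary, PairRatio
from .cohorts import STANDARD_BANDS, CohortSpec, cohort_for
from .io import AgeBand, PeriodAgeRateTable

__all__ = [
    "MultistageParams",
    "interp_anchors",
    "expected_rate",
    "simulate_registry",
    "ground_truth_slopes",
    "ground_truth_summary",
    "gb_like_scenario",
    "scenario_from_config",
]


def interp_anchors(anchors: dict[int, float], starts: list[int]) -> np.ndarray:
    """Linearly interpolate per-cohort values from anchor cohorts.

    Values outside the anchor span are held at the nearest anchor.
    """
    if not anchors:
        raise ValueError("need at least one anchor")
    xs = sorted(anchors)
    ys = [anchors[x] for x in xs]
    return np.interp(starts, xs, ys)


@dataclass
class MultistageParams:
    """Ground-truth generative parameters for a synthetic Lexis surface.

    ``k[i]`` (number of rate-limiting steps, >= 2) and ``A[i]`` (baseline
    hazard per 100,000 person-years at age 1) are per cohort of ``spec``;
    ``period_mult`` maps calendar years to a multiplicative diagnosis-
    intensity factor (unlisted years default to 1); ``person_years`` is
    the population-time per cell, a scalar or a (n_years, n_bands) array.
    """

    spec: CohortSpec
    years: list[int]
    bands: list[AgeBand] = field(default_factory=lambda: list(STANDARD_BANDS))
    k: np.ndarray = field(default_factory=lambda: np.full(17, 6.0))
    A: np.ndarray = field(default_factory=lambda: np.full(17, 1e-6))
    period_mult: dict[int, float] = field(default_factory=dict)
    person_years: float | np.ndarray = 3e6
    seed: int = 0

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        n = self.spec.n_cohorts
        if self.k.shape != (n,) or self.A.shape != (n,):
            raise ValueError(f"k and A must have one value per cohort ({n})")
        if np.any(self.k < 2):
            raise ValueError("k must be >= 2")
        if np.any(self.A < 0):
            raise ValueError("A must be non-negative")
        if np.any(np.asarray(self.person_years) <= 0):
            raise ValueError("person_years must be positive")

    def cohort_params(self, cohort_start: int) -> tuple[float, float]:
        """(A, k) for a birth cohort, clamped to the spec's span."""
        starts = self.spec.starts
        c = min(max(cohort_start, starts[0]), starts[-1])
        i = starts.index(c)
        return float(self.A[i]), float(self.k[i])


def expected_rate(
    age: float,
    cohort_start: int,
    year: int,
    params: MultistageParams,
    integrate_band: AgeBand | None = None,
) -> float:
    """Noise-free incidence per 100,000 person-years.

    ``period_mult[year] * A[cohort] * age**(k[cohort] - 1)``, evaluated at
    the given exact age; when ``integrate_band`` is passed, the hazard is
    instead averaged exactly over the band's 5-year age interval.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    a, k = params.cohort_params(cohort_start)
    mult = params.period_mult.get(year, 1.0)
    if integrate_band is None:
        return mult * a * age ** (k - 1)
    lo = float(integrate_band.lower)
    hi = lo + 5.0
    return mult * a * (hi**k - lo**k) / (k * 5.0)


def _py_matrix(params: MultistageParams) -> np.ndarray:
    shape = (len(params.years), len(params.bands))
    py = np.asarray(params.person_years, dtype=float)
    return np.broadcast_to(py, shape)


def simulate_registry(
    params: MultistageParams,
    seed: int | None = None,
    integrate_bands: bool = False,
) -> PeriodAgeRateTable:
    """Draw one registry table: Poisson counts, then rates per 100,000.

    Each cell (year, band) belongs to the cohort containing
    ``year - band.lower`` (the same Lexis-diagonal convention the
    extraction uses); its expected count is the cohort's hazard at the
    band's representative age times the cell's person-years / 100,000.
    Reproducible: one named pseudo-random stream per table, no global
    state.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    py = _py_matrix(params)
    mean_rate = np.zeros_like(py)
    for i, year in enumerate(params.years):
        for j, band in enumerate(params.bands):
            c = cohort_for(year, band, params.spec)
            if c is None:  # clamp cohorts outside the span to the nearest
                c = year - band.lower
            mean_rate[i, j] = expected_rate(
                band.representative_age, c, year, params,
                integrate_band=band if integrate_bands else None,
            )
    counts = rng.poisson(mean_rate * py / 100000.0).astype(float)
    rate = 100000.0 * counts / py
    return PeriodAgeRateTable(
        years=list(params.years),
        bands=list(params.bands),
        rate=rate,
        count=counts,
        person_years=py.copy(),
        sex="synthetic",
        population="multistage simulation",
    )


def ground_truth_slopes(params: MultistageParams) -> dict[int, float]:
    """True acceleration per cohort: k - 1, independent of age."""
    return {c: float(k) - 1.0 for c, k in zip(params.spec.starts, params.k)}


def ground_truth_summary(params: MultistageParams) -> AccelSummary:
    """Noise-free adjacent-cohort log2 acceleration ratios and their
    mean/SE/mean:SE, for comparison against pipeline estimates.

    Unlike the estimator-side :func:`~cohortaccel.acceleration.summarize`,
    degenerate ground truths are representable rather than errors: a
    constant-k scenario yields all-zero ratios with se = 0 (z undefined,
    NaN), and a two-cohort scenario yields a single ratio with se = NaN.
    """
    starts = params.spec.starts
    if len(starts) < 2:
        raise ValueError("need at least 2 cohorts for ground-truth ratios")
    slopes = ground_truth_slopes(params)
    ratios = [
        PairRatio(
            recent_cohort=c,
            prior_cohort=c - 5,
            common_bands=(),
            slope_recent=slopes[c],
            slope_prior=slopes[c - 5],
            log2_ratio=float(np.log2(slopes[c] / slopes[c - 5])),
        )
        for c in starts[1:]
    ]
    vals = np.array([r.log2_ratio for r in ratios])
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else float("nan")
    z = mean / se if np.isfinite(se) and se > 0 else float("nan")
    return AccelSummary(ratios=tuple(ratios), mean=mean, se=se, z=z)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def gb_like_scenario(seed: int = 0, person_years: float | np.ndarray = 3e6) -> MultistageParams:
    """Default scenario qualitatively mimicking GB males.

    17 cohorts 1895-1975, registry years 1975-2014, bands 25-29 ... 85+;
    k declines linearly from 7 to 5 across cohorts (acceleration 6 -> 4)
    while the baseline scale A rises so that incidence at age 60 climbs
    from about 6 to about 44 per 100,000 person-years, the span seen in
    the GB male melanoma table.  Person-years of 3e6 per cell is a
    realistic national-registry order of magnitude.
    """
    spec = CohortSpec(1895, 1975)
    starts = spec.starts
    k = interp_anchors({1895: 7.0, 1975: 5.0}, starts)
    rate60 = np.geomspace(6.0, 44.0, len(starts))
    A = rate60 / 60.0 ** (k - 1.0)
    return MultistageParams(
        spec=spec,
        years=list(range(1975, 2015)),
        k=k,
        A=A,
        person_years=person_years,
        seed=seed,
    )


def scenario_from_config(source) -> MultistageParams:
    """Build simulation parameters from a YAML scenario file or mapping.

    Keys: first_cohort, last_cohort, min_age, years: [first, last],
    k_anchors and rate60_anchors (cohort -> value, linearly interpolated;
    rate60 is the target incidence at age 60 from which A is derived),
    optional A_anchors (overrides rate60_anchors), period_mult
    (year -> factor), person_years, seed.
    """
    if isinstance(source, dict):
        cfg = source
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    spec = CohortSpec(
        int(cfg.get("first_cohort", 1895)),
        int(cfg.get("last_cohort", 1975)),
        min_age=int(cfg.get("min_age", 25)),
    )
    starts = spec.starts
    y0, y1 = cfg.get("years", [1975, 2014])
    k = interp_anchors({int(c): float(v) for c, v in cfg.get("k_anchors", {1895: 6}).items()}, starts)
    if "A_anchors" in cfg:
        A = interp_anchors({int(c): float(v) for c, v in cfg["A_anchors"].items()}, starts)
    else:
        rate60 = interp_anchors(
            {int(c): float(v) for c, v in cfg.get("rate60_anchors", {1895: 10.0}).items()},
            starts,
        )
        A = rate60 / 60.0 ** (k - 1.0)
    return MultistageParams(
        spec=spec,
        years=list(range(int(y0), int(y1) + 1)),
        k=k,
        A=A,
        period_mult={int(y): float(m) for y, m in cfg.get("period_mult", {}).items()},
        person_years=float(cfg.get("person_years", 3e6)),
        seed=int(cfg.get("seed", 0)),
    )
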