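# Methods

## Model and procedure

The quantity of interest is the *acceleration* of cancer incidence with
age: the derivative of log incidence with respect to log age. Under the
classical multistage picture of carcinogenesis, a cancer requiring `k`
rate-limiting events has hazard approximately `I(t) = A·t^(k−1)` at age
`t`, so the acceleration is the constant `k − 1` and cohorts plot as
straight lines in log-log space. Empirical age-incidence curves are
straight enough that a single OLS slope per cohort is a useful summary.

The pipeline:

1. **Cohort extraction.** A registry table gives rates per 100,000
   person-years by calendar year and 5-year age band. A cell
   `(year y, band [a, a+4])` is assigned to the 5-year birth cohort
   containing `y − a`; equivalently, cohort `c` is observed in band
   `[a, a+4]` during years `c+a … c+a+4`. This pins the Lexis diagonal to
   the band's lower edge. It is the unique simple convention that
   reproduces the observed support of the packaged GB-male table at both
   registry boundaries (the 1895-99 cohort first appears at 80-84 because
   1895+80 = 1975, the registry's first year; the 1975-79 cohort last
   appears at 35-39 because 1979+35 = 2014, its last year). Each cohort
   cell is the unweighted arithmetic mean of its 5 assigned annual rates
   — unweighted because rate-only tables carry no population weights.
2. **Slope per cohort.** OLS regression of `log(rate)` on
   `log(representative age)` over the cohort's usable bands.
   Representative ages are band midpoints (27.5, 32.5, …, 82.5), and
   87.5 for the open-ended 85+ band — the same `lower + 2.5` offset, kept
   so ages stay evenly spaced on the log axis. Zero or missing rates are
   excluded before fitting (their log is undefined); a cohort with fewer
   than 2 usable points has no slope.
3. **Adjacent-pair ratios on common ages.** For cohorts `c` and `c−5`,
   both slopes are re-fitted using only the age bands with positive,
   observed rates in *both* cohorts, so the ratio is never confounded by
   differing age support. The statistic is `r = log2(slope_c /
   slope_{c−5})`; it is missing when fewer than 2 common bands exist or
   either slope is non-positive.
4. **Summary.** Over the non-missing ratios: mean r̄ (equal to log2 of
   the geometric mean of the slope ratios), standard error
   `sd(r)/√n` with the n−1 sample standard deviation, and the ratio
   r̄/SE as the number of standard errors the trend sits from zero.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `CohortSpec.first_start`, `last_start` | 1895, 1975 | birth years of the first/last 5-year cohort (17 cohorts) |
| `CohortSpec.min_age` | 25 years | youngest analysed band; melanoma rates below 25 are too sparse for stable log-log fits |
| `min_coverage` | 1.0 | fraction of the 5 assigned years a cell needs; 1.0 drops diagonals truncated by the registry's year range, lower values keep partial averages |
| summary precision | 2 decimals | output formatting only; full precision kept internally |

Rates are per 100,000 person-years throughout and never rescaled
internally — the log-log slope is invariant to any positive rescaling,
and so are the ratios and summary (a property the tests assert).

## Numerical choices

- Slopes via `scipy.stats.linregress` on natural-log axes; the slope is
  identical in any log base since both axes transform alike. Only the
  final ratio transform is base-fixed at 2.
- The pointwise acceleration curve uses two-point finite differences of
  adjacent usable bands in log-log space, each attached to the
  geometric-mean age of the pair (the natural abscissa for a log-age
  derivative). It is a diagnostic/plotting device, not an input to the
  summary statistic.
- Degenerate inputs are hard errors, not silent NaNs: fewer than 2 usable
  ratios, or all ratios identical (zero standard error), refuse to
  summarize. Missing pair ratios are carried as NaN and rendered as blank
  cells on output.
- Band labels accept hyphen and en-dash range dialects and "85+" /
  "85 and over"; output always uses the hyphen forms.

## Synthetic-data generator

`cohortaccel.simulate` emulates a national registry observed over a fixed
window of calendar years. Per cohort `c` it takes a step count `k[c]`
(≥ 2) and baseline scale `A[c]`, both specified at anchor cohorts and
linearly interpolated, plus an optional per-year multiplicative
diagnosis-intensity factor (a pure period effect). For each (year, band)
cell, the hazard is evaluated at the band's representative age for the
cell's assigned cohort — deliberately matching the estimator's treatment
of bands so that pipeline error is isolated from band-discretisation
error; an exact within-band integration mode exists for sensitivity
checks. Counts are Poisson with mean `rate × person_years / 100,000`,
from one explicitly seeded generator per table (no global state).

The shipped default scenario (`data/gb_like_scenario.yaml`) mimics the GB
male pattern qualitatively: 17 cohorts 1895–1975 observed 1975–2014 in
bands 25-29 … 85+, `k` falling linearly 7 → 5 (true acceleration 6 → 4)
while incidence at age 60 rises from 6 to 44 per 100,000 person-years;
3×10⁶ person-years per cell is a realistic national-registry magnitude.
Ground truth is available in closed form: slope `k[c] − 1` per cohort and
log2 ratios `log2((k[c]−1)/(k[c−5]−1))`. For the ground-truth summary,
degenerate truths stay representable (constant `k` gives all-zero ratios
with SE 0 and undefined z) rather than raising as the estimator-side
summary does, since the generator must be able to describe null scenarios.

What the generator does *not* emulate: within-band age structure in the
population (person-years are uniform unless given per cell), registry
artefacts such as reporting delay or diagnostic drift beyond a smooth
period multiplier, overdispersion beyond Poisson, and any
melanoma-specific dose-response. Passing recovery tests therefore shows
the extraction-and-regression machinery is unbiased under a clean
power-law world with Poisson noise — not that real registry data satisfy
those assumptions.

## Problem sizes used in the checks

The recovery checks run the full pipeline on simulated GB-shaped tables
(40 years × 13 bands): once at 10⁹ person-years per cell, where Poisson
noise is negligible and slopes must land within ±0.05 of `k − 1`, and
over 20 replicate seeds at 3×10⁶ person-years per cell, where the
summary's mean:SE must come out negative in at least 19 of 20 replicates.
The OLS slope is cross-checked against a brute-force grid-refinement
least-squares oracle on 100 random small instances.

## Known limitations

- No formal age-period-cohort regression: period and cohort effects are
  not jointly identified here, and the adjacent-pair statistic will pick
  up strong period trends as apparent cohort trends (the simulator's
  period multiplier lets one quantify that artefact for a scenario).
- No confidence intervals on individual slopes and no weighting by case
  counts; with rate-only tables the information per band is unknown.
- The open-ended 85+ band's position on the age axis (87.5) is a
  convention; individual slopes of old cohorts move slightly under other
  placements, though pair ratios barely do because both cohorts in a pair
  share the same age design.
- 5-year period-band inputs are expanded by carrying each period's rate
  into its constituent years, which flattens within-period trends.
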