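# cohortaccel

Birth-cohort acceleration analysis of cancer registry incidence tables.

Cancer incidence rises with age roughly as a power law, `I(t) ≈ A·t^(k−1)`,
so log incidence against log age is close to a straight line whose slope —
the **acceleration** of cancer with age — is `k − 1` under the classical
multistage model with `k` rate-limiting steps. When overall incidence is
drifting over calendar time, age-specific rates are confounded by year of
birth; the clean unit of analysis is the **birth cohort**, which traces a
diagonal across the registry's calendar-year × age-band plane (the Lexis
diagram). This package is for epidemiologists and biostatisticians who
want to ask: *is the age-incidence curve getting shallower (or steeper)
across successive birth cohorts?*

It implements the full pipeline:

1. **`cohortaccel.io`** — read/write period × age registry rate tables,
   cohort × age tables, and summary rows (plain CSV/TSV; counts +
   person-years or precomputed rates; 5-year period dialects expanded to
   annual years). A GB-male melanoma cohort table (17 cohorts 1895-99 …
   1975-79, ages 25+) ships as a packaged example dataset.
2. **`cohortaccel.cohorts`** — extract non-overlapping 5-year birth
   cohorts along Lexis diagonals: cohort `c` occupies age band `[a, a+4]`
   during calendar years `c+a … c+a+4`, and each cell is the unweighted
   mean of the 5 assigned annual rates.
3. **`cohortaccel.acceleration`** — per-cohort OLS slope of log rate on
   log midpoint age; for each adjacent cohort pair, both slopes re-fitted
   on the **common** age bands only, then `r = log2(slope_recent /
   slope_prior)`; summary mean r̄, its standard error, and r̄/SE. The mean
   of the log2 ratios is the log2 of the geometric mean of the slope
   ratios; a negative value means incidence rises less steeply with age
   in more recent cohorts.
4. **`cohortaccel.simulate`** — a multistage-carcinogenesis registry
   simulator: cohort-varying `(A, k)` power-law hazards, optional
   calendar-period multipliers, Poisson count noise at stated
   person-years — synthetic inputs with *known* ground-truth
   accelerations (`k − 1`) for validating the whole pipeline.
5. **`cohortaccel.plots` / `cohortaccel.cli`** — log-log incidence and
   acceleration figures (each with its plotted data exported as CSV) and
   a `cohortaccel` command with `assemble`, `accelerate`, `summarize`,
   `simulate`, `plot` and `all` subcommands.

## Worked example

```python
import cohortaccel as ca

table = ca.load_table1()                 # packaged GB-male melanoma cohort table
ratios = ca.all_pair_ratios(table)       # 16 adjacent-cohort log2 slope ratios
for r in ratios[-3:]:
    print(f"{ca.cohort_label(r.recent_cohort)} vs {ca.cohort_label(r.prior_cohort)}: "
          f"slopes {r.slope_recent:.2f} / {r.slope_prior:.2f}, log2 ratio {r.log2_ratio:+.2f}")
s = ca.summarize(ratios)
print(f"mean log2 ratio {s.mean:.2f}, SE {s.se:.2f}, mean:SE {s.z:.2f} over {s.n} pairs")
```

prints

```
1965-69 vs 1960-64: slopes 3.29 / 3.30, log2 ratio -0.01
1970-74 vs 1965-69: slopes 2.88 / 3.34, log2 ratio -0.21
1975-79 vs 1970-74: slopes 2.47 / 3.03, log2 ratio -0.29
mean log2 ratio -0.07, SE 0.02, mean:SE -3.31 over 16 pairs
```

Read: the 1975-79 cohort's incidence climbs with age markedly more slowly
than the 1970-74 cohort's (log2 ratio −0.29 ≈ a 18% shallower slope), and
across all 16 adjacent pairs the slope shrinks by a geometric-mean factor
of `2^−0.07 ≈ 0.95` per 5-year cohort — a decline 3.3 standard errors
from zero. Rising incidence with falling acceleration is the signature
pattern produced in other cancers when a protective mechanism is
abrogated.

The same run from the shell, plus figures:

```sh
cohortaccel simulate -o registry.csv --seed 1     # or bring your own registry table
cohortaccel all --input registry.csv -o results/
```

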