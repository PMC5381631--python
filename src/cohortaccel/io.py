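"""Reading, validating and writing the tabular formats of the pipeline.

Three table kinds move through the analysis:

* a registry-style *period x age* rate table (calendar years in one
  dimension, 5-year age bands in the other, incidence per 100,000
  person-years in the cells),
* a *cohort x age* table of 5-year-averaged rates per birth cohort, and
* a one-row summary of adjacent-cohort log2 slope ratios.

All three are plain delimited text (CSV or TSV, autodetected from the
file extension).  Missing cells are blank on disk and NaN in memory;
a missing cell is distinct from a rate of 0.0.
"""

from __future__ import annotations

import io as _stdio
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AgeBand",
    "PeriodAgeRateTable",
    "CohortTable",
    "TableFormatError",
    "parse_band_label",
    "parse_cohort_label",
    "cohort_label",
    "read_rate_table",
    "write_rate_table",
    "read_cohort_table",
    "write_cohort_table",
    "write_summary",
    "read_summary",
    "load_table1",
]

#: Offset from a band's lower edge to its representative (midpoint) age.
#: Closed 5-year bands [a, a+4] cover exact ages [a, a+5), midpoint a+2.5;
#: the open-ended terminal band uses the same offset by convention so that
#: representative ages stay evenly spaced on the log-age axis.
REPRESENTATIVE_AGE_OFFSET = 2.5


class TableFormatError(ValueError):
    """A table violates the format contract (labels, shape or invariants)."""


# ---------------------------------------------------------------------------
# age bands and label dialects
# ---------------------------------------------------------------------------

_CLOSED_BAND_RE = re.compile(r"^\s*(\d+)\s*[-–—]\s*(\d+)\s*$")
_OPEN_BAND_RE = re.compile(r"^\s*(\d+)\s*(?:\+|and\s+over|and\s+older)\s*$", re.IGNORECASE)


@dataclass(frozen=True)
class AgeBand:
    """A 5-year age band, or the open-ended terminal band (e.g. 85+).

    ``upper`` is ``None`` for the open-ended band.  The representative age
    used on the age axis is the band midpoint, ``lower + 2.5`` (87.5 for
    85+ by the same convention).
    """

    lower: int
    upper: int | None = None

    def __post_init__(self) -> None:
        if self.lower < 0 or self.lower % 5 != 0:
            raise TableFormatError(
                f"band lower edge must be a non-negative multiple of 5, got {self.lower}"
            )
        if self.upper is not None and self.upper != self.lower + 4:
            raise TableFormatError(
                f"closed bands must be 5 years wide, got {self.lower}-{self.upper}"
            )

    @property
    def is_open(self) -> bool:
        return self.upper is None

    @property
    def representative_age(self) -> float:
        return self.lower + REPRESENTATIVE_AGE_OFFSET

    @property
    def label(self) -> str:
        return f"{self.lower}+" if self.is_open else f"{self.lower}-{self.upper}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def parse_band_label(label: str) -> AgeBand:
    """Parse an age-band label in any accepted dialect.

    Accepts "25-29" (hyphen), "25–29" (en dash), "85+" and "85 and over".
    """
    m = _CLOSED_BAND_RE.match(label)
    if m:
        return AgeBand(int(m.group(1)), int(m.group(2)))
    m = _OPEN_BAND_RE.match(label)
    if m:
        return AgeBand(int(m.group(1)), None)
    raise TableFormatError(f"unparseable age-band label: {label!r}")


def _check_bands(bands: Sequence[AgeBand]) -> None:
    for a, b in zip(bands, bands[1:]):
        if a.is_open:
            raise TableFormatError("open-ended band must be last")
        if b.lower <= a.lower:
            raise TableFormatError("bands must be sorted ascending and non-overlapping")


# ---------------------------------------------------------------------------
# cohort labels ("1895-99", "1895–1899")
# ---------------------------------------------------------------------------

_COHORT_RE = re.compile(r"^\s*(\d{4})\s*[-–—]\s*(\d{2}|\d{4})\s*$")


def parse_cohort_label(label: str) -> int:
    """Parse a 5-year birth-cohort label such as '1895-99' to its start year."""
    m = _COHORT_RE.match(str(label))
    if not m:
        raise TableFormatError(f"unparseable cohort label: {label!r}")
    start = int(m.group(1))
    end = int(m.group(2))
    if end < 100:
        end += (start // 100) * 100
        if end < start:  # century wrap, e.g. 1995-00... not expected but safe
            end += 100
    if end != start + 4:
        raise TableFormatError(f"cohort label must span 5 birth years: {label!r}")
    return start


def cohort_label(start: int) -> str:
    return f"{start}-{(start + 4) % 100:02d}"


# ---------------------------------------------------------------------------
# period x age rate tables
# ---------------------------------------------------------------------------

_PERIOD_RE = re.compile(r"^\s*(\d{4})\s*[-–—]\s*(\d{2}|\d{4})\s*$")


@dataclass
class PeriodAgeRateTable:
    """Registry-style incidence-rate matrix: calendar year x age band.

    ``rate[i, j]`` is the incidence per 100,000 person-years in calendar
    year ``years[i]`` and age band ``bands[j]``; NaN marks a missing cell.
    Optional ``count`` and ``person_years`` carry the raw ingredients when
    the source table provides counts rather than rates.
    """

    years: list[int]
    bands: list[AgeBand]
    rate: np.ndarray
    count: np.ndarray | None = None
    person_years: np.ndarray | None = None
    sex: str = ""
    population: str = ""

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        self.validate()

    def validate(self) -> None:
        ny, nb = len(self.years), len(self.bands)
        if self.rate.shape != (ny, nb):
            raise TableFormatError(
                f"rate matrix shape {self.rate.shape} does not match "
                f"{ny} years x {nb} bands"
            )
        if list(self.years) != list(range(self.years[0], self.years[0] + ny)):
            raise TableFormatError("non-contiguous years")
        _check_bands(self.bands)
        with np.errstate(invalid="ignore"):
            if np.any(self.rate < 0):
                raise TableFormatError("negative rate")
        if self.count is not None and self.person_years is not None:
            if np.any(self.person_years <= 0):
                raise TableFormatError("person_years must be positive")
            implied = 100000.0 * self.count / self.person_years
            ok = np.isnan(self.rate) | np.isclose(self.rate, implied, rtol=1e-3, atol=0.05)
            if not np.all(ok):
                raise TableFormatError("rate inconsistent with count / person_years")

    @property
    def year_range(self) -> range:
        return range(self.years[0], self.years[-1] + 1)

    def band_index(self, band: AgeBand) -> int:
        return self.bands.index(band)

    def rate_at(self, year: int, band: AgeBand) -> float:
        return float(self.rate[self.years.index(year), self.band_index(band)])


def _load_schema(schema: Mapping | str | Path | None) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            loaded = yaml.safe_load(fh) or {}
        return dict(loaded)
    return dict(schema)


def _delimiter_for(source, override: str | None) -> str:
    if override:
        return override
    name = getattr(source, "name", source if isinstance(source, (str, Path)) else "")
    return "\t" if str(name).endswith(".tsv") else ","


def _read_raw(source, delim: str) -> pd.DataFrame:
    df = pd.read_csv(source, sep=delim, index_col=0, dtype=str, skipinitialspace=True)
    return df


def _parse_year_labels(labels: Sequence[str]) -> list[list[int]]:
    """Each label maps to the list of calendar years it covers.

    Plain integers cover one year; 5-year period labels such as
    "1980-1984" (the dialect of registries publishing quinquennial rates)
    are expanded to their 5 constituent years.
    """
    out: list[list[int]] = []
    for lab in labels:
        s = str(lab).strip()
        if re.fullmatch(r"\d{4}", s):
            out.append([int(s)])
            continue
        m = _PERIOD_RE.match(s)
        if m:
            start = int(m.group(1))
            end = int(m.group(2))
            if end < 100:
                end += (start // 100) * 100
            if end < start:
                raise TableFormatError(f"invalid period label: {lab!r}")
            out.append(list(range(start, end + 1)))
            continue
        raise TableFormatError(f"unparseable year label: {lab!r}")
    return out


def _parse_cells(df: pd.DataFrame, kind: str) -> np.ndarray:
    vals = np.full(df.shape, np.nan)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = df.iat[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            s = str(cell).strip()
            if not s:
                continue
            try:
                vals[i, j] = float(s)
            except ValueError:
                raise TableFormatError(
                    f"unparseable {kind} {s!r} at row {i + 1}, column {j + 1}"
                ) from None
    return vals


def read_rate_table(
    source: str | Path | IO[str],
    schema: Mapping | str | Path | None = None,
) -> PeriodAgeRateTable:
    """Read a period x age incidence table from delimited text.

    ``schema`` (a mapping, or a path to a YAML file) controls the dialect:

    ``orientation``
        "years_rows" (default): years label the rows, age bands the columns;
        "bands_rows": the transpose.
    ``values``
        "rate" (default) or "count"; counts are converted to rates using
        ``person_years``.
    ``person_years``
        scalar person-years per cell (required when ``values: count``).
    ``delimiter``, ``sex``, ``population``
        optional overrides / metadata labels.
    """
    cfg = _load_schema(schema)
    delim = _delimiter_for(source, cfg.get("delimiter"))
    df = _read_raw(source, delim)
    if cfg.get("orientation", "years_rows") == "bands_rows":
        df = df.T

    band_labels = list(df.columns)
    bands = []
    for j, lab in enumerate(band_labels):
        try:
            bands.append(parse_band_label(str(lab)))
        except TableFormatError:
            raise TableFormatError(
                f"unparseable age-band label {lab!r} in column {j + 2}"
            ) from None

    year_groups = _parse_year_labels(list(df.index))
    values = _parse_cells(df, cfg.get("values", "rate"))

    # expand period rows (each period year carries the period's rate)
    years: list[int] = []
    rows: list[np.ndarray] = []
    for grp, row in zip(year_groups, values):
        for y in grp:
            years.append(y)
            rows.append(row)
    order = np.argsort(years)
    years = [years[i] for i in order]
    matrix = np.vstack([rows[i] for i in order])
    if len(set(years)) != len(years):
        raise TableFormatError("duplicate years in table")

    count = person_years = None
    if cfg.get("values", "rate") == "count":
        py = cfg.get("person_years")
        if py is None:
            raise TableFormatError("schema with values=count requires person_years")
        count = matrix
        person_years = np.full_like(matrix, float(py))
        matrix = 100000.0 * count / person_years

    return PeriodAgeRateTable(
        years=years,
        bands=bands,
        rate=matrix,
        count=count,
        person_years=person_years,
        sex=str(cfg.get("sex", "")),
        population=str(cfg.get("population", "")),
    )


def write_rate_table(
    table: PeriodAgeRateTable,
    sink: str | Path | IO[str],
    precision: int = 4,
) -> None:
    """Write a period x age table (years as rows) as delimited text."""
    delim = _delimiter_for(sink, None)
    df = pd.DataFrame(
        np.round(table.rate, precision),
        index=pd.Index(table.years, name="year"),
        columns=[b.label for b in table.bands],
    )
    df.to_csv(sink, sep=delim, float_format=f"%.{precision}f", na_rep="")


# ---------------------------------------------------------------------------
# cohort x age tables
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """5-year-averaged age-specific rates by birth cohort.

    ``rate[i, j]`` is the average incidence per 100,000 person-years for
    the cohort starting in ``cohort_starts[i]`` at age band ``bands[j]``;
    NaN marks an unobserved (out-of-registry) cell.
    """

    cohort_starts: list[int]
    bands: list[AgeBand]
    rate: np.ndarray
    sex: str = ""
    population: str = ""

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        self.validate()

    def validate(self) -> None:
        nc, nb = len(self.cohort_starts), len(self.bands)
        if nc == 0:
            raise TableFormatError("no cohorts")
        if self.rate.shape != (nc, nb):
            raise TableFormatError(
                f"rate matrix shape {self.rate.shape} does not match "
                f"{nc} cohorts x {nb} bands"
            )
        steps = np.diff(self.cohort_starts)
        if nc > 1 and not np.all(steps == 5):
            raise TableFormatError("cohort columns not in 5-year steps")
        _check_bands(self.bands)
        with np.errstate(invalid="ignore"):
            if np.any(self.rate < 0):
                raise TableFormatError("negative rate")
        # each cohort's observed cells must form one contiguous age run
        # (a Lexis diagonal truncated by the registry's year range)
        for start, row in zip(self.cohort_starts, self.rate):
            obs = np.flatnonzero(np.isfinite(row))
            if obs.size and not np.array_equal(obs, np.arange(obs[0], obs[-1] + 1)):
                raise TableFormatError(
                    f"cohort {cohort_label(start)}: observed cells are not contiguous"
                )

    def cohort_index(self, start: int) -> int:
        return self.cohort_starts.index(start)

    def row(self, start: int) -> np.ndarray:
        return self.rate[self.cohort_index(start)]

    def observed_bands(self, start: int) -> list[AgeBand]:
        row = self.row(start)
        return [b for b, r in zip(self.bands, row) if np.isfinite(r)]

    def cell(self, start: int, band: AgeBand) -> float:
        return float(self.row(start)[self.bands.index(band)])


def read_cohort_table(source: str | Path | IO[str]) -> CohortTable:
    """Read a cohort x age table (age bands as rows, cohorts as columns)."""
    delim = _delimiter_for(source, None)
    try:
        df = _read_raw(source, delim)
    except pd.errors.EmptyDataError:
        raise TableFormatError("no cohorts") from None
    if df.shape[1] == 0:
        raise TableFormatError("no cohorts")
    starts = [parse_cohort_label(c) for c in df.columns]
    bands = [parse_band_label(str(b)) for b in df.index]
    vals = _parse_cells(df, "rate").T  # (n_cohorts, n_bands)
    return CohortTable(cohort_starts=starts, bands=bands, rate=vals)


def write_cohort_table(
    table: CohortTable,
    sink: str | Path | IO[str],
    precision: int = 1,
) -> None:
    """Write a cohort x age table; round-trips with :func:`read_cohort_table`
    bit-exactly at the declared decimal precision."""
    delim = _delimiter_for(sink, None)
    df = pd.DataFrame(
        table.rate.T,
        index=pd.Index([b.label for b in table.bands], name="age_band"),
        columns=[cohort_label(c) for c in table.cohort_starts],
    )
    df.to_csv(sink, sep=delim, float_format=f"%.{precision}f", na_rep="")


# ---------------------------------------------------------------------------
# acceleration summaries (the one-row mean / SE / mean:SE layout)
# ---------------------------------------------------------------------------


def write_summary(summary, sink: str | Path | IO[str], precision: int = 2) -> None:
    """Write an acceleration summary as one header + one data row.

    Columns: one per adjacent-cohort pair (labelled by the recent cohort),
    then Mean, SE and "Ratio mean:SE".  Missing pair ratios are emitted as
    blank cells.
    """
    ratios = list(summary.ratios)
    if not ratios:
        raise TableFormatError("nothing to summarize")
    delim = _delimiter_for(sink, None)
    header = [cohort_label(r.recent_cohort) for r in ratios] + ["Mean", "SE", "Ratio mean:SE"]

    def fmt(x: float) -> str:
        return "" if x is None or not np.isfinite(x) else f"{x:.{precision}f}"

    row = [fmt(r.log2_ratio) for r in ratios] + [
        fmt(summary.mean),
        fmt(summary.se),
        fmt(summary.z),
    ]
    text = delim.join(header) + "\n" + delim.join(row) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


def read_summary(source: str | Path | IO[str]) -> dict:
    """Re-read a written summary; returns ``{"ratios": {label: value},
    "mean": ..., "se": ..., "z": ...}`` with NaN for blank cells."""
    delim = _delimiter_for(source, None)
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise TableFormatError("summary must have a header and a data row")
    header = lines[0].split(delim)
    cells = lines[1].split(delim)
    vals = [float(c) if c.strip() else np.nan for c in cells]
    tail = {"Mean": "mean", "SE": "se", "Ratio mean:SE": "z"}
    out: dict = {"ratios": {}}
    for name, v in zip(header, vals):
        if name in tail:
            out[tail[name]] = v
        else:
            out["ratios"][name] = v
    return out


# ---------------------------------------------------------------------------
# packaged fixture
# ---------------------------------------------------------------------------


def load_table1() -> CohortTable:
    """The packaged GB-male melanoma cohort table (17 cohorts 1895-99 to
    1975-79, 13 age bands 25-29 to 85+, rates per 100,000 man-years)."""
    ref = resources.files("cohortaccel").joinpath("data/table1_gb_males.csv")
    with ref.open("r") as fh:
        table = read_cohort_table(_stdio.StringIO(fh.read()))
    table.sex = "male"
    table.population = "Great Britain"
    return table
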