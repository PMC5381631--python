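"""Log-log age-incidence and acceleration plots.

Figures are qualitative companions to the tables: every plot also writes
its plotted data as a CSV next to the figure file, because the data
export — not the rendered pixels — is the testable, diffable surface.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .acceleration import AccelCurve
from .io import CohortTable, cohort_label

__all__ = ["plot_incidence", "plot_acceleration"]


def _data_path(figure_path: Path) -> Path:
    return figure_path.with_suffix(".csv")


def plot_incidence(
    table: CohortTable,
    path: str | Path,
    thin_decadal: bool = False,
    title: str | None = None,
) -> Path:
    """Log-log age-incidence curves, one line per cohort.

    ``thin_decadal=True`` keeps only every other cohort (decadal spacing),
    the usual readability compromise for 17 overlapping curves.
    """
    path = Path(path)
    starts = table.cohort_starts[::2] if thin_decadal else table.cohort_starts
    records = []
    fig, ax = plt.subplots(figsize=(6, 5))
    n_lines = 0
    for c in starts:
        row = table.row(c)
        keep = np.isfinite(row) & (row > 0)
        if keep.sum() < 1:
            continue
        ages = np.array([b.representative_age for b in table.bands])[keep]
        rates = row[keep]
        ax.plot(ages, rates, marker="o", ms=3, lw=1, label=cohort_label(c))
        n_lines += 1
        records += [
            {"cohort": cohort_label(c), "age": a, "rate": r}
            for a, r in zip(ages, rates)
        ]
    if n_lines == 0:
        plt.close(fig)
        raise ValueError("nothing to plot: no cohort has positive rates")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("incidence per 100,000 person-years")
    ax.set_title(title or f"{table.population} {table.sex}".strip())
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    pd.DataFrame.from_records(records).to_csv(_data_path(path), index=False)
    return path


def plot_acceleration(
    curves: list[AccelCurve],
    path: str | Path,
    title: str | None = None,
) -> Path:
    """Pointwise acceleration curves: linear acceleration vs log age."""
    if not curves:
        raise ValueError("nothing to plot: empty curve list")
    path = Path(path)
    records = []
    fig, ax = plt.subplots(figsize=(6, 5))
    for curve in curves:
        ages = [p[0] for p in curve.points]
        acc = [p[1] for p in curve.points]
        ax.plot(ages, acc, marker="o", ms=3, lw=1, label=cohort_label(curve.cohort_start))
        records += [
            {"cohort": cohort_label(curve.cohort_start), "age": a, "acceleration": v}
            for a, v in zip(ages, acc)
        ]
    ax.set_xscale("log")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("acceleration (d log incidence / d log age)")
    ax.set_title(title or "age-specific acceleration")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    pd.DataFrame.from_records(records).to_csv(_data_path(path), index=False)
    return path
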