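"""Summary statistics over simulation output.

All metrics are pure functions of the tidy per-year records and the
cohort ledger tables, so anything computed in-run can be recomputed
identically from saved CSVs. The central quantity is across-generational
fitness: the geometric mean over birth-year cohorts of the mean lifetime
recruit output per cohort member — the fitness measure under which
risk-spreading (variance reduction) pays even at a cost to the arithmetic
mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FitnessSummary",
    "phase_windows",
    "across_generational_fitness",
    "realized_individual_fitness",
    "failed_spawning_proportion",
    "fishing_period_length",
    "median_fishing_period",
    "age_structure",
    "strategy_comparison",
    "bootstrap_ci",
]

CELL_KEYS = ["strategy", "env_forcing", "fishing_F", "replicate"]


@dataclass(frozen=True)
class FitnessSummary:
    """Geometric-mean fitness of the cohorts born in one period."""

    period: str
    geometric_mean_fitness: float
    n_cohorts: int


def phase_windows(records: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Year ranges (inclusive) of the pre, fishing and post phases of one replicate."""
    windows = {}
    for phase in ("pre", "fishing", "post"):
        years = records.loc[records["phase"] == phase, "year"]
        if len(years):
            windows[phase] = (int(years.min()), int(years.max()))
    return windows


def across_generational_fitness(
    cohorts: pd.DataFrame,
    period: tuple[int, int],
    label: str = "",
    include_unfinalized: bool = False,
) -> FitnessSummary:
    """Geometric mean of cohort mean lifetime outputs for cohorts born in ``period``.

    Only finalized cohorts (all members dead) enter by default; a cohort
    whose members produced nothing contributes zero and forces the
    geometric mean to zero — no epsilon padding.
    """
    lo, hi = period
    sel = cohorts[(cohorts["birth_year"] >= lo) & (cohorts["birth_year"] <= hi)]
    if not include_unfinalized:
        sel = sel[sel["finalized"]]
    means = sel["mean_output"].to_numpy(dtype=float)
    n = means.size
    if n == 0:
        return FitnessSummary(label, np.nan, 0)
    if np.any(means <= 0):
        return FitnessSummary(label, 0.0, n)
    return FitnessSummary(label, float(np.exp(np.mean(np.log(means)))), n)


def realized_individual_fitness(records: pd.DataFrame) -> pd.Series:
    """Recruits per mature adult, per year; undefined years are missing."""
    mature = records["mature_count"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            mature > 0, records["recruits"].to_numpy(dtype=float) / mature, np.nan
        )
    return pd.Series(out, index=records.index, name="realized_individual_fitness")


def failed_spawning_proportion(records: pd.DataFrame) -> float:
    """Share of female-seasons that produced zero recruits, over the given rows."""
    spawners = records["spawning_females"].sum()
    if spawners == 0:
        raise ValueError("no spawning females in the requested records")
    return float(records["failed_seasons"].sum() / spawners)


def fishing_period_length(records: pd.DataFrame) -> int:
    """Years with fishing active, onset to moratorium inclusive, for one replicate."""
    return int((records["phase"] == "fishing").sum())


def median_fishing_period(records: pd.DataFrame) -> float:
    """Median fishing-period length over the replicates present in ``records``."""
    lengths = (
        records.assign(is_f=records["phase"] == "fishing")
        .groupby(CELL_KEYS, sort=False)["is_f"]
        .sum()
    )
    return float(lengths.median())


def age_structure(records: pd.DataFrame, years: "list[int] | None" = None) -> dict:
    """Pooled age pyramid plus mean-age and maturation summaries.

    ``years`` restricts to snapshot years (within each replicate); by
    default every supplied row is pooled. The pyramid conserves abundance:
    its sum equals the summed abundance of the pooled rows.
    """
    sel = records if years is None else records[records["year"].isin(years)]
    age_cols = [c for c in sel.columns if c.startswith("age_") and c[4:].isdigit()]
    pyramid = sel[age_cols].sum(axis=0).to_numpy(dtype=np.int64)
    ages = np.array([int(c.split("_")[1]) for c in age_cols])
    total = pyramid.sum()
    mean_age = float((ages * pyramid).sum() / total) if total else np.nan
    return {
        "pyramid": pd.Series(pyramid, index=ages, name="abundance"),
        "mean_age": mean_age,
        "mean_maturation_age": float(sel["mean_maturation_age"].mean()),
        "mean_maturation_length_cm": float(sel["mean_maturation_length_cm"].mean()),
    }


def bootstrap_ci(
    values: np.ndarray,
    rng: np.random.Generator,
    n_boot: int = 2000,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return (np.nan, np.nan)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boots = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1.0 - alpha)))


def strategy_comparison(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    value: str,
    rng: np.random.Generator | None = None,
    n_boot: int = 2000,
) -> pd.DataFrame:
    """Per-cell and pooled differences (A − B) of a replicate-level statistic.

    Both inputs must carry one row per (env_forcing, fishing_F, replicate)
    with the statistic in column ``value`` on a matched scenario grid.
    Returns one row per (E, F) cell plus a pooled row, each with the mean
    difference and a percentile bootstrap CI over replicates.
    """
    keys = ["env_forcing", "fishing_F", "replicate"]
    a = table_a.set_index(keys)[value]
    b = table_b.set_index(keys)[value]
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("scenario grids do not match")
        b = b.reindex(a.index)
    diff = (a - b).rename("difference").reset_index()
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for (e, f), grp in diff.groupby(["env_forcing", "fishing_F"]):
        lo, hi = bootstrap_ci(grp["difference"].to_numpy(), rng, n_boot)
        rows.append(
            {
                "env_forcing": e,
                "fishing_F": f,
                "mean_difference": grp["difference"].mean(),
                "ci_low": lo,
                "ci_high": hi,
                "n": len(grp),
            }
        )
    lo, hi = bootstrap_ci(diff["difference"].to_numpy(), rng, n_boot)
    rows.append(
        {
            "env_forcing": np.nan,
            "fishing_F": np.nan,
            "mean_difference": diff["difference"].mean(),
            "ci_low": lo,
            "ci_high": hi,
            "n": len(diff),
        }
    )
    return pd.DataFrame(rows)
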