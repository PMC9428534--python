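"""Headline summary statistics of a factorial experiment.

Condenses the tidy per-year records and cohort ledgers of a full
MBS-vs-SBS × forcing × fishing experiment into the study-level quantities:
the strategy gap in asymptotic length under fishing, fitness declines and
recoveries around the fishing period, fishing-period lengths, pooled age
structure, realized-fitness drops, and the recruit-biomass comparison
between strategies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import metrics as m

__all__ = ["scenario_summaries", "headline_statistics"]

AGES = np.arange(26)
AGE_COLS = [f"age_{a}" for a in AGES]


def scenario_summaries(records: pd.DataFrame, cohorts: pd.DataFrame) -> pd.DataFrame:
    """One row per scenario-replicate with phase-wise summary statistics.

    Columns: fishing_years; per phase (pre/fishing/post) the mean phenotypic
    L∞, geometric-mean across-generational fitness of cohorts born in the
    phase, period-mean realized individual fitness, period-mean recruit
    biomass, and the pooled age pyramid of the phase's snapshot year (the
    last year of the phase).
    """
    coh_indexed = cohorts.set_index(m.CELL_KEYS).sort_index()
    rows = []
    for key, rec in records.groupby(m.CELL_KEYS, sort=False):
        coh = coh_indexed.loc[key].reset_index()
        windows = m.phase_windows(rec)
        row = dict(zip(m.CELL_KEYS, key))
        row["fishing_years"] = m.fishing_period_length(rec)
        row["terminated"] = bool(rec.terminated.any())
        for phase in ("pre", "fishing", "post"):
            if phase not in windows:
                continue
            window = windows[phase]
            sel = rec[rec.phase == phase]
            fit = m.across_generational_fitness(coh, window, phase)
            row[f"fit_{phase}"] = fit.geometric_mean_fitness
            row[f"n_cohorts_{phase}"] = fit.n_cohorts
            row[f"linf_{phase}"] = sel.mean_linf_cm.mean()
            row[f"rif_{phase}"] = m.realized_individual_fitness(sel).mean()
            row[f"recruit_biomass_{phase}"] = sel.recruit_biomass_kg.mean()
            snap = rec[rec.year == window[1]]
            for a in AGES:
                row[f"pyr_{phase}_{a}"] = int(snap[f"age_{a}"].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled_mean_age(summary: pd.DataFrame, strategy: str) -> float:
    """Abundance-weighted mean age over the pre/during/post snapshot pyramids."""
    pooled = np.zeros(26)
    sub = summary[summary.strategy == strategy]
    for phase in ("pre", "fishing", "post"):
        cols = [f"pyr_{phase}_{a}" for a in AGES]
        present = [c for c in cols if c in sub.columns]
        if present:
            pooled += sub[present].fillna(0).sum().to_numpy()
    return float((AGES * pooled).sum() / pooled.sum())


def _fishing_phase_mean_age(records: pd.DataFrame, strategy: str, F: float) -> float:
    sel = records[
        (records.strategy == strategy)
        & (records.fishing_F == F)
        & (records.phase == "fishing")
    ]
    pyramid = sel[AGE_COLS].sum().to_numpy(dtype=float)
    return float((AGES * pyramid).sum() / pyramid.sum())


def headline_statistics(records: pd.DataFrame, cohorts: pd.DataFrame) -> dict:
    """The study-level statistics, each as ``{"value": ..., "n": ...}``.

    ``n`` reports the number of scenario-replicates (or cells, for pooled
    differences) the statistic is computed from. Percent declines and
    recoveries are ratios of period means, scenario means being taken over
    replicates before ratioing.
    """
    summary = scenario_summaries(records, cohorts)
    f_low = min(records.fishing_F.unique())
    f_high = max(records.fishing_F.unique())
    sc = (
        summary.groupby(["strategy", "env_forcing", "fishing_F"])
        .mean(numeric_only=True)
        .reset_index()
    )
    out: dict = {}

    # strategy gap in L∞ during fishing, pooled over matched cells
    piv = sc.pivot_table(
        index=["env_forcing", "fishing_F"], columns="strategy", values="linf_fishing"
    )
    gap = piv["SBS"] - piv["MBS"]
    out["linf_gap_sbs_minus_mbs_cm"] = {"value": float(gap.mean()), "n": int(gap.size)}

    # across-generational fitness: decline during fishing, recovery after
    decline = (1.0 - sc.fit_fishing / sc.fit_pre) * 100.0
    recovery = sc.fit_post / sc.fit_pre * 100.0
    out["max_fitness_decline_pct"] = {
        "value": float(decline.max()),
        "n": int(decline.notna().sum()),
    }
    out["fitness_recovery_pct"] = {
        "value": float(recovery.mean()),
        "n": int(recovery.notna().sum()),
    }
    high = recovery[sc.fishing_F == f_high]
    out["fitness_recovery_pct_strongest_fishing"] = {
        "value": float(high.mean()),
        "n": int(high.notna().sum()),
    }

    # fishing-period medians at the lowest fishing mortality
    low = summary[summary.fishing_F == f_low]
    for strategy in ("MBS", "SBS"):
        sel = low[low.strategy == strategy].fishing_years
        out[f"median_fishing_years_{strategy.lower()}_low_f"] = {
            "value": float(sel.median()),
            "n": int(sel.size),
        }

    # pooled age structure
    for strategy in ("MBS", "SBS"):
        out[f"mean_age_{strategy.lower()}_yr"] = {
            "value": _pooled_mean_age(summary, strategy),
            "n": int((summary.strategy == strategy).sum()),
        }
    age_low = _fishing_phase_mean_age(records, "MBS", f_low)
    age_high = _fishing_phase_mean_age(records, "MBS", f_high)
    out["mbs_mean_age_decline_pct"] = {
        "value": float((1.0 - age_high / age_low) * 100.0),
        "n": int((summary.strategy == "MBS").sum()),
    }

    # realized individual fitness: largest post-fishing drop among MBS
    mbs = sc[sc.strategy == "MBS"]
    drop = mbs[["rif_pre", "rif_fishing"]].max(axis=1) - mbs.rif_post
    out["mbs_max_realized_fitness_drop"] = {
        "value": float(drop.max()),
        "n": int(drop.notna().sum()),
    }

    # highest pre-fishing fitness over scenario means
    out["max_pre_fishing_fitness"] = {
        "value": float(sc.fit_pre.max()),
        "n": int(sc.fit_pre.notna().sum()),
    }

    # recruit-biomass advantage of MBS at the harshest forcing, lowest F
    e_max = max(records.env_forcing.unique())
    cell = sc[(sc.env_forcing == e_max) & (sc.fishing_F == f_low)].set_index("strategy")
    advantage = (
        cell.loc["MBS", "recruit_biomass_fishing"]
        / cell.loc["SBS", "recruit_biomass_fishing"]
        - 1.0
    ) * 100.0
    n_cell = summary[
        (summary.env_forcing == e_max) & (summary.fishing_F == f_low)
    ].shape[0]
    out["mbs_recruit_biomass_advantage_pct"] = {
        "value": float(advantage),
        "n": int(n_cell),
    }
    return out
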