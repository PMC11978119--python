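"""Stratified summary tables, composition proportions and exports.

One row per (age band x axis level): cohort counts and age moments,
estimator outputs with bootstrap SEs, and an estimability flag.
Non-estimable rows render as an en-dash in markdown and empty cells in
CSV. Every printed percentage is recomputed from the table's own integer
columns by an internal audit on export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AGE_BANDS, AXES, Cohort, assign_strata
from .errors import ValidationError

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "age_band", "level", "n", "n_deaths", "death_pct", "mean_age", "sd_age",
    "le", "le_se", "loss_le", "loss_le_se", "lifetime_cost", "lifetime_cost_se",
    "cost_per_year", "estimable",
]


@dataclass
class StratumSummary:
    age_band: str
    level: str
    n: int
    n_deaths: int
    death_pct: float
    mean_age: float
    sd_age: float
    estimable: bool
    le: float = np.nan
    le_se: float = np.nan
    loss_le: float = np.nan
    loss_le_se: float = np.nan
    lifetime_cost: float = np.nan
    lifetime_cost_se: float = np.nan
    cost_per_year: float = np.nan


def build_summary_table(cohort: Cohort, axis: str,
                        results: dict | None = None) -> pd.DataFrame:
    """Assemble the per-stratum summary for one axis.

    ``results`` maps (age_band, level) to anything exposing the estimator
    fields (a ``StratumEstimate``, optionally with ``*_se`` attributes, or a
    dict); counts and age moments always come from the cohort itself.
    Strata with N = 0 (level absent within a band) are omitted.
    """
    if axis not in AXES:
        raise ValidationError(f"unknown axis {axis!r}")
    df = assign_strata(cohort)
    col = AXES[axis]
    rows: list[StratumSummary] = []
    for band, _, _ in AGE_BANDS:
        band_df = df[df["age_band"] == band]
        for level in sorted(band_df[col].dropna().unique(), key=str):
            sub = band_df[band_df[col] == level]
            if sub.empty:
                log.warning("stratum %s/%s has N = 0; omitted", band, level)
                continue
            n = len(sub)
            deaths = int(sub["died"].sum())
            row = StratumSummary(
                age_band=band, level=str(level), n=n, n_deaths=deaths,
                death_pct=100.0 * deaths / n,
                mean_age=float(sub["age_at_dx"].mean()),
                sd_age=float(sub["age_at_dx"].std(ddof=1)) if n > 1 else 0.0,
                estimable=False,
            )
            res = (results or {}).get((band, str(level)))
            if res is not None:
                get = (res.get if isinstance(res, dict)
                       else lambda k, d=np.nan: getattr(res, k, d))
                row.estimable = bool(get("estimable", False))
                if row.estimable:
                    row.le = float(get("le", np.nan))
                    row.loss_le = float(get("loss_le", np.nan))
                    row.lifetime_cost = float(get("lifetime_cost_usd", np.nan))
                    row.cost_per_year = float(get("cost_per_year_usd", np.nan))
                    row.le_se = float(get("le_se", np.nan))
                    row.loss_le_se = float(get("loss_le_se", np.nan))
                    row.lifetime_cost_se = float(get("lifetime_cost_se", np.nan))
            rows.append(row)
    out = pd.DataFrame([vars(r) for r in rows], columns=SUMMARY_COLUMNS)
    audit_table(out)
    return out


def audit_table(table: pd.DataFrame) -> None:
    """Internal consistency audit: printed percentages must recompute from
    the table's own integer columns (display rounding never feeds back)."""
    recomputed = 100.0 * table["n_deaths"] / table["n"]
    if not np.allclose(recomputed, table["death_pct"], atol=1e-9):
        raise ValidationError("death_pct inconsistent with n_deaths / n")
    if ((table["death_pct"] < 0) | (table["death_pct"] > 100)).any():
        raise ValidationError("death_pct outside [0, 100]")


def composition_proportions(table: pd.DataFrame, level: str = "4",
                            ndigits: int = 1) -> pd.DataFrame:
    """Share (%) of one axis level within each age band and overall.

    With the stage axis and level "4" this is the synchronous-metastatic
    share of each age band.
    """
    rows = []
    for band in table["age_band"].unique():
        sub = table[table["age_band"] == band]
        total = int(sub["n"].sum())
        n_level = int(sub.loc[sub["level"] == level, "n"].sum())
        rows.append({"age_band": band, "n_level": n_level, "n_total": total,
                     "pct": round(100.0 * n_level / total, ndigits) if total else np.nan})
    total = int(table["n"].sum())
    n_level = int(table.loc[table["level"] == level, "n"].sum())
    rows.append({"age_band": "overall", "n_level": n_level, "n_total": total,
                 "pct": round(100.0 * n_level / total, ndigits) if total else np.nan})
    return pd.DataFrame(rows)


def _fmt(value, se=None, nd=2, dash="–"):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return dash
    if se is not None and not (isinstance(se, float) and np.isnan(se)):
        return f"{value:,.{nd}f} ({se:,.{nd}f})"
    return f"{value:,.{nd}f}"


def to_markdown(table: pd.DataFrame) -> str:
    """Render the summary with en-dashes for non-estimable cells."""
    audit_table(table)
    lines = ["| Age group | Level | N | Deaths (%) | Age | LE (SE) | "
             "Loss of LE (SE) | Lifetime cost (SE) | Cost per year |",
             "|---|---|---|---|---|---|---|---|---|"]
    for r in table.itertuples():
        est = bool(r.estimable)
        lines.append(
            f"| {r.age_band} | {r.level} | {r.n:,} "
            f"| {r.n_deaths:,} ({r.death_pct:.2f}%) "
            f"| {r.mean_age:.2f} ± {r.sd_age:.2f} "
            f"| {_fmt(r.le, r.le_se) if est else '–'} "
            f"| {_fmt(r.loss_le, r.loss_le_se) if est else '–'} "
            f"| {_fmt(r.lifetime_cost, r.lifetime_cost_se, 0) if est else '–'} "
            f"| {_fmt(r.cost_per_year, None, 0) if est else '–'} |")
    return "\n".join(lines)


def to_csv(table: pd.DataFrame, path) -> None:
    """CSV export: percentages rounded to 2 decimals, non-estimable cells empty."""
    audit_table(table)
    out = table.copy()
    out["death_pct"] = out["death_pct"].round(2)
    for c in ("mean_age", "sd_age"):
        out[c] = out[c].round(2)
    value_cols = ["le", "le_se", "loss_le", "loss_le_se",
                  "lifetime_cost", "lifetime_cost_se", "cost_per_year"]
    out.loc[~out["estimable"].astype(bool), value_cols] = np.nan
    out.to_csv(path, index=False)


def plot_survival(results: dict, path=None, title: str = ""):
    """Basic patient-vs-referent survival plot per stratum (one axes)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for label, ext in results.items():
        t = np.arange(len(ext.s_patient)) / 12.0
        ax.plot(t, ext.s_patient, label=f"{label} patients")
        tr = np.arange(len(ext.s_referent)) / 12.0
        ax.plot(tr, ext.s_referent, "--", label=f"{label} referents")
    ax.set_xlabel("years since diagnosis")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
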