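"""End-to-end estimation for one stratum and for a full stratified cohort."""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AGE_BANDS, AXES, Cohort, assign_strata
from .config import AnalysisConfig
from .costs import estimate_cost_function, lifetime_cost
from .errors import (InsufficientFollowupError, NonEstimableError,
                     ValidationError)
from .extrapolate import (ExtrapolationResult, check_estimability,
                          km_auc_variance, rolling_extrapolate,
                          truncate_unreliable_tail)
from .lifetable import LifeTable, simulate_reference_cohort
from .survival import kaplan_meier_monthly

log = logging.getLogger(__name__)


@dataclass
class StratumEstimate:
    n: int
    n_deaths: int
    estimable: bool
    le: float = np.nan
    le_referent: float = np.nan
    loss_le: float = np.nan
    lifetime_cost_usd: float = np.nan
    cost_per_year_usd: float = np.nan
    truncated: bool = False
    refusal_reason: str = ""
    extrapolation: ExtrapolationResult | None = None


def estimate_stratum(cohort: Cohort, costs: pd.DataFrame | None,
                     table: LifeTable, config: AnalysisConfig | None = None,
                     seed: int | None = None,
                     keep_curves: bool = False) -> StratumEstimate:
    """Run the full estimator on one (sub)cohort.

    Stages: Monte Carlo matched referents -> monthly Kaplan-Meier ->
    estimability check -> logit-ratio rolling extrapolation -> LE / loss of
    LE -> cost function and discounted lifetime cost. A refusal (survival
    not materially worse than referents) or insufficient follow-up yields a
    non-estimable result, not an exception.
    """
    cfg = config or AnalysisConfig()
    if seed is None:
        seed = cfg.seed
    n, n_deaths = len(cohort), cohort.n_deaths

    km = kaplan_meier_monthly(cohort)
    horizon = int((cfg.age_cap - cohort.df["age_at_dx"].min()) * 12)
    referent = simulate_reference_cohort(
        cohort, table, n_replicates=cfg.n_replicates, seed=seed,
        age_cap=cfg.age_cap, epsilon=cfg.extrapolation.epsilon)

    s_obs = truncate_unreliable_tail(km, cfg.extrapolation.min_at_risk)
    t_trunc = len(s_obs) - 1
    auc_r = float(np.trapezoid(referent.s[: t_trunc + 1]))
    auc_se = (np.sqrt(km_auc_variance(km, t_trunc)) / auc_r) if auc_r > 0 else None
    diag = check_estimability(s_obs, referent.s, cfg.extrapolation, auc_ratio_se=auc_se)
    if not diag.estimable:
        return StratumEstimate(n=n, n_deaths=n_deaths, estimable=False,
                               refusal_reason=diag.reason)
    try:
        ext = rolling_extrapolate(s_obs, referent, cfg.extrapolation,
                                  horizon_months=horizon, check=False)
    except (InsufficientFollowupError, ValidationError) as e:
        return StratumEstimate(n=n, n_deaths=n_deaths, estimable=False,
                               refusal_reason=str(e))

    est = StratumEstimate(
        n=n, n_deaths=n_deaths, estimable=True, le=ext.le,
        le_referent=ext.le_referent, loss_le=ext.loss_le,
        truncated=ext.truncated,
        extrapolation=ext if keep_curves else None)
    if costs is not None and not costs.empty:
        sub = costs[costs["id"].isin(cohort.df["id"])]
        if not sub.empty:
            fn = estimate_cost_function(sub, cohort, K=cfg.terminal_window_K,
                                        cpi=cfg.cpi or None)
            res = lifetime_cost(fn, ext.s_patient, cfg.discount_rate,
                                cfg.exchange_rate, cfg.cost_per_year_method)
            est.lifetime_cost_usd = res.lifetime_cost
            est.cost_per_year_usd = res.cost_per_year
    return est


def estimate_age_banded(cohort: Cohort, costs: pd.DataFrame | None,
                        table: LifeTable, config: AnalysisConfig | None = None,
                        seed: int | None = None) -> StratumEstimate:
    """Cohort-level estimate as the patient-weighted aggregate of per-age-band
    estimates.

    The extrapolation models the pooled logit survival ratio, which drifts
    when the cohort mixes widely different ages (the mixture's relative
    survival flattens as younger patients come to dominate the tail), so the
    estimator's unit of analysis is the age band; cohort-level LE, loss of
    LE and lifetime cost are the patient-weighted means of the band values.
    Raises NonEstimableError if any band is refused.
    """
    cfg = config or AnalysisConfig()
    if seed is None:
        seed = cfg.seed
    df = assign_strata(cohort)
    parts: list[StratumEstimate] = []
    weights: list[int] = []
    for i, (band, _, _) in enumerate(AGE_BANDS):
        sub_df = df[df["age_band"] == band]
        if sub_df.empty:
            continue
        sub = Cohort(sub_df.reset_index(drop=True), cohort.censor_date)
        est = estimate_stratum(sub, costs, table, cfg, seed=seed + i)
        if not est.estimable:
            raise NonEstimableError(f"age band {band}: {est.refusal_reason}")
        parts.append(est)
        weights.append(len(sub))
    w = np.asarray(weights, float)
    w /= w.sum()
    agg = StratumEstimate(
        n=len(cohort), n_deaths=cohort.n_deaths, estimable=True,
        le=float(w @ [p.le for p in parts]),
        le_referent=float(w @ [p.le_referent for p in parts]),
        truncated=any(p.truncated for p in parts))
    agg.loss_le = agg.le_referent - agg.le
    costs_avail = [p.lifetime_cost_usd for p in parts]
    if not any(np.isnan(costs_avail)):
        agg.lifetime_cost_usd = float(w @ costs_avail)
        agg.cost_per_year_usd = float(w @ [p.cost_per_year_usd for p in parts])
    return agg


def le_estimator(cohort: Cohort, costs, table, config, seed) -> float:
    """Pipeline endpoint returning LE (raises NonEstimableError on refusal)."""
    est = estimate_stratum(cohort, None, table, config, seed)
    if not est.estimable:
        raise NonEstimableError(est.refusal_reason)
    return est.le


def loss_le_estimator(cohort: Cohort, costs, table, config, seed) -> float:
    est = estimate_stratum(cohort, None, table, config, seed)
    if not est.estimable:
        raise NonEstimableError(est.refusal_reason)
    return est.loss_le


def lifetime_cost_estimator(cohort: Cohort, costs, table, config, seed) -> float:
    est = estimate_stratum(cohort, costs, table, config, seed)
    if not est.estimable or np.isnan(est.lifetime_cost_usd):
        raise NonEstimableError(est.refusal_reason or "no cost data")
    return est.lifetime_cost_usd


def run_stratified(cohort: Cohort, costs: pd.DataFrame | None,
                   table: LifeTable, config: AnalysisConfig | None = None,
                   axes: tuple[str, ...] = ("stage", "psa_band", "gleason_band"),
                   ) -> dict[str, dict[tuple[str, str], StratumEstimate]]:
    """Estimate every (age band x axis level) stratum on the given axes.

    Records missing the axis variable drop out of that axis only; empty
    strata are skipped with a log message.
    """
    cfg = config or AnalysisConfig()
    df = assign_strata(cohort)
    out: dict[str, dict[tuple[str, str], StratumEstimate]] = {}
    for axis in axes:
        col = AXES[axis]
        out[axis] = {}
        for band, _, _ in AGE_BANDS:
            levels = [l for l in df.loc[df["age_band"] == band, col].dropna().unique()]
            for level in sorted(levels, key=str):
                sel = (df["age_band"] == band) & (df[col] == level)
                sub = Cohort(df.loc[sel].reset_index(drop=True), cohort.censor_date)
                if len(sub) == 0:
                    log.warning("empty stratum %s/%s/%s skipped", axis, band, level)
                    continue
                seed = (cfg.seed + zlib.crc32(f"{axis}/{band}/{level}".encode())) % (2**31)
                out[axis][(band, str(level))] = estimate_stratum(
                    sub, costs, table, cfg, seed=seed)
    return out
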