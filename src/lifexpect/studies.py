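"""Simulation studies validating the estimation pipeline end to end.

Each study generates synthetic registries with known ground truth and
measures how the full pipeline (Monte Carlo referents -> monthly KM ->
estimability -> rolling extrapolation -> costs) recovers it:

* recovery_study — three excess-hazard strata (HR 1 / 2 / 4); the HR=1
  stratum must be refused, and the mean recovered LE / loss of LE /
  lifetime cost over replicate cohorts is compared with exact truth.
* null_refusal_study — cohorts with no excess mortality; the pipeline must
  decline to extrapolate.
* coverage_study / scaling_study — bootstrap SE sanity: nominal-coverage
  confidence intervals and root-n shrinkage.
* composition_metrics — arithmetic of the published registry composition
  through the reporting layer.
"""

from __future__ import annotations

import numpy as np

from .bootstrap import bootstrap_se
from .cohort import Cohort, assign_strata
from .config import AnalysisConfig
from .errors import NonEstimableError, ValidationError
from .pipeline import estimate_age_banded, estimate_stratum, le_estimator
from .published import STAGE_COMPOSITION, cohort_from_composition
from .reporting import build_summary_table, composition_proportions
from .synthetic import GeneratorConfig, make_life_table, simulate_cohort, simulate_costs

THREE_STRATUM = dict(
    n_patients=15000,
    stage_probs={"1": 1 / 3, "2": 1 / 3, "4": 1 / 3},
    stage_hrs={"1": 1.0, "2": 2.0, "4": 4.0},
)


def _study_table(cfg: GeneratorConfig):
    y0, y1 = cfg.dx_year_range
    return make_life_table(cfg.gompertz_b, cfg.gompertz_theta,
                           years=range(y0, y1 + 1), drift=cfg.lifetable_drift)


def recovery_study(n_replicates: int = 20, seed: int = 0,
                   with_costs: bool = True) -> dict:
    """Mean signed recovery error (%) of LE, loss of LE and lifetime cost
    per excess-hazard stratum, over replicate three-stratum cohorts of
    ~5,000 patients per stratum, plus HR=1 refusal and LE-ordering counts.
    """
    base = GeneratorConfig(**THREE_STRATUM)
    table = _study_table(base)
    acfg = AnalysisConfig(bootstrap_B=0)
    errs: dict = {s: {"le": [], "loss": [], "cost": []} for s in ("2", "4")}
    hr1_refused = 0
    ordered = 0
    for rep in range(n_replicates):
        cfg = GeneratorConfig(**{**base.__dict__,
                                 "seed": (seed * 1000 + rep) % (2**31)})
        cohort, truth = simulate_cohort(cfg, table=table)
        costs = simulate_costs(cohort, cfg) if with_costs else None
        df = assign_strata(cohort)
        le_by_stage = {}
        for stg in ("1", "2", "4"):
            sub = Cohort(df[df["stage"] == stg].reset_index(drop=True),
                         cohort.censor_date)
            try:
                est = estimate_age_banded(sub, costs, table, acfg,
                                          seed=(seed * 7919 + rep * 13) % (2**31))
            except NonEstimableError:
                if stg == "1":
                    hr1_refused += 1
                continue
            if stg == "1":
                continue
            tr = truth.row(stg)
            le_by_stage[stg] = est.le
            errs[stg]["le"].append(100 * (est.le / tr["le"] - 1))
            errs[stg]["loss"].append(100 * (est.loss_le / tr["loss_le"] - 1))
            if with_costs and not np.isnan(est.lifetime_cost_usd):
                errs[stg]["cost"].append(
                    100 * (est.lifetime_cost_usd / tr["lifetime_cost_usd"] - 1))
        if {"2", "4"} <= set(le_by_stage) and le_by_stage["2"] > le_by_stage["4"]:
            ordered += 1
    out = {
        "n_replicates": n_replicates,
        "hr1_refusal_rate": hr1_refused / n_replicates,
        "le_ordering_rate": ordered / n_replicates,
    }
    for stg in ("2", "4"):
        out[f"le_err_pct_hr{stg}"] = float(np.mean(errs[stg]["le"]))
        out[f"loss_le_err_pct_hr{stg}"] = float(np.mean(errs[stg]["loss"]))
        if errs[stg]["cost"]:
            out[f"cost_err_pct_hr{stg}"] = float(np.mean(errs[stg]["cost"]))
    return out


def null_refusal_study(n_replicates: int = 200, n_patients: int = 500,
                       seed: int = 0) -> dict:
    """Fraction of no-excess-mortality cohorts the pipeline refuses."""
    base = GeneratorConfig(n_patients=n_patients,
                           stage_probs={"1": 1.0}, stage_hrs={"1": 1.0})
    table = _study_table(base)
    acfg = AnalysisConfig(bootstrap_B=0)
    refused = 0
    for rep in range(n_replicates):
        cfg = GeneratorConfig(**{**base.__dict__,
                                 "seed": (seed * 2000 + rep) % (2**31)})
        cohort, _ = simulate_cohort(cfg, table=table)
        est = estimate_stratum(cohort, None, table, acfg,
                               seed=(seed * 104729 + rep) % (2**31))
        refused += (not est.estimable)
    return {"n_replicates": n_replicates, "n_patients": n_patients,
            "refusal_rate": refused / n_replicates}


def _bootstrap_study_config(n_patients, seed):
    # oldest band: short extrapolation horizon, so the point estimator is
    # near-unbiased and the study isolates interval calibration
    return GeneratorConfig(n_patients=n_patients, age_min=75, age_max=89,
                           stage_probs={"4": 1.0}, stage_hrs={"4": 3.0},
                           seed=seed)


def coverage_study(n_cohorts: int = 100, n_patients: int = 300,
                   B: int = 30, seed: int = 0) -> dict:
    """Empirical coverage of the normal-approximation 95% interval for LE on
    single-band excess-mortality cohorts with known truth."""
    table = _study_table(_bootstrap_study_config(n_patients, 0))
    acfg = AnalysisConfig(bootstrap_B=0, n_replicates=50)
    covered = total = 0
    for rep in range(n_cohorts):
        cfg = _bootstrap_study_config(n_patients, (seed * 3000 + rep) % (2**31))
        cohort, truth = simulate_cohort(cfg, table=table)
        try:
            bs = bootstrap_se(cohort, None, le_estimator, B=B,
                              seed=(seed * 31 + rep) % (2**31),
                              table=table, config=acfg)
        except (ValidationError, NonEstimableError):
            continue
        t = truth.row("4")["le"]
        total += 1
        covered += (bs.point_estimate - 1.96 * bs.se
                    <= t <= bs.point_estimate + 1.96 * bs.se)
    return {"n_cohorts": total, "coverage": covered / total if total else np.nan}


def scaling_study(n_repetitions: int = 20, B: int = 25, seed: int = 0) -> dict:
    """Root-n shrinkage of the bootstrap SE: mean SE at n=4,000 over mean SE
    at n=1,000 (expected near 0.5)."""
    table = _study_table(_bootstrap_study_config(1000, 0))
    acfg = AnalysisConfig(bootstrap_B=0, n_replicates=25)
    ses = {1000: [], 4000: []}
    for rep in range(n_repetitions):
        for n in (1000, 4000):
            cfg = _bootstrap_study_config(n, (seed * 4000 + rep) % (2**31))
            cohort, _ = simulate_cohort(cfg, table=table)
            bs = bootstrap_se(cohort, None, le_estimator, B=B,
                              seed=(seed * 17 + rep) % (2**31),
                              table=table, config=acfg)
            ses[n].append(bs.se)
    ratio = float(np.mean(ses[4000]) / np.mean(ses[1000]))
    return {"n_repetitions": n_repetitions, "se_ratio_4000_1000": ratio,
            "mean_se_1000": float(np.mean(ses[1000])),
            "mean_se_4000": float(np.mean(ses[4000]))}


def composition_metrics() -> dict:
    """Registry-composition arithmetic through the reporting layer: total N,
    metastatic (stage 4) shares per age band and overall, and stage-4 death
    percentages for the two younger bands."""
    cohort = cohort_from_composition(STAGE_COMPOSITION)
    table = build_summary_table(cohort, "stage")
    props = composition_proportions(table, level="4", ndigits=2)
    by_band = props.set_index("age_band")
    idx = table.set_index(["age_band", "level"])
    return {
        "total_n": int(table["n"].sum()),
        "stage4_share_20_64": float(by_band.loc["20-64", "pct"]),
        "stage4_share_65_74": float(by_band.loc["65-74", "pct"]),
        "stage4_share_75_89": float(by_band.loc["75-89", "pct"]),
        "stage4_share_overall": float(by_band.loc["overall", "pct"]),
        "stage4_death_pct_20_64": round(float(idx.loc[("20-64", "4"), "death_pct"]), 2),
        "stage4_death_pct_65_74": round(float(idx.loc[("65-74", "4"), "death_pct"]), 2),
    }
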