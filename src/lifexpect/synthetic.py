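"""Synthetic registry generator with exact ground truth.

Emulates the study's data sources — a male cancer-registry cohort aged
20-89 diagnosed over a fixed calendar window with administrative censoring
at a fixed date, a national period life table, and patient-month healthcare
costs that surge in the final months before death — with every quantity of
interest (life expectancy, loss of LE, expected lifetime cost) computable
exactly from the generating model, so the whole estimation pipeline can be
validated without any registry access.

Generating model
----------------
* Life table: Gompertz annual hazard, q(age) = 1 - exp(-b * exp(theta*age)),
  identical across calendar years unless a drift is configured.
* Survival: each stage stratum carries a proportional excess hazard ratio
  (HR) on the life-table hazard; monthly survival factor (1-q)^(HR/12).
  HR = 1 reproduces the "survival similar to referents" phenomenon that the
  estimator must refuse. PSA and Gleason labels are drawn independently of
  survival (labels with no attached biology).
* Costs: chronic lognormal monthly cost plus a deterministic surge in the
  final K months before the (true) death month.

Ground truth is computed by exact summation over the discrete generating
model (no simulation error): the model is genuinely monthly, so the pooled
survival curve, its trapezoidal LE, and the expected discounted lifetime
cost all have closed forms given the cohort's entry-age/year mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AGE_MAX, AGE_MIN, Cohort
from .costs import DEFAULT_DISCOUNT_RATE, DEFAULT_EXCHANGE_RATE
from .errors import ValidationError
from .lifetable import DEFAULT_AGE_CAP, LifeTable, sample_death_months

#: Gleason pattern pairs used to realise each band label
_GLEASON_PATTERNS = {
    "<=6": (3, 3), "3+4": (3, 4), "4+3": (4, 3), "8": (4, 4), "9-10": (4, 5),
}
#: representative PSA draw range per band (ng/ml)
_PSA_RANGES = {
    "<4": (0.5, 3.9), "4-9": (4.0, 9.9), "10-19": (10.0, 19.9),
    "20-50": (20.0, 50.0), ">50": (50.1, 500.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic registry.

    Defaults emulate the published cohort: males aged 20-89 (age mix centred
    in the early 70s), diagnosed 2008-2019 with administrative censoring at
    2019-12, stage mix dominated by organ-confined disease with roughly a
    third metastatic at diagnosis, excess mortality confined to stage 4,
    and monthly costs on the scale of Taiwanese national-insurance
    reimbursements (TWD) with a terminal surge.
    """
    n_patients: int = 5000
    age_mean: float = 72.5
    age_sd: float = 9.0
    age_min: int = AGE_MIN
    age_max: int = AGE_MAX
    dx_year_range: tuple[int, int] = (2008, 2019)
    censor_year: int = 2019
    censor_month: int = 12
    stage_probs: dict[str, float] = field(default_factory=lambda: {
        "1": 0.115, "2": 0.427, "3": 0.132, "4": 0.326})
    stage_hrs: dict[str, float] = field(default_factory=lambda: {
        "1": 1.0, "2": 1.0, "3": 1.0, "4": 3.0})
    psa_probs: dict[str, float] = field(default_factory=lambda: {
        "<4": 0.11, "4-9": 0.21, "10-19": 0.20, "20-50": 0.17, ">50": 0.31})
    gleason_probs: dict[str, float] = field(default_factory=lambda: {
        "<=6": 0.27, "3+4": 0.15, "4+3": 0.15, "8": 0.15, "9-10": 0.28})
    psa_missing: float = 0.03
    gleason_missing: float = 0.03
    gompertz_b: float = 3.3e-5
    gompertz_theta: float = 0.0916
    lifetable_drift: float = 0.0       # multiplicative qx change per calendar year
    age_cap: int = DEFAULT_AGE_CAP
    chronic_mean: float = 15_000.0     # TWD / month
    chronic_cv: float = 1.0            # lognormal coefficient of variation
    surge: float = 60_000.0            # extra TWD / month near death
    surge_window: int = 6              # K, months before death with surge
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    exchange_rate: float = DEFAULT_EXCHANGE_RATE
    seed: int = 20080101

    def validate(self) -> None:
        for name, probs in (("stage", self.stage_probs), ("psa", self.psa_probs),
                            ("gleason", self.gleason_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} mixture proportions must sum to 1")
        if self.gompertz_b <= 0:
            raise ValidationError("Gompertz b must be positive")
        if any(h <= 0 for h in self.stage_hrs.values()):
            raise ValidationError("hazard ratios must be positive")


@dataclass
class GroundTruth:
    """Per-stage true values from the generating model, computed
    independently of the estimation pipeline."""
    per_stratum: pd.DataFrame  # stage, n, hr, le, le_referent, loss_le, lifetime_cost_usd

    def row(self, stage: str) -> pd.Series:
        return self.per_stratum.set_index("stage").loc[str(stage)]


def make_life_table(b: float, theta: float,
                    years=range(2008, 2020), ages=range(AGE_MIN, DEFAULT_AGE_CAP + 1),
                    drift: float = 0.0, sex: str = "male") -> LifeTable:
    """Gompertz life table q(age) = 1 - exp(-b*exp(theta*age)), clamped to
    [0,1], closed with q = 1 at the terminal age; identical across calendar
    years unless a drift multiplier is given."""
    if b <= 0:
        raise ValidationError("b must be positive")
    years = list(years)
    ages = np.asarray(list(ages))
    hazard = b * np.exp(theta * ages.astype(float))
    qx0 = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    rows = []
    for i, y in enumerate(years):
        qx = np.clip(qx0 * (1.0 + drift) ** i, 0.0, 1.0)
        qx[-1] = 1.0
        rows.append(pd.DataFrame({"sex": sex, "year": y, "age": ages, "qx": qx}))
    return LifeTable(pd.concat(rows, ignore_index=True))


def _truncated_normal_ages(rng, n, cfg: GeneratorConfig) -> np.ndarray:
    ages = np.empty(n, int)
    filled = 0
    while filled < n:
        draw = rng.normal(cfg.age_mean, cfg.age_sd, size=2 * (n - filled))
        ok = draw[(draw >= cfg.age_min) & (draw <= cfg.age_max + 1)]
        take = ok[: n - filled].astype(int)
        take = np.clip(take, cfg.age_min, cfg.age_max)
        ages[filled: filled + len(take)] = take
        filled += len(take)
    return ages


def simulate_cohort(config: GeneratorConfig, seed: int | None = None,
                    table: LifeTable | None = None) -> tuple[Cohort, GroundTruth]:
    """Draw a synthetic registry cohort and its exact ground truth.

    Death months are sampled from the discrete monthly survival implied by
    HR(stage) times the life-table hazard; follow-up is the earlier of the
    death month and the administrative censoring date. The returned cohort
    frame carries a private ``_true_death_month`` column (not part of the
    CSV schema) that the cost generator uses to place the terminal surge.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if table is None:
        y0, y1 = cfg.dx_year_range
        table = make_life_table(cfg.gompertz_b, cfg.gompertz_theta,
                                years=range(y0, y1 + 1), drift=cfg.lifetable_drift)
    n = cfg.n_patients

    ages = _truncated_normal_ages(rng, n, cfg)
    y0, y1 = cfg.dx_year_range
    censor_abs = cfg.censor_year * 12 + cfg.censor_month - 1
    dx_abs = rng.integers(y0 * 12, censor_abs + 1, size=n)  # uniform calendar months
    dx_year = dx_abs // 12
    dx_month = dx_abs % 12 + 1
    admin_months = censor_abs - dx_abs

    stages = rng.choice(list(cfg.stage_probs), p=list(cfg.stage_probs.values()), size=n)
    psa_labels = rng.choice(list(cfg.psa_probs), p=list(cfg.psa_probs.values()), size=n)
    gl_labels = rng.choice(list(cfg.gleason_probs), p=list(cfg.gleason_probs.values()), size=n)
    psa = np.array([rng.uniform(*_PSA_RANGES[l]) for l in psa_labels])
    psa[rng.random(n) < cfg.psa_missing] = np.nan
    gl = np.array([_GLEASON_PATTERNS[l] for l in gl_labels], float)
    gl[rng.random(n) < cfg.gleason_missing] = np.nan

    # death month per patient, drawn per (stage, age, dx_year) group
    true_death = np.empty(n, int)
    df_keys = pd.DataFrame({"stage": stages, "age": ages, "year": dx_year})
    for (stg, age, year), idx in sorted(
            df_keys.groupby(["stage", "age", "year"]).indices.items()):
        hr = cfg.stage_hrs[str(stg)]
        s = table.monthly_curve("male", int(age), int(year), hr, cfg.age_cap)
        u = rng.random(len(idx))
        d = np.maximum(sample_death_months(s, u), 1)
        true_death[idx] = d

    died = true_death <= admin_months
    followup = np.where(died, true_death, admin_months)

    df = pd.DataFrame({
        "id": [f"p{i:06d}" for i in range(n)],
        "sex": "male",
        "age_at_dx": ages,
        "dx_year": dx_year,
        "dx_month": dx_month,
        "stage": stages.astype(str),
        "psa": np.round(psa, 2),
        "gleason_primary": gl[:, 0],
        "gleason_secondary": gl[:, 1],
        "followup_months": followup,
        "died": died,
        "_true_death_month": true_death,
    })
    cohort = Cohort(df, pd.Period(f"{cfg.censor_year}-{cfg.censor_month:02d}", "M"))
    truth = ground_truth(cohort, cfg, table)
    return cohort, truth


def _pooled_true_curve(ages, years, table: LifeTable, hr: float, age_cap: int) -> np.ndarray:
    horizon = (age_cap - int(np.min(ages))) * 12
    acc = np.zeros(horizon + 1)
    keys, counts = np.unique(np.column_stack([ages, years]), axis=0, return_counts=True)
    for (age, year), cnt in zip(keys, counts):
        s = table.monthly_curve("male", int(age), int(year), hr, age_cap)
        acc[: len(s)] += cnt * s
    return acc / counts.sum()


def _expected_lifetime_cost(s: np.ndarray, cfg: GeneratorConfig) -> float:
    """Exact expected discounted lifetime cost (USD) under the generating
    cost model for a subject with discrete survival curve ``s``: chronic
    mean every alive month plus the surge in the last K months of life."""
    H = len(s) - 1
    t = np.arange(1, H + 1)
    disc = (1.0 + cfg.discount_rate) ** (-t / 12.0)
    alive = s[:-1]                       # P(alive in month t) = S(t-1)
    chronic = float(np.sum(alive * disc)) * cfg.chronic_mean
    p_death = s[:-1] - s[1:]             # P(death month = t)
    disc_cum = np.concatenate([[0.0], np.cumsum(disc)])
    surge = 0.0
    K = cfg.surge_window
    for m in range(1, H + 1):
        lo = max(0, m - K)
        surge += p_death[m - 1] * (disc_cum[m] - disc_cum[lo])
    surge *= cfg.surge
    return (chronic + surge) / cfg.exchange_rate


def ground_truth(cohort: Cohort, cfg: GeneratorConfig,
                 table: LifeTable) -> GroundTruth:
    """Exact per-stage LE, loss of LE and expected lifetime cost from the
    generating model, by deterministic summation (no simulation error)."""
    df = cohort.df
    rows = []
    for stg in sorted(df["stage"].unique(), key=str):
        sub = df[df["stage"] == stg]
        hr = cfg.stage_hrs[str(stg)]
        ages = sub["age_at_dx"].to_numpy(int)
        years = sub["dx_year"].to_numpy(int)
        s_p = _pooled_true_curve(ages, years, table, hr, cfg.age_cap)
        s_r = _pooled_true_curve(ages, years, table, 1.0, cfg.age_cap)
        le = float(np.trapezoid(s_p)) / 12.0
        le_r = float(np.trapezoid(s_r)) / 12.0
        cost = _expected_lifetime_cost(s_p, cfg)
        rows.append({"stage": str(stg), "n": len(sub), "hr": hr, "le": le,
                     "le_referent": le_r, "loss_le": le_r - le,
                     "lifetime_cost_usd": cost})
    return GroundTruth(pd.DataFrame(rows))


def simulate_costs(cohort: Cohort, config: GeneratorConfig,
                   seed: int | None = None) -> pd.DataFrame:
    """Patient-month cost records (TWD) for months 1..followup_months.

    Chronic lognormal cost every month, plus the surge in months within K
    of the *true* death month (known to the generator even for records the
    registry censors first). Costs never appear after a patient's
    follow-up end, by construction.
    """
    cfg = config
    rng = np.random.default_rng((cfg.seed + 1) if seed is None else seed)
    df = cohort.df
    if "_true_death_month" not in df.columns:
        raise ValidationError("cohort lacks generator metadata (_true_death_month)")
    ids, months, costs = [], [], []
    if cfg.chronic_cv > 0:
        sigma2 = np.log(1.0 + cfg.chronic_cv ** 2)
        mu_ln = np.log(cfg.chronic_mean) - sigma2 / 2.0
    for pid, fu, death in zip(df["id"], df["followup_months"], df["_true_death_month"]):
        fu = int(fu)
        if fu < 1:
            continue
        m = np.arange(1, fu + 1)
        if cfg.chronic_cv > 0:
            chronic = rng.lognormal(mu_ln, np.sqrt(sigma2), size=fu)
        else:
            chronic = np.full(fu, cfg.chronic_mean)
        surge = np.where(m > int(death) - cfg.surge_window, cfg.surge, 0.0)
        ids.append(np.repeat(pid, fu))
        months.append(m)
        costs.append(chronic + surge)
    if not ids:
        return pd.DataFrame(columns=["id", "month", "cost"])
    out = pd.DataFrame({
        "id": np.concatenate(ids),
        "month": np.concatenate(months),
        "cost": np.round(np.concatenate(costs), 2),
    })
    return out
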