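"""Mean monthly cost function and survival-weighted lifetime cost.

Monthly healthcare costs rise sharply shortly before death, so a plain
"mean cost among survivors at month t" extrapolated to the lifetime horizon
would mis-state costs once the observed window ends. The cost function is
therefore split into a chronic component c(t) (mean cost by month since
diagnosis over person-months not adjacent to an observed death) and a
terminal profile d(k), the mean cost k months before death (k = 1 is the
month of death itself) over the final K observed months of decedents.

The expected cost of a survivor at month t recombines the two using death
probabilities from the (extrapolated) survival curve:

    mu(t) = sum_k P(death at month t+k-1 | alive at t) * d(k)
            + P(no death within K | alive at t) * c(t)

and lifetime cost discounts and sums mu against survival:

    lifetime_cost = sum_t 0.5*(S(t-1)+S(t)) * mu(t) * (1+r)^(-t/12) / X

with annual discount rate r and exchange rate X (TWD per USD). The
mid-month survival weight makes the constant-cost identity
lifetime_cost = c * 12 * LE / X hold exactly on the trapezoidal LE grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_TERMINAL_WINDOW = 6
DEFAULT_DISCOUNT_RATE = 0.03
DEFAULT_EXCHANGE_RATE = 30.93  # TWD per USD

COST_COLUMNS = ["id", "month", "cost"]


@dataclass
class CostFunction:
    """Chronic cost by month since diagnosis plus terminal pre-death profile.

    c[t-1] is the chronic mean for month t = 1..t_max_observed; d[k-1] the
    mean cost k months before death (k = 1..K); c_inf the chronic level used
    beyond the observed window.
    """
    c: np.ndarray
    d: np.ndarray
    c_inf: float
    K: int
    n_terminal_months: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.c < 0) or np.any(self.d < 0) or self.c_inf < 0:
            raise ValidationError("cost components must be non-negative")

    @property
    def t_max_observed(self) -> int:
        return len(self.c)

    def expected_monthly_cost(self, s_full: np.ndarray) -> np.ndarray:
        """mu(t) for t = 1..H, H = len(s_full)-1, mixing chronic and terminal
        costs with death probabilities from the survival curve ``s_full``."""
        s = np.asarray(s_full, float)
        H = len(s) - 1
        chronic = np.full(H, self.c_inf)
        upto = min(H, self.t_max_observed)
        chronic[:upto] = self.c[:upto]
        # p_k(t) = P(death month = t+k-1 | alive entering month t)
        #        = (S(t+k-2) - S(t+k-1)) / S(t-1)
        s_pad = np.concatenate([s, np.zeros(self.K + 1)])
        alive = s_pad[:H]                       # S(t-1), t = 1..H
        mu = np.zeros(H)
        p_total = np.zeros(H)
        t_idx = np.arange(1, H + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            for k in range(1, self.K + 1):
                p_k = np.where(alive > 0,
                               (s_pad[t_idx + k - 2] - s_pad[t_idx + k - 1]) / alive,
                               0.0)
                mu += p_k * self.d[k - 1]
                p_total += p_k
        p_total = np.clip(p_total, 0.0, 1.0)
        mu += (1.0 - p_total) * chronic
        return mu


@dataclass
class LifetimeCostResult:
    lifetime_cost: float       # USD, discounted
    lifetime_cost_undiscounted: float
    cost_per_year: float       # USD / year
    le_years: float
    discount_rate: float
    exchange_rate: float
    cost_per_year_method: str = "undiscounted_total_over_le"


def read_costs_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in COST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cost CSV missing columns: {missing}")
    return df


def _validate_costs(costs: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    if costs.empty:
        raise ValidationError("no cost data")
    if (costs["cost"] < 0).any():
        raise ValidationError("negative costs present")
    meta = cohort.df.set_index("id")[["followup_months", "died"]]
    unknown = ~costs["id"].isin(meta.index)
    if unknown.any():
        raise ValidationError(
            f"cost records for unknown patients, e.g. {costs.loc[unknown, 'id'].iloc[0]!r}")
    joined = costs.join(meta, on="id")
    late = joined["month"] > joined["followup_months"]
    if late.any():
        bad = joined.loc[late, "id"].iloc[0]
        raise ValidationError(f"cost recorded after follow-up end for patient {bad!r}")
    return joined


def estimate_cost_function(costs: pd.DataFrame, cohort: Cohort,
                           K: int = DEFAULT_TERMINAL_WINDOW,
                           cpi: dict[int, float] | None = None) -> CostFunction:
    """Estimate the chronic/terminal decomposition of mean monthly cost.

    The denominator at month t is the number of patients still under
    follow-up at t (so months without a cost row count as zero cost, which
    makes the estimate robust to sparse billing records). Person-months in
    the last K months before an observed death form the terminal profile;
    all other person-months form the chronic component. Optional ``cpi``
    maps calendar year to a price-index multiplier applied per cost month.
    """
    joined = _validate_costs(costs, cohort).copy()
    df = cohort.df
    if cpi:
        dx_year = df.set_index("id")["dx_year"]
        dx_month = df.set_index("id")["dx_month"]
        cal_year = (joined["id"].map(dx_year) * 12 + joined["id"].map(dx_month)
                    - 2 + joined["month"]) // 12
        joined["cost"] = joined["cost"] * cal_year.map(lambda y: cpi.get(int(y), 1.0))

    t_max = int(df["followup_months"].max())
    followup = df["followup_months"].to_numpy(int)
    died = df["died"].to_numpy(bool)

    # person-month denominators on the grid t = 1..t_max
    t_grid = np.arange(1, t_max + 1)
    n_alive = (followup[:, None] >= t_grid[None, :]).sum(axis=0) \
        if len(df) * t_max < 5_000_000 else \
        np.array([(followup >= t).sum() for t in t_grid])
    # terminal person-months: decedent months with followup - month + 1 <= K
    fu_d = followup[died]
    n_terminal = np.zeros(t_max, int)
    for m in fu_d:
        lo = max(1, m - K + 1)
        if m >= 1:
            n_terminal[lo - 1: m] += 1
    n_chronic = n_alive - n_terminal

    joined["k_before_death"] = np.where(
        joined["died"].to_numpy(bool),
        joined["followup_months"].to_numpy(int) - joined["month"].to_numpy(int) + 1,
        np.iinfo(np.int32).max)
    is_terminal = (joined["k_before_death"] >= 1) & (joined["k_before_death"] <= K)
    valid_month = joined["month"] >= 1

    chronic_sum = (joined.loc[~is_terminal & valid_month]
                   .groupby("month")["cost"].sum()
                   .reindex(t_grid, fill_value=0.0).to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(n_chronic > 0, chronic_sum / n_chronic, np.nan)
    # months with zero chronic survivors: carry the last estimable value forward
    if np.isnan(c).any():
        log.info("carrying chronic cost forward over %d empty months",
                 int(np.isnan(c).sum()))
        c = pd.Series(c).ffill().fillna(0.0).to_numpy()

    term = joined.loc[is_terminal & valid_month]
    d_sum = term.groupby("k_before_death")["cost"].sum() \
        .reindex(np.arange(1, K + 1), fill_value=0.0).to_numpy()
    d_n = np.zeros(K, int)
    for m in fu_d:
        kk = min(m, K)
        d_n[:kk] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(d_n > 0, d_sum / d_n, np.nan)
    c_inf = float(np.mean(c[-12:])) if len(c) >= 1 else 0.0
    if np.isnan(d).any():
        log.info("no observed deaths deep enough for the full terminal "
                 "window; missing d(k) fall back to the chronic level")
        d = np.where(np.isnan(d), c_inf, d)

    return CostFunction(c=c, d=d, c_inf=c_inf, K=K, n_terminal_months=d_n)


def lifetime_cost(cost_fn: CostFunction, s_full: np.ndarray,
                  discount_rate: float = DEFAULT_DISCOUNT_RATE,
                  exchange_rate: float = DEFAULT_EXCHANGE_RATE,
                  cost_per_year_method: str = "undiscounted_total_over_le") -> LifetimeCostResult:
    """Survival-weighted, discounted lifetime cost in USD.

    ``cost_per_year_method``: "undiscounted_total_over_le" divides the
    undiscounted lifetime total by LE; "mean_annual_per_survivor" reports
    twelve times the survival-weighted mean monthly cost.
    """
    if discount_rate < 0:
        raise ValidationError("negative discount rate")
    if exchange_rate <= 0:
        raise ValidationError("exchange rate must be positive")
    s = np.asarray(s_full, float)
    H = len(s) - 1
    mu = cost_fn.expected_monthly_cost(s)
    t = np.arange(1, H + 1)
    alive_weight = 0.5 * (s[:-1] + s[1:])
    disc = (1.0 + discount_rate) ** (-t / 12.0)
    total_disc = float(np.sum(alive_weight * mu * disc)) / exchange_rate
    total_undisc = float(np.sum(alive_weight * mu)) / exchange_rate
    le = float(np.trapezoid(s)) / 12.0
    if cost_per_year_method == "undiscounted_total_over_le":
        cpy = total_undisc / le if le > 0 else np.nan
    elif cost_per_year_method == "mean_annual_per_survivor":
        wsum = float(np.sum(alive_weight))
        cpy = 12.0 * float(np.sum(alive_weight * mu)) / wsum / exchange_rate if wsum > 0 else np.nan
    else:
        raise ValidationError(f"unknown cost_per_year_method {cost_per_year_method!r}")
    return LifetimeCostResult(
        lifetime_cost=total_disc, lifetime_cost_undiscounted=total_undisc,
        cost_per_year=cpy, le_years=le, discount_rate=discount_rate,
        exchange_rate=exchange_rate, cost_per_year_method=cost_per_year_method)
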