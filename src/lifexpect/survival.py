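"""Monthly Kaplan-Meier estimation of patient survival.

Follow-up arrives in whole months (bins [m, m+1)); a record with
``followup_months = m`` and ``died`` true is an event at month m, and the
product-limit estimate evaluated at m already includes that month's deaths.
Ties within a month follow the standard convention: deaths are processed
before censorings, so a record censored at m remains in the risk set for
month m's deaths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .cohort import Cohort
from .errors import ValidationError


@dataclass
class MonthlySurvivalCurve:
    """Product-limit survival on the month grid 0..T_obs with its risk sets."""
    s: np.ndarray          # S(t), length T_obs + 1
    n_at_risk: np.ndarray  # subjects with followup >= t
    n_events: np.ndarray   # deaths recorded at month t

    def __post_init__(self):
        s = np.asarray(self.s, float)
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValidationError("survival outside [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValidationError("survival curve must be non-increasing")
        self.s = np.clip(s, 0.0, 1.0)

    @property
    def t_obs(self) -> int:
        return len(self.s) - 1


def kaplan_meier_monthly(cohort: Cohort) -> MonthlySurvivalCurve:
    """Kaplan-Meier estimate of cohort survival on the monthly grid."""
    df = cohort.df
    if df.empty:
        raise ValidationError("empty cohort")
    durations = df["followup_months"].to_numpy(int)
    events = df["died"].to_numpy(bool)
    if durations.max() == 0 and not events.any():
        raise ValidationError("no follow-up information: all records censored at month 0")
    if events.any() and (durations[events] == 0).any():
        warnings.warn("deaths recorded at month 0 force S(0) < 1")

    t_obs = int(durations.max())
    grid = np.arange(t_obs + 1)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    s = kmf.survival_function_at_times(grid).to_numpy(float)

    n_at_risk = (durations[:, None] >= grid[None, :]).sum(axis=0) \
        if len(df) * (t_obs + 1) < 5_000_000 else \
        np.array([(durations >= t).sum() for t in grid])
    n_events = np.bincount(durations[events], minlength=t_obs + 1)
    return MonthlySurvivalCurve(s=s, n_at_risk=n_at_risk, n_events=n_events)
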