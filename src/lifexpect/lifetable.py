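"""National life table model and the Monte Carlo matched reference cohort.

The life table gives the annual death probability q(sex, calendar year, age).
Within a year the hazard is taken constant, so the monthly survival factor is
(1-q)^(1/12). A referent "born" into the table at the patient's age, sex and
calendar year advances one month at a time; attained age and calendar year
both step forward at each diagnosis anniversary. Years beyond the table range
reuse the nearest available year (period life-table convention) and ages
beyond the terminal age are treated as certain death, which guarantees
termination at the age cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_AGE_CAP = 110


class LifeTable:
    """Annual death probabilities keyed by (sex, calendar year, age)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "year", "age", "qx"}
        if not required.issubset(frame.columns):
            raise ValidationError(f"life table needs columns {sorted(required)}")
        if ((frame["qx"] < 0) | (frame["qx"] > 1)).any():
            raise ValidationError("qx outside [0, 1]")
        self._tables: dict[str, np.ndarray] = {}
        self.years: dict[str, np.ndarray] = {}
        self.ages: dict[str, np.ndarray] = {}
        for sex, g in frame.groupby("sex"):
            years = np.sort(g["year"].unique())
            ages = np.sort(g["age"].unique())
            if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
                raise ValidationError(f"ages not contiguous for sex={sex}")
            pivot = g.pivot_table(index="year", columns="age", values="qx")
            pivot = pivot.reindex(index=years, columns=ages)
            if pivot.isna().any().any():
                raise ValidationError(f"incomplete year x age grid for sex={sex}")
            self._tables[str(sex)] = pivot.to_numpy(float)
            self.years[str(sex)] = years.astype(int)
            self.ages[str(sex)] = ages.astype(int)
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def terminal_age(self, sex: str) -> int:
        return int(self.ages[str(sex)][-1])

    def min_age(self, sex: str) -> int:
        return int(self.ages[str(sex)][0])

    def annual_q(self, sex: str, year: int, age: int) -> float:
        """q for one cell; year clamped to the table range, age beyond the
        terminal age returns 1 (closure), age below the minimum is an error."""
        sex = str(sex)
        years, ages = self.years[sex], self.ages[sex]
        if age > ages[-1]:
            return 1.0
        if age < ages[0]:
            raise ValidationError(f"age {age} below life-table minimum {ages[0]}")
        y = int(np.clip(year, years[0], years[-1]))
        if y != year:
            log.debug("year %d clamped to %d", year, y)
        yi = int(np.searchsorted(years, y))
        return float(self._tables[sex][yi, age - ages[0]])

    def monthly_survival_factor(self, sex: str, year: int, age: int) -> float:
        """Constant-within-year monthly survival factor (1-q)^(1/12)."""
        return (1.0 - self.annual_q(sex, year, age)) ** (1.0 / 12.0)

    def monthly_curve(self, sex: str, entry_age: int, entry_year: int,
                      hazard_ratio: float = 1.0,
                      age_cap: int = DEFAULT_AGE_CAP) -> np.ndarray:
        """Deterministic survival curve S(t) on months t = 0..(cap-age)*12
        for a subject entering the table at (entry_age, entry_year), with an
        optional proportional-hazards multiplier on the table hazard.

        S is the cumulative product of monthly factors; under a hazard ratio
        h the monthly factor is (1-q)^(h/12). S reaches 0 by the age cap.
        """
        sex = str(sex)
        if entry_age > self.terminal_age(sex):
            raise ValidationError(
                f"entry age {entry_age} beyond life-table terminal age")
        n_years = max(age_cap - entry_age, 0)
        if n_years == 0:
            return np.array([1.0, 0.0])
        q = np.array([self.annual_q(sex, entry_year + k, entry_age + k)
                      for k in range(n_years)])
        monthly = np.repeat((1.0 - q) ** (hazard_ratio / 12.0), 12)
        s = np.empty(monthly.size + 1)
        s[0] = 1.0
        np.cumprod(monthly, out=s[1:])
        s[-1] = 0.0  # closure at the age cap
        return s

    def expected_life(self, sex: str, entry_age: int, entry_year: int,
                      age_cap: int = DEFAULT_AGE_CAP) -> float:
        """Exact remaining life expectancy (years) from the table by the
        deterministic survivorship-product recursion (trapezoid on months)."""
        s = self.monthly_curve(sex, entry_age, entry_year, 1.0, age_cap)
        return float(np.trapezoid(s)) / 12.0


@dataclass
class ReferentCurve:
    """Pooled survival of the age/sex/calendar-year matched reference group
    on the monthly grid since index date. s[0] = 1; s non-increasing."""
    s: np.ndarray
    n_referents: int

    def __post_init__(self):
        s = np.asarray(self.s, float)
        if s[0] != 1.0 or np.any(np.diff(s) > 1e-12) or s.min() < 0 or s.max() > 1:
            raise ValidationError("referent curve must start at 1 and be non-increasing in [0,1]")
        self.s = s

    @property
    def horizon_months(self) -> int:
        return len(self.s) - 1

    def life_expectancy(self) -> float:
        return float(np.trapezoid(self.s)) / 12.0


def _entry_groups(cohort: Cohort) -> list[tuple[str, int, int, int]]:
    """Distinct (sex, age, dx_year) combinations with patient counts,
    in sorted order for determinism."""
    df = cohort.df
    g = (df.groupby(["sex", "age_at_dx", "dx_year"]).size()
           .sort_index().reset_index(name="n"))
    return [(str(r.sex), int(r.age_at_dx), int(r.dx_year), int(r.n))
            for r in g.itertuples()]


def reference_curve_deterministic(cohort: Cohort, table: LifeTable,
                                  age_cap: int = DEFAULT_AGE_CAP) -> ReferentCurve:
    """Exact (infinite-replicate) matched reference curve: the patient-mix
    average of deterministic life-table curves. Serves as the closed-form
    counterpart of the Monte Carlo simulation."""
    groups = _entry_groups(cohort)
    if not groups:
        raise ValidationError("empty cohort")
    horizon = max((age_cap - age) * 12 for _, age, _, _ in groups)
    acc = np.zeros(horizon + 1)
    total = 0
    for sex, age, year, n in groups:
        s = table.monthly_curve(sex, age, year, 1.0, age_cap)
        acc[: len(s)] += n * s
        total += n
    return ReferentCurve(acc / total, n_referents=total)


def sample_death_months(curve: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Death month d for uniform draws u: smallest t with S(t) < u.

    Equivalent in distribution to the month-by-month Bernoulli walk through
    the life table, but vectorised: one searchsorted per draw.
    """
    return np.searchsorted(-curve, -u, side="right")


def simulate_reference_cohort(cohort: Cohort, table: LifeTable,
                              n_replicates: int = 100, seed: int | None = 0,
                              age_cap: int = DEFAULT_AGE_CAP,
                              epsilon: float = 1e-4) -> ReferentCurve:
    """Monte Carlo matched reference group.

    For every patient, ``n_replicates`` referents with the same entry age,
    sex and calendar year walk month-by-month through the life table until
    death or the age cap; the pooled survivor fraction is the reference
    curve, truncated once it falls to ``epsilon``. The referent age/sex/year
    distribution equals the patient distribution exactly by construction.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    groups = _entry_groups(cohort)
    if not groups:
        raise ValidationError("empty cohort")
    horizon = max((age_cap - age) * 12 for _, age, _, _ in groups)
    death_counts = np.zeros(horizon + 2)
    total = 0
    for sex, age, year, n in groups:
        s = table.monthly_curve(sex, age, year, 1.0, age_cap)
        u = rng.random(n * n_replicates)
        d = sample_death_months(s, u)
        np.add.at(death_counts, d, 1)
        total += n * n_replicates
    # survivor fraction: alive at end of month t iff death month > t
    dead_by = np.cumsum(death_counts)[: horizon + 1]
    s_r = 1.0 - dead_by / total
    s_r[0] = 1.0
    below = np.nonzero(s_r <= epsilon)[0]
    if below.size:
        s_r = s_r[: below[0] + 1]
    return ReferentCurve(s_r, n_referents=total)
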