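"""Registry cohort model: record schema, eligibility filtering, stratification.

A cohort is a pandas DataFrame with one row per patient plus a fixed
administrative censoring date. Strata follow the three clinical axes used
for prostate-cancer registry reporting: AJCC stage, serum PSA band and
Gleason-score band, each crossed with a three-level age band at diagnosis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

#: inclusive age bands at diagnosis (label, low, high)
AGE_BANDS: tuple[tuple[str, int, int], ...] = (
    ("20-64", 20, 64),
    ("65-74", 65, 74),
    ("75-89", 75, 89),
)

AGE_MIN, AGE_MAX = 20, 89

#: PSA (ng/ml) bands. The published labels "<4, 4-9, 10-19, 20-50, >50"
#: leave the gaps (9,10), (19,20) and the point 50 unassigned; we adopt the
#: half-open partition [0,4), [4,10), [10,20), [20,50], (50,inf) so every
#: non-negative value maps to exactly one band.
PSA_BAND_LABELS: tuple[str, ...] = ("<4", "4-9", "10-19", "20-50", ">50")

GLEASON_BAND_LABELS: tuple[str, ...] = ("<=6", "3+4", "4+3", "8", "9-10")

STAGE_LEVELS: tuple[str, ...] = ("1", "2", "3", "4")

#: stratification axes -> column holding the band label
AXES: dict[str, str] = {
    "stage": "stage",
    "psa_band": "psa_band",
    "gleason_band": "gleason_band",
}

COHORT_COLUMNS = [
    "id", "sex", "age_at_dx", "dx_year", "dx_month", "stage", "psa",
    "gleason_primary", "gleason_secondary", "followup_months", "died",
]


def age_band(age: int) -> str | None:
    for label, lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return label
    return None


def psa_band(psa: float) -> str | None:
    """Band a PSA value (ng/ml); NaN / missing -> None."""
    if psa is None or (isinstance(psa, float) and np.isnan(psa)):
        return None
    if psa < 0:
        raise ValidationError(f"negative PSA value {psa!r}")
    if psa < 4:
        return "<4"
    if psa < 10:
        return "4-9"
    if psa < 20:
        return "10-19"
    if psa <= 50:
        return "20-50"
    return ">50"


def gleason_band(primary, secondary) -> str | None:
    """Band a Gleason primary+secondary pattern pair.

    3+4 and 4+3 are kept distinct (different prognosis); any split summing
    to 8 maps to band "8"; 9-10 pools the highest grades. A total of 7 from
    a non-3/4 split (e.g. 2+5) is assigned by the primary pattern.
    Missing either pattern -> None (record drops out of this axis only).
    """
    if primary is None or secondary is None:
        return None
    if isinstance(primary, float) and np.isnan(primary):
        return None
    if isinstance(secondary, float) and np.isnan(secondary):
        return None
    p, s = int(primary), int(secondary)
    if not (1 <= p <= 5 and 1 <= s <= 5):
        raise ValidationError(f"Gleason patterns out of range 1-5: {p}+{s}")
    total = p + s
    if total <= 6:
        return "<=6"
    if total == 7:
        return "3+4" if p <= 3 else "4+3"
    if total == 8:
        return "8"
    return "9-10"


@dataclass(frozen=True)
class StratumKey:
    """Identifies one reporting stratum: age band x one clinical axis level."""
    age_band: str
    axis: str
    level: str

    def __post_init__(self):
        if self.axis not in AXES:
            raise ValidationError(f"unknown stratification axis {self.axis!r}")


@dataclass
class PatientRecord:
    """One registry row. ``followup_months`` counts whole months from
    diagnosis to death or administrative censoring; when ``died`` is true
    the death occurred in month ``followup_months``."""
    id: str
    sex: str
    age_at_dx: int
    dx_year: int
    dx_month: int
    stage: str
    followup_months: int
    died: bool
    psa: float | None = None
    gleason_primary: int | None = None
    gleason_secondary: int | None = None

    def validate(self) -> None:
        if self.followup_months < 0:
            raise ValidationError(f"record {self.id}: negative follow-up")
        if not (1 <= self.dx_month <= 12):
            raise ValidationError(f"record {self.id}: dx_month out of range")
        if str(self.stage) not in STAGE_LEVELS:
            raise ValidationError(f"record {self.id}: stage {self.stage!r}")
        try:
            gleason_band(self.gleason_primary, self.gleason_secondary)
            psa_band(self.psa)
        except ValidationError as e:
            raise ValidationError(f"record {self.id}: {e}") from None


@dataclass
class Cohort:
    """Eligible registry records plus the cohort-wide censoring date."""
    df: pd.DataFrame
    censor_date: pd.Period = field(default_factory=lambda: pd.Period("2019-12", "M"))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_deaths(self) -> int:
        return int(self.df["died"].sum())


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        if isinstance(r, PatientRecord):
            rows.append({
                "id": r.id, "sex": r.sex, "age_at_dx": r.age_at_dx,
                "dx_year": r.dx_year, "dx_month": r.dx_month,
                "stage": str(r.stage), "psa": r.psa,
                "gleason_primary": r.gleason_primary,
                "gleason_secondary": r.gleason_secondary,
                "followup_months": r.followup_months, "died": r.died,
            })
        else:
            rows.append(dict(r))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def filter_eligible(raw: pd.DataFrame, censor_date="2019-12") -> tuple[Cohort, int]:
    """Apply the eligibility rule (ages 20-89 at diagnosis, inclusive).

    Returns the eligible cohort and the number of removed records. An empty
    input yields an empty cohort with a warning rather than an error.
    """
    raw = raw.copy()
    if raw.empty:
        warnings.warn("empty record list: returning empty cohort")
        return Cohort(raw.reindex(columns=COHORT_COLUMNS), pd.Period(censor_date, "M")), 0
    keep = (raw["age_at_dx"] >= AGE_MIN) & (raw["age_at_dx"] <= AGE_MAX)
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("excluded %d records outside ages %d-%d", n_removed, AGE_MIN, AGE_MAX)
    df = raw.loc[keep].reset_index(drop=True)
    df["stage"] = df["stage"].astype(str)
    df["died"] = df["died"].astype(bool)
    if (df["followup_months"] < 0).any():
        raise ValidationError("negative followup_months in input")
    return Cohort(df, pd.Period(censor_date, "M")), n_removed


def assign_strata(cohort: Cohort | pd.DataFrame) -> pd.DataFrame:
    """Attach band columns (age_band, psa_band, gleason_band) to the cohort.

    Missing PSA or Gleason leaves the corresponding band as NA: the record
    drops out of that axis only and still counts on the stage axis.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    out = df.copy()
    out["age_band"] = [age_band(int(a)) for a in out["age_at_dx"]]
    if out["age_band"].isna().any():
        bad = out.loc[out["age_band"].isna(), "id"].tolist()[:5]
        raise ValidationError(f"ineligible ages present (e.g. {bad}); run filter_eligible first")
    out["psa_band"] = [psa_band(v) for v in out.get("psa", pd.Series(np.nan, index=out.index))]
    gp = out.get("gleason_primary", pd.Series(np.nan, index=out.index))
    gs = out.get("gleason_secondary", pd.Series(np.nan, index=out.index))
    bands = []
    for rid, p, s in zip(out["id"], gp, gs):
        try:
            bands.append(gleason_band(p, s))
        except ValidationError as e:
            raise ValidationError(f"record {rid}: {e}") from None
    out["gleason_band"] = bands
    return out


def stratum_cohort(cohort: Cohort, key: StratumKey) -> Cohort:
    """Sub-cohort for one stratum (records with the axis band missing are excluded)."""
    df = assign_strata(cohort)
    col = AXES[key.axis]
    sel = (df["age_band"] == key.age_band) & (df[col] == key.level)
    return Cohort(df.loc[sel].reset_index(drop=True), cohort.censor_date)


def read_cohort_csv(path, censor_date="2019-12") -> tuple[Cohort, int]:
    """Read a registry CSV (header required, UTF-8, empty fields = missing)
    and apply eligibility filtering."""
    df = pd.read_csv(path, dtype={"id": str, "stage": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {missing}")
    df["died"] = df["died"].astype(int).astype(bool)
    return filter_eligible(df, censor_date)


def write_cohort_csv(cohort: Cohort | pd.DataFrame, path) -> None:
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    out = df.reindex(columns=COHORT_COLUMNS).copy()
    out["died"] = out["died"].astype(int)
    out.to_csv(path, index=False)
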