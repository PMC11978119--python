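"""Published composition of the 2008-2019 Taiwanese prostate-cancer cohort.

The national registry data behind the published stage-stratified results
are not publicly deposited; what is public is the printed cohort
composition (patient and death counts per age band x AJCC stage, with age
means). Those counts are inputs here: they parameterise a fixture cohort
whose stratified counts reproduce the published table arithmetic exactly,
which exercises the reporting layer end-to-end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort

#: (age_band, stage) -> (N, deaths, mean age, sd age)
STAGE_COMPOSITION: dict[tuple[str, str], tuple[int, int, float, float]] = {
    ("20-64", "1"): (1016, 39, 60.50, 4.03),
    ("20-64", "2"): (2733, 137, 60.34, 3.97),
    ("20-64", "3"): (718, 53, 60.54, 3.91),
    ("20-64", "4"): (1652, 732, 59.95, 4.20),
    ("65-74", "1"): (1413, 139, 69.92, 2.83),
    ("65-74", "2"): (5057, 631, 70.20, 2.90),
    ("65-74", "3"): (1594, 210, 70.42, 2.79),
    ("65-74", "4"): (3173, 1445, 70.44, 2.90),
    ("75-89", "1"): (1053, 335, 80.38, 3.88),
    ("75-89", "2"): (5093, 1742, 80.57, 3.81),
    ("75-89", "3"): (1681, 606, 80.51, 3.79),
    ("75-89", "4"): (5024, 3268, 81.48, 3.96),
}

TOTAL_N = sum(v[0] for v in STAGE_COMPOSITION.values())  # 30,207

_BAND_AGE = {"20-64": 60, "65-74": 70, "75-89": 81}


def cohort_from_composition(
        composition: dict[tuple[str, str], tuple] = STAGE_COMPOSITION,
        censor_date: str = "2019-12") -> Cohort:
    """Build a synthetic fixture cohort whose (age band x stage) patient and
    death counts equal the published composition.

    Ages are set to a representative in-band value (counts, not age moments,
    are what the composition fixture certifies); deaths get a 12-month
    follow-up and survivors are censored at 60 months.
    """
    rows = []
    i = 0
    for (band, stage), cell in composition.items():
        n, deaths = int(cell[0]), int(cell[1])
        for j in range(n):
            died = j < deaths
            rows.append({
                "id": f"f{i:06d}", "sex": "male",
                "age_at_dx": _BAND_AGE[band],
                "dx_year": 2014, "dx_month": 6, "stage": stage,
                "psa": np.nan, "gleason_primary": np.nan,
                "gleason_secondary": np.nan,
                "followup_months": 12 if died else 60,
                "died": died,
            })
            i += 1
    return Cohort(pd.DataFrame(rows), pd.Period(censor_date, "M"))
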