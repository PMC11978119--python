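import numpy as np
import pandas as pd
import pytest

from lifexpect import Cohort, GeneratorConfig, LifeTable
from lifexpect.synthetic import make_life_table


@pytest.fixture(scope="session")
def gompertz_table() -> LifeTable:
    """Gompertz male life table over calendar years 2008-2019, ages 20-110."""
    return make_life_table(3.3e-5, 0.0916, years=range(2008, 2020))


@pytest.fixture(scope="session")
def flat_table() -> LifeTable:
    """Constant annual death probability 0.05 at every age below the cap."""
    ages = np.arange(20, 111)
    qx = np.full(ages.size, 0.05)
    qx[-1] = 1.0
    frames = [pd.DataFrame({"sex": "male", "year": y, "age": ages, "qx": qx})
              for y in (2008, 2019)]
    return LifeTable(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def zero_mortality_table() -> LifeTable:
    ages = np.arange(20, 111)
    qx = np.zeros(ages.size)
    qx[-1] = 1.0
    return LifeTable(pd.DataFrame({"sex": "male", "year": 2014, "age": ages, "qx": qx}))


def make_cohort(followups, died, ages=None, **kw) -> Cohort:
    """Tiny hand-built cohort on the standard schema."""
    n = len(followups)
    ages = ages if ages is not None else [70] * n
    df = pd.DataFrame({
        "id": [f"t{i}" for i in range(n)],
        "sex": "male",
        "age_at_dx": ages,
        "dx_year": kw.get("dx_year", 2014),
        "dx_month": 6,
        "stage": kw.get("stage", "4"),
        "psa": np.nan,
        "gleason_primary": np.nan,
        "gleason_secondary": np.nan,
        "followup_months": followups,
        "died": died,
    })
    return Cohort(df, pd.Period("2019-12", "M"))


@pytest.fixture
def tiny_cohort() -> Cohort:
    return make_cohort([2, 3, 4, 10, 10], [True, False, True, False, False])


@pytest.fixture(scope="session")
def banded_generator_config() -> GeneratorConfig:
    """Three-stratum study configuration: excess hazard 1 / 2 / 4."""
    return GeneratorConfig(
        n_patients=15000,
        stage_probs={"1": 1 / 3, "2": 1 / 3, "4": 1 / 3},
        stage_hrs={"1": 1.0, "2": 2.0, "4": 4.0},
    )
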