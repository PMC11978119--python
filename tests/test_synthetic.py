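import io

import numpy as np
import pytest

from lifexpect import (GeneratorConfig, make_life_table, simulate_cohort,
                       simulate_costs, write_cohort_csv)
from lifexpect.errors import ValidationError


class TestGompertzLifeTable:
    def test_theta_zero_gives_constant_qx(self):
        t = make_life_table(0.01, 0.0, years=[2014])
        qs = {t.annual_q("male", 2014, a) for a in range(20, 100)}
        assert len(qs) == 1

    def test_table_closes_at_terminal_age(self):
        t = make_life_table(3.3e-5, 0.0916, years=[2014])
        assert t.annual_q("male", 2014, t.terminal_age("male")) == 1.0

    def test_le_matches_independent_recursion(self):
        b, theta = 3.3e-5, 0.0916
        t = make_life_table(b, theta, years=[2014])
        # independent pure-python recursion straight from the Gompertz
        # definition (same closure convention: survival 0 at the age cap)
        s_vals = [1.0]
        for k in range((110 - 70) * 12):
            age = 70 + k // 12
            q = min(1.0, 1 - np.exp(-b * np.exp(theta * age)))
            s_vals.append(s_vals[-1] * (1 - q) ** (1 / 12))
        s_vals[-1] = 0.0
        assert t.expected_life("male", 70, 2014) == pytest.approx(
            np.trapezoid(s_vals) / 12, rel=1e-9)

    def test_invalid_b_rejected(self):
        with pytest.raises(ValidationError):
            make_life_table(-1.0, 0.1)


class TestCohortGenerator:
    def test_seed_determinism_byte_identical_csv(self):
        cfg = GeneratorConfig(n_patients=300, seed=11)
        out = []
        for _ in range(2):
            cohort, _ = simulate_cohort(cfg)
            costs = simulate_costs(cohort, cfg)
            buf1, buf2 = io.StringIO(), io.StringIO()
            write_cohort_csv(cohort, buf1)
            costs.to_csv(buf2, index=False)
            out.append((buf1.getvalue(), buf2.getvalue()))
        assert out[0] == out[1]

    def test_censor_date_before_deaths_censors_everyone(self):
        # near-zero hazard pushes every death time past the censor date
        cfg = GeneratorConfig(n_patients=100, gompertz_b=1e-12, seed=2)
        cohort, _ = simulate_cohort(cfg)
        assert not cohort.df["died"].any()
        # follow-up then equals the administrative window, and KM is flat
        from lifexpect import kaplan_meier_monthly
        km = kaplan_meier_monthly(cohort)
        assert np.all(km.s == 1.0)

    def test_truth_identities(self, banded_generator_config):
        cfg = GeneratorConfig(**{**banded_generator_config.__dict__, "n_patients": 2000})
        _, truth = simulate_cohort(cfg)
        t = truth.per_stratum
        assert np.allclose(t["loss_le"], t["le_referent"] - t["le"])
        unit = t.set_index("stage")
        assert unit.loc["1", "loss_le"] == pytest.approx(0.0, abs=1e-12)
        assert unit.loc["2", "le"] > unit.loc["4", "le"]

    def test_ages_respect_eligibility_window(self):
        cohort, _ = simulate_cohort(GeneratorConfig(n_patients=500, seed=3))
        assert cohort.df["age_at_dx"].between(20, 89).all()

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(GeneratorConfig(stage_probs={"1": 0.5, "4": 0.4}))


class TestCostGenerator:
    def test_costs_never_after_followup(self):
        cfg = GeneratorConfig(n_patients=300, seed=4)
        cohort, _ = simulate_cohort(cfg)
        costs = simulate_costs(cohort, cfg)
        fu = cohort.df.set_index("id")["followup_months"]
        assert (costs["month"] <= costs["id"].map(fu)).all()
        assert (costs["month"] >= 1).all()

    def test_zero_dispersion_gives_exact_chronic_mean(self):
        cfg = GeneratorConfig(n_patients=100, chronic_cv=0.0, surge=0.0, seed=5)
        cohort, _ = simulate_cohort(cfg)
        costs = simulate_costs(cohort, cfg)
        assert (costs["cost"] == cfg.chronic_mean).all()

    def test_zero_surge_keeps_terminal_months_at_chronic_level(self):
        cfg = GeneratorConfig(n_patients=800, surge=0.0, seed=6)
        cohort, _ = simulate_cohort(cfg)
        costs = simulate_costs(cohort, cfg)
        died = cohort.df[cohort.df["died"]]
        fu = died.set_index("id")["followup_months"]
        sub = costs[costs["id"].isin(died["id"])]
        terminal = sub[sub["month"] > sub["id"].map(fu) - 3]
        assert terminal["cost"].mean() == pytest.approx(cfg.chronic_mean, rel=0.1)

    def test_surge_lands_in_final_window(self):
        cfg = GeneratorConfig(n_patients=500, chronic_cv=0.0, seed=7)
        cohort, _ = simulate_cohort(cfg)
        costs = simulate_costs(cohort, cfg)
        died = cohort.df[cohort.df["died"]]
        fu = died.set_index("id")["followup_months"]
        sub = costs[costs["id"].isin(died["id"])].copy()
        k = sub["id"].map(fu) - sub["month"] + 1
        assert (sub.loc[k <= cfg.surge_window, "cost"]
                == cfg.chronic_mean + cfg.surge).all()
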