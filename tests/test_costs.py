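import numpy as np
import pandas as pd
import pytest

from lifexpect import estimate_cost_function, lifetime_cost
from lifexpect.costs import CostFunction
from lifexpect.errors import ValidationError
from tests.conftest import make_cohort


def flat_costs(cohort, amount):
    rows = []
    for pid, fu in zip(cohort.df["id"], cohort.df["followup_months"]):
        for m in range(1, int(fu) + 1):
            rows.append({"id": pid, "month": m, "cost": amount})
    return pd.DataFrame(rows)


def geometric_curve(p, horizon):
    s = p ** np.arange(horizon + 1)
    s[-1] = 0.0
    return s


class TestCostFunctionEstimation:
    def test_constant_costs_no_deaths(self):
        cohort = make_cohort([24, 24, 24], [False] * 3)
        fn = estimate_cost_function(flat_costs(cohort, 1000.0), cohort, K=6)
        assert np.allclose(fn.c, 1000.0)
        assert fn.c_inf == pytest.approx(1000.0)

    def test_terminal_surge_recovered(self):
        rng = np.random.default_rng(1)
        n = 2000
        fus = rng.integers(10, 40, n)
        cohort = make_cohort(list(fus), [True] * n)
        rows = []
        for pid, fu in zip(cohort.df["id"], fus):
            for m in range(1, fu + 1):
                surge = 10_000.0 if fu - m + 1 <= 3 else 0.0
                rows.append({"id": pid, "month": m, "cost": 1000.0 + surge})
        fn = estimate_cost_function(pd.DataFrame(rows), cohort, K=3)
        assert np.allclose(fn.d, 11_000.0, rtol=0.05)
        assert np.allclose(fn.c[:9], 1000.0, rtol=0.05)

    def test_no_cost_records_rejected(self, tiny_cohort):
        with pytest.raises(ValidationError, match="no cost data"):
            estimate_cost_function(pd.DataFrame(columns=["id", "month", "cost"]),
                                   tiny_cohort)

    def test_cost_after_followup_rejected(self, tiny_cohort):
        bad = pd.DataFrame([{"id": "t0", "month": 5, "cost": 10.0}])  # t0 died at 2
        with pytest.raises(ValidationError, match="after follow-up"):
            estimate_cost_function(bad, tiny_cohort)

    def test_unknown_patient_rejected(self, tiny_cohort):
        bad = pd.DataFrame([{"id": "ghost", "month": 1, "cost": 10.0}])
        with pytest.raises(ValidationError, match="unknown"):
            estimate_cost_function(bad, tiny_cohort)

    def test_cpi_multiplier_scales_costs(self):
        cohort = make_cohort([12, 12], [False, False])
        base = estimate_cost_function(flat_costs(cohort, 100.0), cohort)
        adj = estimate_cost_function(flat_costs(cohort, 100.0), cohort,
                                     cpi={2014: 2.0, 2015: 2.0})
        assert np.allclose(adj.c, 2 * base.c)


class TestLifetimeCost:
    def constant_fn(self, c):
        return CostFunction(c=np.full(60, c), d=np.full(6, c), c_inf=c, K=6)

    def test_constant_cost_identity(self):
        s = geometric_curve(0.98, 600)
        res = lifetime_cost(self.constant_fn(30.93), s, discount_rate=0.0,
                            exchange_rate=30.93)
        le = np.trapezoid(s) / 12
        assert res.lifetime_cost == pytest.approx(12 * le, rel=1e-9)

    def test_discounting_strictly_reduces_cost(self):
        s = geometric_curve(0.99, 900)
        fn = self.constant_fn(1000.0)
        r0 = lifetime_cost(fn, s, 0.0, 30.93)
        r3 = lifetime_cost(fn, s, 0.03, 30.93)
        assert r3.lifetime_cost < r0.lifetime_cost
        assert r3.lifetime_cost_undiscounted == pytest.approx(r0.lifetime_cost)

    def test_exponential_closed_form_with_discounting(self):
        p, r = 0.99, 0.03
        s = geometric_curve(p, 3000)
        res = lifetime_cost(self.constant_fn(1.0), s, r, exchange_rate=1.0)
        delta = (1 + r) ** (-1 / 12)
        # sum_t 0.5 (p^{t-1} + p^t) delta^t
        closed = 0.5 * (1 + p) * delta * p ** 0 / (1 - p * delta) / p * p
        closed = 0.5 * (1 / p + 1) * (p * delta) / (1 - p * delta)
        assert res.lifetime_cost == pytest.approx(closed, rel=0.005)

    def test_currency_conversion(self):
        s = np.array([1.0, 1.0, 0.0])
        fn = CostFunction(c=np.full(2, 30.93), d=np.full(6, 30.93), c_inf=30.93, K=6)
        res = lifetime_cost(fn, s, 0.0, exchange_rate=30.93)
        # two months alive at 30.93 TWD/month -> 1 USD per full survival month
        assert res.lifetime_cost == pytest.approx(1.0 + 0.5)

    def test_scaling_linearity(self):
        s = geometric_curve(0.99, 900)
        a = lifetime_cost(self.constant_fn(1000.0), s, 0.03, 30.93)
        b = lifetime_cost(self.constant_fn(3000.0), s, 0.03, 30.93)
        assert b.lifetime_cost == pytest.approx(3 * a.lifetime_cost, rel=1e-12)

    def test_negative_discount_rejected(self):
        with pytest.raises(ValidationError):
            lifetime_cost(self.constant_fn(1.0), np.array([1.0, 0.0]), -0.01, 30.93)

    def test_cost_per_year_methods(self):
        s = geometric_curve(0.99, 2000)
        fn = self.constant_fn(1000.0)
        a = lifetime_cost(fn, s, 0.03, 30.93, "undiscounted_total_over_le")
        b = lifetime_cost(fn, s, 0.03, 30.93, "mean_annual_per_survivor")
        assert a.cost_per_year == pytest.approx(b.cost_per_year, rel=1e-6)
        with pytest.raises(ValidationError):
            lifetime_cost(fn, s, 0.03, 30.93, "nonsense")


def test_terminal_decomposition_feeds_expected_cost():
    """Beyond follow-up the expected cost must blend chronic and terminal
    components with death probabilities from the survival curve."""
    fn = CostFunction(c=np.full(10, 100.0), d=np.full(3, 1000.0), c_inf=100.0, K=3)
    s = np.array([1.0, 0.5, 0.0])  # everyone dies within two months
    mu = fn.expected_monthly_cost(s)
    # month 1: P(die month1)=0.5, P(die month2 | alive)=0.5 -> all terminal
    assert mu[0] == pytest.approx(1000.0)
    assert mu[1] == pytest.approx(1000.0)
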