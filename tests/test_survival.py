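"""Product-limit estimation, log-rank comparison and O/E hazard ratio;
lifelines serves as the independent cross-check."""

import numpy as np
import pandas as pd
import pytest

from netmark.survival import (
    compare_by_median,
    km_curve,
    logrank,
    stratify_by_median,
)
from netmark.synth import SynthConfig, make_survival


def surv(times, events, expr=None):
    n = len(times)
    return pd.DataFrame(
        {
            "subject": [f"s{i}" for i in range(n)],
            "time": times,
            "event": events,
            "expression": expr if expr is not None else np.zeros(n),
        }
    )


class TestStratify:
    def test_strict_median_split(self):
        t = surv([1] * 4, [1] * 4, expr=[1, 2, 3, 4])
        labels = stratify_by_median(t)
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        t = surv([1] * 4, [1] * 4, expr=[1, 2, 2, 3])
        assert list(stratify_by_median(t)) == ["low", "low", "low", "high"]

    def test_order_invariance(self, rng):
        expr = rng.normal(size=20)
        t = surv(np.ones(20), np.ones(20, int), expr)
        perm = rng.permutation(20)
        shuffled = t.iloc[perm].reset_index(drop=True)
        a = stratify_by_median(t).to_numpy()[perm]
        b = stratify_by_median(shuffled).to_numpy()
        assert (a == b).all()

    def test_constant_expression_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            stratify_by_median(surv([1] * 5, [1] * 5, expr=[2] * 5))


class TestKmCurve:
    def test_all_events_hand_computed(self):
        km = km_curve([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_survival_stays_one(self):
        km = km_curve([1, 2, 3], [0, 0, 0])
        assert km.event_times.size == 0 and km.survival_at(10) == 1.0

    def test_censoring_reduces_risk_set(self):
        # risk sets 3, (censor at 2), 1: S(1) = 2/3, S(3) = 2/3 * (1 - 1/1) = 0
        km = km_curve([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == 0.0

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(5, size=100)
        c = rng.uniform(0, 10, size=100)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        km = km_curve(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for et in km.event_times:
            assert km.survival_at(et) == pytest.approx(
                float(kmf.predict(et)), abs=1e-9
            )

    def test_horizon_truncates(self):
        km = km_curve([1, 4, 6], [1, 1, 1], horizon=5)
        assert km.event_times.max() == 4
        assert km.survival_at(5) == pytest.approx(1 / 3)


class TestLogrank:
    def test_identical_groups_null(self):
        g = surv([1, 2, 3, 4], [1, 1, 0, 1])
        cmp_ = logrank(g, g.copy())
        assert cmp_.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert cmp_.hazard_ratio == pytest.approx(1.0)

    def test_toy_hand_computed_tables(self):
        g1 = surv([1, 2], [1, 1])
        g2 = surv([3, 4], [1, 1])
        cmp_ = logrank(g1, g2)
        # per event time (n1, n2, d): t=1 (2,2,1), t=2 (1,2,1),
        # t=3 (0,2,1), t=4 (0,1,1); O1 = 2, E1 = 1/2 + 1/3 = 5/6
        assert cmp_.observed == (2.0, 2.0)
        assert cmp_.expected[0] == pytest.approx(5 / 6)
        # variance terms d*(n1/n)*(n2/n)*(n-d)/(n-1): 1/4 + 2/9 + 0 + 0
        var = 1 / 4 + 2 / 9
        assert cmp_.logrank_chi2 == pytest.approx((2 - 5 / 6) ** 2 / var)

    def test_label_swap_inverts_hr_preserves_chi2(self, rng):
        g1 = surv(rng.exponential(2, 30), rng.integers(0, 2, 30))
        g2 = surv(rng.exponential(4, 30), rng.integers(0, 2, 30))
        a, b = logrank(g1, g2), logrank(g2, g1)
        assert a.logrank_chi2 == pytest.approx(b.logrank_chi2, rel=1e-12)
        assert a.hazard_ratio == pytest.approx(1 / b.hazard_ratio, rel=1e-12)

    def test_matches_lifelines_statistic(self, rng):
        from lifelines.statistics import logrank_test

        g1 = surv(rng.exponential(2, 50), rng.integers(0, 2, 50))
        g2 = surv(rng.exponential(3, 50), rng.integers(0, 2, 50))
        mine = logrank(g1, g2)
        ref = logrank_test(g1.time, g2.time, g1.event, g2.event)
        assert mine.logrank_chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_rejected(self):
        g = surv([1, 2], [0, 0])
        with pytest.raises(ValueError, match="no events"):
            logrank(g, g.copy())


class TestSimulationRecovery:
    def test_hazard_ratio_two_recovered_with_power(self):
        hrs, rejections = [], 0
        n_rep = 50
        for s in range(n_rep):
            cfg = SynthConfig(seed=s, hazard_beta=np.log(2), censor_rate=0.2)
            table = make_survival(cfg, n_subjects=400)
            cmp_, _, _ = compare_by_median(table)
            hrs.append(cmp_.hazard_ratio)
            rejections += cmp_.p < 0.05
        assert 1.7 <= np.mean(hrs) <= 2.4
        assert rejections / n_rep > 0.8
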