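import numpy as np
import pandas as pd
import pytest

from clonediv import survival
from clonediv.io import SurvivalRecord


def rec(time, event, sid="p"):
    return SurvivalRecord(sample_id=sid, time_months=time, event=event)


def brute_logrank_chi2(group_a, group_b):
    """Independent (O-E)^2/V log-rank on small fixtures."""
    rows = [(r.time_months, r.event, 0) for r in group_a] + \
           [(r.time_months, r.event, 1) for r in group_b]
    times = sorted({t for t, e, _ in rows if e})
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        at_risk = [(tt, ee, g) for tt, ee, g in rows if tt >= t]
        n = len(at_risk)
        n1 = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee)
        d1 = sum(1 for tt, ee, g in at_risk if tt == t and ee and g == 0)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        curve = survival.km_estimate([rec(5, False), rec(10, False)])
        assert np.all(curve.survival_probs == 1.0)
        assert curve.median_time is None

    def test_two_events_product_limit_by_hand(self):
        curve = survival.km_estimate([rec(1, True), rec(2, True)])
        by_time = dict(zip(curve.event_times, curve.survival_probs))
        assert by_time[1.0] == pytest.approx(0.5)
        assert by_time[2.0] == pytest.approx(0.0)
        assert curve.median_time == pytest.approx(1.0)

    def test_single_event(self):
        curve = survival.km_estimate([rec(5, True)])
        assert curve.survival_probs[-1] == pytest.approx(0.0)
        assert curve.median_time == pytest.approx(5.0)

    def test_five_record_fixture_exact(self):
        # times 1,2+,3,4+,5 -> S(1)=4/5, S(3)=4/5*2/3, S(5)=0
        records = [rec(1, True), rec(2, False), rec(3, True),
                   rec(4, False), rec(5, True)]
        curve = survival.km_estimate(records)
        by_time = dict(zip(curve.event_times, curve.survival_probs))
        assert by_time[1.0] == pytest.approx(4 / 5)
        assert by_time[3.0] == pytest.approx(4 / 5 * 2 / 3)
        assert by_time[5.0] == pytest.approx(0.0)
        assert curve.median_time == pytest.approx(5.0)

    def test_tied_events_share_time_point(self):
        curve = survival.km_estimate([rec(2, True), rec(2, True), rec(3, False)])
        by_time = dict(zip(curve.event_times, curve.survival_probs))
        assert by_time[2.0] == pytest.approx(1 / 3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rec(-1.0, True)

    def test_at_risk_counts_monotone(self):
        records = [rec(t, True) for t in (1, 2, 3, 4)]
        curve = survival.km_estimate(records)
        assert np.all(np.diff(curve.n_at_risk) <= 0)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        group = [rec(t, True) for t in (1, 3, 7, 9)]
        chi2, p = survival.logrank_test(group, list(group))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_statistic_zero(self):
        a = [rec(5, False)] * 3
        b = [rec(7, False)] * 3
        assert survival.logrank_test(a, b) == (0.0, 1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        a = [rec(t, True) for t in rng.exponential(10, 20)]
        b = [rec(t, True) for t in rng.exponential(20, 20)]
        chi_ab, p_ab = survival.logrank_test(a, b)
        chi_ba, p_ba = survival.logrank_test(b, a)
        assert chi_ab == pytest.approx(chi_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            a = [rec(float(t), bool(e)) for t, e in
                 zip(rng.integers(1, 15, 8), rng.random(8) < 0.8)]
            b = [rec(float(t), bool(e)) for t, e in
                 zip(rng.integers(1, 15, 8), rng.random(8) < 0.8)]
            if not any(r.event for r in a + b):
                continue
            chi2, _ = survival.logrank_test(a, b)
            assert chi2 == pytest.approx(brute_logrank_chi2(a, b), rel=1e-6)

    def test_standardized_statistic_squares_to_chi2(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(10, 40)
        events = rng.random(40) < 0.7
        group = rng.random(40) < 0.5
        a = [rec(t, bool(e)) for t, e, g in zip(times, events, group) if g]
        b = [rec(t, bool(e)) for t, e, g in zip(times, events, group) if not g]
        chi2, _ = survival.logrank_test(a, b)
        z = survival.standardized_logrank(times, events, group)
        assert z ** 2 == pytest.approx(chi2, rel=1e-6)

    def test_power_under_strong_hazard_ratio(self):
        rejections = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            a = [rec(t, True) for t in rng.exponential(10, 50)]
            b = [rec(t, True) for t in rng.exponential(30, 50)]
            _, p = survival.logrank_test(a, b)
            rejections += p < 0.05
        assert rejections / reps > 0.95


class TestMaxstat:
    def _cohort(self, rng, n=120, threshold=1.2, hr=5.0):
        values = rng.choice(np.round(np.arange(0.8, 1.61, 0.1), 2), size=n)
        hazard = np.where(values >= threshold, 0.03 / hr, 0.03)
        times = rng.exponential(1 / hazard)
        censor = rng.uniform(0, 150, n)
        records = [rec(min(t, c), bool(t <= c), sid=f"p{i}")
                   for i, (t, c) in enumerate(zip(times, censor))]
        return values, records

    def test_recovers_planted_threshold(self):
        values, records = self._cohort(np.random.default_rng(0))
        result = survival.maxstat_cutpoint(values, records)
        assert abs(result.best_cutoff - 1.2) <= 0.1
        assert result.p_adjusted < 0.05

    def test_best_cutoff_attains_max(self):
        values, records = self._cohort(np.random.default_rng(1))
        result = survival.maxstat_cutpoint(values, records)
        best = np.argmax(np.abs(result.standardized_statistics))
        assert result.best_cutoff == result.candidate_cutoffs[best]
        assert abs(result.max_statistic) == pytest.approx(
            np.max(np.abs(result.standardized_statistics)))

    def test_two_values_reduces_to_plain_logrank(self):
        rng = np.random.default_rng(2)
        values = np.array([1.0] * 20 + [2.0] * 20)
        times = np.concatenate([rng.exponential(10, 20), rng.exponential(40, 20)])
        records = [rec(t, True, sid=f"p{i}") for i, t in enumerate(times)]
        result = survival.maxstat_cutpoint(values, records)
        assert result.best_cutoff == pytest.approx(1.5)  # boundary above the low value
        group_a = [r for r, v in zip(records, values) if v == 1.0]
        group_b = [r for r, v in zip(records, values) if v == 2.0]
        chi2, _ = survival.logrank_test(group_a, group_b)
        assert result.max_statistic ** 2 == pytest.approx(chi2, rel=1e-6)

    def test_adjusted_p_not_below_unadjusted(self):
        from scipy import stats as sps
        values, records = self._cohort(np.random.default_rng(3))
        result = survival.maxstat_cutpoint(values, records)
        p_unadj = 2 * sps.norm.sf(abs(result.max_statistic))
        assert result.p_adjusted >= p_unadj - 1e-12

    def test_identical_values_rejected(self):
        records = [rec(t, True, sid=f"p{i}") for i, t in enumerate(range(1, 13))]
        with pytest.raises(ValueError, match="identical"):
            survival.maxstat_cutpoint(np.ones(12), records)

    def test_candidates_within_quantile_window(self):
        values, records = self._cohort(np.random.default_rng(4))
        result = survival.maxstat_cutpoint(values, records, quantile_window=(0.2, 0.8))
        for cutoff in result.candidate_cutoffs:
            prop = np.mean(values <= cutoff)
            assert 0.15 <= prop <= 0.85  # boundary is midpoint, allow half-step


class TestStratifiedReport:
    def _frame(self, rng, n=200, m_effect=True):
        rows = []
        for i in range(n):
            status = "M" if rng.random() < 0.5 else "U"
            id_class = "ID_high" if rng.random() < 0.3 else "ID_low"
            scale = 30.0
            if status == "M" and id_class == "ID_high" and m_effect:
                scale = 150.0
            t = rng.exponential(scale)
            c = rng.uniform(0, 120)
            rows.append({"sample_id": f"p{i}", "time_months": min(t, c),
                         "event": t <= c, "mutational_status": status,
                         "id_class": id_class})
        return pd.DataFrame(rows)

    def test_four_groups_and_m_arm_significant(self):
        report = survival.stratified_ttft_report(self._frame(
            np.random.default_rng(0)))
        assert set(report["groups"]) == {"M-ID_low", "M-ID_high",
                                         "U-ID_low", "U-ID_high"}
        assert report["tests"]["M-ID_high vs M-ID_low"]["p_value"] < 0.05

    def test_null_u_arm_not_significant(self):
        pvals = []
        for seed in range(5):
            report = survival.stratified_ttft_report(self._frame(
                np.random.default_rng(seed)))
            pvals.append(report["tests"]["U-ID_high vs U-ID_low"]["p_value"])
        assert np.median(pvals) > 0.05

    def test_single_group_input(self):
        df = pd.DataFrame([{"sample_id": "p0", "time_months": 10.0, "event": True,
                            "mutational_status": "M", "id_class": "ID_low"}])
        report = survival.stratified_ttft_report(df)
        assert list(report["groups"]) == ["M-ID_low"]
        assert report["tests"] == {}
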