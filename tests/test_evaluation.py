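import numpy as np
import pytest

from serialcox import (
    UndefinedResultError,
    concordance_index,
    evaluate,
    km_estimate,
    logrank_test,
    nyear_auroc,
    spearman_correlation,
    stratify_tertiles,
)


def _random_survival(rng, n, tie_free=True):
    risks = rng.normal(size=n)
    times = rng.exponential(20.0, size=n)
    events = rng.integers(0, 2, size=n)
    if events.sum() == 0:
        events[0] = 1
    return risks, times, events


def brute_force_c(risks, times, events):
    num = den = 0.0
    n = len(risks)
    for i in range(n):
        for j in range(n):
            if i == j or not (times[i] < times[j] and events[i] == 1):
                continue
            den += 1
            if risks[i] > risks[j]:
                num += 1
            elif risks[i] == risks[j]:
                num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_ordering(self):
        assert concordance_index([3, 1, 2], [1, 3, 2], [1, 1, 1]) == 1.0

    def test_all_risk_ties_give_half(self):
        assert concordance_index([1, 1, 1], [1, 2, 3], [1, 1, 1]) == 0.5

    def test_hand_case_one_third(self):
        assert concordance_index([2, 1, 3], [1, 2, 3], [1, 1, 0]) == pytest.approx(1 / 3)

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            r, t, e = _random_survival(rng, int(rng.integers(5, 40)))
            assert concordance_index(r, t, e) == pytest.approx(
                brute_force_c(r, t, e), abs=1e-12
            )

    def test_matches_lifelines_on_random_data(self):
        from lifelines.utils import concordance_index as ll_c

        rng = np.random.default_rng(1)
        for _ in range(100):
            r, t, e = _random_survival(rng, 60)
            assert concordance_index(r, t, e) == pytest.approx(
                ll_c(t, -r, e), abs=1e-6
            )

    def test_negating_risks_flips_c(self):
        rng = np.random.default_rng(2)
        r, t, e = _random_survival(rng, 50)
        c = concordance_index(r, t, e)
        assert concordance_index(-r, t, e) == pytest.approx(1 - c, abs=1e-12)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(UndefinedResultError):
            concordance_index([1, 2], [5, 6], [0, 0])


class TestTertiles:
    def test_nine_distinct_risks_split_evenly(self):
        groups = stratify_tertiles(np.arange(9.0))
        sizes = {g: groups.assignment.count(g) for g in ("low", "intermediate", "high")}
        assert sizes == {"low": 3, "intermediate": 3, "high": 3}
        assert groups.assignment[0] == "low" and groups.assignment[8] == "high"

    def test_constant_risks_still_balanced_by_stable_order(self):
        groups = stratify_tertiles(np.zeros(9))
        assert groups.assignment[:3] == ("low",) * 3
        assert groups.assignment[6:] == ("high",) * 3

    def test_large_cohort_outer_groups_balanced(self):
        rng = np.random.default_rng(3)
        groups = stratify_tertiles(rng.normal(size=868))
        sizes = {g: groups.assignment.count(g) for g in ("low", "intermediate", "high")}
        assert abs(sizes["high"] - sizes["low"]) <= 1
        assert sum(sizes.values()) == 868

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            stratify_tertiles([1.0, 2.0])


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([3.0, 5.0, 9.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_hand_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.0) == pytest.approx(1 / 3)
        assert km.survival_at(3.0) == pytest.approx(1 / 3)

    def test_all_events_no_ties_exact_rational(self):
        rng = np.random.default_rng(4)
        t = rng.permutation(np.arange(1.0, 11.0))
        km = km_estimate(t, np.ones(10))
        for k, ti in enumerate(np.sort(t), start=1):
            assert km.survival_at(ti) == pytest.approx((10 - k) / 10, abs=1e-12)

    def test_matches_lifelines_on_random_data(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(5)
        for _ in range(100):
            _, t, e = _random_survival(rng, 40)
            km = km_estimate(t, e)
            kmf = KaplanMeierFitter().fit(t, e)
            for ti, si in zip(km.event_times, km.survival_prob):
                assert si == pytest.approx(
                    float(kmf.predict(ti)), abs=1e-6
                )


class TestLogrank:
    def test_identical_groups_no_difference(self):
        t, e = [1.0, 2.0, 3.0], [1, 0, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_hypergeometric_case(self):
        chi2, _ = logrank_test([1.0, 2.0], [1, 1], [3.0, 4.0], [1, 1])
        assert chi2 == pytest.approx(49 / 17, abs=1e-9)  # per-event-time 2x2 tables

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(6)
        _, ta, ea = _random_survival(rng, 25)
        _, tb, eb = _random_survival(rng, 30)
        assert logrank_test(ta, ea, tb, eb)[0] == pytest.approx(
            logrank_test(tb, eb, ta, ea)[0], abs=1e-10
        )

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(7)
        for _ in range(100):
            _, ta, ea = _random_survival(rng, 30)
            _, tb, eb = _random_survival(rng, 35)
            chi2, p = logrank_test(ta, ea, tb, eb)
            ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-6)
            assert p == pytest.approx(ref.p_value, abs=1e-6)

    def test_zero_events_raises(self):
        with pytest.raises(UndefinedResultError):
            logrank_test([1.0], [0], [2.0], [0])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_correlation([1, 2, 3, 4], [9, 7, 5, 1]) == pytest.approx(-1.0)
        assert spearman_correlation([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_matches_scipy_with_ties(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(5, 50))
            a = rng.integers(0, 10, size=n).astype(float)  # ties likely
            b = rng.normal(size=n)
            if np.all(a == a[0]):
                continue
            assert spearman_correlation(a, b) == pytest.approx(
                spearmanr(a, b).statistic, abs=1e-6
            )

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedResultError):
            spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestNyearAuroc:
    def test_perfect_anti_ordering(self):
        # survivors (>= 24 months) all have lower risk than early deaths
        risks = [5.0, 4.0, 1.0, 0.0]
        times = [6.0, 12.0, 30.0, 40.0]
        events = [1, 1, 0, 1]
        assert nyear_auroc(risks, times, events, 2) == 1.0

    def test_null_risks_near_half(self):
        rng = np.random.default_rng(9)
        n = 4000
        risks = rng.normal(size=n)
        times = rng.exponential(30.0, size=n)
        events = rng.integers(0, 2, size=n)
        auc = nyear_auroc(risks, times, events, 2)
        assert abs(auc - 0.5) < 0.03

    def test_censored_before_threshold_excluded(self):
        risks = np.array([0.0, 1.0, 2.0, 3.0])
        times = np.array([30.0, 10.0, 5.0, 20.0])
        events = np.array([0, 1, 0, 1])  # patient 2 censored before 24 months
        with_ex = nyear_auroc(risks, times, events, 2)
        kept = [0, 1, 3]
        again = nyear_auroc(risks[kept], times[kept], events[kept], 2)
        assert with_ex == pytest.approx(again, abs=1e-12)

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(10)
        for _ in range(100):
            r, t, e = _random_survival(rng, 80)
            cutoff = 24.0
            keep = (t >= cutoff) | (e == 1)
            y = (t[keep] >= cutoff).astype(int)
            if y.min() == y.max():
                continue
            assert nyear_auroc(r, t, e, 2) == pytest.approx(
                roc_auc_score(y, -r[keep]), abs=1e-6
            )

    def test_invariant_to_increasing_transform(self):
        rng = np.random.default_rng(11)
        r, t, e = _random_survival(rng, 60)
        a = nyear_auroc(r, t, e, 2)
        b = nyear_auroc(np.exp(r) + 3.0, t, e, 2)
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_class_raises(self):
        with pytest.raises(UndefinedResultError):
            nyear_auroc([1.0, 2.0], [30.0, 40.0], [0, 0], 1)


class TestEvaluate:
    def test_report_fields_populated_and_in_range(self, small_fit):
        res, _, test = small_fit
        rep = evaluate(res, test)
        assert rep.n == len(test)
        if rep.c_index is not None:
            assert 0.0 <= rep.c_index <= 1.0
        if rep.spearman_rs is not None:
            assert -1.0 <= rep.spearman_rs <= 1.0
        for v in rep.auroc.values():
            if v is not None:
                assert 0.0 <= v <= 1.0
        assert sum(rep.group_sizes.values()) == rep.n
        d = rep.to_dict()
        assert set(d) >= {"c_index", "spearman_rs", "auroc", "logrank_p"}

    def test_degenerate_cohort_flags_missing_metrics(self, small_fit):
        from serialcox import Cohort
        from tests.conftest import make_record

        res, _, _ = small_fit
        recs = tuple(
            make_record(f"p{i}", ["identical text"], 50.0, 0) for i in range(6)
        )
        rep = evaluate(res, Cohort(recs))
        assert "c_index" in rep.missing
        assert rep.c_index is None
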