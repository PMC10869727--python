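"""Concordance, Kaplan-Meier, log-rank, stratification and ROC estimators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mpisurv as m
from conftest import cindex_bruteforce, random_outcomes


class TestConcordance:
    def test_perfect_anti_ordering(self):
        outs = [m.SubjectOutcome(str(i), float(i + 1), 1) for i in range(6)]
        scores = -np.arange(6.0)  # earliest event has highest score
        assert m.concordance_index(scores, outs) == 1.0

    def test_all_tied_scores_give_half(self):
        outs = [m.SubjectOutcome(str(i), float(i + 1), 1) for i in range(5)]
        assert m.concordance_index(np.zeros(5), outs) == 0.5

    @given(st.integers(4, 12), st.integers(0, 3000))
    def test_matches_pair_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        outs = random_outcomes(rng, n, tie_times=True)
        f = rng.normal(0, 1, n)
        try:
            want = cindex_bruteforce(f, outs)
        except ZeroDivisionError:
            return
        assert m.concordance_index(f, outs) == pytest.approx(want, abs=1e-12)

    def test_truncated_matches_enumeration(self, rng):
        outs = random_outcomes(rng, 40)
        f = rng.normal(0, 1, 40)
        h = float(np.median([o.time_days for o in outs]))
        assert m.concordance_index(f, outs, h) == pytest.approx(
            cindex_bruteforce(f, outs, h), abs=1e-12)

    @given(st.integers(4, 12), st.integers(0, 3000))
    def test_score_negation_symmetry(self, n, seed):
        rng = np.random.default_rng(seed)
        outs = random_outcomes(rng, n)
        f = rng.normal(0, 1, n) + np.arange(n) * 1e-9  # tie-free
        try:
            a = m.concordance_index(f, outs)
        except ValueError:
            return
        assert a + m.concordance_index(-f, outs) == pytest.approx(1.0)

    def test_no_comparable_pairs_rejected(self):
        outs = [m.SubjectOutcome("a", 1, 0), m.SubjectOutcome("b", 2, 0)]
        with pytest.raises(ValueError, match="comparable"):
            m.concordance_index([1.0, 2.0], outs)


class TestKaplanMeier:
    def test_uncensored_equals_empirical_survival(self):
        outs = [m.SubjectOutcome(str(i), t, 1)
                for i, t in enumerate([1, 2, 3, 4])]
        curve = m.km_estimate(outs)
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_array_equal(curve.n_at_risk, [4, 3, 2, 1])

    def test_all_censored_flat_at_one(self):
        outs = [m.SubjectOutcome(str(i), float(i + 1), 0) for i in range(4)]
        curve = m.km_estimate(outs)
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        outs = [m.SubjectOutcome("a", 1, 1), m.SubjectOutcome("b", 2, 0),
                m.SubjectOutcome("c", 3, 1), m.SubjectOutcome("d", 4, 1)]
        curve = m.km_estimate(outs)
        np.testing.assert_allclose(curve.event_times, [1, 3, 4])
        np.testing.assert_allclose(curve.survival, [3 / 4, 3 / 8, 0.0])

    def test_survival_nonincreasing_and_starts_at_one(self, rng):
        outs = random_outcomes(rng, 50, tie_times=True)
        curve = m.km_estimate(outs)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival_at(0.0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            m.km_estimate([])


class TestLogRank:
    def test_exchangeable_groups(self):
        outs, labels = [], []
        for g in ("a", "b"):
            for i, (t, d) in enumerate([(1, 1), (2, 0), (3, 1), (5, 1)]):
                outs.append(m.SubjectOutcome(f"{g}{i}", t, d))
                labels.append(g)
        res = m.logrank_test(labels, outs)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_single_group_rejected(self):
        outs = [m.SubjectOutcome("a", 1, 1), m.SubjectOutcome("b", 2, 1)]
        with pytest.raises(ValueError, match="two groups"):
            m.logrank_test(["g", "g"], outs)

    def test_matches_reference_implementation(self):
        from lifelines.statistics import multivariate_logrank_test
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 60
            g = rng.integers(0, 3, n)
            t = rng.exponential(1.0 / np.exp(0.55 * g)) + 0.01
            t = np.round(t, 1) + 0.05  # induce ties
            d = (rng.uniform(size=n) < 0.7).astype(int)
            outs = [m.SubjectOutcome(str(i), float(t[i]), int(d[i]))
                    for i in range(n)]
            res = m.logrank_test([str(x) for x in g], outs)
            ref = multivariate_logrank_test(t, g, d)
            assert res.chi_square == pytest.approx(ref.test_statistic, abs=1e-6)
            assert res.p_value == pytest.approx(ref.p_value, abs=1e-6)

    def test_relabeling_invariance(self, rng):
        outs = random_outcomes(rng, 40, tie_times=True)
        g = rng.integers(0, 2, 40)
        a = m.logrank_test(np.where(g == 0, "x", "y"), outs)
        b = m.logrank_test(np.where(g == 0, "y", "x"), outs)
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)


class TestStratification:
    @staticmethod
    def _scores(n, rng=None):
        vals = (np.random.default_rng(0) if rng is None else rng).normal(0, 1, n)
        vals = np.sort(vals) + np.arange(n) * 1e-9
        perm = np.random.default_rng(1).permutation(n)
        return [m.RiskScore(f"s{i}", float(vals[perm[i]])) for i in range(n)]

    def test_388_subjects_split_194_97_97(self):
        strat = m.stratify_by_quantiles(self._scores(388), (0.5, 0.75))
        assert strat.sizes() == {"low": 194, "intermediate": 97, "high": 97}

    def test_388_median_split_194_194(self):
        strat = m.stratify_by_quantiles(self._scores(388), (0.5,))
        assert strat.sizes() == {"below_median": 194, "above_median": 194}

    def test_four_subjects_median(self):
        strat = m.stratify_by_quantiles(self._scores(4), (0.5,))
        assert strat.sizes() == {"below_median": 2, "above_median": 2}

    def test_strata_ordered_by_score(self):
        scores = self._scores(40)
        strat = m.stratify_by_quantiles(scores, (0.5, 0.75))
        by_id = {s.subject_id: s.score for s in scores}
        lo = max(by_id[s] for s in strat.members("low"))
        mid_lo = min(by_id[s] for s in strat.members("intermediate"))
        mid_hi = max(by_id[s] for s in strat.members("intermediate"))
        hi = min(by_id[s] for s in strat.members("high"))
        assert lo < mid_lo and mid_hi < hi

    def test_tied_scores_rejected_strict(self):
        scores = [m.RiskScore(f"s{i}", 1.0) for i in range(8)]
        with pytest.raises(ValueError, match="degenerate"):
            m.stratify_by_quantiles(scores, (0.5,))
        strat = m.stratify_by_quantiles(scores, (0.5,),
                                        tie_policy="stable_order")
        assert strat.sizes() == {"below_median": 4, "above_median": 4}


class TestHorizonLabels:
    def _outs(self):
        return [m.SubjectOutcome("ev_early", 500, 1),
                m.SubjectOutcome("cens_early", 500, 0),
                m.SubjectOutcome("beyond", 1500, 0)]

    def test_event_before_horizon_positive(self):
        labels, mask = m.horizon_labels(self._outs(), 1000)
        assert labels[0] == 1 and mask[0]

    def test_censored_before_horizon_excluded_by_default(self):
        labels, mask = m.horizon_labels(self._outs(), 1000)
        assert not mask[1]
        assert mask[2] and labels[2] == 0

    def test_censored_as_negative_policy(self):
        labels, mask = m.horizon_labels(self._outs(), 1000,
                                        policy="censored_as_negative")
        assert mask.all() and labels[1] == 0


class TestROC:
    def test_perfect_separation(self):
        auc = m.roc_curve([3, 2, 1, 0], [1, 1, 0, 0]).auc
        assert auc == 1.0

    def test_all_tied_scores(self):
        assert m.roc_curve(np.zeros(6), [1, 0, 1, 0, 1, 0]).auc == 0.5

    @given(st.integers(0, 2000))
    def test_matches_mann_whitney_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        f = rng.choice([0.0, 0.5, 1.0, 2.0], size=n)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            return
        pos, neg = f[y == 1], f[y == 0]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        want = u / (len(pos) * len(neg))
        curve = m.roc_curve(f, y)
        assert curve.auc == pytest.approx(want, abs=1e-12)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            m.roc_curve([1.0, 2.0], [1, 1])


class TestStratifiedROC:
    @staticmethod
    def _strata(groups):
        assignments = {}
        scores = []
        for g, (name, count) in enumerate(groups.items()):
            for i in range(count):
                sid = f"{name}{i}"
                assignments[sid] = name
                scores.append(m.RiskScore(sid, g))
        return m.StratumAssignment(assignments, tuple(groups), (0.5, 0.75))

    def test_all_events_in_high_stratum_vertex(self):
        strat = self._strata({"low": 4, "intermediate": 2, "high": 2})
        labels = {s: int(g == "high")
                  for s, g in strat.assignments.items()}
        curve = m.stratified_roc(strat, labels)
        # first interior vertex: high-only threshold catches every event
        assert curve.tpr[1] == 1.0
        assert curve.fpr[1] == 0.0
        assert curve.fpr.shape == (4,)

    def test_proportional_events_uninformative(self):
        strat = self._strata({"low": 8, "intermediate": 4, "high": 4})
        labels = {}
        for g in ("low", "intermediate", "high"):
            members = strat.members(g)
            for i, s in enumerate(members):
                labels[s] = int(i < len(members) // 2)
        curve = m.stratified_roc(strat, labels)
        assert curve.auc == pytest.approx(0.5, abs=1e-12)

    @given(st.integers(0, 1000))
    def test_equals_ordinal_score_roc(self, seed):
        rng = np.random.default_rng(seed)
        strat = self._strata({"low": 6, "intermediate": 3, "high": 3})
        ids = sorted(strat.assignments)
        labels = {s: int(rng.uniform() < 0.4) for s in ids}
        if len(set(labels.values())) < 2:
            return
        curve = m.stratified_roc(strat, labels)
        ordinal = {"low": 0, "intermediate": 1, "high": 2}
        ref = m.roc_curve([ordinal[strat.assignments[s]] for s in ids],
                          [labels[s] for s in ids])
        assert curve.auc == pytest.approx(ref.auc, abs=1e-12)

    def test_two_level_rejected(self):
        strat = m.StratumAssignment({"a": "below_median", "b": "above_median"},
                                    ("below_median", "above_median"), (0.5,))
        with pytest.raises(ValueError, match="three"):
            m.stratified_roc(strat, {"a": 1, "b": 0})


class TestEventRateSummary:
    @pytest.mark.parametrize("count,size,expected", [
        (72, 1540, 4.68), (19, 388, 4.90), (23, 1540, 1.49), (8, 388, 2.06),
        (33, 1540, 2.14), (5, 388, 1.29), (119, 1540, 7.73), (32, 388, 8.25),
        (128, 1540, 8.31), (35, 388, 9.02), (228, 1540, 14.81),
        (58, 388, 14.95), (0, 388, 0.00),
    ])
    def test_percentages(self, count, size, expected):
        df = m.event_rate_summary([("endpoint", count, size)])
        assert df["percent"].iloc[0] == expected

    def test_count_exceeding_size_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            m.event_rate_summary([("x", 10, 5)])

    def test_half_away_from_zero_rounding(self):
        # 0.125% must round up to 0.13, not banker's-round to 0.12
        df = m.event_rate_summary([("x", 1, 800)])
        assert df["percent"].iloc[0] == 0.13
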