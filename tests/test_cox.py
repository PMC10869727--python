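"""Partial-likelihood objective, gradient, and Newton-Raphson fitter."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

import mpisurv as m
from conftest import pll_bruteforce, random_outcomes


class TestPartialLogLikelihood:
    def test_single_event_subject_is_zero(self):
        assert m.partial_log_likelihood([3.7], [m.SubjectOutcome("a", 1, 1)]) == 0.0

    def test_symmetric_two_subject_risk_set(self):
        outs = [m.SubjectOutcome("a", 1, 1), m.SubjectOutcome("b", 2, 0)]
        assert m.partial_log_likelihood([0.0, 0.0], outs) == pytest.approx(
            -np.log(2), abs=1e-12)

    def test_three_subject_enumeration(self):
        outs = [m.SubjectOutcome("a", 1, 1), m.SubjectOutcome("b", 2, 1),
                m.SubjectOutcome("c", 3, 0)]
        f = np.array([1.0, 0.5, -0.5])
        # direct term-by-term summation: events at t=1 (risk set abc) and t=2 (bc)
        expected = (f[0] - np.log(np.exp(f).sum())
                    + f[1] - np.log(np.exp(f[1]) + np.exp(f[2])))
        assert m.partial_log_likelihood(f, outs) == pytest.approx(expected, rel=1e-12)

    def test_no_events_gives_zero(self):
        outs = [m.SubjectOutcome("a", 1, 0), m.SubjectOutcome("b", 2, 0)]
        assert m.partial_log_likelihood([1.0, -1.0], outs) == 0.0

    def test_length_mismatch_and_nonfinite_rejected(self):
        outs = [m.SubjectOutcome("a", 1, 1)]
        with pytest.raises(ValueError, match="length"):
            m.partial_log_likelihood([1.0, 2.0], outs)
        with pytest.raises(ValueError, match="non-finite"):
            m.partial_log_likelihood([np.nan], outs)

    @given(st.integers(1, 18), st.integers(0, 5000), st.booleans())
    def test_matches_bruteforce_enumeration(self, n, seed, ties):
        rng = np.random.default_rng(seed)
        outs = random_outcomes(rng, n, tie_times=ties)
        f = rng.normal(0, 2, n)
        got = m.partial_log_likelihood(f, outs)
        want = pll_bruteforce(f, outs)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    @given(st.integers(2, 15), st.integers(0, 5000),
           st.floats(-50, 50))
    def test_translation_invariance(self, n, seed, shift):
        rng = np.random.default_rng(seed)
        outs = random_outcomes(rng, n)
        f = rng.normal(0, 1, n)
        a = m.partial_log_likelihood(f, outs)
        b = m.partial_log_likelihood(f + shift, outs)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-8)

    @given(st.integers(2, 15), st.integers(0, 5000))
    def test_nonpositive_with_populated_risk_sets(self, n, seed):
        rng = np.random.default_rng(seed)
        outs = random_outcomes(rng, n)
        f = rng.normal(0, 1, n)
        assert m.partial_log_likelihood(f, outs) <= 1e-12


class TestGradient:
    def test_symmetric_case(self):
        outs = [m.SubjectOutcome("a", 1, 1), m.SubjectOutcome("b", 2, 0)]
        np.testing.assert_allclose(
            m.partial_likelihood_gradient([0.0, 0.0], outs), [0.5, -0.5])

    def test_all_censored_zero_vector(self):
        outs = [m.SubjectOutcome(str(i), i + 1.0, 0) for i in range(5)]
        np.testing.assert_array_equal(
            m.partial_likelihood_gradient(np.ones(5), outs), np.zeros(5))

    @given(st.integers(2, 12), st.integers(0, 5000), st.booleans())
    def test_matches_finite_differences(self, n, seed, ties):
        rng = np.random.default_rng(seed)
        outs = random_outcomes(rng, n, tie_times=ties)
        f = rng.normal(0, 1, n)
        grad = m.partial_likelihood_gradient(f, outs)
        eps = 1e-6
        for k in range(n):
            fp, fm = f.copy(), f.copy()
            fp[k] += eps
            fm[k] -= eps
            fd = (m.partial_log_likelihood(fp, outs)
                  - m.partial_log_likelihood(fm, outs)) / (2 * eps)
            assert grad[k] == pytest.approx(fd, rel=1e-6, abs=1e-6)


class TestFitCox:
    def test_exchangeable_groups_give_zero_beta(self):
        # identical outcome sets in both covariate groups
        outs, z = [], []
        for g in (0, 1):
            for i, (t, d) in enumerate([(1, 1), (2, 0), (3, 1), (4, 0)]):
                outs.append(m.SubjectOutcome(f"g{g}i{i}", t, d))
                z.append(g)
        fit = m.fit_cox(np.array(z, float)[:, None], outs)
        assert abs(fit.coefficients[0]) < 1e-6
        assert fit.converged

    def test_matches_golden_section_1d_maximizer(self):
        # interleaved groups keep the 1-D maximizer finite
        outs = [m.SubjectOutcome(str(i), i + 1.0, 1) for i in range(6)]
        z = np.array([1, 0, 1, 0, 1, 0], float)

        def neg_pll(b):
            return -m.partial_log_likelihood(b * (z - z.mean()), outs)

        res = minimize_scalar(neg_pll, bracket=(-3, 0, 3),
                              method="golden", options={"xtol": 1e-10})
        fit = m.fit_cox(z[:, None], outs)
        assert fit.coefficients[0] == pytest.approx(res.x, abs=1e-4)

    def test_ci_brackets_hazard_ratio(self, rng):
        x = rng.normal(0, 1, 80)
        t = rng.exponential(1.0 / np.exp(0.8 * x)) + 0.01
        outs = [m.SubjectOutcome(str(i), float(t[i]), 1) for i in range(80)]
        fit = m.fit_cox(x[:, None], outs)
        assert fit.converged
        assert 0 < fit.ci95_low[0] < fit.hazard_ratios[0] < fit.ci95_high[0]
        assert fit.n_events == 80

    def test_no_events_rejected(self):
        outs = [m.SubjectOutcome("a", 1, 0), m.SubjectOutcome("b", 2, 0)]
        with pytest.raises(ValueError, match="no events"):
            m.fit_cox(np.array([[0.0], [1.0]]), outs)

    def test_separation_flagged_not_silent(self):
        # covariate perfectly orders all event times: beta diverges
        outs = [m.SubjectOutcome(str(i), i + 1.0, 1) for i in range(8)]
        x = -np.arange(8.0)[:, None]
        fit = m.fit_cox(x, outs, max_iter=200)
        assert not fit.converged

    def test_agreement_with_reference_implementation(self, rng):
        from lifelines import CoxPHFitter
        import pandas as pd
        for seed in range(3):
            r = np.random.default_rng(seed)
            n = 50
            x = r.normal(0, 1, n)
            t = r.exponential(1.0 / np.exp(0.6 * x))
            c = r.exponential(2.0, n)
            tt = np.minimum(t, c) + 0.01
            dd = (t <= c).astype(int)
            outs = [m.SubjectOutcome(str(i), float(tt[i]), int(dd[i]))
                    for i in range(n)]
            fit = m.fit_cox(x[:, None], outs)
            df = pd.DataFrame({"t": tt, "e": dd, "x": x})
            ref = CoxPHFitter().fit(df, "t", "e").params_["x"]
            assert fit.coefficients[0] == pytest.approx(ref, abs=1e-4)


class TestRiskSetIndex:
    def test_every_event_contains_itself_and_is_antitone(self, rng):
        outs = random_outcomes(rng, 15)
        t = np.array([o.time_days for o in outs])
        rs = m.cox.risk_set_index(outs) if hasattr(m, "cox") else None
        from mpisurv.cox import risk_set_index
        rs = risk_set_index(outs)
        items = sorted(rs.items(), key=lambda kv: t[kv[0]])
        for i, r in rs.items():
            assert i in r
        for (i1, r1), (i2, r2) in zip(items, items[1:]):
            if t[i1] < t[i2]:
                assert set(r2) <= set(r1)


class TestSubgroupForest:
    @staticmethod
    def _cohort(rng, n=60, beta=1.0):
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / np.exp(beta * x)) + 0.01
        d = (rng.uniform(size=n) < 0.7).astype(int)
        outs = [m.SubjectOutcome(f"s{i}", float(t[i]), int(d[i]))
                for i in range(n)]
        scores = [m.RiskScore(f"s{i}", float(x[i])) for i in range(n)]
        return scores, outs

    def test_whole_cohort_subgroup_matches_direct_fit(self, rng):
        scores, outs = self._cohort(rng)
        labels = {o.subject_id: "all" for o in outs}
        rows = m.subgroup_forest(scores, outs, labels)
        raw = np.array([s.score for s in scores])
        z = (raw - raw.mean()) / raw.std()
        direct = m.fit_cox(z[:, None], outs)
        assert rows[0].estimable
        assert rows[0].fit.hazard_ratios[0] == pytest.approx(
            direct.hazard_ratios[0], rel=1e-9)

    def test_zero_event_subgroup_not_estimable(self, rng):
        scores, outs = self._cohort(rng, n=20)
        outs = [m.SubjectOutcome(o.subject_id, o.time_days,
                                 0 if i < 10 else o.event)
                for i, o in enumerate(outs)]
        labels = {o.subject_id: ("dead" if i < 10 else "alive")
                  for i, o in enumerate(outs)}
        rows = m.subgroup_forest(scores, outs, labels)
        dead = next(r for r in rows if r.subgroup == "dead")
        assert not dead.estimable and dead.fit is None

    def test_injected_effect_sizes_ordered(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            scores, outs, labels = [], [], {}
            for g, beta in (("mild", 0.5), ("severe", 1.5)):
                x = rng.normal(0, 1, 400)
                t = rng.exponential(1.0 / np.exp(beta * x)) + 0.001
                cens = np.quantile(t, 0.7)
                for i in range(400):
                    sid = f"{g}{i}"
                    tt, dd = (t[i], 1) if t[i] < cens else (cens, 0)
                    outs.append(m.SubjectOutcome(sid, float(tt), dd))
                    scores.append(m.RiskScore(sid, float(x[i])))
                    labels[sid] = g
            rows = {r.subgroup: r for r in
                    m.subgroup_forest(scores, outs, labels)}
            if (rows["severe"].fit.hazard_ratios[0]
                    > rows["mild"].fit.hazard_ratios[0]):
                hits += 1
        assert hits >= int(0.95 * n_rep)

    def test_unknown_coding_rejected(self, rng):
        scores, outs = self._cohort(rng, n=10)
        with pytest.raises(ValueError, match="coding"):
            m.subgroup_forest(scores, outs, {}, score_coding="median_split")

    def test_forest_tsv_schema(self, rng, tmp_path):
        scores, outs = self._cohort(rng)
        labels = {o.subject_id: ("a" if i % 2 else "b")
                  for i, o in enumerate(outs)}
        rows = m.subgroup_forest(scores, outs, labels,
                                 score_coding="binary_top_quartile")
        from mpisurv.cox import write_forest_tsv
        write_forest_tsv(rows, tmp_path / "forest.tsv")
        lines = (tmp_path / "forest.tsv").read_text().splitlines()
        assert lines[0] == "subgroup\tn\tn_events\thr\tci_low\tci_high\tp\testimable"
        assert len(lines) == 3
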