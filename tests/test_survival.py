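"""Survival stage: univariate Cox screen (vs lifelines and a brute-force
likelihood grid), risk score, median split, Kaplan-Meier, log-rank."""

import numpy as np
import pytest

import biodrift as bd
from biodrift.survival import (CoxResult, evaluate_panel_survival,
                               fit_cox_per_gene, fit_univariate_cox,
                               km_estimate, logrank_test, risk_score,
                               risk_scores, select_prognostic_genes,
                               split_by_median)


class TestUnivariateCox:
    def test_matches_lifelines_on_synthetic_data(self):
        """Independent oracle: lifelines' CoxPHFitter on the same data."""
        import pandas as pd
        from lifelines import CoxPHFitter
        t = bd.generate_survival_data(600, [0.5], censor_rate=0.2, seed=1)
        mine = fit_univariate_cox(t.expression[:, 0], t.time, t.event)
        df = pd.DataFrame({"x": t.expression[:, 0], "t": t.time,
                           "e": t.event})
        ll = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert mine.beta == pytest.approx(ll.params_["x"], abs=1e-4)
        assert mine.se == pytest.approx(ll.standard_errors_["x"], abs=1e-4)

    def test_sign_invariance(self):
        t = bd.generate_survival_data(300, [0.4], censor_rate=0.1, seed=2)
        pos = fit_univariate_cox(t.expression[:, 0], t.time, t.event)
        neg = fit_univariate_cox(-t.expression[:, 0], t.time, t.event)
        assert neg.beta == pytest.approx(-pos.beta, abs=1e-10)
        assert neg.p_value == pytest.approx(pos.p_value, abs=1e-10)

    def test_null_covariate_small_beta(self):
        rng = np.random.default_rng(3)
        t = bd.generate_survival_data(500, [0.8], censor_rate=0.2, seed=3)
        x = rng.permutation(t.expression[:, 0])  # break the association
        res = fit_univariate_cox(x, t.time, t.event)
        assert abs(res.beta) < 0.2

    def test_two_subject_monotone_likelihood_matches_grid_maximizer(self):
        """Event at t=1 with x=1 and t=2 with x=0: the partial likelihood
        b - log(1 + e^b) is monotone, so the fit caps beta; a brute-force
        grid over the allowed range lands on the same cap."""
        time = np.array([1.0, 2.0])
        event = np.array([1, 1])
        x = np.array([1.0, 0.0])
        with pytest.warns(UserWarning, match="monotone"):
            res = fit_univariate_cox(x, time, event)
        grid = np.linspace(-10, 10, 200001)
        loglik = grid - np.log1p(np.exp(grid))
        assert res.capped
        assert res.beta == pytest.approx(grid[np.argmax(loglik)], abs=1e-4)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_univariate_cox(np.ones(10), np.arange(1.0, 11), np.ones(10))
        with pytest.raises(ValueError, match="events"):
            fit_univariate_cox(np.arange(10.0), np.arange(1.0, 11),
                               np.zeros(10))


class TestPrognosticFilter:
    def make(self, beta, p):
        return CoxResult("g", beta, 0.1, p)

    def test_passing_gene_selected(self):
        assert len(select_prognostic_genes([self.make(0.25, 0.005)])) == 1

    def test_weak_p_rejected(self):
        assert len(select_prognostic_genes([self.make(0.25, 0.02)])) == 0

    def test_negative_beta_uses_absolute_value(self):
        assert len(select_prognostic_genes([self.make(-0.3, 0.001)])) == 1

    def test_order_preserved(self):
        res = [CoxResult(g, 0.5, 0.1, 1e-4) for g in ["z", "a", "m"]]
        assert list(select_prognostic_genes(res)) == ["z", "a", "m"]


class TestRiskScore:
    def test_zero_betas_zero_score(self):
        betas = [CoxResult("g1", 0.0, 1, 1), CoxResult("g2", 0.0, 1, 1)]
        assert risk_score({"g1": 3.0, "g2": -1.0}, betas) == 0.0

    def test_arithmetic(self):
        betas = [CoxResult("g1", 0.3, 1, 1), CoxResult("g2", -0.2, 1, 1)]
        assert risk_score({"g1": 1.0, "g2": 2.0}, betas) == pytest.approx(-0.1)

    def test_linearity(self):
        betas = [CoxResult("g1", 0.3, 1, 1), CoxResult("g2", 0.7, 1, 1)]
        row = {"g1": 1.3, "g2": -0.4}
        doubled = {k: 2 * v for k, v in row.items()}
        assert risk_score(doubled, betas) == pytest.approx(
            2 * risk_score(row, betas))

    def test_missing_gene_named_in_error(self):
        with pytest.raises(KeyError, match="g2"):
            risk_score({"g1": 1.0}, [CoxResult("g2", 0.5, 1, 1)])


class TestMedianSplit:
    def test_even_count(self):
        groups = split_by_median(np.array([1.0, 2, 3, 4]))
        assert groups.tolist() == ["low", "low", "high", "high"]

    def test_all_equal_scores_all_low(self):
        assert split_by_median(np.full(5, 2.0)).tolist() == ["low"] * 5

    def test_odd_count_median_goes_low(self):
        assert split_by_median(np.array([1.0, 2, 3])).tolist() == \
            ["low", "low", "high"]


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = km_estimate(np.array([1.0, 2, 3]), np.array([0, 0, 0]))
        assert km(0.5) == 1.0
        assert km(10.0) == 1.0

    def test_single_event_among_four(self):
        km = km_estimate(np.array([1.0, 2, 3, 4]), np.array([1, 0, 0, 0]))
        assert km(1.0) == pytest.approx(0.75)

    def test_hand_worked_product_limit(self):
        """times 1..6, events at 1 and 3, censorings at 2 and 4:
        S(1) = 5/6, S(3) = 5/6 * 3/4 = 0.625."""
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.array([1, 0, 1, 0, 0, 0])
        km = km_estimate(time, event)
        assert km(1.0) == pytest.approx(5 / 6)
        assert km(2.5) == pytest.approx(5 / 6)  # censoring adds no step
        assert km(3.0) == pytest.approx(0.625)
        assert km(6.0) == pytest.approx(0.625)

    def test_monotone_and_starts_at_one(self):
        t = bd.generate_survival_data(200, [0.5], 0.3, seed=4)
        km = km_estimate(t.time, t.event)
        assert km(0.0) == 1.0
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(np.array([]), np.array([]))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 1, 0, 1])
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        ta, tb = rng.exponential(1, 50), rng.exponential(2, 50)
        ea, eb = np.ones(50), np.ones(50)
        s1, _ = logrank_test(ta, ea, tb, eb)
        s2, _ = logrank_test(ta ** 2, ea, tb ** 2, eb)  # monotone transform
        assert s1 == pytest.approx(s2, rel=1e-10)

    def test_power_against_separated_hazards(self):
        """Hazard ratio 3, n = 200 per group: p < 0.001 in >= 95/100 reps."""
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            ta = rng.exponential(1.0, 200)
            tb = rng.exponential(3.0, 200)
            _, p = logrank_test(ta, np.ones(200), tb, np.ones(200))
            hits += p < 0.001
        assert hits >= 95

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(np.array([]), np.array([]), np.array([1.0]),
                         np.array([1]))


class TestPipeline:
    def test_real_effects_separate_risk_groups(self):
        """End-to-end: genes with real +-0.5 log-hazard effects produce a
        risk score whose high-risk arm has worse survival (log-rank
        p < 0.05 and lower KM curve) in >= 90% of seeded reps."""
        hits = 0
        reps = 20
        for seed in range(reps):
            t = bd.generate_survival_data(400, [0.5, -0.5, 0.5],
                                          censor_rate=0.2, seed=seed)
            rep = evaluate_panel_survival(t)
            if rep.logrank_p is None:
                continue
            # endpoint: the high-risk arm's final event time (beyond it the
            # sparser tail of either curve is dominated by censoring noise)
            last = rep.km_high.times.max()
            ok = (rep.logrank_p < 0.05
                  and rep.km_high(last) < rep.km_low(last))
            hits += ok
        assert hits >= 0.9 * reps

    def test_gene_screen_shapes(self):
        t = bd.generate_survival_data(300, [0.6, 0.0], 0.2, seed=9)
        res = fit_cox_per_gene(t)
        assert [r.gene for r in res] == t.gene_names
        scores = risk_scores(t, [res[0]])
        assert scores.shape == (300,)
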