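"""Survival estimators against hand calculations, brute-force oracles, and
independent library implementations (lifelines)."""

import itertools

import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index

from eln_aml_strat.survival import (
    ConvergenceError,
    SurvData,
    censor_at_event,
    compare_c,
    cox_fit,
    harrell_c,
    km_fit,
    logrank_test,
    mantel_byar_test,
    nri_censored,
    reverse_km_median_followup,
    survival_at,
)

RNG = np.random.default_rng


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_hand_product_limit(self):
        # events at 2 and 4 among 4 subjects: S = 3/3 * 2/3 = 2/3 after t=2,
        # then * (1 - 1/1) = 0 after t=4
        c = km_fit(SurvData([1, 2, 3, 4], [False, True, False, True]))
        np.testing.assert_allclose(c.times, [2, 4])
        np.testing.assert_allclose(c.survival, [2 / 3, 0.0])

    def test_all_censored_is_unity(self):
        c = km_fit(SurvData([3, 5, 9], [False] * 3))
        assert c.times.size == 0
        assert survival_at(c, 8.0)["estimate"] == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = RNG(1)
        t = rng.exponential(10, 200)
        c = km_fit(SurvData(t, np.ones(200, bool)))
        for q in (2.0, 5.0, 15.0):
            assert survival_at(c, q)["estimate"] == pytest.approx(np.mean(t > q))

    def test_exponential_closed_form(self):
        lam = 0.08
        rng = RNG(7)
        t = rng.exponential(1 / lam, 2000)
        c = km_fit(SurvData(t, np.ones(2000, bool)))
        grid = np.linspace(0.1, 40, 100)
        est = np.array([survival_at(c, g)["estimate"] for g in grid])
        assert np.max(np.abs(est - np.exp(-lam * grid))) < 0.04  # ~KS bound at n=2000

    def test_matches_lifelines_with_censoring(self):
        rng = RNG(3)
        t = rng.exponential(12, 300)
        cens = rng.uniform(0, 30, 300)
        time, ev = np.minimum(t, cens), t <= cens
        ours = km_fit(SurvData(time, ev))
        kmf = KaplanMeierFitter().fit(time, ev)
        theirs = kmf.survival_function_at_times(ours.times).values
        np.testing.assert_allclose(ours.survival, theirs, rtol=1e-10)

    def test_loglog_ci_within_unit_interval(self):
        rng = RNG(4)
        t = rng.exponential(5, 50)
        cens = rng.uniform(0, 10, 50)
        c = km_fit(SurvData(np.minimum(t, cens), t <= cens))
        assert np.all(c.ci_lower >= 0) and np.all(c.ci_upper <= 1)
        assert np.all(c.ci_lower <= c.survival) and np.all(c.survival <= c.ci_upper)


class TestSurvivalAt:
    def test_step_evaluation(self):
        c = km_fit(SurvData([1, 2, 3, 4], [False, True, False, True]))
        assert survival_at(c, 3.0)["estimate"] == pytest.approx(2 / 3)

    def test_time_zero(self):
        c = km_fit(SurvData([1, 2], [True, True]))
        assert survival_at(c, 0.0)["estimate"] == 1.0

    def test_beyond_follow_up_flagged(self):
        c = km_fit(SurvData([1.0], [True]))
        r = survival_at(c, 2.0)
        assert r["estimate"] == 0.0 and r["truncated"]


class TestReverseKm:
    def test_all_censored(self):
        r = reverse_km_median_followup(SurvData([84.4] * 6, [False] * 6))
        assert r["median_months"] == 84.4 and r["reached"]

    def test_all_events_undefined(self):
        r = reverse_km_median_followup(SurvData([5, 9, 11], [True] * 3))
        assert r["median_months"] is None and not r["reached"]

    def test_recovers_censoring_median(self):
        rng = RNG(9)
        death = rng.exponential(100, 4000)
        cens = rng.uniform(20, 140, 4000)  # median 80
        r = reverse_km_median_followup(SurvData(np.minimum(death, cens), death <= cens))
        assert r["median_months"] == pytest.approx(80, abs=4)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def brute_force_logrank(time, event, group):
    """Independent two-group O-E/V computation over explicit risk tables."""
    O = E = V = 0.0
    for t in sorted(set(time[event])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = (at_risk & event & (time == t)).sum()
        d1 = (at_risk & event & (time == t) & (group == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        e = np.array([1, 0, 1, 1] * 2, bool)
        g = np.array(["a"] * 4 + ["b"] * 4)
        r = logrank_test(SurvData(t, e, group=g))
        assert r.statistic == pytest.approx(0.0, abs=1e-12) and r.p == pytest.approx(1.0)

    def test_toy_vs_brute_force(self):
        t = np.array([3, 5, 7, 2, 4, 6], float)
        e = np.array([1, 1, 0, 1, 0, 1], bool)
        g = np.array([0, 0, 0, 1, 1, 1])
        expected = brute_force_logrank(t, e, g)
        r = logrank_test(SurvData(t, e, group=g.astype(str)))
        assert r.statistic == pytest.approx(expected, rel=1e-12)

    def test_three_groups_vs_lifelines(self):
        rng = RNG(12)
        n = 90
        g = np.repeat([0, 1, 2], n // 3)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.4 * g)))
        cens = rng.uniform(5, 50, n)
        time, ev = np.minimum(t, cens), t <= cens
        ours = logrank_test(SurvData(time, ev, group=g))
        theirs = multivariate_logrank_test(time, g, ev)
        assert ours.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert ours.df == 2

    def test_pairwise_returns_all_pairs(self):
        rng = RNG(2)
        g = np.repeat(["a", "b", "c"], 20)
        t = rng.exponential(10, 60)
        res = logrank_test(SurvData(t, np.ones(60, bool), group=g), pairwise=True)
        assert sorted(r.groups for r in res) == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(SurvData([1, 2], [True, True], group=np.array(["a", "a"])))


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def breslow_loglik(beta, x, time, event):
    """Independent Breslow partial log-likelihood for one covariate."""
    ll = 0.0
    for t in sorted(set(time[event])):
        at_risk = time >= t
        dying = at_risk & event & (time == t)
        ll += beta * x[dying].sum() - dying.sum() * np.log(np.exp(beta * x[at_risk]).sum())
    return ll


class TestCox:
    def test_toy_grid_search_oracle(self):
        t = np.array([1, 2, 3, 4, 5], float)
        e = np.array([1, 1, 0, 1, 1], bool)
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        fit = cox_fit(SurvData(t, e, covariates={"x": x}), ties="breslow")
        grid = np.linspace(-4, 4, 8001)
        lls = [breslow_loglik(b, x, t, e) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert fit.coef[0] == pytest.approx(best, abs=2e-3)
        assert fit.loglik == pytest.approx(np.max(lls), abs=1e-6)

    def test_matches_lifelines_efron_with_ties(self):
        rng = RNG(21)
        n = 250
        x1 = rng.binomial(1, 0.4, n).astype(float)
        x2 = rng.normal(0, 1, n)
        t = np.ceil(rng.exponential(1 / (0.1 * np.exp(0.7 * x1 - 0.3 * x2))))  # heavy ties
        cens = np.ceil(rng.uniform(1, 25, n))
        time, ev = np.minimum(t, cens), t <= cens
        fit = cox_fit(SurvData(time, ev, covariates={"x1": x1, "x2": x2}))
        import pandas as pd

        df = pd.DataFrame({"T": time, "E": ev, "x1": x1, "x2": x2})
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-6)

    def test_score_test_equals_logrank_with_breslow(self):
        rng = RNG(5)
        n = 120
        g = rng.binomial(1, 0.5, n)
        t = rng.exponential(1 / (0.05 * np.exp(0.5 * g)))
        cens = rng.uniform(5, 40, n)
        time, ev = np.minimum(t, cens), t <= cens
        fit = cox_fit(SurvData(time, ev, covariates={"g": g.astype(float)}), ties="breslow")
        lr = logrank_test(SurvData(time, ev, group=g))
        assert fit.score_stat == pytest.approx(lr.statistic, rel=1e-9)

    def test_recovers_true_hazard_ratio(self):
        rng = RNG(31)
        n = 1500
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.05 * np.exp(np.log(2.0) * x)))
        cens = rng.uniform(10, 60, n)
        fit = cox_fit(SurvData(np.minimum(t, cens), t <= cens, covariates={"x": x}))
        assert fit.ci_lower[0] < 2.0 < fit.ci_upper[0]
        assert fit.hr[0] == pytest.approx(2.0, rel=0.15)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(SurvData([1, 2, 3], [1, 1, 1], covariates={"x": [0.0, 0.0, 0.0]}))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit(SurvData([1, 2], [False, False], covariates={"x": [0.0, 1.0]}))

    def test_perfect_separation_detected(self):
        # covariate perfectly orders the event times: monotone likelihood
        t = np.arange(1.0, 9.0)
        x = -t
        with pytest.raises(ConvergenceError):
            cox_fit(SurvData(t, np.ones(8, bool), covariates={"x": x}))


# ---------------------------------------------------------------------------
# Censor-at-event and Mantel-Byar
# ---------------------------------------------------------------------------

class TestCensorAtEvent:
    def test_basic(self):
        d = SurvData([60.0], [True])
        out = censor_at_event(d, np.array([12.0]))
        assert out.time[0] == 12.0 and not out.event[0]

    def test_identity_without_intervention(self):
        d = SurvData([5.0, 7.0], [True, False])
        out = censor_at_event(d, np.array([np.nan, np.nan]))
        np.testing.assert_array_equal(out.time, d.time)
        np.testing.assert_array_equal(out.event, d.event)

    def test_tie_resolves_to_censored(self):
        out = censor_at_event(SurvData([10.0], [True]), np.array([10.0]))
        assert out.time[0] == 10.0 and not out.event[0]

    def test_never_increases_time_or_creates_events(self):
        rng = RNG(8)
        t = rng.exponential(10, 100)
        e = rng.random(100) < 0.6
        it = np.where(rng.random(100) < 0.5, t * rng.random(100), np.nan)
        out = censor_at_event(SurvData(t, e), it)
        assert np.all(out.time <= t)
        assert not np.any(out.event & ~e)

    def test_intervention_after_event_rejected(self):
        with pytest.raises(ValueError):
            censor_at_event(SurvData([5.0], [True]), np.array([6.0]))


def _td_null_data(rng, n=300, effect=1.0):
    """Survival with a time-dependent state entered at an independent
    exponential time; hazard multiplied by ``effect`` after entry."""
    lam = 0.08
    entry = rng.exponential(8, n)
    e1 = rng.exponential(size=n)
    t_pre = e1 / lam
    death = np.where(
        t_pre <= entry, t_pre, entry + (e1 - lam * entry) / (lam * effect)
    )
    cens = rng.uniform(10, 60, n)
    time = np.minimum(death, cens)
    ev = death <= cens
    entry = np.where(entry <= time, entry, np.nan)
    return SurvData(time, ev), entry


class TestMantelByar:
    def test_no_entries_flagged(self):
        d = SurvData([1, 2, 3], [True, True, False])
        r = mantel_byar_test(d, np.array([np.nan] * 3))
        assert not r.defined and r.cox is None

    def test_entry_after_event_rejected(self):
        with pytest.raises(ValueError):
            mantel_byar_test(SurvData([5.0], [True]), np.array([6.0]))

    def test_recovers_protective_effect(self):
        data, entry = _td_null_data(RNG(42), n=4000, effect=0.5)
        r = mantel_byar_test(data, entry)
        assert r.defined and r.p < 0.01
        assert r.cox.hr[0] == pytest.approx(0.5, rel=0.2)

    def test_null_not_rejected_on_average(self):
        rng = RNG(77)
        rejections = sum(
            mantel_byar_test(*_td_null_data(rng, n=120)).p < 0.05 for _ in range(60)
        )
        assert rejections <= 9  # binomial(60, 0.05): P(X > 9) < 0.001


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def exhaustive_c(score, time, event):
    conc = comp = 0.0
    n = len(time)
    for i, j in itertools.permutations(range(n), 2):
        if (time[i] < time[j] and event[i]) or (
            time[i] == time[j] and event[i] and not event[j]
        ):
            comp += 1
            if score[i] > score[j]:
                conc += 1
            elif score[i] == score[j]:
                conc += 0.5
    return conc / comp


class TestHarrellC:
    def test_perfect_concordance(self):
        d = SurvData([1, 2, 3], [True] * 3)
        assert harrell_c(np.array([3.0, 2.0, 1.0]), d) == 1.0

    def test_all_tied_scores(self):
        d = SurvData([1, 2, 3], [True] * 3)
        assert harrell_c(np.array([1.0, 1.0, 1.0]), d) == 0.5

    def test_matches_exhaustive_oracle(self):
        rng = RNG(15)
        n = 50
        t = np.round(rng.exponential(10, n), 1)  # some ties
        e = rng.random(n) < 0.7
        s = np.round(rng.normal(0, 1, n), 1)
        ours = harrell_c(s, SurvData(t, e))
        assert ours == exhaustive_c(s, t, e)

    def test_matches_lifelines(self):
        rng = RNG(16)
        n = 80
        t = rng.exponential(10, n)
        e = rng.random(n) < 0.6
        s = rng.normal(0, 1, n)
        assert harrell_c(s, SurvData(t, e)) == pytest.approx(
            concordance_index(t, -s, e), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = RNG(17)
        t = rng.exponential(10, 60)
        e = rng.random(60) < 0.6
        s = rng.normal(0, 1, 60)
        d = SurvData(t, e)
        assert harrell_c(s, d) == harrell_c(np.exp(s), d) == harrell_c(3 * s - 7, d)

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError):
            harrell_c(np.array([1.0, 2.0]), SurvData([5, 5], [False, False]))


class TestCompareC:
    def test_identical_scores(self):
        rng = RNG(18)
        t = rng.exponential(10, 40)
        e = rng.random(40) < 0.7
        s = rng.normal(0, 1, 40)
        r = compare_c(s, s.copy(), SurvData(t, e))
        assert r.delta == 0.0 and r.p == 1.0

    def test_informative_score_wins(self):
        rng = RNG(19)
        n = 600
        risk = rng.normal(0, 1, n)
        t = rng.exponential(1 / (0.05 * np.exp(0.8 * risk)))
        cens = rng.uniform(5, 50, n)
        d = SurvData(np.minimum(t, cens), t <= cens)
        noise = rng.normal(0, 1, n)
        r = compare_c(noise, risk, d)
        assert r.delta > 0 and r.p < 0.05

    def test_jackknife_se_close_to_bootstrap(self):
        rng = RNG(20)
        n = 30
        risk = rng.normal(0, 1, n)
        t = rng.exponential(1 / (0.08 * np.exp(0.6 * risk)))
        cens = rng.uniform(3, 40, n)
        time, ev = np.minimum(t, cens), t <= cens
        d = SurvData(time, ev)
        other = risk + rng.normal(0, 1.2, n)
        r = compare_c(other, risk, d)

        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            db = SurvData(time[idx], ev[idx])
            try:
                boots.append(harrell_c(risk[idx], db) - harrell_c(other[idx], db))
            except ValueError:
                continue
        se_boot = np.std(boots, ddof=1)
        assert r.se == pytest.approx(se_boot, rel=0.25)


# ---------------------------------------------------------------------------
# NRI
# ---------------------------------------------------------------------------

CATS = ("favorable", "intermediate", "adverse")


class TestNri:
    def test_identical_groupings_zero(self):
        rng = RNG(22)
        g = rng.choice(CATS, 30)
        t = rng.exponential(10, 30)
        e = rng.random(30) < 0.5
        r = nri_censored(g, g.copy(), SurvData(t, e), horizon=12.0, n_boot=100, seed=0)
        assert r.total == 0.0 and r.event_component == 0.0 and r.nonevent_component == 0.0

    def test_closed_form_pencina_without_censoring(self):
        # 10 subjects, no censoring before the horizon:
        # up-moved: 2 events, 1 non-event; down-moved: 1 event, 1 non-event;
        # 5 events overall -> NRI_e = (2-1)/5; 5 non-events -> NRI_ne = (1-1)/5
        old = np.array(["favorable"] * 5 + ["intermediate"] * 5)
        new = np.array(
            ["intermediate"] * 3 + ["favorable"] * 2
            + ["favorable"] * 2 + ["intermediate"] * 3
        )
        t = np.array([1, 1, 10, 10, 10, 1, 10, 1, 1, 10], float)
        e = t < 5
        r = nri_censored(old, new, SurvData(t, e), horizon=5.0, n_boot=100, seed=1)
        assert r.event_component == pytest.approx(1 / 5)
        assert r.nonevent_component == pytest.approx(0.0)
        assert r.total == pytest.approx(1 / 5)
        assert r.total == pytest.approx(r.event_component + r.nonevent_component)

    def test_restricted_variant_larger_on_simulated_data(self):
        rng = RNG(23)
        n = 400
        old = rng.choice(CATS, n, p=[0.4, 0.4, 0.2])
        rank = np.array([CATS.index(g) for g in old])
        move = rng.random(n)
        new_rank = np.clip(
            rank + np.where(move < 0.15, 1, np.where(move < 0.25, -1, 0)), 0, 2
        )
        new = np.array(CATS)[new_rank]
        t = rng.exponential(1 / (0.02 * np.exp(0.7 * new_rank)))
        cens = rng.uniform(10, 100, n)
        d = SurvData(np.minimum(t, cens), t <= cens)
        r_all = nri_censored(old, new, d, horizon=60.0, n_boot=100, seed=3)
        r_sub = nri_censored(
            old, new, d, horizon=60.0, n_boot=100, seed=3, restrict_to_reclassified=True
        )
        assert abs(r_sub.total) > abs(r_all.total)

    def test_total_within_bounds_and_ci_brackets(self):
        rng = RNG(24)
        n = 150
        old = rng.choice(CATS, n)
        new = rng.choice(CATS, n)
        t = rng.exponential(20, n)
        e = rng.random(n) < 0.6
        r = nri_censored(old, new, SurvData(t, e), horizon=12.0, n_boot=200, seed=5)
        assert -2.0 <= r.total <= 2.0
        assert r.ci_lower <= r.ci_upper

    def test_seeded_bootstrap_reproducible(self):
        rng = RNG(25)
        old = rng.choice(CATS, 60)
        new = rng.choice(CATS, 60)
        t = rng.exponential(20, 60)
        e = rng.random(60) < 0.5
        d = SurvData(t, e)
        r1 = nri_censored(old, new, d, horizon=12.0, n_boot=150, seed=9)
        r2 = nri_censored(old, new, d, horizon=12.0, n_boot=150, seed=9)
        assert (r1.ci_lower, r1.ci_upper) == (r2.ci_lower, r2.ci_upper)
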