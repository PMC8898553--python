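"""Hierarchical probit SDT estimation and its downstream analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fishmot import inference
from fishmot.design import Condition, build_design_exp1
from fishmot.errors import DegenerateDesignError, InsufficientDataError, InvalidInputError
from fishmot.inference import (
    PosteriorSummary,
    apply_exclusion,
    bayesian_r2,
    contrast_conditions,
    fit_prediction_model,
    fit_sdt_probit,
    per_participant_dprime,
    savage_dickey_bf,
    summarize_dprime_bias,
)
from fishmot.observer import PopulationParams, sample_observers, simulate_responses

FAST = dict(n_chains=2, warmup=300, draws=500)


def make_responses(pop, n_participants, videos=10, set_sizes=(1, 3, 5), seed=0):
    trials = build_design_exp1(
        [f"v{i}" for i in range(videos)], set_sizes=list(set_sizes), n_objects=8, seed=seed
    )
    obs = sample_observers(pop, n_participants, seed=seed + 1)
    return simulate_responses(obs, trials, pop, seed=seed + 2)


class TestProbitFit:
    def test_matches_closed_form_dprime_without_heterogeneity(self):
        """With all random-effect SDs at zero and ~1e4 trials at one
        load, the model's d' equals the pooled closed-form estimate
        within 0.1."""
        pop = PopulationParams(
            alpha_d=2.3, beta_d=0.0, alpha_c=1.1, beta_c=0.0,
            sigma_ad=0, sigma_bd=0, sigma_ac=0, sigma_bc=0,
        )
        trials = build_design_exp1(
            [f"v{i}" for i in range(42)], set_sizes=[3], n_objects=8, seed=3
        )  # 84 trials
        obs = sample_observers(pop, 4, seed=4)
        resp = simulate_responses(obs, trials * 30, pop, seed=5)  # 10080 rows
        post = fit_sdt_probit(resp, seed=6, **FAST)
        model_d = float(np.mean(post.dprime_draws(3)))
        says = resp["response"] == "target"
        tq = resp["queried_is_target"]
        closed = stats.norm.ppf(says[tq].mean()) - stats.norm.ppf(says[~tq].mean())
        assert abs(model_d - closed) < 0.1
        model_c = float(np.mean(post.bias_draws(3)))
        assert abs(model_c - (-stats.norm.ppf(says[~tq].mean()))) < 0.1

    def test_degenerate_all_target_responses(self):
        pop = PopulationParams()
        resp = make_responses(pop, 3, videos=4, seed=10)
        resp = resp.assign(response="target", correct=resp["queried_is_target"])
        with pytest.warns(UserWarning):
            post = fit_sdt_probit(resp, seed=1, n_chains=2, warmup=150, draws=200)
        # no likelihood information separates d' from c; the prior keeps
        # everything finite and shrunk
        assert np.isfinite(post.draws("d_intercept")).all()
        assert abs(np.mean(post.draws("d_load"))) < 1.0

    def test_single_participant_fits(self):
        pop = PopulationParams(sigma_ad=0, sigma_bd=0, sigma_ac=0, sigma_bc=0)
        resp = make_responses(pop, 1, videos=8, seed=20)
        post = fit_sdt_probit(resp, seed=2, n_chains=2, warmup=150, draws=200)
        assert len(post.participants) == 1
        assert np.isfinite(post.draws("d_intercept")).all()

    def test_requires_both_query_types(self):
        pop = PopulationParams()
        resp = make_responses(pop, 2, videos=4, seed=30)
        with pytest.raises(InvalidInputError):
            fit_sdt_probit(resp[resp["queried_is_target"]])

    def test_diagnostics_reported(self):
        pop = PopulationParams()
        resp = make_responses(pop, 4, videos=6, seed=40)
        post = fit_sdt_probit(resp, seed=3, **FAST)
        diag = post.diagnostics()
        assert {"rhat", "ess_bulk"} <= set(diag.columns)
        assert (diag.loc[["d_intercept", "d_load", "c_intercept", "c_load"], "rhat"] < 1.05).all()


@pytest.fixture(scope="module")
def flat_load_post():
    pop = PopulationParams(
        alpha_d=2.0, beta_d=0.0, alpha_c=1.0, beta_c=0.0,
        sigma_ad=0.3, sigma_bd=0.0, sigma_ac=0.2, sigma_bc=0.0,
    )
    resp = make_responses(pop, 8, videos=10, seed=50)
    return fit_sdt_probit(resp, seed=4, **FAST)


@pytest.fixture(scope="module")
def two_condition_post():
    from fishmot.design import build_design_exp2

    videos = [f"v{i}" for i in range(8)]
    pop = PopulationParams(
        alpha_d=2.5, beta_d=-0.3, alpha_c=1.2, beta_c=-0.1,
        condition_offsets={
            Condition.TRADITIONAL: (0.3, 0.0),
            Condition.FAKEFISH: (-0.3, 0.0),
        },
        sigma_ad=0.3, sigma_bd=0.05, sigma_ac=0.2, sigma_bc=0.05,
    )
    trials = []
    for cond in (Condition.TRADITIONAL, Condition.FAKEFISH):
        trials += build_design_exp2(videos, condition=cond, n_objects=8, seed=6)
    obs = sample_observers(pop, 12, seed=7)
    resp = simulate_responses(obs, trials, pop, seed=8)
    return fit_sdt_probit(resp, seed=9, **FAST)


class TestSummaries:
    def test_flat_load_effect_gives_equal_summaries(self, flat_load_post):
        summ = summarize_dprime_bias(flat_load_post, at_loads=[1, 3, 5])
        # no generating load effect: the slope's CI covers zero and the
        # per-load d' intervals overlap
        s = PosteriorSummary.from_draws(flat_load_post.draws("d_load"))
        assert s.ci_low < 0.0 < s.ci_high
        d = summ[summ["measure"] == "dprime"].set_index("load")
        assert d.loc[1, "ci_low"] < d.loc[5, "ci_high"]
        assert d.loc[5, "ci_low"] < d.loc[1, "ci_high"]
        assert ((summ["ci_low"] <= summ["mean"]) & (summ["mean"] <= summ["ci_high"])).all()

    def test_extrapolation_warns(self, flat_load_post):
        with pytest.warns(UserWarning):
            summarize_dprime_bias(flat_load_post, at_loads=[9])

    def test_zero_crossing_load(self):
        """At the load where alpha_d + beta_d*n = 0 the d' summary
        straddles zero."""
        pop = PopulationParams(
            alpha_d=2.0, beta_d=-0.5, alpha_c=0.5, beta_c=0.0,
            sigma_ad=0.1, sigma_bd=0.05, sigma_ac=0.1, sigma_bc=0.02,
        )
        resp = make_responses(pop, 8, videos=10, set_sizes=(1, 3, 4, 5), seed=60)
        post = fit_sdt_probit(resp, seed=5, **FAST)
        summ = summarize_dprime_bias(post, at_loads=[4])
        row = summ[(summ["measure"] == "dprime")].iloc[0]
        assert row["ci_low"] < 0.0 < row["ci_high"]


class TestContrasts:
    def test_contrast_antisymmetry(self, two_condition_post):
        ab = contrast_conditions(two_condition_post, ("TRADITIONAL", "FAKEFISH"))
        ba = contrast_conditions(two_condition_post, ("FAKEFISH", "TRADITIONAL"))
        assert ab["dprime"].mean == pytest.approx(-ba["dprime"].mean, abs=1e-12)
        assert ab["dprime"].ci_low == pytest.approx(-ba["dprime"].ci_high, abs=1e-12)

    def test_contrast_sign_and_magnitude(self, two_condition_post):
        ab = contrast_conditions(two_condition_post, ("TRADITIONAL", "FAKEFISH"))
        assert ab["dprime"].ci_low <= 0.6 and ab["dprime"].ci_high >= 0.2

    def test_missing_condition_raises(self, two_condition_post):
        with pytest.raises(KeyError):
            contrast_conditions(two_condition_post, ("TRADITIONAL", "FISH"))


class TestSavageDickey:
    def test_no_data_gives_bf_one(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 1, 4000)  # posterior equals the N(0,1) prior
        bf = savage_dickey_bf(draws, "null_param")
        assert 0.9 < bf.bf10 < 1.1

    def test_conjugate_normal_oracle(self):
        """Known posterior N(0.5, 0.5^2): the KDE ratio matches the
        closed-form density ratio within 5%."""
        rng = np.random.default_rng(1)
        draws = rng.normal(0.5, 0.5, 8000)
        bf = savage_dickey_bf(draws, "effect")
        closed = stats.norm.pdf(0, 0, 1) / stats.norm.pdf(0, 0.5, 0.5)
        assert bf.bf10 == pytest.approx(closed, rel=0.05)

    def test_strong_effect_large_bf(self):
        pop = PopulationParams(
            alpha_d=3.58, beta_d=-0.5, alpha_c=1.97, beta_c=-0.22,
            sigma_ad=0.3, sigma_bd=0.05, sigma_ac=0.2, sigma_bc=0.05,
        )
        resp = make_responses(pop, 10, videos=23, seed=70)
        post = fit_sdt_probit(resp, seed=10, **FAST)
        bf = savage_dickey_bf(post, "d_load")
        assert bf.bf10 > 10

    def test_instability_flag_far_posterior(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(8.0, 0.5, 4000)  # no mass near zero
        bf = savage_dickey_bf(draws, "far")
        assert bf.unstable and bf.bf10 > 1


class TestExclusion:
    def make_table(self, accs, n_trials=100):
        rows = []
        for p, acc in enumerate(accs):
            n_corr = int(round(acc * n_trials))
            for i in range(n_trials):
                correct = i < n_corr
                rows.append(
                    {
                        "participant": f"p{p}",
                        "condition": "TRADITIONAL",
                        "n_targets": 2,
                        "queried_is_target": i % 2 == 0,
                        "response": "x",
                        "correct": correct,
                    }
                )
        return pd.DataFrame(rows)

    def test_boundary_kept_and_below_excluded(self):
        resp = self.make_table([0.5, 0.49, 1.0, 0.2])
        kept, excluded, flagged = apply_exclusion(resp)
        assert excluded == ["p1", "p3"]
        assert set(kept["participant"]) == {"p0", "p2"}
        assert flagged == []

    def test_missing_cell_flagged_not_dropped(self):
        resp = self.make_table([0.8])
        extra = resp.iloc[:4].assign(participant="p9", condition="FISH")
        both = pd.concat([resp, extra], ignore_index=True)
        kept, excluded, flagged = apply_exclusion(both)
        assert flagged == ["p9"]
        assert "p9" in set(kept["participant"])

    def test_guesser_excluded_about_half_the_time(self):
        """A d'=0 guesser over 23 trials falls below 50% with
        probability P(Binom(23, .5) <= 11) ~ 0.5."""
        rng = np.random.default_rng(3)
        n_excluded = 0
        reps = 400
        for _ in range(reps):
            correct = rng.uniform(size=23) < 0.5
            if correct.mean() < 0.5:
                n_excluded += 1
        expect = stats.binom.cdf(11, 23, 0.5)
        se = np.sqrt(expect * (1 - expect) / reps)
        assert abs(n_excluded / reps - expect) < 3 * se


class TestPerParticipantDprime:
    def test_closed_form_values(self):
        # hit .908 / fa .040 over 500 trials each -> d' ~ 3.08
        rows = []
        for i in range(500):
            rows.append(dict(participant="p", condition="FISH", n_targets=1,
                             queried_is_target=True, response="target" if i < 454 else "distractor",
                             correct=i < 454))
            rows.append(dict(participant="p", condition="FISH", n_targets=1,
                             queried_is_target=False, response="target" if i < 20 else "distractor",
                             correct=i >= 20))
        table = per_participant_dprime(pd.DataFrame(rows))
        row = table.iloc[0]
        assert row["dprime"] == pytest.approx(
            stats.norm.ppf(0.908) - stats.norm.ppf(0.040), abs=1e-6
        )
        assert row["criterion"] == pytest.approx(-stats.norm.ppf(0.040), abs=1e-6)

    def test_equal_rates_give_zero(self):
        rows = []
        for i in range(10):
            for tq in (True, False):
                rows.append(dict(participant="p", condition="F", n_targets=2,
                                 queried_is_target=tq, response="target" if i < 5 else "distractor",
                                 correct=True))
        table = per_participant_dprime(pd.DataFrame(rows))
        assert table.iloc[0]["dprime"] == pytest.approx(0.0, abs=1e-12)

    def test_continuity_correction_for_perfect_cells(self):
        rows = []
        for i in range(23):
            rows.append(dict(participant="p", condition="F", n_targets=2,
                             queried_is_target=True, response="target", correct=True))
            rows.append(dict(participant="p", condition="F", n_targets=2,
                             queried_is_target=False, response="distractor", correct=True))
        table = per_participant_dprime(pd.DataFrame(rows))
        row = table.iloc[0]
        expect = stats.norm.ppf(1 - 1 / 46) - stats.norm.ppf(1 / 46)
        assert np.isfinite(row["dprime"])
        assert row["dprime"] == pytest.approx(expect, abs=1e-9)

    def test_missing_query_type_yields_nan(self):
        rows = [dict(participant="p", condition="F", n_targets=2,
                     queried_is_target=True, response="target", correct=True)] * 5
        table = per_participant_dprime(pd.DataFrame(rows))
        assert np.isnan(table.iloc[0]["dprime"])


def make_dprime_pairs(seed, slope=0.85, noise_sd=0.35, n_p=52):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_p):
        for load in (2, 4):
            a = rng.normal(2.0, 0.7)
            b = slope * a + rng.normal(0, noise_sd)
            rows.append(dict(participant=f"p{p:03d}", condition="A", n_targets=load, dprime=a))
            rows.append(dict(participant=f"p{p:03d}", condition="B", n_targets=load, dprime=b))
    return pd.DataFrame(rows)


class TestPrediction:
    def test_perfect_prediction(self):
        tab = make_dprime_pairs(0, slope=1.0, noise_sd=1e-4)
        pred = fit_prediction_model(tab, "A", "B", seed=0, **FAST)
        s = PosteriorSummary.from_draws(pred.draws("slope"))
        assert s.mean == pytest.approx(1.0, abs=0.02)
        r2 = bayesian_r2(pred)
        assert r2.mean > 0.99

    def test_independent_outcome_slope_covers_zero(self):
        rng = np.random.default_rng(5)
        tab = make_dprime_pairs(5, slope=0.0, noise_sd=0.6)
        pred = fit_prediction_model(tab, "A", "B", seed=1, **FAST)
        s = PosteriorSummary.from_draws(pred.draws("slope"))
        assert s.ci_low < 0.0 < s.ci_high

    def test_permuted_predictor_destroys_r2(self):
        tab = make_dprime_pairs(7)
        rng = np.random.default_rng(8)
        scr = tab.copy()
        mask = scr["condition"] == "A"
        scr.loc[mask, "dprime"] = rng.permutation(scr.loc[mask, "dprime"].to_numpy())
        pred = fit_prediction_model(scr, "A", "B", seed=2, **FAST)
        assert bayesian_r2(pred).mean < 0.15

    def test_constant_predictor_rejected(self):
        tab = make_dprime_pairs(9)
        tab.loc[tab["condition"] == "A", "dprime"] = 2.0
        with pytest.raises(DegenerateDesignError):
            fit_prediction_model(tab, "A", "B")

    def test_too_few_participants_rejected(self):
        tab = make_dprime_pairs(10, n_p=2)
        with pytest.raises(InsufficientDataError):
            fit_prediction_model(tab, "A", "B")
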