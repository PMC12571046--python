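import numpy as np
import pytest

from motr._gibbs import default_priors, polya_gamma
from motr.design import StudyPlan, make_design
from motr.generate import GenerativeParams, simulate_measures
from motr.model import HierarchicalReadingModel, ModelSpec, family_for_measure


@pytest.fixture(scope="module")
def fitted(sim_measures):
    meas, truth = sim_measures
    model = HierarchicalReadingModel.from_measures(meas, "total_duration")
    return model, model.fit(seed=5, chains=2, iterations=700, warmup=300), truth


class TestPriors:
    def test_reading_time_priors(self):
        p = default_priors("lognormal")
        m0, s0 = p.beta_prior(["Intercept", "Gram"])
        assert (m0[0], s0[0]) == (6.0, 1.0)
        assert s0[1] == 0.1
        assert p.sd_rate == 2.0 and p.lkj_eta == 2.0 and p.sigma_rate == 2.0

    def test_binary_priors_have_unit_scales_and_no_sigma(self):
        p = default_priors("bernoulli")
        m0, s0 = p.beta_prior(["Intercept", "Gram"])
        assert (m0[0], s0[0]) == (0.0, 1.0) and s0[1] == 1.0
        assert p.sigma_rate is None

    def test_interaction_prior_override(self):
        p = default_priors("lognormal", beta_sd_overrides={"GramxAgrType": 0.3})
        _, s0 = p.beta_prior(["Intercept", "Gram", "GramxAgrType"])
        assert s0.tolist() == [1.0, 0.1, 0.3]

    def test_prior_predictive_baseline_is_hundreds_of_ms(self):
        """Normal(6, 1) on the log-ms intercept centres the prior
        predictive baseline around e^6 ~ 403 ms."""
        rng = np.random.default_rng(0)
        p = default_priors("lognormal")
        beta0 = rng.normal(p.beta0_mean, p.beta0_sd, 4000)
        sigma = rng.exponential(1 / p.sigma_rate, 4000)
        rt = np.exp(beta0 + sigma * rng.standard_normal(4000))
        med = np.median(rt)
        assert 100.0 < med < 1500.0


class TestPolyaGamma:
    def test_moments_match_theory(self):
        """E[PG(1, c)] = tanh(c/2) / (2c); checked at several tilts."""
        rng = np.random.default_rng(1)
        for c in (1e-6, 0.5, 1.5, 3.0):
            draws = polya_gamma(np.full(40000, c), rng)
            expect = 0.25 if c < 1e-4 else np.tanh(c / 2.0) / (2.0 * c)
            assert abs(draws.mean() - expect) < 4 * draws.std() / 200.0


class TestFit:
    def test_point_mass_recovery_with_degenerate_noise(self):
        design = make_design(StudyPlan(n_participants=12), seed=3)
        params = GenerativeParams(
            beta0=6.0, beta={}, sigma=0.01,
            sd_participant={"Intercept": 0.0, "slopes": 0.0},
            sd_item={"Intercept": 0.0, "slopes": 0.0},
        )
        meas, _ = simulate_measures(design, params, rng=1)
        res = HierarchicalReadingModel.from_measures(meas, "total_duration").fit(
            seed=0, chains=1, iterations=400, warmup=200
        )
        assert abs(res.params["Intercept"] - 6.0) < 0.01
        assert res.draws["sigma"].mean() < 0.05

    def test_seeded_fits_are_identical(self, sim_measures):
        meas, _ = sim_measures
        m = HierarchicalReadingModel.from_measures(meas, "total_duration")
        a = m.fit(seed=9, chains=1, iterations=250, warmup=100)
        b = m.fit(seed=9, chains=1, iterations=250, warmup=100)
        assert np.array_equal(a.fixed_draws, b.fixed_draws)
        c = m.fit(seed=10, chains=1, iterations=250, warmup=100)
        assert not np.array_equal(a.fixed_draws, c.fixed_draws)

    def test_lognormal_equals_normal_on_logged_responses(self, sim_measures):
        meas, _ = sim_measures
        logged = meas.copy()
        logged["total_duration"] = np.log(logged["total_duration"])
        a = HierarchicalReadingModel.from_measures(meas, "total_duration").fit(
            seed=4, chains=1, iterations=250, warmup=100
        )
        b = HierarchicalReadingModel.from_measures(
            logged, "total_duration", response="normal"
        ).fit(seed=4, chains=1, iterations=250, warmup=100)
        assert np.array_equal(a.fixed_draws, b.fixed_draws)

    def test_posterior_covers_truth(self, fitted):
        _, res, truth = fitted
        for name in res.names:
            lo, hi = res.credible_interval(name, level=0.99)
            assert lo - 0.05 < truth["beta"][name] < hi + 0.05

    def test_nonpositive_durations_rejected(self, sim_measures):
        meas, _ = sim_measures
        bad = meas.copy()
        bad.loc[bad.index[0], "total_duration"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            HierarchicalReadingModel.from_measures(bad, "total_duration")

    def test_missing_responses_are_dropped_not_imputed(self, sim_measures):
        meas, _ = sim_measures
        holey = meas.copy()
        holey.loc[holey.index[:100], "total_duration"] = np.nan
        m = HierarchicalReadingModel.from_measures(holey, "total_duration")
        assert len(m.frame) == len(meas) - 100

    def test_binary_measure_routes_to_bernoulli(self):
        assert family_for_measure("fp_reg") == "bernoulli"
        assert family_for_measure("go_past") == "lognormal"
        with pytest.raises(ValueError):
            family_for_measure("speed")

    def test_bernoulli_recovers_base_rate_and_gram(self):
        design = make_design(StudyPlan(n_participants=48), seed=5)
        params = GenerativeParams(
            beta0=-1.5, beta={"Gram": 0.6}, sigma=np.nan,
            sd_participant={"Intercept": 0.3, "slopes": 0.05},
            sd_item={"Intercept": 0.1, "slopes": 0.05},
        )
        meas, _ = simulate_measures(design, params, response="bernoulli", rng=6, measure="fp_reg")
        res = HierarchicalReadingModel.from_measures(meas, "fp_reg").fit(
            seed=2, chains=1, iterations=500, warmup=200
        )
        assert abs(res.params["Intercept"] - (-1.5)) < 0.35
        lo, hi = res.credible_interval("Gram")
        assert lo < 0.6 < hi and res.params["Gram"] > 0.15


class TestResults:
    def test_summary_layout(self, fitted):
        _, res, _ = fitted
        s = res.summary()
        assert list(s.index) == res.names
        for col in ("mean", "lower", "upper", "rhat", "ess_bulk", "resp_mean"):
            assert col in s.columns
        assert (s["lower"] <= s["mean"]).all() and (s["mean"] <= s["upper"]).all()
        assert s["rhat"].notna().all()

    def test_back_transform_matches_closed_form_at_point_mass(self, fitted):
        """With coefficients fixed at (beta0=6, Gram=0.1), the grammaticality
        effect in ms is e^{6.05} - e^{5.95} (= 2 e^6 sinh(0.05))."""
        model, res, _ = fitted
        point = np.zeros((1, len(res.names)))
        point[0, res.names.index("Intercept")] = 6.0
        point[0, res.names.index("Gram")] = 0.1
        res2 = _clone_with_draws(res, point)
        got = res2.back_transform("Gram")
        assert np.isclose(got["mean"], np.exp(6.05) - np.exp(5.95), rtol=1e-12)
        assert np.isclose(got["mean"], 2 * np.exp(6.0) * np.sinh(0.05), rtol=1e-12)

    def test_back_transform_of_null_bernoulli_draws_is_zero(self, sim_measures):
        meas, _ = sim_measures
        binm = meas.copy()
        binm["fp_reg"] = (binm["total_duration"] > binm["total_duration"].median()).astype(float)
        m = HierarchicalReadingModel.from_measures(binm, "fp_reg")
        res = m.fit(seed=1, chains=1, iterations=150, warmup=100)
        zero = _clone_with_draws(res, np.zeros((1, len(res.names))))
        for eff in ("Gram", "AgrType", "GramxAgrType"):
            assert zero.back_transform(eff)["mean"] == 0.0

    def test_unknown_effect_label_raises(self, fitted):
        _, res, _ = fitted
        with pytest.raises(KeyError):
            res.back_transform("GramxTime")

    def test_marginal_mismatch_cost_contract(self, fitted):
        _, res, _ = fitted
        mc = res.marginal_mismatch_cost()
        assert list(mc.index) == ["modAdj", "predAdj"]
        assert ((mc["lower"] <= mc["estimate"]) & (mc["estimate"] <= mc["upper"])).all()
        assert ((mc["tail_prob"] >= 0) & (mc["tail_prob"] <= 1)).all()
        with pytest.raises(ValueError, match="absent"):
            res.marginal_mismatch_cost(elements=("noun",))

    def test_marginal_cost_designed_simulation_separates_elements(self):
        """A penalty present only in the modifying-adjective conditions
        shows up in its marginal cost but not the predicative one."""
        design = make_design(StudyPlan(n_participants=48), seed=6)
        # coefficient pattern whose implied mismatch penalty is 0.2 on the
        # log scale for modAdj and exactly zero for predAdj and verb
        params = GenerativeParams(
            beta0=6.0,
            beta={"Gram": 0.2 / 3, "GramxAgrType": 0.2, "GramxLexCat": -0.1},
            sigma=0.25,
            sd_participant={"Intercept": 0.2, "slopes": 0.03},
            sd_item={"Intercept": 0.08, "slopes": 0.02},
        )
        meas, _ = simulate_measures(design, params, rng=7)
        res = HierarchicalReadingModel.from_measures(meas, "total_duration").fit(
            seed=3, chains=1, iterations=500, warmup=200
        )
        mc = res.marginal_mismatch_cost()
        assert mc.loc["modAdj", "lower"] > 0.0
        assert mc.loc["predAdj", "lower"] < 0.0 < mc.loc["predAdj", "upper"]

    def test_marginal_contrast_weights_sum_to_zero(self, fitted):
        model, res, _ = fitted
        labels = list(model.X_cells.index)
        from motr.design import GENDERS

        w = np.zeros(len(labels))
        for g in GENDERS:
            w[labels.index(f"modAdj:mismatch:{g}")] += 0.5
            w[labels.index(f"modAdj:match:{g}")] -= 0.5
        assert abs(w.sum()) < 1e-12


class TestModelSpec:
    def test_invalid_specs_rejected(self):
        p = default_priors("lognormal")
        with pytest.raises(ValueError, match="warmup"):
            ModelSpec("lognormal", "total_duration", ["Gram"], p, iterations=100, warmup=200)
        with pytest.raises(ValueError, match="family"):
            ModelSpec("poisson", "total_duration", ["Gram"], p)


def _clone_with_draws(res, fixed):
    """Results object sharing model/spec but with substituted beta draws."""
    import copy

    out = copy.copy(res)
    out.draws = dict(res.draws)
    out.draws["beta"] = fixed[None, :, :]
    out._diag = None
    return out
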