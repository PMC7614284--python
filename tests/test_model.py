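"""Model assembly: likelihood, priors, elicitation, and group structure."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from illnessdeath.model import (
    CountData,
    ConfigurationError,
    ModelConfig,
    PriorSet,
    Z975,
    assemble_model,
    elicit_area_sd_prior,
    load_config,
    log_likelihood,
)
from illnessdeath.process import outcome_probabilities
from illnessdeath.synthetic import ScenarioConfig, matching_config, simulate_scenario


def _frame(rows):
    return pd.DataFrame(rows, columns=["area", "gender", "age", "measure", "num", "denom"])


class TestCountData:
    def test_missing_area_gender_default_to_single_group(self):
        df = pd.DataFrame({"age": [0], "measure": ["inc"], "num": [1], "denom": [10]})
        cd = CountData(df)
        assert cd.areas == ["all"] and cd.genders == ["all"]

    def test_numerator_bounded_by_denominator(self):
        with pytest.raises(ValueError, match="exceeds"):
            CountData(_frame([("a", "f", 0, "inc", 11, 10)]))

    def test_unknown_measure_rejected_with_row(self):
        with pytest.raises(ValueError, match="mortality"):
            CountData(_frame([("a", "f", 0, "mortality", 1, 10)]))

    def test_duplicate_cells_rejected(self):
        rows = [("a", "f", 0, "inc", 1, 10)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            CountData(_frame(rows))

    def test_non_integer_counts_rejected(self):
        df = _frame([("a", "f", 0, "inc", 1, 10)]).astype({"num": float})
        df.loc[0, "num"] = 1.5
        with pytest.raises(ValueError, match="integer"):
            CountData(df)


class TestLogLikelihood:
    def test_binomial_arithmetic(self):
        # y=5, n=10, p=0.5: log C(10,5) + 10 log 0.5
        expected = gammaln(11) - 2 * gammaln(6) + 10 * math.log(0.5)
        assert expected == pytest.approx(-1.40204, abs=1e-5)
        data = CountData(_frame([("a", "g", 3, "prev", 5, 10)]))
        sched_probs = {("a", "g"): _const_probs(prev=0.5)}
        total, pointwise = log_likelihood(data, sched_probs)
        assert total == pytest.approx(expected, abs=1e-10)
        assert pointwise[0] == pytest.approx(expected, abs=1e-10)

    def test_zero_denominator_contributes_zero(self):
        data = CountData(_frame([
            ("a", "g", 3, "prev", 0, 0),
            ("a", "g", 4, "prev", 5, 10),
        ]))
        total, pointwise = log_likelihood(data, {("a", "g"): _const_probs(prev=0.5)})
        assert pointwise[0] == 0.0
        assert total == pytest.approx(pointwise[1])

    def test_impossible_data_gives_minus_inf_not_exception(self):
        data = CountData(_frame([("a", "g", 3, "rem", 2, 10)]))
        total, pointwise = log_likelihood(data, {("a", "g"): _const_probs(rem=0.0)})
        assert np.isneginf(total) and np.isneginf(pointwise[0])

    def test_total_is_sum_of_pointwise(self, single_model):
        theta = single_model.initial_point()
        pointwise = single_model.loglik_pointwise(theta)
        groups = single_model.group_rate_schedules(theta)
        probs = {g: outcome_probabilities(s) for g, s in groups.items()}
        total, pw2 = log_likelihood(single_model.data, probs)
        assert total == pytest.approx(pointwise.sum(), rel=1e-12)
        assert np.allclose(pointwise, pw2)


def _const_probs(prev=0.1, inc=0.01, mort=0.01, rem=0.05):
    from illnessdeath.process import OutcomeProbabilities

    n = 101
    return OutcomeProbabilities(
        inc=np.full(n, inc), prev=np.full(n, prev),
        mort=np.full(n, mort), rem=np.full(n, rem),
    )


class TestAreaSdPriorElicitation:
    def test_stated_fold_ratios_round_trip(self):
        prior = elicit_area_sd_prior(5.0, 50.0)
        assert math.exp(2 * Z975 * prior.mean) == pytest.approx(5.0, rel=1e-6)
        assert math.exp(2 * Z975 * prior.ppf(0.975)) == pytest.approx(50.0, rel=1e-6)

    def test_round_trip_verified_by_quadrature(self):
        """Oracle: recompute the gamma mean and 97.5% quantile by numerical
        integration of the density, independent of scipy's ppf."""
        prior = elicit_area_sd_prior(2.0, 20.0)
        k, s = prior.shape, prior.scale
        pdf = lambda x: x ** (k - 1) * np.exp(-x / s) / (s ** k * math.gamma(k))
        mean, _ = integrate.quad(lambda x: x * pdf(x), 0, np.inf)
        assert math.exp(2 * Z975 * mean) == pytest.approx(2.0, rel=1e-6)
        q = prior.ppf(0.975)
        mass, _ = integrate.quad(pdf, 0, q)
        assert mass == pytest.approx(0.975, abs=1e-8)
        assert math.exp(2 * Z975 * q) == pytest.approx(20.0, rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            elicit_area_sd_prior(5.0, 5.0)
        with pytest.raises(ValueError, match="ratio"):
            elicit_area_sd_prior(0.5, 50.0)


class TestGenderPrior:
    def test_scale_implies_stated_rate_ratio_interval(self):
        """N(0, 0.82^2) on the log male offset puts 95% prior probability on
        a male/female rate ratio between about 0.2 and 5."""
        scale = PriorSet().gender_scale
        assert scale == 0.82
        hi = math.exp(Z975 * scale)
        lo = math.exp(-Z975 * scale)
        assert hi == pytest.approx(5.0, rel=0.01)
        assert lo == pytest.approx(0.2, rel=0.01)


class TestAssembleModel:
    def test_single_area_parameter_count(self, single_model):
        # K coefficients per spline rate + one smoothness scale each
        assert single_model.n_params == 2 * 10 + 2

    def test_hierarchical_parameter_count(self):
        sc = ScenarioConfig(variant="hierarchical", seed=0, n_area=4)
        truth, data = simulate_scenario(sc)
        model = assemble_model(matching_config(sc), data)
        # cf: b1 + b2 + log_lambda1 + 4 intercept effects + 4*8 nonlinear
        # inc: 4 areas * 10; smoothness: 2
        assert model.n_params == (3 + 4 + 32) + 40 + 2

    def test_gender_additive_parameter_count(self):
        sc = ScenarioConfig(variant="gendered", seed=0, n_area=2)
        truth, data = simulate_scenario(sc)
        model = assemble_model(matching_config(sc), data)
        # hierarchical cf (3 + 2 + 16) + inc 2*10 + male offsets 10+10 + 2 scales
        assert model.n_params == 21 + 20 + 20 + 2

    def test_remission_records_require_remission_variant(self):
        df = _frame([("a", "g", 60, "rem", 5, 10), ("a", "g", 60, "mort", 1, 100)])
        with pytest.raises(ConfigurationError, match="remission"):
            assemble_model(ModelConfig(A=100), CountData(df))

    def test_hierarchical_needs_multiple_areas(self):
        df = _frame([("a", "g", 60, "mort", 1, 100)])
        with pytest.raises(ConfigurationError, match="2 areas"):
            assemble_model(ModelConfig(A=100, hierarchical=True), CountData(df))

    def test_two_genders_need_gender_mode(self):
        df = _frame([
            ("a", "male", 60, "mort", 1, 100),
            ("a", "female", 60, "mort", 1, 100),
        ])
        with pytest.raises(ConfigurationError, match="gender"):
            assemble_model(ModelConfig(A=100), CountData(df))

    def test_log_posterior_finite_at_initial_point(self, single_model):
        theta = single_model.initial_point()
        assert np.isfinite(single_model.log_posterior(theta))

    def test_rates_positive_probabilities_bounded(self, single_model):
        rng = np.random.default_rng(5)
        theta = single_model.initial_point() + rng.normal(0, 0.3, single_model.n_params)
        rt = single_model.rates(theta)
        assert all(np.all(v >= 0) for v in rt.values())
        probs = single_model.outcome_probs(theta)
        for v in probs.values():
            assert np.all((v >= 0) & (v <= 1))

    def test_prior_gradient_matches_finite_differences(self, single_model):
        rng = np.random.default_rng(6)
        theta = single_model.initial_point() + rng.normal(0, 0.2, single_model.n_params)
        g = single_model.prior_grad(theta)
        for i in range(0, single_model.n_params, 5):
            e = np.zeros(single_model.n_params)
            e[i] = 1e-6
            fd = (single_model.log_prior(theta + e) - single_model.log_prior(theta - e)) / 2e-6
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestStructuralReductions:
    def test_identical_gender_data_centres_male_offsets_at_zero(self, single_data):
        """Duplicating one population's counts as both genders leaves no
        gender signal, so the additive male intercept offset concentrates
        around zero."""
        from illnessdeath.engines import fit_mode_laplace

        df = single_data.frame
        female = df.assign(gender="female")
        male = df.assign(gender="male")
        data = CountData(pd.concat([female, male], ignore_index=True))
        cfg = ModelConfig(A=100, gender="additive",
                          a_base={"cf": 50, "inc": 30})
        model = assemble_model(cfg, data)
        fit = fit_mode_laplace(model, seed=0, n_draws=500)
        block = model.layout.blocks["cf_male"]
        icpt_draws = fit.draws[:, block.offset]
        lo, hi = np.quantile(icpt_draws, [0.025, 0.975])
        assert lo < 0 < hi
        assert abs(np.median(icpt_draws)) < 0.1

    def test_vanishing_area_sd_collapses_to_pooled_fit(self):
        """With the between-area SD pinned near zero, the hierarchical model
        reproduces a common-curve fit to the pooled data: the case-fatality
        intervals overlap age by age."""
        from illnessdeath.dataprep import aggregate_areas
        from illnessdeath.engines import fit_mode_laplace
        from illnessdeath.model import GammaPrior
        from illnessdeath.synthetic import (
            ScenarioConfig, make_true_rates, simulate_dataset,
        )

        sc = ScenarioConfig(variant="hierarchical", seed=4, n_area=2, lambda1=0.0)
        truth = make_true_rates(sc)
        data = simulate_dataset(truth, seed=4)

        tiny = GammaPrior(shape=1e4, scale=1e-10)  # lambda_1 ~ 1e-6, essentially fixed
        cfg_h = ModelConfig(A=100, hierarchical=True,
                            a_base={"cf": 50, "inc": 30},
                            priors=PriorSet(area_sd_prior=tiny))
        fit_h = fit_mode_laplace(assemble_model(cfg_h, data), seed=0, n_draws=500)

        pooled = aggregate_areas(data, {"area0": "all", "area1": "all"})
        cfg_p = ModelConfig(A=100, a_base={"cf": 50, "inc": 30})
        fit_p = fit_mode_laplace(assemble_model(cfg_p, pooled), seed=0, n_draws=500)

        ages = np.arange(55, 96)
        f_p = fit_p.derived["f"][:, 0, ages]
        p_lo, p_hi = np.quantile(f_p, [0.025, 0.975], axis=0)
        for g in range(fit_h.derived["f"].shape[1]):
            f_h = fit_h.derived["f"][:, g, ages]
            h_lo, h_hi = np.quantile(f_h, [0.025, 0.975], axis=0)
            # intervals overlap at every age
            assert np.all(np.maximum(h_lo, p_lo) <= np.minimum(h_hi, p_hi))


class TestConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text(
            "A: 80\nK: 8\nhierarchical: false\nremission: constant\n"
            "a_base:\n  cf: 40\nincreasing:\n  cf: true\n"
            "priors:\n  gender_scale: 0.82\n  area_ratio_guess: 5\n  area_ratio_upper: 50\n"
        )
        cfg = load_config(path)
        assert cfg.A == 80 and cfg.K == 8
        assert cfg.a_base["cf"] == 40 and cfg.increasing["cf"]
        assert cfg.remission == "constant"
        assert math.exp(2 * Z975 * cfg.priors.area_sd_prior.mean) == pytest.approx(5.0, rel=1e-5)
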