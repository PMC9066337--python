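"""Sampling, Monte Carlo, equity adjustment, scenarios and reporting."""

import numpy as np
import pandas.testing as pdt
import pytest

import pmslt
from pmslt.analysis import (
    ParameterDistribution,
    _sample_lag,
    default_distributions,
    target_population_rates,
)
from pmslt.pif import LagSpec


class TestSampling:
    def test_zero_dispersion_returns_centrals(self):
        dists = default_distributions(dispersion_scale=0.0)
        params = pmslt.sample_parameters(dists, seed=1, draw_index=0)
        spec = pmslt.InterventionSpec()
        assert params["p_smartphone"] == spec.p_smartphone
        assert params["p_recognition"] == spec.p_recognition
        assert params["effect"] == pytest.approx(spec.resolved_effect())
        assert params["intervention_cost"] == spec.cost

    def test_effect_ci_implies_sd(self):
        d = ParameterDistribution("effect", "normal", -0.400, ci95=(-0.858, 0.051))
        assert d.sd == pytest.approx((0.051 + 0.858) / 3.92, abs=1e-4)
        assert d.sd == pytest.approx(0.232, abs=1e-3)

    def test_beta_moment_matching_mean(self):
        """Sample mean of a beta(mean 0.45, SD 20%) matches to Monte Carlo error."""
        d = ParameterDistribution("p_recognition", "beta", 0.45, sd_pct=20.0)
        rng = np.random.default_rng(0)
        draws = np.array([d.sample(rng) for _ in range(10_000)])
        assert draws.mean() == pytest.approx(0.45, abs=0.003)
        assert draws.std() == pytest.approx(0.09, abs=0.005)
        assert ((draws > 0) & (draws < 1)).all()

    def test_positive_families_stay_positive(self):
        rng = np.random.default_rng(3)
        logn = ParameterDistribution("regain_rate", "lognormal", 0.03, sd_pct=20.0)
        gam = ParameterDistribution("cost", "gamma", 2_883_000, sd_pct=20.0)
        for _ in range(500):
            assert logn.sample(rng) > 0
            assert gam.sample(rng) > 0

    def test_infeasible_beta_dispersion_rejected(self):
        d = ParameterDistribution("p", "beta", 0.5, sd_pct=110.0)
        with pytest.raises(pmslt.ConfigurationError, match="too large"):
            d.sample(np.random.default_rng(0))

    def test_draws_reproducible_and_independent(self):
        dists = default_distributions()
        a = pmslt.sample_parameters(dists, seed=5, draw_index=3)
        b = pmslt.sample_parameters(dists, seed=5, draw_index=3)
        c = pmslt.sample_parameters(dists, seed=5, draw_index=4)
        assert a == b
        assert a != c

    def test_lag_sampling_respects_invariants(self):
        rng = np.random.default_rng(7)
        for base in (LagSpec(0, 5), LagSpec(10, 30)):
            for _ in range(200):
                lag = _sample_lag(rng, base, 1.0)
                assert 0 <= lag.lag_min <= lag.lag_max


class TestMonteCarlo:
    def test_zero_dispersion_matches_expected_value_run(self, model):
        unc = pmslt.run_monte_carlo(model, n_draws=2, seed=1, dispersion_scale=0.0)
        expected = pmslt.run_scenario(model, "base")
        assert unc.mean("qalys") == pytest.approx(expected.qaly_gain(), abs=1e-9)
        assert unc.mean("net_cost") == pytest.approx(expected.net_cost(), abs=1e-6)
        lo, hi = unc.interval("qalys")
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_reproduces(self, model):
        a = pmslt.run_monte_carlo(model, n_draws=5, seed=11)
        b = pmslt.run_monte_carlo(model, n_draws=5, seed=11)
        pdt.assert_frame_equal(a.draws, b.draws)

    def test_default_draw_count_summary(self, model):
        """A 200-draw run yields ordered percentile intervals around the mean."""
        unc = pmslt.run_monte_carlo(model, n_draws=200, seed=2)
        assert unc.n_draws == 200
        for q in ("qalys", "net_cost"):
            lo, hi = unc.interval(q)
            assert lo < hi
            assert lo < unc.mean(q) < hi
        # subgroup draws add up to the total draw by draw
        np.testing.assert_allclose(
            unc.draws["qalys_maori"] + unc.draws["qalys_non_maori"],
            unc.draws["qalys"],
            rtol=1e-9,
        )

    def test_ui_coverage_on_linear_toy_model(self):
        """For a linear combination of normal inputs the empirical 95% UI at
        2000 draws matches the analytic interval within Monte Carlo error."""
        dists = [
            ParameterDistribution("a", "normal", 10.0, sd_pct=10.0),
            ParameterDistribution("b", "normal", -4.0, sd_pct=25.0),
        ]
        outputs = np.array(
            [
                sum(pmslt.sample_parameters(dists, seed=9, draw_index=d).values())
                for d in range(2000)
            ]
        )
        sd = np.hypot(1.0, 1.0)  # both SDs are 1.0
        lo, hi = np.quantile(outputs, [0.025, 0.975])
        assert lo == pytest.approx(6.0 - 1.96 * sd, abs=0.15)
        assert hi == pytest.approx(6.0 + 1.96 * sd, abs=0.15)


class TestEquity:
    def test_life_expectancy_gap_removed(self, bundle):
        adj = pmslt.equity_adjust(bundle)
        for sex in ("male", "female"):
            le_m = pmslt.life_expectancy(adj, sex, "maori")
            le_n = pmslt.life_expectancy(adj, sex, "non_maori")
            assert le_m == pytest.approx(le_n, abs=1e-12)

    def test_no_gap_bundle_unchanged(self):
        cfg = pmslt.GeneratorConfig(maori_mortality_gap=1.0, maori_pyld_gap=1.0)
        b = pmslt.generate_bundle(1, cfg)
        adj = pmslt.equity_adjust(b)
        pdt.assert_frame_equal(adj.demography, b.demography)

    def test_non_maori_results_bitwise_identical(self, bundle, model):
        spec = pmslt.InterventionSpec()
        plain = model.run(spec)
        adjusted = pmslt.Model(pmslt.equity_adjust(bundle)).run(spec)
        sel = plain.ethnicity == "non_maori"
        np.testing.assert_array_equal(plain.qaly_int[sel], adjusted.qaly_int[sel])
        np.testing.assert_array_equal(plain.cost_int[sel], adjusted.cost_int[sel])

    def test_maori_per_capita_gain_rises(self, bundle, model):
        """Removing the background life-expectancy gap raises the Māori QALY
        gain per 1000: gains are no longer cut short by earlier death."""
        spec = pmslt.InterventionSpec()
        plain = model.run(spec)
        adjusted = pmslt.Model(pmslt.equity_adjust(bundle)).run(spec)
        assert adjusted.qaly_gain(ethnicity="maori") > plain.qaly_gain(ethnicity="maori")


class TestScenarios:
    def test_unknown_scenario_lists_valid_ids(self, model):
        with pytest.raises(pmslt.DomainError, match="s4c_no_regain"):
            pmslt.run_scenario(model, "bogus")

    def test_scenario_overrides(self):
        spec, disc = pmslt.scenario_spec("s1_recognition68")
        assert spec.p_recognition == 0.68 and disc == 0.03
        spec, _ = pmslt.scenario_spec("s3_full_adherence")
        assert spec.resolved_effect() == pytest.approx(-0.609)
        spec, _ = pmslt.scenario_spec("s4b_delay5")
        assert spec.effect_spec.regain_delay == 5.0
        spec, disc = pmslt.scenario_spec("s6b_disc6")
        assert disc == 0.06
        spec, _ = pmslt.scenario_spec("s5_legacy_effect")
        assert spec.resolved_effect() == pytest.approx(-0.430 / 1.69**2)

    def test_base_scenario_deterministic(self, model):
        a = pmslt.run_scenario(model, "base")
        b = pmslt.run_scenario(model, "base")
        assert a.qaly_gain() == b.qaly_gain()

    def test_regain_scenario_ordering(self, model):
        """No regain ≥ 5-year delay ≥ 1-year delay ≥ base."""
        gains = {
            sid: pmslt.run_scenario(model, sid).qaly_gain()
            for sid in ("base", "s4a_delay1", "s4b_delay5", "s4c_no_regain")
        }
        assert (
            gains["s4c_no_regain"]
            > gains["s4b_delay5"]
            > gains["s4a_delay1"]
            > gains["base"]
        )

    def test_enhancement_scenarios_beat_base(self, model):
        base = pmslt.run_scenario(model, "base").qaly_gain()
        for sid in ("s1_recognition68", "s2_effect_x1.5", "s3_full_adherence"):
            assert pmslt.run_scenario(model, sid).qaly_gain() > base, sid

    def test_discount_rate_ordering(self, model):
        q0 = pmslt.run_scenario(model, "s6a_disc0").qaly_gain()
        q3 = pmslt.run_scenario(model, "base").qaly_gain()
        q6 = pmslt.run_scenario(model, "s6b_disc6").qaly_gain()
        assert q0 > q3 > q6


class TestReporting:
    def test_percent_difference_rounding(self):
        assert pmslt.percent_difference(276, 183) == 51
        assert pmslt.percent_difference(183, 183) == 0
        assert pmslt.percent_difference(14_727, 183) == 7948
        with pytest.raises(pmslt.DomainError):
            pmslt.percent_difference(10, 0)

    def test_cost_effectiveness_classification(self):
        assert pmslt.classify_cost_effectiveness(-606_000, 181) == "cost_saving"
        assert pmslt.classify_cost_effectiveness(450_000, 10, 45_000) == "cost_effective"
        assert pmslt.classify_cost_effectiveness(1e9, 1, 45_000) == "not_cost_effective"
        assert pmslt.classify_cost_effectiveness(1e6, 0) == "dominated"

    def test_subgroup_table_arithmetic(self, base_result, bundle):
        table = pmslt.subgroup_table(base_result, bundle)
        all_row = table.loc["all"]
        pop = bundle.demography["population"].sum()
        assert all_row["qalys_per_1000"] == pytest.approx(
            1000 * all_row["qalys"] / pop
        )
        assert all_row["net_cost_usd"] == pytest.approx(
            all_row["net_cost_nzd"] * pmslt.NZD_TO_USD
        )
        # ethnicities partition the total
        assert table.loc["maori", "qalys"] + table.loc["non_maori", "qalys"] == (
            pytest.approx(all_row["qalys"], rel=1e-9)
        )

    def test_target_population_rate_exceeds_total_rate(self, base_result, bundle):
        """Gains accrue only to the overweight/obese target population, so
        per-1000 rates are larger over the smaller target denominator."""
        table = pmslt.subgroup_table(base_result, bundle)
        target = target_population_rates(base_result, bundle)
        assert target["all"] > table.loc["all", "qalys_per_1000"]

    def test_zero_gain_reports_zero_rates(self, model, bundle):
        res = model.run(pmslt.InterventionSpec(p_uptake=0.0))
        table = pmslt.subgroup_table(res, bundle)
        assert (table["qalys_per_1000"] == 0).all()

    def test_scenario_table_shape(self, model):
        table = pmslt.scenario_table(model, ["base", "s6a_disc0", "s4c_no_regain"])
        assert list(table.index) == ["base", "s6a_disc0", "s4c_no_regain"]
        assert table.loc["base", "qalys_pct_diff"] == 0
        assert table.loc["s4c_no_regain", "qalys_pct_diff"] > table.loc[
            "s6a_disc0", "qalys_pct_diff"
        ]


class TestCLI:
    def test_generate_run_report(self, tmp_path):
        from click.testing import CliRunner

        from pmslt.cli import main

        runner = CliRunner()
        r = runner.invoke(main, ["generate", "--seed", "1", "--out", str(tmp_path / "b")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            main,
            ["run", "--bundle", str(tmp_path / "b"), "--out", str(tmp_path / "o"),
             "--scenario", "base"],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "o" / "summary.json").exists()
        assert (tmp_path / "o" / "run_log.json").exists()
        assert (tmp_path / "o" / "subgroups.csv").exists()
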