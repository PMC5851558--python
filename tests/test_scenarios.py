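import copy

import numpy as np
import pytest
from scipy import stats

from ecignet.parameters import SimConfig, se_from_ci
from ecignet.scenarios import (ScenarioSpec, apply_scenario, harm_sweep,
                               prob_surface, scenario_table)
from ecignet.uncertainty import prob_positive, run_monte_carlo


class TestApplyScenario:
    def test_cessation_or_scaling(self, fixture_ps):
        ps2 = apply_scenario(fixture_ps,
                             ScenarioSpec("or_cessation", "scale", 2.5))
        assert ps2.cessation.or_cessation.mean == pytest.approx(2.15, abs=1e-12)
        assert ps2.cessation.or_cessation.se == pytest.approx(
            2.5 * fixture_ps.cessation.or_cessation.se, rel=1e-12)

    def test_initiation_or_scaling_matches_scaled_ci(self, fixture_ps):
        """Scaling 3.50 (2.38-5.16) by 0.9 gives 3.15 with CI bounds
        that scale too (2.14-4.64 at printed precision)."""
        ps2 = apply_scenario(fixture_ps,
                             ScenarioSpec("or_initiation", "scale", 0.9))
        uq = ps2.initiation.or_initiation
        assert uq.mean == pytest.approx(3.15, abs=1e-12)
        # proportional SE scaling == SE implied by the scaled bounds
        assert uq.se == pytest.approx(se_from_ci(0.9 * 2.38, 0.9 * 5.16),
                                      rel=1e-12)
        assert uq.se == pytest.approx(se_from_ci(2.14, 4.64), abs=5e-3)

    def test_identity_scale(self, fixture_ps):
        ps2 = apply_scenario(fixture_ps, ScenarioSpec("or_cessation", "scale", 1.0))
        assert ps2.cessation == fixture_ps.cessation

    def test_pure_and_invertible(self, fixture_ps):
        snapshot = copy.deepcopy(fixture_ps)
        ps2 = apply_scenario(fixture_ps, ScenarioSpec("prev_ever_ecig", "scale", 2.0))
        assert fixture_ps.youth_strata == snapshot.youth_strata  # input untouched
        ps3 = apply_scenario(ps2, ScenarioSpec("prev_ever_ecig", "scale", 0.5))
        for a, b in zip(ps3.youth_strata, fixture_ps.youth_strata):
            assert a.prev_ever_ecig.mean == pytest.approx(
                b.prev_ever_ecig.mean, rel=1e-12)

    def test_prevalence_overflow_clipped_with_warning(self, fixture_ps):
        with pytest.warns(UserWarning, match="clip"):
            ps2 = apply_scenario(fixture_ps,
                                 ScenarioSpec("prev_current_ecig", "scale", 50.0))
        assert max(st.prev_current_ecig.mean for st in ps2.adult_strata) == 1.0
        assert "scenario_clipping" in ps2.metadata

    def test_set_mode_fixes_parameter(self, fixture_ps):
        ps2 = apply_scenario(fixture_ps, ScenarioSpec("or_initiation", "set", 1.0))
        assert ps2.initiation.or_initiation.mean == 1.0
        assert ps2.initiation.or_initiation.se == 0.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("bogus", "scale", 1.0)
        with pytest.raises(ValueError):
            ScenarioSpec("or_cessation", "scale", -1.0)


class TestHarmSweep:
    def test_base_case_point_reproduced(self, fixture_ps, small_cfg):
        res = harm_sweep(fixture_ps, small_cfg, [0.05])
        base = run_monte_carlo(fixture_ps, small_cfg)
        from ecignet.uncertainty import summarize
        s = summarize(base, small_cfg.ci_level)
        assert res.summaries[0].mean["net_years"] == s.mean["net_years"]

    def test_net_years_non_increasing_in_harm(self, fixture_ps, small_cfg):
        res = harm_sweep(fixture_ps, small_cfg, np.linspace(0, 1, 6))
        means = [s.mean["net_years"] for s in res.summaries]
        assert np.all(np.diff(means) <= 1e-9)

    def test_full_harm_strictly_below_zero_harm(self, fixture_ps, small_cfg):
        res = harm_sweep(fixture_ps, small_cfg, [0.0, 1.0])
        assert (res.summaries[1].mean["net_years"]
                < res.summaries[0].mean["net_years"])

    def test_out_of_range_rejected(self, fixture_ps, small_cfg):
        with pytest.raises(ValueError):
            harm_sweep(fixture_ps, small_cfg, [0.0, 1.5])

    def test_tidy_frame(self, fixture_ps, small_cfg):
        df = harm_sweep(fixture_ps, small_cfg, [0.0, 0.5, 1.0]).to_frame()
        assert set(df.columns) == {"scenario", "target", "value", "outcome",
                                   "mean", "ci_lower", "ci_upper",
                                   "prob_positive"}
        assert len(df) == 3 * 5  # grid points x outcomes


class TestProbSurface:
    def test_unit_multiplier_equals_base(self, fixture_ps, small_cfg):
        res = prob_surface(fixture_ps, small_cfg, "or_cessation", [1.0])
        base = prob_positive(run_monte_carlo(fixture_ps, small_cfg))
        assert res.prob_positive[0] == base

    def test_monotone_in_cessation_or(self, fixture_ps, small_cfg):
        res = prob_surface(fixture_ps, small_cfg, "or_cessation",
                           [0.5, 1.0, 2.0, 4.0])
        assert np.all(np.diff(res.prob_positive) >= 0)

    def test_monotone_in_initiation_or(self, fixture_ps, small_cfg):
        res = prob_surface(fixture_ps, small_cfg, "or_initiation",
                           [0.5, 1.0, 1.5])
        assert np.all(np.diff(res.prob_positive) <= 0)

    def test_unit_initiation_or_reduces_to_benefit_branch(self, fixture_ps,
                                                          small_cfg):
        """Fixing the initiation OR at 1 removes the harm branch, so
        P(net > 0) must equal P(benefit > 0) on the same draws."""
        ps1 = apply_scenario(fixture_ps, ScenarioSpec("or_initiation", "set", 1.0))
        draws = run_monte_carlo(ps1, small_cfg)
        assert np.allclose(draws.harm_years, 0.0, atol=1e-9)
        assert prob_positive(draws, "net_years") == pytest.approx(
            prob_positive(draws, "benefit_years"),
            abs=3 * np.sqrt(0.25 / small_cfg.n_iterations))


class TestScenarioTable:
    def test_base_case_only(self, fixture_ps, small_cfg):
        df = scenario_table(fixture_ps, small_cfg, [])
        assert len(df) == 1 and df.loc[0, "scenario"] == "Base Case"

    def test_duplicate_of_base_matches_base(self, fixture_ps, small_cfg):
        df = scenario_table(fixture_ps, small_cfg,
                            [ScenarioSpec("or_cessation", "scale", 1.0,
                                          label="same as base")])
        assert df.loc[1, "net_years_mean"] == df.loc[0, "net_years_mean"]

    def test_rows_carry_transformed_parameter(self, fixture_ps, small_cfg):
        df = scenario_table(
            fixture_ps, small_cfg,
            [ScenarioSpec("or_initiation", "scale", 0.9, label="10% down")])
        # recompute expected point/CI text from the transformed parameter
        ps2 = apply_scenario(fixture_ps,
                             ScenarioSpec("or_initiation", "scale", 0.9))
        uq = ps2.initiation.or_initiation
        z = stats.norm.ppf(0.975)
        expected = (f"{uq.mean:.2f} ({uq.mean - z * uq.se:.2f} to "
                    f"{uq.mean + z * uq.se:.2f})")
        assert df.loc[1, "parameter_point_ci"] == expected
        assert df.loc[1, "scenario"] == "10% down"
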