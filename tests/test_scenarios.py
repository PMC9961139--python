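"""Intervention scenarios: redistribution rules, reduction tables, extrapolation."""

import numpy as np
import pandas as pd
import pytest

from carechain.ami_model import ami_suicide_probability
from carechain.chain_core import validate_chain
from carechain.scenarios import (
    InfeasibleScenarioError,
    ScenarioResult,
    ScenarioSpec,
    apply_access,
    apply_awareness,
    apply_combined,
    diminishing_returns,
    extrapolate_population,
    run_experiment,
)

GRID = (0.04, 0.08, 0.12)


class TestSpecValidation:
    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError, match="positive"):
            ScenarioSpec("awareness", (0.0, 0.04))
        with pytest.raises(ValueError, match="ascending"):
            ScenarioSpec("access", (0.08, 0.04))
        with pytest.raises(ValueError, match="mode"):
            ScenarioSpec("prayer", (0.04,))


class TestAwareness:
    @pytest.mark.parametrize(
        "delta, p11, p12, p14",
        [
            (0.04, 0.2911, 0.5760, 0.1189),
            (0.08, 0.2627, 0.6160, 0.1073),
            (0.12, 0.2343, 0.6560, 0.0957),  # rule-based, not the misprinted table row
        ],
    )
    def test_redistribution_rule_row(self, evidence, config, delta, p11, p12, p14):
        P = apply_awareness(evidence, delta, config).transition
        assert P[0, 0] == pytest.approx(p11, abs=1e-12)
        assert P[0, 1] == pytest.approx(p12, abs=1e-12)
        assert P[0, 3] == pytest.approx(p14, abs=1e-12)
        assert P[0, 4] == pytest.approx(0.014)

    def test_zero_delta_returns_current_state(self, evidence, config, current_chain):
        np.testing.assert_array_equal(
            apply_awareness(evidence, 0.0, config).transition, current_chain.transition
        )

    def test_verbatim_mode_reproduces_printed_rows_including_the_misprint(self, evidence):
        P = apply_awareness(evidence, 0.12, verbatim=True).transition
        assert P[0, 1] == pytest.approx(0.676)  # as printed; rule gives 0.656
        with pytest.raises(ValueError, match="verbatim"):
            apply_awareness(evidence, 0.05, verbatim=True)

    def test_infeasible_delta(self, evidence):
        with pytest.raises(InfeasibleScenarioError):
            apply_awareness(evidence, 0.45)


class TestAccess:
    @pytest.mark.parametrize(
        "delta, p21, p23", [(0.04, 0.084, 0.902), (0.08, 0.044, 0.942), (0.12, 0.004, 0.982)]
    )
    def test_mass_shift_row(self, evidence, config, delta, p21, p23):
        P = apply_access(evidence, delta, config).transition
        assert P[1, 0] == pytest.approx(p21, abs=1e-12)
        assert P[1, 2] == pytest.approx(p23, abs=1e-12)

    def test_boundary_delta_zeroes_the_bounce_back(self, evidence):
        chain = apply_access(evidence, 0.124)
        assert chain.transition[1, 0] == 0.0
        assert validate_chain(chain) == []

    def test_infeasible_delta(self, evidence):
        with pytest.raises(InfeasibleScenarioError):
            apply_access(evidence, 0.125)


class TestCombined:
    @pytest.mark.parametrize(
        "delta, p11, p12, p14, p21, p23",
        [
            (0.02, 0.3053, 0.5560, 0.1247, 0.1040, 0.8820),
            (0.04, 0.2911, 0.5760, 0.1189, 0.0840, 0.9020),
            (0.06, 0.2769, 0.5960, 0.1131, 0.0640, 0.9220),
        ],
    )
    def test_published_rows(self, evidence, config, delta, p11, p12, p14, p21, p23):
        P = apply_combined(evidence, delta, config).transition
        np.testing.assert_allclose(
            [P[0, 0], P[0, 1], P[0, 3], P[1, 0], P[1, 2]],
            [p11, p12, p14, p21, p23],
            atol=1e-12,
        )

    def test_composition_commutes(self, evidence, config):
        # apply_combined asserts commutativity internally; also check against
        # manual composition through the single-lever operations
        combined = apply_combined(evidence, 0.04, config).transition
        via_single = apply_access(evidence, 0.04, config).transition.copy()
        via_single[0] = apply_awareness(evidence, 0.04, config).transition[0]
        np.testing.assert_allclose(combined, via_single, atol=1e-15)

    def test_zero_delta_is_identity(self, evidence, config, current_chain):
        np.testing.assert_array_equal(
            apply_combined(evidence, 0.0, config).transition, current_chain.transition
        )


class TestExperiments:
    @pytest.mark.parametrize(
        "mode, grid, expected_pct",
        [
            ("awareness", GRID, (6.2482, 6.1203, 6.0037)),
            ("access", GRID, (6.2209, 6.0637, 5.9173)),
            ("combined", (0.02, 0.04, 0.06), (6.2311, 6.0807, 5.9373)),
        ],
    )
    def test_published_probability_columns(self, evidence, config, mode, grid, expected_pct):
        result = run_experiment(ScenarioSpec(mode, grid), evidence, config)
        np.testing.assert_allclose(result.suicide_pct, expected_pct, atol=5e-3)
        assert result.baseline_pct == pytest.approx(6.3901, abs=5e-3)

    @pytest.mark.parametrize(
        "mode, expected_reductions",
        [
            ("awareness", (0.1419, 0.2698, 0.3864)),
            ("access", (0.1692, 0.3263, 0.4728)),
        ],
    )
    def test_published_reduction_columns(self, evidence, config, mode, expected_reductions):
        result = run_experiment(ScenarioSpec(mode, GRID), evidence, config)
        np.testing.assert_allclose(result.reductions_pct, expected_reductions, atol=2e-3)

    def test_reductions_recomputed_and_telescoping(self, evidence, config):
        result = run_experiment(ScenarioSpec("combined", (0.02, 0.04, 0.06)), evidence, config)
        t = result.table
        np.testing.assert_allclose(
            t["reduction_vs_baseline_pct"],
            result.baseline_pct - t["suicide_probability_pct"],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            np.cumsum(t["reduction_vs_previous_pct"]), t["reduction_vs_baseline_pct"], atol=1e-12
        )

    @pytest.mark.parametrize("mode", ["awareness", "access", "combined"])
    def test_suicide_probability_non_increasing_in_delta(self, evidence, config, mode):
        upper = {"awareness": 0.44, "access": 0.124, "combined": 0.124}[mode]
        grid = np.arange(0.005, upper, 0.005)
        result = run_experiment(ScenarioSpec(mode, tuple(grid)), evidence, config)
        probs = result.table["suicide_probability_pct"].to_numpy()
        assert np.all(np.diff(probs) <= 1e-12)

    def test_scenario_chains_valid_across_feasible_grid(self, evidence, config):
        for d in np.arange(0.005, 0.124, 0.005):
            assert validate_chain(apply_combined(evidence, float(d), config)) == []

    def test_empty_grid_keeps_only_the_baseline_row(self, evidence, config):
        result = run_experiment(ScenarioSpec("awareness", ()), evidence, config)
        assert len(result.table) == 1
        assert result.table.loc[0, "reduction_vs_baseline_pct"] == 0.0

    def test_infeasible_delta_is_annotated(self, evidence, config):
        with pytest.raises(InfeasibleScenarioError, match="0.2"):
            run_experiment(ScenarioSpec("access", (0.04, 0.2)), evidence, config)


class TestExtrapolation:
    @pytest.mark.parametrize(
        "reduction, population, expected",
        [(0.4728, 1e9, 4.728e6), (0.1419, 1e9, 1.419e6), (0.0, 1e9, 0.0)],
    )
    def test_population_scaling(self, reduction, population, expected):
        assert extrapolate_population(reduction, population) == pytest.approx(expected)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            extrapolate_population(-0.1, 1e9)
        with pytest.raises(ValueError):
            extrapolate_population(0.1, -5)


class TestDiminishingReturns:
    @pytest.mark.parametrize("mode", ["awareness", "access"])
    def test_equal_increments_buy_less_each_time(self, evidence, config, mode):
        result = run_experiment(ScenarioSpec(mode, GRID), evidence, config)
        decreasing, increments = diminishing_returns(result)
        assert decreasing
        assert np.all(np.diff(increments) < 0)

    def test_constant_reduction_series_is_not_diminishing(self):
        table = pd.DataFrame(
            {
                "delta_pct": [0.0, 4.0, 8.0, 12.0],
                "suicide_probability_pct": [6.4, 6.3, 6.2, 6.1],
                "reduction_vs_baseline_pct": [0.0, 0.1, 0.2, 0.3],
                "reduction_vs_previous_pct": [0.0, 0.1, 0.1, 0.1],
            }
        )
        result = ScenarioResult(mode="awareness", baseline_pct=6.4, table=table)
        decreasing, increments = diminishing_returns(result)
        assert not decreasing

    def test_unequal_spacing_is_rejected(self, evidence, config):
        result = run_experiment(ScenarioSpec("access", (0.01, 0.04, 0.05)), evidence, config)
        with pytest.raises(ValueError, match="spaced"):
            diminishing_returns(result)
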