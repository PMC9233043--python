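"""Scenario generators, oracle/fixed-dose rules, metrics, study loop."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from optidose import (
    FixedDoseModel,
    StudyConfig,
    UtilityConfig,
    UtilityMatrix,
    default_grid,
    evaluate_doses,
    generate_dataset,
    oracle_doses,
    pct_improvement,
    run_study,
    scenario_spec,
    true_joint,
    true_joint_curves,
    true_marginals,
)
from optidose.simulate import split_table
from optidose.utility import expected_utility, select_dose_pointwise


class TestTruth:
    def test_scenario1_coefficients_pinned(self, s1_spec):
        np.testing.assert_allclose(s1_spec.beta_x_e, [0.49, -1.11, 0.77, 1.51, 0.0])
        np.testing.assert_allclose(s1_spec.beta_dx_e, [0.23, 0.61, 0.0, 1.69, 0.5])
        np.testing.assert_allclose(s1_spec.beta_x_t, [0.0, 1.14, -0.33, 0.0, 0.0])
        np.testing.assert_allclose(s1_spec.beta_dx_t, [0.03, 0.6, 0.0, -0.42, 1.04])
        assert (s1_spec.beta0_e, s1_spec.beta0_t, s1_spec.alpha) == (0.0, -1.386, 0.8)

    def test_marginals_at_origin(self, s1_spec):
        p_e, p_t = true_marginals(s1_spec, np.zeros((1, 5)), np.array([0.0]))
        assert p_e[0] == pytest.approx(0.5)
        assert p_t[0] == pytest.approx(ndtr(-1.386), abs=1e-12)

    def test_joint_satisfies_frechet(self, s1_spec):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 5))
        joint = true_joint(s1_spec, x, rng.uniform(-1, 1, 50))
        p_e = joint[:, 1] + joint[:, 3]
        p_t = joint[:, 2] + joint[:, 3]
        assert np.all(joint[:, 3] <= np.minimum(p_e, p_t) + 1e-9)
        assert np.all(joint[:, 3] >= np.maximum(0, p_e + p_t - 1) - 1e-9)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            scenario_spec("S99")


class TestGeneration:
    def test_constraints_hold_and_rejection_bounded(self, s1_spec):
        """All retained covariates satisfy both printed linear constraints;
        the rejection fraction stays below 45%."""
        table, rejection = generate_dataset(s1_spec, 10_000, np.random.default_rng(42))
        x = table[[f"x{i}" for i in range(1, 6)]].to_numpy()
        c1 = 1 + 0.23 * x[:, 0] + 0.61 * x[:, 1] + 1.69 * x[:, 3] + 0.5 * x[:, 4]
        c2 = 1 + 0.03 * x[:, 0] + 0.6 * x[:, 1] - 0.42 * x[:, 3] + 1.04 * x[:, 4]
        assert np.all(c1 > 0) and np.all(c2 > 0)
        assert rejection <= 0.45

    def test_outcome_rates_in_stated_ranges(self, s1_spec):
        table, _ = generate_dataset(s1_spec, 20_000, np.random.default_rng(4243))
        assert 0.5 <= table["E"].mean() <= 0.7
        assert 0.1 <= table["T"].mean() <= 0.3

    def test_determinism(self, s1_spec):
        a, _ = generate_dataset(s1_spec, 100, np.random.default_rng(7))
        b, _ = generate_dataset(s1_spec, 100, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_outcome_correlation_positive(self, s1_spec):
        """alpha=0.8 induces positive E/T association beyond the marginals."""
        table, _ = generate_dataset(s1_spec, 20_000, np.random.default_rng(44))
        x = table[[f"x{i}" for i in range(1, 6)]].to_numpy()
        p_e, p_t = true_marginals(s1_spec, x, table["dose"].to_numpy())
        p11_indep = float(np.mean(p_e * p_t))
        p11_obs = float((table["E"] & table["T"]).mean())
        assert p11_obs > p11_indep + 0.02

    def test_noise_covariates_appended(self):
        spec = scenario_spec("S4")
        table, _ = generate_dataset(spec, 50, np.random.default_rng(1))
        assert sum(c.startswith("x") for c in table.columns) == 20

    def test_scenario0_needs_no_rejection(self):
        spec = scenario_spec("S0")
        _, rejection = generate_dataset(spec, 500, np.random.default_rng(2))
        assert rejection == 0.0

    def test_s8_interaction_terms_shift_truth(self):
        s8 = scenario_spec("S8")
        x = np.ones((1, 5))
        pe1, _ = true_marginals(scenario_spec("S1"), x, np.array([0.0]))
        pe8, _ = true_marginals(s8, x, np.array([0.0]))
        assert pe8[0] != pytest.approx(pe1[0])

    def test_binary_law(self):
        spec = scenario_spec("S7")
        table, _ = generate_dataset(spec, 200, np.random.default_rng(3))
        x = table[[f"x{i}" for i in range(1, 6)]].to_numpy()
        assert set(np.unique(x)) <= {0.0, 1.0}


class TestOracle:
    def test_dominates_any_other_rule(self, s1_spec, u1_cfg):
        """Per-patient oracle utility >= utility of any other dose."""
        rng = np.random.default_rng(5)
        table, _ = generate_dataset(s1_spec, 50, rng)
        x = table[[f"x{i}" for i in range(1, 6)]].to_numpy()
        grid = default_grid(51)
        d_opt = oracle_doses(s1_spec, x, grid, u1_cfg)
        u_opt = expected_utility(true_joint(s1_spec, x, d_opt), u1_cfg.matrix, validate=False)
        for d_alt in grid[[0, 12, 25, 38, 50]]:
            u_alt = expected_utility(
                true_joint(s1_spec, x, np.full(50, d_alt)), u1_cfg.matrix, validate=False
            )
            assert np.all(u_opt >= u_alt - 1e-12)

    def test_u2_doses_insensitive_to_copula(self, s1_spec, u2_cfg):
        """With omega1+omega2=1 the p11 term cancels: oracle doses computed
        under alpha=0.8 and under independence coincide."""
        from dataclasses import replace

        rng = np.random.default_rng(6)
        table, _ = generate_dataset(s1_spec, 40, rng)
        x = table[[f"x{i}" for i in range(1, 6)]].to_numpy()
        grid = default_grid(101)
        d_cop = oracle_doses(s1_spec, x, grid, u2_cfg)
        d_ind = oracle_doses(replace(s1_spec, alpha=0.0), x, grid, u2_cfg)
        np.testing.assert_allclose(d_cop, d_ind)


class TestFixedDose:
    def test_consistency_on_dose_only_truth(self):
        """With a dose-only truth whose utility peaks inside the grid, the
        estimated fixed dose converges to the population optimum."""
        spec = scenario_spec("S0")
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5))
        grid = default_grid(201)
        # population optimum under the truth
        curves = true_joint_curves(spec, np.zeros((1, 5)), grid)
        d_star, _ = select_dose_pointwise(curves[0], grid, cfg)
        table, _ = generate_dataset(spec, 20_000, np.random.default_rng(8))
        model = FixedDoseModel().fit(table["dose"].to_numpy(), table[["E", "T"]].to_numpy())
        assert abs(model.optimal_fixed_dose(grid, cfg) - d_star) <= 0.1

    def test_needs_enough_rows(self):
        with pytest.raises(ValueError):
            FixedDoseModel().fit(np.zeros(10), np.zeros((10, 2), dtype=int))

    def test_curve_is_valid_joint(self, s1_spec):
        table, _ = generate_dataset(s1_spec, 300, np.random.default_rng(9))
        model = FixedDoseModel().fit(table["dose"].to_numpy(), table[["E", "T"]].to_numpy())
        curve = model.predict_joint_curve(default_grid(21))
        np.testing.assert_allclose(curve.sum(axis=1), 1.0, atol=1e-9)


class TestMetrics:
    def test_spot_check_three_patients(self, s1_spec, u1_cfg):
        x = np.array([[0.0] * 5, [0.5, -0.2, 0.1, 0.3, 0.0], [1.0, 0.0, 0.0, 0.0, 0.0]])
        doses = np.array([0.2, -0.4, 0.9])
        m = evaluate_doses(s1_spec, x, doses, u1_cfg)
        p_e, p_t = true_marginals(s1_spec, x, doses)
        joint = true_joint(s1_spec, x, doses)
        assert m.mean_dose == pytest.approx(doses.mean())
        assert m.sd_dose == pytest.approx(doses.std(ddof=1))
        assert m.mean_e == pytest.approx(p_e.mean(), abs=1e-9)
        assert m.mean_t == pytest.approx(p_t.mean(), abs=1e-9)
        assert m.mean_utility == pytest.approx(
            100 * expected_utility(joint, u1_cfg.matrix).mean(), abs=1e-9
        )

    def test_constant_rule_sd_zero(self, s1_spec, u1_cfg):
        x = np.random.default_rng(10).normal(size=(20, 5))
        m = evaluate_doses(s1_spec, x, np.full(20, 0.3), u1_cfg)
        assert m.sd_dose == pytest.approx(0.0, abs=1e-12)

    def test_pct_improvement_definition(self):
        assert pct_improvement(66.1, 58.7, 66.1) == pytest.approx(100.0)
        assert pct_improvement(58.7, 58.7, 66.1) == pytest.approx(0.0)
        assert pct_improvement(62.4, 58.7, 66.1) == pytest.approx(50.0)
        assert np.isnan(pct_improvement(1.0, 2.0, 2.0))


class TestStudyLoop:
    def test_smoke_run_emits_all_columns(self):
        cfg = StudyConfig(
            scenario="S1",
            n_train=120,
            n_valid=60,
            utilities=((0.3, 0.5),),
            methods=("M1", "M2", "M3", "M12"),
            replications=2,
            seed=123,
            grid_points=21,
            rf_params=dict(n_estimators=60),
        )
        out = run_study(cfg)
        assert set(out["method"]) == {"M1", "M2", "M3", "M12"}
        for col in ("mean_dose", "sd_dose", "mean_E", "mean_T", "mean_utility", "pct_improvement"):
            assert col in out.columns
        assert out.loc[out.method == "M1", "pct_improvement"].item() == pytest.approx(100.0)
        assert out.loc[out.method == "M12", "pct_improvement"].item() == pytest.approx(0.0)
        assert out.loc[out.method == "M12", "sd_dose"].item() == pytest.approx(0.0, abs=1e-12)

    def test_identical_seed_identical_metrics(self):
        cfg = dict(
            scenario="S1", n_train=80, n_valid=40, utilities=((0.5, 0.5),),
            methods=("M1", "M12"), replications=2, seed=5, grid_points=11,
        )
        a = run_study(StudyConfig(**cfg))
        b = run_study(StudyConfig(**cfg))
        pd.testing.assert_frame_equal(a, b)

    def test_modified_rules_and_pava_methods_run(self):
        cfg = StudyConfig(
            scenario="S1", n_train=100, n_valid=40, utilities=((0.3, 0.5),),
            methods=("M1", "M4", "M5", "M6", "M7", "M8", "M9", "M12"),
            replications=1, seed=77, grid_points=11,
            rf_params=dict(n_estimators=40),
        )
        out = run_study(cfg)
        assert len(out) == 8
        assert out["mean_utility"].between(0, 100).all()
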