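"""Utility matrices, utility functions, and dose-selection rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optidose import (
    UtilityConfig,
    UtilityMatrix,
    default_grid,
    expected_utility,
    select_dose_pointwise,
    select_dose_posterior_mean,
    select_dose_posterior_prob,
    utility_dose_penalty,
    utility_tox_cap,
)
from optidose.copula import joint_from_marginals

from conftest import random_joint


class TestUtilityMatrix:
    def test_canonical_constructor(self):
        m = UtilityMatrix.from_omegas(0.3, 0.5)
        assert (m.u00, m.u10, m.u01, m.u11) == (0.3, 1.0, 0.0, 0.5)

    def test_theta_form(self):
        m = UtilityMatrix.from_theta(0.7)
        assert (m.u00, m.u10, m.u01, m.u11) == (0.0, 1.0, -0.7, pytest.approx(0.3))

    @pytest.mark.parametrize("w1,w2", [(0.0, 0.5), (1.0, 0.5), (0.5, -0.1), (0.5, 1.2)])
    def test_omegas_out_of_range_rejected(self, w1, w2):
        with pytest.raises(ValueError):
            UtilityMatrix.from_omegas(w1, w2)

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            UtilityMatrix(u00=0.5, u10=0.4, u01=0.0, u11=0.3)


class TestExpectedUtility:
    def test_uniform_joint(self):
        m = UtilityMatrix.from_omegas(0.3, 0.5)
        assert expected_utility(np.full(4, 0.25), m) == pytest.approx(0.45)

    def test_two_forms_agree(self):
        """Matrix-weighted sum equals the expanded pE/pT/p11 form."""
        rng = np.random.default_rng(0)
        joint = random_joint(rng, shape=200)
        w1, w2 = 0.37, 0.61
        m = UtilityMatrix.from_omegas(w1, w2)
        p_e = joint[:, 1] + joint[:, 3]
        p_t = joint[:, 2] + joint[:, 3]
        expanded = w1 + (1 - w1) * p_e - w1 * p_t + (w1 + w2 - 1) * joint[:, 3]
        np.testing.assert_allclose(expected_utility(joint, m), expanded, atol=1e-12)

    def test_p11_invariance_when_omegas_sum_to_one(self):
        """With omega1+omega2=1 only the marginals matter: vary p11 inside
        its Frechet interval holding (pE, pT) fixed."""
        rng = np.random.default_rng(1)
        m = UtilityMatrix.from_omegas(0.3, 0.7)
        for _ in range(50):
            p_e, p_t = rng.uniform(0.05, 0.95, size=2)
            lo, hi = max(0.0, p_e + p_t - 1.0), min(p_e, p_t)
            vals = []
            for p11 in np.linspace(lo, hi, 7):
                joint = np.array([1 - p_e - p_t + p11, p_e - p11, p_t - p11, p11])
                vals.append(expected_utility(joint, m))
            np.testing.assert_allclose(vals, vals[0], atol=1e-12)

    def test_invalid_joint_rejected(self):
        m = UtilityMatrix.from_omegas(0.5, 0.5)
        with pytest.raises(ValueError):
            expected_utility(np.array([0.5, 0.5, 0.5, -0.5]), m)
        with pytest.raises(ValueError):
            expected_utility(np.array([0.3, 0.3, 0.3, 0.3]), m)

    def test_constant_shift_moves_utility_not_argmax(self, grid21):
        rng = np.random.default_rng(2)
        curve = random_joint(rng, shape=grid21.size)
        m = UtilityMatrix.from_omegas(0.4, 0.6)
        cfg = UtilityConfig(matrix=m)
        cfg_shift = UtilityConfig(matrix=m.shifted(2.5))
        d0, prof0 = select_dose_pointwise(curve, grid21, cfg)
        d1, prof1 = select_dose_pointwise(curve, grid21, cfg_shift)
        np.testing.assert_allclose(prof1, prof0 + 2.5, atol=1e-12)
        assert d0 == d1


class TestModifiedUtilities:
    def test_tox_cap_inclusive_at_threshold(self):
        """pT exactly at 0.3 triggers the penalty 2*omega1*pT."""
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5), rule="tox_cap")
        joint = np.array([0.5, 0.2, 0.1, 0.2])  # pT = 0.3
        base = expected_utility(joint, cfg.matrix)
        assert utility_tox_cap(joint, cfg) == pytest.approx(base - 2 * 0.5 * 0.3)

    def test_tox_cap_off_below_threshold(self):
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5), rule="tox_cap")
        joint = np.array([0.51, 0.2, 0.09, 0.2])  # pT = 0.29
        assert utility_tox_cap(joint, cfg) == pytest.approx(
            expected_utility(joint, cfg.matrix)
        )

    def test_tox_cap_hand_value(self):
        # pE=0.8, pT=0.4, p11=0.32: base U = 0.5+0.5*0.8-0.5*0.4 = 0.7;
        # penalty 2*0.5*0.4 = 0.4
        joint = np.array([0.12, 0.48, 0.08, 0.32])
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5), rule="tox_cap")
        assert utility_tox_cap(joint, cfg) == pytest.approx(0.3)

    def test_dose_penalty(self):
        m = UtilityMatrix.from_omegas(0.5, 0.5)
        joint = np.array([0.3, 0.4, 0.1, 0.2])
        base = expected_utility(joint, m)
        cfg = UtilityConfig(matrix=m, rule="dose_penalty", delta=0.1, d_fix=0.2)
        assert utility_dose_penalty(joint, 0.2, cfg) == pytest.approx(base)
        assert utility_dose_penalty(joint, 1.2, cfg) == pytest.approx(base - 0.1)
        cfg0 = UtilityConfig(matrix=m, rule="dose_penalty", delta=0.0, d_fix=0.2)
        assert utility_dose_penalty(joint, -0.9, cfg0) == pytest.approx(base)

    def test_dose_penalty_requires_d_fix(self):
        with pytest.raises(ValueError):
            UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5), rule="dose_penalty")


class TestPointwiseRule:
    def test_brute_force_oracle(self, grid21):
        """Grid argmax must equal exhaustive enumeration on random curves."""
        rng = np.random.default_rng(3)
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.35, 0.55))
        for _ in range(25):
            curve = random_joint(rng, shape=grid21.size)
            dose, profile = select_dose_pointwise(curve, grid21, cfg)
            brute = [expected_utility(curve[i], cfg.matrix) for i in range(grid21.size)]
            assert dose == grid21[int(np.argmax(brute))]
            np.testing.assert_allclose(profile, brute, atol=1e-12)

    def test_tie_break_lowest_dose(self, grid21):
        curve = np.tile(np.array([0.25, 0.25, 0.25, 0.25]), (grid21.size, 1))
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5))
        dose, _ = select_dose_pointwise(curve, grid21, cfg)
        assert dose == grid21[0]

    def test_increasing_utility_selects_max_dose(self, grid21):
        p_e = np.linspace(0.1, 0.9, grid21.size)
        curve = joint_from_marginals(p_e, np.full(grid21.size, 0.1), 0.0)
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5))
        dose, _ = select_dose_pointwise(curve, grid21, cfg)
        assert dose == grid21[-1]

    def test_scenario1_stationary_point(self, s1_spec):
        """At x=0 under utility 2 the optimum solves phi(d)=phi(d-1.386),
        i.e. d = 1.386/2."""
        from optidose import oracle_doses

        grid = default_grid(2001)
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5))
        dose = oracle_doses(s1_spec, np.zeros((1, 5)), grid, cfg)[0]
        assert dose == pytest.approx(0.693, abs=1.5e-3)

    def test_empty_grid_rejected(self):
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5))
        with pytest.raises(ValueError):
            select_dose_pointwise(np.zeros((0, 4)), np.array([]), cfg)


class TestPosteriorRules:
    def _draws(self, rng, s, d):
        return random_joint(rng, shape=(s, d))

    def test_single_draw_reduces_to_pointwise(self, grid21):
        rng = np.random.default_rng(4)
        draws = self._draws(rng, 1, grid21.size)
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.4, 0.5))
        d_post, _ = select_dose_posterior_mean(draws, grid21, cfg)
        d_point, _ = select_dose_pointwise(draws[0], grid21, cfg)
        assert d_post == d_point

    def test_symmetric_draws_match_mean_curve(self, grid21):
        """Utility is linear in the cells, so +/- symmetric noise around a
        mean curve leaves the posterior-mean argmax at the mean curve's."""
        rng = np.random.default_rng(5)
        base = random_joint(rng, shape=grid21.size)
        noise = rng.normal(0, 0.01, size=(30, grid21.size, 4))
        noise -= noise.mean(axis=-1, keepdims=True)
        draws = np.concatenate([base + noise, base - noise])
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.4, 0.5))
        d_post, _ = select_dose_posterior_mean(draws, grid21, cfg, validate=False)
        d_mean, _ = select_dose_pointwise(base, grid21, cfg, validate=False)
        assert d_post == d_mean

    def test_posterior_mean_two_doses(self):
        grid = np.array([-1.0, 1.0])
        draws = np.array([[[0.6, 0.2, 0.1, 0.1], [0.2, 0.6, 0.1, 0.1]]])
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5))
        dose, _ = select_dose_posterior_mean(draws, grid, cfg)
        assert dose == 1.0

    def test_posterior_prob_increasing_utility(self):
        """Identical draws with utility increasing in dose: every dose above
        d_fix wins with probability 1; the lowest such dose is returned."""
        grid = np.array([-1.0, 0.0, 1.0])
        p_e = np.array([0.2, 0.5, 0.8])
        curve = joint_from_marginals(p_e, np.full(3, 0.1), 0.0)
        draws = np.tile(curve, (10, 1, 1))
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5), d_fix=-1.0)
        dose, prob = select_dose_posterior_prob(draws, grid, cfg)
        np.testing.assert_allclose(prob, [0.0, 1.0, 1.0])
        assert dose == 0.0

    def test_posterior_prob_degenerate_all_below(self):
        """When no dose ever beats d_fix the probability is 0 everywhere and
        the tie-break returns the lowest grid dose."""
        grid = np.array([-1.0, 0.0, 1.0])
        p_e = np.array([0.2, 0.9, 0.2])
        curve = joint_from_marginals(p_e, np.full(3, 0.1), 0.0)
        draws = np.tile(curve, (5, 1, 1))
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5), d_fix=0.0)
        dose, prob = select_dose_posterior_prob(draws, grid, cfg)
        np.testing.assert_allclose(prob, 0.0)
        assert dose == -1.0

    def test_posterior_prob_majority_wins(self):
        grid = np.array([-1.0, 0.0, 1.0])
        lo = joint_from_marginals(np.array([0.3, 0.4, 0.2]), np.full(3, 0.1), 0.0)
        hi = joint_from_marginals(np.array([0.3, 0.9, 0.4]), np.full(3, 0.1), 0.0)
        # dose 0 beats d_fix in all draws; dose 1 only in half
        draws = np.stack([hi] * 5 + [lo] * 5)
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5), d_fix=-1.0)
        dose, prob = select_dose_posterior_prob(draws, grid, cfg)
        assert dose == 0.0
        assert prob[1] == 1.0 and prob[2] < 1.0

    def test_no_draws_rejected(self, grid21):
        cfg = UtilityConfig(matrix=UtilityMatrix.from_omegas(0.5, 0.5), d_fix=0.0)
        with pytest.raises(ValueError):
            select_dose_posterior_prob(np.zeros((0, grid21.size, 4)), grid21, cfg)


@settings(max_examples=50, deadline=None)
@given(
    cells=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
    w1=st.floats(0.05, 0.95),
    w2=st.floats(0.05, 0.95),
)
def test_expected_utility_bounded_by_matrix_range(cells, w1, w2):
    """The expectation of the utility matrix lies between its extreme cells."""
    joint = np.array(cells) / np.sum(cells)
    m = UtilityMatrix.from_omegas(w1, w2)
    u = expected_utility(joint, m)
    assert m.u01 - 1e-12 <= u <= m.u10 + 1e-12
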