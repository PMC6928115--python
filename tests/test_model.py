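"""Model densities, the stimuli equation, and the complete-data log-likelihood."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from mtssm.model import (
    DesignError,
    DesignSpec,
    ModelParams,
    attraction_prob,
    complete_data_loglik,
    mixture_logdensity,
    stimuli_equation,
    transition_logdensity,
    vonmises_logdensity,
)


def i0_series(kappa, n_terms=60):
    """Power-series oracle for the modified Bessel function of order zero."""
    total = 0.0
    for m in range(n_terms):
        total += (kappa / 2.0) ** (2 * m) / (math.factorial(m) ** 2)
    return total


class TestTransition:
    def test_standard_normal_at_zero_displacement(self):
        assert transition_logdensity(0.3, 0.3, 1.0) == pytest.approx(
            np.log(1.0 / np.sqrt(2 * np.pi))
        )

    def test_unit_displacement(self):
        assert transition_logdensity(1.0, 0.0, 1.0) == pytest.approx(-0.9189385 - 0.5)

    def test_symmetric_in_arguments(self):
        assert transition_logdensity(1.7, -0.4, 0.8) == pytest.approx(
            transition_logdensity(-0.4, 1.7, 0.8)
        )

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            transition_logdensity(0.0, 0.0, 0.0)


class TestVonMises:
    def test_uniform_at_zero_concentration(self):
        assert vonmises_logdensity(1.234, 0.5, 0.0) == pytest.approx(-np.log(2 * np.pi))

    def test_mode_value_against_series_oracle(self):
        # density at y = mu, kappa = 2: e^2 / (2 pi I0(2))
        expected = np.log(np.exp(2.0) / (2 * np.pi * i0_series(2.0)))
        assert vonmises_logdensity(0.7, 0.7, 2.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("kappa", [0.1, 1.0, 10.0, 100.0])
    def test_matches_quadrature_normalized_oracle(self, kappa):
        mu = 0.3
        Z, _ = quad(lambda y: np.exp(kappa * np.cos(y - mu)), -np.pi, np.pi)
        for y in (0.0, 0.3, 1.5, 3.0):
            oracle = kappa * np.cos(y - mu) - np.log(Z)
            assert vonmises_logdensity(y, mu, kappa) == pytest.approx(oracle, abs=1e-10)

    def test_integrates_to_one(self):
        val, _ = quad(lambda y: np.exp(vonmises_logdensity(y, 1.0, 5.0)), 0, 2 * np.pi)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            vonmises_logdensity(0.0, 0.0, -1.0)


class TestMixture:
    params = ModelParams(gamma=np.zeros(1), kappa1=3.0, kappa2=7.0, mu1=2.3, mu2=0.8)

    def test_pure_components(self):
        y = 1.1
        assert mixture_logdensity(y, 1.0, self.params) == pytest.approx(
            vonmises_logdensity(y, self.params.mu1, self.params.kappa1)
        )
        assert mixture_logdensity(y, 0.0, self.params) == pytest.approx(
            vonmises_logdensity(y, self.params.mu2, self.params.kappa2)
        )

    def test_identical_components_collapse(self):
        p = ModelParams(gamma=np.zeros(1), kappa1=4.0, kappa2=4.0, mu1=1.0, mu2=1.0)
        assert mixture_logdensity(0.4, 0.5, p) == pytest.approx(
            vonmises_logdensity(0.4, 1.0, 4.0)
        )

    def test_bounded_by_component_logdensities(self):
        y = np.linspace(0, np.pi, 30)
        l1 = vonmises_logdensity(y, self.params.mu1, self.params.kappa1)
        l2 = vonmises_logdensity(y, self.params.mu2, self.params.kappa2)
        lm = mixture_logdensity(y, 0.37, self.params)
        assert np.all(lm >= np.minimum(l1, l2) - 1e-12)
        assert np.all(lm <= np.maximum(l1, l2) + 1e-12)

    def test_invalid_weight(self):
        with pytest.raises(ValueError):
            mixture_logdensity(1.0, 1.5, self.params)


class TestAttractionProb:
    def test_neutral_point(self):
        assert attraction_prob(0.0, 0.0) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert attraction_prob(500.0, 500.0) == pytest.approx(1.0)
        assert attraction_prob(-500.0, -500.0) == pytest.approx(0.0)

    def test_literal_link_value(self):
        # logistic at beta = 1.32, z = 0 under the literal convention
        assert attraction_prob(1.32, 0.0) == pytest.approx(1 / (1 + np.exp(-1.32)))

    def test_sign_convention_mirrors(self):
        z = np.linspace(-3, 3, 11)
        np.testing.assert_allclose(
            attraction_prob(0.7, z, sign_convention=-1),
            1.0 - attraction_prob(0.7, z, sign_convention=1),
        )

    def test_strictly_increasing_and_half_iff_sum_zero(self):
        z = np.linspace(-5, 5, 201)
        p = attraction_prob(1.2, z)
        assert np.all(np.diff(p) > 0)
        assert attraction_prob(1.2, -1.2) == pytest.approx(0.5)


class TestStimuliEquation:
    def test_categorical_selection_is_exact(self):
        design = DesignSpec.from_levels(["HF", "LF", "NW", "LF"])
        params = ModelParams(gamma=np.array([1.323, 1.337, 1.310]))
        beta = stimuli_equation(design, params)
        np.testing.assert_array_equal(beta, [1.323, 1.337, 1.310, 1.337])

    def test_covariate_only_zero_x(self):
        design = DesignSpec.from_levels(
            ["a", "b"], x=[0.0, 0.0], categorical=False, covariate=True
        )
        params = ModelParams(gamma=np.zeros(2), eta=0.078)
        np.testing.assert_array_equal(stimuli_equation(design, params), [0.0, 0.0])

    def test_full_model_arithmetic(self):
        design = DesignSpec.from_levels(
            ["L1"], x=[1.0], categorical=True, covariate=True, interaction=True
        )
        params = ModelParams(
            gamma=np.array([0.341]), delta=np.array([0.0]), eta=0.402
        )
        assert stimuli_equation(design, params)[0] == pytest.approx(0.743)

    def test_identity_partition_gives_per_trial_coefficients(self):
        J = 4
        design = DesignSpec(np.eye(J, dtype=int))
        gamma = np.array([0.1, -0.5, 2.0, 0.7])
        params = ModelParams(gamma=gamma, delta=np.zeros(J))
        np.testing.assert_array_equal(stimuli_equation(design, params), gamma)

    def test_missing_covariate_raises(self):
        with pytest.raises(DesignError):
            DesignSpec.from_levels(["a", "b"], covariate=True)

    def test_row_sum_violation_raises(self):
        with pytest.raises(DesignError):
            DesignSpec(np.array([[1, 1], [1, 0]]))


class TestCompleteDataLoglik:
    def test_two_term_hand_computation(self):
        # I = J = 1, N = 1, identical components: the measurement part does
        # not depend on Z, so the value decomposes into hand-computable sums
        p = ModelParams(gamma=np.array([0.3]), kappa1=2.0, kappa2=2.0, mu1=1.0, mu2=1.0)
        design = DesignSpec.from_levels(["a"])
        Z = np.array([[0.5, 1.2]])
        Y = np.array([[[0.8, 1.6]]])
        expected = (
            transition_logdensity(0.5, 0.0, 1.0)  # initial-state prior N(0, 1)
            + transition_logdensity(1.2, 0.5, 1.0)
            + vonmises_logdensity(0.8, 1.0, 2.0)
            + vonmises_logdensity(1.6, 1.0, 2.0)
        )
        assert complete_data_loglik(Z, Y, design, p) == pytest.approx(float(expected))

    def test_uniform_measurement_shift_invariance(self):
        rng = np.random.default_rng(1)
        p = ModelParams(gamma=np.array([0.3]), kappa1=1e-12, kappa2=1e-12)
        design = DesignSpec.from_levels(["a", "a"])
        Z = rng.normal(size=(2, 5))
        Y = rng.uniform(0, np.pi - 0.4, size=(2, 2, 5))
        assert complete_data_loglik(Z, Y, design, p) == pytest.approx(
            complete_data_loglik(Z, Y + 0.4, design, p)
        )

    def test_duplicate_trial_adds_measurement_only(self):
        rng = np.random.default_rng(2)
        p = ModelParams(gamma=np.array([0.4]), kappa1=5.0, kappa2=9.0)
        Z = rng.normal(size=(1, 6))
        y = rng.uniform(0, np.pi, size=(1, 1, 6))
        d1 = DesignSpec.from_levels(["a"])
        d2 = DesignSpec.from_levels(["a", "a"])
        single = complete_data_loglik(Z, y, d1, p)
        doubled = complete_data_loglik(Z, np.concatenate([y, y], axis=1), d2, p)
        beta = stimuli_equation(d1, p)
        pi = attraction_prob(beta[0], Z[0])
        meas = mixture_logdensity(y[0, 0], pi, p).sum()
        assert doubled == pytest.approx(single + meas)

    def test_per_trial_state_prior_flag(self):
        rng = np.random.default_rng(3)
        p = ModelParams(gamma=np.array([0.4]), kappa1=5.0, kappa2=9.0)
        Z = rng.normal(size=(1, 4))
        Y = rng.uniform(0, np.pi, size=(1, 2, 4))
        design = DesignSpec.from_levels(["a", "a"])
        once = complete_data_loglik(Z, Y, design, p)
        literal = complete_data_loglik(Z, Y, design, p, per_trial_state_prior=True)
        state = (
            transition_logdensity(Z[0, 0], 0.0, 1.0)
            + transition_logdensity(Z[0, 1:], Z[0, :-1], 1.0).sum()
        )
        assert literal - once == pytest.approx(float(state))


class TestDesignFile:
    def test_read_design_maps_levels_in_first_appearance_order(self, tmp_path):
        from mtssm.model import read_design

        path = tmp_path / "design.csv"
        path.write_text(
            "trial,level,x\n"
            "t1,LF,0.5\n"
            "t2,HF,-0.2\n"
            "t3,LF,1.0\n"
            "t4,NW,0.0\n"
        )
        design = read_design(path, covariate=True)
        assert design.level_labels == ("LF", "HF", "NW")
        np.testing.assert_array_equal(
            design.D, [[1, 0, 0], [0, 1, 0], [1, 0, 0], [0, 0, 1]]
        )
        np.testing.assert_array_equal(design.x, [0.5, -0.2, 1.0, 0.0])

    def test_read_design_without_covariate_column(self, tmp_path):
        from mtssm.model import read_design

        path = tmp_path / "design.csv"
        path.write_text("trial,level\nt1,a\nt2,b\n")
        design = read_design(path)
        assert design.x is None
        assert design.n_levels == 2
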