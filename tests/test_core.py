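"""Link function, transition kernel and emission structure."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from registercr import (
    CoefficientSet,
    LatentState,
    ModelConfig,
    emission_probs,
    logistic_link,
    transition_kernel,
)
from registercr.core import build_design_row, covariate_names

from conftest import intercept_only_params

P, A, D = LatentState.PRESENT, LatentState.ABSENT, LatentState.DEAD


class TestLogisticLink:
    def test_zero_linear_predictor_gives_half(self):
        assert logistic_link(np.zeros(3), np.ones(3) * 0.0) == 0.5

    def test_known_value(self):
        # 1 / (1 + e^{1.5}), high-precision reference
        got = logistic_link(np.array([1.0, 0.5]), np.array([-1.0, -1.0]))
        assert got == pytest.approx(0.182425523806356, abs=1e-12)

    def test_saturation_no_overflow(self):
        assert logistic_link(np.array([745.0]), np.array([1.0])) == \
            pytest.approx(1.0, abs=1e-300)
        assert logistic_link(np.array([-745.0]), np.array([1.0])) == \
            pytest.approx(0.0, abs=1e-300)

    def test_dimension_mismatch_names_lengths(self):
        with pytest.raises(ValueError, match="3.*2|2.*3"):
            logistic_link(np.ones(3), np.ones(2))

    @given(st.floats(-20, 20), st.floats(-20, 20), st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_coefficient(self, b0, b1, db):
        x = np.array([1.0, 2.0])
        lo = logistic_link(x, np.array([b0, b1]))
        hi = logistic_link(x, np.array([b0 + db, b1]))
        assert hi >= lo


class TestTransitionKernel:
    def test_dead_is_absorbing(self):
        params = intercept_only_params(0.5, 0.5, 0.5, 0.5, [0.5])
        out = transition_kernel(D, np.array([1.0]), params)
        assert out == {P: 0.0, A: 0.0, D: 1.0}

    def test_two_stage_factorization(self):
        # survival 0.9 then stay 0.8: P -> {P: .72, A: .18, D: .1}
        params = intercept_only_params(0.9, 0.8, 0.3, 0.5, [0.5])
        out = transition_kernel(P, np.array([1.0]), params)
        assert out[P] == pytest.approx(0.72, abs=1e-12)
        assert out[A] == pytest.approx(0.18, abs=1e-12)
        assert out[D] == pytest.approx(0.10, abs=1e-12)

    def test_certain_survival_no_return(self):
        params = intercept_only_params(1.0, 0.5, 0.0, 0.5, [0.5])
        out = transition_kernel(A, np.array([1.0]), params)
        assert out[A] == 1.0 and out[P] == 0.0 and out[D] == 0.0

    @given(st.integers(0, 2), st.lists(st.floats(-3, 3), min_size=4,
                                       max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_rows_sum_to_one(self, state_idx, coefs):
        rng = np.random.default_rng(abs(hash(tuple(coefs))) % 2**31)
        p = 2
        params = CoefficientSet(*[rng.normal(0, 1.5, p) for _ in range(4)],
                                [rng.normal(0, 1.5, p)])
        x = np.array([1.0, coefs[0]])
        out = transition_kernel(LatentState(state_idx), x, params)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)


class TestEmissionProbs:
    def test_present_detection_product(self):
        params = intercept_only_params(0.9, 0.9, 0.1, 0.3, [0.7, 0.4])
        x = np.array([1.0])
        got = emission_probs(P, P, x, params, np.array([1, 0]))
        assert got == pytest.approx(0.7 * 0.6, abs=1e-12)

    def test_deregistration_probability(self):
        params = intercept_only_params(0.9, 0.9, 0.1, 0.3, [0.7, 0.4])
        x = np.array([1.0])
        assert emission_probs(P, A, x, params, np.zeros(2), e_flag=1) == \
            pytest.approx(0.3, abs=1e-12)

    def test_silent_absence_emits_nothing(self):
        params = intercept_only_params(0.9, 0.9, 0.1, 0.3, [0.7, 0.4])
        assert emission_probs(A, A, np.array([1.0]), params, np.zeros(2)) == 1.0

    def test_detection_impossible_when_not_present(self):
        params = intercept_only_params(0.9, 0.9, 0.1, 0.3, [0.7, 0.4])
        x = np.array([1.0])
        for pair in [(P, A), (A, A), (P, D), (A, D), (D, D)]:
            assert emission_probs(*pair, x, params, np.array([1, 0])) == 0.0

    @pytest.mark.parametrize("n_lists", [1, 2, 4])
    @pytest.mark.parametrize(
        "pair", [(P, P), (A, P), (P, A), (A, A), (P, D), (A, D), (D, D)])
    def test_record_enumeration_sums_to_one(self, n_lists, pair):
        """Summing over every possible observation record for a reachable
        state pair yields exactly 1."""
        rng = np.random.default_rng(7 + n_lists)
        params = CoefficientSet(*[rng.normal(0, 1, 1) for _ in range(4)],
                                [rng.normal(0, 1, 1) for _ in range(n_lists)])
        x = np.array([1.0])
        total = 0.0
        for obs in itertools.product([0, 1], repeat=n_lists):
            for e in (0, 1):
                for d in (0, 1):
                    total += emission_probs(*pair, x, params,
                                            np.array(obs), e, d)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestCovariateEncoding:
    def test_intercept_first_and_reference_all_zero(self):
        cfg = ModelConfig()
        x = build_design_row(cfg, sex_female=0, age=35.0,
                             country_group="Western Europe", tsm=0)
        assert x[0] == 1.0
        assert np.all(x[3:9] == 0.0)  # reference level indicators

    def test_exactly_one_country_indicator(self):
        cfg = ModelConfig()
        x = build_design_row(cfg, 1, 40.0, "MENA", 3)
        assert x[3:9].sum() == 1.0

    def test_negative_tsm_rejected(self):
        with pytest.raises(ValueError, match="time since first migration"):
            build_design_row(ModelConfig(), 0, 30.0, "MENA", -1)

    def test_covariate_names_match_dimension(self):
        for cfg in (ModelConfig(), ModelConfig(tsm_form="categorical")):
            assert len(covariate_names(cfg)) == cfg.n_covariates

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(n_lists=0)
        with pytest.raises(ValueError):
            ModelConfig(first_year=2010, last_year=2009)
        with pytest.raises(ValueError):
            ModelConfig(prior_variance=0.0)
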