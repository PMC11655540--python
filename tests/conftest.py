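"""Shared fixtures: small configurations, toy parameter sets, and a
generative random-record factory used by the enumeration-oracle tests."""

import numpy as np
import pytest

from registercr import CoefficientSet, ModelConfig, SimulationSpec, simulate_cohort
from registercr.likelihood import IndividualRecord


def intercept_only_params(phi, psi, eta, lam, thetas):
    """CoefficientSet with p=1 (intercept only) hitting the given
    probabilities exactly (on the logit scale, +/- saturation)."""
    def logit(p):
        p = min(max(p, 1e-12), 1 - 1e-12)
        return np.log(p / (1 - p)) if 0 < p < 1 else (800.0 if p >= 1 else -800.0)

    def enc(p):
        if p >= 1.0:
            return np.array([800.0])
        if p <= 0.0:
            return np.array([-800.0])
        return np.array([logit(p)])

    return CoefficientSet(enc(phi), enc(psi), enc(eta), enc(lam),
                          [enc(t) for t in thetas])


def make_random_record(rng, n_years, n_lists, p=3, coef_sd=0.8):
    """Simulate one record (with events) from the generative model under
    random covariates and coefficients; returns (record, mask, params).

    Because the record is drawn from the model itself, observations and
    events are always mutually consistent, while masks (forced present /
    absent / dead stretches) arise at random.
    """
    X = np.concatenate([np.ones((n_years, 1)),
                        rng.normal(0, 1, (n_years, p - 1))], axis=1)
    params = CoefficientSet(
        rng.normal(0, coef_sd, p), rng.normal(0, coef_sd, p),
        rng.normal(0, coef_sd, p), rng.normal(0, coef_sd, p),
        [rng.normal(0, coef_sd, p) for _ in range(n_lists)],
    )

    def prob(beta, t):
        return 1.0 / (1.0 + np.exp(-X[t] @ beta))

    obs = np.zeros((n_years, n_lists), dtype=np.int8)
    e_flag = np.zeros(n_years, dtype=np.int8)
    d_flag = np.zeros(n_years, dtype=np.int8)
    r_flag = np.zeros(n_years, dtype=np.int8)
    state = "P"
    deregistered = False
    for t in range(n_years):
        if t > 0 and state != "D":
            prev = state
            if rng.random() >= prob(params.beta_phi, t):
                state = "D"
                if prev == "P":
                    d_flag[t] = 1
            elif prev == "P":
                if rng.random() >= prob(params.beta_psi, t):
                    state = "A"
                    if rng.random() < prob(params.beta_lambda, t):
                        e_flag[t] = 1
                        deregistered = True
            else:
                if rng.random() < prob(params.beta_eta, t):
                    state = "P"
                    if deregistered:
                        r_flag[t] = 1
                        deregistered = False
        if state == "P":
            for l in range(n_lists):
                if rng.random() < prob(params.beta_o[l], t):
                    obs[t, l] = 1
    record = IndividualRecord(X=X, obs=obs, e_flag=e_flag, d_flag=d_flag,
                              r_flag=r_flag)
    return record, record.default_mask(), params


@pytest.fixture(scope="session")
def short_config():
    """Six-year window with four lists: the standard small test setup."""
    return ModelConfig(first_year=2003, last_year=2008, n_lists=4)


@pytest.fixture(scope="session")
def small_cohort(short_config):
    """A 400-individual simulated cohort shared across read-only tests."""
    spec = SimulationSpec(config=short_config, n_individuals=400)
    return simulate_cohort(spec, seed=1234)
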