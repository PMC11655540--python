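"""Generative simulator: determinism, degenerate regimes, and agreement of
empirical frequencies with the analytic kernel."""

import numpy as np
import pandas as pd
import pytest

from registercr import (
    ModelConfig,
    SimulationSpec,
    simulate_cohort,
    true_overcoverage,
)
from registercr.likelihood import _expit
from registercr.simulate import SimulatedCohort, recovery_coefficients

from conftest import intercept_only_params


def _flat_spec(config, n, phi, psi, eta, lam, thetas):
    """Spec with intercept-only-equivalent probabilities (covariate effects
    zeroed so every individual-year shares the same probabilities)."""
    params = intercept_only_params(phi, psi, eta, lam, thetas)
    p = config.n_covariates

    def pad(b):
        out = np.zeros(p)
        out[0] = b[0]
        return out

    from registercr import CoefficientSet
    coeffs = CoefficientSet(pad(params.beta_phi), pad(params.beta_psi),
                            pad(params.beta_eta), pad(params.beta_lambda),
                            [pad(b) for b in params.beta_o])
    return SimulationSpec(config=config, n_individuals=n, coefficients=coeffs)


def test_same_seed_reproduces_cohort_exactly(short_config):
    spec = SimulationSpec(config=short_config, n_individuals=200)
    a = simulate_cohort(spec, seed=5)
    b = simulate_cohort(spec, seed=5)
    for x, y in [(a.individuals, b.individuals),
                 (a.observations, b.observations),
                 (a.events, b.events), (a.truth, b.truth)]:
        pd.testing.assert_frame_equal(x, y)
    c = simulate_cohort(spec, seed=6)
    assert not a.observations.equals(c.observations)


def test_everyone_always_seen_under_degenerate_parameters(short_config):
    """theta = psi = phi = 1: everybody present and detected every year
    from arrival on, with zero ground-truth over-coverage."""
    spec = _flat_spec(short_config, 80, 1.0, 1.0, 0.5, 0.5, [1.0] * 4)
    cohort = simulate_cohort(spec, seed=3)
    obs_any = (cohort.observations.groupby(["id", "year"])["value"].max())
    years = short_config.n_years
    expected_rows = sum(
        short_config.last_year - r + 1
        for r in cohort.individuals["registration_year"])
    assert len(obs_any) == expected_rows
    assert (obs_any == 1).all()
    assert cohort.events.empty
    for y in range(short_config.first_year, short_config.last_year + 1):
        oc = true_overcoverage(cohort, y)
        assert oc == 0.0
    assert (cohort.truth["state"] == "PRESENT").all()


def test_forced_emigration_with_certain_notification(short_config):
    """psi = 0 and lambda = 1: everyone de-registers the year after
    arrival, so the events table holds one de-registration per individual."""
    spec = _flat_spec(short_config, 60, 1.0, 0.0, 0.0, 1.0, [0.8] * 4)
    cohort = simulate_cohort(spec, seed=4)
    dereg = cohort.events[cohort.events["event"] == "deregister"]
    assert len(dereg) == 60
    expected = cohort.individuals.set_index("id")["registration_year"] + 1
    got = dereg.set_index("id")["year"]
    assert got.sort_index().equals(expected.sort_index())


def test_structural_invariants(small_cohort, short_config):
    ind = small_cohort.individuals.set_index("id")
    obs = small_cohort.observations
    reg = ind.loc[obs["id"], "registration_year"].to_numpy()
    assert (obs["year"].to_numpy() >= reg).all()
    assert obs["year"].between(short_config.first_year,
                               short_config.last_year).all()
    # arrival year is never the final year, and arrival state is PRESENT
    assert (ind["registration_year"] <= short_config.last_year - 1).all()
    truth = small_cohort.truth.set_index(["id", "year"])["state"]
    arr = truth.loc[list(zip(ind.index, ind["registration_year"]))]
    assert (arr == "PRESENT").all()
    # a detected year is always a truly-present year
    seen = obs[obs["value"] == 1]
    assert (truth.loc[list(zip(seen["id"], seen["year"]))] == "PRESENT").all()


def test_one_step_transition_frequencies_match_kernel(short_config):
    """Empirical PRESENT -> ABSENT frequency among survivors matches
    1 - psi within 3 Monte-Carlo standard errors (flat parameters)."""
    phi, psi = 0.97, 0.85
    spec = _flat_spec(short_config, 20000, phi, psi, 0.25, 0.5, [0.6] * 4)
    cohort = simulate_cohort(spec, seed=8)
    t = cohort.truth.pivot(index="id", columns="year", values="state")
    moves = stays = 0
    deaths = alive_prev = 0
    for y in range(short_config.first_year + 1, short_config.last_year + 1):
        prev, cur = t[y - 1], t[y]
        present_prev = prev == "PRESENT"
        alive_prev += int((present_prev | (prev == "ABSENT")).sum())
        deaths += int((((prev == "PRESENT") | (prev == "ABSENT"))
                       & (cur == "DEAD")).sum())
        surv = present_prev & (cur != "DEAD") & cur.notna()
        moves += int((surv & (cur == "ABSENT")).sum())
        stays += int((surv & (cur == "PRESENT")).sum())
    n = moves + stays
    frac = moves / n
    se = np.sqrt((1 - psi) * psi / n)
    assert abs(frac - (1 - psi)) < 3 * se
    death_rate = deaths / alive_prev
    se_d = np.sqrt(phi * (1 - phi) / alive_prev)
    assert abs(death_rate - (1 - phi)) < 3 * se_d


def test_true_overcoverage_direct_count(short_config):
    ind = pd.DataFrame({
        "id": [1, 2, 3, 4], "sex": 0, "birth_year": 1970,
        "country_group": "MENA", "registration_year": 2003,
    })
    truth = pd.DataFrame({
        "id": [1, 2, 3, 4], "year": 2005,
        "state": ["PRESENT", "PRESENT", "ABSENT", "ABSENT"],
    })
    cohort = SimulatedCohort(
        individuals=ind, observations=pd.DataFrame(columns=["id", "year",
                                                            "list_id",
                                                            "value"]),
        events=pd.DataFrame(columns=["id", "year", "event"]), truth=truth,
        spec=SimulationSpec(config=short_config, n_individuals=4),
    )
    assert true_overcoverage(cohort, 2005) == 0.5
    with pytest.raises(ValueError, match="outside observation range"):
        true_overcoverage(cohort, 1999)


def test_spec_validation(short_config):
    with pytest.raises(ValueError, match="probability vector"):
        SimulationSpec(config=short_config, n_individuals=10,
                       country_group_probs=np.array([0.5] * 7))
    with pytest.raises(ValueError, match="arrival_year_probs"):
        SimulationSpec(config=short_config, n_individuals=10,
                       arrival_year_probs=np.array([1.0]))


def test_recovery_coefficients_span(short_config):
    truth = recovery_coefficients(short_config).flatten()
    assert truth.min() == -1.5 and truth.max() == 1.5
    assert np.all(np.abs(truth) <= 1.5)
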