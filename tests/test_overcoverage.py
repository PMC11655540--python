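"""Over-coverage estimators: denominator rule, hand-checked estimates,
dominance, and gap summaries."""

import numpy as np
import pandas as pd
import pytest

from registercr import (
    ModelConfig,
    oc_estimate,
    register_trace_oc,
    registered_set,
)
from registercr.likelihood import build_packed
from registercr.overcoverage import gap_summary, oc_table


@pytest.fixture
def toy_tables():
    ind = pd.DataFrame({
        "id": [1, 2, 3, 4, 5],
        "sex": [0, 1, 0, 1, 0],
        "birth_year": [1970, 1980, 1985, 1990, 1975],
        "country_group": ["MENA", "MENA", "Eastern Europe",
                          "Western Europe", "MENA"],
        "registration_year": [2003, 2003, 2004, 2003, 2003],
    })
    obs = pd.DataFrame({
        "id": [1, 2, 1], "year": [2006, 2006, 2004],
        "list_id": [1, 2, 1], "value": [1, 1, 1],
    })
    ev = pd.DataFrame({
        "id": [3, 4, 4, 5],
        "year": [2005, 2004, 2005, 2004],
        "event": ["death", "deregister", "reregister", "deregister"],
    })
    return ind, obs, ev


class TestRegisteredSet:
    def test_removal_rule(self, toy_tables):
        ind, obs, ev = toy_tables
        d = registered_set(ind, ev, 2006)
        # id 3 died (2005), id 5 de-registered without return -> |D| = 3
        assert d.sum() == 3
        assert set(ind.loc[d, "id"]) == {1, 2, 4}

    def test_reregistration_restores_membership(self, toy_tables):
        ind, obs, ev = toy_tables
        d = registered_set(ind, ev, 2006)
        assert bool(d[ind["id"] == 4].all())  # dereg 2004, rereg 2005

    def test_not_yet_arrived_excluded(self, toy_tables):
        ind, obs, ev = toy_tables
        d = registered_set(ind, ev, 2003)
        assert not d[ind["id"] == 3].any()


class TestEstimates:
    def test_model_oc_hand_arithmetic(self, toy_tables):
        ind, obs, ev = toy_tables
        cfg = ModelConfig(first_year=2003, last_year=2008, n_lists=2)
        zhat = np.full((5, cfg.n_years), np.nan)
        col = 2006 - cfg.first_year
        # D_2006 = ids {1, 2, 4} (rows 0, 1, 3); use spec-style values
        zhat[0, col] = 1.0
        zhat[1, col] = 1.0
        zhat[3, col] = 0.5
        zhat[2, col] = 0.0   # excluded rows must not matter
        zhat[4, col] = 0.0
        point, lo, hi, n = oc_estimate(ind, ev, zhat, 2006, cfg)
        assert n == 3
        assert point == pytest.approx(1.0 - 2.5 / 3.0, abs=1e-12)
        assert lo is None and hi is None

    def test_four_individual_formula(self):
        cfg = ModelConfig(first_year=2003, last_year=2004, n_lists=1)
        ind = pd.DataFrame({
            "id": [1, 2, 3, 4], "sex": 0, "birth_year": 1980,
            "country_group": "MENA", "registration_year": 2003,
        })
        ev = pd.DataFrame(columns=["id", "year", "event"])
        zhat = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.5], [1.0, 0.25]])
        point, *_ = oc_estimate(ind, ev, zhat, 2004, cfg)
        assert point == pytest.approx(0.3125, abs=1e-12)

    def test_register_trace_direct_count(self, toy_tables):
        ind, obs, ev = toy_tables
        # D_2006 = {1, 2, 4}; ids 1 and 2 seen in 2006 -> OC = 1/3
        got = register_trace_oc(ind, obs, ev, 2006)
        assert got == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_all_seen_gives_zero(self, toy_tables):
        ind, obs, ev = toy_tables
        extra = pd.DataFrame({"id": [4], "year": [2006], "list_id": [1],
                              "value": [1]})
        got = register_trace_oc(ind, pd.concat([obs, extra]), ev, 2006)
        assert got == 0.0

    def test_empty_group_marker(self, toy_tables):
        ind, obs, ev = toy_tables
        sub = np.zeros(5, dtype=bool)
        assert register_trace_oc(ind, obs, ev, 2006, sub) is None
        cfg = ModelConfig(first_year=2003, last_year=2008, n_lists=2)
        assert oc_estimate(ind, ev, np.ones((5, 6)), 2006, cfg,
                           subgroup=sub) is None


class TestDominanceAndInvariance:
    def _fit_free_zhat(self, cohort, config):
        """Presence array with 1 on detected years and 0.5 elsewhere —
        any valid Zhat must satisfy the dominance ordering."""
        packed = build_packed(cohort.individuals, cohort.observations,
                              cohort.events, config)
        z = np.where(packed.obs_any == 1, 1.0, 0.5)
        return z

    def test_model_never_exceeds_register_trace(self, small_cohort,
                                                short_config):
        z = self._fit_free_zhat(small_cohort, short_config)
        tab = oc_table(small_cohort.individuals, small_cohort.observations,
                       small_cohort.events, z, short_config)
        wide = tab.pivot(index="year", columns="method", values="estimate")
        assert (wide["model"] <= wide["register_trace"] + 1e-12).all()

    def test_invariant_to_row_order_and_duplication(self, small_cohort,
                                                    short_config):
        ind, obs, ev = (small_cohort.individuals, small_cohort.observations,
                        small_cohort.events)
        base = register_trace_oc(ind, obs, ev, 2006)
        shuffled = ind.sample(frac=1.0, random_state=0)
        assert register_trace_oc(shuffled, obs, ev, 2006) == \
            pytest.approx(base, abs=1e-12)
        # duplicating every individual under fresh ids leaves OC unchanged
        shift = ind["id"].max()
        ind2 = pd.concat([ind, ind.assign(id=ind["id"] + shift)])
        obs2 = pd.concat([obs, obs.assign(id=obs["id"] + shift)])
        ev2 = pd.concat([ev, ev.assign(id=ev["id"] + shift)])
        assert register_trace_oc(ind2, obs2, ev2, 2006) == \
            pytest.approx(base, abs=1e-12)


def test_plot_helpers_return_axes(small_cohort, short_config):
    import matplotlib

    matplotlib.use("Agg")
    packed = build_packed(small_cohort.individuals, small_cohort.observations,
                          small_cohort.events, short_config)
    z = np.where(packed.obs_any == 1, 1.0, 0.5)
    tab = oc_table(small_cohort.individuals, small_cohort.observations,
                   small_cohort.events, z, short_config)
    from registercr.overcoverage import plot_gap_summary, plot_overcoverage

    ax = plot_overcoverage(tab)
    assert ax.get_ylabel() == "over-coverage"
    detail = gap_summary(z, packed, aggregate=False)
    ax2 = plot_gap_summary(detail)
    assert ax2.get_xlabel().startswith("posterior presence")
    import matplotlib.pyplot as plt

    plt.close("all")


class TestGapSummary:
    def test_gap_counting_and_exclusions(self, short_config):
        cfg = ModelConfig(first_year=2003, last_year=2007, n_lists=1)
        ind = pd.DataFrame({
            "id": [1], "sex": [0], "birth_year": [1980],
            "country_group": ["MENA"], "registration_year": [2003],
        })
        # seen 2003, unseen 2004-2005, seen 2006, unseen 2007
        obs = pd.DataFrame({"id": [1, 1], "year": [2003, 2006],
                            "list_id": [1, 1], "value": [1, 1]})
        ev = pd.DataFrame(columns=["id", "year", "event"])
        packed = build_packed(ind, obs, ev, cfg)
        z = np.full((1, cfg.n_years), 0.4)
        detail = gap_summary(z, packed, aggregate=False)
        # final year dropped (no next-year flag); detected years excluded
        assert set(detail["year"]) == {2004, 2005}
        row4 = detail[detail["year"] == 2004].iloc[0]
        row5 = detail[detail["year"] == 2005].iloc[0]
        assert row4["gap"] == 1 and row4["seen_next"] == 0
        assert row5["gap"] == 2 and row5["seen_next"] == 1
        assert row5["tsm"] == 2

    def test_aggregate_quantiles(self, small_cohort, short_config):
        packed = build_packed(small_cohort.individuals,
                              small_cohort.observations,
                              small_cohort.events, short_config)
        z = np.where(packed.obs_any == 1, 1.0, 0.3)
        agg = gap_summary(z, packed, aggregate=True)
        assert {"gap", "tsm", "seen_next", "n", "mean", "q50"} <= \
            set(agg.columns)
        assert (agg["n"] >= 1).all()
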