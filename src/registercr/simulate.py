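"""Forward simulation of register panels from the generative model.

The simulator draws a cohort of migrants with arrival years, sex, age at
arrival and country-of-birth group, then propagates each individual's
latent state (PRESENT / ABSENT / DEAD) year by year through the exact
transition and emission structure of the model, emitting list detections,
de-registration, re-registration and death events.  Ground-truth latent
trajectories are returned alongside the three observable tables, so
estimators can be validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    COUNTRY_GROUPS,
    CoefficientSet,
    LatentState,
    ModelConfig,
    build_design_matrix,
)
from .likelihood import _expit

__all__ = [
    "SimulationSpec",
    "SimulatedCohort",
    "default_coefficients",
    "recovery_coefficients",
    "default_spec",
    "simulate_cohort",
    "true_overcoverage",
]

_STATE_LABELS = {LatentState.PRESENT: "PRESENT", LatentState.ABSENT: "ABSENT",
                 LatentState.DEAD: "DEAD"}


def default_coefficients(config: ModelConfig) -> CoefficientSet:
    """Plausible coefficient values for a register cohort of migrants.

    Chosen to reproduce the qualitative structure reported for such data:
    yearly survival near 0.98 at the reference profile, staying probability
    around 0.9 rising with time since migration, modest return rates that
    fall with time away, de-registration around 0.35 (higher for Nordic and
    North-American migrants, lower for Eastern-European and MENA migrants),
    and detection probabilities that rise with time since migration and are
    lower for women.  Covariate order: intercept, sex(female), age(std),
    six country-group indicators (Denmark/Norway, Iceland/Finland, Eastern
    Europe, MENA, USA/Canada/Oceania, Rest of World; reference Western
    Europe), TSM.
    """
    p = config.n_covariates
    if config.tsm_form != "linear" or p != 10:
        raise ValueError("default coefficients assume the default (linear-TSM)"
                         " covariate encoding")

    def v(intercept, sex, age, cg, tsm):
        return np.array([intercept, sex, age, *cg, tsm])

    #           DK/NO IS/FI EastEU MENA  USA/Oc Rest   (reference: WestEU)
    phi = v(3.8, 0.2, -0.6, [0.1, 0.1, 0.0, 0.1, 0.1, -0.1], 0.05)
    psi = v(2.2, 0.3, 0.0, [-0.8, -0.6, 0.5, 0.7, -0.9, 0.2], 0.15)
    eta = v(-1.2, 0.2, 0.0, [0.0, -0.5, 0.4, 0.4, 0.0, 0.1], -0.15)
    lam = v(-0.5, 0.3, 0.0, [0.7, 0.4, -0.6, -0.8, 0.6, -0.3], 0.1)
    theta = []
    for l in range(config.n_lists):
        base = [1.0, 0.0, -0.7, 0.5, -0.3, 0.8, 0.2, -0.5][l % 8]
        theta.append(v(base, -0.3, 0.1,
                       [0.1, 0.0, -0.1, -0.2, 0.1, -0.1], 0.25))
    return CoefficientSet(phi, psi, eta, lam, theta)


def recovery_coefficients(config: ModelConfig) -> CoefficientSet:
    """Fixed ground-truth coefficients for parameter-recovery experiments.

    Values span [-1.5, 1.5] (both endpoints included) across all linear
    predictors, giving a deliberately stressful regime: annual survival
    around 0.8 at the reference profile so every transition type occurs
    often enough to be identified at moderate cohort sizes.
    """
    if config.tsm_form != "linear" or config.n_covariates != 10:
        raise ValueError("recovery coefficients assume the default covariate"
                         " encoding")
    rows = {
        "phi": [1.5, 0.3, -0.4, 0.2, -0.2, 0.4, 0.6, -0.6, 0.1, 0.05],
        "psi": [1.2, 0.4, 0.1, -0.8, -0.5, 0.6, 0.9, -1.0, 0.3, 0.15],
        "eta": [-0.8, 0.3, -0.1, 0.2, -0.6, 0.5, 0.4, -0.2, 0.1, -0.3],
        "lam": [-0.3, 0.4, 0.1, 0.9, 0.5, -0.7, -1.2, 0.8, -0.4, 0.2],
        "o1": [0.8, -0.4, 0.15, 0.3, -0.3, 0.2, -0.2, 0.5, -0.1, 0.35],
        "o2": [-0.2, 0.25, -0.15, -0.4, 0.3, -0.5, 0.4, -0.3, 0.2, 0.3],
        "o3": [-1.0, 0.5, 0.2, 0.6, -0.4, 0.8, -0.6, 0.2, 0.4, 0.45],
        "o4": [0.3, -0.6, -0.25, -1.5, 1.5, -0.9, 1.0, 0.7, -0.8, 0.25],
    }
    beta_o = [np.array(rows[f"o{(l % 4) + 1}"]) for l in range(config.n_lists)]
    return CoefficientSet(np.array(rows["phi"]), np.array(rows["psi"]),
                          np.array(rows["eta"]), np.array(rows["lam"]),
                          beta_o)


@dataclass
class SimulationSpec:
    """Conditions of a simulated register cohort.

    Defaults emulate the motivating study design: arrivals uniform over
    2003-2015 with final observation year 2016, seven country-of-birth
    groups, adult ages at arrival (18 + Gamma), and a near-balanced sex mix.
    """

    config: ModelConfig = field(default_factory=ModelConfig)
    n_individuals: int = 1000
    arrival_year_probs: np.ndarray | None = None   # over first..last-1
    sex_female_prop: float = 0.46
    age_shape: float = 2.0       # age at arrival = 18 + Gamma(shape, scale)
    age_scale: float = 6.0
    age_max: float = 80.0
    country_group_probs: np.ndarray | None = None  # 7 groups, encoding order
    coefficients: CoefficientSet | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        n_arrival = self.config.n_years - 1
        if self.arrival_year_probs is None:
            self.arrival_year_probs = np.full(n_arrival, 1.0 / n_arrival)
        self.arrival_year_probs = np.asarray(self.arrival_year_probs, float)
        if len(self.arrival_year_probs) != n_arrival:
            raise ValueError(
                f"arrival_year_probs must cover the {n_arrival} years "
                f"{self.config.first_year}..{self.config.last_year - 1}"
            )
        if self.country_group_probs is None:
            # Swedish-flavoured mix: MENA and Eastern Europe dominant
            self.country_group_probs = np.array(
                [0.05, 0.04, 0.25, 0.14, 0.32, 0.05, 0.15])
        self.country_group_probs = np.asarray(self.country_group_probs, float)
        if len(self.country_group_probs) != len(COUNTRY_GROUPS):
            raise ValueError("country_group_probs must have 7 entries")
        for name, v in (("arrival_year_probs", self.arrival_year_probs),
                        ("country_group_probs", self.country_group_probs)):
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector "
                                 f"summing to 1 (sum={v.sum():.12f})")
        if not 0.0 <= self.sex_female_prop <= 1.0:
            raise ValueError("sex_female_prop must lie in [0, 1]")
        if self.coefficients is None:
            self.coefficients = default_coefficients(self.config)
        if self.coefficients.n_lists != self.config.n_lists:
            raise ValueError(
                f"coefficients define {self.coefficients.n_lists} lists but "
                f"config has {self.config.n_lists}"
            )


def default_spec(**kwargs) -> SimulationSpec:
    """SimulationSpec with the default study conditions."""
    return SimulationSpec(**kwargs)


@dataclass
class SimulatedCohort:
    """Observable tables plus ground truth from one simulation run."""

    individuals: pd.DataFrame
    observations: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame      # (id, year, state) with state labels
    spec: SimulationSpec

    @property
    def tables(self):
        return self.individuals, self.observations, self.events


def simulate_cohort(spec: SimulationSpec, seed: int | None = None) -> SimulatedCohort:
    """Draw a full synthetic cohort. Deterministic given ``seed``.

    Every individual is PRESENT in their registration year; from the next
    year onward survival is resolved first, then movement.  Deaths are
    recorded only when the previous state was PRESENT; de-registrations are
    drawn on PRESENT -> ABSENT transitions; a re-registration is recorded in
    the first year a previously de-registered individual is PRESENT again.
    Silent emigrants who return generate no event at all.
    """
    cfg = spec.config
    rng = np.random.default_rng(seed)
    n, Y, L = spec.n_individuals, cfg.n_years, cfg.n_lists

    sex = (rng.random(n) < spec.sex_female_prop).astype(int)
    age_arr = 18.0 + rng.gamma(spec.age_shape, spec.age_scale, size=n)
    age_arr = np.minimum(np.floor(age_arr), spec.age_max).astype(int)
    cg_idx = rng.choice(len(COUNTRY_GROUPS), size=n, p=spec.country_group_probs)
    country = np.array(COUNTRY_GROUPS, dtype=object)[cg_idx]
    arr_idx = rng.choice(Y - 1, size=n, p=spec.arrival_year_probs)
    reg_year = cfg.first_year + arr_idx
    birth_year = reg_year - age_arr

    individuals = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "sex": sex,
        "birth_year": birth_year,
        "country_group": country,
        "registration_year": reg_year,
    })

    X = build_design_matrix(cfg, sex, birth_year, country, reg_year)
    params = spec.coefficients
    phi = _expit(X @ params.beta_phi)
    psi = _expit(X @ params.beta_psi)
    eta = _expit(X @ params.beta_eta)
    lam = _expit(X @ params.beta_lambda)
    theta = np.stack([_expit(X @ b) for b in params.beta_o], axis=2)  # (n,Y,L)

    P, A, D = LatentState.PRESENT, LatentState.ABSENT, LatentState.DEAD
    obs_rows: list[tuple] = []
    ev_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    u_obs = rng.random((n, Y, L))
    u_surv = rng.random((n, Y))
    u_move = rng.random((n, Y))
    u_dereg = rng.random((n, Y))

    for i in range(n):
        y0 = arr_idx[i]
        state = P
        deregistered = False
        for y in range(y0, Y):
            year = cfg.first_year + y
            if y > y0:
                prev = state
                if prev is D:
                    pass
                elif u_surv[i, y] >= phi[i, y]:
                    state = D
                    if prev is P:
                        ev_rows.append((i + 1, year, "death"))
                else:
                    if prev is P:
                        if u_move[i, y] >= psi[i, y]:
                            state = A
                            if u_dereg[i, y] < lam[i, y]:
                                ev_rows.append((i + 1, year, "deregister"))
                                deregistered = True
                    else:
                        if u_move[i, y] < eta[i, y]:
                            state = P
                            if deregistered:
                                ev_rows.append((i + 1, year, "reregister"))
                                deregistered = False
            if state is P:
                for l in range(L):
                    if u_obs[i, y, l] < theta[i, y, l]:
                        obs_rows.append((i + 1, year, l + 1, 1))
            truth_rows.append((i + 1, year, _STATE_LABELS[state]))

    observations = pd.DataFrame(obs_rows,
                                columns=["id", "year", "list_id", "value"])
    events = pd.DataFrame(ev_rows, columns=["id", "year", "event"])
    truth = pd.DataFrame(truth_rows, columns=["id", "year", "state"])
    if observations.empty:
        observations = observations.astype(
            {"id": int, "year": int, "list_id": int, "value": int})
    if events.empty:
        events = events.astype({"id": int, "year": int})
        events["event"] = events.get("event", pd.Series(dtype=object))
    observations = observations.sort_values(
        ["id", "year", "list_id"]).reset_index(drop=True)
    events = events.sort_values(["id", "year", "event"]).reset_index(drop=True)
    return SimulatedCohort(individuals, observations, events, truth, spec)


def true_overcoverage(cohort: SimulatedCohort, year: int) -> float | None:
    """Ground-truth over-coverage: the fraction of administratively
    registered individuals in ``year`` whose true state is not PRESENT.

    The administratively registered set mirrors the estimator's denominator:
    arrived by ``year``, no recorded death up to ``year``, and not
    de-registered without a later re-registration by ``year``.  Returns
    None when that set is empty.
    """
    cfg = cohort.spec.config
    if not cfg.first_year <= year <= cfg.last_year:
        raise ValueError(
            f"year {year} outside observation range "
            f"[{cfg.first_year}, {cfg.last_year}]"
        )
    reg = _administratively_registered(cohort.individuals, cohort.events, year)
    if not reg.any():
        return None
    ids = cohort.individuals.loc[reg, "id"]
    tr = cohort.truth
    states = tr[(tr["year"] == year) & tr["id"].isin(ids)]
    return float((states["state"] != "PRESENT").mean())


def _administratively_registered(individuals: pd.DataFrame,
                                 events: pd.DataFrame, year: int) -> np.ndarray:
    """Boolean mask over individuals rows: in the registered set for year."""
    reg = (individuals["registration_year"] <= year).to_numpy()
    ev = events[events["year"] <= year]
    dead = ev.loc[ev["event"] == "death", "id"].unique()
    reg &= ~individuals["id"].isin(dead).to_numpy()
    migr = ev[ev["event"].isin(["deregister", "reregister"])]
    if len(migr):
        last = migr.sort_values(["id", "year"]).groupby("id").tail(1)
        out_ids = last.loc[last["event"] == "deregister", "id"]
        reg &= ~individuals["id"].isin(out_ids).to_numpy()
    return reg
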