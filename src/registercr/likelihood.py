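"""Marginal likelihood of register histories with latent states summed out.

Rather than sampling one latent presence indicator per individual-year, the
per-individual likelihood is computed exactly by a forward recursion over
the three latent states {PRESENT, ABSENT, DEAD}, and per-year presence
posteriors by forward-backward smoothing.  A brute-force path-enumeration
oracle (``brute_force_loglik``) provides an independent check on small
records.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit as sp_expit

from . import _kernels
from ._kernels import FORCED_ABSENT, FORCED_DEAD, FORCED_PRESENT, FREE
from .core import (
    CoefficientSet,
    LatentState,
    ModelConfig,
    build_design_matrix,
    emission_probs,
    transition_kernel,
)

__all__ = [
    "KnownState",
    "IndividualRecord",
    "PackedCohort",
    "build_packed",
    "known_state_mask",
    "predictor_probs",
    "loglik_all",
    "individual_loglik",
    "brute_force_loglik",
    "smoothed_presence",
    "presence_posterior",
    "DataInconsistencyError",
]

# re-export mask codes under a friendlier name
class KnownState:
    FREE = FREE
    FORCED_PRESENT = FORCED_PRESENT
    FORCED_ABSENT = FORCED_ABSENT
    FORCED_DEAD = FORCED_DEAD


class DataInconsistencyError(ValueError):
    """Raised when observations contradict recorded events."""


_STATE_OF_MASK = {
    FORCED_PRESENT: LatentState.PRESENT,
    FORCED_ABSENT: LatentState.ABSENT,
    FORCED_DEAD: LatentState.DEAD,
}


@dataclass
class IndividualRecord:
    """One individual's covariates and yearly record from registration onward.

    Arrays all span the T = last_year - r_i + 1 years from the registration
    year (index 0) to the end of the observation window.
    """

    X: np.ndarray          # (T, p) covariate rows
    obs: np.ndarray        # (T, L) 0/1 list indicators
    e_flag: np.ndarray     # (T,) de-registration notifications
    d_flag: np.ndarray     # (T,) recorded deaths
    r_flag: np.ndarray | None = None   # (T,) recorded re-registrations

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.obs = np.asarray(self.obs, dtype=np.int8)
        self.e_flag = np.asarray(self.e_flag, dtype=np.int8)
        self.d_flag = np.asarray(self.d_flag, dtype=np.int8)
        T = self.X.shape[0]
        if self.r_flag is None:
            self.r_flag = np.zeros(T, dtype=np.int8)
        else:
            self.r_flag = np.asarray(self.r_flag, dtype=np.int8)
        if not (self.obs.shape[0] == T == len(self.e_flag) == len(self.d_flag)
                == len(self.r_flag)):
            raise ValueError("record arrays disagree on the number of years")

    @property
    def n_years(self) -> int:
        return self.X.shape[0]

    def default_mask(self) -> np.ndarray:
        """Known-state mask implied by the record itself."""
        obs_any = (self.obs.sum(axis=1) > 0).astype(np.int8)[None]
        mask, _ = known_state_mask(
            np.zeros(1, dtype=np.int64), obs_any, self.e_flag[None],
            self.d_flag[None], self.r_flag[None],
        )
        return mask[0]


@dataclass
class PackedCohort:
    """Cohort tables packed into dense (n, Y, ...) arrays for the kernels."""

    config: ModelConfig
    ids: np.ndarray            # (n,) original ids, row order
    start: np.ndarray          # (n,) year index of r_i
    X: np.ndarray              # (n, Y, p)
    obs: np.ndarray            # (n, Y, L) int8
    obs_any: np.ndarray        # (n, Y) int8
    e_flag: np.ndarray         # (n, Y) int8
    d_flag: np.ndarray         # (n, Y) int8
    mask: np.ndarray           # (n, Y) int8
    conflicts: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_years(self) -> int:
        return self.X.shape[1]

    def record(self, i: int) -> IndividualRecord:
        """Extract individual i's record (years r_i..last_year)."""
        y0 = self.start[i]
        return IndividualRecord(
            X=self.X[i, y0:], obs=self.obs[i, y0:],
            e_flag=self.e_flag[i, y0:], d_flag=self.d_flag[i, y0:],
        )

    def record_mask(self, i: int) -> np.ndarray:
        return self.mask[i, self.start[i]:].copy()


def known_state_mask(
    start: np.ndarray,
    obs_any: np.ndarray,
    e_flag: np.ndarray,
    d_flag: np.ndarray,
    rereg: np.ndarray,
    ids: np.ndarray | None = None,
) -> tuple[np.ndarray, list]:
    """Per individual-year mask of latent states pinned by the data.

    The registration year and any year with at least one list detection are
    FORCED_PRESENT; years from a recorded de-registration up to (exclusive)
    the next recorded re-registration are FORCED_ABSENT; years from a
    recorded death onward are FORCED_DEAD.  Returns the mask and a list of
    (id, year-index, rule) conflicts where observations contradict events.
    """
    n, Y = obs_any.shape
    mask = np.full((n, Y), FREE, dtype=np.int8)
    conflicts: list = []
    idlab = ids if ids is not None else np.arange(n)
    for i in range(n):
        y0 = start[i]
        mask[i, y0] = FORCED_PRESENT
        for y in range(y0, Y):
            if obs_any[i, y]:
                mask[i, y] = FORCED_PRESENT
        open_from = -1
        for y in range(y0, Y):
            if e_flag[i, y]:
                if open_from < 0:
                    open_from = y
            if rereg[i, y] and open_from >= 0:
                for t in range(open_from, y):
                    if obs_any[i, t]:
                        conflicts.append((idlab[i], t, "detection while de-registered"))
                    mask[i, t] = FORCED_ABSENT
                mask[i, y] = FORCED_PRESENT
                open_from = -1
        if open_from >= 0:
            for t in range(open_from, Y):
                if obs_any[i, t]:
                    conflicts.append((idlab[i], t, "detection while de-registered"))
                mask[i, t] = FORCED_ABSENT
        dy = np.nonzero(d_flag[i])[0]
        if dy.size:
            yd = dy[0]
            for t in range(yd, Y):
                if obs_any[i, t]:
                    conflicts.append((idlab[i], t, "detection after recorded death"))
                mask[i, t] = FORCED_DEAD
    return mask, conflicts


def build_packed(
    individuals: pd.DataFrame,
    observations: pd.DataFrame,
    events: pd.DataFrame,
    config: ModelConfig,
) -> PackedCohort:
    """Pack the three cohort tables into dense arrays.

    Emits a warning (and records conflicts) if observations contradict
    events; such records have marginal likelihood -inf.
    """
    ind = individuals.sort_values("id").reset_index(drop=True)
    ids = ind["id"].to_numpy()
    row = pd.Series(np.arange(len(ids)), index=ids)
    n, Y, L = len(ids), config.n_years, config.n_lists

    X = build_design_matrix(
        config,
        ind["sex"].to_numpy(),
        ind["birth_year"].to_numpy(),
        ind["country_group"].to_numpy(),
        ind["registration_year"].to_numpy(),
    )
    start = (ind["registration_year"].to_numpy() - config.first_year).astype(np.int64)

    obs = np.zeros((n, Y, L), dtype=np.int8)
    if len(observations):
        oi = row.loc[observations["id"]].to_numpy()
        oy = observations["year"].to_numpy() - config.first_year
        ol = observations["list_id"].to_numpy() - 1
        obs[oi, oy, ol] = observations["value"].to_numpy().astype(np.int8)
    obs_any = (obs.sum(axis=2) > 0).astype(np.int8)

    e_flag = np.zeros((n, Y), dtype=np.int8)
    d_flag = np.zeros((n, Y), dtype=np.int8)
    rereg = np.zeros((n, Y), dtype=np.int8)
    if len(events):
        ei = row.loc[events["id"]].to_numpy()
        ey = events["year"].to_numpy() - config.first_year
        kind = events["event"].to_numpy()
        e_flag[ei[kind == "deregister"], ey[kind == "deregister"]] = 1
        d_flag[ei[kind == "death"], ey[kind == "death"]] = 1
        rereg[ei[kind == "reregister"], ey[kind == "reregister"]] = 1

    mask, conflicts = known_state_mask(start, obs_any, e_flag, d_flag, rereg, ids)
    if conflicts:
        shown = ", ".join(f"id {c[0]} year {c[1] + config.first_year} ({c[2]})"
                          for c in conflicts[:5])
        warnings.warn(
            f"{len(conflicts)} individual-years contradict recorded events: "
            f"{shown}{'...' if len(conflicts) > 5 else ''}",
            stacklevel=2,
        )
    return PackedCohort(config, ids, start, X, obs, obs_any, e_flag, d_flag,
                        mask, conflicts)


# ---------------------------------------------------------------------------
# probability assembly


def _expit(eta: np.ndarray) -> np.ndarray:
    """Overflow-safe inverse logit (scipy ufunc)."""
    return sp_expit(eta)


def detection_log_emission(X: np.ndarray, obs: np.ndarray, beta_o: list[np.ndarray]):
    """Per-list log P(o_l | PRESENT) contributions, each (n, Y)."""
    contribs = []
    for l, b in enumerate(beta_o):
        theta = _expit(X @ b)
        o = obs[:, :, l]
        with np.errstate(divide="ignore"):
            c = np.where(o == 1, np.log(theta), np.log1p(-theta))
        contribs.append(c)
    return contribs


def predictor_probs(packed: PackedCohort, params: CoefficientSet):
    """All yearly probabilities needed by the kernels.

    Returns (phi, psi, eta, lam, em_p), each (n, Y); ``em_p`` is the
    detection-product emission probability of the year's list record given
    presence.
    """
    X = packed.X
    phi = _expit(X @ params.beta_phi)
    psi = _expit(X @ params.beta_psi)
    eta = _expit(X @ params.beta_eta)
    lam = _expit(X @ params.beta_lambda)
    logem = sum(detection_log_emission(X, packed.obs, params.beta_o))
    em_p = np.exp(logem)
    return phi, psi, eta, lam, em_p


def loglik_all(packed: PackedCohort, params: CoefficientSet) -> np.ndarray:
    """Per-individual marginal log-likelihood vector."""
    phi, psi, eta, lam, em_p = predictor_probs(packed, params)
    out = np.empty(packed.n)
    _kernels.forward_loglik(packed.start, packed.obs_any, packed.e_flag,
                            packed.d_flag, packed.mask, phi, psi, eta, lam,
                            em_p, out)
    return out


def total_loglik(packed: PackedCohort, params: CoefficientSet) -> float:
    return float(loglik_all(packed, params).sum())


def _pack_single(record: IndividualRecord, mask: np.ndarray | None) -> PackedCohort:
    obs = record.obs[None]
    obs_any = (record.obs.sum(axis=1) > 0).astype(np.int8)[None]
    if mask is None:
        mask = record.default_mask()
    mask = np.asarray(mask, dtype=np.int8)[None]
    return PackedCohort(
        config=None, ids=np.array([0]), start=np.zeros(1, dtype=np.int64),
        X=record.X[None], obs=obs, obs_any=obs_any,
        e_flag=record.e_flag[None], d_flag=record.d_flag[None], mask=mask,
    )


def individual_loglik(
    record: IndividualRecord,
    params: CoefficientSet,
    mask: np.ndarray | None = None,
) -> float:
    """Marginal log-likelihood of one record, latent states summed out.

    ``mask`` defaults to the mask implied by the record.  Records that are
    impossible under the mask (e.g. a detection in a forced-absent year)
    return -inf with a data-inconsistency warning.
    """
    if mask is not None:
        seen = record.obs.sum(axis=1) > 0
        bad = np.nonzero(seen & (np.asarray(mask) != FORCED_PRESENT))[0]
        if bad.size:
            warnings.warn(
                f"detections in non-present masked years {bad.tolist()}; "
                "record is impossible under the mask", stacklevel=2,
            )
    packed = _pack_single(record, mask)
    phi, psi, eta, lam, em_p = _probs_single(record, params)
    out = np.empty(1)
    _kernels.forward_loglik(packed.start, packed.obs_any, packed.e_flag,
                            packed.d_flag, packed.mask, phi, psi, eta, lam,
                            em_p, out)
    return float(out[0])


def _probs_single(record: IndividualRecord, params: CoefficientSet):
    X = record.X[None]
    phi = _expit(X @ params.beta_phi)
    psi = _expit(X @ params.beta_psi)
    eta = _expit(X @ params.beta_eta)
    lam = _expit(X @ params.beta_lambda)
    logem = sum(detection_log_emission(X, record.obs[None], params.beta_o))
    return phi, psi, eta, lam, np.exp(logem)


# ---------------------------------------------------------------------------
# brute-force oracle

_ALL_STATES = (LatentState.PRESENT, LatentState.ABSENT, LatentState.DEAD)

MAX_FREE_YEARS = 12


def brute_force_loglik(
    record: IndividualRecord,
    params: CoefficientSet,
    mask: np.ndarray | None = None,
) -> float:
    """Exact log-likelihood by enumerating every admissible latent path.

    Testing oracle only: cost grows as 3^(free years), so records with more
    than ``MAX_FREE_YEARS`` unconstrained years are refused.
    """
    if mask is None:
        mask = record.default_mask()
    mask = np.asarray(mask)
    T = record.n_years
    n_free = int(np.sum(mask == FREE))
    if n_free > MAX_FREE_YEARS:
        raise ValueError(
            f"{n_free} free years exceeds the enumeration bound "
            f"{MAX_FREE_YEARS} (3^{n_free} paths)"
        )
    allowed = []
    for t in range(T):
        if mask[t] == FREE:
            allowed.append(_ALL_STATES)
        else:
            allowed.append((_STATE_OF_MASK[int(mask[t])],))
    if allowed[0] != (LatentState.PRESENT,):
        return -np.inf  # registration year must be PRESENT
    total = 0.0
    for path in itertools.product(*allowed):
        # registration year: presence certain, only the detection record emits
        p = emission_probs(LatentState.PRESENT, LatentState.PRESENT,
                           record.X[0], params, record.obs[0],
                           int(record.e_flag[0]), int(record.d_flag[0]))
        for t in range(1, T):
            if p == 0.0:
                break
            trans = transition_kernel(path[t - 1], record.X[t], params)
            p *= trans[path[t]]
            if p == 0.0:
                break
            p *= emission_probs(path[t - 1], path[t], record.X[t], params,
                                record.obs[t], int(record.e_flag[t]),
                                int(record.d_flag[t]))
        total += p
    if total <= 0.0:
        return -np.inf
    return float(np.log(total))


def brute_force_state_posterior(
    record: IndividualRecord,
    params: CoefficientSet,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Enumeration-based smoothed state distribution, (T, 3). Oracle only."""
    if mask is None:
        mask = record.default_mask()
    mask = np.asarray(mask)
    T = record.n_years
    n_free = int(np.sum(mask == FREE))
    if n_free > MAX_FREE_YEARS:
        raise ValueError(f"{n_free} free years exceeds the enumeration bound")
    allowed = [
        _ALL_STATES if mask[t] == FREE else (_STATE_OF_MASK[int(mask[t])],)
        for t in range(T)
    ]
    weights = np.zeros((T, 3))
    total = 0.0
    for path in itertools.product(*allowed):
        p = emission_probs(LatentState.PRESENT, LatentState.PRESENT,
                           record.X[0], params, record.obs[0],
                           int(record.e_flag[0]), int(record.d_flag[0]))
        if path[0] != LatentState.PRESENT:
            continue
        for t in range(1, T):
            if p == 0.0:
                break
            trans = transition_kernel(path[t - 1], record.X[t], params)
            p *= trans[path[t]]
            if p == 0.0:
                break
            p *= emission_probs(path[t - 1], path[t], record.X[t], params,
                                record.obs[t], int(record.e_flag[t]),
                                int(record.d_flag[t]))
        if p > 0.0:
            total += p
            for t in range(T):
                weights[t, int(path[t])] += p
    if total <= 0.0:
        return np.full((T, 3), np.nan)
    return weights / total


# ---------------------------------------------------------------------------
# smoothing


def smoothed_presence(packed: PackedCohort, params: CoefficientSet) -> np.ndarray:
    """P(state_y = PRESENT | record, params) for every individual-year.

    Years pinned by the known-state mask are returned exactly 1 (forced
    present) or exactly 0 (forced absent/dead); years before registration
    are NaN.
    """
    phi, psi, eta, lam, em_p = predictor_probs(packed, params)
    zhat = np.empty((packed.n, packed.n_years))
    _kernels.forward_backward(packed.start, packed.obs_any, packed.e_flag,
                              packed.d_flag, packed.mask, phi, psi, eta, lam,
                              em_p, zhat)
    zhat[packed.mask == FORCED_PRESENT] = 1.0
    zhat[(packed.mask == FORCED_ABSENT) | (packed.mask == FORCED_DEAD)] = 0.0
    active = np.arange(packed.n_years)[None, :] >= packed.start[:, None]
    zhat[~active] = np.nan
    return zhat


def presence_posterior(
    record: IndividualRecord,
    params_draws,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior-mean presence probability per year for one record.

    ``params_draws`` is an iterable of CoefficientSet draws (or a single
    CoefficientSet); the smoothed presence probability is averaged over
    draws.  Forced-present years are exactly 1, forced-absent/dead exactly 0.
    """
    if isinstance(params_draws, CoefficientSet):
        params_draws = [params_draws]
    packed = _pack_single(record, mask)
    acc = np.zeros(record.n_years)
    n_draws = 0
    zhat = np.empty((1, record.n_years))
    for params in params_draws:
        phi, psi, eta, lam, em_p = _probs_single(record, params)
        _kernels.forward_backward(packed.start, packed.obs_any, packed.e_flag,
                                  packed.d_flag, packed.mask, phi, psi, eta,
                                  lam, em_p, zhat)
        acc += zhat[0]
        n_draws += 1
    out = acc / n_draws
    m = packed.mask[0]
    out[m == FORCED_PRESENT] = 1.0
    out[(m == FORCED_ABSENT) | (m == FORCED_DEAD)] = 0.0
    return out
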