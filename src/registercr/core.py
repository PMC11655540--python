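"""Core model components: latent states, covariates, coefficients, and the
transition/emission probability structure.

The model tracks, for every registered individual and calendar year, a latent
state in {PRESENT, ABSENT, DEAD}.  Survival, emigration (leaving given
present), return (re-entry given absent), de-registration given emigration,
and per-list detection given presence are all Bernoulli events whose
probabilities are logistic functions of individual covariates: intercept,
sex, age, country-of-birth group (7 levels, reference-coded) and time since
first migration (TSM).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatentState",
    "COUNTRY_GROUPS",
    "REFERENCE_COUNTRY_GROUP",
    "ModelConfig",
    "CoefficientSet",
    "logistic_link",
    "transition_kernel",
    "emission_probs",
    "covariate_names",
    "build_design_row",
    "build_design_matrix",
]


class LatentState(enum.IntEnum):
    """Latent yearly state of an individual.

    DEAD is absorbing.  PRESENT/ABSENT both imply alive.
    """

    PRESENT = 0
    ABSENT = 1
    DEAD = 2


#: Country-of-birth groups, in fixed encoding order.
COUNTRY_GROUPS = (
    "Denmark/Norway",
    "Iceland/Finland",
    "Eastern Europe",
    "Western Europe",
    "MENA",
    "USA/Canada/Oceania",
    "Rest of World",
)

#: Reference level for the country-group indicators (all-zero encoding).
REFERENCE_COUNTRY_GROUP = "Western Europe"


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of the observation window and covariate encoding.

    Parameters
    ----------
    n_lists
        Number of detection lists L (socioeconomic registers).
    first_year, last_year
        Inclusive calendar-year observation window; Y = last - first + 1.
    prior_variance
        Variance ``delta`` of the independent N(0, delta) prior placed on
        every regression coefficient.  Default 2.
    age_form
        ``"standardized"`` (default): age enters as (age - age_center) /
        age_scale; ``"raw"``: age in years.
    tsm_form
        ``"linear"`` (default): TSM = y - r_i as a single linear term;
        ``"categorical"``: reference-coded indicators for TSM = 1..tsm_cap,
        with TSM >= tsm_cap pooled and TSM = 0 as reference.
    reference_country_group
        Country group mapped to the all-zero indicator vector.
    """

    n_lists: int = 4
    first_year: int = 2003
    last_year: int = 2016
    prior_variance: float = 2.0
    age_form: str = "standardized"
    age_center: float = 35.0
    age_scale: float = 10.0
    tsm_form: str = "linear"
    tsm_cap: int = 5
    reference_country_group: str = REFERENCE_COUNTRY_GROUP

    def __post_init__(self) -> None:
        if self.n_lists < 1:
            raise ValueError(f"n_lists must be >= 1, got {self.n_lists}")
        if self.last_year < self.first_year:
            raise ValueError(
                f"last_year ({self.last_year}) < first_year ({self.first_year})"
            )
        if self.prior_variance <= 0:
            raise ValueError(f"prior_variance must be > 0, got {self.prior_variance}")
        if self.age_form not in ("standardized", "raw"):
            raise ValueError(f"unknown age_form {self.age_form!r}")
        if self.tsm_form not in ("linear", "categorical"):
            raise ValueError(f"unknown tsm_form {self.tsm_form!r}")
        if self.reference_country_group not in COUNTRY_GROUPS:
            raise ValueError(
                f"unknown reference_country_group {self.reference_country_group!r}"
            )

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def n_covariates(self) -> int:
        """Length p of the covariate vector (intercept included)."""
        base = 1 + 1 + 1 + (len(COUNTRY_GROUPS) - 1)  # intercept, sex, age, cg
        if self.tsm_form == "linear":
            return base + 1
        return base + self.tsm_cap


def covariate_names(config: ModelConfig) -> list[str]:
    """Names of the columns of the design matrix, in order."""
    names = ["intercept", "sex_female", "age"]
    names += [
        f"cg_{g.replace('/', '_').replace(' ', '_')}"
        for g in COUNTRY_GROUPS
        if g != config.reference_country_group
    ]
    if config.tsm_form == "linear":
        names.append("tsm")
    else:
        names += [f"tsm_{k}" + ("plus" if k == config.tsm_cap else "")
                  for k in range(1, config.tsm_cap + 1)]
    return names


def build_design_row(
    config: ModelConfig,
    sex_female: int,
    age: float,
    country_group: str,
    tsm: int,
) -> np.ndarray:
    """Covariate vector x_iy for one individual-year.

    The first element is the constant 1 (intercept).  ``tsm`` must be >= 0:
    covariates are never evaluated before the registration year.
    """
    if tsm < 0:
        raise ValueError(f"time since first migration must be >= 0, got {tsm}")
    if country_group not in COUNTRY_GROUPS:
        raise ValueError(f"unknown country group {country_group!r}")
    x = np.zeros(config.n_covariates)
    x[0] = 1.0
    x[1] = float(sex_female)
    if config.age_form == "standardized":
        x[2] = (age - config.age_center) / config.age_scale
    else:
        x[2] = age
    nonref = [g for g in COUNTRY_GROUPS if g != config.reference_country_group]
    if country_group != config.reference_country_group:
        x[3 + nonref.index(country_group)] = 1.0
    off = 3 + len(nonref)
    if config.tsm_form == "linear":
        x[off] = float(tsm)
    else:
        k = min(tsm, config.tsm_cap)
        if k >= 1:
            x[off + k - 1] = 1.0
    return x


def build_design_matrix(
    config: ModelConfig,
    sex_female: np.ndarray,
    birth_year: np.ndarray,
    country_group: np.ndarray,
    registration_year: np.ndarray,
) -> np.ndarray:
    """Design array of shape (n, Y, p) over the whole observation window.

    Rows for years before an individual's registration are filled (with
    tsm clipped at 0) but are never referenced by the likelihood.
    """
    n = len(sex_female)
    years = config.years
    Y, p = config.n_years, config.n_covariates
    X = np.zeros((n, Y, p))
    X[:, :, 0] = 1.0
    X[:, :, 1] = np.asarray(sex_female, dtype=float)[:, None]
    age = years[None, :] - np.asarray(birth_year, dtype=float)[:, None]
    if config.age_form == "standardized":
        age = (age - config.age_center) / config.age_scale
    X[:, :, 2] = age
    nonref = [g for g in COUNTRY_GROUPS if g != config.reference_country_group]
    cg = np.asarray(country_group)
    for j, g in enumerate(nonref):
        X[:, :, 3 + j] = (cg == g).astype(float)[:, None]
    off = 3 + len(nonref)
    tsm = np.clip(years[None, :] - np.asarray(registration_year)[:, None], 0, None)
    if config.tsm_form == "linear":
        X[:, :, off] = tsm.astype(float)
    else:
        k = np.minimum(tsm, config.tsm_cap)
        for kk in range(1, config.tsm_cap + 1):
            X[:, :, off + kk - 1] = (k == kk).astype(float)
    return X


@dataclass
class CoefficientSet:
    """Regression coefficients of all linear predictors.

    ``beta_phi`` (survival), ``beta_psi`` (staying given present),
    ``beta_eta`` (return given absent), ``beta_lambda`` (de-registration
    given emigration) and ``beta_o[l]`` (detection in list l given presence)
    all share the covariate dimension p.
    """

    beta_phi: np.ndarray
    beta_psi: np.ndarray
    beta_eta: np.ndarray
    beta_lambda: np.ndarray
    beta_o: list[np.ndarray] = field(default_factory=list)

    PREDICTORS = ("phi", "psi", "eta", "lambda")

    def __post_init__(self) -> None:
        self.beta_phi = np.asarray(self.beta_phi, dtype=float)
        self.beta_psi = np.asarray(self.beta_psi, dtype=float)
        self.beta_eta = np.asarray(self.beta_eta, dtype=float)
        self.beta_lambda = np.asarray(self.beta_lambda, dtype=float)
        self.beta_o = [np.asarray(b, dtype=float) for b in self.beta_o]
        p = self.beta_phi.shape[-1]
        for name, b in self.items():
            if b.shape != (p,):
                raise ValueError(
                    f"coefficient vector {name!r} has length {b.shape[-1]}, "
                    f"expected {p}"
                )

    @property
    def p(self) -> int:
        return len(self.beta_phi)

    @property
    def n_lists(self) -> int:
        return len(self.beta_o)

    def items(self):
        yield "phi", self.beta_phi
        yield "psi", self.beta_psi
        yield "eta", self.beta_eta
        yield "lambda", self.beta_lambda
        for l, b in enumerate(self.beta_o):
            yield f"o{l + 1}", b

    def block_names(self) -> list[str]:
        return [name for name, _ in self.items()]

    def flatten(self) -> np.ndarray:
        """Concatenated beta_Omega, block order phi, psi, eta, lambda, o1..oL."""
        return np.concatenate([b for _, b in self.items()])

    @classmethod
    def from_flat(cls, flat: np.ndarray, p: int, n_lists: int) -> "CoefficientSet":
        flat = np.asarray(flat, dtype=float)
        if flat.shape != ((4 + n_lists) * p,):
            raise ValueError(
                f"flat vector has length {flat.size}, expected {(4 + n_lists) * p}"
            )
        blocks = flat.reshape(4 + n_lists, p)
        return cls(blocks[0], blocks[1], blocks[2], blocks[3],
                   [blocks[4 + l] for l in range(n_lists)])

    def copy(self) -> "CoefficientSet":
        return CoefficientSet(
            self.beta_phi.copy(), self.beta_psi.copy(), self.beta_eta.copy(),
            self.beta_lambda.copy(), [b.copy() for b in self.beta_o],
        )


def logistic_link(x: np.ndarray, beta: np.ndarray) -> float | np.ndarray:
    """Inverse-logit of the linear predictor x . beta.

    Numerically stable for arbitrarily large |x . beta| (saturates to 0/1
    in floating point without overflow).  ``x`` and ``beta`` may carry
    leading batch dimensions as long as the trailing dimension matches.
    """
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.shape[-1] != beta.shape[-1]:
        raise ValueError(
            f"covariate vector has length {x.shape[-1]} but coefficient "
            f"vector has length {beta.shape[-1]}"
        )
    eta = x @ beta
    # scipy.special.expit, inlined sign-split for stability at |eta| ~ 1e3
    out = np.empty_like(eta, dtype=float) if eta.ndim else None
    with np.errstate(over="ignore"):
        if eta.ndim == 0:
            return float(1.0 / (1.0 + np.exp(-eta))) if eta >= 0 else float(
                np.exp(eta) / (1.0 + np.exp(eta))
            )
        pos = eta >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
        ex = np.exp(eta[~pos])
        out[~pos] = ex / (1.0 + ex)
    return out


def transition_kernel(
    state: LatentState, x: np.ndarray, params: CoefficientSet
) -> dict[LatentState, float]:
    """Distribution of the year-y state given the year-(y-1) state.

    Survival (phi) is resolved first, then movement: a surviving PRESENT
    individual stays with probability psi, a surviving ABSENT individual
    returns with probability eta.  DEAD is absorbing.  ``x`` is the year-y
    covariate vector.
    """
    if state == LatentState.DEAD:
        return {LatentState.PRESENT: 0.0, LatentState.ABSENT: 0.0,
                LatentState.DEAD: 1.0}
    phi = logistic_link(x, params.beta_phi)
    if state == LatentState.PRESENT:
        psi = logistic_link(x, params.beta_psi)
        return {
            LatentState.PRESENT: phi * psi,
            LatentState.ABSENT: phi * (1.0 - psi),
            LatentState.DEAD: 1.0 - phi,
        }
    eta = logistic_link(x, params.beta_eta)
    return {
        LatentState.PRESENT: phi * eta,
        LatentState.ABSENT: phi * (1.0 - eta),
        LatentState.DEAD: 1.0 - phi,
    }


def emission_probs(
    state_prev: LatentState,
    state_now: LatentState,
    x: np.ndarray,
    params: CoefficientSet,
    obs: np.ndarray,
    e_flag: int = 0,
    d_flag: int = 0,
) -> float:
    """Probability of the observed year record given the (prev, now) state pair.

    ``obs`` holds the L list indicators o_iyl for the year; ``e_flag`` the
    de-registration notification and ``d_flag`` the recorded-death flag.
    A PRESENT year emits independent Bernoulli(theta_l) list indicators and
    no events.  The de-registration Bernoulli(lambda) fires only on a
    PRESENT -> ABSENT transition.  A death is recorded (d=1 with probability
    one) exactly when the transition into DEAD starts from PRESENT; deaths
    from ABSENT are silent.  Impossible records return probability 0.
    """
    obs = np.asarray(obs)
    any_obs = int(obs.sum()) > 0
    if state_now == LatentState.PRESENT:
        if e_flag or d_flag:
            return 0.0
        prob = 1.0
        for l in range(len(params.beta_o)):
            theta = logistic_link(x, params.beta_o[l])
            prob *= theta if obs[l] else (1.0 - theta)
        return float(prob)
    # state_now is ABSENT or DEAD: no list detections possible
    if any_obs:
        return 0.0
    if state_now == LatentState.ABSENT:
        if d_flag:
            return 0.0
        if state_prev == LatentState.PRESENT:
            lam = logistic_link(x, params.beta_lambda)
            return float(lam if e_flag else 1.0 - lam)
        if state_prev == LatentState.ABSENT:
            return 0.0 if e_flag else 1.0
        return 0.0  # DEAD -> ABSENT impossible
    # state_now DEAD
    if e_flag:
        return 0.0
    if state_prev == LatentState.PRESENT:
        return 1.0 if d_flag else 0.0  # in-country deaths always recorded
    if d_flag:
        return 0.0  # deaths from ABSENT (or already DEAD) leave no record
    return 1.0
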