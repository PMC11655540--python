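"""Model/Results interface tying the likelihood, sampler and estimators
together.

``RegisterCRModel`` wraps a cohort (individuals, observations, events) and
a ``ModelConfig``; ``fit`` runs the blocked Metropolis sampler on the
marginalized posterior and returns a ``RegisterCRResults`` carrying the
coefficient draws, convergence diagnostics, smoothed presence
probabilities and over-coverage estimators.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import overcoverage as oc
from .core import CoefficientSet, ModelConfig, covariate_names
from .io import CohortTables, read_cohort, validate_tables
from .likelihood import build_packed, smoothed_presence, total_loglik
from .sampler import MCMCResult, gelman_rubin, log_prior, run_mcmc

__all__ = ["RegisterCRModel", "RegisterCRResults", "load_draws"]


def _param_names(config: ModelConfig) -> list[str]:
    cov = covariate_names(config)
    blocks = ["phi", "psi", "eta", "lambda"] + [
        f"o{l + 1}" for l in range(config.n_lists)]
    return [f"{b}.{c}" for b in blocks for c in cov]


class RegisterCRModel:
    """Multistate capture-recapture model for register panel data.

    Parameters
    ----------
    individuals, observations, events
        The three cohort tables (see :mod:`registercr.io` for the schema).
    config
        Observation window, number of lists, prior variance and covariate
        encoding.  Defaults to the standard 2003-2016 window with 4 lists.
    validate
        Run the full table validation on construction (default True).
    """

    def __init__(
        self,
        individuals: pd.DataFrame,
        observations: pd.DataFrame,
        events: pd.DataFrame,
        config: ModelConfig | None = None,
        validate: bool = True,
    ):
        self.config = config or ModelConfig()
        self.tables = CohortTables(individuals, observations, events)
        if validate:
            validate_tables(self.tables, self.config)
        self.packed = build_packed(individuals, observations, events,
                                   self.config)
        self.param_names = _param_names(self.config)

    @classmethod
    def from_csv(cls, directory, config: ModelConfig | None = None
                 ) -> "RegisterCRModel":
        config = config or ModelConfig()
        tables = read_cohort(directory, config)
        return cls(*tables, config=config, validate=False)

    @classmethod
    def from_cohort(cls, cohort, config: ModelConfig | None = None
                    ) -> "RegisterCRModel":
        """Build from a :class:`~registercr.simulate.SimulatedCohort`."""
        return cls(cohort.individuals, cohort.observations, cohort.events,
                   config=config or cohort.spec.config)

    # -- likelihood / prior -------------------------------------------------

    def loglike(self, params: CoefficientSet) -> float:
        """Marginal log-likelihood at ``params`` (latent states summed out)."""
        return total_loglik(self.packed, params)

    def logposterior(self, params: CoefficientSet) -> float:
        return self.loglike(params) + log_prior(params,
                                                self.config.prior_variance)

    def coefficient_set(self, flat: np.ndarray) -> CoefficientSet:
        return CoefficientSet.from_flat(flat, self.config.n_covariates,
                                        self.config.n_lists)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_iter: int = 15000,
        burnin: int = 5000,
        thin: int = 10,
        n_chains: int = 2,
        seed: int | None = None,
        prior_only: bool = False,
    ) -> "RegisterCRResults":
        """Sample the posterior of beta_Omega; defaults follow the study
        protocol (15,000 iterations, 5,000 burn-in, thin 10, two chains)."""
        raw = run_mcmc(
            None if prior_only else self.packed,
            self.config.n_covariates, self.config.n_lists,
            delta=self.config.prior_variance, n_iter=n_iter, burnin=burnin,
            thin=thin, n_chains=n_chains, seed=seed, prior_only=prior_only,
            param_names=self.param_names,
        )
        return RegisterCRResults(self, raw)


class RegisterCRResults:
    """Posterior draws and derived estimates from a fitted model."""

    def __init__(self, model: RegisterCRModel, raw: MCMCResult):
        self.model = model
        self.draws = raw.draws                  # (chains, kept, K)
        self.param_names = raw.param_names
        self.meta = raw.meta
        self._zhat_mean: np.ndarray | None = None
        self._zhat_draws: np.ndarray | None = None

    # -- posterior summaries ------------------------------------------------

    @property
    def pooled_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.pooled_draws.mean(axis=0)

    @property
    def posterior_sd(self) -> np.ndarray:
        return self.pooled_draws.std(axis=0, ddof=1)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        a = (1.0 - level) / 2.0
        return np.quantile(self.pooled_draws, [a, 1.0 - a], axis=0).T

    def mean_coefficients(self) -> CoefficientSet:
        return self.model.coefficient_set(self.posterior_mean)

    def rhat(self) -> np.ndarray:
        """Split Gelman-Rubin statistic per coefficient."""
        return gelman_rubin(self.draws)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        ci = self.credible_interval(level)
        return pd.DataFrame({
            "mean": self.posterior_mean,
            "sd": self.posterior_sd,
            f"ci_{(1 - level) / 2:.3f}": ci[:, 0],
            f"ci_{1 - (1 - level) / 2:.3f}": ci[:, 1],
            "rhat": self.rhat(),
        }, index=pd.Index(self.param_names, name="parameter"))

    def __str__(self) -> str:
        lines = ["Register capture-recapture model — posterior summary",
                 f"chains: {self.draws.shape[0]}, retained draws/chain: "
                 f"{self.draws.shape[1]}"]
        with pd.option_context("display.max_rows", None,
                               "display.width", 120):
            lines.append(self.summary().round(4).to_string())
        return "\n".join(lines)

    # -- presence posteriors ------------------------------------------------

    def draw_coefficient_sets(self):
        """Iterate CoefficientSet over pooled retained draws."""
        for flat in self.pooled_draws:
            yield self.model.coefficient_set(flat)

    def presence_posterior(self, per_draw: bool = False) -> np.ndarray:
        """Smoothed presence probabilities Zhat, averaged over draws.

        Returns an (n, Y) array aligned with individuals sorted by id
        (years before registration are NaN).  With ``per_draw=True`` also
        returns the (n_draws, n, Y) per-draw array.
        """
        self._compute_presence(need_draws=per_draw)
        if per_draw:
            return self._zhat_mean, self._zhat_draws
        return self._zhat_mean

    def _compute_presence(self, need_draws: bool = False) -> None:
        if self._zhat_mean is not None and (
                not need_draws or self._zhat_draws is not None):
            return
        packed = self.model.packed
        flats = self.pooled_draws
        acc = np.zeros((packed.n, packed.n_years))
        # float32 keeps the per-draw cube tractable for large cohorts
        store = (np.empty((len(flats), packed.n, packed.n_years),
                          dtype=np.float32) if need_draws else None)
        for k, flat in enumerate(flats):
            z = smoothed_presence(packed, self.model.coefficient_set(flat))
            if store is not None:
                store[k] = z
            acc += np.nan_to_num(z)
        mean = acc / len(flats)
        active = (np.arange(packed.n_years)[None, :]
                  >= packed.start[:, None])
        mean[~active] = np.nan
        self._zhat_mean = mean
        if need_draws:
            self._zhat_draws = store

    def presence_table(self) -> pd.DataFrame:
        """Long-format (id, year, zhat) table of presence posteriors."""
        packed = self.model.packed
        z = self.presence_posterior()
        cfg = self.model.config
        rows = []
        for i in range(packed.n):
            for y in range(packed.start[i], packed.n_years):
                rows.append((packed.ids[i], cfg.first_year + y, z[i, y]))
        return pd.DataFrame(rows, columns=["id", "year", "zhat"])

    # -- over-coverage ------------------------------------------------------

    def overcoverage(
        self,
        years: list[int] | None = None,
        by: list[str] | None = None,
        credible_intervals: bool = True,
    ) -> pd.DataFrame:
        """Model-based and register-trace over-coverage table."""
        self._compute_presence(need_draws=credible_intervals)
        ind, obs, ev = self.model.tables
        return oc.oc_table(
            ind, obs, ev, self._zhat_mean, self.model.config, years=years,
            by=by, zhat_draws=self._zhat_draws if credible_intervals else None,
        )

    def gap_summary(self, aggregate: bool = True) -> pd.DataFrame:
        """Presence probabilities of undetected years by gap length."""
        return oc.gap_summary(self.presence_posterior(), self.model.packed,
                              aggregate=aggregate)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Write per-chain draw CSVs plus a JSON run-metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for c in range(self.draws.shape[0]):
            df = pd.DataFrame(self.draws[c], columns=self.param_names)
            df.to_csv(directory / f"draws_chain{c + 1}.csv", index=False)
        meta = dict(self.meta)
        meta["rhat"] = {n: float(r) for n, r in
                        zip(self.param_names, self.rhat())}
        with open(directory / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)


def load_draws(directory) -> tuple[np.ndarray, list[str], dict]:
    """Load draws written by :meth:`RegisterCRResults.save`.

    Returns (draws (chains, kept, K), parameter names, metadata dict).
    """
    directory = Path(directory)
    paths = sorted(directory.glob("draws_chain*.csv"),
                   key=lambda p: int(p.stem.replace("draws_chain", "")))
    if not paths:
        raise FileNotFoundError(f"no draws_chain*.csv under {directory}")
    frames = [pd.read_csv(p) for p in paths]
    names = list(frames[0].columns)
    draws = np.stack([f.to_numpy() for f in frames])
    meta_path = directory / "run_metadata.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return draws, names, meta
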