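"""Posterior sampling for the regression coefficients.

The latent states are marginalized analytically, so the posterior is over
the regression coefficients beta_Omega alone.  Sampling uses random-walk
Metropolis blocked per linear predictor (phi, psi, eta, lambda, one block
per detection list), with the proposal scale and covariance adapted during
burn-in only, so the post-burn-in chain is a standard Metropolis sampler
with a fixed proposal and detailed balance holds exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular

from .core import CoefficientSet
from .likelihood import PackedCohort, _expit, _kernels

__all__ = ["log_prior", "run_mcmc", "gelman_rubin", "MCMCResult"]


def log_prior(params: CoefficientSet | np.ndarray, delta: float = 2.0) -> float:
    """Log-density of the independent N(0, delta) prior over beta_Omega.

    ``delta`` is the prior *variance* (default 2).
    """
    if delta <= 0:
        raise ValueError(f"prior variance must be > 0, got {delta}")
    flat = params.flatten() if isinstance(params, CoefficientSet) else \
        np.asarray(params, dtype=float)
    K = flat.size
    return float(-0.5 * K * np.log(2.0 * np.pi * delta)
                 - 0.5 * np.dot(flat, flat) / delta)


class _BlockedPosterior:
    """Log-posterior with per-block caching of predictor probabilities.

    Updating one predictor block only requires recomputing that block's
    probability matrix before re-running the forward recursion.
    """

    def __init__(self, packed: PackedCohort, p: int, n_lists: int,
                 delta: float, prior_only: bool = False):
        self.packed = packed
        self.p = p
        self.n_lists = n_lists
        self.delta = delta
        self.prior_only = prior_only
        self.n_blocks = 4 + n_lists
        if packed is not None and not prior_only:
            n, Y, _ = packed.X.shape
            self._shape = (n, Y)
            self._X2 = np.ascontiguousarray(packed.X.reshape(n * Y, p))
            self._obs_idx = [np.flatnonzero(packed.obs[:, :, l].reshape(-1))
                             for l in range(n_lists)]

    def _prob(self, beta: np.ndarray) -> np.ndarray:
        return _expit(self._X2 @ beta).reshape(self._shape)

    def _contrib(self, l: int, beta: np.ndarray) -> np.ndarray:
        theta = _expit(self._X2 @ beta)
        with np.errstate(divide="ignore"):
            out = np.log1p(-theta)
            idx = self._obs_idx[l]
            out[idx] = np.log(theta[idx])
        return out.reshape(self._shape)

    def init_state(self, flat: np.ndarray) -> dict:
        params = CoefficientSet.from_flat(flat, self.p, self.n_lists)
        state = {"flat": flat.copy()}
        if self.prior_only:
            state["loglik"] = 0.0
            return state
        state["phi"] = self._prob(params.beta_phi)
        state["psi"] = self._prob(params.beta_psi)
        state["eta"] = self._prob(params.beta_eta)
        state["lam"] = self._prob(params.beta_lambda)
        state["contribs"] = [self._contrib(l, params.beta_o[l])
                             for l in range(self.n_lists)]
        state["logem"] = sum(state["contribs"])
        state["loglik"] = self._forward(state["phi"], state["psi"],
                                        state["eta"], state["lam"],
                                        np.exp(state["logem"]))
        return state

    def _forward(self, phi, psi, eta, lam, em_p) -> float:
        pk = self.packed
        out = np.empty(pk.n)
        _kernels.forward_loglik(pk.start, pk.obs_any, pk.e_flag, pk.d_flag,
                                pk.mask, phi, psi, eta, lam, em_p, out)
        return float(out.sum())

    def block_slice(self, b: int) -> slice:
        return slice(b * self.p, (b + 1) * self.p)

    def loglik_and_grad(self, flat: np.ndarray) -> tuple[float, np.ndarray]:
        """Marginal log-likelihood and its gradient in beta_Omega.

        The gradient uses the score identity for latent-variable models:
        the derivative of each Bernoulli log-term, weighted by the
        smoothed (pairwise) posterior of the latent transition it attaches
        to, accumulated by ``forward_backward_weights``.
        """
        params = CoefficientSet.from_flat(flat, self.p, self.n_lists)
        pk = self.packed
        n, Y = self._shape
        phi = self._prob(params.beta_phi)
        psi = self._prob(params.beta_psi)
        eta = self._prob(params.beta_eta)
        lam = self._prob(params.beta_lambda)
        thetas = [_expit(self._X2 @ b) for b in params.beta_o]
        logem = np.zeros(n * Y)
        with np.errstate(divide="ignore"):
            for l, th in enumerate(thetas):
                c = np.log1p(-th)
                idx = self._obs_idx[l]
                c[idx] = np.log(th[idx])
                logem += c
        em_p = np.exp(logem).reshape(n, Y)
        out = np.empty(n)
        _kernels.forward_loglik(pk.start, pk.obs_any, pk.e_flag, pk.d_flag,
                                pk.mask, phi, psi, eta, lam, em_p, out)
        ll = float(out.sum())
        gphi = np.zeros((n, Y))
        gpsi = np.zeros((n, Y))
        geta = np.zeros((n, Y))
        glam = np.zeros((n, Y))
        gmP = np.zeros((n, Y))
        _kernels.forward_backward_weights(pk.start, pk.obs_any, pk.e_flag,
                                          pk.d_flag, pk.mask, phi, psi, eta,
                                          lam, em_p, gphi, gpsi, geta, glam,
                                          gmP)
        grads = [self._X2.T @ g.ravel()
                 for g in (gphi, gpsi, geta, glam)]
        gm = gmP.ravel()
        for l, th in enumerate(thetas):
            w = -gm * th
            idx = self._obs_idx[l]
            w[idx] = gm[idx] * (1.0 - th[idx])
            grads.append(self._X2.T @ w)
        return ll, np.concatenate(grads)

    def propose(self, state: dict, b: int, new_block: np.ndarray):
        """Log-posterior delta pieces for replacing block b; returns
        (loglik_new, updated-arrays dict)."""
        if self.prior_only:
            return 0.0, {}
        upd: dict = {}
        if b < 4:
            key = ("phi", "psi", "eta", "lam")[b]
            upd[key] = self._prob(new_block)
            phi = upd.get("phi", state["phi"])
            psi = upd.get("psi", state["psi"])
            eta = upd.get("eta", state["eta"])
            lam = upd.get("lam", state["lam"])
            if "em_p" not in state:
                state["em_p"] = np.exp(state["logem"])
            ll = self._forward(phi, psi, eta, lam, state["em_p"])
        else:
            l = b - 4
            contrib = self._contrib(l, new_block)
            logem = state["logem"] - state["contribs"][l] + contrib
            upd["contrib_l"] = (l, contrib)
            upd["logem"] = logem
            ll = self._forward(state["phi"], state["psi"], state["eta"],
                               state["lam"], np.exp(logem))
        return ll, upd

    def accept(self, state: dict, b: int, new_block: np.ndarray,
               loglik: float, upd: dict) -> None:
        state["flat"][self.block_slice(b)] = new_block
        state["loglik"] = loglik
        if self.prior_only:
            return
        for key in ("phi", "psi", "eta", "lam"):
            if key in upd:
                state[key] = upd[key]
        if "logem" in upd:
            l, contrib = upd["contrib_l"]
            state["contribs"][l] = contrib
            state["logem"] = upd["logem"]
            state.pop("em_p", None)  # stale detection-product cache


def _laplace_approx(post: "_BlockedPosterior", delta: float, K: int,
                    maxiter: int = 200):
    """Gaussian (Laplace) approximation to the marginalized posterior.

    Finds the posterior mode with L-BFGS using the analytic score of the
    marginal likelihood, and the Hessian by finite differences of that
    score.  Returns (mode, covariance, covariance Cholesky), or None if
    the mode search or factorization fails; used to precondition the
    block proposals and to drive the independence move.
    """
    from scipy.optimize import minimize

    def fun(flat):
        ll, g = post.loglik_and_grad(flat)
        f = -(ll - 0.5 * np.dot(flat, flat) / delta)
        gr = -(g - flat / delta)
        return f, gr

    try:
        opt = minimize(fun, np.zeros(K), jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-11})
    except Exception:
        return None
    if not np.all(np.isfinite(opt.x)):
        return None
    mode = opt.x
    # central-difference Hessian of the negative log-posterior score
    h = 1e-4
    H = np.empty((K, K))
    for i in range(K):
        e = np.zeros(K)
        e[i] = h
        _, gp = fun(mode + e)
        _, gm = fun(mode - e)
        H[:, i] = (gp - gm) / (2.0 * h)
    H = 0.5 * (H + H.T)
    try:
        w, V = np.linalg.eigh(H)
    except np.linalg.LinAlgError:
        return None
    w = np.maximum(w, 1e-6)
    cov = (V / w) @ V.T
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return None
    return mode, cov, chol


class MCMCResult:
    """Raw sampler output: retained draws per chain plus run metadata."""

    def __init__(self, draws: np.ndarray, param_names: list[str], meta: dict):
        self.draws = draws              # (chains, kept, K)
        self.param_names = param_names
        self.meta = meta

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


def run_mcmc(
    packed: PackedCohort,
    p: int,
    n_lists: int,
    *,
    delta: float = 2.0,
    n_iter: int = 15000,
    burnin: int = 5000,
    thin: int = 10,
    n_chains: int = 2,
    seed: int | None = None,
    init_sd: float = 0.1,
    prior_only: bool = False,
    param_names: list[str] | None = None,
) -> MCMCResult:
    """Blocked adaptive random-walk Metropolis over beta_Omega.

    Defaults follow the study protocol: 15,000 iterations, first 5,000
    discarded as burn-in, every 10th retained, two chains.  Each sweep of
    per-predictor block updates is followed by one global move — an
    independence proposal from the Laplace approximation of the posterior
    when available, otherwise a covariance-adapted joint random walk —
    to traverse cross-predictor correlations.  Adaptation of the per-block
    proposal scale (targeting acceptance in 0.2-0.4) and covariance runs
    during burn-in only.  Fully reproducible given ``seed``.
    """
    if packed is not None and packed.conflicts and not prior_only:
        items = ", ".join(str(c[:2]) for c in packed.conflicts[:10])
        raise ValueError(
            "data inconsistency: observations contradict recorded events for "
            f"individual-years {items}; fix the tables before fitting"
        )
    if burnin >= n_iter:
        raise ValueError(f"burnin ({burnin}) must be < n_iter ({n_iter})")
    post = _BlockedPosterior(packed, p, n_lists, delta, prior_only=prior_only)
    K = (4 + n_lists) * p
    laplace = None if prior_only else _laplace_approx(post, delta, K)
    kept_idx = np.arange(burnin + thin - 1, n_iter, thin)
    n_kept = len(kept_idx)
    draws = np.empty((n_chains, n_kept, K))
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    accept_rates = np.zeros((n_chains, post.n_blocks + 1))
    scales_out = []

    if laplace is not None:
        lap_mode, lap_cov, lap_chol = laplace
        ind_L = 1.2 * lap_chol   # slight inflation for tail robustness

    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        if laplace is not None:
            flat0 = lap_mode + init_sd * (lap_chol @ rng.standard_normal(K))
        else:
            flat0 = rng.normal(0.0, init_sd, size=K)
        state = post.init_state(flat0)
        if not np.isfinite(state["loglik"]):
            raise RuntimeError(
                "posterior is non-finite at initialization; re-initialize "
                "with a smaller init_sd or check the data for inconsistencies"
            )
        lp_blocks = _block_logpriors(state["flat"], post, delta)
        if laplace is not None:
            scales = np.full(post.n_blocks, 2.38 / np.sqrt(p))
            chols = []
            for b in range(post.n_blocks):
                sl = post.block_slice(b)
                try:
                    chols.append(np.linalg.cholesky(lap_cov[sl, sl]))
                except np.linalg.LinAlgError:
                    chols.append(np.eye(p))
            joint_scale = 2.38 / np.sqrt(K)
            joint_chol = lap_chol.copy()
        else:
            scales = np.full(post.n_blocks, 0.1)
            chols = [np.eye(p) for _ in range(post.n_blocks)]
            # joint refreshment move over all of beta_Omega, cov-adapted
            joint_scale = 0.05
            joint_chol = np.eye(K)
        # burn-in covariance adaptation buffers
        hist = np.empty((burnin, K))
        acc_batch = np.zeros(post.n_blocks + 1)
        n_batch = 0
        acc_post = np.zeros(post.n_blocks + 1)
        n_post = 0
        kpos = 0
        for it in range(n_iter):
            adapting = it < burnin
            for b in range(post.n_blocks):
                sl = post.block_slice(b)
                step = scales[b] * (chols[b] @ rng.standard_normal(p))
                new_block = state["flat"][sl] + step
                lp_new = -0.5 * np.dot(new_block, new_block) / delta
                ll_new, upd = post.propose(state, b, new_block)
                log_alpha = (ll_new + lp_new) - (state["loglik"] + lp_blocks[b])
                if np.log(rng.random()) < log_alpha:
                    post.accept(state, b, new_block, ll_new, upd)
                    lp_blocks[b] = lp_new
                    acc_batch[b] += 1
                    if not adapting:
                        acc_post[b] += 1
            # global update: targets cross-predictor posterior correlations
            # that the per-predictor blocks cannot traverse efficiently.
            # With a Laplace approximation available this is an independence
            # proposal from (an inflated) N(mode, H^-1); otherwise a
            # covariance-adapted joint random walk.
            if laplace is not None:
                z = rng.standard_normal(K)
                new_flat = lap_mode + ind_L @ z
                logq_new = -0.5 * np.dot(z, z)
                dev = solve_triangular(ind_L, state["flat"] - lap_mode,
                                       lower=True)
                logq_cur = -0.5 * np.dot(dev, dev)
                q_corr = logq_cur - logq_new
            else:
                new_flat = state["flat"] + joint_scale * (
                    joint_chol @ rng.standard_normal(K))
                q_corr = 0.0
            lp_new_blocks = _block_logpriors(new_flat, post, delta)
            new_state = post.init_state(new_flat)
            log_alpha = ((new_state["loglik"] + lp_new_blocks.sum())
                         - (state["loglik"] + lp_blocks.sum()) + q_corr)
            if np.log(rng.random()) < log_alpha:
                state = new_state
                lp_blocks = lp_new_blocks
                acc_batch[-1] += 1
                if not adapting:
                    acc_post[-1] += 1
            n_batch += 1
            if not adapting:
                n_post += 1
            if adapting:
                hist[it] = state["flat"]
                if n_batch == 25:
                    rates = acc_batch / 25.0
                    scales[rates[:-1] > 0.4] *= 1.25
                    scales[rates[:-1] < 0.2] *= 0.8
                    if laplace is None:
                        if rates[-1] > 0.4:
                            joint_scale *= 1.25
                        elif rates[-1] < 0.2:
                            joint_scale *= 0.8
                    acc_batch[:] = 0.0
                    n_batch = 0
                if laplace is None and it + 1 in (
                        max(200, burnin // 4), burnin // 2,
                        3 * burnin // 4) and it + 1 >= 200:
                    seg = hist[it // 2:it + 1]
                    for b in range(post.n_blocks):
                        cov = np.cov(seg[:, post.block_slice(b)].T) \
                            + 1e-6 * np.eye(p)
                        try:
                            chols[b] = np.linalg.cholesky(cov)
                            scales[b] = 2.38 / np.sqrt(p)
                        except np.linalg.LinAlgError:
                            pass
                    covK = np.cov(seg.T) + 1e-6 * np.eye(K)
                    try:
                        joint_chol = np.linalg.cholesky(covK)
                        joint_scale = 2.38 / np.sqrt(K)
                    except np.linalg.LinAlgError:
                        pass
            elif n_batch == 25:
                acc_batch[:] = 0.0
                n_batch = 0
            if kpos < n_kept and it == kept_idx[kpos]:
                draws[c, kpos] = state["flat"]
                kpos += 1
        accept_rates[c] = acc_post / max(n_post, 1)
        scales_out.append(scales.tolist() + [float(joint_scale)])

    block_names = CoefficientSet.PREDICTORS + tuple(
        f"o{l + 1}" for l in range(n_lists)) + ("joint",)
    meta = {
        "n_iter": n_iter, "burnin": burnin, "thin": thin,
        "n_chains": n_chains, "n_kept_per_chain": n_kept,
        "seed": seed, "prior_variance": delta, "prior_only": prior_only,
        "acceptance_rates": {
            bn: [float(accept_rates[c, b]) for c in range(n_chains)]
            for b, bn in enumerate(block_names)
        },
        "proposal_scales": scales_out,
    }
    return MCMCResult(draws, param_names or [f"b{k}" for k in range(K)], meta)


def _block_logpriors(flat: np.ndarray, post: _BlockedPosterior,
                     delta: float) -> np.ndarray:
    out = np.empty(post.n_blocks)
    for b in range(post.n_blocks):
        x = flat[post.block_slice(b)]
        out[b] = -0.5 * np.dot(x, x) / delta
    return out


def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Split-R-hat per coefficient from draws of shape (chains, n, K).

    Each chain is split in half and the standard between/within variance
    ratio sqrt(((n-1)/n W + B/n) / W) computed over the resulting 2C
    half-chains.  Requires >= 2 chains and >= 10 retained draws per chain.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3 or draws.shape[0] < 2:
        raise ValueError("gelman_rubin requires draws from >= 2 chains, "
                         f"got shape {draws.shape}")
    if draws.shape[1] < 10:
        raise ValueError("need >= 10 retained draws per chain, got "
                         f"{draws.shape[1]}")
    C, n, K = draws.shape
    half = n // 2
    split = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, nn = split.shape[0], half
    chain_means = split.mean(axis=1)                      # (m, K)
    W = split.var(axis=1, ddof=1).mean(axis=0)            # (K,)
    B = nn * chain_means.var(axis=0, ddof=1)              # (K,)
    var_plus = (nn - 1) / nn * W + B / nn
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    rhat[~np.isfinite(rhat) & (B > 0)] = np.inf
    return rhat
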