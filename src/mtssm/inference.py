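"""Adaptive marginal Metropolis-Hastings estimation of the model parameters.

The latent paths are integrated out (approximately) by the Gaussian
approximation filter, so the sampler targets

    log f(Theta | Y)  ~  sum_i loglik_GA(Y_i | Theta) + log prior(Theta)

on the working scale: gamma, eta and the free delta coordinates enter
directly, the concentrations as log kappa (keeping the positive support
without boundary handling).  Priors are independent N(0, prior_sd^2) on
every working-scale coordinate.  Proposals are Gaussian random walks with
covariance (2.38^2 / d) * Sigma, where Sigma is re-estimated from the
chain history at a fixed interval during burn-in and frozen afterwards so
the kept draws target a fixed kernel.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .filtering import FilterError, ga_filter, ga_smoother
from .model import DesignSpec, ModelParams, log_i0, stimuli_equation

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceConfig",
    "PosteriorDraws",
    "Diagnostics",
    "WorkingParams",
    "initialize_params",
    "initial_proposal_cov",
    "run_mh",
    "gelman_rubin",
    "posterior_summary",
    "adaptive_mh",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class InferenceConfig:
    """Sampler settings (defaults follow the full-scale study configuration)."""

    n_chains: int = 20
    n_iter: int = 10_000
    burn_in: int = 2_500
    adapt_interval: int = 25
    prior_sd: float = 5.0
    seed: int = 0
    n_gh_nodes: int = 21
    thin: int = 1
    latent_thin: int = 10
    n_init_starts: int = 5

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.adapt_interval < 1:
            raise ValueError("adapt_interval must be >= 1")
        if self.thin < 1 or self.latent_thin < 1:
            raise ValueError("thin and latent_thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Kept MCMC draws plus latent-path summaries and bookkeeping."""

    draws: np.ndarray  # (chains, kept, d) on the working scale
    parameter_names: tuple
    acceptance_rate: np.ndarray  # per chain
    latent_summaries: Optional[np.ndarray]  # (I, N+1) posterior-mean smoothed paths
    transform: "WorkingParams"
    config: InferenceConfig

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def pooled(self) -> np.ndarray:
        """All kept draws pooled over chains, shape (chains * kept, d)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def natural_draws(self) -> np.ndarray:
        """Pooled draws mapped to the natural scale (kappa back-transformed)."""
        return self.transform.to_natural(self.pooled())


@dataclass
class Diagnostics:
    """Convergence diagnostics per parameter."""

    rhat: dict
    ess: dict
    traces: np.ndarray  # (chains, kept, d)
    flags: list = field(default_factory=list)


class WorkingParams:
    """Bijection between the sampled working vector and :class:`ModelParams`.

    The working vector stacks, in order: gamma (K entries, if the
    categorical term is active), eta (if the covariate term is active),
    delta_2..delta_K (if the interaction is active; delta_1 = 0 is
    excluded for identifiability), and log kappa1, log kappa2 unless the
    concentrations are held fixed.
    """

    def __init__(
        self,
        design: DesignSpec,
        base: Optional[ModelParams] = None,
        fix_kappa: Optional[tuple] = None,
    ):
        self.design = design
        K = design.n_levels
        self.base = base or ModelParams(gamma=np.zeros(K))
        if self.base.gamma.shape[0] != K:
            self.base = self.base.with_(gamma=np.zeros(K), delta=np.zeros(K))
        self.fix_kappa = fix_kappa
        names: list[str] = []
        if design.categorical:
            names += [f"gamma[{lab}]" for lab in design.level_labels]
        if design.covariate:
            names += ["eta"]
        if design.interaction:
            names += [f"delta[{lab}]" for lab in design.level_labels[1:]]
        if fix_kappa is None:
            names += ["log_kappa1", "log_kappa2"]
        self.names = tuple(names)
        self.dim = len(names)

    def to_params(self, vec: np.ndarray) -> ModelParams:
        vec = np.asarray(vec, dtype=float)
        K = self.design.n_levels
        i = 0
        gamma = np.zeros(K)
        eta = 0.0
        delta = np.zeros(K)
        if self.design.categorical:
            gamma = vec[i:i + K].copy()
            i += K
        if self.design.covariate:
            eta = float(vec[i])
            i += 1
        if self.design.interaction:
            delta[1:] = vec[i:i + K - 1]
            i += K - 1
        if self.fix_kappa is None:
            kappa1 = math.exp(float(vec[i]))
            kappa2 = math.exp(float(vec[i + 1]))
        else:
            kappa1, kappa2 = self.fix_kappa
        return self.base.with_(
            gamma=gamma, delta=delta, eta=eta, kappa1=kappa1, kappa2=kappa2
        )

    def from_params(self, params: ModelParams) -> np.ndarray:
        parts = []
        if self.design.categorical:
            parts.append(params.gamma)
        if self.design.covariate:
            parts.append([params.eta])
        if self.design.interaction:
            parts.append(params.delta[1:])
        if self.fix_kappa is None:
            parts.append([math.log(params.kappa1), math.log(params.kappa2)])
        return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])

    def natural_names(self) -> tuple:
        return tuple(
            n.replace("log_kappa", "kappa") if n.startswith("log_kappa") else n
            for n in self.names
        )

    def to_natural(self, draws: np.ndarray) -> np.ndarray:
        """Map working-scale draws (..., d) to the natural scale."""
        out = np.array(draws, dtype=float, copy=True)
        for i, n in enumerate(self.names):
            if n.startswith("log_kappa"):
                out[..., i] = np.exp(out[..., i])
        return out


def _static_loglik_factory(Y, design: DesignSpec, transform: WorkingParams) -> Callable:
    """Observed mixture log-likelihood with the latent state fixed at 0.

    With z = 0 the mixing weight depends only on beta_j, so the likelihood
    factorizes over observations; used for starting values and the initial
    proposal covariance.
    """
    angles = Y.angles if hasattr(Y, "angles") else np.asarray(Y, dtype=float)
    c1 = np.cos(angles - transform.base.mu1)
    c2 = np.cos(angles - transform.base.mu2)

    def loglik(vec: np.ndarray) -> float:
        params = transform.to_params(vec)
        beta = stimuli_equation(design, params)
        l1 = params.kappa1 * c1 - _LOG_2PI - log_i0(params.kappa1)
        l2 = params.kappa2 * c2 - _LOG_2PI - log_i0(params.kappa2)
        b = beta[None, :, None]
        # log(pi) = -log1p(exp(-beta)), log(1-pi) = -log1p(exp(beta))
        logpi = -np.logaddexp(0.0, -b)
        log1mpi = -np.logaddexp(0.0, b)
        return float(np.logaddexp(logpi + l1, log1mpi + l2).sum())

    return loglik


def initialize_params(
    Y,
    design: DesignSpec,
    seed: int = 0,
    fix_kappa: Optional[tuple] = None,
    base: Optional[ModelParams] = None,
    n_starts: int = 5,
) -> ModelParams:
    """Starting values theta_0 from the static (z = 0) mixture likelihood.

    Numerically maximizes the observed likelihood with the latent state
    pinned at zero, multi-starting the optimizer from seeded jitter around
    neutral values to avoid local optima.
    """
    transform = WorkingParams(design, base, fix_kappa)
    loglik = _static_loglik_factory(Y, design, transform)
    rng = np.random.default_rng(seed)
    center = np.zeros(transform.dim)
    if fix_kappa is None:
        center[-2:] = math.log(10.0)  # moderate concentration start
    best = None
    for s in range(max(1, n_starts)):
        x0 = center if s == 0 else center + 0.5 * rng.standard_normal(transform.dim)
        res = minimize(lambda v: -loglik(v), x0, method="L-BFGS-B")
        if best is None or (res.fun < best.fun and np.all(np.isfinite(res.x))):
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("static-likelihood initialization failed on all starts")
    return transform.to_params(best.x)


def finite_diff_hessian(f: Callable, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of scalar f at x."""
    x = np.asarray(x, dtype=float)
    d = x.shape[0]
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] * h[i])
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _regularized_inverse(A: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Symmetrize, floor the eigenvalues, and invert."""
    A = 0.5 * (A + A.T)
    vals, vecs = np.linalg.eigh(A)
    vals = np.maximum(vals, floor)
    return (vecs / vals) @ vecs.T


def initial_proposal_cov(
    theta0: ModelParams,
    Y,
    design: DesignSpec,
    fix_kappa: Optional[tuple] = None,
    floor: float = 1e-8,
) -> np.ndarray:
    """Initial proposal covariance from the static-likelihood Hessian at theta_0.

    Sigma_0 = (-H)^(-1) with H the finite-difference Hessian of the
    observed static likelihood, regularized by an eigenvalue floor so the
    result is positive definite even when the Hessian is singular.
    """
    transform = WorkingParams(design, theta0, fix_kappa)
    loglik = _static_loglik_factory(Y, design, transform)
    x0 = transform.from_params(theta0)
    H = finite_diff_hessian(loglik, x0)
    if not np.all(np.isfinite(H)):
        raise RuntimeError("non-finite entries in the static-likelihood Hessian")
    return _regularized_inverse(-H, floor)


def adaptive_mh(
    logpost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    Sigma0: np.ndarray,
    n_iter: int,
    burn_in: int,
    adapt_interval: int,
    rng: np.random.Generator,
    thin: int = 1,
    on_kept: Optional[Callable[[int, np.ndarray], None]] = None,
    mix_kernel: Optional[tuple] = None,
    mix_every: int = 4,
    cov_adapt_after: Optional[int] = None,
) -> tuple[np.ndarray, float]:
    """Generic adaptive random-walk Metropolis chain.

    Proposal covariance lambda * (2.38^2 / d) * Sigma.  During burn-in,
    every ``adapt_interval`` iterations, Sigma is re-estimated from the
    chain history and the global scale lambda is nudged by a
    Robbins-Monro step toward the 0.234 target acceptance rate (the
    initial Sigma typically understates the marginal posterior spread, so
    scale adaptation is what lets the chain leave the starting basin
    within a short burn-in).  Both are frozen after burn-in so kept draws
    target a fixed kernel.  Returns (kept draws, acceptance rate over the
    post burn-in phase); ``on_kept(k, x)`` is invoked for every kept draw.

    ``mix_kernel = (u, s)`` mixes in a second symmetric proposal — a
    scalar random walk of sd ``s`` along the fixed direction ``u``, used
    every ``mix_every``-th iteration — for targets with a known slow
    ridge that the adapted full-covariance walk traverses poorly.

    Covariance re-estimation only starts once the history holds
    ``cov_adapt_after`` iterations (default 150 d): a d-dimensional
    covariance estimated from a short, autocorrelated transient is worse
    than the analytic starting Sigma, and scale-only adaptation already
    calibrates the step size.  Short burn-ins therefore adapt the scale
    only; study-scale burn-ins re-estimate the full covariance as well.
    """
    x = np.asarray(x0, dtype=float).copy()
    d = x.shape[0]
    base_scale = 2.38 ** 2 / d
    log_lambda = 0.0
    if mix_kernel is not None:
        # the mix kernel owns its direction: remove it from the main
        # kernel's covariance so it cannot dominate the adapted scale
        u_hat = mix_kernel[0] / np.linalg.norm(mix_kernel[0])
        proj = np.eye(d) - np.outer(u_hat, u_hat)
    else:
        proj = np.eye(d)
    Sigma = proj @ np.asarray(Sigma0, dtype=float) @ proj
    L = np.linalg.cholesky(base_scale * Sigma + 1e-9 * np.eye(d))
    lp = logpost(x)
    if not np.isfinite(lp):
        raise RuntimeError("log-posterior not finite at the chain start")
    history = np.empty((n_iter, d))
    kept = []
    n_acc_post = 0
    n_post = 0
    n_acc_block = 0
    n_main_block = 0
    block = 0
    for t in range(n_iter):
        is_mix = mix_kernel is not None and t % mix_every == mix_every - 1
        if is_mix:
            u_dir, s_dir = mix_kernel
            prop = x + (s_dir * rng.standard_normal()) * u_dir
        else:
            prop = x + math.exp(0.5 * log_lambda) * (L @ rng.standard_normal(d))
        try:
            lp_prop = logpost(prop)
        except FilterError as exc:  # reject, do not crash
            logger.warning("filter failure at proposal (iter %d): %s", t, exc)
            lp_prop = -np.inf
        if math.log(rng.random()) < lp_prop - lp:
            x = prop
            lp = lp_prop
            accepted = True
        else:
            accepted = False
        history[t] = x
        if t >= burn_in:
            n_post += 1
            n_acc_post += accepted
            k = t - burn_in
            if k % thin == 0:
                kept.append(x.copy())
                if on_kept is not None:
                    on_kept(len(kept) - 1, x)
        else:
            if not is_mix:  # scale targets the full-covariance kernel only
                n_acc_block += accepted
                n_main_block += 1
            if (t + 1) % adapt_interval == 0 and n_main_block:
                block += 1
                acc_block = n_acc_block / n_main_block
                n_acc_block = 0
                n_main_block = 0
                gain = max(0.2, block ** -0.5)
                log_lambda += gain * (acc_block - 0.234)
                logger.debug(
                    "adapt block %d: acceptance %.3f, log-scale %.3f",
                    block, acc_block, log_lambda,
                )
                min_hist = 150 * d if cov_adapt_after is None else cov_adapt_after
                if t + 1 >= max(d + 2, min_hist):
                    cov = np.atleast_2d(np.cov(history[(t + 1) // 2 : t + 1].T))
                    cov = proj @ cov @ proj + 1e-9 * np.eye(d)
                    try:
                        L = np.linalg.cholesky(base_scale * cov)
                        Sigma = cov
                    except np.linalg.LinAlgError:
                        pass  # keep previous factor
    return np.asarray(kept), (n_acc_post / max(1, n_post))


def _refine_gamma_level(
    angles: np.ndarray, design: DesignSpec, theta0: ModelParams, n_gh_nodes: int
) -> ModelParams:
    """Line-search the common gamma level against the filter likelihood.

    A constant added to every gamma_k can be traded against a constant
    shift of the latent paths, so the static (z = 0) optimum is
    systematically offset in this direction whenever the latent walk
    wanders; the marginal likelihood, which integrates the paths out,
    pins the level.  A two-stage grid search along it costs a few dozen
    filter passes and puts the chains in the right basin.
    """
    I = angles.shape[0]

    def level_ll(c: float) -> float:
        p = theta0.with_(gamma=theta0.gamma + c)
        beta = stimuli_equation(design, p)
        try:
            return sum(
                ga_filter(angles[i], beta, p, n_gh_nodes=n_gh_nodes).loglik
                for i in range(I)
            )
        except FilterError:
            return -np.inf

    coarse = np.linspace(-3.0, 3.0, 25)
    c_best = coarse[int(np.argmax([level_ll(c) for c in coarse]))]
    fine = c_best + np.linspace(-0.25, 0.25, 11)
    c_best = fine[int(np.argmax([level_ll(c) for c in fine]))]
    return theta0.with_(gamma=theta0.gamma + c_best)


def run_mh(
    Y,
    design: DesignSpec,
    config: InferenceConfig,
    base_params: Optional[ModelParams] = None,
    fix_kappa: Optional[tuple] = None,
    theta0: Optional[ModelParams] = None,
    Sigma0: Optional[np.ndarray] = None,
    compute_latent: bool = True,
) -> PosteriorDraws:
    """Sample the posterior of Theta by adaptive marginal Metropolis-Hastings.

    The target combines the filter-based approximate marginal likelihood,
    summed over subjects, with independent N(0, prior_sd^2) priors on each
    working-scale coordinate.  Chains start at the static-likelihood
    optimum theta_0 dispersed by draws from the initial proposal
    covariance; everything is reproducible from ``config.seed``.
    """
    angles = Y.angles if hasattr(Y, "angles") else np.asarray(Y, dtype=float)
    I = angles.shape[0]
    transform = WorkingParams(design, base_params, fix_kappa)
    d = transform.dim
    if theta0 is None:
        theta0 = initialize_params(
            Y, design, seed=config.seed, fix_kappa=fix_kappa,
            base=transform.base, n_starts=config.n_init_starts,
        )
        if design.categorical:
            theta0 = _refine_gamma_level(angles, design, theta0, config.n_gh_nodes)
    prior_var = config.prior_sd ** 2
    if Sigma0 is None:
        Sigma0 = initial_proposal_cov(theta0, Y, design, fix_kappa=fix_kappa)
    # temper the proposal covariance with the prior precision: the posterior
    # can never be flatter than the prior, so flat-likelihood directions get
    # proposal variance ~ prior_var instead of the regularization blow-up
    Sigma0 = _regularized_inverse(
        np.linalg.inv(Sigma0 + 1e-12 * np.eye(d)) + np.eye(d) / prior_var
    )
    level_var = transform.base.z0_var / max(1, I)
    if design.categorical:
        # the common gamma level is pinned only by the initial-state prior
        # (a level shift trades against shifting every latent path), so its
        # posterior variance is ~ z0_var / I — invisible to the static
        # Hessian; seed the proposal covariance with that direction
        K = design.n_levels
        u_hat = np.zeros(d)
        u_hat[:K] = 1.0 / math.sqrt(K)
        Sigma0 = Sigma0 + (K * level_var) * np.outer(u_hat, u_hat)
    x0 = transform.from_params(theta0)

    # dedicated proposal along the gamma-level ridge (see _refine_gamma_level):
    # a scalar walk at the ridge's own posterior scale — the z0-prior term
    # plus whatever variance the tempered Hessian grants the direction —
    # keeps this slow direction mixing regardless of the adapted covariance
    mix_kernel = None
    if design.categorical:
        s_level = 2.4 * math.sqrt(float(u_hat @ Sigma0 @ u_hat))
        mix_kernel = (u_hat, s_level)

    def logpost(vec: np.ndarray) -> float:
        params = transform.to_params(vec)
        beta = stimuli_equation(design, params)
        ll = 0.0
        for i in range(I):
            fr = ga_filter(
                angles[i], beta, params,
                n_gh_nodes=config.n_gh_nodes, subject_label=str(i),
            )
            ll += fr.loglik
        lp = -0.5 * np.sum(vec * vec) / prior_var - 0.5 * d * (_LOG_2PI + np.log(prior_var))
        return ll + lp

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(config.n_chains)]
    L0 = np.linalg.cholesky(Sigma0 + 1e-12 * np.eye(d))

    all_draws = []
    acc_rates = []
    latent_sum = np.zeros_like(angles[:, 0, :], dtype=float)
    latent_count = 0

    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        start = x0 + L0 @ rng.standard_normal(d) if config.n_chains > 1 else x0.copy()

        def on_kept(k: int, vec: np.ndarray) -> None:
            nonlocal latent_count
            if not compute_latent or k % config.latent_thin != 0:
                return
            params = transform.to_params(vec)
            beta = stimuli_equation(design, params)
            for i in range(I):
                fr = ga_smoother(
                    ga_filter(angles[i], beta, params, n_gh_nodes=config.n_gh_nodes),
                    params,
                )
                latent_sum[i] += fr.m_smooth
            latent_count += 1

        draws, acc = adaptive_mh(
            logpost, start, Sigma0,
            n_iter=config.n_iter, burn_in=config.burn_in,
            adapt_interval=config.adapt_interval, rng=rng,
            thin=config.thin, on_kept=on_kept, mix_kernel=mix_kernel,
        )
        if acc < 0.1 or acc > 0.5:
            logger.warning("chain %d acceptance rate %.3f outside [0.1, 0.5]", c, acc)
        all_draws.append(draws)
        acc_rates.append(acc)

    latent = latent_sum / latent_count if (compute_latent and latent_count) else None
    return PosteriorDraws(
        draws=np.asarray(all_draws),
        parameter_names=transform.names,
        acceptance_rate=np.asarray(acc_rates),
        latent_summaries=latent,
        transform=transform,
        config=config,
    )


def gelman_rubin(draws) -> Diagnostics:
    """Classic between/within-chain Gelman-Rubin R-hat plus effective sample size.

    R-hat follows the original (non-split) definition: with m chains of
    length n, W the mean within-chain variance and B/n the variance of the
    chain means, R-hat = sqrt(((n-1)/n W + B/n) / W).  Chains that are all
    identical constants give R-hat = 1 by convention.
    """
    arr = draws.draws if hasattr(draws, "draws") else np.asarray(draws, dtype=float)
    if arr.ndim == 2:
        raise ValueError("at least 2 chains required; for one chain split it in halves")
    m, n, d = arr.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains with >= 10 kept draws each")
    names = (
        tuple(draws.parameter_names)
        if hasattr(draws, "parameter_names")
        else tuple(f"p{i}" for i in range(d))
    )
    import arviz as az

    rhat = {}
    ess = {}
    flags = []
    for p in range(d):
        chains = arr[:, :, p]
        W = chains.var(axis=1, ddof=1).mean()
        B_over_n = chains.mean(axis=1).var(ddof=1)
        if W <= 0:
            r = 1.0
        else:
            r = math.sqrt(((n - 1) / n * W + B_over_n) / W)
        rhat[names[p]] = float(r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess[names[p]] = float(az.ess(np.ascontiguousarray(chains)))
        if r > 1.1:
            flags.append(f"{names[p]}: R-hat {r:.3f} > 1.1")
    return Diagnostics(rhat=rhat, ess=ess, traces=arr, flags=flags)


def posterior_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior table: q0.05, mean, q0.975 and R-hat per natural-scale parameter.

    The asymmetric (q0.05, q0.975) interval matches the conventional
    reporting layout for this model; note it spans 92.5% probability.
    """
    natural = draws.transform.to_natural(draws.draws)
    names = draws.transform.natural_names()
    diag = gelman_rubin(draws)
    rhat_by_working = dict(zip(draws.parameter_names, diag.rhat.values()))
    rows = []
    for p, name in enumerate(names):
        pooled = natural[:, :, p].ravel()
        rows.append(
            {
                "parameter": name,
                "q0.05": float(np.quantile(pooled, 0.05)),
                "mean": float(pooled.mean()),
                "q0.975": float(np.quantile(pooled, 0.975)),
                "rhat": float(rhat_by_working[draws.parameter_names[p]]),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
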