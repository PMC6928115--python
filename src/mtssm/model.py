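"""Densities and design algebra of the mouse-tracking state-space model.

The generative model for subject i, trial j, time step n:

    z_{i,n} | z_{i,n-1}  ~  N(z_{i,n-1}, sigma_i^2)            (latent AR(1) walk)
    y_{ijn} | z_{i,n}    ~  pi_{ijn} vM(mu1, kappa1)
                            + (1 - pi_{ijn}) vM(mu2, kappa2)   (angle mixture)
    pi_{ijn} = logistic(beta_j + z_{i,n})                      (attraction prob.)
    beta_j   = sum_k d_jk gamma_k + x_j (eta + sum_k d_jk delta_k)

vM(mu, kappa) is the von Mises law on the circle; component 1 sits at the
distractor direction mu1 (top-left), component 2 at the target direction
mu2 (top-right).  beta_j is the "stimuli equation": a linear predictor over
a K-level categorical factor (gamma), a continuous covariate (eta) and
their interaction (delta, with delta_1 = 0 for identifiability).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, i0e

__all__ = [
    "DesignSpec",
    "ModelParams",
    "transition_logdensity",
    "vonmises_logdensity",
    "mixture_logdensity",
    "attraction_prob",
    "stimuli_equation",
    "complete_data_loglik",
    "read_design",
    "DEFAULT_MU1",
    "DEFAULT_MU2",
]

#: Default fixed component directions: the screen-corner geometry maps the
#: top-left (distractor) label to 3*pi/4 and the top-right (target) to pi/4.
DEFAULT_MU1 = 3.0 * np.pi / 4.0
DEFAULT_MU2 = np.pi / 4.0

_LOG_2PI = np.log(2.0 * np.pi)


class DesignError(ValueError):
    """Raised for inconsistent experimental-design specifications."""


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: partition matrix, covariate, and active terms.

    ``D`` is the J x K Boolean partition matrix (each trial belongs to
    exactly one level of the categorical factor); ``x`` the optional
    per-trial continuous covariate.  The flags select which terms of the
    stimuli equation are active; inactive terms contribute zero.
    """

    D: np.ndarray
    x: Optional[np.ndarray] = None
    categorical: bool = True
    covariate: bool = False
    interaction: bool = False
    level_labels: tuple = None

    def __post_init__(self) -> None:
        D = np.asarray(self.D)
        if D.ndim != 2:
            raise DesignError("D must be a J x K matrix")
        if not np.all(np.isin(D, (0, 1))):
            raise DesignError("D must be Boolean (0/1)")
        if not np.all(D.sum(axis=1) == 1):
            raise DesignError("each row of D must sum to exactly 1")
        if D.shape[1] > D.shape[0]:
            raise DesignError("K must not exceed J")
        object.__setattr__(self, "D", D.astype(float))
        if self.x is not None:
            x = np.asarray(self.x, dtype=float)
            if x.shape != (D.shape[0],):
                raise DesignError("x must have length J")
            if not np.all(np.isfinite(x)):
                raise DesignError("x contains non-finite values")
            object.__setattr__(self, "x", x)
        if self.interaction and not (self.categorical and self.covariate):
            raise DesignError("interaction requires categorical and covariate terms")
        if self.covariate and self.x is None:
            raise DesignError("covariate term active but x is absent")
        labels = self.level_labels or tuple(f"L{k + 1}" for k in range(D.shape[1]))
        if len(labels) != D.shape[1]:
            raise DesignError("level_labels length must equal K")
        object.__setattr__(self, "level_labels", tuple(labels))

    @property
    def n_trials(self) -> int:
        return self.D.shape[0]

    @property
    def n_levels(self) -> int:
        return self.D.shape[1]

    @classmethod
    def from_levels(
        cls,
        levels: Sequence,
        x: Optional[Sequence] = None,
        categorical: bool = True,
        covariate: bool = False,
        interaction: bool = False,
    ) -> "DesignSpec":
        """Build the partition matrix from per-trial level labels.

        Levels are mapped to columns of D in order of first appearance
        (stable and documented, so coefficient order is predictable).
        """
        labels = list(dict.fromkeys(levels))
        D = np.array([[1 if lev == lab else 0 for lab in labels] for lev in levels])
        return cls(
            D,
            None if x is None else np.asarray(x, dtype=float),
            categorical=categorical,
            covariate=covariate,
            interaction=interaction,
            level_labels=tuple(str(lab) for lab in labels),
        )


@dataclass(frozen=True)
class ModelParams:
    """Model parameters Theta = (gamma, delta, eta, kappa1, kappa2) plus fixed quantities.

    ``mu1``/``mu2`` (component directions) and ``sigma`` (latent innovation
    SD, default 1) are fixed, not estimated; ``z0_mean``/``z0_var`` give
    the N(z0_mean, z0_var) prior on the initial latent state.
    """

    gamma: np.ndarray
    delta: np.ndarray = None
    eta: float = 0.0
    kappa1: float = 1.0
    kappa2: float = 1.0
    mu1: float = DEFAULT_MU1
    mu2: float = DEFAULT_MU2
    sigma: float = 1.0
    z0_mean: float = 0.0
    z0_var: float = 1.0

    def __post_init__(self) -> None:
        gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        object.__setattr__(self, "gamma", gamma)
        delta = self.delta
        if delta is None:
            delta = np.zeros_like(gamma)
        delta = np.atleast_1d(np.asarray(delta, dtype=float))
        if delta.shape != gamma.shape:
            raise ValueError("delta must have the same length K as gamma")
        if delta.size and delta[0] != 0.0:
            raise ValueError("delta[0] must be 0 (identifiability constraint)")
        object.__setattr__(self, "delta", delta)
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("kappa1 and kappa2 must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.z0_var <= 0:
            raise ValueError("z0_var must be positive")

    @property
    def n_levels(self) -> int:
        return self.gamma.shape[0]

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def transition_logdensity(z_curr, z_prev, sigma) -> np.ndarray:
    """Log of the AR(1) Gaussian transition density N(z_curr; z_prev, sigma^2)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    d = np.asarray(z_curr, dtype=float) - np.asarray(z_prev, dtype=float)
    return -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * (d / sigma) ** 2


def log_i0(kappa) -> np.ndarray:
    """log I0(kappa), the modified Bessel function of order zero, stable for large kappa."""
    kappa = np.asarray(kappa, dtype=float)
    return np.log(i0e(kappa)) + kappa


def vonmises_logdensity(y, mu, kappa) -> np.ndarray:
    """Log von Mises density log[ exp(kappa cos(y - mu)) / (2 pi I0(kappa)) ].

    Computed via the exponentially scaled Bessel function so it stays
    finite for large concentrations; kappa = 0 gives the circular uniform.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be non-negative")
    y = np.asarray(y, dtype=float)
    return kappa * np.cos(y - mu) - _LOG_2PI - log_i0(kappa)


def mixture_logdensity(y, pi, params: ModelParams) -> np.ndarray:
    """Log density of the two-component von Mises mixture at mixing weight pi."""
    pi = np.asarray(pi, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must lie in [0, 1]")
    l1 = vonmises_logdensity(y, params.mu1, params.kappa1)
    l2 = vonmises_logdensity(y, params.mu2, params.kappa2)
    with np.errstate(divide="ignore"):
        return np.logaddexp(np.log(pi) + l1, np.log1p(-pi) + l2)


def attraction_prob(beta_j, z, sign_convention: int = 1) -> np.ndarray:
    """Probability that a movement angle is drawn from the distractor component.

    The literal link (``sign_convention=+1``, the default) is
    pi = (1 + exp(-beta - z))^(-1), increasing in both beta and z.
    ``sign_convention=-1`` negates (beta + z) before the logistic,
    reproducing the orientation in which larger beta + z means *lower*
    distractor activation; both are evaluated overflow-safely.
    """
    if sign_convention not in (1, -1):
        raise ValueError("sign_convention must be +1 or -1")
    return expit(sign_convention * (np.asarray(beta_j, dtype=float) + np.asarray(z, dtype=float)))


def stimuli_equation(design: DesignSpec, params: ModelParams) -> np.ndarray:
    """Per-trial linear predictor beta_j of the stimuli equation.

    beta_j = sum_k d_jk gamma_k + x_j (eta + sum_k d_jk delta_k), with
    inactive design terms contributing zero.
    """
    J = design.n_trials
    if design.categorical and params.gamma.shape[0] != design.n_levels:
        raise DesignError("gamma length must equal the number of levels K")
    beta = np.zeros(J)
    if design.categorical:
        beta = beta + design.D @ params.gamma
    if design.covariate or design.interaction:
        if design.x is None:
            raise DesignError("covariate/interaction term active but x is absent")
        slope = np.full(J, params.eta if design.covariate else 0.0)
        if design.interaction:
            slope = slope + design.D @ params.delta
        beta = beta + design.x * slope
    return beta


def complete_data_loglik(
    Z: np.ndarray,
    Y,
    design: DesignSpec,
    params: ModelParams,
    per_trial_state_prior: bool = False,
) -> float:
    """Joint log-density of latent paths and observed angles.

    Sum of the initial-state log-prior, the AR(1) transition log-densities
    and the mixture measurement log-densities.  By default the latent-path
    prior is counted once per subject (the path is shared across that
    subject's trials); ``per_trial_state_prior=True`` restores the
    literal J-fold counting of the factorized complete-data density.
    """
    angles = Y.angles if hasattr(Y, "angles") else np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    I, J, Np1 = angles.shape
    if Z.shape != (I, Np1):
        raise ValueError(f"Z must have shape {(I, Np1)}, got {Z.shape}")
    if design.n_trials != J:
        raise ValueError("design has a different number of trials than Y")

    lp_z0 = -0.5 * _LOG_2PI - 0.5 * np.log(params.z0_var) \
        - 0.5 * (Z[:, 0] - params.z0_mean) ** 2 / params.z0_var
    lp_trans = transition_logdensity(Z[:, 1:], Z[:, :-1], params.sigma)
    state_part = lp_z0.sum() + lp_trans.sum()
    if per_trial_state_prior:
        state_part *= J

    beta = stimuli_equation(design, params)
    pi = attraction_prob(beta[None, :, None], Z[:, None, :])
    meas_part = mixture_logdensity(angles, pi, params).sum()
    return float(state_part + meas_part)


def read_design(
    path,
    categorical: bool = True,
    covariate: bool = False,
    interaction: bool = False,
) -> DesignSpec:
    """Read a `trial,level,x` delimited design file.

    Level strings are mapped to columns of D in first-appearance order.
    The ``x`` column is optional unless the covariate term is active.
    """
    df = pd.read_csv(path)
    if "level" not in df.columns:
        raise DesignError("design file must have a 'level' column")
    x = df["x"].to_numpy(float) if "x" in df.columns else None
    return DesignSpec.from_levels(
        df["level"].tolist(), x,
        categorical=categorical, covariate=covariate, interaction=interaction,
    )
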