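"""Synthetic mouse-tracking angle data with the model's exact statistical structure.

The generator is the model read forwards: latent AR(1) walks per subject,
per-trial stimuli-equation values from an experimental design, and angles
drawn from the two-component von Mises mixture, folded into [0, pi] by the
same absolute-value convention the preprocessing applies to observed
trajectories (so simulator and likelihood stay consistent).

The default scenario emulates a lexical-decision-style study: 22 subjects,
72 trials balanced over a 3-level stimulus factor with a standardized
per-trial covariate, 101 normalized time steps, components at the screen
corners (3*pi/4 distractor, pi/4 target) with concentrations 20 and 45 and
design coefficients of the magnitude reported for such experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import DEFAULT_MU1, DEFAULT_MU2, DesignSpec, ModelParams, attraction_prob, stimuli_equation
from .preprocess import AngleDataset

__all__ = ["SimulationScenario", "simulate_latent", "simulate_angles", "simulate_dataset", "default_scenario"]

DEFAULT_SCENARIO_SEED = 20191217


@dataclass(frozen=True)
class SimulationScenario:
    """Dimensions, true parameters, design and seed of a simulated study."""

    I: int
    J: int
    K: int
    N: int
    theta_true: ModelParams
    design: DesignSpec
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.I, self.J, self.K, self.N) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.design.n_trials != self.J or self.design.n_levels != self.K:
            raise ValueError("design dimensions inconsistent with (J, K)")


def simulate_latent(scenario: SimulationScenario, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw the I x (N+1) latent AR(1) paths.

    z_{i,0} ~ N(z0_mean, z0_var); z_{i,n} = z_{i,n-1} + sigma * eps.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    p = scenario.theta_true
    z = np.empty((scenario.I, scenario.N + 1))
    z[:, 0] = p.z0_mean + np.sqrt(p.z0_var) * rng.standard_normal(scenario.I)
    steps = p.sigma * rng.standard_normal((scenario.I, scenario.N))
    z[:, 1:] = z[:, [0]] + np.cumsum(steps, axis=1)
    return z


def simulate_angles(
    latent: np.ndarray,
    scenario: SimulationScenario,
    rng: Optional[np.random.Generator] = None,
    fold: bool = True,
) -> AngleDataset:
    """Draw the angle array given latent paths.

    For each (i, j, n): component 1 (distractor, mu1) is selected with the
    attraction probability pi_{ijn} and the angle is drawn from the
    selected von Mises law (numpy's envelope-rejection sampler).  With
    ``fold=True`` (default) angles are folded into [0, pi] by absolute
    value, matching what preprocessing does to observed trajectories; at
    the concentrated component directions the model works with, folding
    moves negligible mass.  ``fold=False`` leaves the draws on the full
    circle — the exact model density, which calibration studies of the
    sampler require (the likelihood does not model the fold).
    """
    rng = rng or np.random.default_rng(scenario.seed + 1)
    p = scenario.theta_true
    beta = stimuli_equation(scenario.design, p)
    pi = attraction_prob(beta[None, :, None], latent[:, None, :])
    pick1 = rng.random(pi.shape) < pi
    mu = np.where(pick1, p.mu1, p.mu2)
    kappa = np.where(pick1, p.kappa1, p.kappa2)
    angles = rng.vonmises(mu, kappa)
    if fold:
        angles = np.abs(angles)
    return AngleDataset(angles)


def simulate_dataset(scenario: SimulationScenario) -> tuple[AngleDataset, np.ndarray]:
    """Simulate latent paths and angles in one reproducible call."""
    rng = np.random.default_rng(scenario.seed)
    latent = simulate_latent(scenario, rng)
    return simulate_angles(latent, scenario, rng), latent


def default_scenario(
    I: int = 22,
    J: int = 72,
    K: int = 3,
    N: int = 101,
    seed: int = DEFAULT_SCENARIO_SEED,
    theta_true: Optional[ModelParams] = None,
) -> SimulationScenario:
    """Study-sized scenario: balanced K-level factor, standard-normal covariate.

    Dimension overrides keep the structure (balance, covariate law, true
    coefficient values) so scaled-down instances remain the same study in
    miniature.  J must be divisible by K to stay balanced.
    """
    if J % K != 0:
        raise ValueError("J must be divisible by K for a balanced design")
    rng = np.random.default_rng(seed)
    levels = np.repeat([f"L{k + 1}" for k in range(K)], J // K)
    x = rng.standard_normal(J)
    design = DesignSpec.from_levels(levels, x, categorical=True, covariate=True, interaction=True)
    if theta_true is None:
        gamma = np.resize([0.34, 1.30, 1.31], K).astype(float)
        delta = np.resize([0.0, -0.385, -0.336], K).astype(float)
        delta[0] = 0.0
        theta_true = ModelParams(
            gamma=gamma,
            delta=delta,
            eta=0.40,
            kappa1=20.0,
            kappa2=45.0,
            mu1=DEFAULT_MU1,
            mu2=DEFAULT_MU2,
        )
    return SimulationScenario(I=I, J=J, K=K, N=N, theta_true=theta_true, design=design, seed=seed)
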