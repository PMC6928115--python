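"""Posterior predictive goodness-of-fit, attraction curves, and profile clustering.

The goodness-of-fit index is a bounded histogram-overlap measure: observed
and replicate angle distributions are binned into 36 equal cells on
[0, pi], replicate histograms are averaged over M simulated datasets, and

    fit = 100 * (1 - 0.5 * sum_b |h_obs(b) - h_rep_mean(b)|)

so 100% means the average replicate reproduces the observed angle
distribution exactly and 0% means disjoint support.  The overall index
pools all cells of the data array; the by-subject index applies the same
formula per subject and reports the per-subject values and their mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .filtering import ga_filter, ga_smoother
from .inference import PosteriorDraws
from .model import DesignSpec, ModelParams, attraction_prob, stimuli_equation
from .preprocess import AngleDataset
from .simulate import SimulationScenario, simulate_angles, simulate_latent

logger = logging.getLogger(__name__)

__all__ = [
    "FitReport",
    "WindowStat",
    "ProfileClusters",
    "posterior_predictive_fit",
    "attraction_curve_by_condition",
    "window_statistic",
    "cluster_profiles",
    "histogram_overlap_fit",
]

N_BINS = 36


@dataclass(frozen=True)
class FitReport:
    """0-100% posterior predictive fit indices (0 = bad fit, 100 = optimal)."""

    overall_fit: float
    by_subject_fit: np.ndarray
    by_subject_mean: float
    n_replicates: int


@dataclass(frozen=True)
class WindowStat:
    """Mean attraction probability over a window of normalized process time."""

    window: tuple
    p_delta: float


@dataclass(frozen=True)
class ProfileClusters:
    """Cluster assignment of per-subject latent movement profiles."""

    assignments: np.ndarray  # subject -> cluster id (1-based)
    k: int
    silhouette: float


def _hist(angles: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    counts, _ = np.histogram(angles, bins=n_bins, range=(0.0, np.pi))
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def histogram_overlap_fit(h_obs: np.ndarray, h_rep_mean: np.ndarray) -> float:
    """The 0-100% overlap index between two normalized histograms."""
    return float(100.0 * (1.0 - 0.5 * np.abs(h_obs - h_rep_mean).sum()))


def _draws_to_params(draws: Union[PosteriorDraws, ModelParams], M: int, rng: np.random.Generator):
    if isinstance(draws, ModelParams):
        return [draws] * M
    pooled = draws.pooled()
    n_avail = pooled.shape[0]
    if M > n_avail:
        logger.info("M=%d exceeds %d available draws; sampling with replacement", M, n_avail)
    idx = rng.integers(0, n_avail, size=M)
    return [draws.transform.to_params(pooled[i]) for i in idx]


def posterior_predictive_fit(
    draws: Union[PosteriorDraws, ModelParams],
    Y: AngleDataset,
    design: DesignSpec,
    M: int = 5000,
    seed: Optional[int] = None,
    n_bins: int = N_BINS,
) -> FitReport:
    """Simulation-based goodness-of-fit of the fitted model to the observed angles.

    Draws M parameter vectors with replacement from the kept posterior
    draws (or reuses a single :class:`ModelParams`, e.g. the truth in
    closure checks) and simulates a full replicate dataset per vector.

    The overall index simulates replicates with fresh latent paths from
    the AR(1) prior — it asks whether the fitted model reproduces the
    pooled angle distribution of the whole experiment.  The by-subject
    index asks whether the model reproduces *this* subject's angles given
    that subject's inferred dynamics, so its replicate paths are drawn
    from the subject's smoothed posterior marginals (evaluated at the
    posterior-mean parameters); with fresh prior paths every replicate
    subject is exchangeable and the index would only measure latent-path
    variability, not fit.
    """
    if M < 100:
        raise ValueError("M must be >= 100")
    angles = Y.angles
    I, J, Np1 = angles.shape
    ss = np.random.SeedSequence(seed)
    # separate substreams so the overall index is independent of the
    # subject-conditional replicates (and exactly invariant to relabeling)
    rng, rng_cond = (np.random.default_rng(s) for s in ss.spawn(2))
    params_list = _draws_to_params(draws, M, rng)

    # subject-conditional latent posterior at the central parameter value
    central = params_list[0] if isinstance(draws, ModelParams) else (
        draws.transform.to_params(draws.pooled().mean(axis=0))
    )
    beta_c = stimuli_equation(design, central)
    sm = np.empty((I, Np1))
    sP = np.empty((I, Np1))
    for i in range(I):
        fr = ga_smoother(ga_filter(angles[i], beta_c, central), central)
        sm[i] = fr.m_smooth
        sP[i] = fr.P_smooth

    h_obs_overall = _hist(angles, n_bins)
    h_obs_subj = np.stack([_hist(angles[i], n_bins) for i in range(I)])
    acc_overall = np.zeros(n_bins)
    acc_subj = np.zeros((I, n_bins))
    for params in params_list:
        scen = SimulationScenario(
            I=I, J=J, K=design.n_levels, N=Np1 - 1,
            theta_true=params, design=design,
            seed=int(rng.integers(2 ** 31)),
        )
        latent = simulate_latent(scen, rng)
        rep = simulate_angles(latent, scen, rng).angles
        acc_overall += _hist(rep, n_bins)
        z_cond = sm + np.sqrt(sP) * rng_cond.standard_normal(sm.shape)
        rep_cond = simulate_angles(z_cond, scen, rng_cond).angles
        for i in range(I):
            acc_subj[i] += _hist(rep_cond[i], n_bins)
    acc_overall /= M
    acc_subj /= M
    by_subject = np.array(
        [histogram_overlap_fit(h_obs_subj[i], acc_subj[i]) for i in range(I)]
    )
    return FitReport(
        overall_fit=histogram_overlap_fit(h_obs_overall, acc_overall),
        by_subject_fit=by_subject,
        by_subject_mean=float(by_subject.mean()),
        n_replicates=M,
    )


def attraction_curve_by_condition(
    params: ModelParams,
    design: DesignSpec,
    z_grid: np.ndarray,
    sign_convention: int = 1,
) -> dict:
    """Attraction-probability curves pi(z) per design condition.

    For each level of the categorical factor (and, when the covariate is
    active, at its minimum, median and maximum observed values) the
    logistic link is evaluated at the posterior-mean beta over the latent
    grid.  Keys are level labels, or (level, covariate-label) pairs.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    curves = {}
    levels = design.level_labels if design.categorical else ("all",)
    if design.covariate:
        xv = {"low": float(np.min(design.x)), "mid": float(np.median(design.x)), "high": float(np.max(design.x))}
    for k, lab in enumerate(levels):
        d_row = np.zeros(design.n_levels)
        if design.categorical:
            d_row[k] = 1.0
        base = float(d_row @ params.gamma) if design.categorical else 0.0
        if design.covariate:
            slope = params.eta + (float(d_row @ params.delta) if design.interaction else 0.0)
            for xlab, xval in xv.items():
                beta = base + xval * slope
                curves[(lab, xlab)] = attraction_prob(beta, z_grid, sign_convention)
        else:
            curves[lab] = attraction_prob(base, z_grid, sign_convention)
    return curves


def window_statistic(pi_curve: np.ndarray, window: tuple) -> WindowStat:
    """p_Delta: the mean of the attraction curve over an inclusive step-index window.

    This is the normalized discrete approximation of the integral of the
    probability curve over the selected span of process time.
    """
    pi_curve = np.asarray(pi_curve, dtype=float)
    lo, hi = int(window[0]), int(window[1])
    if lo > hi or lo < 0 or hi >= pi_curve.shape[0]:
        raise ValueError(f"window {window} outside curve support (0, {pi_curve.shape[0] - 1})")
    seg = pi_curve[lo : hi + 1]
    if seg.size == 0:
        raise ValueError("empty window")
    return WindowStat(window=(lo, hi), p_delta=float(seg.mean()))


def _moving_average(paths: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, paths)


def cluster_profiles(
    latent_summaries: np.ndarray,
    k: Union[int, str] = "auto",
    presmooth: bool = True,
) -> ProfileClusters:
    """Group subjects by the functional similarity of their latent profiles.

    Agglomerative (Ward) clustering on the Euclidean distance between
    smoothed-mean latent paths; ``k="auto"`` scans 2..min(8, I-1) and
    takes the silhouette maximizer.  Identical profiles degenerate to a
    single cluster (with a logged warning).
    """
    paths = np.asarray(latent_summaries, dtype=float)
    I = paths.shape[0]
    if I < 2:
        raise ValueError("need at least 2 subjects to cluster")
    if isinstance(k, int) and k > I:
        raise ValueError("k cannot exceed the number of subjects")
    X = _moving_average(paths) if presmooth else paths
    if np.allclose(X, X[0]):
        logger.warning("all latent profiles identical; reporting a single cluster")
        return ProfileClusters(assignments=np.ones(I, dtype=int), k=1, silhouette=float("nan"))
    Z = linkage(X, method="ward")
    if k == "auto":
        best = None
        for kk in range(2, min(8, I - 1) + 1):
            labels = fcluster(Z, t=kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            s = silhouette_score(X, labels)
            if best is None or s > best[0]:
                best = (s, kk, labels)
        if best is None:
            return ProfileClusters(assignments=np.ones(I, dtype=int), k=1, silhouette=float("nan"))
        s, kk, labels = best
        return ProfileClusters(assignments=labels, k=kk, silhouette=float(s))
    labels = fcluster(Z, t=int(k), criterion="maxclust")
    uniq = len(np.unique(labels))
    s = silhouette_score(X, labels) if uniq > 1 else float("nan")
    return ProfileClusters(assignments=labels, k=uniq, silhouette=float(s))
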