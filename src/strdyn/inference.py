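"""Grid Approximate Bayesian Computation over instability-rate parameters.

The late-time model DRL for each parameter combination is compared to the
empirical DRL by Kullback-Leibler divergence (the summary statistic); a
soft Gaussian rejection kernel with scale sigma — calibrated from the
spread of divergences across a primate-like ensemble — converts the
divergences into an approximate posterior over the parameter grid:

    Pr(theta | data)  propto  Pr(theta) exp(-D_KL^2(theta) / 2 sigma^2)

Bayes factors integrate the same weights over each family's grid and are
compared between parameterizations as ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .rates import ParamGrid

__all__ = [
    "InferenceConfig",
    "PosteriorGrid",
    "kl_divergence",
    "primate_sigma",
    "posterior",
    "bayes_factor",
    "bayes_factor_ratio",
    "hdr",
    "posterior_expectation",
    "run_grid_abc",
]


@dataclass
class InferenceConfig:
    """KL summary-statistic settings.

    A pseudocount is added to the raw counts of every length class up to
    ``L_max_kl`` (for the empirical and for every model DRL alike) before
    conditional renormalization on [L_min, L_max_kl]; the divergence uses
    natural logarithms.
    """

    L_min: int = 4
    L_max_kl: int = 200
    pseudocount: float = 1.0
    sigma: float | None = None

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.L_min >= self.L_max_kl:
            raise ValueError("L_min must be below L_max_kl")


def _prep(counts, cfg: InferenceConfig) -> np.ndarray:
    """Pseudocount + conditional renormalization on [L_min, L_max_kl]."""
    if hasattr(counts, "to_array"):
        counts = counts.to_array(cfg.L_max_kl)
    arr = np.zeros(cfg.L_max_kl + 1)
    src = np.asarray(counts, dtype=float)
    n = min(len(src), cfg.L_max_kl + 1)
    arr[:n] = src[:n]
    arr[1:] += cfg.pseudocount
    arr[: cfg.L_min] = 0.0
    return arr / arr.sum()


def kl_divergence(model_counts, empirical_counts, cfg: InferenceConfig | None = None
                  ) -> float:
    """D_KL(empirical || model) in nats over [L_min, L_max_kl].

    Both inputs are raw (or expected) counts per length; pseudocounting
    makes the statistic finite for any pair.  Zero iff the conditioned
    distributions coincide.
    """
    cfg = cfg or InferenceConfig()
    p = _prep(empirical_counts, cfg)
    q = _prep(model_counts, cfg)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def primate_sigma(ensemble, reference, cfg: InferenceConfig | None = None) -> float:
    """Rejection scale from the divergence spread of an ensemble.

    Computes the KL divergence of each ensemble member against the
    reference, discards the largest ceil(5%) values (2 of 36), and sets
    sigma to half the largest retained divergence.
    """
    cfg = cfg or InferenceConfig()
    members = list(ensemble)
    if len(members) < 3:
        raise ValueError("ensemble too small to calibrate sigma")
    div = sorted(kl_divergence(m, reference, cfg) for m in members)
    n_drop = int(np.ceil(0.05 * len(div)))
    retained = div[: len(div) - n_drop]
    return retained[-1] / 2.0


@dataclass
class PosteriorGrid:
    grid: ParamGrid
    prior: np.ndarray
    kl: np.ndarray
    posterior: np.ndarray
    sigma: float
    log_weights: np.ndarray = field(default=None)

    def max_posterior(self):
        """Grid point of maximum posterior mass; ties broken toward the
        lexicographically smallest parameter vector."""
        best = np.flatnonzero(self.posterior == self.posterior.max())
        pts = self.grid.points()
        return min((pts[i] for i in best), key=lambda p: p.theta)

    def mean_posterior(self) -> np.ndarray:
        """Component-wise posterior expectation of the parameter vector."""
        pts = np.array([p.theta for p in self.grid.points()], dtype=float)
        return pts.T @ self.posterior


def posterior(
    kl: np.ndarray, prior: np.ndarray, sigma: float, grid: ParamGrid
) -> PosteriorGrid:
    """Soft-rejection ABC posterior on the grid (log-space; no silent NaN)."""
    kl = np.asarray(kl, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive (degenerate ensemble?)")
    with np.errstate(divide="ignore"):
        logw = np.where(prior > 0, np.log(prior), -np.inf) - kl**2 / (2 * sigma**2)
    lz = logsumexp(logw)
    if not np.isfinite(lz):
        raise FloatingPointError("all posterior weights vanished")
    post = np.exp(logw - lz)
    return PosteriorGrid(grid, prior, kl, post, sigma, logw)


def bayes_factor(kl: np.ndarray, prior: np.ndarray, sigma: float) -> float:
    """Grid quadrature of prior x acceptance probability (Eq. of the
    rejection kernel); comparable across models only at equal sigma."""
    kl = np.asarray(kl, dtype=float)
    return float(np.sum(prior * np.exp(-(kl**2) / (2 * sigma**2))))


def bayes_factor_ratio(
    m1: tuple, m2: tuple
) -> float:
    """BF(M1)/BF(M2); each argument is (kl, prior, sigma).

    Raises if the two models were scored against different sigmas.
    """
    kl1, p1, s1 = m1
    kl2, p2, s2 = m2
    if not np.isclose(s1, s2):
        raise ValueError("Bayes factors are comparable only at equal sigma")
    return bayes_factor(kl1, p1, s1) / bayes_factor(kl2, p2, s2)


def hdr(post: np.ndarray, levels=(0.68, 0.95, 0.997)) -> dict:
    """Highest-density regions: boolean masks of the smallest set of grid
    cells holding each probability level (ties at the cut included)."""
    post = np.asarray(post, dtype=float)
    order = np.argsort(post)[::-1]
    csum = np.cumsum(post[order])
    out = {}
    for level in levels:
        k = int(np.searchsorted(csum, level) + 1)
        k = min(k, len(post))
        cut = post[order[k - 1]]
        mask = post >= cut  # include ties at the threshold
        out[level] = mask
    return out


def posterior_expectation(post: PosteriorGrid, f) -> np.ndarray:
    """E[f(theta)] under the grid posterior; f maps a ParamSpec to a
    scalar or vector (e.g. a rate curve or a model DRL)."""
    pts = post.grid.points()
    acc = None
    for p, w in zip(pts, post.posterior):
        val = np.asarray(f(p), dtype=float) * w
        acc = val if acc is None else acc + val
    return acc


def run_grid_abc(
    grid: ParamGrid,
    prior: np.ndarray,
    empirical_counts,
    sigma: float,
    model_fn,
    cfg: InferenceConfig | None = None,
    return_models: bool = False,
):
    """Score every grid point and assemble the posterior.

    ``model_fn(spec)`` must return the model's late-time DRL as expected
    counts per length (genome scale).  Returns a PosteriorGrid (and the
    model DRLs if requested).
    """
    cfg = cfg or InferenceConfig()
    pts = grid.points()
    if len(prior) != len(pts):
        raise ValueError("prior length does not match grid size")
    kls = np.empty(len(pts))
    models = []
    for i, spec in enumerate(pts):
        counts = model_fn(spec)
        kls[i] = kl_divergence(counts, empirical_counts, cfg)
        if return_models:
            models.append(np.asarray(counts, dtype=float))
    pg = posterior(kls, prior, sigma, grid)
    return (pg, models) if return_models else pg
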