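"""Hierarchical Bayesian inference of burst kinetics by Gibbs sampling.

The generative model for read counts x_ij of gene i in cell j is

    s_i     ~ Gamma(alpha_s, beta_s,i)          (scale parameterization)
    k_on,i  ~ Gamma(alpha_kon, beta_kon)
    k_off,i ~ Gamma(alpha_koff, beta_koff)
    p_ij    ~ Beta(k_on,i, k_off,i)
    x_ij    ~ Poisson(t_i * t_j * s_i * p_ij)

where t_i is a gene-length offset and t_j a per-cell scale-normalization
factor.  All four full conditionals are non-standard univariate densities
and are updated with slice sampling; the rates are sampled on the log scale
(with the Jacobian correction) because their posteriors span orders of
magnitude, while p_ij is sampled on its natural (0, 1) scale.

The log posterior is tracked every iteration as a convergence monitor, and
point estimates are posterior means over the second half of the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import _kernel
from .preprocess import CountMatrix, length_offsets

__all__ = [
    "HyperParams",
    "GibbsState",
    "GibbsChain",
    "PosteriorEstimate",
    "slice_sample",
    "log_posterior",
    "run_gibbs",
    "point_estimates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HyperParams:
    """Gamma hyperpriors (shape alpha, scale beta) for the kinetic rates.

    ``beta_s`` is per gene; when None it defaults to the empirical-Bayes
    choice max_j x_ij, which makes the prior on s_i close to flat over the
    range the data can support.  The defaults beta_kon = beta_koff = 100
    spread the rate priors over the identifiable parameter region.
    """

    alpha_s: float = 1.0
    beta_s: np.ndarray | None = None
    alpha_kon: float = 1.0
    beta_kon: float = 100.0
    alpha_koff: float = 1.0
    beta_koff: float = 100.0

    def __post_init__(self) -> None:
        for name in ("alpha_s", "alpha_kon", "beta_kon", "alpha_koff", "beta_koff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta_s is not None and np.any(np.asarray(self.beta_s) <= 0):
            raise ValueError("beta_s entries must be positive")

    def resolve_beta_s(self, counts: np.ndarray) -> np.ndarray:
        if self.beta_s is not None:
            b = np.broadcast_to(np.asarray(self.beta_s, dtype=float), (counts.shape[0],))
            return np.array(b, dtype=float)
        return np.maximum(counts.max(axis=1).astype(float), 1.0)


@dataclass
class GibbsState:
    """One configuration of the latent variables."""

    p: np.ndarray  # (G, J) in (0, 1)
    kon: np.ndarray  # (G,)
    koff: np.ndarray  # (G,)
    s: np.ndarray  # (G,)


@dataclass
class GibbsChain:
    """Recorded Gibbs trajectories for one count matrix."""

    kon: np.ndarray  # (n_iter, G)
    koff: np.ndarray
    s: np.ndarray
    log_posterior: np.ndarray  # (n_iter,)
    p_mean: np.ndarray  # (G, J), mean over the second half of the chain
    n_iter: int
    seed: int
    gene_ids: tuple[str, ...] = field(default_factory=tuple)
    cell_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def default_burn_in(self) -> int:
        return self.n_iter // 2


@dataclass
class PosteriorEstimate:
    """Posterior means (and Monte-Carlo SEs) of the kinetic parameters."""

    kon: np.ndarray
    koff: np.ndarray
    s: np.ndarray
    p: np.ndarray  # (G, J)
    kon_se: np.ndarray
    koff_se: np.ndarray
    s_se: np.ndarray
    gene_ids: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# reference implementations (pure Python; the numba kernel mirrors these)
# ---------------------------------------------------------------------------


def slice_sample(
    logdensity,
    current: float,
    width: float,
    rng: np.random.Generator,
    max_steps: int = 50,
):
    """One update of a univariate slice sampler (step out + shrinkage).

    Follows Neal's scheme: draw a slice level under the density at the
    current point, expand an interval of size ``width`` by stepping out at
    most ``max_steps`` times, then shrink on rejected proposals.  Leaves the
    target invariant for any (possibly unnormalized) log density.
    """
    f0 = logdensity(current)
    if not np.isfinite(f0):
        raise ValueError("log density must be finite at the current point")
    log_y = f0 - rng.exponential()
    left = current - rng.uniform(0.0, width)
    right = left + width
    j = int(rng.uniform() * max_steps)
    k = max_steps - 1 - j
    while j > 0 and logdensity(left) > log_y:
        left -= width
        j -= 1
    while k > 0 and logdensity(right) > log_y:
        right += width
        k -= 1
    while True:
        prop = rng.uniform(left, right)
        if logdensity(prop) >= log_y:
            return prop
        if prop < current:
            left = prop
        else:
            right = prop


def _offsets(cm: CountMatrix) -> np.ndarray:
    ti = length_offsets(cm)
    tj = cm.norm_factors if cm.norm_factors is not None else np.ones(cm.n_cells)
    return np.outer(ti, tj)


def log_posterior(state: GibbsState, cm: CountMatrix, hyper: HyperParams) -> float:
    """Joint log posterior (up to the constant P(X)) of a state.

    Sum of the Poisson log likelihood with rate t_i t_j s_i p_ij, the
    Beta(k_on,i, k_off,i) log density of each p_ij, and the three gamma
    log priors in their scale parameterization.
    """
    p, kon, koff, s = state.p, state.kon, state.koff, state.s
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("all p_ij must lie strictly inside (0, 1)")
    x = cm.counts.astype(float)
    tt = _offsets(cm)
    b_s = hyper.resolve_beta_s(cm.counts)
    lam = tt * s[:, None] * p
    lp = float(np.sum(x * np.log(lam) - lam - gammaln(x + 1.0)))
    lp += float(
        np.sum(
            gammaln(kon + koff)[:, None]
            - gammaln(kon)[:, None]
            - gammaln(koff)[:, None]
            + (kon[:, None] - 1.0) * np.log(p)
            + (koff[:, None] - 1.0) * np.log(1.0 - p)
        )
    )

    def gamma_logpdf(v, alpha, beta):
        return -v / beta + (alpha - 1.0) * np.log(v) - alpha * np.log(beta) - gammaln(alpha)

    lp += float(np.sum(gamma_logpdf(s, hyper.alpha_s, b_s)))
    lp += float(np.sum(gamma_logpdf(kon, hyper.alpha_kon, hyper.beta_kon)))
    lp += float(np.sum(gamma_logpdf(koff, hyper.alpha_koff, hyper.beta_koff)))
    return lp


# full-conditional log densities (up to constants), exposed for testing and
# for driving the generic slice sampler outside the numba kernel


def conditional_logdens_p(p: float, x_ij: float, lam: float, kon: float, koff: float) -> float:
    """log P(p_ij | ...) up to a constant; lam = t_i t_j s_i."""
    if p <= 0.0 or p >= 1.0:
        return -np.inf
    return (kon - 1.0 + x_ij) * np.log(p) + (koff - 1.0) * np.log1p(-p) - lam * p


def conditional_logdens_s(s: float, alpha: float, beta: float, sum_x: float, sum_tp: float) -> float:
    """log P(s_i | ...) up to a constant; sum_tp = sum_j t_i t_j p_ij."""
    if s <= 0.0:
        return -np.inf
    return (alpha - 1.0 + sum_x) * np.log(s) - s / beta - s * sum_tp


def _initial_state(cm: CountMatrix, tt: np.ndarray) -> GibbsState:
    x = cm.counts.astype(float)
    xn = x / tt
    xmax = np.maximum(xn.max(axis=1), 1e-8)
    p0 = (xn + 0.5) / (xmax[:, None] + 1.0)
    s0 = np.maximum(xn.max(axis=1), 0.5)
    g = cm.n_genes
    return GibbsState(p=p0, kon=np.ones(g), koff=np.ones(g), s=s0)


def run_gibbs(
    cm: CountMatrix,
    hyper: HyperParams | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
) -> GibbsChain:
    """Run the systematic-scan Gibbs sampler on a (filtered) count matrix.

    Each iteration updates every p_ij, then k_on,i, k_off,i and s_i for each
    gene, all by slice sampling.  The full per-iteration traces of the rates
    and the log posterior are recorded; p_ij is summarized by its running
    mean over the second half of the chain.  Reproducible from ``seed``.
    """
    if hyper is None:
        hyper = HyperParams()
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    tt = _offsets(cm)
    init = _initial_state(cm, tt)
    b_s = hyper.resolve_beta_s(cm.counts)
    g = cm.n_genes
    a_s = np.full(g, hyper.alpha_s)
    a_on = np.full(g, hyper.alpha_kon)
    b_on = np.full(g, hyper.beta_kon)
    a_off = np.full(g, hyper.alpha_koff)
    b_off = np.full(g, hyper.beta_koff)
    logger.info("Gibbs: %d genes x %d cells, %d iterations, seed %d", g, cm.n_cells, n_iter, seed)
    kon_tr, koff_tr, s_tr, lp_tr, p_mean = _kernel.run_chain(
        cm.counts.astype(np.float64),
        tt,
        init.p,
        init.kon,
        init.koff,
        init.s,
        a_s,
        b_s,
        a_on,
        b_on,
        a_off,
        b_off,
        int(n_iter),
        int(seed) % (2**32),
    )
    return GibbsChain(
        kon=kon_tr,
        koff=koff_tr,
        s=s_tr,
        log_posterior=lp_tr,
        p_mean=p_mean,
        n_iter=int(n_iter),
        seed=int(seed),
        gene_ids=cm.gene_ids,
        cell_ids=cm.cell_ids,
    )


def _batch_se(draws: np.ndarray, n_batches: int = 20) -> np.ndarray:
    """Batch-means Monte-Carlo standard error along axis 0."""
    n = draws.shape[0]
    nb = min(n_batches, max(2, n // 2))
    usable = (n // nb) * nb
    batches = draws[:usable].reshape(nb, usable // nb, *draws.shape[1:]).mean(axis=1)
    return batches.std(axis=0, ddof=1) / np.sqrt(nb)


def point_estimates(chain: GibbsChain, burn_in: int | None = None) -> PosteriorEstimate:
    """Posterior means over post-burn-in draws (default: second half)."""
    if burn_in is None:
        burn_in = chain.default_burn_in
    if burn_in >= chain.n_iter:
        raise ValueError("burn_in leaves no post-burn-in samples")
    kon = chain.kon[burn_in:]
    koff = chain.koff[burn_in:]
    s = chain.s[burn_in:]
    return PosteriorEstimate(
        kon=kon.mean(axis=0),
        koff=koff.mean(axis=0),
        s=s.mean(axis=0),
        p=chain.p_mean,
        kon_se=_batch_se(kon),
        koff_se=_batch_se(koff),
        s_se=_batch_se(s),
        gene_ids=chain.gene_ids,
    )
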