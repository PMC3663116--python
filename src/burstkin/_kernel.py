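"""Numba inner loops for the Gibbs sampler.

Everything here is a straight transcription of the four full-conditional
slice updates plus the running log-posterior; the public interface lives in
:mod:`burstkin.gibbs`.  The kernel uses numba's own np.random state, seeded
once at entry, so a run is reproducible from a single integer seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# slice-sampler tuning: widths in natural units for p and in log units for
# the rates; cap on step-out expansions
W_P = 0.2
W_LOG = 1.0
MAX_STEPS = 50

_NEG_INF = -1.0e308


@njit(cache=True)
def _logdens_p(p, xij, lam, kon, koff):
    """Full conditional of p_ij up to a constant: Beta(kon,koff) x Poisson.

    lam = t_i * t_j * s_i; terms constant in p are dropped.
    """
    if p <= 0.0 or p >= 1.0:
        return _NEG_INF
    return (kon - 1.0 + xij) * math.log(p) + (koff - 1.0) * math.log(1.0 - p) - lam * p


@njit(cache=True)
def _logdens_logkon(u, koff, alpha, beta, n_cells, sum_logp):
    """Full conditional of ln(kon_i): gamma prior, beta terms, log Jacobian."""
    kon = math.exp(u)
    return (
        alpha * u
        - kon / beta
        + n_cells * (math.lgamma(kon + koff) - math.lgamma(kon))
        + kon * sum_logp
    )


@njit(cache=True)
def _logdens_logkoff(u, kon, alpha, beta, n_cells, sum_log1mp):
    koff = math.exp(u)
    return (
        alpha * u
        - koff / beta
        + n_cells * (math.lgamma(kon + koff) - math.lgamma(koff))
        + koff * sum_log1mp
    )


@njit(cache=True)
def _logdens_logs(u, alpha, beta, sum_x, sum_tp):
    """Full conditional of ln(s_i): gamma prior and Poisson terms."""
    s = math.exp(u)
    return alpha * u - s / beta + sum_x * u - s * sum_tp


# ---------------------------------------------------------------------------
# generic slice update (step out + shrink); one copy per conditional because
# numba dispatch on function-valued arguments is costly in inner loops
# ---------------------------------------------------------------------------


@njit(cache=True)
def _slice_p(x0, xij, lam, kon, koff, w, max_steps):
    ly = _logdens_p(x0, xij, lam, kon, koff) - np.random.exponential()
    u = np.random.uniform(0.0, w)
    left = x0 - u
    right = left + w
    jl = int(np.random.uniform(0.0, 1.0) * max_steps)
    jr = max_steps - 1 - jl
    while jl > 0 and _logdens_p(left, xij, lam, kon, koff) > ly:
        left -= w
        jl -= 1
    while jr > 0 and _logdens_p(right, xij, lam, kon, koff) > ly:
        right += w
        jr -= 1
    while True:
        x1 = np.random.uniform(left, right)
        if _logdens_p(x1, xij, lam, kon, koff) >= ly:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


@njit(cache=True)
def _slice_logkon(x0, koff, alpha, beta, n_cells, sum_logp, w, max_steps):
    ly = _logdens_logkon(x0, koff, alpha, beta, n_cells, sum_logp) - np.random.exponential()
    u = np.random.uniform(0.0, w)
    left = x0 - u
    right = left + w
    jl = int(np.random.uniform(0.0, 1.0) * max_steps)
    jr = max_steps - 1 - jl
    while jl > 0 and _logdens_logkon(left, koff, alpha, beta, n_cells, sum_logp) > ly:
        left -= w
        jl -= 1
    while jr > 0 and _logdens_logkon(right, koff, alpha, beta, n_cells, sum_logp) > ly:
        right += w
        jr -= 1
    while True:
        x1 = np.random.uniform(left, right)
        if _logdens_logkon(x1, koff, alpha, beta, n_cells, sum_logp) >= ly:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


@njit(cache=True)
def _slice_logkoff(x0, kon, alpha, beta, n_cells, sum_log1mp, w, max_steps):
    ly = _logdens_logkoff(x0, kon, alpha, beta, n_cells, sum_log1mp) - np.random.exponential()
    u = np.random.uniform(0.0, w)
    left = x0 - u
    right = left + w
    jl = int(np.random.uniform(0.0, 1.0) * max_steps)
    jr = max_steps - 1 - jl
    while jl > 0 and _logdens_logkoff(left, kon, alpha, beta, n_cells, sum_log1mp) > ly:
        left -= w
        jl -= 1
    while jr > 0 and _logdens_logkoff(right, kon, alpha, beta, n_cells, sum_log1mp) > ly:
        right += w
        jr -= 1
    while True:
        x1 = np.random.uniform(left, right)
        if _logdens_logkoff(x1, kon, alpha, beta, n_cells, sum_log1mp) >= ly:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


@njit(cache=True)
def _slice_logs(x0, alpha, beta, sum_x, sum_tp, w, max_steps):
    ly = _logdens_logs(x0, alpha, beta, sum_x, sum_tp) - np.random.exponential()
    u = np.random.uniform(0.0, w)
    left = x0 - u
    right = left + w
    jl = int(np.random.uniform(0.0, 1.0) * max_steps)
    jr = max_steps - 1 - jl
    while jl > 0 and _logdens_logs(left, alpha, beta, sum_x, sum_tp) > ly:
        left -= w
        jl -= 1
    while jr > 0 and _logdens_logs(right, alpha, beta, sum_x, sum_tp) > ly:
        right += w
        jr -= 1
    while True:
        x1 = np.random.uniform(left, right)
        if _logdens_logs(x1, alpha, beta, sum_x, sum_tp) >= ly:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


@njit(cache=True)
def _log_posterior(x, tt, p, kon, koff, s, a_s, b_s, a_on, b_on, a_off, b_off):
    G, J = x.shape
    lp = 0.0
    for i in range(G):
        for j in range(J):
            lam = tt[i, j] * s[i] * p[i, j]
            lp += x[i, j] * math.log(lam) - lam - math.lgamma(x[i, j] + 1.0)
            lp += (
                math.lgamma(kon[i] + koff[i])
                - math.lgamma(kon[i])
                - math.lgamma(koff[i])
                + (kon[i] - 1.0) * math.log(p[i, j])
                + (koff[i] - 1.0) * math.log(1.0 - p[i, j])
            )
        lp += -s[i] / b_s[i] + (a_s[i] - 1.0) * math.log(s[i]) - a_s[i] * math.log(b_s[i]) - math.lgamma(a_s[i])
        lp += -kon[i] / b_on[i] + (a_on[i] - 1.0) * math.log(kon[i]) - a_on[i] * math.log(b_on[i]) - math.lgamma(a_on[i])
        lp += -koff[i] / b_off[i] + (a_off[i] - 1.0) * math.log(koff[i]) - a_off[i] * math.log(b_off[i]) - math.lgamma(a_off[i])
    return lp


@njit(cache=True)
def run_chain(x, tt, p0, kon0, koff0, s0, a_s, b_s, a_on, b_on, a_off, b_off, n_iter, seed):
    """Systematic-scan Gibbs chain.

    Per iteration: every p_ij (gene-major), then kon_i, koff_i, s_i for each
    gene.  Returns per-iteration traces of the rates and the log posterior,
    plus the running mean of p over the second half of the chain.
    """
    np.random.seed(seed)
    G, J = x.shape
    p = p0.copy()
    kon = kon0.copy()
    koff = koff0.copy()
    s = s0.copy()
    kon_tr = np.empty((n_iter, G))
    koff_tr = np.empty((n_iter, G))
    s_tr = np.empty((n_iter, G))
    lp_tr = np.empty(n_iter)
    burn = n_iter // 2
    p_sum = np.zeros((G, J))
    n_kept = 0
    for it in range(n_iter):
        for i in range(G):
            lam_base = s[i]
            for j in range(J):
                p[i, j] = _slice_p(
                    p[i, j], x[i, j], tt[i, j] * lam_base, kon[i], koff[i], W_P, MAX_STEPS
                )
        for i in range(G):
            sum_logp = 0.0
            sum_log1mp = 0.0
            sum_tp = 0.0
            sum_x = 0.0
            for j in range(J):
                sum_logp += math.log(p[i, j])
                sum_log1mp += math.log(1.0 - p[i, j])
                sum_tp += tt[i, j] * p[i, j]
                sum_x += x[i, j]
            kon[i] = math.exp(
                _slice_logkon(math.log(kon[i]), koff[i], a_on[i], b_on[i], J, sum_logp, W_LOG, MAX_STEPS)
            )
            koff[i] = math.exp(
                _slice_logkoff(math.log(koff[i]), kon[i], a_off[i], b_off[i], J, sum_log1mp, W_LOG, MAX_STEPS)
            )
            s[i] = math.exp(
                _slice_logs(math.log(s[i]), a_s[i], b_s[i], sum_x, sum_tp, W_LOG, MAX_STEPS)
            )
        kon_tr[it] = kon
        koff_tr[it] = koff
        s_tr[it] = s
        lp_tr[it] = _log_posterior(x, tt, p, kon, koff, s, a_s, b_s, a_on, b_on, a_off, b_off)
        if it >= burn:
            p_sum += p
            n_kept += 1
    return kon_tr, koff_tr, s_tr, lp_tr, p_sum / n_kept
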