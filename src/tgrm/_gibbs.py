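"""Numba inner loops for single-site Gibbs updates of marker effects.

The samplers keep a running residual ``e = y - mu - W a`` so each marker
update costs O(n).  Randomness is drawn outside (from a seeded
``numpy.random.Generator``) and passed in as arrays, which keeps chains
bit-reproducible and the compiled code free of RNG state.

``W`` must be Fortran-ordered so column slices are contiguous.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sweep_dense", "sweep_mixture"]


@njit(cache=True, fastmath=False)
def sweep_dense(W, wtw, e, a, var_a, sigma2e, z):
    """One sweep for priors with no point mass (BRR, Bayes A, BL).

    ``var_a[p]`` is the current prior variance of effect p.  Markers with
    ``wtw[p] <= 0`` (flagged zero-variance columns) are skipped.
    """
    n, P = W.shape
    for p in range(P):
        c = wtw[p]
        if c <= 0.0 or var_a[p] <= 0.0:
            continue
        ap_old = a[p]
        r = c * ap_old
        for i in range(n):
            r += W[i, p] * e[i]
        lam = sigma2e / var_a[p]
        denom = c + lam
        ap_new = r / denom + z[p] * np.sqrt(sigma2e / denom)
        diff = ap_new - ap_old
        if diff != 0.0:
            for i in range(n):
                e[i] -= W[i, p] * diff
        a[p] = ap_new


@njit(cache=True, fastmath=False)
def sweep_mixture(W, wtw, e, a, delta, var_a, sigma2e, pi, z, u):
    """One sweep for point-mass mixture priors (Bayes B, Bayes Cpi).

    ``pi`` is the probability of the point mass at zero (exclusion).  The
    indicator and the effect are updated jointly: the effect is integrated
    out of the inclusion odds, then drawn from its conditional if included.
    Returns the number of included markers.
    """
    n, P = W.shape
    log_prior_odds = np.log(1.0 - pi) - np.log(pi) if 0.0 < pi < 1.0 else (
        np.inf if pi <= 0.0 else -np.inf
    )
    n_incl = 0
    for p in range(P):
        c = wtw[p]
        if c <= 0.0 or var_a[p] <= 0.0:
            a[p] = 0.0
            delta[p] = 0
            continue
        ap_old = a[p]
        r = c * ap_old
        for i in range(n):
            r += W[i, p] * e[i]
        lam = sigma2e / var_a[p]
        denom = c + lam
        log_odds = (
            log_prior_odds
            + 0.5 * np.log(lam / denom)
            + 0.5 * r * r / (sigma2e * denom)
        )
        if log_odds > 35.0:
            prob_in = 1.0
        elif log_odds < -35.0:
            prob_in = 0.0
        else:
            prob_in = 1.0 / (1.0 + np.exp(-log_odds))
        if u[p] < prob_in:
            ap_new = r / denom + z[p] * np.sqrt(sigma2e / denom)
            delta[p] = 1
            n_incl += 1
        else:
            ap_new = 0.0
            delta[p] = 0
        diff = ap_new - ap_old
        if diff != 0.0:
            for i in range(n):
                e[i] -= W[i, p] * diff
        a[p] = ap_new
    return n_incl
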