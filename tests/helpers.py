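"""Reference (oracle) implementations used only by the tests.

These deliberately use slow, direct linear algebra so they stay independent
of the package's optimised code paths.
"""

from __future__ import annotations

import numpy as np


def solve_mme_dense(y, X, Z_blocks, sigma2_e):
    """Henderson's mixed-model equations solved densely.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design
    Z_blocks : list of (Z, sigma2) random-effect designs with iid variances
    sigma2_e : residual variance

    Returns (beta_hat, [u_hat per block], C_inv) with C_inv the inverse
    coefficient matrix (multiply by sigma2_e for sampling (co)variances).
    """
    W = np.hstack([X] + [Z for Z, _ in Z_blocks])
    C = W.T @ W
    p = X.shape[1]
    start = p
    for Z, s2 in Z_blocks:
        q = Z.shape[1]
        C[np.arange(start, start + q), np.arange(start, start + q)] += sigma2_e / s2
        start += q
    C_inv = np.linalg.inv(C)
    sol = C_inv @ (W.T @ y)
    beta = sol[:p]
    us, start = [], p
    for Z, _ in Z_blocks:
        q = Z.shape[1]
        us.append(sol[start:start + q])
        start += q
    return beta, us, C_inv


def dense_kernel_gibbs(y, K, sigma2_u, sigma2_e, n_iter, burn_in, thin, seed,
                       masked=None):
    """Single-kernel BLUP Gibbs sampler in the original (unrotated) basis.

    Variances are fixed; genetic values are drawn jointly from their full
    conditional N(C r / sigma2_e, C) with C = (I_obs/sigma2_e + K^{-1}/
    sigma2_u)^{-1}; masked lines contribute no likelihood term.  Serves as
    the slow oracle for the eigenbasis sampler.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    obs = np.ones(n, dtype=bool)
    if masked is not None:
        obs[np.asarray(masked, dtype=int)] = False
    Kinv = np.linalg.inv(K + 1e-8 * np.eye(n))
    mu = float(np.mean(y[obs]))
    g = np.zeros(n)
    g_sum = np.zeros(n)
    kept = 0
    D_obs = np.diag(obs.astype(float))
    prec = D_obs / sigma2_e + Kinv / sigma2_u
    cov = np.linalg.inv(prec)
    L = np.linalg.cholesky((cov + cov.T) / 2.0)
    for it in range(1, n_iter + 1):
        r = np.where(obs, (y - mu), 0.0) / sigma2_e
        mean = cov @ r
        g = mean + L @ rng.standard_normal(n)
        mu = float(np.mean(y[obs] - g[obs])) + rng.standard_normal() * np.sqrt(
            sigma2_e / obs.sum()
        )
        if it > burn_in and (it - burn_in) % thin == 0:
            g_sum += g
            kept += 1
    return g_sum / kept
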