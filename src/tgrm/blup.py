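"""Kernel-based genomic prediction models.

Two Bayesian BLUP-style models fitted by Gibbs sampling:

- :class:`KernelBLUP` — ``y = mu + sum_t Z_u u_t + Z_e s + e`` with one or
  more line x line kernels (``u_t ~ N(0, sigma2_t K_t)``) and fixed trial
  effects.  With a single VanRaden kernel this is gBLUP; with one
  trait-weighted kernel it is TGRM-BLUP; with several it is the
  multi-kernel model.
- :class:`MultiTraitGBLUP` — ``Y = mu + Z_U U + e`` with matrix-normal
  genetic values (row covariance a kernel, column covariance unstructured)
  and unstructured residual covariance, both under inverse-Wishart priors.

Both models rotate the random effects into each kernel's eigenbasis, where
the conditional precision is diagonal (KernelBLUP) or block-diagonal by
eigencomponent (multi-trait), and treat unobserved phenotypes — including
the masked prediction targets of a cross-validation fold — by data
augmentation, which keeps the design balanced inside the sampler.  Masked
lines receive genomic values through their kernel rows; their observed
phenotypes never enter the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import Kernel
from .wgr import WGRConfig

__all__ = [
    "KernelBLUP",
    "KernelBLUPResults",
    "MultiTraitGBLUP",
    "MultiTraitResults",
]

_EIG_TOL = 1e-8


def _safe_cholesky(S: np.ndarray) -> np.ndarray:
    """Cholesky factor robust to tiny negative eigenvalues from round-off."""
    S = (S + S.T) / 2.0
    jitter = 1e-12 * max(float(np.trace(S)) / max(S.shape[0], 1), 1.0)
    for _ in range(3):
        try:
            return np.linalg.cholesky(S + jitter * np.eye(S.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 1e3
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, 1e-10 * max(w.max(), 1.0))
    return np.linalg.cholesky((V * w) @ V.T)


def _pd_clip(S: np.ndarray, rel: float = 1e-10) -> np.ndarray:
    """Symmetrise and clip eigenvalues to keep a covariance scale PD."""
    S = (S + S.T) / 2.0
    w, V = np.linalg.eigh(S)
    floor = rel * max(float(w.max()), 1e-300)
    if w.min() >= floor:
        return S
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def _psd_inverse(S: np.ndarray) -> np.ndarray:
    """Symmetric PD inverse via eigenvalue clipping (robust to near-singular
    covariance draws)."""
    S = (S + S.T) / 2.0
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, 1e-10 * max(float(w.max()), 1e-300))
    return (V / w) @ V.T


def _eigh_cached(kernel: Kernel):
    """Eigendecomposition with tiny-eigenvalue clipping, cached on the kernel."""
    cache = getattr(kernel, "_eig_cache", None)
    if cache is None:
        d, V = np.linalg.eigh(kernel.values)
        # components below a relative tolerance (including bent-in 1e-6
        # eigenvalues) are dropped: 1/d weighting on them is pure noise
        tol = max(_EIG_TOL, 1e-6 * float(d.max()) if d.size else 0.0)
        d = np.where(d < tol, 0.0, d)
        cache = (d, V)
        kernel._eig_cache = cache
    return cache


def _response_matrix(response, line_ids):
    """Long (line_id, trial, value) table or line Series -> lines x trials
    matrix over ``line_ids`` with NaN for unobserved cells."""
    if isinstance(response, pd.Series):
        frame = response.rename("value").rename_axis("line_id").reset_index()
        frame["trial"] = "all"
        response = frame
    piv = response.pivot_table(index="line_id", columns="trial", values="value",
                               aggfunc="mean")
    unknown = set(piv.index) - set(line_ids)
    if unknown:
        raise ValueError(f"response lines missing from kernels: {sorted(unknown)[:5]}")
    return piv.reindex(line_ids)


class KernelBLUP:
    """Single- or multi-kernel BLUP with fixed trial effects.

    Parameters
    ----------
    response : DataFrame (line_id, trial, value) or Series indexed by line
        Observations; a line may appear in several trials.
    kernels : mapping label -> Kernel, or a single Kernel
        All kernels must cover the same line set in the same order; lines
        present in the kernels but absent from the response (or listed in
        ``masked_lines``) are predicted, not fitted.
    masked_lines : iterable of str
        Lines whose phenotypes are excluded from the likelihood (CV test
        folds).
    config : WGRConfig
        Supplies chain length, prior_r2, df_prior and seed (``method`` is
        ignored).
    """

    def __init__(self, response, kernels, masked_lines=(), config: WGRConfig | None = None):
        if isinstance(kernels, Kernel):
            kernels = {kernels.kind: kernels}
        self.kernel_labels = list(kernels)
        self.kernels = kernels
        first = kernels[self.kernel_labels[0]]
        self.line_ids = np.asarray(first.line_ids, dtype=object)
        for lab in self.kernel_labels[1:]:
            if not np.array_equal(kernels[lab].line_ids, self.line_ids):
                raise ValueError("kernels must share an identical line set/order")
        self.config = config or WGRConfig()

        Y = _response_matrix(response, self.line_ids)
        self.trials = list(Y.columns)
        mask = np.asarray(Y.notna())
        masked_lines = set(masked_lines)
        unknown = masked_lines - set(self.line_ids)
        if unknown:
            raise ValueError(f"masked lines not in kernels: {sorted(unknown)[:5]}")
        line_masked = np.array([l in masked_lines for l in self.line_ids])
        mask[line_masked, :] = False
        self.observed = mask                    # cells entering the likelihood
        self.Y_obs = np.asarray(Y, dtype=float)
        self.masked_lines = masked_lines
        if not mask.any():
            raise ValueError("no observed cells remain after masking")

    def fit(self, fixed: dict | None = None) -> "KernelBLUPResults":
        """Gibbs sampling; ``fixed`` may pin ``sigma2_e`` and/or per-kernel
        variances via ``{"sigma2_e": v, "sigma2_u": {label: v}}``."""
        cfg = self.config
        fixed = fixed or {}
        rng = np.random.default_rng(cfg.seed)
        n = len(self.line_ids)
        E = len(self.trials)
        K = len(self.kernel_labels)
        df = cfg.df_prior
        R2 = cfg.prior_r2

        obs = self.observed
        y_obs_vals = self.Y_obs[obs]
        vy = float(np.var(y_obs_vals))
        if vy <= 0:
            vy = 1.0

        eigs = {lab: _eigh_cached(self.kernels[lab]) for lab in self.kernel_labels}
        mean_diag = {
            lab: max(float(np.trace(self.kernels[lab].values)) / n, 1e-8)
            for lab in self.kernel_labels
        }
        S_e = vy * (1.0 - R2) * (df + 2.0) / df
        S_u = {lab: R2 * vy / K / mean_diag[lab] * (df + 2.0) / df
               for lab in self.kernel_labels}

        s2e_fixed = "sigma2_e" in fixed
        s2u_fixed = dict(fixed.get("sigma2_u", {}))
        sigma2e = float(fixed.get("sigma2_e", vy * (1.0 - R2)))
        sigma2u = {lab: float(s2u_fixed.get(lab, R2 * vy / K / mean_diag[lab]))
                   for lab in self.kernel_labels}

        alpha = {lab: np.zeros(n) for lab in self.kernel_labels}
        u = {lab: np.zeros(n) for lab in self.kernel_labels}
        g = np.zeros(n)
        mu = np.full(E, float(np.mean(y_obs_vals)))
        Y = np.where(obs, self.Y_obs, 0.0)

        n_kept = 0
        g_sum = np.zeros(n)
        u_sum = {lab: np.zeros(n) for lab in self.kernel_labels}
        mu_sum = np.zeros(E)
        s2u_sum = {lab: 0.0 for lab in self.kernel_labels}
        s2e_sum = 0.0

        miss = ~obs
        for it in range(1, cfg.n_iter + 1):
            # data augmentation for unobserved cells keeps the design balanced
            if miss.any():
                pred = mu[None, :] + g[:, None]
                Y[miss] = pred[miss] + rng.standard_normal(int(miss.sum())) * np.sqrt(sigma2e)

            # per-trial intercepts (flat prior); mu absorbs the grand mean and
            # s_e = mu_e - mean(mu) are the trial effects
            col_res = (Y - g[:, None]).mean(axis=0)
            mu = col_res + rng.standard_normal(E) * np.sqrt(sigma2e / n)

            r_base = (Y - mu[None, :]).sum(axis=1)  # line-level residual sums
            for lab in self.kernel_labels:
                d, V = eigs[lab]
                r = r_base - E * (g - u[lab])
                rt = V.T @ r
                pos = d > 0
                prec = E / sigma2e + np.where(pos, 1.0 / (sigma2u[lab] * np.where(pos, d, 1.0)), np.inf)
                var = np.where(pos, 1.0 / prec, 0.0)
                mean = var * rt / sigma2e
                alpha_new = mean + rng.standard_normal(n) * np.sqrt(var)
                alpha[lab] = alpha_new
                u_new = V @ alpha_new
                g = g - u[lab] + u_new
                u[lab] = u_new

                if lab not in s2u_fixed:
                    m = int(pos.sum())
                    quad = float(np.sum(alpha_new[pos] ** 2 / d[pos]))
                    sigma2u[lab] = max(
                        (quad + df * S_u[lab]) / rng.chisquare(df + m), 1e-12
                    )

            if not s2e_fixed:
                resid = Y - mu[None, :] - g[:, None]
                sigma2e = max(
                    (float(np.sum(resid**2)) + df * S_e) / rng.chisquare(df + n * E),
                    1e-12,
                )

            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                n_kept += 1
                g_sum += g
                mu_sum += mu
                s2e_sum += sigma2e
                for lab in self.kernel_labels:
                    u_sum[lab] += u[lab]
                    s2u_sum[lab] += sigma2u[lab]

        gebv = pd.Series(g_sum / n_kept, index=self.line_ids, name="gebv")
        u_mean = pd.DataFrame(
            {lab: u_sum[lab] / n_kept for lab in self.kernel_labels}, index=self.line_ids
        )
        mu_mean = mu_sum / n_kept
        return KernelBLUPResults(
            model=self,
            gebv=gebv,
            kernel_values=u_mean,
            kernel_variances={lab: s2u_sum[lab] / n_kept for lab in self.kernel_labels},
            sigma2_e=s2e_sum / n_kept,
            intercept=float(np.mean(mu_mean)),
            trial_effects=pd.Series(mu_mean - np.mean(mu_mean), index=self.trials),
            n_retained=n_kept,
        )


@dataclass
class KernelBLUPResults:
    """Posterior means of a kernel BLUP fit."""

    model: KernelBLUP
    gebv: pd.Series                 # total genomic value per line (sum over kernels)
    kernel_values: pd.DataFrame     # per-kernel genomic values
    kernel_variances: dict
    sigma2_e: float
    intercept: float
    trial_effects: pd.Series
    n_retained: int

    def predict_gebv(self, line_ids=None) -> pd.Series:
        if line_ids is None:
            return self.gebv.copy()
        missing = [l for l in line_ids if l not in self.gebv.index]
        if missing:
            raise KeyError(f"unknown lines: {missing[:5]}")
        return self.gebv.loc[list(line_ids)]

    def summary(self) -> str:
        lines = [
            f"Kernel BLUP fit: {len(self.model.kernel_labels)} kernel(s), "
            f"{len(self.gebv)} lines, {len(self.trial_effects)} trial(s)",
            f"  retained draws: {self.n_retained}",
            f"  residual variance: {self.sigma2_e:.6g}",
            f"  intercept: {self.intercept:.6g}",
        ]
        for lab, v in self.kernel_variances.items():
            lines.append(f"  sigma2[{lab}]: {v:.6g}")
        if self.model.masked_lines:
            lines.append(f"  masked (predicted-only) lines: {len(self.model.masked_lines)}")
        return "\n".join(lines)


class MultiTraitGBLUP:
    """Multi-trait gBLUP with unstructured covariances and missing cells.

    Parameters
    ----------
    Y : DataFrame, lines x traits
        Trait phenotypes (typically trial-averaged BLUPs); NaN marks a
        missing cell.  Must cover the kernel's line set.
    kernel : Kernel
    config : WGRConfig (method ignored)
    """

    def __init__(self, Y: pd.DataFrame, kernel: Kernel, config: WGRConfig | None = None):
        self.kernel = kernel
        self.line_ids = np.asarray(kernel.line_ids, dtype=object)
        Y = Y.reindex(self.line_ids)
        self.traits = list(Y.columns)
        if len(self.traits) < 1:
            raise ValueError("need at least one trait")
        obs_per_trait = Y.notna().sum(axis=0)
        thin_traits = obs_per_trait[obs_per_trait < 3]
        if len(thin_traits):
            raise ValueError(
                f"traits observed for <3 lines: {list(thin_traits.index)}"
            )
        self.Y_obs = np.asarray(Y, dtype=float)
        self.observed = ~np.isnan(self.Y_obs)
        self.config = config or WGRConfig()

    def fit(self) -> "MultiTraitResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n = len(self.line_ids)
        T = len(self.traits)
        df0 = T + 2  # inverse-Wishart prior df: proper, weakly informative
        R2 = cfg.prior_r2

        d, V = _eigh_cached(self.kernel)
        pos = d > 0
        d_safe = np.where(pos, d, 1.0)

        Yf = pd.DataFrame(self.Y_obs, columns=self.traits)
        Sp = Yf.cov(min_periods=2).fillna(0.0).to_numpy()
        Sp = Sp + np.eye(T) * (1e-6 + 1e-3 * np.trace(Sp) / T)
        # with df0 = T + 2 the inverse-Wishart mean is Psi/(df0 - T - 1) = Psi
        Psi_g = R2 * Sp
        Psi_e = (1.0 - R2) * Sp

        Sigma_g = Psi_g.copy()
        Sigma_e = Psi_e.copy()
        mu = np.nanmean(self.Y_obs, axis=0)
        miss = ~self.observed

        # warm start: per-trait kernel-ridge genetic values (heritability 1/2)
        # and model-based fill of the missing cells — data augmentation from a
        # cold start mixes very slowly when many cells are unobserved
        K = self.kernel.values
        U = np.zeros((n, T))
        for t in range(T):
            o = self.observed[:, t]
            yc = self.Y_obs[o, t] - mu[t]
            Koo = K[np.ix_(o, o)] + np.eye(int(o.sum()))
            w = np.linalg.solve(Koo, yc)
            U[:, t] = K[:, o] @ w
        Y = np.where(self.observed, self.Y_obs, mu[None, :] + U)

        # group rows by missingness pattern once
        patterns = {}
        for i in range(n):
            key = tuple(np.flatnonzero(miss[i]))
            if key:
                patterns.setdefault(key, []).append(i)
        patterns = {k: np.asarray(v, dtype=int) for k, v in patterns.items()}

        n_kept = 0
        U_sum = np.zeros((n, T))
        Sg_sum = np.zeros((T, T))
        Se_sum = np.zeros((T, T))
        mu_sum = np.zeros(T)

        for it in range(1, cfg.n_iter + 1):
            # --- augment missing cells from the conditional residual normal
            if patterns:
                R = Y - mu[None, :] - U
                for key, rows in patterns.items():
                    m_idx = np.asarray(key, dtype=int)
                    o_idx = np.setdiff1d(np.arange(T), m_idx)
                    if o_idx.size:
                        Soo = Sigma_e[np.ix_(o_idx, o_idx)]
                        Smo = Sigma_e[np.ix_(m_idx, o_idx)]
                        A = np.linalg.solve(Soo, Smo.T).T  # regression of miss on obs
                        cond_mean = R[np.ix_(rows, o_idx)] @ A.T
                        cond_cov = Sigma_e[np.ix_(m_idx, m_idx)] - A @ Smo.T
                    else:
                        cond_mean = np.zeros((rows.size, m_idx.size))
                        cond_cov = Sigma_e[np.ix_(m_idx, m_idx)]
                    L = _safe_cholesky(cond_cov)
                    z = rng.standard_normal((rows.size, m_idx.size))
                    draw = cond_mean + z @ L.T
                    Y[np.ix_(rows, m_idx)] = (mu[m_idx][None, :] + U[np.ix_(rows, m_idx)] + draw)

            # --- trait intercepts
            Lmu = _safe_cholesky(Sigma_e / n)
            mu = (Y - U).mean(axis=0) + Lmu @ rng.standard_normal(T)

            # --- rotated genetic values, row-wise conditionals
            Yt = V.T @ (Y - mu[None, :])
            Se_inv = _psd_inverse(Sigma_e)
            Sg_inv = _psd_inverse(Sigma_g)
            prec = Se_inv[None, :, :] + Sg_inv[None, :, :] / d_safe[:, None, None]
            prec += (1e-10 * (np.trace(Se_inv) + np.trace(Sg_inv)) / T) * np.eye(T)[None, :, :]
            rhs = Yt @ Se_inv.T
            Lp = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs[:, :, None])[:, :, 0]
            z = rng.standard_normal((n, T, 1))
            noise = np.linalg.solve(np.transpose(Lp, (0, 2, 1)), z)[:, :, 0]
            Ut = mean + noise
            Ut[~pos, :] = 0.0
            U = V @ Ut

            # --- covariances
            m_pos = int(pos.sum())
            Sg_scale = _pd_clip(Psi_g + (Ut[pos].T / d[pos]) @ Ut[pos])
            Sigma_g = stats.invwishart.rvs(df0 + m_pos, Sg_scale, random_state=rng)
            Resid = Y - mu[None, :] - U
            Se_scale = _pd_clip(Psi_e + Resid.T @ Resid)
            Sigma_e = stats.invwishart.rvs(df0 + n, Se_scale, random_state=rng)
            Sigma_g = np.atleast_2d(Sigma_g)
            Sigma_e = np.atleast_2d(Sigma_e)

            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                n_kept += 1
                U_sum += U
                Sg_sum += Sigma_g
                Se_sum += Sigma_e
                mu_sum += mu

        return MultiTraitResults(
            model=self,
            U=pd.DataFrame(U_sum / n_kept, index=self.line_ids, columns=self.traits),
            genetic_covariance=pd.DataFrame(
                Sg_sum / n_kept, index=self.traits, columns=self.traits
            ),
            residual_covariance=pd.DataFrame(
                Se_sum / n_kept, index=self.traits, columns=self.traits
            ),
            intercepts=pd.Series(mu_sum / n_kept, index=self.traits),
            n_retained=n_kept,
        )


@dataclass
class MultiTraitResults:
    """Posterior means of a multi-trait gBLUP fit."""

    model: MultiTraitGBLUP
    U: pd.DataFrame
    genetic_covariance: pd.DataFrame
    residual_covariance: pd.DataFrame
    intercepts: pd.Series
    n_retained: int

    def predict_gebv(self, trait: str, line_ids=None) -> pd.Series:
        col = self.U[trait]
        if line_ids is None:
            return col.copy()
        missing = [l for l in line_ids if l not in col.index]
        if missing:
            raise KeyError(f"unknown lines: {missing[:5]}")
        return col.loc[list(line_ids)]

    def summary(self) -> str:
        h2 = np.diag(self.genetic_covariance) / (
            np.diag(self.genetic_covariance) + np.diag(self.residual_covariance)
        )
        lines = [
            f"Multi-trait gBLUP fit: {len(self.model.line_ids)} lines x "
            f"{len(self.model.traits)} traits",
            f"  retained draws: {self.n_retained}",
            "  per-trait h2: "
            + ", ".join(f"{t}={v:.2f}" for t, v in zip(self.model.traits, h2)),
        ]
        return "\n".join(lines)
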