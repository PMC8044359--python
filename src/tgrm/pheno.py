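"""Phenotype adjustment for augmented block designs.

:class:`AugmentedBlockModel` fits, by EM-REML, the mixed model

    y = mu + covariate*beta + check + new:entry + block + batch + e

where check varieties (replicated across blocks) carry fixed effects,
unreplicated entries enter a random iid "entry" term whose variance is the
genetic variance, and block and batch are random iid nuisance terms.
Entries are assumed unrelated at this stage.  Entry BLUPs and their
prediction error variances (PEV) come from the mixed-model equations at the
converged variance components; deregression divides each BLUP by its
reliability ``r2 = 1 - PEV/sigma2_g`` to undo shrinkage before the BLUPs are
used as responses in whole-genome regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AugmentedBlockModel",
    "AugmentedBlockResults",
    "DeregressedValues",
    "deregress",
    "deregressed_blups",
    "extract_genetic_params",
]

_RANDOM_FACTORS = ("entry", "block", "batch")


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


class AugmentedBlockModel:
    """Mixed model for one trait measured in an augmented block design.

    Parameters
    ----------
    records : DataFrame
        Plot-level records with columns ``line_id, trait, trial, block,
        batch, is_check, covariate, value`` (one trait only; use
        :func:`deregressed_blups` for multi-trait tables).
    include_covariate : bool, optional
        Include the heading-date-style covariate as a fixed regression.
        Defaults to True when the column is present and non-missing.
    """

    def __init__(self, records: pd.DataFrame, include_covariate: bool | None = None):
        traits = records["trait"].unique()
        if len(traits) != 1:
            raise ValueError(f"records contain {len(traits)} traits; fit one at a time")
        self.trait = traits[0]
        rec = records.reset_index(drop=True)
        self.records = rec
        self.y = rec["value"].to_numpy(dtype=float)
        if np.isnan(self.y).any():
            raise ValueError("missing phenotype values in records")
        n = len(rec)

        is_check = rec["is_check"].to_numpy(dtype=bool)
        if include_covariate is None:
            cov = rec["covariate"].to_numpy(dtype=float) if "covariate" in rec else np.full(n, np.nan)
            include_covariate = np.isfinite(cov).all() and np.nanstd(cov) > 0
        self.include_covariate = bool(include_covariate)

        # fixed part: intercept, optional covariate, trial contrasts, one
        # dummy per check variety (entries anchor the intercept)
        cols = [np.ones(n)]
        names = ["mu"]
        if self.include_covariate:
            cols.append(rec["covariate"].to_numpy(dtype=float))
            names.append("beta_covariate")
        trials = pd.unique(rec["trial"])
        for t in trials[1:]:
            cols.append((rec["trial"] == t).to_numpy(dtype=float))
            names.append(f"trial[{t}]")
        self.check_ids = list(pd.unique(rec.loc[is_check, "line_id"]))
        # entries anchor the intercept; in an all-check design fall back to
        # reference coding (first check absorbed by the intercept)
        check_cols = self.check_ids if (~is_check).any() else self.check_ids[1:]
        for c in check_cols:
            cols.append(((rec["line_id"] == c) & is_check).to_numpy(dtype=float))
            names.append(f"check[{c}]")
        self.X = np.column_stack(cols)
        self.fixed_names = names

        # random part
        self.entry_ids = list(pd.unique(rec.loc[~is_check, "line_id"]))
        entry_codes = pd.Categorical(rec["line_id"], categories=self.entry_ids).codes
        self.Z = {}
        if self.entry_ids:
            Zg = np.zeros((n, len(self.entry_ids)))
            obs = entry_codes >= 0
            Zg[np.flatnonzero(obs), entry_codes[obs]] = 1.0
            self.Z["entry"] = Zg
        for factor in ("block", "batch"):
            levels = pd.unique(rec[factor])
            if len(levels) > 1:
                codes = pd.Categorical(rec[factor], categories=levels).codes
                self.Z[factor] = _dummies(codes, len(levels))
        if "block" in self.Z and "batch" in self.Z:
            pb = pd.factorize(rec["block"])[0]
            pc = pd.factorize(rec["batch"])[0]
            if len(np.unique(pb)) == len(np.unique(pc)) and len(
                np.unique(pb * 10_000 + pc)
            ) == len(np.unique(pb)):
                warnings.warn(
                    "block and batch partitions coincide; their variances are confounded",
                    stacklevel=2,
                )

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        maxiter: int = 200,
        tol: float = 1e-8,
        variances: dict | None = None,
        algorithm: str = "ai",
        track_loglik: bool = False,
        check_convergence: bool = True,
    ) -> "AugmentedBlockResults":
        """REML estimation; pass ``variances`` to fix components and skip REML.

        ``algorithm="ai"`` (default) uses average-information updates with
        step halving and an EM fallback whenever an AI step would leave the
        parameter space or reduce the restricted likelihood; ``"em"`` runs
        pure EM steps (slower near variance boundaries but monotone in the
        likelihood).  ``variances`` maps ``{"entry", "block", "batch",
        "residual"}`` to fixed values (absent factors are ignored).
        """
        y, X = self.y, self.X
        n, p = X.shape
        factors = [f for f in _RANDOM_FACTORS if f in self.Z]
        names = factors + ["residual"]

        vy = float(np.var(y, ddof=1)) if n > 1 else 1.0
        theta0 = {f: vy / (2 * max(len(factors), 1)) for f in factors}
        theta0["residual"] = vy / 2 if vy > 0 else 1.0

        fixed = variances is not None
        if fixed:
            for k, v in variances.items():
                if k in theta0:
                    theta0[k] = float(v)

        path, loglik_path = [], []
        comp = dict(theta0)
        n_iter = 0
        converged = True
        if not fixed and factors:
            # relationship matrices of each variance component (residual = I)
            Ms = {f: self.Z[f] @ self.Z[f].T for f in factors}
            Ms["residual"] = np.eye(n)
            th = np.array([theta0[k] for k in names])
            floor = 1e-10 * max(vy, 1.0)

            def _loglik_score(th_vec):
                V = sum(th_vec[i] * Ms[k] for i, k in enumerate(names))
                Vinv = np.linalg.inv(V)
                XtVX = X.T @ Vinv @ X
                P = Vinv - Vinv @ X @ np.linalg.solve(XtVX, X.T @ Vinv)
                Py = P @ y
                _, ld_v = np.linalg.slogdet(V)
                _, ld_x = np.linalg.slogdet(XtVX)
                ll = -0.5 * (ld_v + ld_x + float(y @ Py))
                return ll, P, Py

            ll, P, Py = _loglik_score(th)
            loglik_path.append(ll)
            converged = False
            for n_iter in range(1, maxiter + 1):
                MPy = {k: Ms[k] @ Py for k in names}
                score = np.array([
                    -0.5 * (float(np.sum(P * Ms[k])) - float(Py @ MPy[k]))
                    for k in names
                ])
                AI = np.empty((len(names), len(names)))
                PMPy = {k: P @ MPy[k] for k in names}
                for i, ki in enumerate(names):
                    for j, kj in enumerate(names):
                        AI[i, j] = 0.5 * float(MPy[ki] @ PMPy[kj])
                q_em = np.array([Ms[k].shape[0] if k == "residual" else self.Z[k].shape[1]
                                 for k in names])

                use_em = algorithm == "em"
                accepted = False
                if not use_em:
                    # active set: components pinned at the floor with a
                    # negative score stay constrained out of the AI system
                    active = np.array([
                        th[i] > 100.0 * floor or score[i] > 0.0
                        for i in range(len(names))
                    ])
                    delta = np.zeros(len(names))
                    try:
                        idx = np.flatnonzero(active)
                        delta[idx] = np.linalg.solve(
                            AI[np.ix_(idx, idx)] + 1e-12 * np.eye(idx.size),
                            score[idx],
                        )
                    except np.linalg.LinAlgError:
                        delta = None
                    if delta is not None and np.any(delta):
                        step = 1.0
                        for _ in range(8):  # step halving
                            cand = np.maximum(th + step * delta, floor)
                            ll_new, P_new, Py_new = _loglik_score(cand)
                            if ll_new >= ll - 1e-10:
                                accepted = True
                                break
                            step /= 2.0
                if not accepted:
                    # EM update, monotone in the restricted likelihood
                    cand = np.array([
                        max(th[i] + th[i] ** 2 *
                            (float(Py @ MPy[k]) - float(np.sum(P * Ms[k]))) / q_em[i],
                            floor)
                        for i, k in enumerate(names)
                    ])
                    ll_new, P_new, Py_new = _loglik_score(cand)

                rel = max(
                    abs(cand[i] - th[i]) / th[i] if max(cand[i], th[i]) > 1e-8 * vy else 0.0
                    for i in range(len(names))
                )
                th, ll, P, Py = cand, ll_new, P_new, Py_new
                comp = {k: float(th[i]) for i, k in enumerate(names)}
                path.append(dict(comp))
                if track_loglik:
                    loglik_path.append(ll)
                if rel < tol:
                    converged = True
                    break
            if not converged and check_convergence:
                raise RuntimeError(
                    f"REML did not converge in {maxiter} iterations; "
                    f"component path tail: {path[-3:]}"
                )
        elif track_loglik and factors:
            loglik_path.append(self._reml_loglik(comp, factors))

        # mixed-model equations at the final components
        W = np.hstack([X] + [self.Z[f] for f in factors]) if factors else X
        WtW = W.T @ W
        Wty = W.T @ y
        offs, start = {}, p
        for f in factors:
            offs[f] = (start, start + self.Z[f].shape[1])
            start += self.Z[f].shape[1]

        # final solve at converged components
        C = WtW.copy()
        for f in factors:
            lam = comp["residual"] / max(comp[f], 1e-10)
            a, b = offs[f]
            C[np.arange(a, b), np.arange(a, b)] += lam
        Cinv = np.linalg.inv(C)
        theta = Cinv @ Wty

        fixed_effects = pd.Series(theta[:p], index=self.fixed_names)
        if "entry" in offs:
            a, b = offs["entry"]
            blups = pd.Series(theta[a:b], index=self.entry_ids, name=self.trait)
            pev = pd.Series(
                np.diag(Cinv[a:b, a:b]) * comp["residual"], index=self.entry_ids
            )
        else:
            blups = pd.Series(dtype=float, name=self.trait)
            pev = pd.Series(dtype=float)

        return AugmentedBlockResults(
            model=self,
            trait=self.trait,
            fixed_effects=fixed_effects,
            variance_components=dict(comp),
            blups=blups,
            pev=pev,
            converged=converged,
            n_iter=n_iter,
            component_path=path,
            loglik_path=loglik_path,
        )

    def _reml_loglik(self, comp: dict, factors) -> float:
        """Direct dense REML log-likelihood (small designs only)."""
        n = len(self.y)
        V = np.eye(n) * comp["residual"]
        for f in factors:
            V += comp[f] * (self.Z[f] @ self.Z[f].T)
        Vinv = np.linalg.inv(V)
        X = self.X
        XtVX = X.T @ Vinv @ X
        P = Vinv - Vinv @ X @ np.linalg.solve(XtVX, X.T @ Vinv)
        sign, logdet_v = np.linalg.slogdet(V)
        sign2, logdet_x = np.linalg.slogdet(XtVX)
        return -0.5 * (logdet_v + logdet_x + float(self.y @ P @ self.y))


@dataclass
class AugmentedBlockResults:
    """Converged fit: variance components, fixed effects, BLUPs and PEVs."""

    model: AugmentedBlockModel
    trait: str
    fixed_effects: pd.Series
    variance_components: dict
    blups: pd.Series
    pev: pd.Series
    converged: bool
    n_iter: int
    component_path: list
    loglik_path: list = field(default_factory=list)

    @property
    def sigma2_g(self) -> float:
        return self.variance_components.get("entry", 0.0)

    def reliability(self) -> pd.Series:
        if self.sigma2_g <= 0:
            raise ValueError("entry variance is zero; reliability undefined")
        return 1.0 - self.pev / self.sigma2_g

    def deregress(self, reliability_floor: float = 0.1) -> "DeregressedValues":
        return deregress(self, reliability_floor)

    def summary(self) -> str:
        lines = [
            f"Augmented block design fit: trait {self.trait!r}",
            f"  plots: {len(self.model.y)}, entries: {len(self.blups)}, "
            f"checks: {len(self.model.check_ids)}",
            f"  converged: {self.converged} in {self.n_iter} EM iterations",
            "  variance components:",
        ]
        for k, v in self.variance_components.items():
            lines.append(f"    {k:<10} {v:.6g}")
        lines.append("  fixed effects:")
        for k, v in self.fixed_effects.items():
            lines.append(f"    {k:<18} {v:.6g}")
        if len(self.blups):
            r2 = self.reliability() if self.sigma2_g > 0 else pd.Series(dtype=float)
            lines.append(
                f"  entry BLUPs: mean {self.blups.mean():.4g}, "
                f"mean reliability {r2.mean():.3f}" if len(r2) else "  entry BLUPs: none"
            )
        return "\n".join(lines)


@dataclass
class DeregressedValues:
    """Deregressed entry BLUPs for one trait, with exclusions."""

    trait: str
    table: pd.DataFrame        # line_id, trait, value, reliability
    excluded: pd.DataFrame     # line_id, reason

    @property
    def values(self) -> pd.Series:
        return self.table.set_index("line_id")["value"]


def deregress(fit: AugmentedBlockResults, reliability_floor: float = 0.1) -> DeregressedValues:
    """Deregress entry BLUPs: ``g* = g_hat / (1 - PEV/sigma2_g)``.

    Entries whose reliability falls at or below ``reliability_floor`` (which
    includes any entry with PEV >= sigma2_g) are excluded rather than allowed
    to blow up the ratio.
    """
    if fit.sigma2_g <= 0:
        raise ValueError("entry variance component is zero; cannot deregress")
    r2 = 1.0 - fit.pev / fit.sigma2_g
    ok = r2 > reliability_floor
    rows = pd.DataFrame(
        {
            "line_id": fit.blups.index[ok],
            "trait": fit.trait,
            "value": (fit.blups[ok] / r2[ok]).to_numpy(),
            "reliability": r2[ok].to_numpy(),
        }
    )
    excl = pd.DataFrame(
        {
            "line_id": fit.blups.index[~ok],
            "reason": np.where(
                fit.pev[~ok] >= fit.sigma2_g, "pev >= sigma2_g", "reliability <= floor"
            ),
        }
    )
    return DeregressedValues(fit.trait, rows, excl)


def deregressed_blups(
    records: pd.DataFrame,
    traits=None,
    reliability_floor: float = 0.1,
    per_trial: bool = False,
    **fit_kwargs,
):
    """Fit the augmented model and deregress, per trait (optionally per trial).

    Returns ``(table, fits)`` where ``table`` is a long DataFrame with
    columns ``line_id, trait, trial, value, reliability`` (``trial`` is
    ``"all"`` when trials are fitted jointly) and ``fits`` maps
    ``(trait, trial)`` to the underlying results objects.
    """
    traits = list(traits) if traits is not None else list(pd.unique(records["trait"]))
    frames, fits = [], {}
    for trait in traits:
        rec_t = records[records["trait"] == trait]
        trials = list(pd.unique(rec_t["trial"])) if per_trial else ["all"]
        for trial in trials:
            rec = rec_t if trial == "all" else rec_t[rec_t["trial"] == trial]
            res = AugmentedBlockModel(rec).fit(**fit_kwargs)
            dr = res.deregress(reliability_floor)
            tab = dr.table.copy()
            tab.insert(2, "trial", trial)
            frames.append(tab)
            fits[(trait, trial)] = res
    return pd.concat(frames, ignore_index=True), fits


def extract_genetic_params(mt_results):
    """Per-trait h2 and genetic/phenotypic correlations from a multi-trait fit.

    Accepts any object exposing ``genetic_covariance`` and
    ``residual_covariance`` (T x T DataFrames), e.g.
    :class:`tgrm.blup.MultiTraitResults`.
    """
    Sg = np.asarray(mt_results.genetic_covariance, dtype=float)
    Se = np.asarray(mt_results.residual_covariance, dtype=float)
    traits = list(mt_results.genetic_covariance.columns)
    for name, S in (("genetic", Sg), ("residual", Se)):
        if np.linalg.eigvalsh(S).min() < -1e-8:
            raise ValueError(f"{name} covariance estimate is not PSD")

    def _corr(S):
        d = np.sqrt(np.diag(S))
        with np.errstate(divide="ignore", invalid="ignore"):
            R = S / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        return pd.DataFrame(R, index=traits, columns=traits)

    h2 = pd.Series(np.diag(Sg) / (np.diag(Sg) + np.diag(Se)), index=traits, name="h2")
    return {
        "h2": h2,
        "genomic_correlation": _corr(Sg),
        "phenotypic_correlation": _corr(Sg + Se),
    }
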