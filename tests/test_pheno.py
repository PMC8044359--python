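"""Augmented-design mixed model: MME oracle, REML behaviour, deregression."""

import numpy as np
import pandas as pd
import pytest

from tgrm.pheno import (
    AugmentedBlockModel,
    AugmentedBlockResults,
    deregress,
    deregressed_blups,
    extract_genetic_params,
)
from tgrm.simdata import FieldDesign, apply_field_design

from .helpers import solve_mme_dense


def _toy_records():
    """Balanced two-block toy: 6 entries (3 per block), one check in both."""
    rows = []
    rng = np.random.default_rng(11)
    g = rng.normal(size=6)
    blocks = [0, 0, 0, 1, 1, 1]
    for i in range(6):
        rows.append((f"E{i}", "t", "T1", f"B{blocks[i]}", "K0", False,
                     np.nan, 1.0 + g[i] + rng.normal(0, 0.3)))
    for b in range(2):
        rows.append(("CHK", "t", "T1", f"B{b}", "K0", True,
                     np.nan, 1.0 + 0.4 + rng.normal(0, 0.3)))
    return pd.DataFrame(rows, columns=["line_id", "trait", "trial", "block",
                                       "batch", "is_check", "covariate", "value"])


class TestMMEOracle:
    def test_blups_match_dense_mme_with_fixed_components(self):
        rec = _toy_records()
        model = AugmentedBlockModel(rec)
        comps = {"entry": 0.8, "block": 0.3, "residual": 0.2}
        res = model.fit(variances=comps)

        # independent dense solve
        y = rec["value"].to_numpy()
        X = model.X
        Zg, Zb = model.Z["entry"], model.Z["block"]
        beta, (ug, ub), C_inv = solve_mme_dense(
            y, X, [(Zg, 0.8), (Zb, 0.3)], 0.2)
        assert np.allclose(res.blups.to_numpy(), ug, atol=1e-8)
        assert np.allclose(res.fixed_effects.to_numpy(), beta, atol=1e-8)
        p = X.shape[1]
        pev_oracle = np.diag(C_inv)[p:p + 6] * 0.2
        assert np.allclose(res.pev.to_numpy(), pev_oracle, atol=1e-10)

    def test_single_check_no_entries_degenerates(self):
        rec = _toy_records()
        rec = rec[rec["is_check"]].copy()
        res = AugmentedBlockModel(rec).fit(variances={"block": 0.3, "residual": 0.2})
        assert len(res.blups) == 0


class TestREML:
    def test_recovers_generating_entry_variance(self):
        ratios = []
        for s in range(6):
            rng = np.random.default_rng(300 + s)
            bv = pd.Series(rng.normal(size=250), index=[f"L{i}" for i in range(250)])
            recs = apply_field_design(
                bv, FieldDesign(n_trials=2, n_blocks=10, n_checks=2,
                                block_var_share=0.0, batch_var_share=0.0),
                h2=0.6, seed=rng)
            res = AugmentedBlockModel(recs).fit()
            ratios.append(res.variance_components["entry"] / float(bv.var(ddof=0)))
        assert abs(np.mean(ratios) - 1.0) < 0.2

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(5)
        bv = pd.Series(rng.normal(size=60), index=[f"L{i}" for i in range(60)])
        recs = apply_field_design(
            bv, FieldDesign(n_trials=1, n_blocks=6, n_checks=2,
                            block_var_share=0.15, batch_var_share=0.05),
            h2=0.5, seed=7)
        res = AugmentedBlockModel(recs).fit(
            algorithm="em", maxiter=40, tol=0.0, track_loglik=True,
            check_convergence=False)
        ll = np.asarray(res.loglik_path)
        assert len(ll) > 10 and np.all(np.diff(ll) > -1e-7)

    def test_confounded_block_batch_warns(self):
        rec = _toy_records()
        rec["batch"] = rec["block"]  # identical partitions
        with pytest.warns(UserWarning, match="confounded"):
            AugmentedBlockModel(rec)


class TestDeregress:
    @staticmethod
    def _fit_like(blups, pev, sigma2_g, trait="t"):
        return AugmentedBlockResults(
            model=None, trait=trait,
            fixed_effects=pd.Series(dtype=float),
            variance_components={"entry": sigma2_g, "residual": 1.0},
            blups=pd.Series(blups), pev=pd.Series(pev, index=pd.Series(blups).index),
            converged=True, n_iter=1, component_path=[])

    def test_arithmetic_example(self):
        fit = self._fit_like({"a": 0.5}, {"a": 0.2}, sigma2_g=0.8)
        out = deregress(fit)
        assert out.table["value"].iloc[0] == pytest.approx(0.5 / 0.75)
        assert out.table["reliability"].iloc[0] == pytest.approx(0.75)

    def test_zero_pev_identity(self):
        fit = self._fit_like({"a": 0.3, "b": -1.2}, {"a": 0.0, "b": 0.0}, 1.0)
        out = deregress(fit)
        assert np.allclose(out.table["value"], [0.3, -1.2])

    def test_half_reliability_doubles(self):
        fit = self._fit_like({"a": 0.3, "b": -0.7}, {"a": 0.5, "b": 0.5}, 1.0)
        out = deregress(fit)
        assert np.allclose(out.table["value"], [0.6, -1.4])

    def test_pev_at_or_above_sigma2g_excluded_not_blown_up(self):
        fit = self._fit_like({"a": 0.5, "b": 0.5}, {"a": 1.0, "b": 1.5}, 1.0)
        out = deregress(fit)
        assert len(out.table) == 0
        assert set(out.excluded["reason"]) == {"pev >= sigma2_g"}

    def test_deregression_only_inflates(self):
        rng = np.random.default_rng(1)
        blups = dict(zip("abcdef", rng.normal(size=6)))
        pev = dict(zip("abcdef", rng.uniform(0, 0.8, size=6)))
        out = deregress(self._fit_like(blups, pev, 1.0))
        tab = out.table.set_index("line_id")
        for line, g in blups.items():
            assert abs(tab.loc[line, "value"]) >= abs(g) - 1e-12

    def test_scale_equivariance(self):
        rec = _toy_records()
        res1 = AugmentedBlockModel(rec).fit(
            variances={"entry": 0.8, "block": 0.3, "residual": 0.2})
        rec2 = rec.assign(value=rec["value"] * 3.0)
        res2 = AugmentedBlockModel(rec2).fit(
            variances={"entry": 0.8 * 9, "block": 0.3 * 9, "residual": 0.2 * 9})
        d1, d2 = deregress(res1).table, deregress(res2).table
        assert np.allclose(d2["value"], 3.0 * d1["value"], rtol=1e-8)

    def test_multi_trait_driver_long_format(self):
        rng = np.random.default_rng(3)
        frames = []
        for trait in ("t1", "t2"):
            bv = pd.Series(rng.normal(size=80), index=[f"L{i}" for i in range(80)])
            frames.append(apply_field_design(
                bv, FieldDesign(n_trials=1, n_blocks=8, n_checks=2), 0.6,
                seed=rng, trait_id=trait))
        tab, fits = deregressed_blups(pd.concat(frames, ignore_index=True))
        assert set(tab["trait"]) == {"t1", "t2"}
        assert set(fits) == {("t1", "all"), ("t2", "all")}


class TestExtractGeneticParams:
    class _MT:
        def __init__(self, Sg, Se, traits):
            self.genetic_covariance = pd.DataFrame(Sg, index=traits, columns=traits)
            self.residual_covariance = pd.DataFrame(Se, index=traits, columns=traits)

    def test_diagonal_genetic_covariance_zero_correlations(self):
        mt = self._MT(np.diag([1.0, 2.0]), np.diag([1.0, 1.0]), ["a", "b"])
        out = extract_genetic_params(mt)
        assert out["genomic_correlation"].loc["a", "b"] == 0.0

    def test_h2_ratio(self):
        mt = self._MT(np.array([[0.6]]), np.array([[0.4]]), ["a"])
        assert extract_genetic_params(mt)["h2"]["a"] == pytest.approx(0.6)

    def test_non_psd_rejected(self):
        Sg = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        mt = self._MT(Sg, np.eye(2), ["a", "b"])
        with pytest.raises(ValueError, match="PSD"):
            extract_genetic_params(mt)
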