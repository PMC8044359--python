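"""Kernel BLUP and multi-trait GBLUP: closed forms, oracles, invariants."""

import numpy as np
import pandas as pd
import pytest

from tgrm.blup import KernelBLUP, MultiTraitGBLUP
from tgrm.kernels import Kernel
from tgrm.wgr import WGRConfig

from .helpers import dense_kernel_gibbs

SHORT = dict(n_iter=2000, burn_in=600, thin=2)


def _random_kernel(rng, n, rank=None):
    A = rng.normal(size=(n, rank or max(n // 2, 2)))
    K = A @ A.T / A.shape[1]
    K = K / np.diag(K).mean()
    return Kernel(K, [f"L{i:03d}" for i in range(n)], "GRM")


def _kernel_data(seed=0, n=100, h2=0.6):
    rng = np.random.default_rng(seed)
    kern = _random_kernel(rng, n)
    L = np.linalg.cholesky(kern.values + 1e-8 * np.eye(n))
    g = L @ rng.normal(size=n)
    y = g + rng.normal(0, np.sqrt((1 - h2) / h2 * g.var()), size=n)
    return kern, g, pd.Series(y, index=kern.line_ids)


class TestKernelBLUP:
    def test_identity_kernel_shrinkage_closed_form(self):
        # one observation per line, K = I, variances fixed: the posterior
        # mean is ridge shrinkage towards the mean by s2g/(s2g+s2e)
        rng = np.random.default_rng(1)
        n = 80
        ids = [f"L{i}" for i in range(n)]
        y = pd.Series(rng.normal(size=n), index=ids)
        kern = Kernel(np.eye(n), ids, "I")
        s2g, s2e = 1.5, 0.5
        fit = KernelBLUP(y, {"K": kern}, config=WGRConfig(
            seed=2, n_iter=6000, burn_in=1000, thin=2)).fit(
            fixed={"sigma2_e": s2e, "sigma2_u": {"K": s2g}})
        lam = s2g / (s2g + s2e)
        expected = lam * (y - y.mean())
        resid = fit.gebv.to_numpy() - expected.to_numpy()
        assert np.max(np.abs(resid)) < 0.12
        assert np.corrcoef(fit.gebv, expected)[0, 1] > 0.995

    def test_rotated_sampler_matches_dense_gibbs_oracle(self):
        kern, g, y = _kernel_data(seed=3, n=30)
        masked_idx = [0, 1, 2, 3, 4]
        masked = [kern.line_ids[i] for i in masked_idx]
        s2g, s2e = 0.8, 0.4
        fit = KernelBLUP(y, {"K": kern}, masked, WGRConfig(
            seed=4, n_iter=8000, burn_in=2000, thin=2)).fit(
            fixed={"sigma2_e": s2e, "sigma2_u": {"K": s2g}})
        oracle = dense_kernel_gibbs(y.to_numpy(), kern.values, s2g, s2e,
                                    8000, 2000, 2, seed=99, masked=masked_idx)
        assert np.corrcoef(fit.gebv.to_numpy(), oracle)[0, 1] > 0.99
        assert np.max(np.abs(fit.gebv.to_numpy() - oracle)) < 0.15

    def test_two_identical_kernels_match_single_kernel_gebv(self):
        kern, g, y = _kernel_data(seed=5)
        cfg = WGRConfig(seed=6, **SHORT)
        single = KernelBLUP(y, {"K": kern}, config=cfg).fit()
        double = KernelBLUP(y, {"K1": kern, "K2": kern}, config=cfg).fit()
        assert np.corrcoef(single.gebv, double.gebv)[0, 1] >= 0.98

    def test_interpolation_limit_small_residual(self):
        # full-rank kernel so the genetic values can reach any vector
        rng = np.random.default_rng(7)
        kern = _random_kernel(rng, 60, rank=200)
        y = pd.Series(rng.normal(size=60), index=kern.line_ids)
        fit = KernelBLUP(y, {"K": kern}, config=WGRConfig(seed=8, **SHORT)).fit(
            fixed={"sigma2_e": 1e-4, "sigma2_u": {"K": 10.0}})
        centered = y - y.mean()
        assert np.corrcoef(fit.gebv, centered)[0, 1] > 0.999

    def test_line_permutation_equivariance(self):
        kern, g, y = _kernel_data(seed=9, n=40)
        perm = np.random.default_rng(10).permutation(40)
        kern_p = Kernel(kern.values[np.ix_(perm, perm)], kern.line_ids[perm], "GRM")
        cfg = WGRConfig(seed=11, **SHORT)
        a = KernelBLUP(y, {"K": kern}, config=cfg).fit()
        b = KernelBLUP(y.iloc[perm], {"K": kern_p}, config=cfg).fit()
        assert np.corrcoef(a.gebv.reindex(b.gebv.index), b.gebv)[0, 1] > 0.99

    def test_trial_shift_absorbed_by_trial_effect(self):
        kern, g, y = _kernel_data(seed=12, n=50)
        long = pd.concat([
            pd.DataFrame({"line_id": y.index, "trial": "T1", "value": y.to_numpy()}),
            pd.DataFrame({"line_id": y.index, "trial": "T2",
                          "value": y.to_numpy() + np.random.default_rng(13).normal(0, .2, 50)}),
        ])
        cfg = WGRConfig(seed=14, **SHORT)
        base = KernelBLUP(long, {"K": kern}, config=cfg).fit()
        shifted = long.copy()
        shifted.loc[shifted["trial"] == "T2", "value"] += 5.0
        shift_fit = KernelBLUP(shifted, {"K": kern}, config=cfg).fit()
        diff = shift_fit.trial_effects["T2"] - base.trial_effects["T2"]
        assert diff == pytest.approx(5.0 * 0.5, abs=0.1)  # half into s, half into mu
        assert shift_fit.intercept - base.intercept == pytest.approx(2.5, abs=0.1)
        assert np.corrcoef(base.gebv, shift_fit.gebv)[0, 1] > 0.995

    def test_masked_line_predictions_and_errors(self):
        kern, g, y = _kernel_data(seed=15)
        masked = list(kern.line_ids[:10])
        fit = KernelBLUP(y, {"K": kern}, masked, WGRConfig(seed=16, **SHORT)).fit()
        assert np.isfinite(fit.predict_gebv(masked)).all()
        assert np.allclose(fit.kernel_values.sum(axis=1), fit.gebv)
        with pytest.raises(KeyError):
            fit.predict_gebv(["NOPE"])

    def test_unknown_masked_line_rejected(self):
        kern, g, y = _kernel_data(seed=17, n=20)
        with pytest.raises(ValueError, match="masked"):
            KernelBLUP(y, {"K": kern}, ["NOPE"])

    def test_mismatched_kernel_line_sets_rejected(self):
        rng = np.random.default_rng(18)
        k1 = _random_kernel(rng, 20)
        k2 = Kernel(k1.values, [f"X{i}" for i in range(20)], "GRM")
        y = pd.Series(rng.normal(size=20), index=k1.line_ids)
        with pytest.raises(ValueError, match="identical line set"):
            KernelBLUP(y, {"a": k1, "b": k2})


class TestMultiTrait:
    def test_t1_reduces_to_single_kernel_model(self):
        kern, g, y = _kernel_data(seed=20, n=90)
        cfg = WGRConfig(seed=21, **SHORT)
        single = KernelBLUP(y, {"K": kern}, config=cfg).fit()
        mt = MultiTraitGBLUP(y.to_frame("t"), kern, cfg).fit()
        assert np.corrcoef(single.gebv, mt.predict_gebv("t"))[0, 1] >= 0.99

    def test_zero_genetic_correlation_recovered(self):
        rng = np.random.default_rng(22)
        n = 150
        kern = _random_kernel(rng, n)
        L = np.linalg.cholesky(kern.values + 1e-8 * np.eye(n))
        U = np.column_stack([L @ rng.normal(size=n), L @ rng.normal(size=n)])
        Y = pd.DataFrame(U + rng.normal(0, 0.7, size=(n, 2)),
                         index=kern.line_ids, columns=["a", "b"])
        res = MultiTraitGBLUP(Y, kern, WGRConfig(seed=23, n_iter=3000,
                                                 burn_in=1000, thin=2)).fit()
        Sg = res.genetic_covariance
        r_g = Sg.loc["a", "b"] / np.sqrt(Sg.loc["a", "a"] * Sg.loc["b", "b"])
        assert abs(r_g) < 0.3

    def test_correlated_helper_trait_improves_masked_prediction(self):
        # focal trait masked on test lines, helper trait (r_g = 0.9)
        # observed everywhere: the joint fit should beat single-trait
        wins = 0
        for s in range(6):
            rng = np.random.default_rng(600 + s)
            n = 120
            kern = _random_kernel(rng, n)
            L = np.linalg.cholesky(kern.values + 1e-8 * np.eye(n))
            z1, z2 = L @ rng.normal(size=n), L @ rng.normal(size=n)
            u_f = z1
            u_h = 0.9 * z1 + np.sqrt(1 - 0.81) * z2
            Y = pd.DataFrame({
                "focal": u_f + rng.normal(0, 0.8, n),
                "helper": u_h + rng.normal(0, 0.8, n),
            }, index=kern.line_ids)
            masked = list(kern.line_ids[:40])
            Ym = Y.copy()
            Ym.loc[masked, "focal"] = np.nan
            cfg = WGRConfig(seed=s, **SHORT)
            mt = MultiTraitGBLUP(Ym, kern, cfg).fit()
            st = KernelBLUP(Y["focal"], {"K": kern}, masked, cfg).fit()
            acc_mt = np.corrcoef(mt.predict_gebv("focal", masked), u_f[:40])[0, 1]
            acc_st = np.corrcoef(st.predict_gebv(masked), u_f[:40])[0, 1]
            wins += acc_mt > acc_st
        assert wins >= 4

    def test_sparse_trait_rejected(self):
        rng = np.random.default_rng(24)
        kern = _random_kernel(rng, 10)
        Y = pd.DataFrame(np.nan, index=kern.line_ids, columns=["a", "b"])
        Y["a"] = rng.normal(size=10)
        Y.iloc[:2, 1] = rng.normal(size=2)
        with pytest.raises(ValueError, match="<3 lines"):
            MultiTraitGBLUP(Y, kern)
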