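"""Bayesian alphabet samplers: shrinkage, method relationships, calibration."""

import numpy as np
import pandas as pd
import pytest

from tgrm.genotypes import GenotypeMatrix
from tgrm.simdata import SimConfig, TraitArchitecture, simulate_endophenotypes, simulate_genotypes
from tgrm.wgr import (
    METHODS,
    WGRConfig,
    WholeGenomeRegression,
    effect_recovery_report,
    fit_wgr,
)

SHORT = dict(n_iter=1500, burn_in=500, thin=2)


def _signal_data(seed=0, n=150, p=80, h2=0.6, n_qtl=10):
    rng = np.random.default_rng(seed)
    W = rng.choice([0.0, 2.0], size=(n, p))
    beta = np.zeros(p)
    qtl = rng.choice(p, n_qtl, replace=False)
    beta[qtl] = rng.normal(size=n_qtl)
    g = (W - W.mean(0)) @ beta
    g = g / g.std()
    y = g + rng.normal(0, np.sqrt((1 - h2) / h2), size=n)
    return y, W, g, beta


class TestConfig:
    def test_default_chain_settings(self):
        cfg = WGRConfig()
        assert (cfg.n_iter, cfg.burn_in, cfg.thin) == (20_000, 5_000, 5)

    @pytest.mark.parametrize("bad", [
        dict(method="BayesZ"),
        dict(burn_in=30_000),
        dict(thin=0),
        dict(prior_r2=1.5),
    ])
    def test_invalid_settings_rejected(self, bad):
        with pytest.raises(ValueError):
            WGRConfig(**bad)


class TestSamplers:
    @pytest.mark.parametrize("method", METHODS)
    def test_null_signal_shrinks_everything(self, method):
        rng = np.random.default_rng(1)
        W = rng.choice([0.0, 2.0], size=(240, 60))
        y = rng.normal(size=240)
        res = fit_wgr(y, W, WGRConfig(method=method, seed=2, **SHORT))
        gebv = (W - W.mean(0)) @ res.effects.to_numpy()
        assert np.var(gebv) / np.var(y) < 0.1

    def test_brr_matches_closed_form_ridge_with_fixed_variances(self):
        rng = np.random.default_rng(3)
        n, P = 200, 50
        W = rng.choice([0.0, 1.0, 2.0], size=(n, P))
        y = W @ rng.normal(0, 0.2, P) + rng.normal(0, 1, n)
        y = y - y.mean()
        s2a, s2e = 0.04, 1.0
        res = fit_wgr(y, W, WGRConfig(method="BRR", seed=4, n_iter=8000,
                                      burn_in=2000, thin=2),
                      fixed={"sigma2_marker": s2a, "sigma2_e": s2e, "mu": 0.0})
        ridge = np.linalg.solve(W.T @ W + (s2e / s2a) * np.eye(P), W.T @ y)
        assert np.max(np.abs(res.effects.to_numpy() - ridge)) < 0.02

    def test_bayesb_with_pi_zero_behaves_like_bayesa(self):
        y, W, _, _ = _signal_data(seed=5)
        cfg = dict(seed=6, **SHORT)
        a = fit_wgr(y, W, WGRConfig(method="BayesA", **cfg))
        b = fit_wgr(y, W, WGRConfig(method="BayesB", **cfg), fixed={"pi": 0.0})
        r = np.corrcoef(a.effects, b.effects)[0, 1]
        assert r >= 0.95

    def test_bayescpi_with_pi_zero_behaves_like_brr(self):
        y, W, _, _ = _signal_data(seed=7)
        cfg = dict(seed=8, **SHORT)
        a = fit_wgr(y, W, WGRConfig(method="BRR", **cfg))
        b = fit_wgr(y, W, WGRConfig(method="BayesCpi", **cfg), fixed={"pi": 0.0})
        assert np.corrcoef(a.effects, b.effects)[0, 1] >= 0.95

    def test_fixed_seed_reproducible(self):
        y, W, _, _ = _signal_data(seed=9, n=80, p=40)
        cfg = WGRConfig(method="BayesCpi", seed=10, **SHORT)
        r1 = fit_wgr(y, W, cfg)
        r2 = fit_wgr(y, W, cfg)
        assert np.array_equal(r1.effects.to_numpy(), r2.effects.to_numpy())
        assert r1.sigma2_e == r2.sigma2_e

    def test_marker_order_equivariance_distributional(self):
        # permuting columns permutes estimates up to MCMC noise: both fits
        # approximate the same posterior mean
        y, W, _, _ = _signal_data(seed=11, h2=0.8)
        perm = np.random.default_rng(12).permutation(W.shape[1])
        a = fit_wgr(y, W, WGRConfig(method="BRR", seed=13, n_iter=4000,
                                    burn_in=1500, thin=2))
        b = fit_wgr(y, W[:, perm], WGRConfig(method="BRR", seed=14, n_iter=4000,
                                             burn_in=1500, thin=2))
        unpermuted = np.empty_like(b.effects.to_numpy())
        unpermuted[perm] = b.effects.to_numpy()
        assert np.corrcoef(a.effects.to_numpy(), unpermuted)[0, 1] >= 0.95

    def test_zero_variance_marker_warned_and_zeroed(self):
        y, W, _, _ = _signal_data(seed=15, n=60, p=20)
        W = W.copy()
        W[:, 4] = 2.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = WholeGenomeRegression(y, W, WGRConfig(method="BayesB", seed=16, **SHORT))
        res = model.fit()
        assert res.effects.iloc[4] == 0.0

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            WholeGenomeRegression(np.ones(10), np.zeros((10, 3)) + [0, 1, 2])

    def test_missing_values_rejected(self):
        y = np.array([1.0, np.nan, 0.5])
        with pytest.raises(ValueError, match="complete"):
            WholeGenomeRegression(y, np.zeros((3, 2)))

    def test_brr_sigma2e_calibrated_on_own_prior(self):
        # data generated from the BRR model itself: posterior-mean residual
        # variance averages to the generating value within 10%
        est = []
        for s in range(8):
            rng = np.random.default_rng(40 + s)
            n, P = 400, 60
            W = rng.choice([0.0, 2.0], size=(n, P))
            s2a, s2e = 0.01, 1.0
            y = W @ rng.normal(0, np.sqrt(s2a), P) + rng.normal(0, np.sqrt(s2e), n)
            res = fit_wgr(y, W, WGRConfig(method="BRR", seed=s, **SHORT))
            est.append(res.sigma2_e)
        assert abs(np.mean(est) - 1.0) < 0.1

    def test_pi_recovers_sparsity_direction(self):
        # oligogenic signal: BayesB posterior pi (exclusion prob) should be
        # large, and inclusion probabilities highest at true QTL
        y, W, _, beta = _signal_data(seed=17, n=250, p=100, h2=0.8, n_qtl=5)
        res = fit_wgr(y, W, WGRConfig(method="BayesB", seed=18, **SHORT))
        assert res.pi > 0.5
        top = np.argsort(res.inclusion_prob.to_numpy())[-5:]
        assert len(set(top) & set(np.flatnonzero(beta))) >= 3


class TestRecoveryReport:
    def _setup(self):
        cfg = SimConfig(n_lines_discovery=100, n_lines_elite=20, n_overlap=2,
                        n_markers=50, n_ld_blocks=50, seed=20)
        G, _ = simulate_genotypes(cfg)
        bv, truth = simulate_endophenotypes(
            G, [TraitArchitecture("t", 10, 0.7)], 21)
        return G, truth

    def test_perfect_estimates_correlation_one(self):
        G, truth = self._setup()
        res = type("R", (), {})()
        eff = pd.Series(truth.true_effects["t"], index=G.marker_ids)
        fake = _fake_results(eff)
        rep = effect_recovery_report(fake, truth, G, "t")
        assert rep["effect_correlation"] == pytest.approx(1.0)
        assert rep["breeding_value_correlation"] == pytest.approx(1.0)

    def test_negated_estimates_correlation_minus_one(self):
        G, truth = self._setup()
        eff = pd.Series(-truth.true_effects["t"], index=G.marker_ids)
        rep = effect_recovery_report(_fake_results(eff), truth, G, "t")
        assert rep["effect_correlation"] == pytest.approx(-1.0)

    def test_marker_mismatch_rejected(self):
        G, truth = self._setup()
        eff = pd.Series(np.ones(10), index=[f"X{i}" for i in range(10)])
        with pytest.raises(ValueError, match="match"):
            effect_recovery_report(_fake_results(eff), truth, G, "t")


def _fake_results(effects: pd.Series):
    from tgrm.wgr import MarkerEffectsResults, WGRConfig

    return MarkerEffectsResults(
        method="BRR", effects=effects, mu=0.0, sigma2_e=1.0, pi=None,
        inclusion_prob=None, mean_marker_variance=0.0, n_retained=1,
        config=WGRConfig())
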