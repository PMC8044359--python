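"""Synthetic-data generator: construction examples and invariants."""

import numpy as np
import pandas as pd
import pytest

from tgrm.simdata import (
    FieldDesign,
    SimConfig,
    SimTruth,
    StudyConfig,
    TraitArchitecture,
    apply_field_design,
    simulate_endophenotypes,
    simulate_focal_trait,
    simulate_genotypes,
    simulate_two_panel_study,
)


class TestGenotypes:
    def test_fully_inbred_without_residual_het(self):
        cfg = SimConfig(n_lines_discovery=40, n_lines_elite=30, n_overlap=4,
                        n_markers=60, n_ld_blocks=12, residual_het_rate=0.0, seed=1)
        G, _ = simulate_genotypes(cfg)
        assert np.isin(G.dosages, (0.0, 2.0)).all()

    def test_one_marker_per_block_markers_independent(self):
        cfg = SimConfig(n_lines_discovery=400, n_lines_elite=50, n_overlap=5,
                        n_markers=40, n_ld_blocks=40, residual_het_rate=0.0, seed=2)
        G, _ = simulate_genotypes(cfg)
        X = G.dosages - G.dosages.mean(0)
        R = np.corrcoef(X.T)
        off = np.abs(R[np.triu_indices_from(R, k=1)])
        assert np.nanmean(off) < 3.0 / np.sqrt(G.n_lines)

    def test_two_founders_perfect_within_block_ld(self):
        # brute-force oracle: with 2 founders and no residual hets, each
        # line's block haplotype is one of two mosaics, so polymorphic
        # markers within a block are perfectly correlated (|r| = 1)
        cfg = SimConfig(n_lines_discovery=100, n_lines_elite=20, n_overlap=2,
                        n_markers=10, n_ld_blocks=2, n_founders_per_block=2,
                        residual_het_rate=0.0, seed=3)
        G, record = simulate_genotypes(cfg)
        block = record["block_of_marker"]
        X = G.dosages
        for b in range(2):
            idx = np.flatnonzero(block == b)
            poly = [j for j in idx if X[:, j].std() > 0]
            for a in poly:
                for c in poly:
                    r = np.corrcoef(X[:, a], X[:, c])[0, 1]
                    assert abs(abs(r) - 1.0) < 1e-12

    def test_overlap_lines_identical_across_panels(self, small_panel):
        G, record, cfg = small_panel
        disc = G.subset_lines(record["discovery_lines"])
        elite = G.subset_lines(record["elite_lines"])
        for line in record["discovery_lines"][: cfg.n_overlap]:
            i = list(disc.line_ids).index(line)
            j = list(elite.line_ids).index(line)
            assert np.array_equal(disc.dosages[i], elite.dosages[j])

    def test_seed_reproducibility(self):
        cfg = SimConfig(n_lines_discovery=30, n_lines_elite=25, n_overlap=3,
                        n_markers=50, n_ld_blocks=10, seed=9)
        G1, _ = simulate_genotypes(cfg)
        G2, _ = simulate_genotypes(cfg)
        assert np.array_equal(G1.dosages, G2.dosages)

    def test_too_few_founders_rejected(self):
        with pytest.raises(ValueError, match="founders"):
            SimConfig(n_founders_per_block=1)


class TestEndophenotypes:
    @staticmethod
    def _geno(seed=4, n=200, p=100):
        cfg = SimConfig(n_lines_discovery=n, n_lines_elite=20, n_overlap=2,
                        n_markers=p, n_ld_blocks=p, residual_het_rate=0.0, seed=seed)
        return simulate_genotypes(cfg)[0]

    def test_no_qtl_gives_zero_breeding_values(self):
        G = self._geno()
        bv, _ = simulate_endophenotypes(G, [TraitArchitecture("t", 0, 0.5)], 1)
        assert np.allclose(bv["t"], 0.0)

    def test_fully_shared_qtl_correlation_one(self):
        G = self._geno()
        idx = list(range(10))
        archs = [
            TraitArchitecture("a", 10, 0.5, shared_qtl_map=[("b", idx, 1.0)]),
            TraitArchitecture("b", 10, 0.5, shared_qtl_map=[("a", idx, 1.0)]),
        ]
        bv, _ = simulate_endophenotypes(G, archs, 2)
        assert np.corrcoef(bv["a"], bv["b"])[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_partially_shared_qtl_genetic_correlation(self):
        # analytic oracle: 50 shared QTL at effect correlation 0.8 plus 50
        # private each, equal variances -> r_g = 0.8 * 50/100 = 0.4
        reps = []
        idx = list(range(50))
        for s in range(20):
            G = self._geno(seed=100 + s, n=300, p=200)
            archs = [
                TraitArchitecture("a", 100, 0.5, shared_qtl_map=[("b", idx, 0.8)]),
                TraitArchitecture("b", 100, 0.5, shared_qtl_map=[("a", idx, 0.8)]),
            ]
            bv, _ = simulate_endophenotypes(G, archs, 200 + s)
            reps.append(np.corrcoef(bv["a"], bv["b"])[0, 1])
        mean_r = np.mean(reps)
        mc_se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(mean_r - 0.4) < 3 * mc_se + 0.02

    def test_inconsistent_shared_map_rejected(self):
        G = self._geno()
        archs = [
            TraitArchitecture("a", 10, 0.5, shared_qtl_map=[("b", [0, 1], 0.5)]),
            TraitArchitecture("b", 10, 0.5),  # no mirror entry
        ]
        with pytest.raises(ValueError, match="mirror"):
            simulate_endophenotypes(G, archs, 3)


class TestFocalTrait:
    @staticmethod
    def _bv(rng, n=300, t=3, independent=True):
        vals = rng.normal(size=(n, t))
        return pd.DataFrame(vals, index=[f"L{i}" for i in range(n)],
                            columns=[f"EP{j}" for j in range(t)])

    def test_zero_weights_zero_variance(self, rng):
        bv = self._bv(rng)
        focal, _ = simulate_focal_trait(bv, [0, 0, 0], 0.0, 0.5, 1)
        assert float(focal.var()) == 0.0

    def test_single_weight_copies_endophenotype(self, rng):
        bv = self._bv(rng)
        focal, _ = simulate_focal_trait(bv, [0, 1, 0], 0.0, 0.5, 1)
        assert np.allclose(focal, bv.iloc[:, 1])

    def test_equal_weights_variance_adds(self, rng):
        # independent unit-variance endophenotypes: var(sum) = 3 var(one)
        bv = self._bv(rng, n=5000)
        focal, _ = simulate_focal_trait(bv, [1, 1, 1], 0.0, 0.5, 1)
        ratio = float(focal.var()) / float(bv.iloc[:, 0].var())
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_invalid_h2_rejected(self, rng):
        bv = self._bv(rng)
        with pytest.raises(ValueError, match="h2"):
            simulate_focal_trait(bv, [1, 1, 1], 0.0, 1.5, 1)


class TestFieldDesign:
    def test_no_noise_returns_genetic_value_exactly(self, rng):
        bv = pd.Series(rng.normal(size=40), index=[f"L{i}" for i in range(40)])
        des = FieldDesign(n_trials=1, n_blocks=4, n_checks=1,
                          block_var_share=0.0, batch_var_share=0.0, mu=5.0)
        recs = apply_field_design(bv, des, h2=1.0, seed=1)
        entries = recs[~recs["is_check"]]
        assert np.allclose(entries["value"],
                           bv.reindex(entries["line_id"]).to_numpy() + 5.0)

    def test_check_records_differ_only_by_block_effects(self, rng):
        bv = pd.Series(rng.normal(size=30), index=[f"L{i}" for i in range(30)])
        des = FieldDesign(n_trials=1, n_blocks=5, n_checks=1,
                          block_var_share=0.3, batch_var_share=0.0)
        recs = apply_field_design(bv, des, h2=1.0, seed=2)
        chk = recs[recs["is_check"]]
        assert chk["block"].nunique() == 5
        # same genetic value everywhere: spread comes from blocks only
        assert chk.groupby("block")["value"].nunique().max() == 1

    def test_entry_conservation_and_check_count(self, rng):
        bv = pd.Series(rng.normal(size=57), index=[f"L{i}" for i in range(57)])
        des = FieldDesign(n_trials=2, n_blocks=6, n_checks=3)
        recs = apply_field_design(bv, des, h2=0.5, seed=3)
        entries = recs[~recs["is_check"]]
        counts = entries.groupby("line_id").size()
        assert set(counts.index) == set(bv.index) and (counts == 2).all()
        assert recs["is_check"].sum() == 2 * 6 * 3

    def test_realized_h2_brute_force(self):
        # empirical oracle: with block/batch shares at 0 the entry-mean h2
        # is var(g) / var(y), targeted at 0.6
        ratios = []
        for s in range(50):
            rng = np.random.default_rng(700 + s)
            bv = pd.Series(rng.normal(size=500), index=[f"L{i}" for i in range(500)])
            des = FieldDesign(n_trials=1, n_blocks=10, n_checks=1,
                              block_var_share=0.0, batch_var_share=0.0)
            recs = apply_field_design(bv, des, h2=0.6, seed=rng)
            entries = recs[~recs["is_check"]].set_index("line_id")["value"]
            g = bv.reindex(entries.index)
            ratios.append(float(g.var() / entries.var()))
        assert 0.55 < np.mean(ratios) < 0.65

    def test_more_blocks_than_entries_rejected(self, rng):
        bv = pd.Series(rng.normal(size=3), index=list("abc"))
        with pytest.raises(ValueError, match="blocks"):
            apply_field_design(bv, FieldDesign(n_blocks=10), 0.5, 1)


class TestStudyBuilder:
    def test_study_reproducible_and_consistent(self):
        cfg = StudyConfig(seed=5, n_lines_discovery=60, n_lines_elite=50,
                          n_overlap=6, n_markers=120, n_ld_blocks=24)
        s1 = simulate_two_panel_study(cfg)
        s2 = simulate_two_panel_study(StudyConfig(
            seed=5, n_lines_discovery=60, n_lines_elite=50,
            n_overlap=6, n_markers=120, n_ld_blocks=24))
        assert np.array_equal(s1.genotypes.dosages, s2.genotypes.dosages)
        pd.testing.assert_frame_equal(s1.discovery_records, s2.discovery_records)
        # breeding values reproducible from stored effects and dosages
        X = s1.genotypes.dosages - s1.genotypes.dosages.mean(0)
        for t in s1.endophenotype_ids:
            bv = X @ s1.truth.true_effects[t]
            assert np.allclose(bv, s1.truth.breeding_values(t).to_numpy(), atol=1e-8)

    def test_truth_round_trip(self, tmp_path):
        cfg = StudyConfig(seed=6, n_lines_discovery=40, n_lines_elite=30,
                          n_overlap=4, n_markers=60, n_ld_blocks=12,
                          trait_subset=("EP1", "EP2"))
        study = simulate_two_panel_study(cfg)
        path = tmp_path / "truth.json"
        study.truth.to_json(path)
        back = SimTruth.from_json(path)
        assert set(back.true_effects) == set(study.truth.true_effects)
        pd.testing.assert_frame_equal(
            back.true_breeding_values, study.truth.true_breeding_values)
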