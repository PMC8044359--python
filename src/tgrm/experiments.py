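"""Scaled two-panel prediction experiments on synthetic data.

:class:`TwoPanelExperiment` wires the full method chain — simulation, QC,
augmented-design adjustment, whole-genome regression, kernel construction
and cross-validated kernel BLUP — into reusable comparisons:

- ``endo_cv(trait, method)``: trait-specific kernel BLUP vs gBLUP for one
  endophenotype, per-trial deregressed-BLUP response in the elite panel;
- ``focal_cv(method)``: multi-kernel TGRM-BLUP vs gBLUP vs multi-trait
  gBLUP for the focal trait, entry-mean response, overlap lines forced into
  training.

Because the win-proportion statistic conditions on one realised dataset, a
single synthetic study can land at 0 or 1 whenever the two models are not
exactly tied; :func:`pooled_endo_comparison` therefore averages run-level
wins over independent study replicates.  A replicate whose adjustment stage
loses a trait (the genetic variance component collapsing to zero in a
low-heritability, single-replicate design) contributes no runs — the rule
is applied per replicate, before any model comparison is run.

Problem sizes default to a desk-scale study: 400 discovery lines, 250 elite
lines, 12 overlapping, 2000 markers in 200 LD blocks, five-fold CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .blup import KernelBLUP, MultiTraitGBLUP
from .cv import CVReport, make_fold_plan, run_cv
from .genoqc import QCThresholds, qc_pipeline
from .kernels import build_grm_vanraden, build_tgrm, center_scale, tgrm_weights
from .pheno import AugmentedBlockModel, deregressed_blups
from .simdata import StudyConfig, simulate_two_panel_study
from .wgr import WGRConfig, WholeGenomeRegression

__all__ = ["ExperimentSettings", "TwoPanelExperiment", "pooled_endo_comparison"]


@dataclass
class ExperimentSettings:
    """Problem sizes and chain lengths of one scaled experiment."""

    n_discovery: int = 400
    n_elite: int = 250
    n_overlap: int = 12
    n_markers: int = 2000
    n_ld_blocks: int = 200
    k_folds: int = 5
    maf: float = 0.05
    # chain lengths: effect estimation, kernel-model CV fits, multi-trait CV fits
    wgr_chain: tuple = (3000, 1000, 2)
    kernel_chain: tuple = (1500, 500, 2)
    mt_chain: tuple = (1200, 400, 2)


class TwoPanelExperiment:
    """One synthetic study replicate with cached analysis stages."""

    def __init__(self, seed: int, settings: ExperimentSettings | None = None):
        self.seed = int(seed)
        self.settings = settings or ExperimentSettings()

    # ------------------------------------------------------------ stages
    @cached_property
    def study(self):
        s = self.settings
        return simulate_two_panel_study(StudyConfig(
            seed=self.seed, n_lines_discovery=s.n_discovery,
            n_lines_elite=s.n_elite, n_overlap=s.n_overlap,
            n_markers=s.n_markers, n_ld_blocks=s.n_ld_blocks,
        ))

    @cached_property
    def _qc(self):
        thr = QCThresholds(marker_maf_min=self.settings.maf)
        study = self.study
        union = sorted(set(study.discovery_lines) | set(study.elite_lines))
        Gd, _, _ = qc_pipeline(study.genotypes.subset_lines(study.discovery_lines), thr)
        Ge, _, _ = qc_pipeline(study.genotypes.subset_lines(study.elite_lines), thr)
        Gu, _, _ = qc_pipeline(study.genotypes.subset_lines(union), thr)
        return Gd, Ge, Gu

    @property
    def discovery_genotypes(self):
        return self._qc[0]

    @property
    def elite_genotypes(self):
        return self._qc[1]

    @cached_property
    def elite_grm(self):
        return build_grm_vanraden(self._qc[1])

    @cached_property
    def union_grm(self):
        return build_grm_vanraden(self._qc[2])

    @cached_property
    def _elite_centered(self):
        return center_scale(self._qc[1])

    @cached_property
    def discovery_dereg(self) -> pd.DataFrame:
        """Deregressed discovery BLUPs for every endophenotype; traits whose
        adjustment produced no usable entries are simply absent."""
        tab, _ = deregressed_blups(self.study.discovery_records)
        return tab

    def elite_dereg(self, trait: str) -> pd.DataFrame | None:
        recs = self.study.elite_records
        tab, _ = deregressed_blups(recs[recs["trait"] == trait], per_trial=True)
        return tab if len(tab) else None

    @cached_property
    def focal_entry_means(self) -> pd.Series:
        frames = []
        recs = self.study.focal_records
        for trial in pd.unique(recs["trial"]):
            res = AugmentedBlockModel(recs[recs["trial"] == trial]).fit()
            frames.append(pd.Series(res.blups.to_numpy(), index=res.blups.index))
        means = pd.concat(frames, axis=1).mean(axis=1)
        return means.reindex(self.elite_grm.line_ids).dropna()

    # --------------------------------------------------------- model parts
    def marker_effects(self, trait: str, method: str):
        """Whole-genome regression on the discovery panel; None if the
        adjustment stage produced no deregressed values for the trait."""
        Gd = self.discovery_genotypes
        sub = self.discovery_dereg
        sub = sub[(sub["trait"] == trait) & sub["line_id"].isin(Gd.line_ids)]
        if len(sub) < self.settings.k_folds * 3:
            return None
        Gsub = Gd.subset_lines(sub["line_id"].tolist())
        it, burn, thin = self.settings.wgr_chain
        cfg = WGRConfig(method=method, n_iter=it, burn_in=burn, thin=thin,
                        seed=_child_seed(self.seed, "wgr", trait, method))
        return WholeGenomeRegression(
            sub["value"].to_numpy(), Gsub.dosages, cfg, marker_ids=Gd.marker_ids
        ).fit()

    def tgrm(self, trait: str, method: str):
        res = self.marker_effects(trait, method)
        if res is None:
            return None
        w = tgrm_weights(res.effects, marker_ids=self.elite_genotypes.marker_ids)
        return build_tgrm(self._elite_centered, w, kind=f"TGRM:{trait}")

    def _kernel_fit_fn(self, response, kernels):
        it, burn, thin = self.settings.kernel_chain

        def fit(masked_lines, fit_seed):
            cfg = WGRConfig(n_iter=it, burn_in=burn, thin=thin, seed=fit_seed)
            return KernelBLUP(response, kernels, masked_lines, cfg).fit().predict_gebv()

        return fit

    # --------------------------------------------------------- comparisons
    def endo_cv(self, trait: str, method: str, n_runs: int = 5) -> dict | None:
        """TGRM-BLUP vs gBLUP for one endophenotype; None when the trait was
        lost in adjustment (either panel)."""
        tk = self.tgrm(trait, method)
        resp = self.elite_dereg(trait)
        if tk is None or resp is None:
            return None
        resp = resp[["line_id", "trial", "value"]]
        lines = [l for l in self.elite_grm.line_ids if l in set(resp["line_id"])]
        if len(lines) < self.settings.k_folds * 3:
            return None
        plans = make_fold_plan(lines, k=self.settings.k_folds, n_runs=n_runs,
                               seed=_child_seed(self.seed, "cv", trait))
        report = run_cv(plans, {
            "gBLUP": self._kernel_fit_fn(resp, {"K": self.elite_grm}),
            "TGRM": self._kernel_fit_fn(resp, {"K": tk}),
        }, resp, grouping="trial")
        out = report.compare("TGRM", "gBLUP")
        out["report"] = report
        return out

    def focal_cv(self, method: str = "BayesB", n_runs: int = 10) -> dict:
        """Multi-kernel TGRM-BLUP vs gBLUP vs multi-trait gBLUP (focal trait)."""
        study = self.study
        endos = study.endophenotype_ids
        focal_obs = self.focal_entry_means
        overlap = [l for l in focal_obs.index if l in set(study.discovery_lines)]
        plans = make_fold_plan(list(focal_obs.index), k=self.settings.k_folds,
                               n_runs=n_runs, forced_train=overlap,
                               seed=_child_seed(self.seed, "cv", "focal"))

        kernels = {}
        for trait in endos:
            tk = self.tgrm(trait, method)
            if tk is not None:
                kernels[trait] = tk
        if not kernels:
            raise RuntimeError("no endophenotype kernels available")

        grm_u = self.union_grm
        disc_means = self.discovery_dereg.pivot_table(
            index="line_id", columns="trait", values="value")
        traits = [t for t in endos if t in disc_means.columns]
        Y = pd.DataFrame(index=grm_u.line_ids, columns=traits + ["focal"], dtype=float)
        common = Y.index.intersection(disc_means.index)
        Y.loc[common, traits] = disc_means.reindex(common)[traits]
        fc = Y.index.intersection(focal_obs.index)
        Y.loc[fc, "focal"] = focal_obs.reindex(fc)
        it, burn, thin = self.settings.mt_chain

        def mt_fit(masked_lines, fit_seed):
            Ym = Y.copy()
            Ym.loc[list(masked_lines), "focal"] = np.nan
            cfg = WGRConfig(n_iter=it, burn_in=burn, thin=thin, seed=fit_seed)
            return MultiTraitGBLUP(Ym, grm_u, cfg).fit().predict_gebv("focal")

        report = run_cv(plans, {
            "gBLUP": self._kernel_fit_fn(focal_obs, {"K": self.elite_grm}),
            "MK-TGRM": self._kernel_fit_fn(focal_obs, kernels),
            "MT-gBLUP": mt_fit,
        }, focal_obs)
        return {
            "report": report,
            "vs_gBLUP": report.compare("MK-TGRM", "gBLUP"),
            "vs_MT": report.compare("MK-TGRM", "MT-gBLUP"),
        }


def pooled_endo_comparison(seeds, trait: str, method: str, n_runs: int = 5,
                           settings: ExperimentSettings | None = None) -> dict:
    """Run-level wins pooled over independent study replicates.

    Returns the pooled win proportion, the per-replicate details, and the
    replicates skipped because the trait did not survive adjustment.
    """
    wins = 0
    total = 0
    acc_t, acc_g = [], []
    per_seed, skipped = {}, []
    for seed in seeds:
        exp = TwoPanelExperiment(seed, settings)
        out = exp.endo_cv(trait, method, n_runs=n_runs)
        if out is None:
            skipped.append(seed)
            continue
        wins += out["wins"]
        total += out["n_runs"]
        acc_t.append(out["mean_a"])
        acc_g.append(out["mean_b"])
        per_seed[seed] = {k: out[k] for k in
                          ("wins", "n_runs", "win_proportion", "mean_a", "mean_b")}
    return {
        "trait": trait,
        "method": method,
        "win_proportion": wins / total if total else np.nan,
        "n_runs": total,
        "mean_tgrm": float(np.mean(acc_t)) if acc_t else np.nan,
        "mean_gblup": float(np.mean(acc_g)) if acc_g else np.nan,
        "per_seed": per_seed,
        "skipped_seeds": skipped,
    }


def _child_seed(base: int, *tags) -> int:
    """Deterministic child seed below 2**31 from a base seed and str tags."""
    h = np.uint64(base % (2**31))
    for tag in tags:
        for ch in str(tag):
            h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**61))
    return int(h % (2**31 - 1))
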