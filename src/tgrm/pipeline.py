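"""Config-driven pipeline reproducing the two-panel prediction experiment.

Stages (each a function reading/writing documented artifacts under one
output directory, so any stage can be rerun in isolation):

1. ``simulate`` — synthetic two-panel study (genotypes, phenotypes, truth).
2. ``qc`` — per-panel marker/individual filtering and mean imputation; the
   per-analysis MAF threshold is applied separately to each panel's line
   subset, so panels retain different marker sets.
3. ``adjust`` — augmented-design mixed models; deregressed BLUPs for the
   endophenotypes (discovery jointly, elite per trial) and trial BLUPs plus
   entry means for the focal trait.
4. ``effects`` — Bayesian whole-genome regressions on the discovery panel,
   one per (method, endophenotype).
5. ``kernels`` — VanRaden GRMs and trait-specific (squared-effect-weighted)
   kernels on the prediction panel; markers filtered out of a panel simply
   carry no weight there.
6. ``evaluate`` — repeated five-fold CV: trait-specific kernel BLUP vs gBLUP
   per endophenotype, and multi-kernel BLUP vs gBLUP vs multi-trait gBLUP
   for the focal trait (overlap lines forced into training); win-rate
   summary tables; genetic parameters from a discovery multi-trait fit.

One global seed fans out deterministically to per-stage and per-fit seeds.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .blup import KernelBLUP, MultiTraitGBLUP
from .cv import make_fold_plan, run_cv
from .genoqc import QCThresholds, qc_pipeline
from .kernels import build_grm_vanraden, build_tgrm, center_scale, tgrm_weights
from .pheno import AugmentedBlockModel, deregressed_blups, extract_genetic_params
from .simdata import FieldDesign, StudyConfig, simulate_two_panel_study
from .wgr import WGRConfig, WholeGenomeRegression

__all__ = ["DEFAULT_CONFIG", "load_config", "run_stage", "run_all", "STAGES"]

log = logging.getLogger("tgrm.pipeline")

MCMC_PRESETS = {
    "full": {"n_iter": 20_000, "burn_in": 5_000, "thin": 5, "n_runs": 50},
    "test": {"n_iter": 3_000, "burn_in": 1_000, "thin": 2, "n_runs": 10},
}

DEFAULT_CONFIG = {
    "seed": 1,
    "mcmc": "test",
    "simulate": {
        "n_lines_discovery": 120,
        "n_lines_elite": 90,
        "n_overlap": 8,
        "n_markers": 300,
        "n_ld_blocks": 60,
        "traits": ["EP1", "EP2"],
        "elite_trials": 2,
        "focal_trials": 2,
        "discovery_blocks": 10,
        "elite_blocks": 8,
    },
    "analysis": {
        "methods": ["BayesB"],
        "n_runs": None,        # None -> preset default
        "k": 5,
        "threshold": 0.9,
        "maf": 0.05,
        "reliability_floor": 0.1,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Default config, optionally merged with a YAML file and overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _stage_seed(cfg: dict, stage: str) -> int:
    names = ["simulate", "qc", "adjust", "effects", "kernels", "evaluate"]
    ss = np.random.SeedSequence(int(cfg["seed"])).spawn(len(names))
    return int(np.random.default_rng(ss[names.index(stage)]).integers(2**31 - 1))


def _mcmc_config(cfg: dict, seed: int, method: str = "BRR") -> WGRConfig:
    preset = MCMC_PRESETS[cfg.get("mcmc", "test")]
    return WGRConfig(
        method=method, n_iter=preset["n_iter"], burn_in=preset["burn_in"],
        thin=preset["thin"], seed=seed,
    )


def _n_runs(cfg: dict) -> int:
    n = cfg["analysis"].get("n_runs")
    return int(n) if n else MCMC_PRESETS[cfg.get("mcmc", "test")]["n_runs"]


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; rerun the {produced_by!r} stage first"
        )
    return path


# ------------------------------------------------------------------- stages
def stage_simulate(cfg: dict, outdir: Path) -> None:
    sim = cfg["simulate"]
    d = outdir / "sim"
    d.mkdir(parents=True, exist_ok=True)
    study_cfg = StudyConfig(
        seed=_stage_seed(cfg, "simulate"),
        n_lines_discovery=sim["n_lines_discovery"],
        n_lines_elite=sim["n_lines_elite"],
        n_overlap=sim["n_overlap"],
        n_markers=sim["n_markers"],
        n_ld_blocks=sim["n_ld_blocks"],
        trait_subset=tuple(sim["traits"]) if sim.get("traits") else None,
        discovery_design=FieldDesign(
            n_trials=1, n_blocks=sim.get("discovery_blocks", 18), n_checks=2,
            batch_size=24, block_var_share=0.10, batch_var_share=0.05,
            covariate_beta=0.3, include_covariate=True,
        ),
        elite_design=FieldDesign(
            n_trials=sim.get("elite_trials", 3), n_blocks=sim.get("elite_blocks", 10),
            n_checks=2, batch_size=24, block_var_share=0.10, batch_var_share=0.05,
        ),
        focal_design=FieldDesign(
            n_trials=sim.get("focal_trials", 6), n_blocks=sim.get("elite_blocks", 10),
            n_checks=2, batch_size=40, block_var_share=0.08, batch_var_share=0.02,
        ),
    )
    study = simulate_two_panel_study(study_cfg)
    tio.write_dosage_csv(study.genotypes, d / "genotypes.csv")
    tio.write_vcf(study.genotypes, d / "genotypes.vcf")
    tio.write_phenotypes_csv(study.discovery_records, d / "discovery_phenotypes.csv")
    tio.write_phenotypes_csv(study.elite_records, d / "elite_phenotypes.csv")
    tio.write_phenotypes_csv(study.focal_records, d / "focal_phenotypes.csv")
    study.truth.to_json(d / "truth.json")
    with open(d / "panels.json", "w") as fh:
        json.dump(
            {
                "discovery": study.discovery_lines,
                "elite": study.elite_lines,
                "overlap": [l for l in study.discovery_lines if l in set(study.elite_lines)],
                "endophenotypes": study.endophenotype_ids,
            },
            fh, indent=1,
        )
    log.info("simulate: %d lines x %d markers, traits=%s",
             study.genotypes.n_lines, study.genotypes.n_markers,
             study.endophenotype_ids)


def stage_qc(cfg: dict, outdir: Path) -> None:
    d = outdir / "qc"
    d.mkdir(parents=True, exist_ok=True)
    G = tio.read_dosage_csv(_require(outdir / "sim" / "genotypes.csv", "simulate"))
    with open(_require(outdir / "sim" / "panels.json", "simulate")) as fh:
        panels = json.load(fh)
    maf = float(cfg["analysis"].get("maf", 0.05))
    thresholds = QCThresholds(marker_maf_min=maf)
    for name, lines in (
        ("discovery", panels["discovery"]),
        ("elite", panels["elite"]),
        ("union", sorted(set(panels["discovery"]) | set(panels["elite"]))),
    ):
        sub = G.subset_lines(lines)
        clean, mrep, irep = qc_pipeline(sub, thresholds)
        tio.write_dosage_csv(clean, d / f"{name}_geno.csv")
        mrep.to_csv(d / f"{name}_marker_report.tsv", sep="\t", index=False)
        irep.to_csv(d / f"{name}_individual_report.tsv", sep="\t", index=False)
        log.info("qc[%s]: kept %d/%d markers, %d/%d lines (MAF>=%s)",
                 name, clean.n_markers, G.n_markers, clean.n_lines, sub.n_lines, maf)


def stage_adjust(cfg: dict, outdir: Path) -> None:
    d = outdir / "adjust"
    d.mkdir(parents=True, exist_ok=True)
    floor = float(cfg["analysis"].get("reliability_floor", 0.1))
    disc = tio.read_phenotypes_csv(_require(outdir / "sim" / "discovery_phenotypes.csv", "simulate"))
    elite = tio.read_phenotypes_csv(_require(outdir / "sim" / "elite_phenotypes.csv", "simulate"))
    focal = tio.read_phenotypes_csv(_require(outdir / "sim" / "focal_phenotypes.csv", "simulate"))

    disc_tab, _ = deregressed_blups(disc, reliability_floor=floor)
    disc_tab.to_csv(d / "discovery_dereg.csv", index=False)
    elite_tab, _ = deregressed_blups(elite, reliability_floor=floor, per_trial=True)
    elite_tab.to_csv(d / "elite_dereg.csv", index=False)

    # focal trait: plain (regressed) entry BLUPs per trial and their average
    frames = []
    for trial in pd.unique(focal["trial"]):
        res = AugmentedBlockModel(focal[focal["trial"] == trial]).fit()
        frames.append(pd.DataFrame({
            "line_id": res.blups.index, "trait": "focal",
            "trial": trial, "value": res.blups.to_numpy(),
        }))
    trial_blups = pd.concat(frames, ignore_index=True)
    trial_blups.to_csv(d / "focal_trial_blups.csv", index=False)
    means = trial_blups.groupby("line_id", sort=False)["value"].mean().reset_index()
    means["trait"] = "focal"
    means[["line_id", "trait", "value"]].to_csv(d / "focal_entry_means.csv", index=False)
    log.info("adjust: %d discovery dereg values, %d elite, %d focal lines "
             "(reliability floor %s)", len(disc_tab), len(elite_tab), len(means), floor)


def stage_effects(cfg: dict, outdir: Path) -> None:
    d = outdir / "effects"
    d.mkdir(parents=True, exist_ok=True)
    G = tio.read_dosage_csv(_require(outdir / "qc" / "discovery_geno.csv", "qc"))
    dereg = pd.read_csv(_require(outdir / "adjust" / "discovery_dereg.csv", "adjust"))
    with open(_require(outdir / "sim" / "panels.json", "simulate")) as fh:
        traits = json.load(fh)["endophenotypes"]
    methods = cfg["analysis"]["methods"]
    ss = np.random.SeedSequence(_stage_seed(cfg, "effects")).spawn(len(methods) * len(traits))
    i = 0
    for method in methods:
        for trait in traits:
            sub = dereg[dereg["trait"] == trait]
            sub = sub[sub["line_id"].isin(G.line_ids)]
            seed = int(np.random.default_rng(ss[i]).integers(2**31 - 1))
            i += 1
            if len(sub) < 15:
                # the trait did not survive adjustment (e.g. the genetic
                # variance collapsed); drop it from the analysis
                log.warning("effects[%s,%s]: only %d deregressed values; "
                            "trait skipped", method, trait, len(sub))
                continue
            Gsub = G.subset_lines(sub["line_id"].tolist())
            wcfg = _mcmc_config(cfg, seed, method)
            res = WholeGenomeRegression(
                sub["value"].to_numpy(), Gsub.dosages, wcfg, marker_ids=G.marker_ids
            ).fit()
            tio.write_effects_tsv(res.to_table(), d / f"effects_{method}_{trait}.tsv")
            log.info("effects[%s,%s]: n=%d P=%d chain=%d/%d/%d seed=%d",
                     method, trait, len(sub), G.n_markers,
                     wcfg.n_iter, wcfg.burn_in, wcfg.thin, seed)


def stage_kernels(cfg: dict, outdir: Path) -> None:
    d = outdir / "kernels"
    d.mkdir(parents=True, exist_ok=True)
    with open(_require(outdir / "sim" / "panels.json", "simulate")) as fh:
        panels = json.load(fh)
    for name in ("discovery", "elite", "union"):
        G = tio.read_dosage_csv(_require(outdir / "qc" / f"{name}_geno.csv", "qc"))
        tio.write_kernel_csv(build_grm_vanraden(G), d / f"grm_{name}.csv")
    G_elite = tio.read_dosage_csv(outdir / "qc" / "elite_geno.csv")
    M = center_scale(G_elite)
    effects_dir = _require(outdir / "effects", "effects")
    for method in cfg["analysis"]["methods"]:
        for trait in panels["endophenotypes"]:
            path = effects_dir / f"effects_{method}_{trait}.tsv"
            if not path.exists():  # trait skipped during effect estimation
                continue
            eff = tio.read_effects_tsv(path)
            effects = pd.Series(eff["effect"].to_numpy(), index=eff["marker_id"])
            w = tgrm_weights(effects, marker_ids=G_elite.marker_ids)
            k = build_tgrm(M, w, kind=f"TGRM:{trait}")
            tio.write_kernel_csv(k, d / f"tgrm_{method}_{trait}.csv")
    log.info("kernels: GRMs + %d TGRMs written",
             len(cfg["analysis"]["methods"]) * len(panels["endophenotypes"]))


def stage_evaluate(cfg: dict, outdir: Path) -> None:
    d = outdir / "results"
    d.mkdir(parents=True, exist_ok=True)
    ana = cfg["analysis"]
    k_folds, threshold = int(ana["k"]), float(ana["threshold"])
    n_runs = _n_runs(cfg)
    with open(_require(outdir / "sim" / "panels.json", "simulate")) as fh:
        panels = json.load(fh)
    traits = panels["endophenotypes"]
    methods = ana["methods"]
    kdir = outdir / "kernels"
    grm_elite = tio.read_kernel_csv(_require(kdir / "grm_elite.csv", "kernels"))
    grm_union = tio.read_kernel_csv(_require(kdir / "grm_union.csv", "kernels"))
    elite_dereg = pd.read_csv(_require(outdir / "adjust" / "elite_dereg.csv", "adjust"))
    focal_means = pd.read_csv(_require(outdir / "adjust" / "focal_entry_means.csv", "adjust"))
    disc_dereg = pd.read_csv(outdir / "adjust" / "discovery_dereg.csv")
    seed0 = _stage_seed(cfg, "evaluate")

    def kernel_fit_fn(response, kernel):
        def fit(masked_lines, seed):
            kcfg = _mcmc_config(cfg, seed)
            return KernelBLUP(response, {"K": kernel}, masked_lines, kcfg).fit().predict_gebv()
        return fit

    # ---- (i) endophenotypes: trait-specific kernel BLUP vs gBLUP, per trial
    win_rows, endo_records = [], []
    for t_i, trait in enumerate(traits):
        resp = elite_dereg[elite_dereg["trait"] == trait][["line_id", "trial", "value"]]
        lines = [l for l in grm_elite.line_ids if l in set(resp["line_id"])]
        have_kernels = all((kdir / f"tgrm_{m}_{trait}.csv").exists() for m in methods)
        if not have_kernels or len(lines) < k_folds * 3:
            log.warning("evaluate[%s]: trait skipped (lost in adjustment or "
                        "effect estimation)", trait)
            continue
        plans = make_fold_plan(lines, k=k_folds, n_runs=n_runs, seed=seed0 + t_i)
        fns = {"gBLUP": kernel_fit_fn(resp, grm_elite)}
        for method in methods:
            tk = tio.read_kernel_csv(kdir / f"tgrm_{method}_{trait}.csv")
            fns[f"TGRM-{method}"] = kernel_fit_fn(resp, tk)
        report = run_cv(plans, fns, resp, grouping="trial")
        rec = report.records.copy()
        rec.insert(0, "trait", trait)
        endo_records.append(rec)
        for method in methods:
            c = report.compare(f"TGRM-{method}", "gBLUP", threshold)
            win_rows.append({"method": method, "trait": trait, **{
                k: c[k] for k in ("win_proportion", "significant",
                                  "mean_a", "mean_b", "percent_improvement")}})
    endo_summary = pd.DataFrame(win_rows)
    endo_summary.to_csv(d / "endo_summary.tsv", sep="\t", index=False)
    pd.concat(endo_records, ignore_index=True).to_csv(
        d / "endo_cv_records.tsv", sep="\t", index=False)
    endo_summary.pivot_table(index="method", columns="trait",
                             values="win_proportion").to_csv(
        d / "win_proportions.tsv", sep="\t")

    # ---- (ii) focal trait: multi-kernel vs gBLUP vs multi-trait gBLUP
    focal_obs = pd.Series(focal_means["value"].to_numpy(),
                          index=focal_means["line_id"]).reindex(grm_elite.line_ids).dropna()
    overlap = [l for l in panels["overlap"] if l in focal_obs.index]
    plans = make_fold_plan(list(focal_obs.index), k=k_folds, n_runs=n_runs,
                           forced_train=overlap, seed=seed0 + 1000)

    # multi-trait phenotype matrix over the union panel: endophenotypes
    # observed in discovery, focal observed in elite
    disc_means = disc_dereg.pivot_table(index="line_id", columns="trait", values="value")
    traits_mt = [t for t in traits if t in disc_means.columns]
    Y = pd.DataFrame(index=grm_union.line_ids, columns=traits_mt + ["focal"], dtype=float)
    Y.loc[Y.index.intersection(disc_means.index), traits_mt] = disc_means.reindex(
        Y.index.intersection(disc_means.index))[traits_mt]
    Y.loc[Y.index.intersection(focal_obs.index), "focal"] = focal_obs.reindex(
        Y.index.intersection(focal_obs.index))

    def mt_fit_fn(masked_lines, seed):
        Ym = Y.copy()
        Ym.loc[list(masked_lines), "focal"] = np.nan
        res = MultiTraitGBLUP(Ym, grm_union, _mcmc_config(cfg, seed)).fit()
        return res.predict_gebv("focal")

    fns = {"gBLUP": kernel_fit_fn(focal_obs, grm_elite), "MT-gBLUP": mt_fit_fn}
    for method in methods:
        kernels = {}
        for trait in traits:
            path = kdir / f"tgrm_{method}_{trait}.csv"
            if path.exists():
                kernels[trait] = tio.read_kernel_csv(path)
        if not kernels:
            log.warning("evaluate: no endophenotype kernels for %s; "
                        "multi-kernel model skipped", method)
            continue

        def mk_fit_fn(masked_lines, seed, _kernels=kernels):
            kcfg = _mcmc_config(cfg, seed)
            return KernelBLUP(focal_obs, _kernels, masked_lines, kcfg).fit().predict_gebv()

        fns[f"MK-TGRM-{method}"] = mk_fit_fn
    focal_report = run_cv(plans, fns, focal_obs)
    focal_report.records.to_csv(d / "focal_cv_records.tsv", sep="\t", index=False)
    rows = []
    for method in methods:
        if f"MK-TGRM-{method}" not in focal_report.run_means.columns:
            continue
        for baseline in ("gBLUP", "MT-gBLUP"):
            c = focal_report.compare(f"MK-TGRM-{method}", baseline, threshold)
            rows.append(c)
    pd.DataFrame(rows).to_csv(d / "focal_summary.tsv", sep="\t", index=False)

    # ---- genetic parameters from a discovery multi-trait fit
    grm_disc = tio.read_kernel_csv(kdir / "grm_discovery.csv")
    Yd = disc_means.reindex(grm_disc.line_ids)
    mt = MultiTraitGBLUP(Yd, grm_disc, _mcmc_config(cfg, seed0 + 2000)).fit()
    params = extract_genetic_params(mt)
    params["h2"].to_csv(d / "genetic_params_h2.tsv", sep="\t")
    params["genomic_correlation"].to_csv(d / "genetic_params_rg.tsv", sep="\t")
    params["phenotypic_correlation"].to_csv(d / "genetic_params_rp.tsv", sep="\t")
    log.info("evaluate: %d runs x %d folds, threshold %.2f; summaries written",
             n_runs, k_folds, threshold)


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "adjust": stage_adjust,
    "effects": stage_effects,
    "kernels": stage_kernels,
    "evaluate": stage_evaluate,
}


def run_stage(name: str, cfg: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name not in STAGES:
        raise KeyError(f"unknown stage {name!r}; choose from {list(STAGES)}")
    STAGES[name](cfg, outdir)


def run_all(cfg: dict, outdir) -> None:
    """Execute every stage in order and record the configuration used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("run-all: seed=%s mcmc=%s runs=%d", cfg["seed"], cfg.get("mcmc"),
                 _n_runs(cfg))
        with open(outdir / "config_used.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        for name in STAGES:
            log.info("stage %s ...", name)
            STAGES[name](cfg, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()
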