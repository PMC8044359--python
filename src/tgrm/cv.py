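"""Repeated k-fold cross-validation with the win-rate comparison rule.

Model quality is compared by repeated resampling: in each of ``n_runs``
independent runs the line set is split into ``k`` folds, every fold is
predicted by a model trained with that fold's phenotypes masked, and the
fold accuracies (Pearson correlation between predicted genomic values and
observations, per trial and then averaged) are averaged into one accuracy
per run.  Method A is declared significantly better than method B when A's
run accuracy strictly exceeds B's in at least a threshold proportion
(default 90%) of runs — a comparison that, unlike a t-test, does not
depend on the number of resampling runs and tolerates the dependence
between runs drawn from one dataset.

Lines present in both the training and prediction populations can be forced
into the training portion of every run (``forced_train``), so the test
folds only ever contain lines unseen by every stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FoldPlan", "CVReport", "make_fold_plan", "run_cv", "compare_methods"]


@dataclass
class FoldPlan:
    """One resampling run: a fold assignment over non-forced lines."""

    run: int
    k: int
    assignment: dict            # line_id -> fold (1..k)
    forced_train: frozenset
    seed: int

    def test_lines(self, fold: int) -> list:
        return [l for l, f in self.assignment.items() if f == fold]


def make_fold_plan(line_ids, k: int = 5, n_runs: int = 50, forced_train=(), seed: int = 0):
    """Independent random k-fold partitions for each run.

    Forced-training lines never appear in a test fold; the remaining lines
    are partitioned into folds whose sizes differ by at most one.
    """
    line_ids = list(line_ids)
    forced = frozenset(forced_train)
    unknown = forced - set(line_ids)
    if unknown:
        raise ValueError(f"forced_train lines not in line set: {sorted(unknown)[:5]}")
    free = [l for l in line_ids if l not in forced]
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(free) < k:
        raise ValueError(f"only {len(free)} assignable lines for k={k} folds")

    plans = []
    children = np.random.SeedSequence(seed).spawn(n_runs)
    for r, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        perm = rng.permutation(len(free))
        folds = np.array_split(perm, k)
        assignment = {}
        for f, idx in enumerate(folds, start=1):
            for i in idx:
                assignment[free[i]] = f
        plans.append(FoldPlan(run=r, k=k, assignment=assignment,
                              forced_train=forced, seed=seed))
    return plans


def _fold_accuracy(gebv: pd.Series, observed, test_lines, grouping) -> float | None:
    """Mean per-trial Pearson correlation on the test lines; None if any
    correlation is undefined (degenerate predictions or observations)."""
    pred = gebv.reindex(test_lines)
    if pred.isna().any():
        raise ValueError("model did not return predictions for all test lines")
    if isinstance(observed, pd.Series):
        groups = [observed.reindex(test_lines)]
    else:
        obs = observed[observed["line_id"].isin(test_lines)]
        if grouping == "trial":
            groups = [
                sub.groupby("line_id")["value"].mean().reindex(test_lines)
                for _, sub in obs.groupby("trial")
            ]
        else:
            groups = [obs.groupby("line_id")["value"].mean().reindex(test_lines)]
    rs = []
    for gobs in groups:
        ok = gobs.notna()
        if ok.sum() < 3:
            raise ValueError("fewer than 3 test observations in a trial group")
        x, yv = pred[ok].to_numpy(), gobs[ok].to_numpy()
        if np.std(x) == 0 or np.std(yv) == 0:
            return None
        rs.append(float(np.corrcoef(x, yv)[0, 1]))
    return float(np.mean(rs))


@dataclass
class CVReport:
    """Per-run/fold/method accuracies plus summaries."""

    records: pd.DataFrame           # run, fold, method, r
    run_means: pd.DataFrame         # runs x methods
    excluded_runs: list = field(default_factory=list)

    @property
    def methods(self) -> list:
        return list(self.run_means.columns)

    def mean_accuracy(self) -> pd.Series:
        return self.run_means.mean(axis=0)

    def compare(self, method_a: str, baseline: str, threshold: float = 0.9) -> dict:
        return compare_methods(self, method_a, baseline, threshold)

    def summary_table(self, baseline: str, threshold: float = 0.9) -> pd.DataFrame:
        """Win proportion and mean improvement of every method vs a baseline."""
        rows = []
        for m in self.methods:
            if m == baseline:
                continue
            c = self.compare(m, baseline, threshold)
            rows.append(
                {
                    "method": m,
                    "baseline": baseline,
                    "mean_accuracy": c["mean_a"],
                    "baseline_accuracy": c["mean_b"],
                    "win_proportion": c["win_proportion"],
                    "percent_improvement": c["percent_improvement"],
                    "significant": c["significant"],
                }
            )
        return pd.DataFrame(rows)


def run_cv(plans, methods: dict, observed, grouping: str | None = None) -> CVReport:
    """Execute cross-validation for several methods on shared fold plans.

    Parameters
    ----------
    plans : list of FoldPlan
    methods : mapping name -> callable(masked_lines, seed) -> Series
        Each callable fits its model with the given lines' phenotypes masked
        and returns genomic predictions covering at least those lines.
    observed : Series (line -> value) or DataFrame (line_id, trial, value)
        Held-out observations the predictions are correlated against.
    grouping : {"trial", None}
        With ``"trial"``, fold accuracy is the equal-weight average of
        per-trial correlations.
    """
    rows = []
    excluded = []
    base_ss = np.random.SeedSequence(plans[0].seed if plans else 0)
    for plan in plans:
        run_ok = True
        run_rows = []
        for fold in range(1, plan.k + 1):
            test = plan.test_lines(fold)
            child = np.random.SeedSequence((plan.seed, plan.run, fold))
            fit_seed = int(np.random.default_rng(child).integers(2**31 - 1))
            for name, fit_fn in methods.items():
                gebv = fit_fn(test, fit_seed)
                r = _fold_accuracy(gebv, observed, test, grouping)
                if r is None:
                    run_ok = False
                run_rows.append({"run": plan.run, "fold": fold, "method": name, "r": r})
        if run_ok:
            rows.extend(run_rows)
        else:
            excluded.append(plan.run)
            warnings.warn(
                f"run {plan.run} excluded: undefined correlation "
                "(degenerate predictions)",
                stacklevel=2,
            )
    records = pd.DataFrame(rows, columns=["run", "fold", "method", "r"])
    if len(records):
        run_means = records.pivot_table(index="run", columns="method", values="r",
                                        aggfunc="mean")
        run_means = run_means[list(methods)]
        run_means.columns.name = None
    else:
        run_means = pd.DataFrame(columns=list(methods))
    return CVReport(records=records, run_means=run_means, excluded_runs=excluded)


def compare_methods(report: CVReport, method_a: str, baseline: str,
                    threshold: float = 0.9) -> dict:
    """Win-rate declaration for method A against a baseline.

    A run is a win when A's run-mean accuracy strictly exceeds the
    baseline's (ties are not wins); significance is declared when the win
    proportion reaches the threshold (inclusive).
    """
    for m in (method_a, baseline):
        if m not in report.run_means.columns:
            raise KeyError(f"method {m!r} not in report")
    a = report.run_means[method_a]
    b = report.run_means[baseline]
    if a.isna().any() or b.isna().any() or len(a) != len(b):
        raise ValueError("methods do not share a complete, aligned run set")
    n_runs = len(a)
    wins = int((a > b).sum())
    ties = int((a == b).sum())
    win_prop = wins / n_runs if n_runs else np.nan
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return {
        "method": method_a,
        "baseline": baseline,
        "n_runs": n_runs,
        "wins": wins,
        "ties": ties,
        "win_proportion": win_prop,
        "significant": bool(win_prop >= threshold),
        "mean_a": mean_a,
        "mean_b": mean_b,
        "percent_improvement": 100.0 * (mean_a - mean_b) / abs(mean_b)
        if mean_b != 0
        else np.nan,
    }
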