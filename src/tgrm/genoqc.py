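"""Marker and individual quality control for SNP dosage panels.

Filtering conventions follow common practice for inbred GBS panels: removal
uses strict inequalities (a marker at exactly the MAF threshold is kept),
allele frequencies are computed from non-missing calls with heterozygotes
contributing one allele, and markers are filtered before individuals.  A
second, stricter MAF pass (default 0.05) is applied per analysis subset
after extracting each study's lines, which is why marker counts differ
between analyses run on the same master panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "filter_markers",
    "filter_individuals",
    "impute_mean",
    "qc_pipeline",
]


@dataclass
class QCThresholds:
    marker_maf_min: float = 0.02       # pre-imputation stage; per-analysis passes use 0.05
    marker_missing_max: float = 0.6
    marker_het_max: float = 0.1
    indiv_missing_max: float = 0.7
    indiv_het_max: float = 0.1

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def filter_markers(G: GenotypeMatrix, t: QCThresholds | None = None):
    """Drop markers failing MAF / missingness / heterozygosity thresholds.

    Removal is strict: MAF < threshold, missingness > threshold, het rate >
    threshold.  Returns the filtered matrix and a removal report listing each
    removed marker with its (first) failing criterion.
    """
    t = t or QCThresholds()
    maf = G.maf()
    miss = G.marker_missing_rate()
    het = G.marker_het_rate()

    reasons = np.full(G.n_markers, "", dtype=object)
    all_missing = np.isnan(maf)
    reasons[all_missing | (miss > t.marker_missing_max)] = "missing"
    low_maf = ~all_missing & (maf < t.marker_maf_min) & (reasons == "")
    reasons[low_maf] = "maf"
    high_het = ~np.isnan(het) & (het > t.marker_het_max) & (reasons == "")
    reasons[high_het] = "het"

    keep = reasons == ""
    if not keep.any():
        raise ValueError(
            f"all {G.n_markers} markers removed "
            f"(maf={np.sum(reasons == 'maf')}, missing={np.sum(reasons == 'missing')}, "
            f"het={np.sum(reasons == 'het')})"
        )
    report = pd.DataFrame(
        {"marker_id": G.marker_ids[~keep], "reason": reasons[~keep],
         "maf": maf[~keep], "missing": miss[~keep], "het": het[~keep]}
    )
    return G.take_markers(np.flatnonzero(keep)), report


def filter_individuals(G: GenotypeMatrix, t: QCThresholds | None = None):
    """Drop lines with excess missingness or heterozygosity (strict >)."""
    t = t or QCThresholds()
    miss = G.line_missing_rate()
    het = G.line_het_rate()

    reasons = np.full(G.n_lines, "", dtype=object)
    reasons[miss > t.indiv_missing_max] = "missing"
    high_het = ~np.isnan(het) & (het > t.indiv_het_max) & (reasons == "")
    reasons[high_het] = "het"

    keep = reasons == ""
    if not keep.any():
        raise ValueError("all individuals removed by QC")
    report = pd.DataFrame(
        {"line_id": G.line_ids[~keep], "reason": reasons[~keep],
         "missing": miss[~keep], "het": het[~keep]}
    )
    return G.take_lines(np.flatnonzero(keep)), report


def impute_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the marker's mean observed dosage."""
    mask = G.missing_mask
    if not mask.any():
        return G.copy()
    n_obs = (~mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = G.marker_ids[n_obs == 0]
        raise ValueError(f"markers with no observed calls (filter first): {list(bad[:5])}")
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(G.dosages, axis=0)
    dosages = np.where(mask, col_mean[None, :], G.dosages)
    return GenotypeMatrix(dosages, G.line_ids.copy(), G.marker_ids.copy())


def qc_pipeline(G: GenotypeMatrix, t: QCThresholds | None = None, impute: bool = True):
    """Markers-first QC then optional mean imputation.

    Returns (G_clean, marker_report, individual_report).
    """
    t = t or QCThresholds()
    G1, mrep = filter_markers(G, t)
    G2, irep = filter_individuals(G1, t)
    if impute:
        G2 = impute_mean(G2)
    return G2, mrep, irep
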