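"""Core container for SNP dosage data.

Lines (inbred individuals) are rows, biallelic markers are columns.  Dosages
count copies of the alternate allele and live in {0, 1, 2}; missing calls are
stored as ``nan`` in a float array so that masking and per-marker summaries
stay vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Lines x markers allele-dosage matrix with identifiers.

    Parameters
    ----------
    dosages : ndarray of float, shape (n_lines, n_markers)
        Allele dosages in {0, 1, 2}; ``nan`` marks a missing call.
    line_ids : sequence of str
    marker_ids : sequence of str
    """

    dosages: np.ndarray
    line_ids: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        n, p = self.dosages.shape
        if len(self.line_ids) != n:
            raise ValueError(f"{len(self.line_ids)} line ids for {n} rows")
        if len(self.marker_ids) != p:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {p} columns")
        # raw calls are {0,1,2}; mean-imputed values may be fractional
        valid = np.isnan(self.dosages) | (
            (self.dosages >= 0.0) & (self.dosages <= 2.0)
        )
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"dosages must lie in [0, 2] or be nan; found {bad[:5]}")

    # ------------------------------------------------------------------ shape
    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    # -------------------------------------------------------------- summaries
    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker (nan if no calls)."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def marker_missing_rate(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def marker_het_rate(self) -> np.ndarray:
        """Heterozygote fraction among non-missing calls per marker."""
        obs = ~self.missing_mask
        het = (self.dosages == 1.0) & obs
        with np.errstate(invalid="ignore"):
            return np.where(obs.sum(0) > 0, het.sum(0) / np.maximum(obs.sum(0), 1), np.nan)

    def line_missing_rate(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def line_het_rate(self) -> np.ndarray:
        obs = ~self.missing_mask
        het = (self.dosages == 1.0) & obs
        with np.errstate(invalid="ignore"):
            return np.where(obs.sum(1) > 0, het.sum(1) / np.maximum(obs.sum(1), 1), np.nan)

    # ------------------------------------------------------------- subsetting
    def subset_lines(self, ids) -> "GenotypeMatrix":
        idx = self._line_index(ids)
        return GenotypeMatrix(self.dosages[idx], self.line_ids[idx], self.marker_ids)

    def subset_markers(self, ids) -> "GenotypeMatrix":
        pos = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            idx = np.array([pos[m] for m in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown marker id {e.args[0]!r}") from None
        return GenotypeMatrix(self.dosages[:, idx], self.line_ids, self.marker_ids[idx])

    def take_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosages[:, idx], self.line_ids, self.marker_ids[idx])

    def take_lines(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosages[idx], self.line_ids[idx], self.marker_ids)

    def _line_index(self, ids) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([pos[l] for l in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown line id {e.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), self.line_ids.copy(), self.marker_ids.copy()
        )
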