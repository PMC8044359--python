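"""Genomic relationship matrices: standard (VanRaden) and trait-weighted.

The trait-specific kernel is ``G* = M D M' / P`` where ``M`` is the
centered, unit-variance-scaled dosage matrix and ``D`` a diagonal matrix of
per-marker weights proportional to the squared estimated additive effect,
``a_p^2 / sum_q a_q^2``.  Raw weights sum to one; by default they are
rescaled to sum to ``P`` so that equal effects reproduce the unweighted
kernel ``M M'/P`` exactly and variance components remain on a comparable
scale across weighted and unweighted models (``normalize="sum_to_P"``; the
raw convention is available as ``"sum_to_1"``).

The baseline kernel uses VanRaden's second definition: each marker deviation
is standardised by its own ``2 p (1-p)`` before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "CenteredDosages",
    "WeightVector",
    "Kernel",
    "center_scale",
    "tgrm_weights",
    "build_tgrm",
    "build_grm_vanraden",
    "bend_psd",
    "align_effects",
]


@dataclass
class CenteredDosages:
    """Column-centered, unit-sample-variance dosage matrix with provenance."""

    M: np.ndarray
    line_ids: np.ndarray
    marker_ids: np.ndarray
    col_means: np.ndarray
    col_scales: np.ndarray

    @property
    def n_lines(self) -> int:
        return self.M.shape[0]

    @property
    def n_markers(self) -> int:
        return self.M.shape[1]


@dataclass
class WeightVector:
    """Non-negative per-marker kernel weights with a normalization tag."""

    weights: np.ndarray
    marker_ids: np.ndarray
    normalize: str  # "sum_to_P" | "sum_to_1"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        target = len(w) if self.normalize == "sum_to_P" else 1.0
        if abs(w.sum() - target) > 1e-10 * max(target, 1.0):
            raise ValueError(f"weights sum {w.sum()} != declared target {target}")
        self.weights = w


@dataclass
class Kernel:
    """Symmetric PSD line x line relationship matrix."""

    values: np.ndarray
    line_ids: np.ndarray
    kind: str = "GRM"           # "GRM" or "TGRM:<trait>"
    bending: float | None = None  # diagonal shift applied, if any

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kernel must be square")
        asym = np.abs(K - K.T).max() if K.size else 0.0
        if asym > 1e-10:
            raise ValueError(f"kernel asymmetry {asym:.2e} exceeds 1e-10")
        self.values = (K + K.T) / 2.0
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        if len(self.line_ids) != K.shape[0]:
            raise ValueError("line id count does not match kernel size")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    def subset(self, ids) -> "Kernel":
        pos = {l: i for i, l in enumerate(self.line_ids)}
        idx = np.array([pos[l] for l in ids], dtype=int)
        return Kernel(self.values[np.ix_(idx, idx)], self.line_ids[idx], self.kind, self.bending)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)


def center_scale(G: GenotypeMatrix) -> CenteredDosages:
    """Center each marker column and scale it to unit sample variance."""
    X = np.asarray(G.dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("dosages contain missing values; impute first")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    if (scales <= 0).any():
        bad = G.marker_ids[scales <= 0]
        raise ValueError(f"zero-variance markers (filter first): {list(bad[:5])}")
    M = (X - means) / scales
    return CenteredDosages(M, G.line_ids.copy(), G.marker_ids.copy(), means, scales)


def align_effects(effects: pd.Series, marker_ids) -> np.ndarray:
    """Effects re-indexed to ``marker_ids``; markers without an estimated
    effect (e.g. filtered out of the training panel) get effect 0."""
    s = effects.reindex(marker_ids)
    return s.fillna(0.0).to_numpy(dtype=float)


def tgrm_weights(effects, marker_ids=None, normalize: str = "sum_to_P") -> WeightVector:
    """Squared-effect marker weights ``a_p^2 / sum a_q^2``.

    Parameters
    ----------
    effects : array-like or pandas Series
        Per-marker additive effects (a Series is aligned to ``marker_ids``).
    normalize : {"sum_to_P", "sum_to_1"}
        Post-scaling of the raw (sum-to-one) weights.
    """
    if isinstance(effects, pd.Series):
        if marker_ids is None:
            marker_ids = effects.index.to_numpy(dtype=object)
            a = effects.to_numpy(dtype=float)
        else:
            marker_ids = np.asarray(marker_ids, dtype=object)
            a = align_effects(effects, marker_ids)
    else:
        a = np.asarray(effects, dtype=float)
        if marker_ids is None:
            marker_ids = np.array([f"M{i}" for i in range(len(a))], dtype=object)
        marker_ids = np.asarray(marker_ids, dtype=object)
    if normalize not in ("sum_to_P", "sum_to_1"):
        raise ValueError(f"unknown normalization {normalize!r}")
    ss = float(np.sum(a**2))
    if ss <= 0:
        raise ValueError("all marker effects are zero; weighted kernel undefined")
    w = a**2 / ss
    if normalize == "sum_to_P":
        w = w * len(w)
    return WeightVector(w, marker_ids, normalize)


def build_tgrm(M: CenteredDosages, d: WeightVector, kind: str | None = None,
               bend_eps: float = 1e-6) -> Kernel:
    """Weighted kernel ``M diag(d) M' / P``, bent to PSD if needed."""
    if M.n_markers != len(d.weights):
        raise ValueError(f"{M.n_markers} markers vs {len(d.weights)} weights")
    P = M.n_markers
    K = (M.M * d.weights[None, :]) @ M.M.T / P
    kern = Kernel((K + K.T) / 2.0, M.line_ids, kind or "TGRM")
    return bend_psd(kern, bend_eps)


def build_grm_vanraden(G: GenotypeMatrix, inbred: bool = True,
                       bend_eps: float = 1e-6) -> Kernel:
    """VanRaden's second GRM: each marker deviation standardised by its own
    expected variance before averaging.

    ``G = (1/P) sum_p (w_p - 2p_p)(w_p - 2p_p)' / v_p`` with allele
    frequencies from the observed dosages.  For fully inbred lines the
    dosage variance is ``v_p = 4 p (1-p)`` (no heterozygotes), which keeps
    the mean diagonal near one; ``inbred=False`` uses the outbred
    Hardy-Weinberg variance ``2 p (1-p)``.
    """
    X = np.asarray(G.dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("dosages contain missing values; impute first")
    p = X.mean(axis=0) / 2.0
    if ((p <= 0) | (p >= 1)).any():
        bad = G.marker_ids[(p <= 0) | (p >= 1)]
        raise ValueError(f"fixed markers (filter first): {list(bad[:5])}")
    c = 4.0 if inbred else 2.0
    Z = (X - 2.0 * p) / np.sqrt(c * p * (1.0 - p))
    K = Z @ Z.T / G.n_markers
    return bend_psd(Kernel((K + K.T) / 2.0, G.line_ids, "GRM"), bend_eps)


def bend_psd(K: Kernel, eps: float = 1e-6) -> Kernel:
    """Shift the diagonal so the smallest eigenvalue is at least ``eps``.

    Eigenvalues above -1e-8 count as zero (round-off from rank-deficient
    products), leaving the kernel untouched.
    """
    w = np.linalg.eigvalsh(K.values)
    lam_min = float(w[0])
    if lam_min >= -1e-8:
        return K
    shift = eps - lam_min
    return Kernel(K.values + shift * np.eye(K.n_lines), K.line_ids, K.kind, bending=shift)
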