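"""File-format adapters: dosage CSV, minimal VCF, phenotype and result tables.

All tabular formats round-trip exactly (``write o read = id``).  The VCF
adapter is genotype-only: it writes GT fields on synthetic coordinates and
reads any VCF 4.x via cyvcf2, mapping genotypes to dosages (``./.`` becomes
missing).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .kernels import Kernel
from .simdata import PHENO_COLUMNS

__all__ = [
    "write_dosage_csv", "read_dosage_csv",
    "write_vcf", "read_vcf",
    "write_phenotypes_csv", "read_phenotypes_csv",
    "write_kernel_csv", "read_kernel_csv",
    "write_effects_tsv", "read_effects_tsv",
    "write_gebv_tsv", "read_gebv_tsv",
]


# ------------------------------------------------------------------- dosages
def write_dosage_csv(G: GenotypeMatrix, path) -> None:
    """Lines x markers CSV; header row of marker ids, first column line_id;
    missing calls are empty cells."""
    G.to_frame().to_csv(path, index_label="line_id", na_rep="")


def read_dosage_csv(path) -> GenotypeMatrix:
    frame = pd.read_csv(path, index_col=0)
    if frame.index.name != "line_id":
        raise ValueError(f"{path}: line 1: expected first column 'line_id', "
                         f"found {frame.index.name!r}")
    return GenotypeMatrix(
        frame.to_numpy(dtype=float),
        frame.index.to_numpy(dtype=object).astype(str).astype(object),
        frame.columns.to_numpy(dtype=object),
    )


# ----------------------------------------------------------------------- vcf
_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT only, on synthetic single-chromosome
    coordinates (POS = marker rank)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.line_ids)) + "\n")
        for j, marker in enumerate(G.marker_ids):
            calls = "\t".join(
                _GT.get(d, "./.") if np.isfinite(d) else "./."
                for d in G.dosages[:, j]
            )
            fh.write(f"1\t{j + 1}\t{marker}\tA\tT\t.\t.\t.\tGT\t{calls}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF into dosages (alt-allele counts)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    marker_ids, columns = [], []
    for idx, var in enumerate(vcf):
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        col = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]  # last element is the phasing flag
            col[i] = np.nan if any(al < 0 for al in alleles) else float(sum(alleles))
        columns.append(col)
    if not columns:
        raise ValueError(f"{path}: no variant records found")
    return GenotypeMatrix(
        np.column_stack(columns), samples, np.asarray(marker_ids, dtype=object)
    )


# ---------------------------------------------------------------- phenotypes
def write_phenotypes_csv(records: pd.DataFrame, path) -> None:
    records.loc[:, PHENO_COLUMNS].to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in PHENO_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: line 1: missing phenotype columns {missing}")
    frame["is_check"] = frame["is_check"].astype(bool)
    return frame[PHENO_COLUMNS]


# ------------------------------------------------------------------- kernels
def write_kernel_csv(kernel: Kernel, path) -> None:
    """Square CSV with line-id header row and column; the kernel kind is
    carried in a leading comment line."""
    with open(path, "w") as fh:
        fh.write(f"#kind={kernel.kind}\n")
        kernel.to_frame().to_csv(fh, index_label="line_id", lineterminator="\n")


def read_kernel_csv(path) -> Kernel:
    with open(path) as fh:
        first = fh.readline()
        kind = "GRM"
        if first.startswith("#kind="):
            kind = first.strip().split("=", 1)[1]
            frame = pd.read_csv(fh, index_col=0)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh, index_col=0)
    if not np.array_equal(frame.index.to_numpy(dtype=object),
                          frame.columns.to_numpy(dtype=object)):
        raise ValueError(f"{path}: line 2: kernel row/column ids differ")
    return Kernel(frame.to_numpy(dtype=float),
                  frame.index.to_numpy(dtype=object), kind)


# ------------------------------------------------------------ effect tables
def write_effects_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_effects_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    for col in ("marker_id", "effect"):
        if col not in frame.columns:
            raise ValueError(f"{path}: line 1: missing column {col!r}")
    return frame


def write_gebv_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gebv_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    for col in ("line_id", "model", "gebv"):
        if col not in frame.columns:
            raise ValueError(f"{path}: line 1: missing column {col!r}")
    return frame
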