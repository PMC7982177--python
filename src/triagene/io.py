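"""Readers and writers for the tab-delimited dialects used across the pipeline.

All tables are plain TSV. Conventions:

* GWAS summary: columns ``SNP, CHR, BP, P`` (header row).
* eQTL table: columns ``SNP, GENE, P, TYPE`` with ``TYPE`` in {cis, trans}.
* Gene annotation: BED-like, no header, 0-based half-open:
  ``chrom <TAB> start <TAB> end <TAB> gene``.
* Gene sets: GMT (``name <TAB> description <TAB> gene ...``).
* Expression: two-line header (sample IDs, then group labels), then one row
  per gene: ``gene <TAB> value ...``.
* Dosage matrix: header row of SNP IDs, then one row per sample:
  ``sample <TAB> dosage ...``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

GWAS_COLUMNS = ["SNP", "CHR", "BP", "P"]
EQTL_COLUMNS = ["SNP", "GENE", "P", "TYPE"]
ANNOTATION_COLUMNS = ["chrom", "start", "end", "gene"]


class InputFormatError(ValueError):
    """An input file does not match the expected dialect."""


def read_gwas(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    missing = [c for c in GWAS_COLUMNS[:1] + ["P"] if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing GWAS columns {missing}")
    return df


def write_gwas(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in GWAS_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_eqtl(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "GENE": str, "TYPE": str})
    missing = [c for c in EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing eQTL columns {missing}")
    return df


def write_eqtl(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=EQTL_COLUMNS)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=ANNOTATION_COLUMNS,
        dtype={"chrom": str, "gene": str},
    )
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "gene"].tolist()
        raise InputFormatError(f"{path}: start >= end for genes {bad}")
    return df


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False, columns=ANNOTATION_COLUMNS)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputFormatError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_expression(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Return (genes x samples DataFrame, array of group labels)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        groups = fh.readline().rstrip("\n").split("\t")
        body = fh.read()
    samples, labels = header[1:], np.asarray(groups[1:], dtype=object)
    if len(samples) != len(labels):
        raise InputFormatError(f"{path}: sample/group header length mismatch")
    df = pd.read_csv(_io.StringIO(body), sep="\t", header=None, index_col=0)
    df.columns = samples
    df.index.name = "gene"
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        import warnings

        warnings.warn(f"{path}: dropped {n_missing} gene rows with missing values")
        df = df.dropna()
    return df, labels


def write_expression(df: pd.DataFrame, groups: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["gene", *map(str, df.columns)]) + "\n")
        fh.write("\t".join(["group", *map(str, groups)]) + "\n")
        df.to_csv(fh, sep="\t", header=False)


def read_dosage(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Return (samples x SNPs int matrix, sample IDs, SNP IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=np.int8), list(map(str, df.index)), list(map(str, df.columns))


def write_dosage(genotypes: np.ndarray, sample_ids: list[str], snp_ids: list[str],
                 path: str | Path) -> None:
    pd.DataFrame(genotypes, index=sample_ids, columns=snp_ids).to_csv(path, sep="\t")
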