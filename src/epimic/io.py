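"""Readers and writers for genotype tables, scan results and reports.

Two genotype dialects are supported:

* ``csv`` — header row, one column per SNP with dosage values 0/1/2 (``NA``
  = missing), an optional ``class`` column holding the 0/1 phenotype, and
  an optional leading sample-id column;
* ``plink_raw`` — whitespace-separated PLINK ``.raw`` dosage text with the
  FID/IID/PAT/MAT/SEX/PHENOTYPE preamble, PHENOTYPE coded 1/2 and remapped
  to 0/1.

Genotype coding is taken at face value as minor-allele dosage; a warning is
logged when a SNP's empirical allele frequency exceeds 0.5.  Every output
file embeds the run parameters (seed, permutation count, exponent, package
version) as ``#`` header comments so any run is reconstructible.
"""
from __future__ import annotations

import logging
import re
from typing import Optional

import numpy as np
import pandas as pd

from .epistasis import (GenotypeMatrix, NetworkSummary, PhenotypeVector,
                        ScanResult)

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "read_gene_map",
    "write_dataset_csv",
    "write_scan",
    "read_scan",
    "write_edges",
    "write_report",
]

logger = logging.getLogger(__name__)

_ID_COLUMNS = {"sample_id", "sample", "id", "iid"}
_PLINK_PREAMBLE = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_ALLELE_SUFFIX = re.compile(r"_[ACGT]$")


class GenotypeParseError(ValueError):
    """A genotype file violated the 0/1/2/NA contract."""


def _parse_genotype_frame(frame: pd.DataFrame, path) -> np.ndarray:
    values = np.full(frame.shape, -1, dtype=np.int8)
    for j, col in enumerate(frame.columns):
        series = frame[col]
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.notna() & ~numeric.isin((0, 1, 2))
        bad |= series.notna() & numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise GenotypeParseError(
                f"{path}: invalid genotype {series.iloc[row]!r} for SNP "
                f"{col!r} at data line {row + 1} (expected 0, 1, 2 or NA)"
            )
        filled = numeric.fillna(-1).to_numpy()
        values[:, j] = filled.astype(np.int8)
    return values


def _warn_major_coding(values: np.ndarray, snp_ids):
    observed = np.ma.masked_equal(values, -1)
    freqs = observed.mean(axis=0) / 2.0
    flipped = [sid for sid, q in zip(snp_ids, np.atleast_1d(freqs))
               if q is not np.ma.masked and q > 0.5]
    if flipped:
        logger.warning("empirical MAF > 0.5 for %d SNP(s) (%s); dosages are "
                       "taken at face value", len(flipped),
                       ", ".join(map(str, flipped[:5])))


def read_genotypes(path, fmt: str = "csv"):
    """Read a genotype table; returns ``(GenotypeMatrix, PhenotypeVector | None)``."""
    if fmt == "csv":
        df = pd.read_csv(path, comment="#", dtype=str)
        first = df.columns[0]
        if first.lower() in _ID_COLUMNS:
            sample_ids = df[first].astype(str).tolist()
            df = df.drop(columns=[first])
        else:
            sample_ids = [f"S{i + 1}" for i in range(len(df))]
        phen = None
        class_cols = [c for c in df.columns if c.lower() == "class"]
        if class_cols:
            raw = pd.to_numeric(df[class_cols[0]], errors="raise")
            phen = PhenotypeVector(raw.to_numpy())
            df = df.drop(columns=class_cols)
        snp_ids = list(df.columns)
    elif fmt == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", comment="#", dtype=str)
        missing = [c for c in _PLINK_PREAMBLE if c not in df.columns]
        if missing:
            raise GenotypeParseError(
                f"{path}: plink_raw file lacks preamble column(s) "
                f"{', '.join(missing)}"
            )
        sample_ids = df["IID"].astype(str).tolist()
        raw = pd.to_numeric(df["PHENOTYPE"], errors="raise").to_numpy()
        if not np.isin(raw, (1, 2)).all():
            raise GenotypeParseError(
                f"{path}: PHENOTYPE must be coded 1 (control) / 2 (case)"
            )
        phen = PhenotypeVector(raw - 1)
        df = df.drop(columns=_PLINK_PREAMBLE)
        snp_ids = [_ALLELE_SUFFIX.sub("", c) for c in df.columns]
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    values = _parse_genotype_frame(df, path)
    _warn_major_coding(values, snp_ids)
    return GenotypeMatrix(values, sample_ids, snp_ids), phen


def read_phenotypes(path) -> PhenotypeVector:
    """Read a one-column 0/1 phenotype file (optional header)."""
    raw = pd.read_csv(path, comment="#", header=None).iloc[:, -1]
    raw = pd.to_numeric(raw, errors="coerce").dropna()
    return PhenotypeVector(raw.to_numpy())


def read_gene_map(path) -> dict:
    """Read a SNP-to-gene TSV (columns: snp_id, gene)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: gene map needs snp_id and gene columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _header_lines(**params) -> str:
    from . import __version__
    items = {"version": __version__, **params}
    return "".join(f"# {k}={v}\n" for k, v in items.items() if v is not None)


def write_dataset_csv(path, G: GenotypeMatrix, y: Optional[PhenotypeVector],
                      seed=None):
    """Write a genotype CSV (sample_id, class, one column per SNP)."""
    df = pd.DataFrame(G.values, columns=G.snp_ids).astype(object)
    df = df.mask(df == -1, "NA")
    if y is not None:
        df.insert(0, "class", y.labels)
    df.insert(0, "sample_id", G.sample_ids)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed=seed))
        df.to_csv(fh, index=False)


def write_scan(scan: ScanResult, path):
    """Write a scan result TSV with its run parameters in the header."""
    with open(path, "w") as fh:
        fh.write(_header_lines(seed=scan.seed, m=scan.m,
                               exponent=scan.exponent, alpha=scan.alpha))
        scan.to_dataframe().to_csv(fh, sep="\t", index=False)


def read_scan(path) -> pd.DataFrame:
    """Reload a scan TSV written by :func:`write_scan`."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_edges(summary: NetworkSummary, edges_path, nodes_path, **params):
    """Write Gephi-importable edge and node CSVs."""
    with open(edges_path, "w") as fh:
        fh.write(_header_lines(**params))
        summary.edges.to_csv(fh, index=False)
    with open(nodes_path, "w") as fh:
        fh.write(_header_lines(average_degree=summary.average_degree,
                               **params))
        summary.nodes.to_csv(fh, index=False)


def write_report(df: pd.DataFrame, path, **params):
    """Write an experiment report TSV."""
    with open(path, "w") as fh:
        fh.write(_header_lines(**params))
        df.to_csv(fh, sep="\t", index=False)
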