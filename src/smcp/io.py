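"""Readers and writers for genotype matrices, phenotype tables and reports.

Genotypes are held as integer allele counts (0/1/2) with ``MISSING`` (-1)
marking missing calls.  Three dialects are supported: VCF (via cyvcf2, GT
field only), PLINK text ``.ped``/``.map`` pairs, and a plain TSV with one
row per subject and one column per SNP.  Columns are always ordered by
(chromosome, position); adjacency between columns j and j+1 is meaningful
only within a chromosome.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call
MISSING: int = -1

#: string tokens treated as missing in TSV genotype files
_NA_TOKENS = {"", ".", "NA", "na", "NaN", "nan", "-1"}


class FormatError(ValueError):
    """A file could not be parsed under the requested dialect."""


class SchemaError(ValueError):
    """A table is missing required columns or violates uniqueness."""


def _chrom_key(chrom: str):
    """Sort key placing numeric chromosomes first, in numeric order."""
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs allele-count matrix with its SNP map.

    Parameters
    ----------
    subjects : list of str
        Subject identifiers, one per row of ``codes``.
    snps : pandas.DataFrame
        One row per SNP with columns ``id``, ``chrom``, ``pos`` (and
        optionally ``gene``), in the column order of ``codes``.
    codes : ndarray of int
        n x p matrix with entries in {0, 1, 2} or ``MISSING``.
    metadata : dict
        Provenance, e.g. which allele was counted.
    """

    subjects: list
    snps: pd.DataFrame
    codes: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        n, p = self.codes.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 subjects and p >= 1 SNPs, got {n} x {p}")
        if len(self.subjects) != n:
            raise ValueError("subject list does not match row count")
        if len(self.snps) != p:
            raise ValueError("SNP map does not match column count")
        vals = np.unique(self.codes)
        bad = vals[(vals != MISSING) & ((vals < 0) | (vals > 2))]
        if bad.size:
            raise ValueError(f"invalid genotype codes: {bad.tolist()}")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def p(self) -> int:
        return self.codes.shape[1]

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Return a copy with columns ordered by (chromosome, position)."""
        keys = [
            (_chrom_key(str(c)), int(q), i)
            for i, (c, q) in enumerate(zip(self.snps["chrom"], self.snps["pos"]))
        ]
        order = [i for *_, i in sorted(keys)]
        return GenotypeMatrix(
            subjects=list(self.subjects),
            snps=self.snps.iloc[order].reset_index(drop=True),
            codes=self.codes[:, order],
            metadata=dict(self.metadata),
        )


@dataclass
class PhenotypeTable:
    """Quantitative trait plus covariates for a set of subjects.

    ``covariates`` holds numeric columns only; categorical covariates are
    expanded to k-1 indicator columns at read time (reference level =
    lexicographically first).
    """

    subjects: list
    trait: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self):
        self.trait = np.asarray(self.trait, dtype=float)
        if len(self.subjects) != self.trait.shape[0]:
            raise ValueError("subject list does not match trait length")
        if len(self.covariates) not in (0, len(self.subjects)):
            raise ValueError("covariate rows do not match subjects")


# ---------------------------------------------------------------------------
# genotype readers

def read_genotypes(path, format: str, map_path=None) -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` under the named dialect.

    Parameters
    ----------
    path : path-like
        File to read. For ``plink_text`` this may be the ``.ped`` file or
        the common prefix of the ``.ped``/``.map`` pair.
    format : {"vcf", "plink_text", "tsv"}
    map_path : path-like, optional
        For ``tsv`` only: a PLINK-style ``.map`` file supplying chromosome
        and position for each SNP ID. Without it, TSV columns are placed on
        a single pseudo-chromosome in file order.

    Returns
    -------
    GenotypeMatrix
        Codes count the file's alternate allele (VCF) or the
        lexicographically later allele (PLINK text, TSV); the convention is
        recorded in ``metadata``. Columns are sorted by (chromosome,
        position).
    """
    path = Path(path)
    if format == "tsv":
        gm = _read_tsv(path, map_path)
    elif format == "vcf":
        gm = _read_vcf(path)
    elif format == "plink_text":
        gm = _read_plink_text(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if gm.p == 0:
        raise FormatError(f"{path}: no usable SNPs")
    return gm.sorted_by_position()


def _read_tsv(path: Path, map_path=None) -> GenotypeMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no usable SNPs")
    codes = np.full(df.shape, MISSING, dtype=np.int16)
    for j, col in enumerate(df.columns):
        for i, tok in enumerate(df.iloc[:, j]):
            tok = "" if tok is None or (isinstance(tok, float) and np.isnan(tok)) else str(tok).strip()
            if tok in _NA_TOKENS:
                continue
            try:
                v = int(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: line {i + 2}: non-integer genotype {tok!r} for SNP {col}"
                ) from None
            if v not in (0, 1, 2):
                raise FormatError(
                    f"{path}: line {i + 2}: genotype code {v} outside 0/1/2 for SNP {col}"
                )
            codes[i, j] = v
    snp_ids = [str(c) for c in df.columns]
    if map_path is not None:
        snps = _read_map(Path(map_path))
        snps = snps.set_index("id").loc[snp_ids].reset_index()
    else:
        snps = pd.DataFrame(
            {"id": snp_ids, "chrom": "0", "pos": np.arange(1, len(snp_ids) + 1)}
        )
    return GenotypeMatrix(
        subjects=[str(s) for s in df.index],
        snps=snps,
        codes=codes,
        metadata={"source": str(path), "format": "tsv", "counted_allele": "as-coded"},
    )


def _read_vcf(path: Path) -> GenotypeMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: cannot open as VCF: {exc}") from exc
    subjects = list(vcf.samples)
    ids, chroms, poss, cols = [], [], [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types
        col = np.full(len(subjects), MISSING, dtype=np.int16)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(str(variant.CHROM))
        poss.append(int(variant.POS))
        cols.append(col)
    if n_multi:
        warnings.warn(f"{path}: skipped {n_multi} multiallelic site(s)", stacklevel=2)
    if not cols:
        raise FormatError(f"{path}: no usable biallelic SNPs")
    codes = np.stack(cols, axis=1)
    snps = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(
        subjects=subjects,
        snps=snps,
        codes=codes,
        metadata={"source": str(path), "format": "vcf", "counted_allele": "ALT"},
    )


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}: line {ln}: expected 4 fields, got {len(parts)}")
            rows.append({"chrom": parts[0], "id": parts[1], "pos": int(parts[3])})
    return pd.DataFrame(rows)


def _read_plink_text(path: Path) -> GenotypeMatrix:
    path = Path(path)
    if path.suffix == ".ped":
        ped, mp = path, path.with_suffix(".map")
    elif path.suffix == ".map":
        ped, mp = path.with_suffix(".ped"), path
    else:
        ped, mp = path.with_suffix(".ped"), path.with_suffix(".map")
    if not ped.exists():
        raise FileNotFoundError(ped)
    snps = _read_map(mp)
    p = len(snps)
    subjects, allele_rows = [], []
    with open(ped) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * p:
                raise FormatError(
                    f"{ped}: line {ln}: expected {6 + 2 * p} fields, got {len(parts)}"
                )
            subjects.append(parts[1])
            allele_rows.append(parts[6:])
    if not subjects:
        raise FormatError(f"{ped}: empty pedigree file")
    alleles = np.array(allele_rows, dtype=object).reshape(len(subjects), p, 2)
    codes = np.full((len(subjects), p), MISSING, dtype=np.int16)
    counted = []
    for j in range(p):
        a = alleles[:, j, :]
        observed = sorted({x for x in a.ravel() if x != "0"})
        if not observed:
            counted.append(".")
            continue
        # lexicographically later allele is counted (no declared reference)
        ref = observed[-1]
        counted.append(ref)
        ok = (a != "0").all(axis=1)
        codes[ok, j] = (a[ok] == ref).sum(axis=1)
    gm = GenotypeMatrix(
        subjects=subjects,
        snps=snps[["id", "chrom", "pos"]].copy(),
        codes=codes,
        metadata={
            "source": str(ped),
            "format": "plink_text",
            "counted_allele": "lexicographically-later",
            "counted_allele_per_snp": counted,
        },
    )
    return gm


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(path, trait_col: str = "trait", id_col=None) -> PhenotypeTable:
    """Read a delimited phenotype table.

    The first column (or ``id_col``) holds subject IDs and must be unique;
    ``trait_col`` is the quantitative trait. Every remaining column is a
    covariate; non-numeric covariates are expanded into k-1 indicator
    columns with the lexicographically first level as reference.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if id_col is None:
        id_col = df.columns[0]
    if trait_col not in df.columns:
        raise SchemaError(f"{path}: no trait column {trait_col!r}")
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise SchemaError(f"{path}: duplicate subject IDs: {dups}")
    trait = pd.to_numeric(df[trait_col], errors="coerce").to_numpy(dtype=float)
    cov_cols = [c for c in df.columns if c not in (id_col, trait_col)]
    cov = df[cov_cols].copy()
    if cov_cols:
        cov = pd.get_dummies(cov, drop_first=True, dtype=float)
        cov = cov[sorted(cov.columns)]
        cov = cov.astype(float)
    cov.index = pd.RangeIndex(len(df))
    return PhenotypeTable(subjects=ids.tolist(), trait=trait, covariates=cov)


# ---------------------------------------------------------------------------
# reports

REPORT_COLUMNS = [
    "snp",
    "chromosome",
    "position",
    "gene",
    "univariate_estimate",
    "univariate_p",
    "smcp_estimate",
    "smcp_loo_p",
    "lasso_estimate",
    "lasso_loo_p",
]


def write_report(report, path) -> None:
    """Write an association report as TSV plus a JSON metadata sidecar.

    ``report`` must expose a ``table`` DataFrame with the standard report
    columns and a ``metadata`` dict. SNPs absent from a model's support get
    empty cells in that model's columns.
    """
    path = Path(path)
    table = report.table.reindex(columns=REPORT_COLUMNS)
    table.to_csv(path, sep="\t", index=False, na_rep="")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump(report.metadata, fh, indent=2, default=_json_default)
    logger.info("wrote report %s (%d rows) and sidecar %s", path, len(table), sidecar)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def write_genotypes_tsv(geno: GenotypeMatrix, path, na_token: str = "NA") -> None:
    """Write a GenotypeMatrix in the TSV dialect ``read_genotypes`` accepts."""
    df = pd.DataFrame(geno.codes, index=geno.subjects, columns=geno.snps["id"])
    df = df.astype(object).where(geno.codes != MISSING, na_token)
    df.index.name = "subject"
    df.to_csv(path, sep="\t")


def write_map(geno: GenotypeMatrix, path) -> None:
    """Write the SNP map in PLINK ``.map`` layout (chrom, id, 0, pos)."""
    with open(path, "w") as fh:
        for _, row in geno.snps.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")


def write_phenotypes_tsv(pheno: PhenotypeTable, path) -> None:
    """Write a PhenotypeTable as TSV (subject, trait, covariates)."""
    df = pd.DataFrame({"subject": pheno.subjects, "trait": pheno.trait})
    for c in pheno.covariates.columns:
        df[c] = np.asarray(pheno.covariates[c])
    df.to_csv(path, sep="\t", index=False)
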