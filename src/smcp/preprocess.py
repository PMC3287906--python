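"""Covariate residualization and per-SNP genotype standardization.

The penalized fit works on a design where every genotype column is centered
and scaled over its *nonmissing* subjects so that sum(x_ij) = 0 and
sum(x_ij^2) = n_j; missing cells are set to 0 after standardization and
therefore drop out of every inner product. With this scaling the marginal
loss (1/(2 n_j)) * sum_i (y_i - x_ij b)^2 has unit curvature in b, and the
per-SNP least-squares estimate reduces to z_j = (x_j . y) / n_j.

Covariates (sex, age, smoking, population-group dummies) are removed up
front by regressing the trait on them and carrying the residuals forward as
the working response; this mirrors the usual two-stage adjustment for
confounding and population stratification in GWAS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import MISSING, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)


class CollinearityError(ValueError):
    """Covariate design is rank deficient."""


@dataclass
class StandardizedDesign:
    """Standardized genotype design plus marginal statistics.

    Attributes
    ----------
    x : ndarray, n x p
        Standardized genotype scores; missing cells are exactly 0.
    y : ndarray, length n
        Centered (covariate-residualized) working response.
    n_j : ndarray of int
        Nonmissing subject count per SNP.
    z : ndarray
        Marginal estimates z_j = (x_j . y) / n_j.
    scale_j, mean_j : ndarray
        Per-SNP scale and mean used, for back-transformation to the
        per-allele scale.
    yy_j : ndarray
        sum of y_i^2 over subjects nonmissing at SNP j (marginal null loss).
    ybar_j : ndarray
        Mean of y over subjects nonmissing at SNP j.
    observed : ndarray of bool, n x p
        Nonmissing mask.
    excluded : ndarray of bool
        Monomorphic (zero-variance) SNPs, kept out of the fit.
    snps : DataFrame
        SNP map aligned with columns.
    """

    x: np.ndarray
    y: np.ndarray
    n_j: np.ndarray
    z: np.ndarray
    scale_j: np.ndarray
    mean_j: np.ndarray
    yy_j: np.ndarray
    ybar_j: np.ndarray
    observed: np.ndarray
    excluded: np.ndarray
    snps: pd.DataFrame
    subjects: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of SNPs that participate in the fit."""
        return ~self.excluded


def residualize_trait(pheno: PhenotypeTable) -> np.ndarray:
    """OLS residuals of the trait on (intercept + covariates).

    With no covariates this is plain centering. Raises
    :class:`CollinearityError` naming the offending columns when the
    covariate design (with intercept) is rank deficient.
    """
    y = np.asarray(pheno.trait, dtype=float)
    if np.isnan(y).any():
        raise ValueError("trait contains missing values; drop those subjects first")
    cov = pheno.covariates
    if cov is None or cov.shape[1] == 0:
        return y - y.mean()
    X = sm.add_constant(np.asarray(cov, dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, list(cov.columns))
        raise CollinearityError(f"collinear covariate columns: {bad}")
    res = sm.OLS(y, X).fit()
    return np.asarray(res.resid)


def _collinear_columns(X: np.ndarray, names: list) -> list:
    """Columns lying in the span of the preceding ones (intercept first)."""
    bad = []
    for k in range(1, X.shape[1]):
        prev = X[:, :k]
        coef, *_ = np.linalg.lstsq(prev, X[:, k], rcond=None)
        resid = X[:, k] - prev @ coef
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, k])):
            bad.append(names[k - 1])
    return bad


def standardize(geno: GenotypeMatrix, y: np.ndarray) -> StandardizedDesign:
    """Standardize each genotype column over its nonmissing subjects.

    Monomorphic columns (zero variance among nonmissing subjects, or fewer
    than 2 nonmissing subjects) are flagged ``excluded`` and carry an
    all-zero column; they stay out of the fit but remain in reports with
    estimate 0.
    """
    codes = np.asarray(geno.codes)
    y = np.asarray(y, dtype=float)
    n, p = codes.shape
    if y.shape[0] != n:
        raise ValueError("response not aligned to genotype subjects")
    observed = codes != MISSING
    g = np.where(observed, codes, 0).astype(float)
    n_j = observed.sum(axis=0)
    safe_n = np.maximum(n_j, 1)
    mean_j = g.sum(axis=0) / safe_n
    dev = np.where(observed, g - mean_j, 0.0)
    ss = (dev**2).sum(axis=0)
    scale_j = np.sqrt(ss / safe_n)
    excluded = (scale_j <= 0) | (n_j < 2)
    if excluded.any():
        logger.info("excluding %d monomorphic/degenerate SNP(s)", int(excluded.sum()))
    safe_scale = np.where(excluded, 1.0, scale_j)
    x = dev / safe_scale
    x[:, excluded] = 0.0
    z = (x * y[:, None]).sum(axis=0) / safe_n
    z[excluded] = 0.0
    yy_j = (observed * (y**2)[:, None]).sum(axis=0)
    ybar_j = (observed * y[:, None]).sum(axis=0) / safe_n
    return StandardizedDesign(
        x=x,
        y=y,
        n_j=n_j,
        z=z,
        scale_j=scale_j,
        mean_j=mean_j,
        yy_j=yy_j,
        ybar_j=ybar_j,
        observed=observed,
        excluded=excluded,
        snps=geno.snps.reset_index(drop=True),
        subjects=list(geno.subjects),
    )


def align_study(geno: GenotypeMatrix, pheno: PhenotypeTable):
    """Join genotypes and phenotypes on subject ID.

    Subjects missing from either table, or with a missing trait value, are
    dropped (the count is logged). Returns ``(geno_sub, pheno_sub)`` in
    genotype row order.
    """
    pheno_idx = {s: i for i, s in enumerate(pheno.subjects)}
    keep_rows, keep_pidx = [], []
    for i, s in enumerate(geno.subjects):
        k = pheno_idx.get(s)
        if k is None or np.isnan(pheno.trait[k]):
            continue
        keep_rows.append(i)
        keep_pidx.append(k)
    dropped = geno.n - len(keep_rows)
    if dropped:
        logger.info("dropped %d subject(s) without phenotype", dropped)
    if len(keep_rows) < 2:
        raise ValueError("fewer than 2 subjects remain after phenotype join")
    geno_sub = GenotypeMatrix(
        subjects=[geno.subjects[i] for i in keep_rows],
        snps=geno.snps.reset_index(drop=True),
        codes=geno.codes[keep_rows, :],
        metadata=dict(geno.metadata),
    )
    cov = pheno.covariates.iloc[keep_pidx].reset_index(drop=True) if pheno.covariates.shape[1] else pheno.covariates.iloc[:0]
    pheno_sub = PhenotypeTable(
        subjects=[pheno.subjects[k] for k in keep_pidx],
        trait=pheno.trait[keep_pidx],
        covariates=cov,
    )
    return geno_sub, pheno_sub
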