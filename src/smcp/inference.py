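"""Significance for selected SNPs and method evaluation.

Selected SNPs from a penalized fit get a leave-one-out (LOO) p-value: the
model is refit at the same tuning with that SNP's coefficient pinned to 0,
and the statistic D = n * log(RSS_without / RSS_with) — joint residual sums
of squares over each model's support — is referred to a chi-square with 1
degree of freedom. The refit keeps tau fixed (no re-selection), so the
p-value conditions on the chosen tuning and is approximate rather than
selection-adjusted.

Single-SNP association uses a per-SNP simple linear regression Wald test,
with Benjamini-Hochberg control of the false discovery rate across SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import solver
from .penalties import ld_weights
from .preprocess import StandardizedDesign, residualize_trait, standardize
from .solver import FitResult

logger = logging.getLogger(__name__)


@dataclass
class AssociationReport:
    """Per-SNP association table plus fit metadata.

    ``table`` carries one row per SNP with univariate, SMCP and lasso
    estimates and p-values; a model's cells are empty (NaN) for SNPs
    outside its support. ``metadata`` records tuning values and seeds.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)


@dataclass
class EvaluationSummary:
    """True/false positive counts per replicate and method, with summaries."""

    counts: pd.DataFrame  # columns: replicate, method, tp, fp, support_size
    summary: pd.DataFrame  # index: method; columns: tp_mean, tp_sd, fp_mean, fp_sd


def _joint_rss(beta: np.ndarray, support: np.ndarray, design: StandardizedDesign) -> float:
    resid = design.y.copy()
    if support.size:
        resid -= design.x[:, support] @ beta[support]
    return float(resid @ resid)


def loo_pvalue(
    j: int,
    fit_result: FitResult,
    design: StandardizedDesign,
    tol: float = solver.DEFAULT_TOL,
    max_sweeps: int = solver.DEFAULT_MAX_SWEEPS,
) -> float:
    """LOO p-value for a SNP in the fitted support.

    Raises ValueError when j is not selected. D is clipped at 0 so the
    p-value never exceeds 1 by round-off.
    """
    if j not in fit_result.support:
        raise ValueError(f"SNP index {j} is not in the fitted support")
    active = design.active.copy()
    active[j] = False
    init = fit_result.beta.copy()
    init[j] = 0.0
    refit = solver._fit(design, fit_result.config, active, init, tol, max_sweeps)
    rss_with = _joint_rss(fit_result.beta, fit_result.support, design)
    rss_without = _joint_rss(refit.beta, refit.support, design)
    if rss_with <= 0:
        return 0.0
    d = design.n * np.log(rss_without / rss_with)
    d = max(d, 0.0)
    return float(stats.chi2.sf(d, df=1))


def loo_pvalues(fit_result: FitResult, design: StandardizedDesign, **kw) -> dict:
    """LOO p-values for every SNP in the support, keyed by SNP index."""
    return {int(j): loo_pvalue(int(j), fit_result, design, **kw) for j in fit_result.support}


def univariate_scan(design: StandardizedDesign) -> pd.DataFrame:
    """Per-SNP simple linear regression of y on the per-allele genotype.

    Closed-form two-variable OLS over each SNP's nonmissing subjects.
    Returns a DataFrame with per-allele ``estimate``, standardized-scale
    ``estimate_std`` (= z_j), ``t``, ``p`` and a ``degenerate`` flag;
    monomorphic SNPs get estimate 0 and p = 1.
    """
    n_j = design.n_j.astype(float)
    z = design.z
    # subset-centered total sum of squares of y at each SNP
    syy = design.yy_j - n_j * design.ybar_j**2
    rss = np.maximum(syy - n_j * z**2, 0.0)
    df = n_j - 2
    ok = (~design.excluded) & (df > 0)
    se2 = np.full(design.p, np.nan)
    se2[ok] = rss[ok] / (df[ok] * n_j[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(ok & (se2 > 0), z / np.sqrt(se2), np.inf)
    pvals = np.ones(design.p)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df[ok])
    pvals = np.clip(pvals, 0.0, 1.0)
    safe_scale = np.where(design.scale_j > 0, design.scale_j, 1.0)
    est = np.where(design.excluded, 0.0, z / safe_scale)
    return pd.DataFrame(
        {
            "estimate": est,
            "estimate_std": z,
            "t": np.where(ok, tstat, 0.0),
            "p": np.where(design.excluded, 1.0, pvals),
            "degenerate": design.excluded,
        }
    )


def bh_adjust(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up at FDR level q.

    Returns ``(rejected_indices, adjusted_pvalues)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return np.flatnonzero(reject), p_adj


def _prepare_design(study) -> StandardizedDesign:
    y = residualize_trait(study.pheno)
    return standardize(study.geno, y)


def evaluate_replicates(
    replicates,
    truth,
    methods=("smcp", "lasso", "univariate_bh"),
    eta: float = solver.DEFAULT_ETA,
    gamma: float = solver.DEFAULT_GAMMA,
    q: float = 0.05,
    n_tau: int = 100,
    tol: float = solver.DEFAULT_TOL,
    max_sweeps: int = solver.DEFAULT_MAX_SWEEPS,
) -> EvaluationSummary:
    """True/false positives per replicate for SMCP, lasso and single-SNP BH.

    ``replicates`` is a sequence of simulated studies (objects with
    ``geno``/``pheno``); ``truth`` the causal SNP index set shared by all
    replicates. Selected sets are the EBIC-tuned supports for the penalized
    methods and the BH rejection set for the univariate scan.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    truth = set(int(t) for t in truth)
    rows = []
    for r, study in enumerate(replicates):
        design = _prepare_design(study)
        selections = {}
        if "smcp" in methods:
            sigma = ld_weights(design)
            path = solver.fit_path(
                design, eta=eta, gamma=gamma, sigma=sigma,
                tol=tol, max_sweeps=max_sweeps, n_tau=n_tau,
            )
            selections["smcp"] = set(path.selected_fit.support.tolist())
        if "lasso" in methods:
            path = solver.fit_lasso_path(
                design, tol=tol, max_sweeps=max_sweeps, n_tau=n_tau
            )
            selections["lasso"] = set(path.selected_fit.support.tolist())
        if "univariate_bh" in methods:
            scan = univariate_scan(design)
            rejected, _ = bh_adjust(scan["p"].to_numpy(), q=q)
            selections["univariate_bh"] = set(rejected.tolist())
        for method, sel in selections.items():
            tp = len(sel & truth)
            fp = len(sel - truth)
            rows.append(
                {"replicate": r, "method": method, "tp": tp, "fp": fp,
                 "support_size": len(sel)}
            )
    counts = pd.DataFrame(rows)
    summary = (
        counts.groupby("method")
        .agg(
            tp_mean=("tp", "mean"),
            tp_sd=("tp", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            fp_mean=("fp", "mean"),
            fp_sd=("fp", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        )
    )
    return EvaluationSummary(counts=counts, summary=summary)


def build_report(
    design: StandardizedDesign,
    scan: pd.DataFrame,
    smcp_fit: FitResult | None = None,
    smcp_loo: dict | None = None,
    lasso_fit: FitResult | None = None,
    lasso_loo: dict | None = None,
    metadata: dict | None = None,
    selected_only: bool = False,
) -> AssociationReport:
    """Assemble the per-SNP association table.

    With ``selected_only`` the table is restricted to SNPs in either
    penalized support (the layout used for reporting hits); otherwise all
    SNPs are included.
    """
    p = design.p
    snps = design.snps
    tab = pd.DataFrame(
        {
            "snp": snps["id"].to_numpy(),
            "chromosome": snps["chrom"].to_numpy(),
            "position": snps["pos"].to_numpy(),
            "gene": snps["gene"].to_numpy() if "gene" in snps else [""] * p,
            "univariate_estimate": scan["estimate"].to_numpy(),
            "univariate_p": scan["p"].to_numpy(),
            "smcp_estimate": np.nan,
            "smcp_loo_p": np.nan,
            "lasso_estimate": np.nan,
            "lasso_loo_p": np.nan,
        }
    )
    for fit_result, loo, prefix in (
        (smcp_fit, smcp_loo, "smcp"),
        (lasso_fit, lasso_loo, "lasso"),
    ):
        if fit_result is None:
            continue
        S = fit_result.support
        tab.loc[S, f"{prefix}_estimate"] = fit_result.beta_raw[S]
        if loo:
            for j, pv in loo.items():
                tab.loc[j, f"{prefix}_loo_p"] = pv
    if selected_only:
        keep = tab["smcp_estimate"].notna() | tab["lasso_estimate"].notna()
        tab = tab.loc[keep].reset_index(drop=True)
    return AssociationReport(table=tab, metadata=metadata or {})
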