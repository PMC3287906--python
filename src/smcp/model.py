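"""Model/Results surface tying the pipeline together.

``SMCP`` is built from a genotype matrix and a phenotype table; construction
joins subjects, residualizes the trait on the covariates, standardizes the
genotype columns and computes the adjacency (LD) weights. ``fit`` runs the
EBIC-tuned penalized path and returns an :class:`SMCPResults` carrying the
selected model, per-SNP estimates, leave-one-out p-values and a summary
table; ``fit_lasso`` does the same for the soft-threshold comparator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import inference, solver
from .io import GenotypeMatrix, PhenotypeTable
from .penalties import ld_weights
from .preprocess import StandardizedDesign, align_study, residualize_trait, standardize


class SMCP:
    """Smoothed-MCP penalized GWAS model for a quantitative trait.

    Parameters
    ----------
    geno, pheno
        Genotypes and phenotypes; subjects are joined by ID and the trait
        is residualized on the covariates before fitting.
    eta
        Fraction of the penalty level devoted to LD smoothing (default
        0.1; 0 gives a pure MCP fit).
    gamma
        MCP concavity (default 3; very large values approach the lasso).
    """

    def __init__(
        self,
        geno: GenotypeMatrix,
        pheno: PhenotypeTable,
        eta: float = solver.DEFAULT_ETA,
        gamma: float = solver.DEFAULT_GAMMA,
    ):
        geno, pheno = align_study(geno, pheno)
        self.geno = geno
        self.pheno = pheno
        self.eta = float(eta)
        self.gamma = float(gamma)
        y = residualize_trait(pheno)
        self.design: StandardizedDesign = standardize(geno, y)
        self.sigma = ld_weights(self.design) if self.design.p >= 2 else np.zeros(0)

    @classmethod
    def from_study(cls, study, **kw) -> "SMCP":
        """Build from a :class:`~smcp.simulate.SimulatedStudy`."""
        return cls(study.geno, study.pheno, **kw)

    @classmethod
    def from_files(cls, genotype_path, phenotype_path, format="tsv", map_path=None, **kw):
        from .io import read_genotypes, read_phenotypes

        geno = read_genotypes(genotype_path, format=format, map_path=map_path)
        pheno = read_phenotypes(phenotype_path)
        return cls(geno, pheno, **kw)

    def fit(
        self,
        tau_grid=None,
        n_tau: int = 100,
        tol: float = solver.DEFAULT_TOL,
        max_sweeps: int = solver.DEFAULT_MAX_SWEEPS,
        ebic_gamma: float | None = None,
        compute_loo: bool = True,
    ) -> "SMCPResults":
        """EBIC-tuned SMCP path; returns the results object."""
        path = solver.fit_path(
            self.design,
            eta=self.eta,
            tau_grid=tau_grid,
            gamma=self.gamma,
            sigma=self.sigma,
            tol=tol,
            max_sweeps=max_sweeps,
            n_tau=n_tau,
            ebic_gamma=ebic_gamma,
        )
        return SMCPResults(self, path, method="smcp", compute_loo=compute_loo)

    def fit_lasso(
        self,
        tau_grid=None,
        n_tau: int = 100,
        tol: float = solver.DEFAULT_TOL,
        max_sweeps: int = solver.DEFAULT_MAX_SWEEPS,
        ebic_gamma: float | None = None,
        compute_loo: bool = True,
    ) -> "SMCPResults":
        """EBIC-tuned lasso comparator on the same design."""
        path = solver.fit_lasso_path(
            self.design,
            tau_grid=tau_grid,
            tol=tol,
            max_sweeps=max_sweeps,
            n_tau=n_tau,
            ebic_gamma=ebic_gamma,
        )
        return SMCPResults(self, path, method="lasso", compute_loo=compute_loo)

    def univariate_scan(self) -> pd.DataFrame:
        """Single-SNP simple-regression scan on the working response."""
        return inference.univariate_scan(self.design)


class SMCPResults:
    """Fitted penalized GWAS model at the EBIC-selected tuning point."""

    def __init__(self, model: SMCP, path: solver.TuningPath, method: str, compute_loo=True):
        self.model = model
        self.path = path
        self.method = method
        self.fit_result = path.selected_fit
        self.tau = path.selected_tau
        self.ebic = float(path.ebic[path.selected_index])
        self._loo = (
            inference.loo_pvalues(self.fit_result, model.design) if compute_loo else None
        )

    @property
    def support(self) -> np.ndarray:
        """Indices of selected SNPs (exactly the nonzero coefficients)."""
        return self.fit_result.support

    @property
    def params(self) -> np.ndarray:
        """Per-allele effect estimates (back-transformed scale)."""
        return self.fit_result.beta_raw

    @property
    def params_standardized(self) -> np.ndarray:
        return self.fit_result.beta

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def loo_pvalues(self) -> dict:
        """Leave-one-out p-values for the selected SNPs (index -> p)."""
        if self._loo is None:
            self._loo = inference.loo_pvalues(self.fit_result, self.model.design)
        return self._loo

    def selected_table(self) -> pd.DataFrame:
        """Selected SNPs with per-allele estimates and LOO p-values."""
        snps = self.model.design.snps
        loo = self.loo_pvalues()
        S = self.support
        return pd.DataFrame(
            {
                "snp": snps["id"].iloc[S].to_numpy(),
                "chromosome": snps["chrom"].iloc[S].to_numpy(),
                "position": snps["pos"].iloc[S].to_numpy(),
                "estimate": self.fit_result.beta_raw[S],
                "estimate_std": self.fit_result.beta[S],
                "loo_p": [loo[int(j)] for j in S],
            }
        )

    def to_report(self, other: "SMCPResults | None" = None, selected_only=True):
        """AssociationReport combining univariate, this fit and optionally
        a comparator fit (typically SMCP + lasso)."""
        scan = self.model.univariate_scan()
        kwargs = {}
        for res in (self, other):
            if res is None:
                continue
            key = "smcp" if res.method == "smcp" else "lasso"
            kwargs[f"{key}_fit"] = res.fit_result
            kwargs[f"{key}_loo"] = res.loo_pvalues()
        meta = {
            "eta": self.model.eta,
            "gamma": self.model.gamma,
            "selected_tau": {self.method: self.tau},
            "ebic": {self.method: self.ebic},
            "converged": {self.method: self.converged},
            "n": self.model.design.n,
            "p": self.model.design.p,
        }
        if other is not None:
            meta["selected_tau"][other.method] = other.tau
            meta["ebic"][other.method] = other.ebic
            meta["converged"][other.method] = other.converged
        return inference.build_report(
            self.model.design, scan, metadata=meta, selected_only=selected_only, **kwargs
        )

    def summary(self) -> str:
        """Human-readable summary of the selected model."""
        d = self.model.design
        lines = [
            f"{'SMCP' if self.method == 'smcp' else 'LASSO'} penalized GWAS fit",
            "=" * 40,
            f"subjects: {d.n}    SNPs: {d.p} ({int(d.excluded.sum())} excluded)",
            f"eta = {self.model.eta:g}   gamma = {self.fit_result.config.gamma:g}",
            f"selected tau = {self.tau:.4g} (EBIC = {self.ebic:.2f})",
            f"support size = {self.support.size}   converged = {self.converged}",
            "",
        ]
        tab = self.selected_table()
        if len(tab):
            lines.append(tab.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        else:
            lines.append("(no SNPs selected)")
        return "\n".join(lines)
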