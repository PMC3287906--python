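"""Shared fixtures: small simulated studies and standardized designs."""

import numpy as np
import pytest

from smcp.penalties import ld_weights
from smcp.preprocess import residualize_trait, standardize
from smcp.simulate import CausalBlock, CovariateSpec, SimConfig, simulate_study


def make_design(
    n=200,
    p=30,
    rho=0.5,
    seed=0,
    maf_range=(0.1, 0.4),
    causal_blocks=(),
    noise_sd=1.0,
    missing_rate=0.0,
    covariates=False,
    n_chrom=1,
):
    """Simulate a study and return its StandardizedDesign (plus the study)."""
    cfg = SimConfig(
        n=n,
        p=p,
        rho=rho,
        maf_range=maf_range,
        causal_blocks=list(causal_blocks),
        covariate_spec=CovariateSpec(enabled=covariates),
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        n_chrom=n_chrom,
        seed=seed,
    )
    study = simulate_study(cfg)
    y = residualize_trait(study.pheno)
    return standardize(study.geno, y), study


@pytest.fixture
def small_design():
    design, _ = make_design(n=150, p=20, rho=0.4, seed=11)
    return design


@pytest.fixture
def causal_design():
    """Design with one 3-SNP causal block (indices 8-10) and strong LD."""
    design, study = make_design(
        n=300,
        p=40,
        rho=0.7,
        seed=5,
        causal_blocks=[CausalBlock(start=8, effects=(0.8, 0.9, 0.7), maf=0.2)],
        noise_sd=1.0,
    )
    return design, study


@pytest.fixture
def sigma_of():
    return ld_weights
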