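"""MCP sparsity penalty, LD-weighted smoothing penalty, and the objective.

The full objective minimized by the solver is

    sum_j (1/(2 n_j)) sum_i (y_i - x_ij b_j)^2        (marginal loss)
    + sum_j rho1(|b_j|; lambda1, gamma)               (MCP)
    + (lambda2/2) sum_j sigma_j (|b_j| - |b_{j+1}|)^2 (LD smoothing)

where sigma_j is the absolute Pearson correlation of adjacent genotype
columns (0 across chromosome boundaries).  The smoothing term acts on
*absolute* effects because the sign of b_j depends on the arbitrary choice
of which allele is counted; a fused-lasso penalty on raw differences would
inherit that ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import StandardizedDesign


@dataclass
class PenaltyConfig:
    """Tuning state for one SMCP fit.

    ``lambda1``/``lambda2`` derive from ``(eta, tau)`` via
    ``solver.reparameterize``: lambda1 = (1 - eta) * tau is the MCP level,
    lambda2 = eta * tau the smoothing level. ``sigma`` holds the p-1
    adjacency weights.
    """

    lambda1: float
    lambda2: float
    gamma: float
    sigma: np.ndarray
    eta: float | None = None
    tau: float | None = None

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty levels must be nonnegative")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1 (gamma = 1 is the hard-threshold limit)")
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any((self.sigma < 0) | (self.sigma > 1)):
            raise ValueError("adjacency weights must lie in [0, 1]")


def mcp_value(t, lambda1: float, gamma: float):
    """MCP penalty rho1(|t|): lambda1*|t| - t^2/(2*gamma) up to |t| =
    gamma*lambda1, then constant gamma*lambda1^2/2.

    Vectorized over ``t``. gamma must be >= 1; gamma -> inf recovers the
    soft-threshold (lasso) penalty lambda1*|t|, gamma = 1 the hard
    threshold.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    if lambda1 < 0:
        raise ValueError("lambda1 must be >= 0")
    a = np.abs(np.asarray(t, dtype=float))
    inner = lambda1 * a - a**2 / (2.0 * gamma)
    plateau = 0.5 * gamma * lambda1**2
    out = np.where(a <= gamma * lambda1, inner, plateau)
    return out if out.ndim else float(out)


def mcp_derivative(t, lambda1: float, gamma: float):
    """d/dt of :func:`mcp_value` where differentiable.

    Equals (lambda1 - |t|/gamma)_+ * sign(t); at t = 0 the subdifferential
    bound lambda1 is returned.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    t = np.asarray(t, dtype=float)
    mag = np.maximum(lambda1 - np.abs(t) / gamma, 0.0)
    out = np.where(t == 0, lambda1, mag * np.sign(t))
    return out if out.ndim else float(out)


def ld_weights(design: StandardizedDesign, snps=None) -> np.ndarray:
    """Adjacency weights sigma_j = |Pearson r| of genotype columns j, j+1.

    Correlations use subjects nonmissing at both SNPs; the weight is 0
    across chromosome boundaries, when fewer than 3 shared nonmissing
    subjects exist, or when either column is degenerate on the shared set.
    """
    snps = design.snps if snps is None else snps
    p = design.p
    if p < 2:
        raise ValueError("need at least 2 SNPs for adjacency weights")
    chrom = np.asarray(snps["chrom"], dtype=object)
    sigma = np.zeros(p - 1)
    x = design.x
    obs = design.observed
    all_observed = obs.all()
    for j in range(p - 1):
        if str(chrom[j]) != str(chrom[j + 1]):
            continue
        if design.excluded[j] or design.excluded[j + 1]:
            continue
        if all_observed:
            a, b = x[:, j], x[:, j + 1]
        else:
            shared = obs[:, j] & obs[:, j + 1]
            if shared.sum() < 3:
                continue
            a, b = x[shared, j], x[shared, j + 1]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom <= 0:
            continue
        sigma[j] = min(abs(float(a @ b) / denom), 1.0)
    return sigma


def smoothing_value(beta: np.ndarray, config: PenaltyConfig) -> float:
    """(lambda2/2) * sum_j sigma_j (|b_j| - |b_{j+1}|)^2; sign-invariant."""
    beta = np.asarray(beta, dtype=float)
    if config.sigma.shape[0] != beta.shape[0] - 1:
        raise ValueError("sigma must have length p - 1")
    if config.lambda2 == 0:
        return 0.0
    d = np.abs(beta[:-1]) - np.abs(beta[1:])
    return float(0.5 * config.lambda2 * np.sum(config.sigma * d**2))


def marginal_loss(beta: np.ndarray, design: StandardizedDesign) -> float:
    """Sum over SNPs of the per-SNP squared-error loss (1/(2 n_j)) * RSS_j.

    Expands to yy_j/(2 n_j) - z_j b_j + b_j^2/2 under the standardization
    sum(x^2) = n_j; excluded SNPs contribute their null loss.
    """
    beta = np.asarray(beta, dtype=float)
    safe_n = np.maximum(design.n_j, 1)
    const = float(np.sum(design.yy_j / (2.0 * safe_n)))
    act = design.active
    b = beta[act]
    return const + float(np.sum(-design.z[act] * b + 0.5 * b**2))


def objective(beta: np.ndarray, design: StandardizedDesign, config: PenaltyConfig) -> float:
    """Full SMCP objective: marginal loss + MCP + smoothing."""
    beta = np.asarray(beta, dtype=float)
    pen1 = float(np.sum(mcp_value(beta[design.active], config.lambda1, config.gamma)))
    return marginal_loss(beta, design) + pen1 + smoothing_value(beta, config)
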