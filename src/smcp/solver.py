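"""Coordinate descent over the SMCP objective and the EBIC tuning path.

The objective is nonconvex (MCP), so coordinate descent delivers a
stationary point, not a certified global optimum; warm starts down a
decreasing tau grid are the standard mitigation. The lasso comparator uses
the same machinery with gamma effectively infinite and no smoothing, in
which case each coordinate update is plain soft-thresholding of z_j and
the problem is separable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from ._cd import cd_sweep, update_one
from .penalties import PenaltyConfig, objective
from .preprocess import StandardizedDesign

logger = logging.getLogger(__name__)

#: gamma used to emulate the soft-threshold (lasso) limit of the MCP
LASSO_GAMMA = 1e12

DEFAULT_ETA = 0.1
DEFAULT_GAMMA = 3.0
DEFAULT_TOL = 1e-6
DEFAULT_MAX_SWEEPS = 1000


@dataclass
class FitResult:
    """Solution of one penalized fit at a fixed tuning point."""

    beta: np.ndarray
    beta_raw: np.ndarray
    support: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    config: PenaltyConfig
    sweeps: int


@dataclass
class TuningPath:
    """Fits along a decreasing tau grid with per-fit EBIC."""

    tau_grid: np.ndarray
    fits: list
    ebic: np.ndarray
    selected_index: int

    @property
    def selected_tau(self) -> float:
        return float(self.tau_grid[self.selected_index])

    @property
    def selected_fit(self) -> FitResult:
        return self.fits[self.selected_index]


def reparameterize(eta: float, tau: float) -> tuple:
    """Map (eta, tau) to (lambda1, lambda2) = ((1-eta)*tau, eta*tau).

    eta is the fraction of the total penalty level devoted to LD
    smoothing; eta = 0 recovers a pure MCP fit.
    """
    if not 0.0 <= eta < 1.0:
        raise ValueError("eta must lie in [0, 1)")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return (1.0 - eta) * tau, eta * tau


def coordinate_update(
    j: int, beta: np.ndarray, design: StandardizedDesign, config: PenaltyConfig
) -> float:
    """Exact minimizer of the 1-D objective in coordinate j, neighbors fixed."""
    p = design.p
    s_left = float(config.sigma[j - 1]) if j > 0 else 0.0
    b_left = float(beta[j - 1]) if j > 0 else 0.0
    s_right = float(config.sigma[j]) if j < p - 1 else 0.0
    b_right = float(beta[j + 1]) if j < p - 1 else 0.0
    return float(
        update_one(
            float(design.z[j]),
            b_left,
            b_right,
            s_left,
            s_right,
            float(config.lambda1),
            float(config.lambda2),
            float(config.gamma),
        )
    )


def fit(
    design: StandardizedDesign,
    config: PenaltyConfig,
    init: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
) -> FitResult:
    """Cyclic coordinate descent until max coefficient change < tol.

    Deterministic given ``init`` (default all-zero) and the fixed
    ascending sweep order. ``active`` coordinates exclude monomorphic
    SNPs, whose coefficients stay 0.
    """
    return _fit(design, config, design.active, init, tol, max_sweeps)


def _fit(design, config, active, init, tol, max_sweeps) -> FitResult:
    p = design.p
    beta = np.zeros(p) if init is None else np.array(init, dtype=float)
    beta[~active] = 0.0
    z = np.ascontiguousarray(design.z, dtype=float)
    sigma = np.ascontiguousarray(config.sigma, dtype=float)
    act = np.ascontiguousarray(active, dtype=np.bool_)
    trace = []
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        maxdiff = cd_sweep(
            beta, z, sigma, act,
            float(config.lambda1), float(config.lambda2), float(config.gamma),
        )
        trace.append(objective(beta, design, config))
        if maxdiff < tol:
            converged = True
            break
    if not converged:
        logger.warning("coordinate descent did not converge in %d sweeps", max_sweeps)
    support = np.flatnonzero(beta != 0.0)
    safe_scale = np.where(design.scale_j > 0, design.scale_j, 1.0)
    return FitResult(
        beta=beta,
        beta_raw=beta / safe_scale,
        support=support,
        objective_trace=np.asarray(trace),
        converged=converged,
        config=config,
        sweeps=sweeps,
    )


def ebic(fit_result: FitResult, design: StandardizedDesign, ebic_gamma: float | None = None) -> float:
    """Extended BIC of a fitted support.

    EBIC = n*log(RSS/n) + k*log(n) + 2*g*log(C(p, k)) with k the support
    size, p the number of SNPs eligible for selection, and RSS the joint
    least-squares residual sum of squares of y on the selected columns
    (the support is scored, not the penalized coefficient values, so the
    criterion compares candidate models rather than shrinkage levels).
    The default g = 1 - log(n)/(2*log(p)), clipped to [0, 1], is the usual
    consistency choice for p growing polynomially in n. Returns +inf for
    k >= n.
    """
    n = design.n
    p_eff = int(design.active.sum())
    k = int(fit_result.support.size)
    if k >= n:
        return np.inf
    if ebic_gamma is None:
        ebic_gamma = default_ebic_gamma(n, p_eff)
    if k:
        S = fit_result.support
        coef, *_ = np.linalg.lstsq(design.x[:, S], design.y, rcond=None)
        resid = design.y - design.x[:, S] @ coef
    else:
        resid = design.y
    rss = float(resid @ resid)
    if rss <= 0:
        return -np.inf
    comb = gammaln(p_eff + 1) - gammaln(k + 1) - gammaln(p_eff - k + 1)
    return float(n * np.log(rss / n) + k * np.log(n) + 2.0 * ebic_gamma * comb)


def default_ebic_gamma(n: int, p: int) -> float:
    if p <= 1:
        return 1.0
    return float(np.clip(1.0 - np.log(n) / (2.0 * np.log(p)), 0.0, 1.0))


def make_tau_grid(design: StandardizedDesign, eta: float, n_tau: int = 100) -> np.ndarray:
    """Decreasing log-spaced tau grid from tau_max down to 0.01*tau_max.

    tau_max is the smallest tau at which the fit from zero stays empty:
    lambda1 = (1-eta)*tau >= max_j |z_j|.
    """
    zmax = float(np.max(np.abs(design.z[design.active]))) if design.active.any() else 0.0
    if zmax <= 0:
        zmax = 1.0
    tau_max = zmax / (1.0 - eta) * (1.0 + 1e-10)
    return np.geomspace(tau_max, 0.01 * tau_max, n_tau)


def fit_path(
    design: StandardizedDesign,
    eta: float = DEFAULT_ETA,
    tau_grid: np.ndarray | None = None,
    gamma: float = DEFAULT_GAMMA,
    sigma: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    n_tau: int = 100,
    ebic_gamma: float | None = None,
    max_support: int | None = None,
) -> TuningPath:
    """Warm-started SMCP path over a decreasing tau grid, tuned by EBIC.

    ``sigma`` defaults to all-zero adjacency weights when eta = 0 (they are
    then irrelevant) and must be supplied otherwise. The selected tau is
    the EBIC argmin; ties break toward the larger tau (sparser model).

    The path stops early once the support exceeds ``max_support`` (default
    n/2): EBIC is meaningless as k approaches n (the refit RSS collapses),
    and such models are never selected anyway.
    """
    if sigma is None:
        if eta > 0:
            raise ValueError("sigma (adjacency weights) required when eta > 0")
        sigma = np.zeros(max(design.p - 1, 0))
    if tau_grid is None:
        tau_grid = make_tau_grid(design, eta, n_tau)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size > 1 and np.any(np.diff(tau_grid) >= 0):
        raise ValueError("tau_grid must be strictly decreasing")
    if max_support is None:
        max_support = max(design.n // 2, 1)
    fits, crit, taus = [], [], []
    beta = None
    prev_support = 0
    for t in tau_grid:
        lam1, lam2 = reparameterize(eta, float(t))
        config = PenaltyConfig(
            lambda1=lam1, lambda2=lam2, gamma=gamma, sigma=sigma, eta=eta, tau=float(t)
        )
        fr = fit(design, config, init=beta, tol=tol, max_sweeps=max_sweeps)
        beta = fr.beta
        if fr.support.size > prev_support + max(20, design.p // 10):
            logger.debug("support jumped from %d to %d at tau=%.4g",
                         prev_support, fr.support.size, t)
        prev_support = fr.support.size
        fits.append(fr)
        taus.append(float(t))
        if fr.support.size > max_support:
            crit.append(np.inf)
            logger.debug("path stopped at tau=%.4g: support %d > %d",
                         t, fr.support.size, max_support)
            break
        crit.append(ebic(fr, design, ebic_gamma))
    crit = np.asarray(crit)
    selected = int(np.argmin(crit))  # first occurrence = largest tau on ties
    return TuningPath(
        tau_grid=np.asarray(taus), fits=fits, ebic=crit, selected_index=selected
    )


def fit_lasso_path(
    design: StandardizedDesign,
    tau_grid: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    n_tau: int = 100,
    ebic_gamma: float | None = None,
) -> TuningPath:
    """Lasso comparator: soft-threshold limit (gamma -> inf), no smoothing."""
    return fit_path(
        design,
        eta=0.0,
        tau_grid=tau_grid,
        gamma=LASSO_GAMMA,
        sigma=np.zeros(max(design.p - 1, 0)),
        tol=tol,
        max_sweeps=max_sweeps,
        n_tau=n_tau,
        ebic_gamma=ebic_gamma,
    )


def mcp_threshold(z, lambda1: float, gamma: float):
    """Analytic one-SNP MCP estimate (the separable, no-smoothing solution).

    soft(z, lambda1)/(1 - 1/gamma) for |z| <= gamma*lambda1, else z.
    """
    z = np.asarray(z, dtype=float)
    soft = np.sign(z) * np.maximum(np.abs(z) - lambda1, 0.0)
    if np.isinf(gamma):
        inner = soft
    else:
        inner = soft / (1.0 - 1.0 / gamma) if gamma > 1 else np.where(np.abs(z) > lambda1, z, 0.0)
    out = np.where(np.abs(z) <= gamma * lambda1, inner, z)
    return out if out.ndim else float(out)
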