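"""Numba coordinate-descent kernels.

Because the loss is marginal (per-SNP), a coordinate update never touches a
residual vector: the 1-D problem for coordinate j depends only on z_j, the
two neighboring coefficients, and the adjacency weights. Writing u = |b|
with optimal sign s = sign(z_j), the 1-D objective (up to a constant) is

    f(u) = 0.5*(1 + w)*u^2 - a*u + rho1(u; lambda1, gamma),   u >= 0,

with w = lambda2*(sigma_L + sigma_R) and
a = |z_j| + lambda2*(sigma_L*|b_L| + sigma_R*|b_R|).

The exact global minimizer is found by evaluating f at the stationary
points of its two MCP regimes (u <= gamma*lambda1, u > gamma*lambda1) plus
the regime boundary and 0. When the inner-regime curvature
c1 = 1 + w - 1/gamma is nonpositive (possible only at gamma = 1 with no
smoothing) the inner branch is linear/concave and its minimum lies at an
endpoint, which the same candidate set covers, so the update stays exact.
"""

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def update_one(zj, b_left, b_right, s_left, s_right, lambda1, lambda2, gamma):
    """Exact minimizer of the 1-D SMCP coordinate objective."""
    w = lambda2 * (s_left + s_right)
    a = abs(zj) + lambda2 * (s_left * abs(b_left) + s_right * abs(b_right))
    s = 1.0 if zj >= 0.0 else -1.0
    thr = gamma * lambda1
    c2 = 1.0 + w
    c1 = c2 - 1.0 / gamma

    best_u = 0.0
    best_f = 0.0  # f(0) = 0
    # inner-regime stationary point, clamped to [0, thr]
    if c1 > 1e-12 and a > lambda1:
        u = (a - lambda1) / c1
        if u > thr:
            u = thr
        f = 0.5 * c2 * u * u - a * u + lambda1 * u - u * u / (2.0 * gamma)
        if f < best_f:
            best_f = f
            best_u = u
    # regime boundary (covers the degenerate c1 <= 0 case exactly)
    if thr > 0.0:
        u = thr
        f = 0.5 * c2 * u * u - a * u + 0.5 * gamma * lambda1 * lambda1
        if f < best_f:
            best_f = f
            best_u = u
    # outer (flat-penalty) regime stationary point
    u = a / c2
    if u >= thr:
        f = 0.5 * c2 * u * u - a * u + 0.5 * gamma * lambda1 * lambda1
        if f < best_f:
            best_f = f
            best_u = u
    return s * best_u


@njit(cache=True)
def cd_sweep(beta, z, sigma, active, lambda1, lambda2, gamma):
    """One cyclic ascending sweep in place; returns max |change|."""
    p = beta.shape[0]
    maxdiff = 0.0
    for j in range(p):
        if not active[j]:
            continue
        if j > 0:
            s_left = sigma[j - 1]
            b_left = beta[j - 1]
        else:
            s_left = 0.0
            b_left = 0.0
        if j < p - 1:
            s_right = sigma[j]
            b_right = beta[j + 1]
        else:
            s_right = 0.0
            b_right = 0.0
        new = update_one(z[j], b_left, b_right, s_left, s_right, lambda1, lambda2, gamma)
        d = abs(new - beta[j])
        if d > maxdiff:
            maxdiff = d
        beta[j] = new
    return maxdiff
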