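"""Coordinate descent, tuning path, EBIC, and their analytic oracles."""

import numpy as np
import pytest

from smcp import solver
from smcp.penalties import PenaltyConfig, ld_weights, objective
from smcp.solver import (
    coordinate_update,
    ebic,
    fit,
    fit_lasso_path,
    fit_path,
    make_tau_grid,
    mcp_threshold,
    reparameterize,
)
from .conftest import make_design


def _config(d, lam1, lam2=0.0, gamma=3.0, sigma=None):
    sigma = np.zeros(d.p - 1) if sigma is None else sigma
    return PenaltyConfig(lambda1=lam1, lambda2=lam2, gamma=gamma, sigma=sigma)


class TestReparameterize:
    def test_no_smoothing(self):
        assert reparameterize(0.0, 1.0) == (1.0, 0.0)

    def test_unpenalized(self):
        assert reparameterize(0.3, 0.0) == (0.0, 0.0)

    def test_ten_percent_smoothing_split(self):
        lam1, lam2 = reparameterize(0.1, 1.655)
        assert lam1 == pytest.approx(1.4895)
        assert lam2 == pytest.approx(0.1655)

    @pytest.mark.parametrize("eta", [1.0, 1.5, -0.1])
    def test_invalid_eta(self, eta):
        with pytest.raises(ValueError):
            reparameterize(eta, 1.0)


def _grid_minimize(zj, bl, br, sl, sr, lam1, lam2, gamma):
    """Dense grid-search oracle for the 1-D coordinate objective."""
    lim = 3 * abs(zj) + 3
    b = np.arange(-lim, lim, 1e-4)
    loss = 0.5 * b**2 - zj * b
    a = np.abs(b)
    pen1 = np.where(a <= gamma * lam1, lam1 * a - a**2 / (2 * gamma), gamma * lam1**2 / 2)
    pen2 = 0.5 * lam2 * (sl * (abs(bl) - a) ** 2 + sr * (a - abs(br)) ** 2)
    f = loss + pen1 + pen2
    return b[np.argmin(f)]


class TestCoordinateUpdate:
    def test_unpenalized_returns_marginal_estimate(self, small_design):
        d = small_design
        cfg = _config(d, 0.0)
        for j in (0, d.p // 2, d.p - 1):
            assert coordinate_update(j, np.zeros(d.p), d, cfg) == pytest.approx(d.z[j])

    def test_zero_signal_zero_neighbors_stays_zero(self, small_design):
        d = small_design
        d.z[3] = 0.0
        cfg = _config(d, 0.5, lam2=1.0, sigma=np.full(d.p - 1, 0.5))
        assert coordinate_update(3, np.zeros(d.p), d, cfg) == 0.0

    def test_active_neighbor_lowers_entry_threshold(self, small_design):
        # the smoothing term pulls a just-below-threshold SNP into the model
        # when its LD neighbor carries a strong effect
        d = small_design
        lam1, lam2 = 0.5, 0.6
        d.z[5] = 0.48  # below lam1: stays out without help
        sigma = np.full(d.p - 1, 0.9)
        cfg = _config(d, lam1, lam2=lam2, sigma=sigma)
        beta = np.zeros(d.p)
        assert coordinate_update(5, beta, d, cfg) == 0.0
        beta[6] = 0.8
        assert coordinate_update(5, beta, d, cfg) != 0.0

    @pytest.mark.parametrize("gamma", [1.5, 3.0, 12.0])
    def test_matches_grid_search(self, small_design, gamma):
        d = small_design
        rng = np.random.default_rng(100)
        beta = np.zeros(d.p)
        for _ in range(60):
            j = int(rng.integers(1, d.p - 1))
            d.z[j] = rng.uniform(-2, 2)
            beta[j - 1] = rng.uniform(-2, 2)
            beta[j + 1] = rng.uniform(-2, 2)
            sigma = rng.uniform(0, 1, d.p - 1)
            lam1, lam2 = rng.uniform(0, 1.5), rng.uniform(0, 1.5)
            cfg = _config(d, lam1, lam2=lam2, gamma=gamma, sigma=sigma)
            got = coordinate_update(j, beta, d, cfg)
            want = _grid_minimize(
                d.z[j], beta[j - 1], beta[j + 1],
                sigma[j - 1], sigma[j], lam1, lam2, gamma,
            )
            assert got == pytest.approx(want, abs=2e-4)

    def test_hard_threshold_boundary_mode(self, small_design):
        # gamma = 1: keep-or-kill. Large z is kept at its marginal value,
        # small z is zeroed.
        d = small_design
        cfg = _config(d, 0.5, gamma=1.0)
        d.z[2] = 1.4
        assert coordinate_update(2, np.zeros(d.p), d, cfg) == pytest.approx(1.4)
        d.z[2] = 0.2
        assert coordinate_update(2, np.zeros(d.p), d, cfg) == 0.0


class TestFit:
    def test_separable_matches_analytic_mcp(self, small_design):
        d = small_design
        cfg = _config(d, 0.15)
        fr = fit(d, cfg)
        np.testing.assert_allclose(fr.beta, mcp_threshold(d.z, 0.15, 3.0), atol=1e-8)
        assert fr.converged

    def test_full_shrinkage_above_zmax(self, small_design):
        d = small_design
        cfg = _config(d, float(np.max(np.abs(d.z))) * 1.01)
        fr = fit(d, cfg)
        assert fr.support.size == 0

    def test_objective_trace_never_increases(self):
        rng = np.random.default_rng(0)
        for rep in range(20):
            d, _ = make_design(n=80, p=15, rho=0.6, seed=200 + rep)
            sigma = ld_weights(d)
            tau = rng.uniform(0.05, 1.0) * float(np.max(np.abs(d.z)))
            lam1, lam2 = reparameterize(0.1, tau)
            cfg = PenaltyConfig(lambda1=lam1, lambda2=lam2, gamma=3.0, sigma=sigma)
            fr = fit(d, cfg, init=rng.normal(0, 0.2, d.p))
            tr = fr.objective_trace
            assert np.all(np.diff(tr) <= 1e-9 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_deterministic_given_init(self, small_design):
        d = small_design
        cfg = _config(d, 0.1, lam2=0.05, sigma=ld_weights(d))
        a = fit(d, cfg)
        b = fit(d, cfg)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_support_is_exact_nonzeros(self, small_design):
        d = small_design
        fr = fit(d, _config(d, 0.2))
        np.testing.assert_array_equal(fr.support, np.flatnonzero(fr.beta != 0))


class TestPaths:
    def test_first_grid_point_empty_support(self, small_design):
        d = small_design
        path = fit_path(d, eta=0.1, sigma=ld_weights(d), n_tau=20)
        assert path.fits[0].support.size == 0
        assert np.all(np.diff(path.tau_grid) < 0)

    def test_lasso_update_is_soft_threshold(self, small_design):
        d = small_design
        path = fit_lasso_path(d, n_tau=20)
        for t, fr in zip(path.tau_grid, path.fits):
            soft = np.sign(d.z) * np.maximum(np.abs(d.z) - t, 0)
            np.testing.assert_allclose(fr.beta, soft, atol=1e-10)
            assert fr.sweeps <= 2

    def test_lasso_equals_mcp_soft_limit(self, small_design):
        d = small_design
        grid = make_tau_grid(d, 0.0, 15)
        a = fit_lasso_path(d, tau_grid=grid)
        b = fit_path(d, eta=0.0, gamma=solver.LASSO_GAMMA, tau_grid=grid,
                     sigma=np.zeros(d.p - 1))
        for fa, fb in zip(a.fits, b.fits):
            np.testing.assert_allclose(fa.beta, fb.beta, atol=1e-6)

    def test_tau_zero_returns_marginal_estimates(self, small_design):
        d = small_design
        fr = fit(d, _config(d, 0.0))
        np.testing.assert_allclose(fr.beta, d.z, atol=1e-10)

    def test_warm_start_path_changes_are_incremental(self, small_design):
        d = small_design
        path = fit_path(d, eta=0.1, sigma=ld_weights(d), n_tau=40)
        sizes = [f.support.size for f in path.fits]
        assert max(abs(np.diff(sizes))) <= d.p // 2

    def test_sign_flip_equivariance_of_fit_and_ebic(self):
        d, _ = make_design(n=150, p=20, rho=0.5, seed=31)
        sigma = ld_weights(d)
        tau = 0.3 * float(np.max(np.abs(d.z)))
        lam1, lam2 = reparameterize(0.1, tau)
        cfg = PenaltyConfig(lambda1=lam1, lambda2=lam2, gamma=3.0, sigma=sigma)
        fr = fit(d, cfg)
        flip = np.ones(d.p)
        flip[[2, 7, 11]] = -1.0
        import copy

        d2 = copy.copy(d)
        d2.x = d.x * flip
        d2.z = d.z * flip
        fr2 = fit(d2, cfg)
        np.testing.assert_allclose(fr2.beta, fr.beta * flip, atol=1e-10)
        np.testing.assert_array_equal(fr2.support, fr.support)
        assert objective(fr2.beta, d2, cfg) == pytest.approx(
            objective(fr.beta, d, cfg), rel=1e-12
        )
        assert ebic(fr2, d2) == pytest.approx(ebic(fr, d), rel=1e-12)


class TestEBIC:
    def test_null_model_value(self, small_design):
        d = small_design
        fr = fit(d, _config(d, float(np.max(np.abs(d.z))) * 1.1))
        rss0 = float(d.y @ d.y)
        assert ebic(fr, d, ebic_gamma=1.0) == pytest.approx(d.n * np.log(rss0 / d.n))

    def test_gamma_zero_is_plain_bic(self, small_design):
        d = small_design
        fr = fit(d, _config(d, 0.1))
        k = fr.support.size
        from scipy.special import gammaln

        comb = gammaln(d.p + 1) - gammaln(k + 1) - gammaln(d.p - k + 1)
        assert ebic(fr, d, ebic_gamma=1.0) - ebic(fr, d, ebic_gamma=0.0) == pytest.approx(
            2.0 * comb
        )

    def test_combinatorial_term_by_hand(self):
        # p = 10, k = 2, gamma = 1 -> extra term 2*log C(10,2) = 2*log 45
        d, _ = make_design(n=100, p=10, rho=0.0, seed=44)
        grid = make_tau_grid(d, 0.0, 60)
        path = fit_lasso_path(d, tau_grid=grid)
        for fr in path.fits:
            if fr.support.size == 2:
                diff = ebic(fr, d, ebic_gamma=1.0) - ebic(fr, d, ebic_gamma=0.0)
                assert diff == pytest.approx(2 * np.log(45.0))
                return
        pytest.skip("no k=2 point on this path")

    def test_oversaturated_model_infinite(self, small_design):
        d = small_design
        fr = fit(d, _config(d, 0.0))
        fr.support = np.arange(d.n + 1)  # force k >= n
        assert ebic(fr, d) == np.inf
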