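"""MCP penalty, adjacency weights, smoothing term, and the full objective."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smcp.penalties import (
    PenaltyConfig,
    ld_weights,
    marginal_loss,
    mcp_derivative,
    mcp_value,
    objective,
    smoothing_value,
)
from .conftest import make_design


class TestMCP:
    def test_zero_at_origin(self):
        assert mcp_value(0.0, 1.3, 3.0) == 0.0

    def test_plateau_value(self):
        # beyond gamma*lambda the penalty is flat at gamma*lambda^2/2
        assert mcp_value(5.0, 1.0, 3.0) == pytest.approx(1.5)
        assert mcp_value(-5.0, 1.0, 3.0) == pytest.approx(1.5)

    def test_soft_threshold_limit(self):
        assert mcp_value(0.4, 1.0, 1e12) == pytest.approx(0.4, abs=1e-10)

    def test_gamma_below_one_rejected(self):
        with pytest.raises(ValueError):
            mcp_value(1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            mcp_derivative(1.0, 1.0, 0.99)

    @given(
        lam=st.floats(0.01, 5.0),
        gamma=st.floats(1.0, 50.0),
        t=st.floats(-10, 10),
    )
    @settings(deadline=None, max_examples=200)
    def test_continuous_symmetric_and_bounded(self, lam, gamma, t):
        v = mcp_value(t, lam, gamma)
        assert v >= 0
        assert v == pytest.approx(mcp_value(-t, lam, gamma))
        assert v <= lam * abs(t) + 1e-12
        # continuity at the regime boundary
        b = gamma * lam
        assert mcp_value(b - 1e-9, lam, gamma) == pytest.approx(
            mcp_value(b + 1e-9, lam, gamma), abs=1e-6
        )

    def test_derivative_flat_region(self):
        assert mcp_derivative(3.0 * 1.0 + 1.0, 1.0, 3.0) == 0.0

    def test_derivative_value_and_oddness(self):
        assert mcp_derivative(1.5, 1.0, 3.0) == pytest.approx(0.5)
        assert mcp_derivative(-1.5, 1.0, 3.0) == pytest.approx(-0.5)

    def test_derivative_matches_finite_difference(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            lam, gamma = rng.uniform(0.1, 2), rng.uniform(1.5, 10)
            t = rng.uniform(-3, 3)
            if abs(abs(t) - gamma * lam) < 1e-3 or abs(t) < 1e-3:
                continue  # kink / boundary
            h = 1e-6
            fd = (mcp_value(t + h, lam, gamma) - mcp_value(t - h, lam, gamma)) / (2 * h)
            assert mcp_derivative(t, lam, gamma) == pytest.approx(fd, abs=1e-5)


class TestLDWeights:
    def test_identical_and_negated_columns(self, small_design):
        d = small_design
        d.x[:, 1] = d.x[:, 0]
        d.x[:, 2] = -d.x[:, 0]
        s = ld_weights(d)
        assert s[0] == pytest.approx(1.0)
        assert s[1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        d, _ = make_design(n=10000, p=10, rho=0.0, seed=21)
        assert np.all(ld_weights(d) < 0.05)

    def test_zero_across_chromosome_boundary(self):
        d, _ = make_design(n=300, p=10, rho=0.9, seed=3, n_chrom=2)
        s = ld_weights(d)
        assert s[4] == 0.0  # boundary between chrom 1 (cols 0-4) and 2 (cols 5-9)
        assert np.all(s[:4] > 0)

    def test_weights_in_unit_interval(self, small_design):
        s = ld_weights(small_design)
        assert np.all((s >= 0) & (s <= 1))


class TestSmoothing:
    def _cfg(self, sigma, lam2=2.0):
        return PenaltyConfig(lambda1=0.0, lambda2=lam2, gamma=3.0, sigma=np.asarray(sigma))

    def test_constant_beta_costs_nothing(self):
        cfg = self._cfg(np.ones(4))
        assert smoothing_value(np.full(5, 3.3), cfg) == 0.0

    def test_sign_flip_free(self):
        cfg = self._cfg([1.0])
        assert smoothing_value(np.array([1.0, -1.0]), cfg) == 0.0

    def test_direct_evaluation(self):
        cfg = self._cfg([0.5], lam2=2.0)
        assert smoothing_value(np.array([1.0, 0.0]), cfg) == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_any_sign_pattern(self, seed):
        rng = np.random.default_rng(seed)
        p = 8
        beta = rng.normal(size=p)
        cfg = self._cfg(rng.uniform(0, 1, p - 1), lam2=rng.uniform(0, 3))
        signs = rng.choice([-1.0, 1.0], size=p)
        assert smoothing_value(beta * signs, cfg) == pytest.approx(
            smoothing_value(beta, cfg), rel=1e-12
        )


class TestObjective:
    def test_null_beta_gives_null_loss(self, small_design):
        d = small_design
        cfg = PenaltyConfig(lambda1=0.3, lambda2=0.1, gamma=3.0, sigma=np.zeros(d.p - 1))
        expect = float(np.sum(d.yy_j / (2.0 * np.maximum(d.n_j, 1))))
        assert objective(np.zeros(d.p), d, cfg) == pytest.approx(expect)

    def test_unpenalized_minimum_at_z(self, small_design):
        d = small_design
        cfg = PenaltyConfig(lambda1=0.0, lambda2=0.0, gamma=3.0, sigma=np.zeros(d.p - 1))
        base = objective(d.z.copy(), d, cfg)
        rng = np.random.default_rng(8)
        for _ in range(10):
            pert = d.z + rng.normal(0, 0.05, d.p)
            assert objective(pert, d, cfg) >= base - 1e-12

    def test_single_snp_hand_oracle(self):
        # n=3, x=(-sqrt(1.5),0,sqrt(1.5)), y=(-1,0,1), beta=0.5,
        # lambda1=0.1, gamma=3, lambda2=0:
        #   loss = (2 - 2*0.5*2*sqrt(1.5) + 0.25*3)/6 = 0.0500850428694703
        #   |b| = 0.5 > gamma*lambda1 = 0.3 -> plateau 3*0.01/2 = 0.015
        import pandas as pd
        from smcp.preprocess import StandardizedDesign

        s = np.sqrt(1.5)
        x = np.array([[-s], [0.0], [s]])
        y = np.array([-1.0, 0.0, 1.0])
        d = StandardizedDesign(
            x=x, y=y, n_j=np.array([3]), z=np.array([(x[:, 0] @ y) / 3]),
            scale_j=np.array([1.0]), mean_j=np.array([1.0]),
            yy_j=np.array([2.0]), ybar_j=np.array([0.0]),
            observed=np.ones((3, 1), bool), excluded=np.zeros(1, bool),
            snps=pd.DataFrame({"id": ["m0"], "chrom": ["1"], "pos": [1]}),
        )
        cfg = PenaltyConfig(lambda1=0.1, lambda2=0.0, gamma=3.0, sigma=np.zeros(0))
        assert objective(np.array([0.5]), d, cfg) == pytest.approx(
            0.0500850428694703 + 0.015, abs=1e-12
        )

    def test_sign_flip_invariance_of_objective(self, small_design):
        d = small_design
        cfg = PenaltyConfig(
            lambda1=0.2, lambda2=0.3, gamma=3.0,
            sigma=np.random.default_rng(1).uniform(0, 1, d.p - 1),
        )
        rng = np.random.default_rng(2)
        beta = rng.normal(0, 0.3, d.p)
        signs = rng.choice([-1.0, 1.0], d.p)
        # flipping beta signs leaves penalties unchanged; the loss term
        # changes only through -z*beta, so flip z's sign alongside (as an
        # allele flip would)
        d2 = _flip_design(d, signs)
        assert objective(beta * signs, d2, cfg) == pytest.approx(
            objective(beta, d, cfg), rel=1e-12
        )


def _flip_design(d, signs):
    import copy

    d2 = copy.copy(d)
    d2.x = d.x * signs
    d2.z = d.z * signs
    return d2
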