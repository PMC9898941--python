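"""Correlated-Bernoulli model: feasibility bounds, latent solves, pattern
distributions, and the thresholding sampler."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mentropy import (
    BernoulliParams,
    ReadMatrix,
    bivariate_normal_cdf,
    build_latent_model,
    pairwise_correlation_bounds,
    pattern_distribution,
    sample_reads,
    solve_latent_correlation,
)
from mentropy.corr_bernoulli import _latent_pattern_probs, _pair_closed_form


def brute_force_correlation_bounds(p_i, p_j, grid=200_001):
    """Oracle: scan the joint success cell over its Frechet interval and
    convert each valid 2x2 table to a correlation."""
    lo = max(0.0, p_i + p_j - 1.0)
    hi = min(p_i, p_j)
    p11 = np.linspace(lo, hi, grid)
    sd = np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))
    r = (p11 - p_i * p_j) / sd
    return r.min(), r.max()


class TestPairwiseBounds:
    @pytest.mark.parametrize(
        "p_i,p_j,expected",
        [
            (0.5, 0.5, (-1.0, 1.0)),
            (0.3, 0.7, (-1.0, 0.4285714285714286)),
            (0.9, 0.1, (-1.0, 0.1111111111111111)),
        ],
    )
    def test_known_values(self, p_i, p_j, expected):
        lo, hi = pairwise_correlation_bounds(p_i, p_j)
        assert lo == pytest.approx(expected[0], abs=1e-12)
        assert hi == pytest.approx(expected[1], abs=1e-12)

    @pytest.mark.parametrize("p_i,p_j", [(0.3, 0.7), (0.9, 0.1), (0.2, 0.2),
                                         (0.45, 0.85)])
    def test_matches_brute_force(self, p_i, p_j):
        lo, hi = pairwise_correlation_bounds(p_i, p_j)
        blo, bhi = brute_force_correlation_bounds(p_i, p_j)
        assert lo == pytest.approx(blo, abs=1e-4)
        assert hi == pytest.approx(bhi, abs=1e-4)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_marginal_rejected(self, p):
        with pytest.raises(ValueError, match="degenerate"):
            pairwise_correlation_bounds(p, 0.5)


class TestLatentSolve:
    def test_independence_maps_to_zero(self):
        assert solve_latent_correlation(0.5, 0.5, 0.0) == 0.0

    def test_comonotone_maps_to_one(self):
        assert solve_latent_correlation(0.5, 0.5, 1.0) == pytest.approx(1.0)

    def test_median_dichotomization_closed_form(self):
        # tetrachoric identity r = 2 arcsin(rho) / pi at p = 1/2
        rho = solve_latent_correlation(0.5, 0.5, 0.5)
        assert rho == pytest.approx(np.sin(np.pi * 0.5 / 2), abs=1e-4)
        assert rho == pytest.approx(0.70711, abs=1e-4)

    def test_infeasible_correlation_names_bound(self):
        with pytest.raises(ValueError, match="upper bound"):
            solve_latent_correlation(0.3, 0.7, 0.9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        p_i=st.floats(0.05, 0.95),
        p_j=st.floats(0.05, 0.95),
        t=st.floats(0.0, 1.0),
    )
    def test_solve_residual_below_tolerance(self, p_i, p_j, t):
        lo, hi = pairwise_correlation_bounds(p_i, p_j)
        r = lo + t * (hi - lo)
        rho = solve_latent_correlation(p_i, p_j, r)
        sd = np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))
        target = r * sd + p_i * p_j
        z_i, z_j = stats.norm.ppf([p_i, p_j])
        assert bivariate_normal_cdf(z_i, z_j, rho) == pytest.approx(
            target, abs=1e-8
        )


class TestBivariateNormalCdf:
    def test_matches_scipy(self, rng):
        for _ in range(50):
            h, k = rng.normal(size=2) * 1.5
            rho = rng.uniform(-0.99, 0.99)
            ref = stats.multivariate_normal.cdf(
                [h, k], mean=np.zeros(2), cov=[[1, rho], [rho, 1]]
            )
            assert bivariate_normal_cdf(h, k, rho) == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("h,k,rho", [(0, 0.5, 0.3), (0.5, 0, -0.4),
                                         (0, 0, 0.6), (0, -0.5, 0.2)])
    def test_zero_arguments(self, h, k, rho):
        ref = stats.multivariate_normal.cdf(
            [h, k], mean=np.zeros(2), cov=[[1, rho], [rho, 1]]
        )
        assert bivariate_normal_cdf(h, k, rho) == pytest.approx(ref, abs=1e-12)


class TestBuildLatentModel:
    def test_identity_for_independent_median(self):
        model = build_latent_model(BernoulliParams.independent(0.5, 4))
        assert np.allclose(model.z, 0.0)
        assert np.allclose(model.Sigma, np.eye(4))
        assert not model.repaired

    def test_tetrachoric_offdiagonals(self):
        model = build_latent_model(BernoulliParams.exchangeable(0.5, 0.5, 4))
        off = model.Sigma[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.70711, atol=1e-4)

    def test_independent_nonhomogeneous(self):
        model = build_latent_model(
            BernoulliParams.independent(np.array([0.3, 0.6]))
        )
        assert np.allclose(model.Sigma, np.eye(2))
        assert model.z == pytest.approx(stats.norm.ppf([0.3, 0.6]).tolist())


class TestPatternDistribution:
    def test_uniform_for_fair_independent_pair(self):
        d = pattern_distribution(BernoulliParams.independent(0.5, 2))
        assert np.allclose(d.q, 0.25)

    def test_printed_two_site_closed_form(self):
        d = pattern_distribution(BernoulliParams.exchangeable(0.5, 0.5, 2))
        assert d.q == pytest.approx([0.375, 0.125, 0.125, 0.375], abs=1e-12)

    def test_product_form_nonhomogeneous(self):
        d = pattern_distribution(BernoulliParams.independent(np.array([0.3, 0.6])))
        assert d.q == pytest.approx([0.28, 0.42, 0.12, 0.18], abs=1e-12)

    def test_perfect_correlation_two_point(self):
        d = pattern_distribution(BernoulliParams.exchangeable(0.3, 1.0, 4))
        assert d.q[0] == pytest.approx(0.7, abs=1e-9)
        assert d.q[-1] == pytest.approx(0.3, abs=1e-9)
        assert np.all(d.q[1:-1] < 1e-9)

    @pytest.mark.parametrize(
        "params",
        [
            BernoulliParams.exchangeable(0.4, 0.35, 3),
            BernoulliParams.exchangeable(np.array([0.3, 0.5, 0.6, 0.45]), 0.3),
            BernoulliParams.ar1(np.array([0.2, 0.5, 0.7, 0.4]), 0.45),
            BernoulliParams.independent(np.array([0.1, 0.9, 0.5])),
        ],
        ids=["exch-homog", "exch-mixed", "ar1-mixed", "indep"],
    )
    def test_normalization_and_moment_recovery(self, params):
        d = pattern_distribution(params)
        assert np.all(d.q >= 0)
        assert d.q.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.abs(d.marginals() - params.p).max() < 1e-6
        assert np.abs(d.implied_correlation() - params.R).max() < 1e-5

    def test_degenerate_site_held_constant(self):
        p = np.array([0.0, 0.4, 1.0])
        params = BernoulliParams(p, np.eye(3))
        d = pattern_distribution(params)
        # patterns are 0 _ 1: only indices 0b001 and 0b011 have mass
        assert d.q[0b001] == pytest.approx(0.6)
        assert d.q[0b011] == pytest.approx(0.4)
        assert d.q.sum() == pytest.approx(1.0)

    def test_identity_R_matches_product_form_exactly(self, rng):
        p = rng.uniform(0.05, 0.95, size=4)
        d = pattern_distribution(BernoulliParams.independent(p))
        expected = np.array([
            np.prod([p[s] if (i >> (3 - s)) & 1 else 1 - p[s] for s in range(4)])
            for i in range(16)
        ])
        assert d.q == pytest.approx(expected.tolist(), abs=1e-12)

    def test_thresholding_path_matches_two_site_closed_form(self):
        for p in np.arange(0.1, 0.95, 0.1):
            for r in (0.0, 0.25, 0.5, 0.75, 1.0):
                lo, hi = pairwise_correlation_bounds(p, p)
                if not lo <= r <= hi:
                    continue
                params = BernoulliParams.exchangeable(p, r, 2)
                latent = _latent_pattern_probs(build_latent_model(params))
                closed = _pair_closed_form(p, p, r)
                assert np.abs(latent - closed).max() < 1e-6

    def test_infeasible_parameters_propagate(self):
        with pytest.raises(ValueError, match="feasible"):
            BernoulliParams.exchangeable(np.array([0.3, 0.7]), 0.9)


class TestSampleReads:
    def test_deterministic_given_seed(self):
        params = BernoulliParams.ar1(np.array([0.3, 0.5, 0.7]), 0.4)
        a = sample_reads(params, 50, seed=7)
        b = sample_reads(params, 50, seed=7)
        assert np.array_equal(a.x, b.x)

    def test_perfect_correlation_gives_constant_rows(self):
        reads = sample_reads(BernoulliParams.exchangeable(0.5, 1.0, 4), 200,
                             seed=3)
        row_sums = reads.x.sum(axis=1)
        assert np.isin(row_sums, (0, 4)).all()

    def test_moments_converge(self):
        params = BernoulliParams.exchangeable(np.array([0.3, 0.6]), 0.4)
        reads = sample_reads(params, 100_000, seed=11)
        se = 3 * np.sqrt(np.array([0.3 * 0.7, 0.6 * 0.4]) / 100_000)
        assert np.abs(reads.x.mean(axis=0) - [0.3, 0.6]).max() < se.max()
        assert np.corrcoef(reads.x.T)[0, 1] == pytest.approx(0.4, abs=0.02)

    def test_empirical_patterns_match_distribution(self):
        params = BernoulliParams.ar1(np.array([0.3, 0.5, 0.7]), 0.4)
        reads = sample_reads(params, 100_000, seed=13)
        q = pattern_distribution(params).q
        res = stats.chisquare(reads.pattern_counts(), 100_000 * q)
        assert res.pvalue > 0.001


class TestParamsValidation:
    def test_asymmetric_R_rejected(self):
        R = np.eye(2)
        R[0, 1] = 0.3
        with pytest.raises(ValueError, match="symmetric"):
            BernoulliParams(np.array([0.5, 0.5]), R)

    def test_degenerate_site_with_correlation_rejected(self):
        R = np.full((2, 2), 0.5)
        np.fill_diagonal(R, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            BernoulliParams(np.array([0.0, 0.5]), R)

    def test_constructors_agree(self):
        exch = BernoulliParams.exchangeable(0.4, 0.0, 3)
        ind = BernoulliParams.independent(0.4, 3)
        assert np.allclose(exch.R, ind.R)
        ar = BernoulliParams.ar1(0.4, 0.5, 3)
        assert ar.R[0, 2] == pytest.approx(0.25)
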