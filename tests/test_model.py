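"""Moments and likelihoods checked against independent density oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from twinpgs import (
    InvalidParameterError,
    ModelParams,
    TwinPair,
    censored_pair_loglik,
    dataset_loglik,
    expected_moments,
    pair_loglik,
)
from twinpgs.model import TwinData, bvn_cdf

from conftest import random_pairs


class TestExpectedMoments:
    def test_reduces_to_plain_ace(self):
        """Without moderation or a PGS effect the classic ACE moments appear:
        MZ covariance a2 + c2, DZ covariance a2/2 + c2."""
        a2, c02, e02 = 0.5, 0.2, 0.3
        p = ModelParams(aL=math.sqrt(a2), c0=math.sqrt(c02), e0=math.sqrt(e02))
        for pgs in (-1.3, 0.0, 2.0):
            mz = expected_moments(p, TwinPair("MZ", 0, 0, pgs, pgs))
            assert mz.v1 == pytest.approx(a2 + c02 + e02)
            assert mz.cov12 == pytest.approx(a2 + c02)
            dz = expected_moments(p, TwinPair("DZ", 0, 0, pgs, -pgs))
            assert dz.cov12 == pytest.approx(0.5 * a2 + c02)

    def test_hand_substitution_moderated(self):
        """Moderated variance at pgs = 1, recomputed by direct arithmetic."""
        p = ModelParams(
            b0=0.0, aL=math.sqrt(0.495), aP=math.sqrt(0.055),
            c0=0.3162, e0=0.5916, bc=0.131, be=0.079,
        )
        m = expected_moments(p, TwinPair("MZ", 0, 0, 1.0, 1.0))
        v_hand = 0.495 + (0.3162 + 0.131) ** 2 + (0.5916 + 0.079) ** 2
        cov_hand = 0.495 + (0.3162 + 0.131) ** 2
        assert m.v1 == pytest.approx(v_hand, abs=1e-12)
        assert m.v2 == pytest.approx(v_hand, abs=1e-12)
        assert m.cov12 == pytest.approx(cov_hand, abs=1e-12)
        assert m.mu1 == pytest.approx(math.sqrt(0.055), abs=1e-12)

    def test_e_only_model(self):
        p = ModelParams(e0=1.0)
        m = expected_moments(p, TwinPair("DZ", 0, 0, 1.7, -0.4))
        assert m.v1 == m.v2 == 1.0
        assert m.cov12 == 0.0

    @given(
        pgs=st.floats(-3, 3),
        aL=st.floats(0.1, 1.0),
        c0=st.floats(0, 1.0),
        e0=st.floats(0.1, 1.0),
        bc=st.floats(-0.3, 0.3),
        be=st.floats(-0.3, 0.3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_mz_covariance_dominates_dz(self, pgs, aL, c0, e0, bc, be):
        """With equal PGS values an MZ pair's implied covariance is at least
        the DZ pair's, equality only when the latent genetic path vanishes."""
        p = ModelParams(aL=aL, c0=c0, e0=e0, bc=bc, be=be)
        mz = expected_moments(p, TwinPair("MZ", 0, 0, pgs, pgs))
        dz = expected_moments(p, TwinPair("DZ", 0, 0, pgs, pgs))
        assert mz.cov12 >= dz.cov12 - 1e-12
        if aL > 1e-3:
            assert mz.cov12 > dz.cov12

    def test_covariance_ignores_pgs_without_moderation(self):
        p = ModelParams(aL=0.6, aP=0.4, c0=0.3, e0=0.7)
        covs = {
            expected_moments(p, TwinPair("DZ", 0, 0, p1, p2)).cov12
            for p1, p2 in [(-2, 1), (0, 0), (1.5, 1.5)]
        }
        assert len(covs) == 1

    def test_marginal_variance_recovers_printed_decomposition(self):
        """Marginalizing the conditional moments over a unit-variance PGS
        (pgs1 = pgs2) recovers aL^2 + aP^2 + c^2-terms + e^2-terms,
        i.e. the law of total variance, to Monte-Carlo accuracy."""
        p = ModelParams(aL=0.6, aP=0.3, c0=0.4, e0=0.5, bc=0.1, be=0.08)
        rng = np.random.default_rng(5)
        pgs = rng.standard_normal(400_000)
        v = p.aL**2 + (p.c0 + p.bc * pgs) ** 2 + (p.e0 + p.be * pgs) ** 2
        mu = p.b0 + p.aP * pgs
        total = np.mean(v) + np.var(mu)
        expected = p.aL**2 + p.aP**2 + p.c0**2 + p.e0**2 + p.bc**2 + p.be**2
        assert total == pytest.approx(expected, rel=5e-3)

    def test_invalid_params_raise(self):
        with pytest.raises(InvalidParameterError):
            ModelParams(aL=-0.1)
        with pytest.raises(InvalidParameterError):
            ModelParams(e0=0.0)
        with pytest.raises(InvalidParameterError):
            ModelParams(b0=float("nan"))


class TestTwinPairValidation:
    def test_mz_pgs_must_match(self):
        with pytest.raises(ValueError, match="MZ"):
            TwinPair("MZ", 0, 0, 0.5, -0.5)

    def test_unknown_zygosity(self):
        with pytest.raises(ValueError, match="zygosity"):
            TwinPair("OS", 0, 0, 0, 0)

    def test_case_insensitive(self):
        assert TwinPair("mz", 0, 0, 1, 1).is_mz


class TestPairLoglik:
    def test_independent_standard_normals_at_mode(self):
        p = ModelParams(e0=1.0)
        assert pair_loglik(p, TwinPair("DZ", 0, 0, 0, 0)) == pytest.approx(
            -math.log(2 * math.pi)
        )

    def test_matches_generic_mvn_density(self, params_mid):
        """The closed-form pair density equals scipy's generic multivariate
        normal evaluated at the same implied moments."""
        rng = np.random.default_rng(2)
        for pair in random_pairs(rng, 50):
            m = expected_moments(params_mid, pair)
            ref = multivariate_normal.logpdf(
                [pair.y1, pair.y2],
                mean=[m.mu1, m.mu2],
                cov=[[m.v1, m.cov12], [m.cov12, m.v2]],
            )
            assert pair_loglik(params_mid, pair) == pytest.approx(ref, abs=1e-10)

    def test_near_singular_covariance_stays_finite(self):
        """As cov12 approaches the variance the density grows but stays
        finite for any strictly positive-definite point."""
        pair = TwinPair("MZ", 0.3, 0.3, 0.0, 0.0)
        vals = []
        for e0 in (0.3, 0.1, 0.03, 0.01):
            p = ModelParams(aL=1.0, c0=0.0, e0=e0)
            vals.append(pair_loglik(p, pair))
        assert all(np.isfinite(v) for v in vals)
        # log-density at equal y-values increases as the pair correlation -> 1
        assert vals == sorted(vals)

    def test_censored_flag_rejected(self, params_mid):
        with pytest.raises(ValueError):
            pair_loglik(params_mid, TwinPair("DZ", 0, 0, 0, 0, cens1=True))


class TestBvnCdf:
    def test_against_scipy_mvn(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            h, k = rng.normal(0, 1.5, 2)
            rho = rng.uniform(-0.99, 0.99)
            ref = multivariate_normal.cdf([h, k], cov=[[1, rho], [rho, 1]])
            assert float(bvn_cdf(h, k, rho)) == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("h,k,rho", [(0, 0, 0.5), (0, 1, -0.3), (1, 0, 0.9)])
    def test_zero_arguments(self, h, k, rho):
        ref = multivariate_normal.cdf([h, k], cov=[[1, rho], [rho, 1]])
        assert float(bvn_cdf(h, k, rho)) == pytest.approx(ref, abs=1e-9)

    def test_independence(self):
        assert float(bvn_cdf(0.7, -0.2, 0.0)) == pytest.approx(
            norm.cdf(0.7) * norm.cdf(-0.2), abs=1e-12
        )


class TestCensoredLoglik:
    def test_inactive_floor_equals_plain(self, params_mid):
        pair = TwinPair("DZ", -1.0, 0.5, 0.3, -0.5)
        assert censored_pair_loglik(params_mid, pair, -50.0) == pytest.approx(
            pair_loglik(params_mid, pair)
        )

    def test_both_censored_independent_factorizes(self):
        p = ModelParams(aL=0.0, c0=0.0, e0=0.8, b0=0.2)  # cov12 = 0
        floor = -0.5
        pair = TwinPair("DZ", floor, floor, 0.0, 0.0, True, True)
        expected = 2 * norm.logcdf((floor - 0.2) / 0.8)
        assert censored_pair_loglik(p, pair, floor) == pytest.approx(expected)

    @pytest.mark.parametrize("zyg,y2,c2", [("DZ", -1.0, True), ("MZ", 0.5, False)])
    def test_matches_quadrature(self, params_mid, zyg, y2, c2):
        """Censored contributions agree with direct numerical integration of
        the bivariate density over the censored region."""
        floor = -1.0
        pgs = (0.3, 0.3) if zyg == "MZ" else (0.3, -0.5)
        pair = TwinPair(zyg, floor, y2 if not c2 else floor, *pgs, True, c2)
        m = expected_moments(params_mid, pair)
        cov = np.array([[m.v1, m.cov12], [m.cov12, m.v2]])

        def dens(y1, y2_):
            d = np.array([y1 - m.mu1, y2_ - m.mu2])
            return math.exp(-0.5 * d @ np.linalg.solve(cov, d)) / (
                2 * math.pi * math.sqrt(np.linalg.det(cov))
            )

        if c2:
            ref, _ = integrate.dblquad(dens, -9, floor, -9, floor)
        else:
            ref, _ = integrate.quad(lambda y1: dens(y1, pair.y2), -9, floor)
        assert censored_pair_loglik(params_mid, pair, floor) == pytest.approx(
            math.log(ref), abs=1e-6
        )

    def test_limit_floor_to_minus_infinity(self, params_mid):
        """A floor ten SDs below the mean leaves the likelihood of an
        uncensored pair unchanged to 1e-8."""
        pair = TwinPair("MZ", 0.4, -0.2, 0.6, 0.6)
        far = params_mid.b0 - 10.0
        assert censored_pair_loglik(params_mid, pair, far) == pytest.approx(
            pair_loglik(params_mid, pair), abs=1e-8
        )


class TestDatasetLoglik:
    def test_single_pair(self, params_mid):
        pair = TwinPair("DZ", 0.1, -0.3, 0.2, 0.8)
        assert dataset_loglik(params_mid, [pair]) == pytest.approx(
            -2 * pair_loglik(params_mid, pair)
        )

    def test_duplication_additivity(self, params_mid):
        rng = np.random.default_rng(4)
        pairs = random_pairs(rng, 7)
        one = dataset_loglik(params_mid, pairs)
        assert dataset_loglik(params_mid, pairs * 3) == pytest.approx(3 * one)

    def test_vectorized_matches_per_pair_loop(self, params_mid):
        rng = np.random.default_rng(6)
        pairs = random_pairs(rng, 100)
        loop = -2 * sum(pair_loglik(params_mid, p) for p in pairs)
        assert dataset_loglik(params_mid, TwinData.from_pairs(pairs)) == pytest.approx(
            loop, rel=1e-12
        )

    def test_empty_dataset_rejected(self, params_mid):
        with pytest.raises(ValueError):
            dataset_loglik(params_mid, [])
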