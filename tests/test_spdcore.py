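"""Closed-form oracles for SPD distances, means, and shrinkage."""

import numpy as np
import pytest

from cveptl import spdcore
from cveptl.spdcore import (
    ShrinkageConfig,
    dist_ai,
    dist_le,
    expm_sym,
    invsqrt,
    is_spd,
    logm_spd,
    mean_ai,
    mean_le,
    scm,
    shrink,
    sqrtm_spd,
)

from conftest import spd


class TestScm:
    def test_matches_numpy_cov(self, rng):
        X = rng.normal(size=(4, 50))
        np.testing.assert_allclose(scm(X), np.cov(X), atol=1e-12)

    def test_rank_deficient_when_short(self, rng):
        X = rng.normal(size=(6, 4))
        w = np.linalg.eigvalsh(scm(X))
        assert w.min() < 1e-12

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            scm(np.ones((3, 1)))


class TestDistances:
    def test_ai_identity_to_scaled_identity(self):
        # d(I, 2I) = sqrt(n) * ln 2
        for n in (2, 3, 5):
            d = dist_ai(np.eye(n), 2 * np.eye(n))
            assert d == pytest.approx(np.sqrt(n) * np.log(2), abs=1e-12)

    def test_le_closed_form_diagonal(self):
        P = np.diag([1.0, np.e**2])
        assert dist_le(P, np.eye(2)) == pytest.approx(2.0, abs=1e-12)

    def test_metrics_agree_for_commuting_pairs(self, rng):
        w1 = rng.uniform(0.5, 3.0, size=4)
        w2 = rng.uniform(0.5, 3.0, size=4)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        P1 = (Q * w1) @ Q.T
        P2 = (Q * w2) @ Q.T
        assert dist_ai(P1, P2) == pytest.approx(dist_le(P1, P2), rel=1e-9)

    def test_symmetry_and_separation(self, rng):
        P1, P2 = spd(rng, 4), spd(rng, 4)
        assert dist_ai(P1, P2) == pytest.approx(dist_ai(P2, P1), rel=1e-9)
        assert dist_ai(P1, P1) == pytest.approx(0.0, abs=1e-9)
        assert dist_ai(P1, P2) > 0

    def test_ai_congruence_invariance(self, rng):
        P1, P2 = spd(rng, 4), spd(rng, 4)
        W = rng.normal(size=(4, 4))  # invertible a.s.
        d0 = dist_ai(P1, P2)
        d1 = dist_ai(W @ P1 @ W.T, W @ P2 @ W.T)
        assert d1 == pytest.approx(d0, rel=1e-8)

    def test_ai_inversion_invariance(self, rng):
        P1, P2 = spd(rng, 3), spd(rng, 3)
        assert dist_ai(np.linalg.inv(P1), np.linalg.inv(P2)) == pytest.approx(
            dist_ai(P1, P2), rel=1e-8
        )

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError):
            dist_ai(np.diag([1.0, -1.0]), np.eye(2))


class TestMeans:
    def test_le_mean_is_geometric_for_diagonals(self):
        P1, P2 = np.diag([1.0, 4.0]), np.diag([4.0, 9.0])
        expected = np.diag([2.0, 6.0])
        np.testing.assert_allclose(mean_le([P1, P2]), expected, atol=1e-12)

    def test_le_mean_of_identical_matrices(self, rng):
        P = spd(rng, 4)
        np.testing.assert_allclose(mean_le([P, P, P]), P, atol=1e-10)

    def test_ai_mean_two_matrices_closed_form(self, rng):
        P1, P2 = spd(rng, 4), spd(rng, 4)
        M = mean_ai([P1, P2])
        # The geodesic midpoint is equidistant from both ends...
        assert dist_ai(P1, M) == pytest.approx(dist_ai(M, P2), rel=1e-8)
        # ...at half the total distance.
        assert dist_ai(P1, M) == pytest.approx(0.5 * dist_ai(P1, P2), rel=1e-8)

    def test_ai_mean_stationarity(self, rng):
        mats = [spd(rng, 4) for _ in range(5)]
        M = mean_ai(mats, tol=1e-11)
        M_ihalf = invsqrt(M)
        grad = np.mean([logm_spd(M_ihalf @ P @ M_ihalf.T) for P in mats], axis=0)
        assert np.linalg.norm(grad, "fro") < 1e-9

    def test_ai_mean_congruence_equivariance(self, rng):
        mats = [spd(rng, 3) for _ in range(4)]
        W = rng.normal(size=(3, 3))
        M1 = mean_ai([W @ P @ W.T for P in mats], tol=1e-11)
        M0 = mean_ai(mats, tol=1e-11)
        np.testing.assert_allclose(M1, W @ M0 @ W.T, rtol=1e-7, atol=1e-9)

    def test_means_agree_for_commuting_family(self, rng):
        ws = rng.uniform(0.5, 2.0, size=(4, 3))
        mats = [np.diag(w) for w in ws]
        np.testing.assert_allclose(mean_ai(mats), mean_le(mats), atol=1e-9)

    def test_empty_mean_rejected(self):
        with pytest.raises(ValueError):
            mean_le([])


class TestMatrixFunctions:
    def test_log_exp_roundtrip(self, rng):
        P = spd(rng, 5)
        np.testing.assert_allclose(expm_sym(logm_spd(P)), P, rtol=1e-9, atol=1e-9)

    def test_invsqrt_whitens(self, rng):
        P = spd(rng, 5)
        M = invsqrt(P)
        np.testing.assert_allclose(M @ P @ M, np.eye(5), atol=1e-9)

    def test_sqrtm_squares_back(self, rng):
        P = spd(rng, 4)
        S = sqrtm_spd(P)
        np.testing.assert_allclose(S @ S, P, rtol=1e-9, atol=1e-9)

    def test_is_spd(self, rng):
        assert is_spd(spd(rng, 3))
        assert not is_spd(np.diag([1.0, 0.0]))
        assert not is_spd(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestShrinkage:
    def test_lambda_zero_returns_scm(self, rng):
        P = spd(rng, 4)
        cfg = ShrinkageConfig(method="schafer_strimmer", lam=0.0)
        np.testing.assert_array_equal(shrink(P, cfg), P)

    def test_lambda_one_returns_target(self, rng):
        P = spd(rng, 4)
        for method, target in [
            ("ledoit_wolf", np.trace(P) * np.eye(4)),
            ("blankertz", np.trace(P) / 4 * np.eye(4)),
            ("schafer_strimmer", np.diag(np.diag(P))),
        ]:
            cfg = ShrinkageConfig(method=method, lam=1.0)
            np.testing.assert_allclose(shrink(P, cfg), target, atol=1e-14)

    def test_blankertz_hand_example(self):
        P = np.diag([1.0, 3.0])
        cfg = ShrinkageConfig(method="blankertz", lam=0.5)
        np.testing.assert_allclose(shrink(P, cfg), np.diag([1.5, 2.5]), atol=1e-14)

    def test_rank_deficient_becomes_spd(self, rng):
        X = rng.normal(size=(8, 5))  # more channels than samples
        P = scm(X)
        assert not is_spd(P, tol=1e-10)
        out = shrink(P, ShrinkageConfig(method="schafer_strimmer"), data=X)
        assert is_spd(out)

    def test_analytic_lambda_in_unit_interval(self, rng):
        X = rng.normal(size=(5, 30))
        P = scm(X)
        target = np.diag(np.diag(P))
        lam = spdcore._analytic_lambda(P, target, X)
        assert 0.0 <= lam <= 1.0

    def test_analytic_lambda_vanishes_with_more_samples(self, rng):
        # With genuinely correlated channels the SCM converges to the truth,
        # so the optimal shrinkage toward the diagonal target goes to zero.
        A = np.linalg.cholesky(spd(np.random.default_rng(0), 5))
        lams = []
        for nt in (8, 5000):
            vals = []
            for _ in range(10):
                X = A @ rng.normal(size=(5, nt))
                P = scm(X)
                vals.append(spdcore._analytic_lambda(P, np.diag(np.diag(P)), X))
            lams.append(np.mean(vals))
        assert lams[0] > 3 * lams[1]

    def test_analytic_requires_data(self, rng):
        P = spd(rng, 3)
        with pytest.raises(ValueError, match="data"):
            shrink(P, ShrinkageConfig(method="schafer_strimmer", lam=None))

    def test_none_method_identity(self, rng):
        P = spd(rng, 3)
        np.testing.assert_array_equal(shrink(P, ShrinkageConfig(method="none")), P)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ShrinkageConfig(method="oas")
        with pytest.raises(ValueError):
            ShrinkageConfig(lam=1.5)
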