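"""PCA reduction, FAST-MCD, robust distances and the tolerance-ellipse screen."""

import itertools

import numpy as np
import pytest
from scipy.special import gammainc

from blendspec import (
    chi_square_cutoff,
    fast_mcd,
    flag_outliers,
    pca_fit,
    robust_distances,
)
from blendspec.outliers import consistency_factor

from conftest import make_block


class TestPCA:
    def test_rank_one_data_fully_explained(self, rng):
        direction = rng.random(5)
        X = np.outer(rng.standard_normal(15), direction)
        res = pca_fit(X, 1)
        assert res.explained_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_covariance_eigendecomposition(self, rng):
        """Scores/loadings agree with an independent eigensolver up to sign."""
        X = rng.random((20, 6))
        k = 4
        res = pca_fit(X, k)
        cov = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order[:k]]
        for j in range(k):
            v, w = res.loadings[:, j], evecs[:, j]
            sign = np.sign(v @ w)
            np.testing.assert_allclose(v, sign * w, atol=1e-8)
        np.testing.assert_allclose(
            res.scores, (X - X.mean(0)) @ res.loadings, atol=1e-8
        )

    def test_full_rank_ratios_sum_to_one(self, rng):
        X = rng.random((10, 4))
        res = pca_fit(X, 4)
        assert res.explained_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal_and_ratios_monotone(self, rng):
        res = pca_fit(rng.random((25, 8)), 5)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)
        assert np.all(np.diff(res.explained_ratio) <= 1e-12)

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError, match="k="):
            pca_fit(rng.random((5, 8)), 5)


class TestFastMCD:
    def test_matches_exhaustive_subset_oracle(self, rng):
        """On n=10 the minimal covariance determinant over all C(10,7)
        subsets is found exactly."""
        X = rng.standard_normal((10, 2))
        X[:2] += 6.0  # two displaced points the subset should dodge
        res = fast_mcd(X, seed=0)
        assert res.h == 7
        best = min(
            np.linalg.det(np.cov(X[list(idx)], rowvar=False, ddof=1))
            for idx in itertools.combinations(range(10), 7)
        )
        assert res.determinant == pytest.approx(best, rel=1e-10)

    def test_displaced_points_excluded_from_support(self, rng):
        X = 0.1 * rng.standard_normal((43, 2))
        X[40:] += 100.0
        res = fast_mcd(X, seed=1)
        assert not res.support[40:].any()

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((30, 2))
        a = fast_mcd(X, seed=7)
        b = fast_mcd(X, seed=7)
        np.testing.assert_array_equal(a.support, b.support)
        np.testing.assert_array_equal(a.scatter, b.scatter)

    def test_cstep_determinants_never_increase(self, rng):
        X = rng.standard_normal((40, 2))
        X[:5] *= 8.0
        res = fast_mcd(X, seed=3)
        assert np.all(np.diff(res.det_history) <= 1e-9 * res.det_history[0])

    def test_degenerate_geometry_raises_or_handles(self, rng):
        # exactly collinear scores: no non-singular subset exists
        t = rng.standard_normal(20)
        X = np.column_stack([t, 2.0 * t])
        with pytest.raises(ValueError, match="degenerate"):
            fast_mcd(X, seed=0)
        # near-identical points: a legal near-singular result (scale
        # equivariance means tiny spread is not itself degenerate)
        Y = np.ones((20, 2)) + 1e-9 * rng.standard_normal((20, 2))
        res = fast_mcd(Y, seed=0)
        assert 0 < res.determinant < 1e-30

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="n >= 4"):
            fast_mcd(np.zeros((3, 2)))


class TestRobustDistances:
    def test_center_has_zero_distance(self):
        d = robust_distances(np.array([[1.0, 2.0]]), [1.0, 2.0], np.eye(2))
        assert d[0] == 0.0

    def test_identity_covariance_is_euclidean(self):
        d = robust_distances(np.array([[3.0, 4.0]]), [0.0, 0.0], np.eye(2))
        assert d[0] == pytest.approx(5.0)

    def test_matches_explicit_inverse_oracle(self, rng):
        X = rng.standard_normal((15, 2))
        center = rng.standard_normal(2)
        A = rng.standard_normal((2, 2))
        cov = A @ A.T + 0.5 * np.eye(2)
        d = robust_distances(X, center, cov)
        inv = np.linalg.inv(cov)
        expected = np.sqrt([ (x - center) @ inv @ (x - center) for x in X ])
        np.testing.assert_allclose(d, expected, atol=1e-10)

    def test_non_positive_definite_errors(self):
        with pytest.raises(ValueError, match="positive definite"):
            robust_distances(np.zeros((2, 2)), [0, 0], np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestFlagOutliers:
    def test_cutoff_matches_gamma_bisection_oracle(self):
        """97.5% chi-square quantile (2 df) by bisection on the regularized
        gamma CDF, independent of scipy.stats.chi2.ppf."""
        def chi2_cdf(x):
            return gammainc(1.0, x / 2.0)  # 2 df

        lo, hi = 0.0, 50.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if chi2_cdf(mid) < 0.975:
                lo = mid
            else:
                hi = mid
        assert chi_square_cutoff(0.975, 2) == pytest.approx(np.sqrt(lo), abs=1e-8)

    def test_clean_data_flag_rate_near_nominal(self, rng):
        """Mean flag rate of clean bivariate-normal scores stays in [1%, 5%]
        at the 97.5% ellipse (Monte Carlo over seeds)."""
        from blendspec.outliers import fast_mcd as mcd

        rates = []
        cutoff = chi_square_cutoff(0.975, 2)
        for s in range(60):
            X = rng.standard_normal((90, 2))
            res = mcd(X, seed=s, n_starts=150)
            d = robust_distances(X, res.location, res.scatter)
            c = consistency_factor(d**2, 2)
            rates.append(np.mean(d / np.sqrt(c) > cutoff))
        assert 0.01 <= np.mean(rates) <= 0.05

    def test_gross_offset_spectra_are_flagged(self, rng):
        """Five spectra with a +0.5 uniform reflectance offset among 90 are
        all caught by the PCA+MCD screen."""
        from blendspec import inject_outliers, mix_spectra, make_endmembers, sample_blends

        ems = make_endmembers(seed=4)
        design = sample_blends(seed=4)
        vis, _ = mix_spectra(ems, design, seed=4)
        (corrupted,), labels = inject_outliers([vis], k=5, magnitude=0.5, seed=4)
        kept, report = flag_outliers(corrupted, seed=4)
        assert report.flagged[labels].all()
        assert kept.n_samples + report.flagged.sum() == 90

    def test_flags_invariant_to_affine_score_transform(self, rng):
        """The robust distance is affine-equivariant, so flag decisions do
        not change under a common invertible affine map of the score plane
        (checked at the MCD level with matched subsets)."""
        X = rng.standard_normal((40, 2))
        X[:3] += 8.0
        A = np.array([[2.0, 0.7], [-0.3, 1.5]])
        Y = X @ A.T + np.array([5.0, -2.0])
        res_x = fast_mcd(X, seed=9)
        res_y = fast_mcd(Y, seed=9)
        dx = robust_distances(X, res_x.location, res_x.scatter)
        dy = robust_distances(Y, res_y.location, res_y.scatter)
        cutoff = chi_square_cutoff(0.975, 2)
        fx = dx / np.sqrt(consistency_factor(dx**2, 2)) > cutoff
        fy = dy / np.sqrt(consistency_factor(dy**2, 2)) > cutoff
        np.testing.assert_array_equal(fx, fy)

    def test_ties_at_cutoff_are_kept(self, rng):
        """Flagging uses a strict inequality."""
        block = make_block(rng.random((12, 6)))
        kept, report = flag_outliers(block, quantile=0.975, seed=0)
        at_cutoff = np.isclose(report.robust_distance, report.cutoff)
        assert not report.flagged[at_cutoff].any()

    def test_report_bookkeeping(self, rng):
        block = make_block(rng.random((15, 8)))
        kept, report = flag_outliers(block, seed=2)
        assert report.h == int(0.75 * 15)
        assert len(report.kept_ids) + report.flagged.sum() == 15
        np.testing.assert_array_equal(
            report.flagged, report.robust_distance > report.cutoff
        )
        frame = report.to_frame()
        assert list(frame.columns) == ["sample_id", "pc1", "pc2", "distance", "flagged"]

    def test_cross_check_against_sklearn_mincovdet(self, rng):
        """Independent MCD route: sklearn's MinCovDet support determinant
        is not better (smaller) than ours on the same data."""
        MinCovDet = pytest.importorskip("sklearn.covariance").MinCovDet
        X = rng.standard_normal((40, 2))
        X[:4] += 10.0
        ours = fast_mcd(X, seed=0)
        ref = MinCovDet(support_fraction=0.75, random_state=0).fit(X)
        det_ref = np.linalg.det(
            np.cov(X[ref.support_], rowvar=False, ddof=1)
        )
        assert ours.determinant <= det_ref * (1 + 1e-8)
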