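import itertools

import numpy as np
import pytest

from burnscar.initialization import (auto_initial_contour, fit_nir,
                                     fitting_error, kmeans_split,
                                     rectangle_initial_contour)
from burnscar.raster_io import BandRoles, Scene
from burnscar.synthetic_scenes import SceneSpec, make_burn_pair


class TestFit:
    def test_exact_linear_relation(self):
        fit = fit_nir(np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 6, 8]))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-12)

    def test_identity(self):
        x = np.random.default_rng(0).uniform(size=100)
        fit = fit_nir(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        x1 = rng.uniform(0, 1, 10_000)
        x2 = 3.0 * x1 + 1.0 + rng.normal(0, 0.01, 10_000)
        fit = fit_nir(x1, x2)
        assert 2.99 <= fit.slope <= 3.01
        assert fit.intercept == pytest.approx(1.0, abs=0.01)

    def test_constant_x1_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fit_nir(np.ones(10), np.arange(10.0))


class TestFittingError:
    def test_scaled_squared_residuals(self):
        from burnscar.initialization import RegressionFit
        fit = RegressionFit(slope=1.0, intercept=0.0, residual_variance=0.25)
        x1 = np.zeros(3)
        d = 0.5
        x2 = np.array([0.0, d, 2 * d])
        err = fitting_error(x1, x2, fit)
        np.testing.assert_allclose(err, [0.0, d**2 / 0.25, 4 * d**2 / 0.25])

    def test_mean_error_is_one_on_fit_data(self):
        rng = np.random.default_rng(2)
        x1 = rng.uniform(size=500)
        x2 = 2 * x1 + rng.normal(0, 0.1, 500)
        fit = fit_nir(x1, x2)
        assert fitting_error(x1, x2, fit).mean() == pytest.approx(1.0)

    def test_invariant_to_joint_rescaling(self):
        rng = np.random.default_rng(3)
        x1 = rng.uniform(1, 2, 400)
        x2 = 1.5 * x1 + rng.normal(0, 0.05, 400)
        e1 = fitting_error(x1, x2, fit_nir(x1, x2))
        k = 37.5
        e2 = fitting_error(k * x1, k * x2, fit_nir(k * x1, k * x2))
        np.testing.assert_allclose(e1, e2, rtol=1e-9)

    def test_degenerate_fit_raises(self):
        from burnscar.initialization import RegressionFit
        fit = RegressionFit(slope=1.0, intercept=0.0, residual_variance=0.0)
        with pytest.raises(ValueError, match="no-change"):
            fitting_error(np.zeros(4), np.zeros(4), fit)


def exhaustive_two_partition(values):
    """Minimum within-cluster SSE over all 2-partitions (threshold form).

    For 1-D data the optimal 2-partition is an interval split of the sorted
    values, so scanning all split points is exhaustive.
    """
    v = np.sort(np.asarray(values, dtype=float))
    best = np.inf
    for i in range(1, len(v)):
        lo, hi = v[:i], v[i:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        best = min(best, sse)
    return best


class TestKmeansSplit:
    def test_two_point_clusters(self):
        labels, centers = kmeans_split(np.array([0.0, 0, 0, 10, 10]), seed=0)
        np.testing.assert_allclose(centers, [0, 10])
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1])

    def test_matches_exhaustive_oracle_on_short_lists(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(3, 13)
            vals = np.round(rng.uniform(0, 1, n), 3)
            if np.unique(vals).size < 2:
                continue
            labels, centers = kmeans_split(vals, seed=0)
            sse = sum(((vals[labels == c] - vals[labels == c].mean()) ** 2).sum()
                      for c in (0, 1) if (labels == c).any())
            best = exhaustive_two_partition(vals)
            assert sse == pytest.approx(best, abs=1e-9)

    def test_agrees_with_lloyd_iterations(self):
        """The exact interval-split optimum is never worse than scikit-learn's
        restarted Lloyd algorithm, and matches it on typical data."""
        from sklearn.cluster import KMeans
        rng = np.random.default_rng(0)
        for _ in range(10):
            vals = rng.uniform(0, 1, 200)
            labels, _ = kmeans_split(vals, seed=0)
            sse = sum(((vals[labels == c] - vals[labels == c].mean()) ** 2).sum()
                      for c in (0, 1))
            km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(vals[:, None])
            assert sse <= km.inertia_ + 1e-9

    def test_separated_gaussians_recovered(self):
        rng = np.random.default_rng(5)
        lo = rng.normal(0, 1, 300)
        hi = rng.normal(10, 1, 200)
        labels, _ = kmeans_split(np.concatenate([lo, hi]), seed=0)
        np.testing.assert_array_equal(labels[:300], 0)
        np.testing.assert_array_equal(labels[300:], 1)

    def test_seed_does_not_change_separated_partition(self):
        vals = np.concatenate([np.zeros(20), np.ones(30)])
        l1, _ = kmeans_split(vals, seed=0)
        l2, _ = kmeans_split(vals, seed=99)
        np.testing.assert_array_equal(l1, l2)

    def test_identical_values_raise(self):
        with pytest.raises(ValueError):
            kmeans_split(np.ones(5), seed=0)


class TestAutoContour:
    def test_lowered_patch_detected(self):
        roles = BandRoles(red=0, nir=1, mir=2, cva_bands=(0, 1, 2))
        rng = np.random.default_rng(6)
        pix1 = rng.uniform(100, 160, size=(64, 64, 3))
        pix2 = pix1 + rng.normal(0, 1.0, size=pix1.shape)
        patch = np.zeros((64, 64), dtype=bool)
        patch[20:36, 20:36] = True
        pix2[:, :, 1][patch] *= 0.5
        init = auto_initial_contour(Scene(pix1, roles), Scene(pix2, roles),
                                    seed=0)
        assert init.mask[patch].all()
        assert init.mask.sum() <= 1.2 * patch.sum()

    def test_phi0_matches_mask(self, scene_pair):
        pre, post, _ = scene_pair
        init = auto_initial_contour(pre, post, seed=0)
        assert (init.phi0 > 0).sum() == init.mask.sum()
        assert init.source == "auto"

    def test_jaccard_against_truth(self, small_pairs):
        """The regression/K-means mask lands on the real scar."""
        scores = []
        for pre, post, truth in small_pairs:
            m = auto_initial_contour(pre, post, seed=0).mask
            inter = np.logical_and(m == 1, truth == 1).sum()
            union = np.logical_or(m == 1, truth == 1).sum()
            scores.append(inter / union)
        assert np.median(scores) >= 0.5


class TestRectangles:
    def test_count_by_construction(self):
        init = rectangle_initial_contour((32, 32), spacing=8)
        from scipy import ndimage
        _, n = ndimage.label(init.mask)
        assert n == 16
        assert init.source == "rectangles"

    def test_both_phases_present(self):
        init = rectangle_initial_contour((40, 56), spacing=8)
        assert 0 < init.mask.sum() < init.mask.size

    def test_translation_periodicity(self):
        s = 8
        init = rectangle_initial_contour((64, 64), spacing=s)
        np.testing.assert_array_equal(init.mask[:-s, :], init.mask[s:, :])
        np.testing.assert_array_equal(init.mask[:, :-s], init.mask[:, s:])

    @pytest.mark.parametrize("spacing", [3, 64])
    def test_invalid_spacing(self, spacing):
        with pytest.raises(ValueError):
            rectangle_initial_contour((64, 64), spacing=spacing)
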