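import numpy as np
import pandas as pd
import pytest

from thorson.spatial_regression import (
    build_weights,
    candidate_screen,
    fit_sar_lag,
    haversine_km,
    logit_transform,
    morans_correlogram,
    morans_i,
    pairwise_distances,
    select_model,
)

KM_PER_DEG = 111.19  # great-circle km per degree at the equator (R=6371)


@pytest.fixture()
def scatter(rng):
    n = 200
    return rng.uniform(30, 40, n), rng.uniform(0, 10, n)


class TestLogit:
    def test_half_is_zero(self):
        assert logit_transform(0.5) == 0.0

    def test_symmetry(self, rng):
        p = rng.uniform(0, 1, 50)
        assert np.allclose(logit_transform(p) + logit_transform(1 - p), 0.0)

    def test_clipping_at_bounds(self):
        assert logit_transform(1.0) == pytest.approx(np.log(0.999 / 0.001))
        assert logit_transform(0.0) == pytest.approx(-np.log(0.999 / 0.001))

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            logit_transform(1.2)


class TestScreen:
    def test_duplicated_column_rejected_orthogonal_kept(self, rng):
        x = rng.standard_normal(100)
        z = rng.standard_normal(100)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": z})
        subsets = candidate_screen(X)
        assert ("a", "b") not in subsets and ("a", "c") in subsets

    def test_known_correlation_pair_rejected(self, rng):
        # build r = 0.7 between a and b by construction
        n = 4000
        e = rng.standard_normal((n, 2))
        a = e[:, 0]
        b = 0.7 * a + np.sqrt(1 - 0.7**2) * e[:, 1]
        X = pd.DataFrame({"a": a, "b": b, "c": rng.standard_normal(n)})
        subsets = candidate_screen(X)
        assert ("a", "b") not in subsets
        assert ("a", "b", "c") not in subsets
        assert ("a", "c") in subsets and ("b", "c") in subsets

    def test_constant_column_warned_away(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(20), "k": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            subsets = candidate_screen(X)
        assert subsets == [("a",)]


class TestMorans:
    def test_brute_force_equivalence_small_n(self, rng):
        n = 40
        lats = rng.uniform(30, 32, n)
        lons = rng.uniform(0, 2, n)
        z = rng.standard_normal(n)
        d = pairwise_distances(lats, lons)
        w = ((d > 0) & (d <= 100)).astype(float)
        zc = z - z.mean()
        brute = (n / w.sum()) * sum(
            w[i, j] * zc[i] * zc[j] for i in range(n) for j in range(n)
        ) / (zc @ zc)
        assert morans_i(z, w) == pytest.approx(brute, abs=1e-12)

    def test_iid_null_expectation(self, rng):
        n = 120
        lats = rng.uniform(30, 36, n)
        lons = rng.uniform(0, 6, n)
        acc = []
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # iid fields rarely cross zero
            for _ in range(40):
                c = morans_correlogram(rng.standard_normal(n), lats, lons,
                                       bin_width_km=100, max_dist_km=400)
                acc.append(c.morans_i)
        mean_i = np.mean(acc, axis=0)
        assert np.all(np.abs(mean_i - (-1 / (n - 1))) < 0.02)

    def test_smooth_gradient_first_bin_positive(self, rng):
        n = 150
        lats = rng.uniform(30, 40, n)
        lons = rng.uniform(0, 10, n)
        z = lats + 0.3 * rng.standard_normal(n)
        c = morans_correlogram(z, lats, lons, bin_width_km=100)
        assert c.morans_i[0] > 0.5

    def test_planted_scale_recovered_within_one_bin(self, rng):
        # meridional cosine field of half-wavelength L: I(d) crosses zero
        # near L/2 on a transect spanning one full wavelength
        L = 400.0
        n = 150
        lat0 = 30.0
        lats = lat0 + rng.uniform(0, 2 * L / KM_PER_DEG, n)
        lons = np.full(n, 5.0)
        z = np.cos(np.pi * (lats - lat0) * KM_PER_DEG / L)
        c = morans_correlogram(z, lats, lons, bin_width_km=50, max_dist_km=700)
        assert c.patch_size is not None
        assert abs(c.patch_size - L / 2) <= 50.0

    def test_no_crossing_flagged(self, rng):
        n = 30
        lats = rng.uniform(30, 31, n)
        lons = rng.uniform(0, 1, n)
        z = lats * 100  # pure gradient over a tiny extent: I stays positive
        with pytest.warns(UserWarning, match="no positive-to-negative"):
            c = morans_correlogram(z, lats, lons, bin_width_km=200,
                                   max_dist_km=200)
        assert c.patch_size is None


class TestWeights:
    def test_rows_sum_to_one_or_zero(self, scatter):
        w = build_weights(*scatter, patch_size_km=200.0)
        sums = w.sum(axis=1)
        assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))

    def test_three_collinear_equidistant_points(self):
        # along a meridian great-circle distances are exactly proportional
        lats = np.array([30.0, 31.0, 32.0])
        lons = np.array([5.0, 5.0, 5.0])
        d = haversine_km(30, 5, 31, 5)
        w = build_weights(lats, lons, patch_size_km=2.5 * d)
        # middle point: equal weights; edge points: 2:1 split near:far
        assert w[1, 0] == pytest.approx(0.5) and w[1, 2] == pytest.approx(0.5)
        assert w[0, 1] == pytest.approx(2 / 3) and w[0, 2] == pytest.approx(1 / 3)

    def test_isolated_points_flagged(self):
        lats = np.array([30.0, 50.0])
        lons = np.array([0.0, 0.0])
        with pytest.warns(UserWarning, match="no neighbour"):
            w = build_weights(lats, lons, patch_size_km=10.0)
        assert not w.any()

    def test_coincident_points_error(self):
        with pytest.raises(ValueError, match="coincident"):
            build_weights(np.array([30.0, 30.0, 31.0]),
                          np.array([1.0, 1.0, 1.0]), 100.0)


class TestSarLag:
    def make_design(self, rng, n=200):
        lats = rng.uniform(30, 40, n)
        lons = rng.uniform(0, 10, n)
        W = build_weights(lats, lons, 300.0)
        X = rng.standard_normal((n, 2))
        return W, X, np.column_stack([np.ones(n), X])

    def test_rho_fixed_zero_equals_ols_exactly(self, rng):
        W, X, Xd = self.make_design(rng)
        y = Xd @ [1.0, 0.5, -0.8] + 0.5 * rng.standard_normal(len(Xd))
        fit = fit_sar_lag(y, X, W, rho_fixed=0.0)
        ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert np.abs(fit.params["estimate"].to_numpy() - ols).max() < 1e-6

    def test_perfect_fit_with_zero_weights_r2_one(self, rng):
        n = 50
        X = rng.standard_normal((n, 1))
        y = 2.0 + 3.0 * X[:, 0]
        W = np.zeros((n, n))
        fit = fit_sar_lag(y, X, W, rho_fixed=0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_null_rho_centred_near_zero(self, rng):
        W, X, Xd = self.make_design(rng)
        rhos = []
        for _ in range(20):
            y = Xd @ [1.0, 0.5, -0.8] + 0.5 * rng.standard_normal(len(Xd))
            rhos.append(fit_sar_lag(y, X, W).rho)
        assert abs(np.mean(rhos)) < 0.15

    def test_planted_rho_recovered(self, rng):
        W, X, Xd = self.make_design(rng)
        n = len(Xd)
        y = np.linalg.solve(np.eye(n) - 0.4 * W,
                            Xd @ [1.0, 0.5, -0.8] + 0.5 * rng.standard_normal(n))
        fit = fit_sar_lag(y, X, W)
        assert abs(fit.rho - 0.4) <= 2.5 * fit.rho_se
        assert fit.aic < fit.aic_ols  # the spatial term earns its parameter

    def test_singular_design_errors(self, rng):
        W, X, _ = self.make_design(rng, n=50)
        X2 = np.column_stack([X[:, 0], X[:, 0]])
        with pytest.raises(ValueError, match="singular"):
            fit_sar_lag(rng.standard_normal(50), X2, W)


class TestSelectModel:
    def test_generating_subset_wins_aic(self, rng):
        n = 200
        lats = rng.uniform(30, 40, n)
        lons = rng.uniform(0, 10, n)
        W = build_weights(lats, lons, 300.0)
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        exact = contains = 0
        reps = 12
        for _ in range(reps):
            y = 1.0 + 2.0 * X["a"].to_numpy() + 0.4 * rng.standard_normal(n)
            best, table = select_model(y, X, W)
            exact += best.terms == ("intercept", "a")
            contains += "a" in best.terms
        # AIC keeps the generating predictor always and, despite its known
        # tendency to admit a spurious extra term, picks the exact
        # generating subset in the majority of replicates
        assert contains == reps
        assert exact > reps / 2

    def test_single_candidate_trivial(self, rng):
        n = 60
        lats = rng.uniform(30, 34, n)
        lons = rng.uniform(0, 4, n)
        W = build_weights(lats, lons, 200.0)
        X = pd.DataFrame({"a": rng.standard_normal(n)})
        y = X["a"].to_numpy() + 0.1 * rng.standard_normal(n)
        best, table = select_model(y, X, W)
        assert best.terms == ("intercept", "a") and len(table) == 1
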