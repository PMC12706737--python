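"""Distance regression, Moran's I, ordinary kriging and rank-sum tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from harborair import spatial as SP


def make_obs(x, y, values, dist=None):
    return pd.DataFrame({
        "x": x, "y": y, "value": values,
        "distance_to_water": dist if dist is not None else np.abs(x) + 1.0})


class TestDistanceRegression:
    def test_perfect_log_linear_fit(self):
        d = np.array([10.0, 100.0, 1000.0])
        obs = make_obs(d, np.zeros(3), [10.0, 6.0, 2.0], dist=d)
        res = SP.distance_regression(obs)
        assert res["slope"] == pytest.approx(-4.0)
        assert res["r2"] == pytest.approx(1.0)

    def test_constant_response_null_fit(self):
        d = np.array([10.0, 100.0, 1000.0, 5000.0])
        obs = make_obs(d, np.zeros(4), [5.0] * 4, dist=d)
        res = SP.distance_regression(obs)
        assert res["slope"] == pytest.approx(0.0, abs=1e-12)
        assert res["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_r2_invariant_to_affine_response_rescale(self):
        rng = np.random.default_rng(3)
        d = np.exp(rng.uniform(3, 8, 20))
        v = 100.0 - 10.0 * np.log10(d) + rng.normal(0, 5, 20)
        obs1 = make_obs(d, np.zeros(20), v, dist=d)
        obs2 = make_obs(d, np.zeros(20), 3.0 * v + 7.0, dist=d)
        assert SP.distance_regression(obs1)["r2"] == \
            pytest.approx(SP.distance_regression(obs2)["r2"])

    def test_singular_design_rejected(self):
        obs = make_obs(np.full(5, 100.0), np.zeros(5), np.arange(5.0),
                       dist=np.full(5, 100.0))
        with pytest.raises(ValueError, match="singular"):
            SP.distance_regression(obs)


class TestMoransI:
    def test_brute_force_five_points_binary_weights(self):
        """Hand evaluation of the Moran sum with explicit binary weights."""
        values = np.array([1.0, 3.0, 2.0, 8.0, 5.0])
        w = np.array([
            [0, 1, 0, 0, 1],
            [1, 0, 1, 0, 0],
            [0, 1, 0, 1, 0],
            [0, 0, 1, 0, 1],
            [1, 0, 0, 1, 0]], dtype=float)
        n = 5
        z = values - values.mean()
        num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
        expected = (n / w.sum()) * num / (z @ z)
        obs = make_obs(np.arange(5.0), np.zeros(5), values)
        res = SP.morans_i(obs, weights=w, n_perm=99, seed=0)
        assert res["I"] == pytest.approx(expected)
        assert res["expected_I"] == pytest.approx(-0.25)

    def test_spatially_random_field_near_null(self):
        rng = np.random.default_rng(21)
        obs = make_obs(rng.uniform(0, 100, 40), rng.uniform(0, 100, 40),
                       rng.normal(0, 1, 40))
        res = SP.morans_i(obs, n_perm=499, seed=1)
        assert abs(res["I"] - res["expected_I"]) < 0.1
        assert res["p_perm"] > 0.05

    def test_gradient_field_positive_autocorrelation(self):
        x = np.linspace(0, 100, 30)
        rng = np.random.default_rng(22)
        obs = make_obs(x, rng.uniform(0, 10, 30), x + rng.normal(0, 5, 30))
        res = SP.morans_i(obs, n_perm=499, seed=2)
        assert res["I"] > res["expected_I"]
        assert res["p_perm"] < 0.01

    def test_permutation_p_uniform_under_null(self):
        """KS check of the permutation p distribution at reduced n_perm."""
        rng = np.random.default_rng(23)
        xy = rng.uniform(0, 50, size=(15, 2))
        pvals = []
        for rep in range(120):
            obs = make_obs(xy[:, 0], xy[:, 1], rng.normal(0, 1, 15))
            pvals.append(SP.morans_i(obs, n_perm=49, seed=rep)["p_perm"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_coincident_points_rejected(self):
        obs = make_obs(np.array([0.0, 0.0, 1, 2, 3]), np.zeros(5), np.arange(5.0))
        with pytest.raises(ValueError, match="coincident"):
            SP.morans_i(obs, n_perm=9, seed=0)


@pytest.fixture(scope="module")
def scattered():
    rng = np.random.default_rng(31)
    xy = rng.uniform(0, 100, size=(25, 2))
    z = np.sin(xy[:, 0] / 20.0) + 0.5 * np.cos(xy[:, 1] / 15.0)
    return make_obs(xy[:, 0], xy[:, 1], z)


class TestKriging:

    def test_exact_interpolation_at_zero_nugget(self, scattered):
        vgm = {"nugget": 0.0, "psill": 1.0, "range": 30.0}
        res = SP.ordinary_kriging(scattered, variogram=vgm)
        np.testing.assert_allclose(res["predictions"],
                                   scattered["value"].to_numpy(), atol=1e-8)

    def test_weights_sum_to_one_everywhere(self, scattered):
        grid = pd.DataFrame({"x": [10.0, 55.0, 90.0], "y": [10.0, 40.0, 80.0]})
        res = SP.ordinary_kriging(scattered, grid=grid,
                                  variogram={"nugget": 0.1, "psill": 1.0,
                                             "range": 30.0})
        np.testing.assert_allclose(res["weights"].sum(axis=1), 1.0, atol=1e-10)

    def test_constant_field_constant_predictions(self):
        rng = np.random.default_rng(32)
        xy = rng.uniform(0, 100, size=(10, 2))
        obs = make_obs(xy[:, 0], xy[:, 1], np.full(10, 4.2))
        res = SP.ordinary_kriging(obs)
        np.testing.assert_allclose(res["predictions"], 4.2, atol=1e-8)
        assert res["loo_rmse"] == pytest.approx(0.0, abs=1e-8)

    def test_variogram_recovery_from_gaussian_field(self):
        """Exponential-variogram parameters recovered within 30% at n=100."""
        rng = np.random.default_rng(33)
        xy = rng.uniform(0, 200, size=(100, 2))
        true_psill, true_range = 2.0, 25.0
        z = SP.simulate_gaussian_field(xy, 0.0, true_psill, true_range, seed=33)
        emp = SP.empirical_variogram(xy, z)
        fit = SP.fit_variogram(emp)
        assert fit["sill"] == pytest.approx(true_psill, rel=0.3)
        assert fit["range"] == pytest.approx(true_range, rel=0.3)

    def test_too_few_observations_rejected(self):
        obs = make_obs(np.arange(3.0), np.zeros(3), np.arange(3.0))
        with pytest.raises(ValueError):
            SP.ordinary_kriging(obs)


class TestRankSum:
    def test_fully_enumerated_three_vs_three(self):
        """All 20 rank assignments enumerated: extreme split has p = 2/20."""
        res = SP.ranksum_test([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(0.1)

    def test_identical_groups_maximal_p(self):
        res = SP.ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p"] == pytest.approx(1.0)

    def test_exact_agrees_with_scipy_on_untied_data(self):
        rng = np.random.default_rng(41)
        a = rng.normal(0, 1, 5)
        b = rng.normal(1, 1, 6)
        ours = SP.ranksum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours["p"] == pytest.approx(ref.pvalue, abs=0.02)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(42)
        near = rng.lognormal(np.log(800), 0.3, 10)
        far = rng.lognormal(np.log(200), 0.3, 10)
        res = SP.ranksum_test(near, far)
        assert res["p"] < 0.005

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            SP.ranksum_test([1.0], [2.0, 3.0])
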