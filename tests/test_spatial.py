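"""Angular variography, model fitting, permutation tests and kriging."""

import numpy as np
import pytest

import dermadisperse as dd
from dermadisperse._angles import UNIFORM_AXIAL_SILL, axial_difference
from dermadisperse.spatial import (
    MitosisAngleField,
    Variogram,
    empirical_pairwise_variogram,
)

CENTRE = (200.0, 200.0)
RADIAL_UNIFORM_SILL = 675.0  # E[(U1-U2)^2]/2 for two U[0,90] relative angles


class TestAxisAngles:
    @pytest.mark.parametrize("a,b,expect", [
        ((0, 0), (1, 0), 0.0),
        ((0, 0), (0, 1), 90.0),
        ((0, 0), (1, 1), 45.0),
        ((2, 2), (1, 1), 45.0),   # swapped order, same axis
    ])
    def test_axis_angle_values(self, a, b, expect):
        assert dd.mitosis_axis_angle(a, b) == pytest.approx(expect)

    def test_coincident_daughters_rejected(self):
        with pytest.raises(ValueError):
            dd.mitosis_axis_angle((1, 1), (1, 1))

    @pytest.mark.parametrize("angle,expect", [(0.0, 0.0), (90.0, 90.0), (45.0, 45.0)])
    def test_relative_angle_radial_tangential(self, angle, expect):
        # division at (100, 0), condensate at origin: radial line is the x axis
        got = dd.angle_relative_to_condensate(((100.0, 0.0), angle), (0.0, 0.0))
        assert got == pytest.approx(expect)

    def test_event_at_centre_rejected(self):
        with pytest.raises(ValueError):
            dd.angle_relative_to_condensate(((0.0, 0.0), 10.0), (0.0, 0.0))


class TestEmpiricalVariogram:
    def test_constant_field_zero_semivariance(self, rng):
        f = MitosisAngleField(rng.uniform(0, 400, 100), rng.uniform(0, 400, 100),
                              np.full(100, 37.0))
        vg = dd.empirical_angular_variogram(f, CENTRE)
        assert np.allclose(vg.gamma, 0.0)

    def test_single_bin_matches_bruteforce_pairwise(self):
        angles = np.array([0.0, 30.0, 60.0, 90.0])
        # 4 samples at nearly the same distance from the centre -> one bin
        f = MitosisAngleField(np.array([210.0, 190.0, 200.0, 200.0]),
                              np.array([200.0, 200.0, 210.0, 190.0]), angles)
        vg = dd.empirical_angular_variogram(f, CENTRE, n_bins=1, min_pairs=1)
        d2 = [axial_difference(a, b) ** 2
              for i, a in enumerate(angles) for b in angles[i + 1:]]
        assert vg.gamma[0] == pytest.approx(np.mean(d2) / 2.0, rel=1e-12)
        assert vg.n_pairs[0] == 6

    def test_uniform_axial_field_flat_at_theoretical_sill(self):
        rng = np.random.default_rng(7)
        f = MitosisAngleField(rng.uniform(0, 400, 4000), rng.uniform(0, 400, 4000),
                              rng.uniform(0, 180, 4000))
        vg = dd.empirical_angular_variogram(f, CENTRE, frame="absolute")
        assert np.all(np.abs(vg.gamma / UNIFORM_AXIAL_SILL - 1) < 0.10)

    def test_variogram_invariant_to_axial_relabelling(self, rng):
        x, y = rng.uniform(0, 400, 200), rng.uniform(0, 400, 200)
        ang = rng.uniform(0, 180, 200)
        flip = rng.random(200) < 0.5
        vg1 = dd.empirical_angular_variogram(MitosisAngleField(x, y, ang), CENTRE)
        vg2 = dd.empirical_angular_variogram(
            MitosisAngleField(x, y, np.where(flip, ang + 180.0, ang)), CENTRE)
        np.testing.assert_allclose(vg1.gamma, vg2.gamma, rtol=1e-12)

    def test_directional_cone_filters_samples(self, rng):
        x, y = rng.uniform(0, 400, 500), rng.uniform(0, 400, 500)
        f = MitosisAngleField(x, y, rng.uniform(0, 180, 500))
        omni = dd.empirical_angular_variogram(f, CENTRE, n_bins=5, min_pairs=3)
        d0 = dd.empirical_angular_variogram(f, CENTRE, n_bins=5, min_pairs=3,
                                            direction=0.0)
        assert d0.n_pairs.sum() < omni.n_pairs.sum()


class TestVariogramFit:
    def test_flat_variogram_is_pure_nugget(self):
        h = np.linspace(10, 300, 10)
        vg = Variogram(h, np.full(10, 500.0), np.full(10, 50))
        m = dd.fit_variogram_model(vg, 1)
        assert m.sills[0] <= 1e-6 * m.total_sill or m.nugget_to_sill_ratio > 0.99
        assert m.nugget == pytest.approx(500.0, rel=1e-6)

    def test_noiseless_nested_model_recovered_within_5pct(self):
        h = np.linspace(10, 300, 15)
        g = 70 * (1 - np.exp(-h / 20)) + 30 * (1 - np.exp(-h / 59))
        m = dd.fit_variogram_model(Variogram(h, g, np.full(15, 100)), 2, seed=0)
        assert m.nugget == pytest.approx(0.0, abs=0.5)
        assert m.sills[0] == pytest.approx(70.0, rel=0.05)
        assert m.sills[1] == pytest.approx(30.0, rel=0.05)
        assert m.effective_ranges[0] == pytest.approx(60.0, rel=0.05)
        assert m.effective_ranges[1] == pytest.approx(177.0, rel=0.05)
        assert m.variance_fractions[0] == pytest.approx(0.70, abs=0.02)

    def test_too_few_bins_rejected(self):
        vg = Variogram(np.array([10.0, 20.0, 30.0]), np.ones(3), np.ones(3, int))
        with pytest.raises(ValueError):
            dd.fit_variogram_model(vg, 1)


class TestPermutationRangeTest:
    def test_structured_field_rejects_null(self):
        f, _ = dd.gen_mitosis_field(dd.AngleFieldParams(
            n_samples=600, tangential_concentration_near=4.0, decay_range=60.0,
            seed=4))
        res = dd.permutation_range_test(f, CENTRE, n_perm=200, seed=5)
        assert res.p_value < 0.01
        assert res.observed_integral_range > 0

    def test_constant_field_degenerate(self, rng):
        f = MitosisAngleField(rng.uniform(0, 400, 60), rng.uniform(0, 400, 60),
                              np.full(60, 90.0))
        with pytest.raises(ValueError):
            dd.permutation_range_test(f, CENTRE, n_perm=50)

    def test_null_rejection_rate_calibrated(self):
        """Under i.i.d. angles the rejection rate at q = 0.1 stays within
        3 Monte Carlo standard errors of 0.1 (200 replicates)."""
        q, n_rep, n_perm = 0.1, 200, 99
        rejections = 0
        for rep in range(n_rep):
            f, _ = dd.gen_mitosis_field(dd.AngleFieldParams(
                n_samples=120, tangential_concentration_near=0.0, seed=3000 + rep))
            res = dd.permutation_range_test(f, CENTRE, n_perm=n_perm,
                                            seed=rep, n_bins=10)
            rejections += res.p_value < q
        rate = rejections / n_rep
        se = np.sqrt(q * (1 - q) / n_rep)
        assert abs(rate - q) <= 3 * se


class TestOrdinaryKriging:
    MODEL = dd.VariogramModel(nugget=0.0, sills=(100.0,), ranges=(40.0,))

    def test_zero_nugget_exact_interpolation(self):
        f = MitosisAngleField(np.array([0.0, 100.0, 50.0]),
                              np.array([0.0, 0.0, 80.0]),
                              np.array([10.0, 50.0, 120.0]))
        pred, W = dd.ordinary_kriging(f, self.MODEL, [(0.0, 0.0), (50.0, 80.0)])
        np.testing.assert_allclose(pred, [10.0, 120.0], atol=1e-8)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-10)

    def test_constant_field_constant_prediction(self, rng):
        f = MitosisAngleField(rng.uniform(0, 100, 20), rng.uniform(0, 100, 20),
                              np.full(20, 77.0))
        pred, W = dd.ordinary_kriging(f, self.MODEL, rng.uniform(0, 100, (30, 2)))
        np.testing.assert_allclose(pred, 77.0, atol=1e-8)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-10)

    def test_two_sample_weights_match_direct_linear_solve(self):
        f = MitosisAngleField(np.array([0.0, 60.0]), np.array([0.0, 0.0]),
                              np.array([30.0, 150.0]))
        target = (20.0, 10.0)
        _, W = dd.ordinary_kriging(f, self.MODEL, [target])
        g = self.MODEL.gamma
        d01 = 60.0
        A = np.array([[0.0, g(d01), 1.0], [g(d01), 0.0, 1.0], [1.0, 1.0, 0.0]])
        b = np.array([g(np.hypot(20.0, 10.0)), g(np.hypot(40.0, 10.0)), 1.0])
        w_direct = np.linalg.solve(A, b)[:2]
        np.testing.assert_allclose(W[0], w_direct, atol=1e-10)

    def test_colocated_samples_averaged_not_singular(self):
        f = MitosisAngleField(np.array([0.0, 0.0, 50.0]), np.array([0.0, 0.0, 0.0]),
                              np.array([20.0, 40.0, 100.0]))
        with pytest.warns(UserWarning):
            pred, W = dd.ordinary_kriging(f, self.MODEL, [(25.0, 0.0)])
        assert np.isfinite(pred).all()


class TestRandomnessMap:
    def test_iid_field_mostly_random_under_quantile_rule(self):
        f, _ = dd.gen_mitosis_field(dd.AngleFieldParams(
            n_samples=200, tangential_concentration_near=0.0, seed=12))
        vg = empirical_pairwise_variogram(f, n_bins=10, min_pairs=20)
        m = dd.fit_variogram_model(vg, 1, weighting="npairs_h2")
        rmap = dd.local_randomness_map(f, m, n_perm=60, grid=40, alpha=0.01, seed=4)
        assert rmap.randomness_ratio > 0.9

    def test_patch_field_mostly_nonrandom_under_mean_test(self):
        patches = [(i * 100, 0, (i + 1) * 100, 400, (20.0, 70.0)[i % 2], 6.0)
                   for i in range(4)]
        f, _ = dd.gen_mitosis_field(dd.AngleFieldParams(
            n_samples=300, patches=patches, seed=11))
        vg = empirical_pairwise_variogram(f, n_bins=10, min_pairs=20)
        m = dd.fit_variogram_model(vg, 1, weighting="npairs_h2")
        rmap = dd.local_randomness_map(f, m, n_perm=60, grid=40, alpha=0.01,
                                       seed=3, method="mean_test")
        assert rmap.randomness_ratio < 0.2
        assert rmap.correlated_fraction == pytest.approx(1 - rmap.randomness_ratio)

    def test_too_few_permutations_rejected(self):
        f, _ = dd.gen_mitosis_field(dd.AngleFieldParams(n_samples=50, seed=1))
        m = dd.VariogramModel(nugget=10.0, sills=(100.0,), ranges=(40.0,))
        with pytest.raises(ValueError):
            dd.local_randomness_map(f, m, n_perm=10)
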