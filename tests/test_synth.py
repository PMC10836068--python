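import numpy as np
import pytest
from scipy import optimize

from flimetab.config import AcquisitionConfig
from flimetab.decay_model import DecayParams, bin_probabilities
from flimetab.errors import PartitionError
from flimetab.synth import (ParameterMaps, Region, SceneSpec, bimodal_scene,
                            build_scene, expected_decay_counts,
                            simulate_decay_cube, simulate_intensity_images,
                            tumor_scene, uniform_scene)
from flimetab.pixelfit import intensity_mask


class TestBuildScene:
    def test_zero_variance_region_is_exactly_constant(self):
        maps = build_scene(uniform_scene((8, 8), a1_mean=0.7, a1_sd=0.0))
        assert (maps.a1 == 0.7).all()
        assert (maps.a2 == 1.0 - 0.7).all()  # complement, exact in floats
        np.testing.assert_allclose(maps.a2, 0.3, atol=1e-15)

    def test_bimodal_scene_region_means_and_two_modes(self):
        spec = bimodal_scene((64, 64), a1_means=(0.55, 0.75), a1_sd=0.02,
                             seed=5)
        maps = build_scene(spec)
        for region, mean in zip(spec.regions, (0.55, 0.75)):
            assert maps.a1[region.mask].mean() == pytest.approx(mean,
                                                                abs=0.01)
        # the pooled histogram has peaks at both planted means separated
        # by a depleted valley
        counts, edges = np.histogram(maps.a1.ravel(),
                                     bins=np.arange(0.45, 0.86, 0.02))
        centers = (edges[:-1] + edges[1:]) / 2
        valley = counts[np.abs(centers - 0.65) < 0.02].max()
        assert counts[np.abs(centers - 0.55) < 0.02].max() > 10 * valley
        assert counts[np.abs(centers - 0.75) < 0.02].max() > 10 * valley

    def test_out_of_range_a1_mean_is_domain_error(self):
        with pytest.raises(ValueError):
            build_scene(uniform_scene((8, 8), a1_mean=1.2))

    def test_overlapping_regions_rejected(self):
        full = np.ones((8, 8), dtype=bool)
        r = Region("a", full, 0.6, 0.0, 0.3, 2.5, 100.0)
        r2 = Region("b", full, 0.7, 0.0, 0.3, 2.5, 100.0)
        with pytest.raises(PartitionError):
            build_scene(SceneSpec([r, r2]))

    def test_incomplete_cover_rejected(self):
        half = np.zeros((8, 8), dtype=bool)
        half[:4] = True
        r = Region("a", half, 0.6, 0.0, 0.3, 2.5, 100.0)
        with pytest.raises(PartitionError):
            build_scene(SceneSpec([r]))

    def test_deterministic_given_seed(self):
        a = build_scene(uniform_scene((16, 16), a1_sd=0.05, seed=3))
        b = build_scene(uniform_scene((16, 16), a1_sd=0.05, seed=3))
        assert np.array_equal(a.a1, b.a1)

    def test_ground_truth_satisfies_map_invariants(self):
        maps = build_scene(tumor_scene((32, 32), seed=2))
        maps.validate()


class TestSimulateDecayCube:
    def test_expected_counts_conserve_photon_budget(self, small_acq):
        # normalization of the bin probabilities makes the time-sum of
        # expected counts equal each pixel's photon budget exactly
        truth = build_scene(uniform_scene((16, 16), a1_sd=0.05, seed=1))
        expected = expected_decay_counts(truth, small_acq)
        np.testing.assert_allclose(
            expected.sum(axis=2), small_acq.mean_photons_per_pixel,
            rtol=1e-12)

    def test_pure_short_component_single_exp_refit(self, acq):
        # a1 = 1 everywhere: the noiseless expected histogram must be
        # refittable by an independent single-exponential ML search to
        # the planted 0.3 ns (folding is negligible at this lifetime)
        shape = (4, 4)
        ones = np.ones(shape)
        truth = ParameterMaps(a1=ones.copy(), a2=0 * ones,
                              tau1=0.3 * ones, tau2=2.5 * ones,
                              tau_m=0.3 * ones, intensity=100 * ones)
        y = expected_decay_counts(truth, acq)[0, 0]

        def nll(tau):
            p = bin_probabilities(DecayParams(1.0, tau, 6.0), acq,
                                  fold=False)
            return -(y @ np.log(p))

        res = optimize.minimize_scalar(nll, bounds=(0.05, 1.0),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        assert res.x == pytest.approx(0.3, abs=1e-6)

    def test_grand_mean_total_counts_near_budget(self):
        acq = AcquisitionConfig(frame_shape=(64, 64),
                                mean_photons_per_pixel=5000)
        truth = build_scene(uniform_scene((64, 64), a1_sd=0.0, seed=0))
        cube = simulate_decay_cube(truth, acq, seed=11)
        grand_mean = cube.total_counts().mean()
        # Poisson: sd of the average of 4096 pixel totals
        assert abs(grand_mean - 5000) < 3 * np.sqrt(5000 / 4096)

    def test_deterministic_given_seed(self, small_acq):
        truth = build_scene(uniform_scene((16, 16), a1_sd=0.02, seed=4))
        a = simulate_decay_cube(truth, small_acq, seed=9)
        b = simulate_decay_cube(truth, small_acq, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_cube_invariants(self, small_acq):
        truth = build_scene(uniform_scene((16, 16), seed=4))
        cube = simulate_decay_cube(truth, small_acq, seed=9)
        cube.validate()
        assert cube.counts.shape == (16, 16, small_acq.n_time_bins)


class TestIntensityImages:
    def test_zero_scale_background_is_exactly_zero(self, small_acq):
        spec = tumor_scene((16, 16), background_intensity=0.0, seed=1)
        truth = build_scene(spec)
        egfp, mcherry = simulate_intensity_images(truth, small_acq, seed=2)
        bg = spec.regions[1].mask
        assert (egfp[bg] == 0).all() and (mcherry[bg] == 0).all()

    def test_otsu_threshold_recovers_tumor_region(self):
        spec = tumor_scene((64, 64), tumor_intensity=1000.0,
                           background_intensity=10.0, seed=3)
        truth = build_scene(spec)
        acq = AcquisitionConfig(frame_shape=(64, 64))
        egfp, _ = simulate_intensity_images(truth, acq, seed=3)
        mask = intensity_mask(egfp.astype(float), "otsu")
        agreement = (mask.include == spec.regions[0].mask).mean()
        assert agreement >= 0.99

    def test_deterministic_given_seed(self, small_acq):
        truth = build_scene(tumor_scene((16, 16), seed=1))
        a = simulate_intensity_images(truth, small_acq, seed=7)
        b = simulate_intensity_images(truth, small_acq, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
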