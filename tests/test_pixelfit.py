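import numpy as np
import pytest

from flimetab.config import AcquisitionConfig
from flimetab.decay_model import DecayParams, model_bin_probabilities
from flimetab.errors import EmptySelectionError
from flimetab.experiments import fit_scene
from flimetab.pixelfit import (FitOptions, ROIMask, fit_cube, fit_pixel,
                               intensity_mask, spatial_bin)
from flimetab.synth import (DecayCube, build_scene, simulate_decay_cube,
                            uniform_scene)


def make_cube(counts, acq):
    counts = np.asarray(counts)
    return DecayCube(counts=counts.astype(np.uint32),
                     time_axis_ns=acq.time_axis_ns[:counts.shape[2]],
                     acquisition=acq)


def noiseless_cube(params, acq, photons=5000.0):
    """Integer cube whose identical pixels hold the rounded expectation."""
    p = model_bin_probabilities(params, acq)
    pixel = np.round(photons * p).astype(np.uint32)
    counts = np.broadcast_to(pixel, acq.frame_shape + pixel.shape).copy()
    return make_cube(counts, acq)


class TestSpatialBin:
    def test_uniform_counts_quadruple_in_interior(self, small_acq):
        cube = make_cube(np.ones((6, 6, small_acq.n_time_bins)), small_acq)
        binned = spatial_bin(cube, 2)
        assert (binned.counts[:-1, :-1] == 4).all()  # interior + top edges
        assert (binned.counts[-1, -1] == 1).all()    # corner sub-window

    def test_anchor_pixel_sums_its_window(self, small_acq):
        counts = np.zeros((2, 2, small_acq.n_time_bins), dtype=int)
        for k, total in enumerate([1, 2, 3, 4]):
            counts[k // 2, k % 2, 0] = total
        binned = spatial_bin(make_cube(counts, small_acq), 2)
        assert binned.total_counts()[0, 0] == 10

    def test_totals_never_decrease(self, small_acq, rng):
        counts = rng.poisson(3.0, size=(8, 8, small_acq.n_time_bins))
        cube = make_cube(counts, small_acq)
        binned = spatial_bin(cube, 2)
        assert (binned.total_counts() >= cube.total_counts()).all()

    def test_block_mode_conserves_grand_total(self, small_acq, rng):
        counts = rng.poisson(3.0, size=(8, 8, small_acq.n_time_bins))
        cube = make_cube(counts, small_acq)
        blocked = spatial_bin(cube, 2, mode="block")
        assert blocked.counts.shape[:2] == (4, 4)
        assert blocked.counts.sum() == cube.counts.sum()

    def test_binning_noiseless_uniform_cube_leaves_fit_unchanged(self, acq):
        truth = DecayParams(0.6, 0.35, 2.2)
        acq4 = AcquisitionConfig(frame_shape=(4, 4))
        cube = noiseless_cube(truth, acq4, photons=5000)
        unbinned = fit_pixel(cube.counts[1, 1], acq4)
        binned = spatial_bin(cube, 2)
        rebinned = fit_pixel(binned.counts[1, 1], acq4)
        assert rebinned.params.a1 == pytest.approx(unbinned.params.a1,
                                                   rel=1e-6)
        assert rebinned.params.tau1 == pytest.approx(unbinned.params.tau1,
                                                     rel=1e-6)
        assert rebinned.params.tau2 == pytest.approx(unbinned.params.tau2,
                                                     rel=1e-6)


class TestIntensityMask:
    def test_zero_threshold_includes_everything(self, rng):
        image = rng.poisson(20.0, size=(16, 16)).astype(float)
        mask = intensity_mask(image, ("fixed", 0.0))
        assert mask.include.all()

    def test_threshold_above_maximum_warns_and_is_empty(self, rng):
        image = rng.poisson(20.0, size=(16, 16)).astype(float)
        with pytest.warns(UserWarning):
            mask = intensity_mask(image, ("fixed", image.max() + 1))
        assert mask.empty

    def test_raising_threshold_never_adds_pixels(self, rng):
        image = rng.poisson(50.0, size=(16, 16)).astype(float)
        previous = intensity_mask(image, ("fixed", 0.0)).include
        for thresh in (30.0, 50.0, 70.0):
            current = intensity_mask(image, ("fixed", thresh)).include
            assert not (current & ~previous).any()
            previous = current

    def test_quantile_rule_records_provenance(self, rng):
        image = rng.poisson(20.0, size=(8, 8)).astype(float)
        mask = intensity_mask(image, ("quantile", 0.5))
        assert "quantile" in mask.provenance


class TestFitPixel:
    @pytest.mark.parametrize("truth", [
        DecayParams(0.6, 0.35, 2.2),
        DecayParams(0.8, 0.3, 2.5),
        DecayParams(0.4, 0.2, 1.8),
    ])
    def test_noiseless_recovery_within_1e3_relative(self, truth, acq):
        y = 5000 * model_bin_probabilities(truth, acq)
        result = fit_pixel(y, acq)
        assert result.fit_ok
        assert result.params.a1 == pytest.approx(truth.a1, rel=1e-3)
        assert result.params.tau1 == pytest.approx(truth.tau1, rel=1e-3)
        assert result.params.tau2 == pytest.approx(truth.tau2, rel=1e-3)

    def test_high_photon_poisson_recovery_within_1_percent(self, acq):
        truth = DecayParams(0.6, 0.35, 2.2)
        rng = np.random.default_rng(7)
        y = rng.poisson(1e6 * model_bin_probabilities(truth, acq))
        result = fit_pixel(y, acq)
        assert result.params.a1 == pytest.approx(truth.a1, rel=0.01)
        assert result.params.tau1 == pytest.approx(truth.tau1, rel=0.01)
        assert result.params.tau2 == pytest.approx(truth.tau2, rel=0.01)

    def test_noiseless_recovery_with_gaussian_irf(self):
        acq = AcquisitionConfig(irf_sigma_ns=0.1)
        truth = DecayParams(0.6, 0.35, 2.2)
        y = 20000 * model_bin_probabilities(truth, acq)
        result = fit_pixel(y, acq)
        assert result.params.a1 == pytest.approx(truth.a1, rel=1e-3)
        assert result.params.tau2 == pytest.approx(truth.tau2, rel=1e-3)

    def test_all_zero_histogram_flagged_unfit(self, acq):
        result = fit_pixel(np.zeros(acq.n_time_bins), acq)
        assert result.params is None
        assert not result.fit_ok
        assert "min_photons" in result.message


class TestFitCube:
    def test_identical_noiseless_pixels_give_constant_maps(self):
        acq = AcquisitionConfig(frame_shape=(4, 4))
        truth = DecayParams(0.6, 0.35, 2.2)
        cube = noiseless_cube(truth, acq)
        mask = ROIMask(np.ones((4, 4), dtype=bool))
        maps = fit_cube(cube, mask, acq)
        assert maps.fit_ok.all()
        # pixels differ only in the edge sub-window scale, which leaves
        # the profiled objective's optimum unchanged
        assert np.ptp(maps.a1) < 1e-6
        single = fit_pixel(spatial_bin(cube, 2).counts[0, 0], acq)
        assert maps.a1[0, 0] == single.params.a1

    def test_masked_out_pixels_carry_missing_values(self):
        acq = AcquisitionConfig(frame_shape=(4, 4))
        cube = noiseless_cube(DecayParams(0.6, 0.35, 2.2), acq)
        include = np.zeros((4, 4), dtype=bool)
        include[0, 0] = True
        maps = fit_cube(cube, ROIMask(include), acq)
        assert np.isfinite(maps.a1[0, 0])
        assert np.isnan(maps.a1[~include]).all()
        assert not maps.fit_ok[~include].any()

    def test_empty_mask_raises_empty_selection(self):
        acq = AcquisitionConfig(frame_shape=(4, 4))
        cube = noiseless_cube(DecayParams(0.6, 0.35, 2.2), acq)
        with pytest.raises(EmptySelectionError):
            fit_cube(cube, ROIMask(np.zeros((4, 4), dtype=bool)), acq)

    def test_fitted_maps_satisfy_parameter_invariants(self):
        acq = AcquisitionConfig(frame_shape=(8, 8),
                                mean_photons_per_pixel=5000)
        truth = build_scene(uniform_scene((8, 8), a1_sd=0.03, seed=2))
        fitted = fit_scene(truth, acq, seed=3)
        assert fitted.fit_ok.all()
        fitted.validate()
        ok = fitted.valid_mask()
        assert (fitted.tau1[ok] < fitted.tau2[ok]).all()

    def test_estimator_error_shrinks_with_photon_budget(self):
        # constant-a1 scene so the measured error is photon noise alone
        # (with per-pixel a1 scatter the 2x2 binning imposes an averaging
        # floor that masks the budget trend)
        medians = []
        for budget in (500, 5000, 50000):
            acq = AcquisitionConfig(frame_shape=(32, 32),
                                    mean_photons_per_pixel=budget)
            truth = build_scene(uniform_scene((32, 32), a1_mean=0.65,
                                              a1_sd=0.0, seed=3))
            fitted = fit_scene(truth, acq, seed=11)
            ok = fitted.valid_mask()
            medians.append(np.median(np.abs(fitted.a1[ok] - truth.a1[ok])))
        assert medians[0] > medians[1] > medians[2]
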