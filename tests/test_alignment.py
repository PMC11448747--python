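"""Tests for measurement normalization, curve inversion and the alignment loop."""

import warnings

import numpy as np
import pytest

from rtmalign import (
    AlignmentWarning,
    MeasurementError,
    MeasurementSet,
    NonMonotonicCurveError,
    OutOfRangeError,
    SyntheticScene,
    axial_resolution,
    estimate,
    forward_measurements,
    interpolate_d_sample,
    normalized_measurement,
    run_simulated_alignment,
    working_distance_error,
)

F_O = 4.5


class TestNormalizedMeasurement:
    def test_identical_cameras_reduce_to_pixel_ratio(self):
        ms = MeasurementSet(
            distances_px={"a": 1000.0, "b": 995.0, "c": 990.0},
            pixel_pitch_um={"a": 1.12, "b": 1.12, "c": 1.12},
        )
        ratios = normalized_measurement(ms, "a")
        assert ratios == pytest.approx({"a": 1.0, "b": 0.995, "c": 0.990})

    def test_pixel_pitch_compensation(self):
        ms = MeasurementSet(
            distances_px={"a": 1000.0, "b": 995.0, "c": 189.2},
            pixel_pitch_um={"a": 1.12, "b": 1.12, "c": 5.86},
        )
        ratios = normalized_measurement(ms, "a")
        assert ratios["c"] == pytest.approx((189.2 * 5.86) / (1000.0 * 1.12))

    def test_equal_distances_are_the_aligned_fixed_point(self):
        ms = MeasurementSet(
            distances_px={"a": 892.9, "b": 892.9},
            pixel_pitch_um={"a": 1.12, "b": 1.12},
        )
        assert set(normalized_measurement(ms, "a").values()) == {1.0}

    def test_invalid_measurements_rejected(self):
        with pytest.raises(MeasurementError):
            MeasurementSet(distances_px={"a": -5.0}, pixel_pitch_um={"a": 1.12})
        ms = MeasurementSet(distances_px={"a": 10.0}, pixel_pitch_um={"a": 1.12})
        with pytest.raises(MeasurementError):
            normalized_measurement(ms, "missing")

    def test_csv_round_trip(self, tmp_path):
        ms = MeasurementSet(
            distances_px={"a": 892.9, "b": 880.1},
            pixel_pitch_um={"a": 1.12, "b": 1.12},
        )
        path = tmp_path / "m.csv"
        ms.to_csv(path)
        back = MeasurementSet.from_csv(path)
        assert back.distances_px == pytest.approx(ms.distances_px)
        assert back.pixel_pitch_um == pytest.approx(ms.pixel_pitch_um)


class TestInterpolation:
    def test_on_grid_ratio_inverts_exactly(self, curves):
        c = curves["bf400"]
        i = int(np.searchsorted(c.d_sample_grid, 4.48))
        ratio = c.normalized[i]
        assert interpolate_d_sample(c, float(ratio)) == pytest.approx(
            c.d_sample_grid[i], abs=1e-12
        )

    def test_unit_ratio_maps_to_focal_length(self, curves):
        assert interpolate_d_sample(curves["bf400"], 1.0) == pytest.approx(
            F_O, abs=1e-9
        )

    def test_off_grid_round_trip_within_one_step(self, config, curves):
        true_ds = 4.4605  # deliberately off the 1 um grid
        ms = forward_measurements(config, SyntheticScene(true_d_sample=true_ds))
        ratios = normalized_measurement(ms, "bf300")
        recovered = interpolate_d_sample(curves["bf400"], ratios["bf400"])
        assert recovered == pytest.approx(true_ds, abs=1e-3)

    def test_out_of_range_ratio_fails_loudly(self, curves):
        with pytest.raises(OutOfRangeError, match="wider"):
            interpolate_d_sample(curves["bf400"], 50.0)

    def test_non_monotonic_curve_is_ambiguous(self, curves):
        from dataclasses import replace

        c = curves["bf400"]
        broken = replace(c, normalized=np.abs(c.normalized - 1.0) + 1.0)
        with pytest.raises(NonMonotonicCurveError):
            interpolate_d_sample(broken, 1.05)


class TestWorkingDistanceError:
    @pytest.mark.parametrize(
        "interp, expected", [(4.5, 0.0), (4.62, +0.12), (4.38, -0.12)]
    )
    def test_sign_convention(self, interp, expected):
        assert working_distance_error(interp, F_O) == pytest.approx(expected)

    def test_positive_error_means_too_far(self, config, curves):
        ms = forward_measurements(config, SyntheticScene(true_d_sample=4.53))
        result = estimate(config, ms, curves)
        assert result.working_distance_error_mm > 0
        assert result.direction == "too far away"

    def test_negative_error_means_too_close(self, config, curves):
        ms = forward_measurements(config, SyntheticScene(true_d_sample=4.46))
        result = estimate(config, ms, curves)
        assert result.working_distance_error_mm < 0
        assert result.direction == "too close"


class TestAxialResolution:
    def test_reference_wavelength_and_na(self):
        assert axial_resolution(532.0, 0.65) == pytest.approx(2.518, abs=5e-4)

    def test_unit_na_gives_twice_the_wavelength(self):
        assert axial_resolution(532.0, 1.0) == pytest.approx(0.532 * 2)

    def test_strictly_decreasing_in_na(self):
        nas = np.linspace(0.2, 1.4, 25)
        dz = [axial_resolution(532.0, na) for na in nas]
        assert np.all(np.diff(dz) < 0)

    def test_unit_safety_of_convergence_comparison(self, config, curves):
        # a 3 um true offset is larger than dz = 2.518 um: must NOT converge
        # (a mm-vs-um confusion would call 0.003 mm < 2.518 "converged")
        ms = forward_measurements(config, SyntheticScene(true_d_sample=F_O + 0.003))
        result = estimate(config, ms, curves)
        assert not result.converged
        # and a 1 um offset is within dz: must converge
        ms = forward_measurements(config, SyntheticScene(true_d_sample=F_O + 0.001))
        assert estimate(config, ms, curves).converged


class TestEstimate:
    def test_fixed_point_at_focal_distance(self, config, curves):
        ms = forward_measurements(config, SyntheticScene(true_d_sample=F_O))
        result = estimate(config, ms, curves)
        assert result.working_distance_error_mm == pytest.approx(0.0, abs=1e-9)
        assert result.converged
        assert result.direction == "aligned"

    @pytest.mark.parametrize("true_ds", [4.35, 4.42, 4.47, 4.52, 4.54])
    def test_noiseless_round_trip_recovers_truth(self, config, curves, true_ds):
        ms = forward_measurements(config, SyntheticScene(true_d_sample=true_ds))
        result = estimate(config, ms, curves)
        assert result.d_sample_interpolated == pytest.approx(true_ds, abs=1e-3)
        assert result.working_distance_error_mm == pytest.approx(
            true_ds - F_O, abs=1e-3
        )

    def test_cross_check_channels_agree_when_consistent(self, config, curves):
        ms = forward_measurements(config, SyntheticScene(true_d_sample=4.44))
        result = estimate(config, ms, curves)
        spread = max(result.per_channel_d_sample.values()) - min(
            result.per_channel_d_sample.values()
        )
        assert spread < 1e-3

    def test_discrepant_channels_trigger_warning(self, config, curves):
        ms = forward_measurements(config, SyntheticScene(true_d_sample=4.44))
        distances = dict(ms.distances_px)
        distances["bf350"] *= 1.02  # corrupt one channel by 2%
        bad = MeasurementSet(distances_px=distances, pixel_pitch_um=ms.pixel_pitch_um)
        with pytest.warns(AlignmentWarning, match="spread"):
            estimate(config, bad, curves)

    def test_report_contains_key_quantities(self, config, curves):
        ms = forward_measurements(config, SyntheticScene(true_d_sample=4.44))
        text = estimate(config, ms, curves).report()
        assert "working distance error" in text
        assert "too close" in text
        assert "2.518" in text


class TestSimulatedAlignment:
    def test_zero_noise_converges_after_one_correction(self, config, curves):
        for offset in (-0.1, 0.045):
            traj = run_simulated_alignment(
                config, F_O + offset, noise_sd=0.0, max_iterations=5, curves=curves
            )
            assert traj[-1].converged
            assert traj[-1].iteration <= 2  # one correction + one confirming pass
            # the single correction lands within the interpolation error bound
            assert abs(traj[-1].true_d_sample - F_O) < 1e-3

    def test_zero_offset_converges_immediately(self, config, curves):
        traj = run_simulated_alignment(
            config, F_O, noise_sd=0.0, max_iterations=5, curves=curves
        )
        assert len(traj) == 1 and traj[0].converged

    def test_zero_noise_error_contracts(self, config, curves):
        traj = run_simulated_alignment(
            config, F_O - 0.1, noise_sd=0.0, max_iterations=5, curves=curves
        )
        offsets = [abs(r.true_d_sample - F_O) for r in traj]
        assert np.all(np.diff(offsets) <= 0)

    def test_fixed_seed_is_reproducible(self, config, curves):
        kwargs = dict(noise_sd=0.005, max_iterations=8, seed=42, curves=curves)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AlignmentWarning)
            a = run_simulated_alignment(config, F_O - 0.1, **kwargs)
            b = run_simulated_alignment(config, F_O - 0.1, **kwargs)
        assert a == b

    def test_non_convergence_reported_not_raised(self, config, curves):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AlignmentWarning)
            traj = run_simulated_alignment(
                config, F_O - 0.1, noise_sd=0.005, max_iterations=1, seed=7,
                curves=curves,
            )
        assert len(traj) == 1
        assert not traj[-1].converged
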