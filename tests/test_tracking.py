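import numpy as np
import pytest

from needletrack import (
    PeakObservation,
    TrackingImage,
    build_tracking_images,
    estimate_lateral,
    estimate_tip,
    find_peak,
    make_overlay,
    precompute_tof_grid,
    simulate_tof,
    sos_water,
)
from needletrack.geometry import SIDE_ARRAYS

FS = 1.0e8
C = 1540.0


def image_with(entries, n_samples=4000, n_cols=32):
    amp = np.zeros((n_samples, n_cols))
    for (row, col), value in entries.items():
        amp[row, col] = value
    return TrackingImage(1, amp, FS, C)


def peaks_from_tofs(tofs, h=15, w=1.0):
    return [
        PeakObservation(h=float(h), v=t * C * 1e3, w=wk, t_m=t, h_element=h)
        for t, wk in zip(tofs, np.broadcast_to(w, (len(tofs),)))
    ]


class TestImages:
    def test_128_sequences_give_4_images_of_32_columns(self, geometry):
        decoded = np.random.default_rng(0).normal(size=(128, 500))
        images = build_tracking_images(decoded, geometry, C)
        assert len(images) == 4
        for k, im in enumerate(images):
            assert im.amplitudes.shape == (500, 32)
            assert im.side_array_id == k + 1
            # column c of image k is exactly element k*32+c's sequence
            np.testing.assert_array_equal(im.amplitudes[:, 7], decoded[k * 32 + 7])

    def test_wrong_element_count_rejected(self, geometry):
        with pytest.raises(ValueError):
            build_tracking_images(np.zeros((127, 100)), geometry, C)


class TestFindPeak:
    def test_single_entry_distance(self):
        peak = find_peak(image_with({(1000, 5): 2.0}))
        assert peak.h == 5
        assert peak.v == pytest.approx(1000 / FS * C * 1e3)  # 15.4 mm
        assert peak.w == pytest.approx(2.0)
        assert peak.t_m == pytest.approx(peak.v * 1e-3 / C)

    def test_tie_breaks_toward_earlier_sample(self):
        peak = find_peak(image_with({(900, 3): 1.0, (1000, 3): 1.0}))
        assert peak.v == pytest.approx(900 / FS * C * 1e3)

    def test_tie_breaks_toward_smaller_column(self):
        peak = find_peak(image_with({(900, 7): 1.0, (900, 2): 1.0}))
        assert peak.h == 2

    def test_negative_amplitude_detected(self):
        peak = find_peak(image_with({(500, 4): -3.0}))
        assert peak.w == pytest.approx(3.0)

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError):
            find_peak(image_with({}))
        with pytest.raises(ValueError):
            find_peak(image_with({}), mode="envelope")

    def test_envelope_mode_recovers_subcolumn_source(self):
        """A 1/r amplitude profile across columns yields an interpolated
        h at the true lateral position."""
        rng_t = np.arange(4000) / FS
        burst = np.sin(2 * np.pi * 4e6 * rng_t[:60]) * np.hanning(60)
        y_true, depth = 3.1, 30.0  # mm; columns at (m-15.5)*1.2
        amp = np.zeros((4000, 32))
        cols_y = (np.arange(32) - 15.5) * 1.2
        for m in range(32):
            r = np.hypot(cols_y[m] - y_true, depth)
            start = 1500 + m  # arbitrary small per-column shift
            amp[start : start + 60, m] = burst / r
        peak = find_peak(TrackingImage(1, amp, FS, C), mode="envelope")
        h_true = y_true / 1.2 + 15.5
        assert peak.h == pytest.approx(h_true, abs=0.05)
        assert peak.h_element == int(round(h_true))


class TestLateral:
    def make(self, hs):
        return [PeakObservation(h=h, v=10.0, w=1.0, t_m=1e-5) for h in hs]

    def test_centre(self, geometry):
        assert estimate_lateral(self.make([15.5] * 4), geometry) == pytest.approx(0.0)

    def test_one_pitch_off_centre(self, geometry):
        assert estimate_lateral(self.make([16.5] * 4), geometry) == pytest.approx(1.2)

    def test_mean_symmetry(self, geometry):
        assert estimate_lateral(self.make([15, 16, 15, 16]), geometry) == pytest.approx(0.0)

    def test_wrong_count_rejected(self, geometry):
        with pytest.raises(ValueError):
            estimate_lateral(self.make([15]), geometry)


class TestTofGrid:
    def test_default_grid_dimensions(self, grid):
        assert grid.x_values.size == 1601
        assert grid.z_values.size == 3201
        assert grid.tof.shape == (4, 1601, 3201)

    def test_mirror_symmetry_between_outer_rows(self, grid):
        np.testing.assert_allclose(grid.tof[0], grid.tof[3][::-1], rtol=1e-12)
        np.testing.assert_allclose(grid.tof[1], grid.tof[2][::-1], rtol=1e-12)

    def test_monotone_in_depth(self, grid):
        iz20 = np.searchsorted(grid.z_values, 20.0)
        iz80 = grid.z_values.size - 1
        ix0 = np.searchsorted(grid.x_values, 0.0)
        for k in range(4):
            assert grid.tof[k, ix0, iz80] > grid.tof[k, ix0, iz20]
            assert np.all(np.diff(grid.tof[k, ix0, iz20:]) > 0)

    def test_invalid_spacing_rejected(self, geometry):
        with pytest.raises(ValueError):
            precompute_tof_grid(geometry, spacing=0.0)
        with pytest.raises(ValueError):
            precompute_tof_grid(geometry, x_range=(10.0, -10.0))


class TestEstimateTip:
    def test_recovers_on_grid_sensor(self, geometry, grid):
        """Forward–inverse consistency: peaks built from exact times of
        flight at a grid node localise to that node."""
        sensor = np.array([10.0, 0.0, 40.0])
        tofs = simulate_tof(
            geometry, sensor, 1540.0, [(a, 15) for a in SIDE_ARRAYS]
        )
        est = estimate_tip(peaks_from_tofs(tofs), grid, geometry)
        assert abs(est.x - 10.0) <= 0.025 + 1e-12
        assert abs(est.z - 40.0) <= 0.025 + 1e-12
        assert est.side == "right"

    def test_equal_weights_match_unweighted(self, geometry, grid):
        tofs = simulate_tof(
            geometry, [4.0, 0.0, 25.0], 1540.0, [(a, 15) for a in SIDE_ARRAYS]
        ) + np.array([3e-8, -2e-8, 1e-8, -4e-8])
        e1 = estimate_tip(peaks_from_tofs(tofs, w=1.0), grid, geometry)
        e5 = estimate_tip(peaks_from_tofs(tofs, w=5.0), grid, geometry)
        assert (e1.x, e1.z) == (e5.x, e5.z)

    def test_in_plane_sensor_stays_in_plane(self, geometry, grid):
        tofs = simulate_tof(
            geometry, [0.0, -0.6, 40.0], 1540.0, [(a, 15) for a in SIDE_ARRAYS]
        )
        est = estimate_tip(peaks_from_tofs(tofs), grid, geometry)
        assert est.x == 0.0
        assert est.side == "in-plane"

    def test_sign_symmetry(self, geometry, grid):
        """Negating the sensor's out-of-plane coordinate negates x̃ and
        leaves z̃ unchanged (mirror-symmetric geometry)."""
        els = [(a, 15) for a in SIDE_ARRAYS]
        t_pos = simulate_tof(geometry, [7.0, -0.6, 33.0], 1540.0, els)
        t_neg = simulate_tof(geometry, [-7.0, -0.6, 33.0], 1540.0, els)
        e_pos = estimate_tip(peaks_from_tofs(t_pos), grid, geometry)
        e_neg = estimate_tip(peaks_from_tofs(t_neg), grid, geometry)
        assert e_pos.x == pytest.approx(-e_neg.x)
        assert e_pos.z == pytest.approx(e_neg.z)
        assert (e_pos.side, e_neg.side) == ("right", "left")

    def test_under_determined_rejected(self, geometry, grid):
        peaks = peaks_from_tofs([2e-5] * 4, w=0.0)
        with pytest.raises(ValueError):
            estimate_tip(peaks, grid, geometry)

    def test_weight_sensitivity(self, geometry, grid):
        """Inflating one weight pulls the solution toward satisfying
        that time of flight exactly."""
        els = [(a, 15) for a in SIDE_ARRAYS]
        tofs = simulate_tof(geometry, [5.0, -0.6, 40.0], 1540.0, els)
        tofs = tofs + np.array([120e-9, 0.0, 0.0, 0.0])  # inconsistent set
        misfits = []
        for w0 in (1.0, 5.0, 25.0):
            peaks = peaks_from_tofs(tofs, w=[w0, 1.0, 1.0, 1.0])
            est = estimate_tip(peaks, grid, geometry)
            ts0 = (
                np.hypot(geometry.side_row_x_offsets[0] - est.x, est.z)
                * 1e-3
                / 1540.0
            )
            misfits.append(abs(tofs[0] - ts0))
        assert misfits[0] > misfits[1] > misfits[2]

    def test_accelerated_equals_exhaustive(self, geometry, small_grid):
        """The recentring search returns the same node as brute force on
        random (inconsistent) peak sets, on a grid fine enough that the
        coarse stage actually subsamples."""
        fine = precompute_tof_grid(
            geometry, x_range=(-10.0, 10.0), z_range=(10.0, 50.0), spacing=0.1
        )
        rng = np.random.default_rng(5)
        for g in (small_grid, fine):
            for _ in range(25):
                sensor = [rng.uniform(-9, 9), -0.6, rng.uniform(12, 48)]
                tofs = simulate_tof(
                    geometry, sensor, 1540.0, [(a, 15) for a in SIDE_ARRAYS]
                )
                tofs = tofs + rng.uniform(-2e-7, 2e-7, 4)
                peaks = peaks_from_tofs(tofs, w=rng.uniform(0.5, 1.0, 4))
                e_fast = estimate_tip(peaks, g, geometry, search="coarse_fine")
                e_full = estimate_tip(peaks, g, geometry, search="exhaustive")
                assert (e_fast.x, e_fast.z) == (e_full.x, e_full.z)


class TestSosWater:
    def test_polynomial_values(self):
        # frozen from the published pure-water polynomial coefficients
        assert sos_water(20.0) == pytest.approx(1482.38, abs=0.05)
        assert sos_water(25.0) == pytest.approx(1496.73, abs=0.05)

    @pytest.mark.parametrize("t", [-1.0, 100.0])
    def test_out_of_range_rejected(self, t):
        with pytest.raises(ValueError):
            sos_water(t)


class TestOverlay:
    def make_estimate(self, x):
        side = "in-plane" if x == 0 else ("left" if x < 0 else "right")
        from needletrack.tracking import TipEstimate

        return TipEstimate(x=x, y=2.0, z=30.0, side=side, residual=0.0, peaks=[])

    def test_in_plane_zero_cross(self):
        ann = make_overlay(self.make_estimate(0.0))
        assert ann.arm_length_mm == 0.0
        assert ann.side == "in-plane"
        assert ann.centre == (2.0, 30.0)

    def test_out_of_plane_scaling_and_side(self):
        assert make_overlay(self.make_estimate(10.0), scale=1.0).arm_length_mm == 10.0
        assert make_overlay(self.make_estimate(10.0)).side == "right"
        assert make_overlay(self.make_estimate(-5.0)).side == "left"
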