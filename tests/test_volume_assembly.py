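"""Frame stacking, elevational resampling, skin removal, fluence flattening."""

import numpy as np
import pytest

from panopaus.core import BeamformedFrame, Volume
from panopaus.scan_geometry import scan_positions
from panopaus.volume_assembly import (
    SkinContour,
    detect_skin,
    fluence_compensate,
    remove_skin,
    resample_uniform,
    stack_frames,
)


def frames_from_array(data, dz=0.01925, dx=0.3):
    """Split a (z, x, y) array into BeamformedFrames."""
    return [
        BeamformedFrame(image=data[:, :, k], axial_spacing_mm=dz,
                        lateral_spacing_mm=dx)
        for k in range(data.shape[2])
    ]


def flat_contour(shape_xy, index):
    return SkinContour(
        depth_index=np.full(shape_xy, index, dtype=int),
        threshold=0.5, smooth_window=1,
    )


class TestStackFrames:
    def test_scotch_yoke_positions_pass_through(self, mini_spec, rng):
        positions = scan_positions(mini_spec)
        data = rng.random((16, 8, len(positions)))
        vol = stack_frames(frames_from_array(data), positions)
        assert np.allclose(vol.y_coords_mm, positions - positions[0])
        assert vol.shape == data.shape

    def test_single_frame_degenerate(self, rng):
        data = rng.random((16, 8, 1))
        vol = stack_frames(frames_from_array(data), [0.0])
        assert vol.shape[2] == 1

    def test_shuffled_positions_rejected(self, rng):
        data = rng.random((8, 4, 3))
        with pytest.raises(ValueError, match="increasing"):
            stack_frames(frames_from_array(data), [0.0, 2.0, 1.0])

    def test_shape_mismatch_rejected(self):
        a = BeamformedFrame(np.zeros((8, 4)), 0.01925, 0.3)
        b = BeamformedFrame(np.zeros((8, 5)), 0.01925, 0.3)
        with pytest.raises(ValueError, match="shape"):
            stack_frames([a, b], [0.0, 1.0])

    def test_wavelength_mismatch_rejected(self):
        a = BeamformedFrame(np.zeros((8, 4)), 0.01925, 0.3, wavelength_nm=756)
        b = BeamformedFrame(np.zeros((8, 4)), 0.01925, 0.3, wavelength_nm=866)
        with pytest.raises(ValueError, match="wavelength"):
            stack_frames([a, b], [0.0, 1.0])


class TestResampleUniform:
    def test_already_uniform_identity(self, rng):
        data = rng.random((6, 4, 11))
        vol = Volume(data, (0.01925, 0.3, 0.1),
                     y_coords_mm=0.1 * np.arange(11))
        out = resample_uniform(vol, 0.1)
        assert out.shape == vol.shape
        assert np.allclose(out.data, vol.data, atol=1e-12)

    def test_linear_field_exact(self, mini_spec):
        """Linear interpolation reproduces affine functions exactly."""
        positions = scan_positions(mini_spec)
        y = positions - positions[0]
        data = np.broadcast_to(
            2.0 + 3.0 * y, (6, 4, y.size)
        ).copy()
        vol = Volume(data, (0.01925, 0.3, 1.0), y_coords_mm=y)
        out = resample_uniform(vol, 0.5)
        y_new = 0.5 * np.arange(out.shape[2])
        expected = np.broadcast_to(2.0 + 3.0 * y_new, out.shape)
        assert np.allclose(out.data, expected, atol=1e-10)

    def test_default_scan_gives_424_planes(self, default_spec, rng):
        positions = scan_positions(default_spec)
        data = rng.random((2, 2, positions.size))
        vol = Volume(data, (0.01925, 0.3, 1.0),
                     y_coords_mm=positions - positions[0])
        out = resample_uniform(vol, 0.059)
        assert out.shape[2] == int(np.floor(positions[-1] / 0.059)) + 1
        assert out.shape[2] == 424

    def test_integral_conserved_for_smooth_field(self, default_spec):
        """Resampling a smooth field conserves its volume integral ~1%."""
        positions = scan_positions(default_spec)
        y = positions - positions[0]
        field = 1.0 + np.sin(2 * np.pi * y / y[-1])
        data = np.broadcast_to(field, (3, 3, y.size)).copy()
        vol = Volume(data, (0.01925, 0.3, 1.0), y_coords_mm=y)
        out = resample_uniform(vol, 0.059)
        integral_in = np.trapezoid(vol.data[0, 0], y)
        integral_out = np.trapezoid(
            out.data[0, 0], 0.059 * np.arange(out.shape[2])
        )
        assert integral_out == pytest.approx(integral_in, rel=0.01)

    def test_single_frame_rejected(self):
        vol = Volume(np.zeros((4, 4, 1)), (1, 1, 1), y_coords_mm=[0.0])
        with pytest.raises(ValueError, match="2 frames"):
            resample_uniform(vol)


class TestDetectSkin:
    def us_volume(self, data):
        return Volume(data, (0.01925, 0.3, 0.5), modality="us")

    def test_bright_plane_found(self, default_spec, rng):
        """A skin plane at 2 mm depth is found near row 104."""
        from panopaus.synthetic_data import Phantom, simulate_us_frame

        ph = Phantom(skin_depth_mm=2.0)
        frames = [
            simulate_us_frame(ph, default_spec, y, n_axial=256, seed=k)
            for k, y in enumerate(np.linspace(0, 5, 5))
        ]
        vol = self.us_volume(np.stack(frames, axis=2))
        contour = detect_skin(vol)
        expected = 2.0 / default_spec.axial_pixel_mm  # ~104
        assert np.all(np.abs(contour.depth_index - expected) <= 4)

    def test_tilted_plane_tracked(self):
        nz, nx, ny = 64, 32, 16
        data = np.full((nz, nx, ny), 0.01)
        plane = (20 + np.arange(nx) * 0.5).astype(int)  # tilt along x
        for j in range(nx):
            data[plane[j], j, :] = 1.0
        contour = detect_skin(self.us_volume(data), smooth_window=3)
        assert np.all(
            np.abs(contour.depth_index - plane[:, None]) <= 1
        )

    def test_outlier_column_removed_by_median(self):
        nz, nx, ny = 64, 21, 21
        data = np.full((nz, nx, ny), 0.01)
        data[30, :, :] = 1.0
        data[:, 10, 10] = 0.01
        data[5, 10, 10] = 1.0  # one spuriously shallow column
        contour = detect_skin(self.us_volume(data), smooth_window=5)
        assert contour.depth_index[10, 10] == 30

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            detect_skin(self.us_volume(np.zeros((8, 4, 4))))

    def test_non_us_volume_rejected(self):
        vol = Volume(np.ones((8, 4, 4)), (1, 1, 1), modality="pa")
        with pytest.raises(ValueError, match="US"):
            detect_skin(vol)


class TestRemoveSkin:
    def test_offset_40_removes_to_row_140(self):
        vol = Volume(np.ones((200, 4, 3)), (0.01925, 0.3, 0.5))
        out = remove_skin(vol, flat_contour((4, 3), 100), offset_pixels=40)
        assert np.all(out.data[:140] == 0)
        assert np.all(out.data[140:] == 1)

    def test_offset_zero_cuts_at_contour(self):
        vol = Volume(np.ones((50, 4, 3)), (0.01925, 0.3, 0.5))
        out = remove_skin(vol, flat_contour((4, 3), 10), offset_pixels=0)
        assert np.all(out.data[:10] == 0)
        assert np.all(out.data[10:] == 1)

    def test_40_pixels_is_0_77_mm(self, default_spec):
        assert 40 * default_spec.axial_pixel_mm == pytest.approx(0.77)

    def test_idempotent(self, rng):
        vol = Volume(rng.random((60, 4, 3)), (0.01925, 0.3, 0.5))
        contour = flat_contour((4, 3), 10)
        once = remove_skin(vol, contour, 20)
        twice = remove_skin(once, contour, 20)
        assert np.array_equal(once.data, twice.data)

    def test_offset_past_bottom_warns_and_zeroes(self):
        vol = Volume(np.ones((30, 4, 3)), (0.01925, 0.3, 0.5))
        with pytest.warns(UserWarning, match="past the bottom"):
            out = remove_skin(vol, flat_contour((4, 3), 10), offset_pixels=40)
        assert np.all(out.data == 0)


class TestFluenceCompensate:
    def test_homogeneous_background_flattens_to_one(self, rng):
        nz, nx, ny = 80, 16, 4
        data = np.zeros((nz, nx, ny))
        data[20:] = 0.05 + 0.001 * rng.random((60, nx, ny))
        vol = Volume(data, (0.01925, 0.3, 0.5))
        out = fluence_compensate(vol, flat_contour((nx, ny), 20))
        assert np.allclose(out.data[20:], 1.0, rtol=0.05)

    def test_exponential_decay_flattened_inclusion_preserved(self):
        """Background flattened to ~1; inclusion contrast preserved ~5%."""
        nz, nx, ny = 120, 32, 3
        z = np.arange(nz)
        decay = np.exp(-0.02 * z)
        data = np.broadcast_to(decay[:, None, None], (nz, nx, ny)).copy()
        # bright inclusion at rows 60-64, 10x local background
        contrast = 10.0
        data[60:65, 10:14, :] *= contrast
        vol = Volume(data, (0.01925, 0.3, 0.5))
        out = fluence_compensate(vol, flat_contour((nx, ny), 0),
                                 signal_threshold=0.5)
        background = out.data[20:50]
        assert np.allclose(background, 1.0, rtol=0.05)
        inclusion = out.data[60:65, 10:14, :].mean()
        local_bg = out.data[60:65, 20:30, :].mean()
        assert inclusion / local_bg == pytest.approx(contrast, rel=0.05)

    def test_wavelengths_normalized_independently(self):
        """Each volume (one per wavelength) is normalized on its own."""
        nz, nx, ny = 60, 8, 2
        z = np.arange(nz)
        contour = flat_contour((nx, ny), 0)
        for rate in (0.01, 0.05):
            decay = np.exp(-rate * z)
            data = np.broadcast_to(decay[:, None, None], (nz, nx, ny)).copy()
            out = fluence_compensate(
                Volume(data, (0.01925, 0.3, 0.5)), contour,
                signal_threshold=1.1,
            )
            assert np.allclose(out.data[5:-5], 1.0, rtol=0.02)

    def test_all_zero_frame_passes_through(self):
        data = np.zeros((20, 4, 2))
        data[10:, :, 1] = 0.5
        vol = Volume(data, (1, 1, 1))
        out = fluence_compensate(vol, flat_contour((4, 2), 0))
        assert np.all(out.data[:, :, 0] == 0)

    def test_rank_order_preserved_within_rows(self, rng):
        """Division by a per-row positive scalar keeps voxel ordering."""
        nz, nx, ny = 40, 12, 3
        data = 0.1 + rng.random((nz, nx, ny))
        vol = Volume(data, (1, 1, 1))
        out = fluence_compensate(vol, flat_contour((nx, ny), 0))
        for k in range(ny):
            for i in range(nz):
                assert np.array_equal(
                    np.argsort(data[i, :, k]), np.argsort(out.data[i, :, k])
                )


def test_end_to_end_thread_depths(default_spec):
    """Simulated thread phantom -> assembled volume peaks at 12/18/24 mm."""
    import dataclasses

    from panopaus.reconstruction import calibrate_energy, das_beamform
    from panopaus.synthetic_data import make_thread_phantom, simulate_scan

    spec = dataclasses.replace(default_spec, frames_per_scan=7)
    phantom = make_thread_phantom()
    rf, us, positions = simulate_scan(
        phantom, spec, wavelengths_nm=(797.0,), energy_jitter=0.02,
        seed=0, n_samples=704, noise_std=1e-4,
    )
    frames = [
        das_beamform(calibrate_energy(fr), spec) for fr in rf[797.0]
    ]
    vol = stack_frames(frames, positions)
    vol = resample_uniform(vol, 1.0)
    dz = vol.spacing_mm[0]
    found = []
    for d in (12.0, 18.0, 24.0):
        band = slice(int((d - 2) / dz), int((d + 2) / dz))
        sub = vol.data[band]
        iz = np.unravel_index(np.argmax(sub), sub.shape)[0] + band.start
        found.append(iz * dz)
    # coherent summation along the thread skews the envelope peak ~0.1% of
    # depth deeper, so allow 2 axial pixels
    assert np.allclose(found, [12.0, 18.0, 24.0], atol=dz * 2.001)
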