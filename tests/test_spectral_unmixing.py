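"""Spectral unmixing, sO2 computation, median filtering, projection, ROIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from panopaus.core import Volume
from panopaus.spectral_unmixing import (
    DEFAULT_EXTINCTION,
    ChromophoreMaps,
    ExtinctionTable,
    ROIPolygon,
    SO2Volume,
    _odd_window,
    compute_so2,
    median_filter_mm,
    median_filter_map,
    roi_stats,
    so2_map,
    unmix,
)


def volumes_from_concentrations(c_hb, c_hbo2, table=DEFAULT_EXTINCTION):
    """Synthesize noiseless per-wavelength PA volumes from concentrations."""
    out = {}
    for w in table.wavelengths_nm:
        hb, hbo2 = table.row(w)
        out[w] = Volume(hb * c_hb + hbo2 * c_hbo2, (1, 1, 1))
    return out


def vol(data):
    return Volume(np.asarray(data, dtype=float), (1, 1, 1))


class TestExtinctionTable:
    def test_spectral_structure(self):
        """Hb dominates at 756, isosbestic at 797, HbO2 dominates at 866."""
        t = DEFAULT_EXTINCTION
        hb756, hbo2756 = t.row(756)
        hb797, hbo2797 = t.row(797)
        hb866, hbo2866 = t.row(866)
        assert hb756 > hbo2756
        assert abs(hb797 - hbo2797) / hb797 < 0.05
        assert hbo2866 > hb866

    def test_mismatched_columns_rejected(self):
        with pytest.raises(ValueError):
            ExtinctionTable((756, 797), (1.0,), (1.0, 2.0))


class TestUnmix:
    def test_pure_hbo2_column(self):
        c_hb = np.zeros((2, 2, 2))
        c_hbo2 = np.ones((2, 2, 2))
        maps = unmix(volumes_from_concentrations(c_hb, c_hbo2))
        assert np.allclose(maps.c_hb.data, 0.0, atol=1e-10)
        assert np.allclose(maps.c_hbo2.data, 1.0, atol=1e-10)

    def test_mixture_recovered_exactly(self):
        c_hb = np.full((2, 2, 2), 0.3)
        c_hbo2 = np.full((2, 2, 2), 0.7)
        maps = unmix(volumes_from_concentrations(c_hb, c_hbo2))
        assert np.allclose(maps.c_hb.data, 0.3, atol=1e-10)
        assert np.allclose(maps.c_hbo2.data, 0.7, atol=1e-10)

    def test_negative_solution_truncated(self):
        """A spectrum solving to C_Hb < 0 is clamped to zero."""
        t = DEFAULT_EXTINCTION
        E = t.matrix()
        c_true = np.array([-0.5, 1.0])  # infeasible mixture
        p = E @ c_true
        # oracle: the unconstrained normal-equations solve is negative
        c_ls = np.linalg.lstsq(E, p, rcond=None)[0]
        assert c_ls[0] < 0
        vols = {w: vol(np.full((1, 1, 1), p[i]))
                for i, w in enumerate(t.wavelengths_nm)}
        maps = unmix(vols)
        assert maps.c_hb.data[0, 0, 0] == 0.0
        assert maps.c_hbo2.data[0, 0, 0] >= 0.0

    def test_truncation_never_increases_magnitude(self, rng):
        """Clamping is the coordinate-wise projection onto C >= 0."""
        t = DEFAULT_EXTINCTION
        E = t.matrix()
        P = rng.normal(0, 1, size=(3, 50))
        C_unc = np.linalg.pinv(E) @ P
        vols = {w: vol(P[i].reshape(1, 1, -1))
                for i, w in enumerate(t.wavelengths_nm)}
        maps = unmix(vols)
        C_trunc = np.stack([maps.c_hb.data.ravel(),
                            maps.c_hbo2.data.ravel()])
        assert np.allclose(C_trunc, np.maximum(C_unc, 0.0), atol=1e-12)
        assert (np.abs(C_trunc) <= np.abs(C_unc) + 1e-12).all()

    @given(
        hb=st_.floats(0.0, 10.0), hbo2=st_.floats(0.0, 10.0)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_exact(self, hb, hbo2):
        """Synthesize-then-unmix recovers any non-negative pair to 1e-10."""
        maps = unmix(volumes_from_concentrations(
            np.full((1, 1, 1), hb), np.full((1, 1, 1), hbo2)
        ))
        assert maps.c_hb.data[0, 0, 0] == pytest.approx(hb, abs=1e-10)
        assert maps.c_hbo2.data[0, 0, 0] == pytest.approx(hbo2, abs=1e-10)

    def test_noise_bias_below_noise_level(self, rng):
        """sO2 bias on a 0.84 vessel stays below the 5% amplitude noise."""
        sigma = 0.05
        n = 1000
        so2_true = 0.84
        t = DEFAULT_EXTINCTION
        E = t.matrix()
        c_true = np.array([1.0 - so2_true, so2_true])
        p = np.outer(E @ c_true, np.ones(n))
        p_noisy = p * (1.0 + sigma * rng.standard_normal(p.shape))
        vols = {w: vol(p_noisy[i].reshape(1, 1, -1))
                for i, w in enumerate(t.wavelengths_nm)}
        so2 = compute_so2(unmix(vols))
        bias = abs(np.nanmean(so2.so2.data) - so2_true)
        assert bias < sigma

    def test_single_wavelength_rejected(self):
        with pytest.raises(ValueError, match="two wavelengths"):
            unmix({797.0: vol(np.ones((1, 1, 1)))})

    def test_rank_deficient_table_rejected(self):
        degenerate = ExtinctionTable((700.0, 800.0), (1.0, 2.0), (2.0, 4.0))
        vols = {700.0: vol(np.ones((1, 1, 1))),
                800.0: vol(np.ones((1, 1, 1)))}
        with pytest.raises(ValueError, match="rank"):
            unmix(vols, degenerate)


class TestComputeSO2:
    def test_pure_hbo2_is_one(self):
        maps = ChromophoreMaps(vol(np.zeros((1, 1, 1))),
                               vol(np.full((1, 1, 1), 5.0)))
        assert compute_so2(maps).so2.data[0, 0, 0] == 1.0

    def test_equal_concentrations_half(self):
        maps = ChromophoreMaps(vol(np.full((1, 1, 1), 2.0)),
                               vol(np.full((1, 1, 1), 2.0)))
        assert compute_so2(maps).so2.data[0, 0, 0] == 0.5

    def test_zero_total_is_undefined_and_excluded(self):
        c = np.zeros((1, 1, 2))
        c_hbo2 = np.zeros((1, 1, 2))
        c_hbo2[0, 0, 1] = 1.0
        so2 = compute_so2(ChromophoreMaps(vol(c), vol(c_hbo2)))
        assert np.isnan(so2.so2.data[0, 0, 0])
        assert so2.defined_mask.sum() == 1
        assert np.nanmean(so2.so2.data) == 1.0


class TestMedianFilter:
    def test_constant_volume_unchanged(self):
        v = Volume(np.full((4, 20, 80), 3.0), (1.0, 0.3, 0.059))
        out = median_filter_mm(v, (0.4, 0.9))
        assert np.allclose(out.data, 3.0)

    def test_impulse_removed(self):
        data = np.zeros((2, 21, 21))
        data[1, 10, 10] = 100.0
        v = Volume(data, (1.0, 1.0, 1.0))
        out = median_filter_mm(v, (3.0, 3.0))
        assert out.data[1, 10, 10] == 0.0

    def test_window_rounding_rule(self):
        """4 mm at 0.059 mm spacing -> 67 voxels (nearest odd to 67.8)."""
        assert _odd_window(4.0, 0.059) == 67
        assert _odd_window(1.0, 0.3) == 3
        assert _odd_window(0.059, 0.059) == 1

    def test_window_exceeding_volume_rejected(self):
        v = Volume(np.zeros((2, 4, 4)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="exceeds"):
            median_filter_mm(v, (9.0, 1.0))

    def test_map_filter_preserves_undefined(self):
        arr = np.full((11, 11), 0.9)
        arr[5, 5] = np.nan
        out = median_filter_map(arr, (1.0, 1.0), (3.0, 3.0))
        assert np.isnan(out[5, 5])
        assert np.allclose(out[~np.isnan(out)], 0.9)


class TestSO2Map:
    def test_single_nonzero_voxel_projects_its_so2(self):
        c_hb = np.zeros((4, 1, 1))
        c_hbo2 = np.zeros((4, 1, 1))
        c_hb[2] = 1.0
        c_hbo2[2] = 3.0
        maps = ChromophoreMaps(vol(c_hb), vol(c_hbo2))
        m = so2_map(compute_so2(maps), maps.c_hbo2)
        assert m.so2[0, 0] == pytest.approx(0.75)
        assert m.depth_index[0, 0] == 2

    def test_tie_goes_to_shallower_voxel(self):
        c_hbo2 = np.zeros((4, 1, 1))
        c_hbo2[[1, 3]] = 2.0
        c_hb = np.zeros((4, 1, 1))
        c_hb[1] = 2.0  # so2 0.5 at shallow max, 1.0 at deep max
        maps = ChromophoreMaps(vol(c_hb), vol(c_hbo2))
        m = so2_map(compute_so2(maps), maps.c_hbo2)
        assert m.depth_index[0, 0] == 1
        assert m.so2[0, 0] == pytest.approx(0.5)

    def test_invariant_to_positive_column_rescale(self, rng):
        c_hb = rng.random((6, 3, 3)) + 0.1
        c_hbo2 = rng.random((6, 3, 3)) + 0.1
        scale = rng.random((3, 3)) * 5 + 0.5
        m1 = so2_map(
            compute_so2(ChromophoreMaps(vol(c_hb), vol(c_hbo2))),
            vol(c_hbo2),
        )
        m2 = so2_map(
            compute_so2(ChromophoreMaps(vol(c_hb * scale),
                                        vol(c_hbo2 * scale))),
            vol(c_hbo2 * scale),
        )
        assert np.allclose(m1.so2, m2.so2)
        assert np.array_equal(m1.depth_index, m2.depth_index)

    def test_all_undefined_column_is_undefined(self):
        zeros = np.zeros((3, 1, 1))
        maps = ChromophoreMaps(vol(zeros), vol(zeros))
        m = so2_map(compute_so2(maps), maps.c_hbo2)
        assert np.isnan(m.so2[0, 0])


class TestROIStats:
    def square(self, frame, lo=0.5, hi=3.5):
        return ROIPolygon(frame, ((lo, lo), (hi, lo), (hi, hi), (lo, hi)))

    def so2_volume_const(self, value, shape=(6, 6, 3)):
        c_hbo2 = np.full(shape, value)
        c_hb = np.full(shape, 1.0 - value)
        return compute_so2(ChromophoreMaps(vol(c_hb), vol(c_hbo2)))

    def test_constant_region(self):
        so2 = self.so2_volume_const(0.9)
        mean, std, n = roi_stats(so2, [self.square(0), self.square(1)])
        assert mean == pytest.approx(0.9)
        assert std == pytest.approx(0.0, abs=1e-12)
        assert n > 0

    def test_empty_roi_rejected(self):
        so2 = self.so2_volume_const(0.9)
        with pytest.raises(ValueError, match="empty ROI"):
            roi_stats(so2, [])

    def test_undefined_only_roi_rejected(self):
        zeros = np.zeros((6, 6, 3))
        so2 = compute_so2(ChromophoreMaps(vol(zeros), vol(zeros)))
        with pytest.raises(ValueError, match="no defined"):
            roi_stats(so2, [self.square(0)])

    def test_out_of_bounds_polygon_rejected(self):
        so2 = self.so2_volume_const(0.9)
        bad = ROIPolygon(0, ((-5.0, 0.0), (2.0, 0.0), (2.0, 2.0)))
        with pytest.raises(ValueError, match="outside"):
            roi_stats(so2, [bad])

    def test_polygon_text_format_round_trip(self, tmp_path):
        from panopaus.spectral_unmixing import (
            read_roi_polygons,
            write_roi_polygons,
        )

        polys = [self.square(0), self.square(2, 1.0, 2.5)]
        path = tmp_path / "rois.txt"
        write_roi_polygons(path, polys)
        back = read_roi_polygons(path)
        assert back == polys
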