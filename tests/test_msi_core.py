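"""Data model, imzML round-trips, TIC normalization, ion images, masking."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungtarget.analytes import AnalyteDefinition
from lungtarget.msi_core import (
    EmptyDatasetError,
    ImzMLIntegrityError,
    MSIDataset,
    compute_tissue_mask,
    extract_ion_image,
    read_imzml,
    tic_normalize,
    write_imzml,
)
from lungtarget.synthetic_lung import simulate_msi

from conftest import jaccard, small_scenario


def continuous_dataset(matrix, mz=None, coords=None, **kw):
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    if mz is None:
        mz = 400.0 + 10.0 * np.arange(m)
    if coords is None:
        coords = [(i % 4 + 1, i // 4 + 1) for i in range(n)]
    kw.setdefault("mz_range", (300.0, 1000.0))
    return MSIDataset(
        np.array(coords), mode="continuous", mz_axis=np.asarray(mz, float),
        intensity_matrix=matrix, **kw,
    )


# ---------------------------------------------------------------------------
# dataset invariants
# ---------------------------------------------------------------------------

class TestDatasetValidation:
    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            continuous_dataset([[1.0, 2.0], [3.0, 4.0]], coords=[(1, 1), (1, 1)])

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            continuous_dataset([[1.0, -2.0]])

    def test_mz_outside_range_rejected(self):
        with pytest.raises(ValueError, match="mz_range"):
            continuous_dataset([[1.0, 2.0]], mz=[350.0, 1200.0])

    def test_processed_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            MSIDataset(
                np.array([[1, 1]]), mode="processed",
                mz_arrays=[np.array([400.0, 500.0])],
                intensity_arrays=[np.array([1.0])],
                mz_range=(300, 1000),
            )

    def test_no_pixels_rejected(self):
        with pytest.raises(EmptyDatasetError):
            MSIDataset(
                np.empty((0, 2)), mode="continuous",
                mz_axis=np.array([400.0]), intensity_matrix=np.empty((0, 1)),
            )


# ---------------------------------------------------------------------------
# imzML round-trip
# ---------------------------------------------------------------------------

class TestImzMLRoundTrip:
    def test_continuous_round_trip_identity(self, tmp_path):
        ds = continuous_dataset(
            [[1.5, 0.0, 3.25], [2.0, 4.0, 0.5], [0.0, 0.0, 7.0], [9.0, 1.0, 2.0]],
            pixel_size=10.0,
        )
        path = tmp_path / "four.imzML"
        write_imzml(ds, path)
        back = read_imzml(path)
        assert back.mode == "continuous"
        assert back.polarity == ds.polarity
        assert back.pixel_size == ds.pixel_size
        assert back.mz_range == ds.mz_range
        np.testing.assert_array_equal(back.coordinates, ds.coordinates)
        np.testing.assert_array_equal(back.mz_axis, ds.mz_axis)
        np.testing.assert_array_equal(back.intensity_matrix, ds.intensity_matrix)

    def test_single_pixel_round_trip(self, tmp_path):
        ds = continuous_dataset([[5.0, 6.0]], coords=[(3, 7)])
        path = tmp_path / "one.imzML"
        write_imzml(ds, path)
        back = read_imzml(path)
        np.testing.assert_array_equal(back.coordinates, [[3, 7]])
        np.testing.assert_array_equal(back.intensity_matrix, [[5.0, 6.0]])

    def test_processed_round_trip_ragged_axes(self, tmp_path):
        ds = MSIDataset(
            np.array([[1, 1], [2, 1]]), mode="processed",
            mz_arrays=[np.array([400.1, 500.2]), np.array([350.0, 410.0, 900.5])],
            intensity_arrays=[np.array([1.0, 2.0]), np.array([3.0, 4.0, 5.0])],
            mz_range=(300, 1000),
        )
        path = tmp_path / "ragged.imzML"
        write_imzml(ds, path)
        back = read_imzml(path)
        assert back.mode == "processed"
        for i in range(2):
            np.testing.assert_array_equal(back.mz_arrays[i], ds.mz_arrays[i])
            np.testing.assert_array_equal(back.intensity_arrays[i], ds.intensity_arrays[i])

    def test_synthetic_section_round_trip(self, tmp_path):
        scenario = small_scenario(
            grid_size=(50, 50), lumen_radius=(3.0, 4.0),
            epithelium_thickness=2.0, subepithelium_thickness=2.0,
        )
        ds, _truth = simulate_msi(scenario, seed=3)
        path = tmp_path / "lung.imzML"
        write_imzml(ds, path)
        back = read_imzml(path)
        np.testing.assert_array_equal(back.coordinates, ds.coordinates)
        np.testing.assert_array_equal(back.intensity_matrix, ds.intensity_matrix)

    def test_missing_ibd_rejected(self, tmp_path):
        ds = continuous_dataset([[1.0, 2.0]])
        path = tmp_path / "x.imzML"
        write_imzml(ds, path)
        (tmp_path / "x.ibd").unlink()
        with pytest.raises(ImzMLIntegrityError, match="ibd"):
            read_imzml(path)

    def test_corrupted_ibd_fails_checksum(self, tmp_path):
        ds = continuous_dataset([[1.0, 2.0], [3.0, 4.0]])
        path = tmp_path / "x.imzML"
        write_imzml(ds, path)
        ibd = tmp_path / "x.ibd"
        data = bytearray(ibd.read_bytes())
        data[-1] ^= 0xFF
        ibd.write_bytes(bytes(data))
        with pytest.raises(ImzMLIntegrityError, match="SHA-1"):
            read_imzml(path)

    def test_swapped_ibd_fails_uuid(self, tmp_path):
        for stem in ("a", "b"):
            write_imzml(continuous_dataset([[1.0, 2.0]]), tmp_path / f"{stem}.imzML")
        (tmp_path / "a.ibd").unlink()
        (tmp_path / "b.ibd").rename(tmp_path / "a.ibd")
        with pytest.raises(ImzMLIntegrityError):
            read_imzml(tmp_path / "a.imzML")


# ---------------------------------------------------------------------------
# TIC normalization
# ---------------------------------------------------------------------------

class TestTicNormalize:
    def test_proportions(self):
        ds = continuous_dataset([[10.0, 30.0]])
        out = tic_normalize(ds, target=1.0)
        np.testing.assert_allclose(out.intensity_matrix[0], [0.25, 0.75])

    def test_default_target_preserves_global_scale(self):
        ds = continuous_dataset([[1.0, 3.0], [6.0, 2.0]])  # TICs 4, 8 -> mean 6
        out = tic_normalize(ds)
        np.testing.assert_allclose(out.tic(), [6.0, 6.0])

    def test_idempotent(self):
        ds = continuous_dataset([[1.0, 3.0], [6.0, 2.0]])
        once = tic_normalize(ds, target=5.0)
        twice = tic_normalize(once, target=5.0)
        np.testing.assert_allclose(twice.intensity_matrix, once.intensity_matrix)

    def test_already_normalized_unchanged(self):
        ds = continuous_dataset([[2.0, 3.0], [1.0, 4.0]])  # both TIC 5
        out = tic_normalize(ds, target=5.0)
        np.testing.assert_allclose(out.intensity_matrix, ds.intensity_matrix)

    def test_zero_tic_pixels_dropped_and_reported(self):
        ds = continuous_dataset([[1.0, 1.0], [0.0, 0.0], [2.0, 2.0]])
        out = tic_normalize(ds)
        assert out.n_pixels == 2
        assert out.metadata["dropped_zero_tic"] == 1

    def test_all_zero_errors(self):
        ds = continuous_dataset([[0.0, 0.0]])
        with pytest.raises(EmptyDatasetError):
            tic_normalize(ds)

    @given(
        st.lists(
            st.lists(st.floats(0.1, 1e4), min_size=3, max_size=3),
            min_size=2, max_size=6,
        )
    )
    def test_within_pixel_ratios_conserved(self, rows):
        ds = continuous_dataset(rows)
        out = tic_normalize(ds)
        raw = np.asarray(rows)
        ratio_raw = raw[:, 0] / raw[:, 1]
        ratio_norm = out.intensity_matrix[:, 0] / out.intensity_matrix[:, 1]
        np.testing.assert_allclose(ratio_norm, ratio_raw, rtol=1e-12)

    def test_removes_multiplicative_drift_exactly(self, small_sc):
        quiet = small_sc.without_noise()
        import dataclasses

        drifty = dataclasses.replace(quiet, tic_drift_sigma=0.4)
        ds_quiet, _ = simulate_msi(quiet, seed=5)
        ds_drift, _ = simulate_msi(drifty, seed=5)
        a = tic_normalize(ds_quiet, target=1000.0)
        b = tic_normalize(ds_drift, target=1000.0)
        keep = ds_quiet.tic() > 0
        np.testing.assert_allclose(
            b.intensity_matrix, a.intensity_matrix[keep[ds_drift.tic() > 0]], rtol=1e-9
        )


# ---------------------------------------------------------------------------
# ion images
# ---------------------------------------------------------------------------

class TestExtractIonImage:
    def test_closed_window_membership(self):
        ds = MSIDataset(
            np.array([[1, 1]]), mode="processed",
            mz_arrays=[np.array([416.10, 416.30])],
            intensity_arrays=[np.array([5.0, 7.0])],
            mz_range=(300, 1000),
        )
        img = extract_ion_image(ds, AnalyteDefinition("salmeterol", 416.1, tolerance=0.1))
        assert img.grid[0, 0] == 5.0

    def test_empty_window_gives_zero_not_missing(self):
        ds = continuous_dataset([[1.0, 2.0]], mz=[400.0, 500.0])
        img = extract_ion_image(ds, AnalyteDefinition("x", 450.0, tolerance=1.0))
        assert img.grid[0, 0] == 0.0

    def test_unacquired_cells_are_nan(self):
        ds = continuous_dataset([[1.0], [2.0], [3.0]], mz=[400.0],
                                coords=[(1, 1), (2, 1), (1, 2)])
        img = extract_ion_image(ds, AnalyteDefinition("x", 400.0, tolerance=0.5))
        assert np.isnan(img.grid[1, 1])
        assert np.isfinite(img.grid[0, 0])

    def test_window_outside_range_named_in_error(self):
        ds = continuous_dataset([[1.0, 2.0]])
        with pytest.raises(ValueError, match="window"):
            extract_ion_image(ds, AnalyteDefinition("x", 1500.0, tolerance=0.1))

    def test_additive_over_disjoint_windows(self):
        rng = np.random.default_rng(0)
        ds = continuous_dataset(rng.uniform(0, 10, size=(6, 8)),
                                mz=400.0 + np.arange(8.0))
        w1 = AnalyteDefinition("w1", 401.0, tolerance=1.4)  # covers 400-402
        w2 = AnalyteDefinition("w2", 404.0, tolerance=1.4)  # covers 403-405
        w12 = AnalyteDefinition("w12", 402.5, tolerance=2.9)  # covers 400-405
        total = extract_ion_image(ds, w12).grid
        np.testing.assert_allclose(
            extract_ion_image(ds, w1).grid + extract_ion_image(ds, w2).grid, total
        )

    def test_reproduces_noiseless_truth(self, small_sc, small_noiseless_section):
        ds, truth = small_noiseless_section
        name = small_sc.inhaled_channel
        analyte = next(a for a in small_sc.analyte_definitions() if a.name == name)
        img = extract_ion_image(ds, analyte)
        np.testing.assert_allclose(img.grid, truth.noiseless_channels[name])

    def test_ppm_tolerance_window(self):
        a = AnalyteDefinition("x", 500.0, tolerance=20.0, tolerance_unit="ppm")
        lo, hi = a.window()
        np.testing.assert_allclose([lo, hi], [500.0 - 0.01, 500.0 + 0.01])


# ---------------------------------------------------------------------------
# tissue mask
# ---------------------------------------------------------------------------

class TestTissueMask:
    def test_uniform_phantom_exact(self):
        matrix = np.zeros((9, 2))
        matrix[4:] = [5.0, 5.0]
        coords = [(i % 3 + 1, i // 3 + 1) for i in range(9)]
        ds = continuous_dataset(matrix, coords=coords)
        mask = compute_tissue_mask(dataset=ds, threshold_quantile=0.0)
        np.testing.assert_array_equal(mask.grid.ravel(), matrix.sum(1) > 0)

    def test_all_zero_errors(self):
        ds = continuous_dataset(np.zeros((4, 2)))
        with pytest.raises(EmptyDatasetError):
            compute_tissue_mask(dataset=ds)

    def test_default_scenario_jaccard(self, default_section):
        ds, truth = default_section
        mask = compute_tissue_mask(dataset=ds)
        assert jaccard(mask.grid, truth.tissue_mask) >= 0.95

    def test_marker_union_method(self, default_sc, default_section):
        from lungtarget.analytes import by_role

        ds, truth = default_section
        imgs = [
            extract_ion_image(ds, by_role(default_sc.analyte_definitions(), role))
            for role in ("marker_alveolar", "marker_bronchiolar", "marker_vessel")
        ]
        mask = compute_tissue_mask(marker_images=imgs, method="marker_union",
                                  threshold_quantile=0.45)
        assert jaccard(mask.grid, truth.tissue_mask) >= 0.8
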