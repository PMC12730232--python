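"""Marker-ion segmentation and per-ROI spectral preprocessing."""

import numpy as np
import pytest

from simslipid.datacube import bin_events
from simslipid.roi import (
    RoiMask,
    marker_image,
    preprocess_roi,
    read_mask_tsv,
    remove_interference,
    roi_spectrum,
    segment_rois,
    tic_normalize,
    write_mask_tsv,
)
from simslipid.simulate import render_arm


def _image_with_blobs(axis, nx=32, ny=32, centers=((8, 8), (24, 22)), r=4,
                      marker_mz=184.0733, level=100.0):
    events = []
    for cy, cx in centers:
        for y in range(ny):
            for x in range(nx):
                if (x - cx) ** 2 + (y - cy) ** 2 <= r**2:
                    events.append(((x, y), marker_mz, level))
    return bin_events(events, axis, nx, ny, 1)


class TestMarkerImage:
    def test_positive_marker_is_cell_footprint(self, axis):
        img = _image_with_blobs(axis)
        marker = marker_image(img)
        assert (marker.values > 0).sum() == pytest.approx(
            2 * ((np.arange(-4, 5)[:, None] ** 2 +
                  np.arange(-4, 5)[None, :] ** 2) <= 16).sum()
        )

    def test_negative_marker_sums_two_fa_windows(self, axis):
        events = [((0, 0), 255.233, 3.0), ((0, 0), 283.264, 4.0)]
        img = bin_events(events, axis, 2, 2, -1)
        marker = marker_image(img)
        assert marker.values[0, 0] == 7.0

    def test_marker_contrast_on_synthetic_fixture(self, small_sim_config):
        image, truth = render_arm(small_sim_config, "control", 1)
        marker = marker_image(image)
        cells = np.zeros((image.ny, image.nx), bool)
        for m in truth.cell_masks:
            cells |= m.mask
        inside = marker.values[cells].mean()
        outside = marker.values[~cells].mean() + 1e-12
        assert inside >= 5 * outside


class TestSegmentRois:
    def test_two_clean_blobs(self, axis):
        img = _image_with_blobs(axis)
        rois = segment_rois(marker_image(img), min_roi_pixels=10)
        assert len(rois) == 2
        assert rois[0].anchor < rois[1].anchor  # deterministic ordering
        assert all(r.pixel_count >= 10 for r in rois)

    def test_uniform_image_yields_nothing(self):
        from simslipid.datacube import IonImage

        marker = IonImage(nx=8, ny=8, values=np.ones((8, 8)), center_mz=184.07,
                          half_width=0.05)
        assert segment_rois(marker) == []

    def test_all_zero_marker(self):
        from simslipid.datacube import IonImage

        marker = IonImage(nx=8, ny=8, values=np.zeros((8, 8)), center_mz=184.07,
                          half_width=0.05)
        assert segment_rois(marker) == []

    def test_recovers_planted_cells_under_poisson_noise(self, sim_config):
        image, truth = render_arm(sim_config, "control", 1)
        rois = segment_rois(marker_image(image))
        assert len(rois) >= 4
        matched = 0
        for planted in truth.cell_masks:
            best = max(
                (np.logical_and(r.mask, planted.mask).sum()
                 / np.logical_or(r.mask, planted.mask).sum()
                 for r in rois),
                default=0.0,
            )
            matched += best >= 0.8
        assert matched >= 4


class TestRoiSpectrum:
    def test_single_pixel_mask(self, small_axis):
        img = bin_events([((1, 1), 105.0, 9.0)], small_axis, 4, 4, 1)
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = True
        spec = roi_spectrum(img, RoiMask(mask, 1))
        assert np.array_equal(spec.raw, img.pixel_spectrum(1, 1))

    def test_partition_additivity(self, small_axis, rng):
        events = [
            ((int(rng.integers(4)), int(rng.integers(4))),
             float(rng.uniform(100, 110)), 1.0)
            for _ in range(300)
        ]
        img = bin_events(events, small_axis, 4, 4, 1)
        full = roi_spectrum(img, RoiMask(np.ones((4, 4), bool), 1))
        top = np.zeros((4, 4), bool); top[:2] = True
        bottom = ~top
        parts = (roi_spectrum(img, RoiMask(top, 1)).raw
                 + roi_spectrum(img, RoiMask(bottom, 2)).raw)
        assert np.array_equal(full.raw, parts)
        assert full.raw.sum() == pytest.approx(300)

    def test_empty_mask_rejected(self, small_axis):
        img = bin_events([((0, 0), 105.0, 1.0)], small_axis, 2, 2, 1)
        with pytest.raises(ValueError, match="empty"):
            roi_spectrum(img, RoiMask(np.zeros((2, 2), bool), 1))


class TestInterference:
    def test_planted_indium_peak_zeroed(self, small_sim_config):
        image, truth = render_arm(small_sim_config, "control", 1)
        rois = truth.cell_masks
        # take a background-covering mask to see substrate peaks
        bg = np.ones((image.ny, image.nx), bool)
        for m in rois:
            bg &= ~m.mask
        spec = roi_spectrum(image, RoiMask(bg, 99))
        axis = spec.mass_axis
        in_bin = int(axis.bin_of(114.904))
        assert spec.raw[in_bin] > 0
        cleaned = remove_interference(spec)
        assert cleaned.raw[in_bin] == 0
        assert in_bin in cleaned.removed_bins

    def test_empty_list_is_identity(self, small_axis):
        img = bin_events([((0, 0), 105.0, 5.0)], small_axis, 2, 2, 1)
        spec = roi_spectrum(img, RoiMask(np.ones((2, 2), bool), 1))
        same = remove_interference(spec, interference_mzs=[])
        assert np.array_equal(same.raw, spec.raw)

    def test_idempotent(self, small_axis):
        img = bin_events([((0, 0), 105.0, 5.0), ((0, 0), 103.0, 2.0)],
                         small_axis, 2, 2, 1)
        spec = roi_spectrum(img, RoiMask(np.ones((2, 2), bool), 1))
        once = remove_interference(spec, interference_mzs=[103.0])
        twice = remove_interference(once, interference_mzs=[103.0])
        assert np.array_equal(once.raw, twice.raw)
        assert once.removed_bins == twice.removed_bins


class TestTicNormalize:
    def test_simple_fractions(self, small_axis):
        img = bin_events([((0, 0), 100.01, 2.0), ((0, 0), 105.0, 2.0)],
                         small_axis, 1, 1, 1)
        spec = tic_normalize(roi_spectrum(img, RoiMask(np.ones((1, 1), bool), 1)))
        nz = spec.normalized[spec.normalized > 0]
        assert np.allclose(nz, [0.5, 0.5])
        assert spec.normalized.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, small_axis, rng):
        raw = rng.integers(0, 50, size=small_axis.n_bins).astype(float)
        from simslipid.roi import RoiSpectrum

        a = RoiSpectrum(1, raw, small_axis, 1)
        b = RoiSpectrum(1, raw * 10, small_axis, 1)
        assert np.allclose(tic_normalize(a).normalized,
                           tic_normalize(b).normalized)

    def test_zero_total_rejected(self, small_axis):
        from simslipid.roi import RoiSpectrum

        spec = RoiSpectrum(1, np.zeros(small_axis.n_bins), small_axis, 1)
        with pytest.raises(ValueError):
            tic_normalize(spec)

    def test_removal_happens_before_normalization(self, small_axis):
        img = bin_events([((0, 0), 103.0, 50.0), ((0, 0), 105.0, 50.0)],
                         small_axis, 1, 1, 1)
        mask = RoiMask(np.ones((1, 1), bool), 1)
        spec = preprocess_roi(img, mask, interference_mzs=[103.0])
        assert spec.normalized[int(small_axis.bin_of(103.0))] == 0
        assert spec.normalized[int(small_axis.bin_of(105.0))] == pytest.approx(1.0)


def test_mask_tsv_roundtrip(tmp_path, rng):
    mask = RoiMask(rng.random((8, 8)) > 0.6, 3)
    path = tmp_path / "mask.tsv"
    write_mask_tsv(mask, path)
    back = read_mask_tsv(path, shape=(8, 8), roi_id=3)
    assert np.array_equal(back.mask, mask.mask)
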