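"""ROI measurement: background estimation, thresholding, pooling, blinding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ps6quant import (RegionROI, SectionImage, StainFieldSpec, aggregate_animal,
                      blind_order, estimate_background, generate_section,
                      measure_roi, stain_mask)
from ps6quant.quantify import (BackgroundEstimate, StainMeasurement,
                               rasterize_polygon)

FULL = [(0.0, 0.0), (31.0, 0.0), (31.0, 31.0), (0.0, 31.0)]


def _image(arr, **kw):
    return SectionImage(np.asarray(arr, dtype=float), **kw)


def _full_roi(shape):
    h, w = shape
    return RegionROI(region="NDI", polygon=[(0, 0), (w - 1, 0),
                                            (w - 1, h - 1), (0, h - 1)])


class TestBackground:
    def test_constant_field(self):
        img = _image(np.full((32, 32), 0.8))
        bg = estimate_background(img, _full_roi((32, 32)))
        assert bg.level == pytest.approx(0.2)
        assert bg.mad == 0.0

    def test_half_half_median_midpoint(self):
        data = np.full((32, 32), 0.8)
        data[:16] = 0.2
        bg = estimate_background(_image(data), _full_roi((32, 32)))
        assert bg.level == pytest.approx(0.5)  # midpoint of 0.2 and 0.8 inverted

    def test_recovers_generator_background(self):
        # cells cover <10% of the ROI: estimate within 2 MAD of truth
        for seed in range(50):
            spec = StainFieldSpec(image_shape=(96, 96), seed=seed)
            img, truth = generate_section(spec)
            assert truth.fraction() < 0.10
            roi = _full_roi(img.shape)
            bg = estimate_background(img, roi)
            assert abs(bg.level - (1 - spec.background_level)) <= 2 * bg.mad

    def test_roi_outside_image_is_error(self):
        img = _image(np.full((32, 32), 0.8))
        roi = RegionROI(region="NDI", polygon=[(0, 0), (40, 0), (40, 40), (0, 40)])
        with pytest.raises(ValueError, match="outside image"):
            estimate_background(img, roi)


class TestStainMask:
    def test_noise_free_mask_equals_ground_truth(self):
        spec = StainFieldSpec(image_shape=(96, 96), noise_sd=0.0,
                              background_stain_sd=0.0, seed=5)
        img, truth = generate_section(spec)
        roi = _full_roi(img.shape)
        # identical within the ROI raster (the ROI polygon excludes the
        # border pixel ring, the frame-level truth does not)
        assert np.array_equal(stain_mask(img, roi),
                              truth.mask & roi.pixel_mask(img.shape))

    def test_cell_free_noisy_roi_nearly_empty(self):
        # default noise, no cells: k=5 admits at most 1% false positives
        for seed in range(100):
            spec = StainFieldSpec(image_shape=(64, 64), cell_density=0.0,
                                  seed=seed)
            img, _ = generate_section(spec)
            roi = _full_roi(img.shape)
            m = measure_roi(img, roi)
            assert m.fraction <= 0.01

    def test_huge_k_gives_empty_mask(self):
        img, _ = generate_section(StainFieldSpec(image_shape=(64, 64), seed=1))
        assert stain_mask(img, _full_roi(img.shape), k=1e9).sum() == 0

    def test_k_must_be_positive(self):
        img, _ = generate_section(StainFieldSpec(image_shape=(64, 64), seed=1))
        with pytest.raises(ValueError, match="k must be positive"):
            stain_mask(img, _full_roi(img.shape), k=0)


class TestMeasureROI:
    def test_ten_of_hundred_pixels(self):
        # noise off: 10 stained px in a 100-px ROI -> fraction 0.1
        data = np.full((10, 10), 0.85)
        data.flat[:10] = 0.5
        roi = RegionROI(region="NDI", mask=np.ones((10, 10), dtype=bool))
        m = measure_roi(_image(data), roi)
        assert m.fraction == pytest.approx(0.1)
        assert m.stained_area_px == 10 and m.total_area_px == 100

    def test_fully_stained_roi_against_reference_background(self):
        # a saturated ROI measured against a stain-free reference background
        data = np.full((10, 10), 0.5)
        roi = RegionROI(region="NDI", mask=np.ones((10, 10), dtype=bool))
        reference = BackgroundEstimate(level=0.15, mad=0.01)
        m = measure_roi(_image(data), roi, background=reference)
        assert m.fraction == 1.0

    def test_areas_in_physical_units(self):
        data = np.full((10, 10), 0.85)
        data.flat[:10] = 0.5
        roi = RegionROI(region="NDI", mask=np.ones((10, 10), dtype=bool))
        m = measure_roi(_image(data, resolution_um=1.6), roi)
        assert m.total_area_um2 == pytest.approx(100 * 1.6 ** 2)
        assert m.stained_area_um2 == pytest.approx(10 * 1.6 ** 2)

    def test_recovery_against_ground_truth(self):
        # measured vs true fraction across 40 varied ROIs at default noise
        errs = []
        for seed in range(40):
            mult = [0.5, 1.0, 2.0, 3.0][seed % 4]
            spec = StainFieldSpec(image_shape=(96, 96),
                                  cell_density=350.0 * mult, seed=seed)
            img, truth = generate_section(spec)
            roi = _full_roi(img.shape)
            m = measure_roi(img, roi)
            errs.append(abs(m.fraction - truth.fraction()))
        assert np.mean(errs) <= 0.02

    def test_zero_area_roi_is_error(self):
        img = _image(np.full((32, 32), 0.8))
        roi = RegionROI(region="NDI", mask=np.zeros((32, 32), dtype=bool))
        with pytest.raises(ValueError, match="zero pixel area"):
            measure_roi(img, roi)

    def test_measurement_invariants(self):
        with pytest.raises(ValueError):
            StainMeasurement(stained_area_px=5, total_area_px=0,
                             stained_area_um2=5, total_area_um2=0,
                             fraction=0, threshold_used=0.2)
        with pytest.raises(ValueError):
            StainMeasurement(stained_area_px=11, total_area_px=10,
                             stained_area_um2=11, total_area_um2=10,
                             fraction=1.1, threshold_used=0.2)


def _meas(stained, total):
    return StainMeasurement(stained_area_px=stained, total_area_px=total,
                            stained_area_um2=float(stained),
                            total_area_um2=float(total),
                            fraction=stained / total, threshold_used=0.2)


class TestAggregate:
    def test_area_weighted_pool(self):
        pooled = aggregate_animal([_meas(10, 100), _meas(30, 100)])
        assert pooled.fraction == pytest.approx(0.2)
        assert pooled.level == "animal_region"

    def test_single_roi_identity(self):
        pooled = aggregate_animal([_meas(7, 50)])
        assert pooled.fraction == 7 / 50

    def test_equal_area_pool_equals_mean_of_ratios(self):
        ms = [_meas(5, 200), _meas(40, 200), _meas(11, 200)]
        pooled = aggregate_animal(ms)
        assert pooled.fraction == pytest.approx(np.mean([m.fraction for m in ms]))

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            aggregate_animal([])

    @given(st.lists(st.tuples(st.integers(0, 1000), st.integers(1, 1000)),
                    min_size=1, max_size=8))
    def test_pooled_fraction_between_min_and_max(self, pairs):
        ms = [_meas(min(s, t), t) for s, t in pairs]
        pooled = aggregate_animal(ms)
        fracs = [m.fraction for m in ms]
        assert min(fracs) - 1e-12 <= pooled.fraction <= max(fracs) + 1e-12


class TestRasterize:
    def test_pixel_center_rule(self):
        # rectangle from 0.5 to 2.5 covers centers 1 and 2 in each axis
        mask = rasterize_polygon([(0.5, 0.5), (2.5, 0.5), (2.5, 2.5), (0.5, 2.5)],
                                 (5, 5))
        expected = np.zeros((5, 5), dtype=bool)
        expected[1:3, 1:3] = True
        assert np.array_equal(mask, expected)

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError, match="simple"):
            rasterize_polygon([(0, 0), (4, 4), (4, 0), (0, 4)], (8, 8))


class TestBlindOrder:
    def _records(self, n):
        return pd.DataFrame({
            "blinded_id": [f"B{i:04d}" for i in range(n)],
            "roi_id": [f"a{i}" for i in range(n)],
            "animal_id": [f"an{i % 4}" for i in range(n)],
            "group": ["control", "trained"] * (n // 2),
            "region": ["NDI"] * n,
            "image_path": [f"images/a{i}.tif" for i in range(n)],
        })

    def test_permutation_and_blindness(self):
        recs = self._records(8)
        presentation, key = blind_order(recs, seed=3)
        assert sorted(presentation["blinded_id"]) == sorted(recs["blinded_id"])
        # schema-level blindness: nothing identifying in presented records
        assert set(presentation.columns) == {"position", "blinded_id",
                                             "image_path"}
        for col in ("group", "animal_id", "region", "roi_id"):
            assert col not in presentation.columns
        # the sealed key carries the unblinding information
        assert {"blinded_id", "animal_id", "group"} <= set(key.columns)

    def test_seed_reproducible(self):
        recs = self._records(8)
        p1, _ = blind_order(recs, seed=11)
        p2, _ = blind_order(recs, seed=11)
        assert p1.equals(p2)
        p3, _ = blind_order(recs, seed=12)
        assert not p1["blinded_id"].tolist() == p3["blinded_id"].tolist()

    def test_empty_input(self):
        presentation, key = blind_order([], seed=0)
        assert presentation.empty and key.empty

    def test_duplicate_blinded_ids_rejected(self):
        recs = self._records(4)
        recs.loc[1, "blinded_id"] = recs.loc[0, "blinded_id"]
        with pytest.raises(ValueError, match="duplicate"):
            blind_order(recs, seed=0)
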