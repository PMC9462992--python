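"""Preprocessing, heatmaps, endpoint decoding, augmentation and the split."""

import numpy as np
import pandas as pd
import pytest

from aopmeter import dataio, phantom
from aopmeter.dataio import (DetectionError, Sample, SpatialMap, augment,
                             extract_endpoints, make_heatmaps, preprocess,
                             split_by_patient)


class TestPreprocess:
    def test_intensity_endpoints(self):
        img = np.full((32, 32), 255.0)
        out, _ = preprocess(img, (32, 32))
        assert np.allclose(out, 1.0)
        out0, _ = preprocess(np.zeros((32, 32)), (32, 32))
        assert np.allclose(out0, -1.0)
        outm, _ = preprocess(np.full((32, 32), 127.5), (32, 32))
        assert np.allclose(outm, 0.0, atol=1e-6)

    def test_spatial_map_scales_points(self):
        _, smap = preprocess(np.zeros((652, 800)), (384, 416))
        u, v = 0.35, 0.6
        x, y = smap.apply((800 * u, 652 * v))
        assert x == pytest.approx(416 * u)
        assert y == pytest.approx(384 * v)

    def test_spatial_map_invertible(self):
        smap = SpatialMap(sx=416 / 800, sy=384 / 652)
        p = (123.4, 456.7)
        back = smap.invert(smap.apply(p))
        assert np.allclose(back, p, atol=1e-9)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((0, 0)))


class TestHeatmaps:
    SHAPE = (64, 64)

    def test_peak_is_one_on_integer_endpoint(self):
        hm = make_heatmaps(((10, 20), (40, 30)), self.SHAPE, sigma=6)
        assert hm[0, 30, 40] == pytest.approx(1.0)  # map 0 = right endpoint
        assert hm[1, 20, 10] == pytest.approx(1.0)  # map 1 = left endpoint
        assert hm[2, 25, 25] == pytest.approx(1.0)  # map 2 = midpoint

    def test_value_at_sigma(self):
        hm = make_heatmaps(((10, 20), (40, 30)), self.SHAPE, sigma=6)
        assert hm[1, 20, 16] == pytest.approx(np.exp(-0.5), rel=1e-5)

    def test_round_trip_argmax(self):
        smap = SpatialMap(1.0, 1.0)
        hm = make_heatmaps(((10, 20), (40, 30)), self.SHAPE, sigma=4)
        left, right = extract_endpoints(hm, smap)
        assert left == (10.0, 20.0) and right == (40.0, 30.0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            make_heatmaps(((1, 1), (2, 2)), self.SHAPE, sigma=0)

    def test_endpoint_outside_rejected(self):
        with pytest.raises(ValueError):
            make_heatmaps(((-3, 1), (2, 2)), self.SHAPE, sigma=2)


class TestExtractEndpoints:
    def test_tie_breaks_row_major(self):
        hm = np.zeros((3, 8, 8))
        hm[:, 2, 5] = 1.0
        hm[:, 4, 1] = 1.0  # equal maximum, later in row-major order
        left, right = extract_endpoints(hm, SpatialMap(1.0, 1.0))
        assert right == (5.0, 2.0)

    def test_maps_back_through_scale(self):
        hm = np.zeros((3, 16, 16))
        hm[0, 7, 10] = 1.0
        hm[1, 3, 2] = 1.0
        left, right = extract_endpoints(hm, SpatialMap(sx=0.5, sy=0.25))
        assert right == (20.0, 28.0)
        assert left == (4.0, 12.0)

    def test_all_zero_heatmap_fails(self):
        with pytest.raises(DetectionError):
            extract_endpoints(np.zeros((3, 8, 8)), SpatialMap(1.0, 1.0))


def _mk_sample(img, endpoints, sigma=4.0):
    h, w = img.shape
    heat = (make_heatmaps(endpoints, (h, w), sigma) if endpoints
            else np.zeros((3, h, w), np.float32))
    return Sample(image=img.astype(np.float32),
                  mask=(img > 0).astype(np.uint8),
                  heatmaps=heat, class_label=1, endpoints=endpoints,
                  spatial_map=SpatialMap(1.0, 1.0), transform_record={})


class TestAugment:
    def test_identity_transform(self, rng):
        img = rng.random((32, 32)).astype(np.float32) * 2 - 1
        s = _mk_sample(img, ((8.0, 8.0), (24.0, 24.0)))
        out = augment(s, rng, rotation_range=(0, 0), scale_range=(1, 1))
        assert np.allclose(out.image, s.image, atol=1e-6)
        assert np.array_equal(out.mask, s.mask)
        assert np.allclose(out.endpoints, s.endpoints, atol=1e-9)

    def test_rotation_closed_form(self):
        rng = np.random.default_rng(0)
        img = np.zeros((33, 33), np.float32)
        s = _mk_sample(img, ((20.0, 16.0), (26.0, 16.0)))
        out = augment(s, rng, rotation_range=(30, 30), scale_range=(1, 1))
        c = np.array([16.0, 16.0])
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        for p_in, p_out in zip(s.endpoints, out.endpoints):
            expect = R @ (np.array(p_in) - c) + c
            assert np.allclose(p_out, expect, atol=1e-6)
        assert out.transform_record["rotation_deg"] == pytest.approx(30.0)

    def test_mask_labels_preserved(self, desk_spec, rng):
        ps = phantom.generate_standard(desk_spec, "P0", 3)
        samples = dataio.samples_from_phantoms([ps])
        out = augment(samples[0], rng)
        assert set(np.unique(out.mask)) <= set(np.unique(samples[0].mask))

    def test_heatmaps_rebuilt_at_new_endpoints(self, rng):
        img = np.zeros((48, 48), np.float32)
        s = _mk_sample(img, ((14.0, 20.0), (34.0, 26.0)))
        out = augment(s, rng, rotation_range=(-20, 20), scale_range=(0.95, 1.05))
        (xl, yl), (xr, yr) = out.endpoints
        k = np.unravel_index(np.argmax(out.heatmaps[0]), out.heatmaps[0].shape)
        assert np.hypot(k[1] - xr, k[0] - yr) < 1.0

    def test_out_of_frame_endpoints_fall_back_to_identity(self):
        rng = np.random.default_rng(1)
        img = np.zeros((32, 32), np.float32)
        s = _mk_sample(img, ((1.0, 1.0), (30.0, 30.0)))
        out = augment(s, rng, rotation_range=(45, 45), scale_range=(1.4, 1.4),
                      max_retries=3)
        assert out.endpoints == s.endpoints  # unaugmented fallback


class TestSplitByPatient:
    @staticmethod
    def manifest(counts):
        rows = []
        for pid, (n_std, n_non) in counts.items():
            for k in range(n_std):
                rows.append({"patient_id": pid, "is_standard": True})
            for k in range(n_non):
                rows.append({"patient_id": pid, "is_standard": False})
        return pd.DataFrame(rows)

    def test_divisible_case_exact(self):
        man = self.manifest({f"P{i}": (1, 0) for i in range(10)})
        plan = split_by_patient(man, seed=0)
        assert (len(plan.train_ids), len(plan.val_ids), len(plan.test_ids)) == (5, 2, 3)

    def test_patient_sets_disjoint(self):
        man = self.manifest({f"P{i}": (2, 1) for i in range(13)})
        plan = split_by_patient(man, seed=4)
        t, v, e = map(set, (plan.train_ids, plan.val_ids, plan.test_ids))
        assert not (t & v or t & e or v & e)
        assert t | v | e == set(man.patient_id)

    def test_stratified_shares_near_target(self, rng):
        counts = {f"P{i}": (int(rng.integers(1, 5)), int(rng.integers(0, 4)))
                  for i in range(20)}
        man = self.manifest(counts)
        plan = split_by_patient(man, seed=9)
        max_patient = max(a + b for a, b in counts.values())
        for stratum in (True, False):
            total = int((man.is_standard == stratum).sum())
            got = int(((man.is_standard == stratum)
                       & man.patient_id.isin(plan.test_ids)).sum())
            assert abs(got - 0.3 * total) <= max_patient

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            split_by_patient(self.manifest({"P0": (1, 0), "P1": (1, 0)}))
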