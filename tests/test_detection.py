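"""Detection: count exactness, area triage, error modes, corrections, crops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitia.detection import (
    STATUS_OUT_OF_THRESHOLD,
    STATUS_OVERLAP,
    STATUS_READY,
    Detection,
    DetectionParams,
    DetectionReport,
    Edit,
    apply_corrections,
    audit_error_rate,
    detect_flies,
    extract_crop,
    status_for_area,
)
from sitia.plate import PlateImage
from sitia.synthetic import SceneSpec, render_plate

FLY_LEN = 24.0
PARAMS = DetectionParams.for_fly_length(FLY_LEN)


def _scene(**kwargs):
    defaults = dict(
        n_flies=30, width_px=900, height_px=700, fly_length_px=FLY_LEN, seed=1
    )
    defaults.update(kwargs)
    return render_plate(SceneSpec(**defaults))


class TestDetectFlies:
    def test_clean_scene_count_and_centroid_match(self):
        image, records = _scene(n_flies=90, width_px=1000, height_px=750, seed=2)
        report = detect_flies(image, PARAMS)
        assert len(report) == 90
        assert all(d.status == STATUS_READY for d in report.detections)
        # every detection matches a distinct ground-truth fly closely
        taken = set()
        for d in report.detections:
            dists = [
                (np.hypot(d.centroid_x - r.centroid_x, d.centroid_y - r.centroid_y), i)
                for i, r in enumerate(records)
            ]
            dist, idx = min(dists)
            assert dist <= FLY_LEN / 2
            assert idx not in taken
            taken.add(idx)

    def test_touching_pair_flagged_overlap(self):
        image, _ = _scene(n_flies=6, overlap_pairs=1, seed=5)
        report = detect_flies(image, PARAMS)
        counts = report.counts()
        assert counts[STATUS_OVERLAP] == 1  # the merged pair component
        assert counts[STATUS_READY] == 4

    def test_isolated_stain_is_false_positive_ready(self):
        image, records = _scene(n_flies=10, n_stains=1, seed=3)
        report = detect_flies(image, PARAMS)
        ready = report.counts()[STATUS_READY]
        assert ready == len(records) + 1  # stain misread as a valid fly

    def test_stain_touching_fly_inflates_past_max(self):
        image, _ = _scene(n_flies=10, n_stains=1, stain_touching_fly=True, seed=3)
        report = detect_flies(image, PARAMS)
        assert report.counts()[STATUS_OVERLAP] >= 1

    def test_blank_image_empty_report(self):
        blank = PlateImage(np.full((100, 120, 3), 224, dtype=np.uint8))
        report = detect_flies(blank, PARAMS)
        assert len(report) == 0

    def test_deterministic(self):
        image, _ = _scene(seed=8)
        a = detect_flies(image, PARAMS).to_json()
        b = detect_flies(image, PARAMS).to_json()
        assert a == b

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(min_area_px2=500, max_area_px2=400)


class TestAuditErrorRate:
    @pytest.mark.parametrize(
        "n, k, expected",
        [(9216, 49, 0.53), (100, 0, 0.00), (8, 1, 12.50)],
    )
    def test_values(self, n, k, expected):
        assert audit_error_rate(n, k) == expected

    def test_zero_detections_undefined(self):
        with pytest.raises(ValueError):
            audit_error_rate(0, 0)


class TestCorrections:
    @pytest.fixture()
    def report(self):
        image, _ = _scene(n_flies=10, n_stains=1, seed=3)
        return detect_flies(image, PARAMS)

    def test_remove_false_positive(self, report):
        victim = report.detections[0].detection_id
        out = apply_corrections(report, [Edit.remove(victim)])
        assert len(out) == len(report) - 1
        assert len(report) == 11  # original untouched

    def test_add_manual_detection(self, report):
        out = apply_corrections(report, [Edit.add(10, 10)])
        added = [d for d in out.detections if d.source == "manual"]
        assert len(added) == 1
        assert added[0].status == STATUS_READY
        ids = [d.detection_id for d in out.detections]
        assert len(ids) == len(set(ids))

    def test_empty_edits_identity(self, report):
        out = apply_corrections(report, [])
        assert out.to_json() == report.to_json()

    def test_unknown_id_raises(self, report):
        with pytest.raises(KeyError, match="999"):
            apply_corrections(report, [Edit.remove(999)])


class TestExtractCrop:
    def _detection(self, x, y):
        return Detection(0, x, y, (int(x) - 5, int(y) - 5, int(x) + 5, int(y) + 5), 50.0, STATUS_READY)

    def test_center_crop_equals_window(self):
        px = np.random.default_rng(0).integers(0, 255, (100, 100, 3), dtype=np.uint8)
        image = PlateImage(px)
        crop = extract_crop(image, self._detection(50, 50), 32)
        np.testing.assert_array_equal(crop, px[34:66, 34:66])

    def test_corner_crop_padded_to_exact_side(self):
        px = np.random.default_rng(0).integers(0, 255, (100, 100, 3), dtype=np.uint8)
        image = PlateImage(px)
        crop = extract_crop(image, self._detection(0, 0), 32)
        assert crop.shape == (32, 32, 3)
        # the padded corner replicates the image's edge pixel
        assert (crop[0, 0] == px[0, 0]).all()

    def test_deterministic(self):
        px = np.random.default_rng(1).integers(0, 255, (80, 80, 3), dtype=np.uint8)
        image = PlateImage(px)
        a = extract_crop(image, self._detection(12, 70), 48)
        b = extract_crop(image, self._detection(12, 70), 48)
        np.testing.assert_array_equal(a, b)


@settings(derandomize=True, max_examples=200)
@given(area=st.floats(min_value=1.0, max_value=10000.0))
def test_status_is_pure_function_of_area(area):
    params = DetectionParams(min_area_px2=100.0, max_area_px2=1000.0)
    status = status_for_area(area, params)
    if area > 1000.0:
        assert status == STATUS_OVERLAP
    elif area < 100.0:
        assert status == STATUS_OUT_OF_THRESHOLD
    else:
        assert status == STATUS_READY


def test_report_roundtrips(tmp_path):
    image, _ = _scene(seed=4)
    report = detect_flies(image, PARAMS)
    json_path = tmp_path / "report.json"
    report.to_json(json_path)
    back = DetectionReport.from_json(json_path)
    assert back.to_json() == report.to_json()
    csv_text = report.to_csv()
    assert csv_text.count("\n") == len(report) + 1
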