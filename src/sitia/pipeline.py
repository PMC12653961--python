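"""End-to-end orchestration: image -> detect -> classify -> route -> GCode.

The run directory receives every stage artifact (detection report, per-fly
classifications, route, laser program, annotated overlay, run report), so a
run is fully inspectable and reproducible from its config and seed.  Manual
corrections — detection edits and sex-label overrides — are declarative
inputs rather than interactive steps, and label corrections are appended to
a correction store for future retraining.

Only flies labeled female are routed and fired on: the entire point of the
sorting step is male-only release, so males are never targeted.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from sitia.classifier.data import FEMALE, MALE
from sitia.classifier.nn import Cnn6
from sitia.classifier.training import canonical_resize, load_model, predict_sex
from sitia.detection import (
    STATUS_OUT_OF_THRESHOLD,
    STATUS_OVERLAP,
    STATUS_READY,
    DetectionParams,
    DetectionReport,
    Edit,
    apply_corrections,
    detect_flies,
    extract_crop,
)
from sitia.gcode import Calibration, generate_gcode
from sitia.plate import PlateImage
from sitia.router import AcoParams, RouteInstance, plan_route

# overlay palette: detection status and classified sex, as an operator would
# see them on screen
STATUS_COLORS = {
    STATUS_READY: (0, 170, 0),  # green
    STATUS_OVERLAP: (220, 0, 0),  # red
    STATUS_OUT_OF_THRESHOLD: (255, 140, 0),  # orange
}
SEX_COLORS = {FEMALE: (255, 105, 180), MALE: (30, 90, 220)}  # pink / blue


def calibration_for_image(
    width_px: int,
    height_px: int,
    plate_width_mm: float = 140.0,
    plate_height_mm: float = 101.0,
) -> Calibration:
    """Calibration mapping the full image onto the physical plate rectangle."""
    return Calibration(
        mm_per_px_x=plate_width_mm / width_px,
        mm_per_px_y=plate_height_mm / height_px,
        plate_width_mm=plate_width_mm,
        plate_height_mm=plate_height_mm,
        flip_y=True,
    )


@dataclass
class PipelineConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    model_dir: str | Path | None = None
    crop_px: int = 48
    route_method: str = "greedy"
    aco: AcoParams | None = None
    calibration: Calibration | None = None  # default: derived from image size
    laser_power: int = 255
    dwell_ms: int = 500
    out_dir: str | Path = "run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {}
        if "detection" in doc:
            kwargs["detection"] = DetectionParams(**doc["detection"])
        if "aco" in doc:
            kwargs["aco"] = AcoParams(**doc["aco"])
        if "calibration" in doc:
            kwargs["calibration"] = Calibration(**doc["calibration"])
        for key in (
            "model_dir",
            "crop_px",
            "route_method",
            "laser_power",
            "dwell_ms",
            "out_dir",
            "seed",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)


@dataclass
class RunReport:
    """Bookkeeping for one pipeline run; counts are internally consistent."""

    detected: dict[str, int]
    corrected_detections: int
    classified: dict[str, int]
    corrected_labels: int
    routed: int
    fired: int
    route_length_px: float
    route_method: str
    seed: int
    manifest: dict[str, str]
    wall_time_s: dict[str, float]

    def to_json(self, path: str | Path | None = None, include_timings: bool = True) -> str:
        doc = {
            "detected": self.detected,
            "corrected_detections": self.corrected_detections,
            "classified": self.classified,
            "corrected_labels": self.corrected_labels,
            "routed": self.routed,
            "fired": self.fired,
            "route_length_px": round(self.route_length_px, 3),
            "route_method": self.route_method,
            "seed": self.seed,
            "manifest": self.manifest,
        }
        if include_timings:
            doc["wall_time_s"] = {k: round(v, 3) for k, v in self.wall_time_s.items()}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _draw_box(px: np.ndarray, bbox, color, thickness: int = 2) -> None:
    x0, y0, x1, y1 = (int(v) for v in bbox)
    h, w = px.shape[:2]
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    t = thickness
    px[y0 : min(y0 + t, h), x0:x1] = color
    px[max(y1 - t, 0) : y1, x0:x1] = color
    px[y0:y1, x0 : min(x0 + t, w)] = color
    px[y0:y1, max(x1 - t, 0) : x1] = color


def render_overlay(
    image: PlateImage,
    report: DetectionReport,
    labels: dict[int, str] | None = None,
) -> np.ndarray:
    """Annotated copy of the plate: status boxes, sex-colored when classified."""
    px = image.pixels.copy()
    labels = labels or {}
    for d in report.detections:
        color = STATUS_COLORS[d.status]
        if d.detection_id in labels:
            color = SEX_COLORS[labels[d.detection_id]]
        _draw_box(px, d.bbox, color)
    return px


def store_corrections(
    corrections: list[dict],
    store_path: str | Path,
    crops: dict[int, np.ndarray] | None = None,
    crops_dir: str | Path | None = None,
) -> int:
    """Append label corrections (crop id, old label, new label) to a CSV log.

    When the corrected crops are supplied they are exported as PNGs for
    future retraining.  Returns the total number of rows now in the log.
    """
    store_path = Path(store_path)
    store_path.parent.mkdir(parents=True, exist_ok=True)
    new_file = not store_path.exists()
    with store_path.open("a", newline="") as fh:
        writer = csv.writer(fh)
        if new_file:
            writer.writerow(["crop_id", "old_label", "new_label"])
        for rec in corrections:
            writer.writerow([rec["crop_id"], rec["old_label"], rec["new_label"]])
    if crops and crops_dir is not None:
        crops_dir = Path(crops_dir)
        crops_dir.mkdir(parents=True, exist_ok=True)
        for rec in corrections:
            cid = rec["crop_id"]
            if cid in crops:
                Image.fromarray(crops[cid]).save(
                    crops_dir / f"crop_{cid:06d}_{rec['new_label']}.png"
                )
    with store_path.open(newline="") as fh:
        return sum(1 for _ in fh) - 1


def run_pipeline(
    image: PlateImage | str | Path,
    cfg: PipelineConfig,
    model: Cnn6 | None = None,
    detection_edits: list[Edit] | None = None,
    label_corrections: dict[int, str] | None = None,
) -> RunReport:
    """Execute detect -> classify -> route -> GCode and write all artifacts.

    ``label_corrections`` maps detection ids to operator-confirmed sex
    labels; they override the classifier and are appended to the correction
    store.  Deterministic for a fixed config, seed and model.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    times: dict[str, float] = {}

    if not isinstance(image, PlateImage):
        image = PlateImage.from_png(image)

    t0 = time.perf_counter()
    try:
        report = detect_flies(image, cfg.detection)
    except Exception as exc:  # noqa: BLE001 - stage name added for operators
        raise RuntimeError(f"detection stage failed: {exc}") from exc
    times["detect"] = time.perf_counter() - t0

    edits = detection_edits or []
    if edits:
        report = apply_corrections(report, edits)
    report.to_json(out / "detections.json")
    manifest["detections"] = "detections.json"

    if model is None:
        if cfg.model_dir is None:
            raise ValueError("pipeline needs a model (cfg.model_dir or model=)")
        model = load_model(cfg.model_dir)

    t0 = time.perf_counter()
    corrections = label_corrections or {}
    classified = []
    crops_by_id: dict[int, np.ndarray] = {}
    correction_rows = []
    side = model.spec.input_side_px
    for d in report.detections:
        if d.status != STATUS_READY:
            continue
        crop = extract_crop(image, d, cfg.crop_px)
        crops_by_id[d.detection_id] = crop
        label, confidence = predict_sex(model, canonical_resize(crop, side))
        corrected = d.detection_id in corrections
        if corrected and corrections[d.detection_id] != label:
            correction_rows.append(
                {
                    "crop_id": d.detection_id,
                    "old_label": label,
                    "new_label": corrections[d.detection_id],
                }
            )
            label = corrections[d.detection_id]
        classified.append(
            {
                "detection_id": d.detection_id,
                "centroid_x": round(d.centroid_x, 3),
                "centroid_y": round(d.centroid_y, 3),
                "label": label,
                "confidence": round(confidence, 4),
                "corrected": bool(corrected),
            }
        )
    times["classify"] = time.perf_counter() - t0
    (out / "classified.json").write_text(json.dumps(classified, indent=2))
    manifest["classified"] = "classified.json"
    if correction_rows:
        store_corrections(
            correction_rows,
            out / "corrections.csv",
            crops=crops_by_id,
            crops_dir=out / "retraining_crops",
        )
        manifest["corrections"] = "corrections.csv"

    # route over females only: males are never targeted
    females = [c for c in classified if c["label"] == FEMALE]
    t0 = time.perf_counter()
    instance = RouteInstance(
        origin=(0.0, 0.0),
        targets=tuple((c["centroid_x"], c["centroid_y"]) for c in females),
    )
    aco = cfg.aco
    if cfg.route_method == "aco" and aco is None:
        aco = AcoParams(seed=cfg.seed)
    route = plan_route(instance, cfg.route_method, aco_params=aco)
    times["route"] = time.perf_counter() - t0
    route.to_json(out / "route.json")
    manifest["route"] = "route.json"

    t0 = time.perf_counter()
    cal = cfg.calibration or calibration_for_image(image.width, image.height)
    program = generate_gcode(
        route, instance, cal, laser_power=cfg.laser_power, dwell_ms=cfg.dwell_ms
    )
    program.write(out / "kill.gcode")
    times["gcode"] = time.perf_counter() - t0
    manifest["gcode"] = "kill.gcode"

    overlay = render_overlay(
        image, report, {c["detection_id"]: c["label"] for c in classified}
    )
    Image.fromarray(overlay).save(out / "annotated.png")
    manifest["overlay"] = "annotated.png"

    run_report = RunReport(
        detected=report.counts(),
        corrected_detections=len(edits),
        classified={
            FEMALE: sum(1 for c in classified if c["label"] == FEMALE),
            MALE: sum(1 for c in classified if c["label"] == MALE),
        },
        corrected_labels=len(correction_rows),
        routed=len(females),
        fired=program.target_count,
        route_length_px=route.length_px,
        route_method=cfg.route_method,
        seed=cfg.seed,
        manifest=manifest,
        wall_time_s=times,
    )
    run_report.to_json(out / "report.json")
    return run_report
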