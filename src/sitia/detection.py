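"""First pipeline stage: localize and triage every individual on a plate.

Segmentation recipe: grayscale -> Gaussian blur -> Otsu threshold (dark
foreground on a light plate) -> morphological opening -> 8-connected
components.  Each component becomes one candidate detection triaged by area:

* ``ready``            — area within [min_area, max_area]: a single fly
* ``overlap``          — area above max_area: merged/touching individuals
* ``out_of_threshold`` — area below min_area: fragment or speck

Two error modes are expected from plate stains and handled by manual
correction rather than automatic splitting: a stain touching a fly inflates
the component past the maximum threshold, and an isolated stain of fly-like
area is misread as a valid detection.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu

from sitia.plate import PlateImage

STATUS_READY = "ready"
STATUS_OVERLAP = "overlap"
STATUS_OUT_OF_THRESHOLD = "out_of_threshold"
STATUSES = (STATUS_READY, STATUS_OVERLAP, STATUS_OUT_OF_THRESHOLD)

SOURCE_AUTOMATIC = "automatic"
SOURCE_MANUAL = "manual"

# components smaller than this many px^2 are noise specks, not candidates
COMPONENT_FLOOR_PX2 = 8.0


@dataclass(frozen=True)
class DetectionParams:
    """Segmentation and area-triage parameters.

    Defaults target a full-resolution 4000x3000 plate; use
    :meth:`for_fly_length` to derive scale-free thresholds from the expected
    fly body length in pixels.
    """

    min_area_px2: float = 400.0
    max_area_px2: float = 4000.0
    blur_radius_px: float = 2.0
    threshold_mode: str = "otsu"
    fixed_threshold: int | None = None
    morphology_open_px: int = 1

    def __post_init__(self) -> None:
        if self.min_area_px2 >= self.max_area_px2:
            raise ValueError(
                f"min_area_px2 ({self.min_area_px2}) must be < max_area_px2 "
                f"({self.max_area_px2})"
            )
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold_mode must be 'otsu' or 'fixed'")
        if self.threshold_mode == "fixed" and not (
            self.fixed_threshold is not None and 0 <= self.fixed_threshold <= 255
        ):
            raise ValueError("fixed threshold_mode needs fixed_threshold in 0..255")
        if self.blur_radius_px < 0 or self.morphology_open_px < 0:
            raise ValueError("blur radius and opening size must be non-negative")

    @classmethod
    def for_fly_length(cls, fly_length_px: float, **overrides) -> "DetectionParams":
        """Area thresholds scaled to the expected fly length.

        The band [0.18, 0.58] * length^2 was calibrated once against the
        renderer's measured component areas: single flies fall inside it and
        merged pairs above it across the supported size range.
        """
        kwargs = dict(
            min_area_px2=0.18 * fly_length_px**2,
            max_area_px2=0.58 * fly_length_px**2,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class Detection:
    """One localized candidate fly."""

    detection_id: int
    centroid_x: float
    centroid_y: float
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    area_px2: float
    status: str
    source: str = SOURCE_AUTOMATIC

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.source not in (SOURCE_AUTOMATIC, SOURCE_MANUAL):
            raise ValueError(f"unknown source {self.source!r}")
        if self.area_px2 <= 0:
            raise ValueError("area_px2 must be positive")
        x0, y0, x1, y1 = self.bbox
        if not (x0 <= self.centroid_x < x1 and y0 <= self.centroid_y < y1):
            raise ValueError("bbox must contain the centroid")


@dataclass
class DetectionReport:
    """All detections on one plate plus status tallies."""

    detections: list[Detection]
    image_width: int
    image_height: int

    def counts(self) -> dict[str, int]:
        tally = {s: 0 for s in STATUSES}
        for d in self.detections:
            tally[d.status] += 1
        return tally

    def __len__(self) -> int:
        return len(self.detections)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "image_width": self.image_width,
            "image_height": self.image_height,
            "counts": self.counts(),
            "detections": [
                {
                    "detection_id": d.detection_id,
                    "centroid_x": round(d.centroid_x, 3),
                    "centroid_y": round(d.centroid_y, 3),
                    "bbox": list(d.bbox),
                    "area_px2": round(d.area_px2, 3),
                    "status": d.status,
                    "source": d.source,
                }
                for d in self.detections
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DetectionReport":
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and not source.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        detections = [
            Detection(
                detection_id=d["detection_id"],
                centroid_x=d["centroid_x"],
                centroid_y=d["centroid_y"],
                bbox=tuple(d["bbox"]),
                area_px2=d["area_px2"],
                status=d["status"],
                source=d["source"],
            )
            for d in doc["detections"]
        ]
        return cls(detections, doc["image_width"], doc["image_height"])

    def to_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(
            [
                "detection_id",
                "centroid_x",
                "centroid_y",
                "x0",
                "y0",
                "x1",
                "y1",
                "area",
                "status",
                "source",
            ]
        )
        for d in self.detections:
            writer.writerow(
                [
                    d.detection_id,
                    f"{d.centroid_x:.3f}",
                    f"{d.centroid_y:.3f}",
                    *d.bbox,
                    f"{d.area_px2:.3f}",
                    d.status,
                    d.source,
                ]
            )
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


def status_for_area(area_px2: float, params: DetectionParams) -> str:
    """Pure area->status triage rule for automatic detections."""
    if area_px2 > params.max_area_px2:
        return STATUS_OVERLAP
    if area_px2 < params.min_area_px2:
        return STATUS_OUT_OF_THRESHOLD
    return STATUS_READY


def detect_flies(image: PlateImage, params: DetectionParams) -> DetectionReport:
    """Segment a plate image into candidate detections with status triage.

    Deterministic for fixed inputs; a blank image yields an empty report.
    """
    gray = image.gray()
    if params.blur_radius_px > 0:
        gray = gaussian(gray, sigma=params.blur_radius_px)
    if params.threshold_mode == "otsu":
        if gray.max() == gray.min():  # uniform image: nothing to segment
            return DetectionReport([], image.width, image.height)
        thresh = threshold_otsu(gray)
    else:
        thresh = params.fixed_threshold / 255.0
    fg = gray < thresh
    if params.morphology_open_px > 0:
        size = 2 * params.morphology_open_px + 1
        fg = ndimage.binary_opening(fg, structure=np.ones((size, size)))
    labels, n = ndimage.label(fg, structure=np.ones((3, 3)))
    detections: list[Detection] = []
    if n:
        idx = np.arange(1, n + 1)
        areas = ndimage.sum_labels(np.ones_like(gray), labels, idx)
        centroids = ndimage.center_of_mass(fg, labels, idx)
        slices = ndimage.find_objects(labels)
        det_id = 0
        for comp, (area, (cy, cx), sl) in enumerate(zip(areas, centroids, slices)):
            if area < COMPONENT_FLOOR_PX2:
                continue
            y_sl, x_sl = sl
            detections.append(
                Detection(
                    detection_id=det_id,
                    centroid_x=float(cx),
                    centroid_y=float(cy),
                    bbox=(x_sl.start, y_sl.start, x_sl.stop, y_sl.stop),
                    area_px2=float(area),
                    status=status_for_area(float(area), params),
                    source=SOURCE_AUTOMATIC,
                )
            )
            det_id += 1
    return DetectionReport(detections, image.width, image.height)


def audit_error_rate(n_detections: int, n_incorrect: int) -> float:
    """Percentage of incorrectly sorted detections, to two decimals."""
    if n_detections <= 0:
        raise ValueError("error rate is undefined for zero detections")
    if not 0 <= n_incorrect <= n_detections:
        raise ValueError("need 0 <= n_incorrect <= n_detections")
    return round(100.0 * n_incorrect / n_detections, 2)


# -- manual corrections ------------------------------------------------------


@dataclass(frozen=True)
class Edit:
    """One manual correction: add a missed fly, remove a false positive, or
    relabel a detection's status."""

    op: str  # add | remove | relabel
    detection_id: int | None = None
    x: float | None = None
    y: float | None = None
    status: str | None = None

    @classmethod
    def add(cls, x: float, y: float) -> "Edit":
        return cls(op="add", x=x, y=y)

    @classmethod
    def remove(cls, detection_id: int) -> "Edit":
        return cls(op="remove", detection_id=detection_id)

    @classmethod
    def relabel(cls, detection_id: int, status: str) -> "Edit":
        return cls(op="relabel", detection_id=detection_id, status=status)


def apply_corrections(report: DetectionReport, edits: list[Edit]) -> DetectionReport:
    """Return a new report with manual edits applied (input left unmodified).

    Added detections get ``source=manual`` and ``status=ready`` with a small
    nominal bounding box around the given centroid.
    """
    by_id = {d.detection_id: d for d in report.detections}
    removed: set[int] = set()
    relabeled: dict[int, str] = {}
    added: list[Detection] = []
    next_id = max(by_id, default=-1) + 1
    for e in edits:
        if e.op == "remove":
            if e.detection_id not in by_id:
                raise KeyError(f"remove edit references unknown id {e.detection_id}")
            removed.add(e.detection_id)
        elif e.op == "relabel":
            if e.detection_id not in by_id:
                raise KeyError(f"relabel edit references unknown id {e.detection_id}")
            if e.status not in STATUSES:
                raise ValueError(f"unknown status {e.status!r}")
            relabeled[e.detection_id] = e.status
        elif e.op == "add":
            if not (0 <= e.x < report.image_width and 0 <= e.y < report.image_height):
                raise ValueError(f"manual centroid ({e.x}, {e.y}) outside image bounds")
            half = 8
            x0 = max(0, int(e.x) - half)
            y0 = max(0, int(e.y) - half)
            x1 = min(report.image_width, int(e.x) + half + 1)
            y1 = min(report.image_height, int(e.y) + half + 1)
            added.append(
                Detection(
                    detection_id=next_id,
                    centroid_x=float(e.x),
                    centroid_y=float(e.y),
                    bbox=(x0, y0, x1, y1),
                    area_px2=float((x1 - x0) * (y1 - y0)),
                    status=STATUS_READY,
                    source=SOURCE_MANUAL,
                )
            )
            next_id += 1
        else:
            raise ValueError(f"unknown edit op {e.op!r}")
    kept = [
        replace(d, status=relabeled.get(d.detection_id, d.status))
        for d in report.detections
        if d.detection_id not in removed
    ]
    return DetectionReport(kept + added, report.image_width, report.image_height)


def extract_crop(image: PlateImage, detection: Detection, crop_px: int) -> np.ndarray:
    """Square uint8 crop of side ``crop_px`` centered on the detection.

    Crops that straddle the image border are edge-padded so the side length
    is always exact.
    """
    if crop_px < 16:
        raise ValueError("crop_px must be >= 16")
    cx = int(round(detection.centroid_x))
    cy = int(round(detection.centroid_y))
    half = crop_px // 2
    x0, x1 = cx - half, cx - half + crop_px
    y0, y1 = cy - half, cy - half + crop_px
    px = image.pixels
    pad_left = max(0, -x0)
    pad_top = max(0, -y0)
    pad_right = max(0, x1 - image.width)
    pad_bottom = max(0, y1 - image.height)
    window = px[max(0, y0) : min(image.height, y1), max(0, x0) : min(image.width, x1)]
    if any((pad_left, pad_top, pad_right, pad_bottom)):
        window = np.pad(
            window,
            ((pad_top, pad_bottom), (pad_left, pad_right), (0, 0)),
            mode="edge",
        )
    return np.ascontiguousarray(window)
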