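"""Synthetic anesthesia-plate scenes with exact ground truth.

Renders schematic *Drosophila suzukii* onto a light plate background: a dark
ellipsoidal body with two (dorsal view) or one (lateral view) wing ellipses.
Males carry one dark circular spot per wing; females carry a serrated
(toothed) ovipositor marker at the posterior — the two dimorphic cues a sex
classifier must learn.  Scenes can include touching fly pairs and mid-gray
plate "stains", which reproduce the two real-world detection error modes:
a merged component whose area exceeds the maximum threshold, and an isolated
stain misread as a valid fly.

Rendering is schematic rather than photorealistic on purpose: detection and
classification operate on the shape and contrast cues the markers provide,
and the generator must know the exact position, sex and touching-group of
every individual so that downstream accuracy can be scored automatically.

All geometry is seeded; identical specs produce bit-identical images.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw
from skimage.transform import rotate as _sk_rotate

from sitia.classifier.data import FEMALE, MALE, LabeledCrop
from sitia.plate import PlateImage

# Gray levels (fraction of white) for each rendered element.
PLATE_GRAY = 0.88
WING_GRAY = 0.55
STAIN_GRAY = 0.45
BODY_GRAY = 0.20
SPOT_GRAY = 0.05
NOISE_SD = 0.012
# Anything darker than this can only be a male wing spot.
DARK_MARKER_MAX = 0.13

MIN_SPRITE_LENGTH_PX = 8
MIN_CROP_PX = 16

DORSAL = "dorsal"
LATERAL = "lateral"

__all__ = [
    "SceneSpec",
    "GroundTruthRecord",
    "render_fly_sprite",
    "render_plate",
    "make_crop_dataset",
    "rule_based_sex",
    "posterior_tooth_count",
    "typical_fly_area",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "write_ground_truth_json",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic plate scene."""

    width_px: int = 1000
    height_px: int = 750
    n_flies: int = 90
    female_fraction: float = 0.5
    overlap_pairs: int = 0
    n_stains: int = 0
    stain_touching_fly: bool = False
    fly_length_px: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.overlap_pairs < 0 or 2 * self.overlap_pairs > self.n_flies:
            raise ValueError("need 2 * overlap_pairs <= n_flies")
        if self.n_stains < 0:
            raise ValueError("n_stains must be >= 0")
        if self.fly_length_px < MIN_SPRITE_LENGTH_PX:
            raise ValueError(f"fly_length_px must be >= {MIN_SPRITE_LENGTH_PX}")
        if min(self.width_px, self.height_px) < 4 * self.fly_length_px:
            raise ValueError("plate must be at least 4 fly lengths on each side")


@dataclass(frozen=True)
class GroundTruthRecord:
    """True position, sex, view and touching-group of one rendered fly."""

    fly_id: int
    centroid_x: float
    centroid_y: float
    sex: str
    view: str
    touching_group: int | None = None


def typical_fly_area(fly_length_px: float) -> float:
    """Expected foreground area (px^2) of one rendered fly of the given length.

    The constant was measured once from the renderer's geometry (body +
    wings + markers) and is used to derive scale-free detection thresholds.
    """
    return 0.42 * fly_length_px**2


# ---------------------------------------------------------------------------
# sprite rendering
# ---------------------------------------------------------------------------


def render_fly_sprite(
    sex: str,
    view: str,
    length_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one fly as an RGBA float patch (head up, axis vertical).

    Males get one dark circular spot per wing; females a serrated posterior
    marker (an ovipositor base fringed with small teeth).  Raises if
    ``length_px`` is below the minimum at which the markers are drawable.
    """
    if sex not in (MALE, FEMALE):
        raise ValueError(f"sex must be {MALE!r} or {FEMALE!r}")
    if view not in (DORSAL, LATERAL):
        raise ValueError(f"view must be {DORSAL!r} or {LATERAL!r}")
    if length_px < MIN_SPRITE_LENGTH_PX:
        raise ValueError(
            f"length_px={length_px} too small to draw the dimorphic markers; "
            f"minimum is {MIN_SPRITE_LENGTH_PX}"
        )
    L = float(length_px)
    h, w = int(math.ceil(1.6 * L)), int(math.ceil(1.3 * L))
    gray = np.zeros((h, w))
    alpha = np.zeros((h, w))
    cx = w / 2.0
    cy = 0.45 * h
    a = L / 2.0
    b = max(1.2, 0.18 * L) * (1.0 + 0.12 * (rng.random() - 0.5))

    def paint(rr, cc, value):
        gray[rr, cc] = value
        alpha[rr, cc] = 1.0

    # wings (under the body), extending down-outward from a root on the axis
    root_r, root_c = cy - 0.2 * a, cx
    wl = 0.62 * L
    ww = max(1.0, 0.11 * L)
    theta = math.radians(20.0 + 8.0 * rng.random())
    sides = (-1, 1) if view == DORSAL else (1,)
    spot_centers = []
    for s in sides:
        d_r, d_c = math.cos(theta), s * math.sin(theta)
        ctr_r = root_r + 0.5 * wl * d_r
        ctr_c = root_c + 0.5 * wl * d_c
        rr, cc = draw.ellipse(
            ctr_r, ctr_c, wl / 2.0, ww, shape=(h, w), rotation=-s * theta
        )
        paint(rr, cc, WING_GRAY)
        spot_centers.append((root_r + 0.68 * wl * d_r, root_c + 0.68 * wl * d_c))

    # body, head
    rr, cc = draw.ellipse(cy, cx, a, b, shape=(h, w))
    paint(rr, cc, BODY_GRAY)
    rr, cc = draw.disk((cy - a + 0.05 * L, cx), max(1.0, 0.10 * L), shape=(h, w))
    paint(rr, cc, BODY_GRAY)

    if sex == FEMALE:
        # ovipositor base plus a fringe of small teeth: the serrated marker
        base_r = max(1.5, 0.10 * L)
        base_c = max(1.5, 0.16 * L)
        rr, cc = draw.ellipse(cy + a - 0.02 * L, cx, base_r, base_c, shape=(h, w))
        paint(rr, cc, BODY_GRAY)
        yb = cy + a + 0.06 * L
        tl = max(2.0, 0.14 * L)
        tw = max(0.8, 0.045 * L)
        # teeth anchored within the base width so the sprite stays connected
        pitch = min(max(1.8, 0.085 * L), 0.6 * base_c)
        for i in range(4):
            x = cx + (i - 1.5) * pitch
            rr, cc = draw.polygon(
                [yb, yb, yb + tl], [x - tw, x + tw, x], shape=(h, w)
            )
            paint(rr, cc, BODY_GRAY)
    else:
        # radius floor keeps a solid spot core through bilinear re-rotation
        for sr, sc in spot_centers:
            rr, cc = draw.disk((sr, sc), max(1.8, 0.09 * L), shape=(h, w))
            paint(rr, cc, SPOT_GRAY)

    rgba = np.empty((h, w, 4), dtype=np.float32)
    rgba[..., 0] = rgba[..., 1] = rgba[..., 2] = gray
    rgba[..., 3] = alpha
    return rgba


def posterior_tooth_count(sprite_rgba: np.ndarray, length_px: float) -> int:
    """Count serration teeth of an (unrotated) sprite's posterior contour.

    Probes a scan row through the tooth band below the body and counts
    distinct runs of foreground pixels (the alternating protrusions).
    """
    mask = sprite_rgba[..., 3] > 0.5
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return 0
    tl = max(2.0, 0.14 * float(length_px))
    probe = rows[-1] - int(math.ceil(0.4 * tl))
    line = mask[probe]
    # runs of consecutive foreground pixels
    return int(np.sum(np.diff(np.concatenate(([0], line.view(np.int8), [0]))) == 1))


def rule_based_sex(pixels: np.ndarray) -> str:
    """Hand-coded sex rule for generated crops (the learnability oracle).

    A connected blob of very dark pixels (a wing spot) marks a male; crops
    without one are female (their marker is the toothed posterior, which
    contains no very dark pixels).  Exact on generator output by construction.
    """
    px = np.asarray(pixels)
    if px.dtype == np.uint8:
        px = px.astype(np.float64) / 255.0
    gray = px.mean(axis=2) if px.ndim == 3 else px
    labels, n = ndimage.label(gray < DARK_MARKER_MAX, structure=np.ones((3, 3)))
    if n and np.max(ndimage.sum_labels(np.ones_like(gray), labels, np.arange(1, n + 1))) >= 2:
        return MALE
    return FEMALE


# ---------------------------------------------------------------------------
# plate scenes
# ---------------------------------------------------------------------------


def _rotate_sprite(rgba: np.ndarray, angle_deg: float) -> np.ndarray:
    return _sk_rotate(
        rgba.astype(np.float64),
        angle_deg,
        resize=True,
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )


def _alpha_centroid(rgba: np.ndarray) -> tuple[float, float]:
    alpha = rgba[..., 3]
    total = alpha.sum()
    ys, xs = np.mgrid[0 : alpha.shape[0], 0 : alpha.shape[1]]
    return float((ys * alpha).sum() / total), float((xs * alpha).sum() / total)


class _Canvas:
    def __init__(self, height: int, width: int):
        self.gray = np.full((height, width), PLATE_GRAY)
        self.fg_mask = np.zeros((height, width), dtype=bool)

    def composite(self, rgba: np.ndarray, top: int, left: int) -> tuple[float, float]:
        """Alpha-blend a sprite; returns the realized (x, y) centroid."""
        h, w = rgba.shape[:2]
        ch, cw = self.gray.shape
        if top < 0 or left < 0 or top + h > ch or left + w > cw:
            raise ValueError("sprite placement out of canvas bounds")
        g, al = rgba[..., 0], rgba[..., 3]
        region = self.gray[top : top + h, left : left + w]
        region[...] = region * (1 - al) + g * al
        self.fg_mask[top : top + h, left : left + w] |= al > 0.5
        cy, cx = _alpha_centroid(rgba)
        return left + cx, top + cy


def _masks_touch(
    m1: np.ndarray, off1: tuple[int, int], m2: np.ndarray, off2: tuple[int, int]
) -> bool:
    """True if two local boolean masks intersect or are 8-adjacent."""
    t = min(off1[0], off2[0])
    l = min(off1[1], off2[1])
    b = max(off1[0] + m1.shape[0], off2[0] + m2.shape[0])
    r = max(off1[1] + m1.shape[1], off2[1] + m2.shape[1])
    g1 = np.zeros((b - t, r - l), dtype=bool)
    g2 = np.zeros_like(g1)
    g1[off1[0] - t : off1[0] - t + m1.shape[0], off1[1] - l : off1[1] - l + m1.shape[1]] = m1
    g2[off2[0] - t : off2[0] - t + m2.shape[0], off2[1] - l : off2[1] - l + m2.shape[1]] = m2
    return bool(
        np.any(ndimage.binary_dilation(g1, structure=np.ones((3, 3))) & g2)
    )


def render_plate(spec: SceneSpec) -> tuple[PlateImage, list[GroundTruthRecord]]:
    """Render a plate scene; returns the image and one record per fly.

    Non-pair flies are placed with centroid spacing of at least two fly
    lengths, which keeps their masks disjoint; members of an overlap pair are
    nudged together until their masks touch.  Stains are drawn only where no
    fly already is, so a touching stain merges with the fly's component
    without repainting it.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.fly_length_px
    margin = 1.1 * L
    min_sep = 2.0 * L
    canvas = _Canvas(spec.height_px, spec.width_px)

    n_f = int(round(spec.n_flies * spec.female_fraction))
    sexes = [FEMALE] * n_f + [MALE] * (spec.n_flies - n_f)
    rng.shuffle(sexes)

    lo_x, hi_x = margin, spec.width_px - margin
    lo_y, hi_y = margin, spec.height_px - margin
    if lo_x >= hi_x or lo_y >= hi_y:
        raise ValueError("plate too small for the fly length; enlarge the plate")

    anchors: list[tuple[float, float]] = []  # nominal positions already accepted
    max_tries = 400 * spec.n_flies
    tries = 0

    def sample_position(extra_sep: float = 0.0) -> tuple[float, float]:
        nonlocal tries
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "fly placement failed: plate too crowded — increase "
                    "width_px/height_px or reduce n_flies"
                )
            x = lo_x + (hi_x - lo_x) * rng.random()
            y = lo_y + (hi_y - lo_y) * rng.random()
            if all(
                math.hypot(x - ax, y - ay) >= min_sep + extra_sep
                for ax, ay in anchors
            ):
                return x, y

    def make_sprite(sex: str):
        view = DORSAL if rng.random() < 0.8 else LATERAL
        length = L * (0.95 + 0.10 * rng.random())
        sprite = render_fly_sprite(sex, view, length, rng)
        rotated = _rotate_sprite(sprite, rng.uniform(0.0, 360.0))
        return rotated, view

    records: list[GroundTruthRecord] = []
    single_info: list[tuple[np.ndarray, tuple[int, int], float, float]] = []
    fly_id = 0

    def place(sprite: np.ndarray, x: float, y: float) -> tuple[tuple[int, int], float, float]:
        cy, cx = _alpha_centroid(sprite)
        top = int(round(y - cy))
        left = int(round(x - cx))
        gx, gy = canvas.composite(sprite, top, left)
        return (top, left), gx, gy

    # overlap pairs first
    for pair_idx in range(spec.overlap_pairs):
        x1, y1 = sample_position(extra_sep=1.2 * L)
        s1, v1 = make_sprite(sexes[fly_id])
        s2, v2 = make_sprite(sexes[fly_id + 1])
        m1 = s1[..., 3] > 0.5
        m2 = s2[..., 3] > 0.5
        c1 = _alpha_centroid(s1)
        ang = rng.uniform(0.0, 2 * math.pi)
        placed = None
        for factor in (0.5, 0.42, 0.34, 0.26, 0.18, 0.10):
            x2 = x1 + factor * L * math.cos(ang)
            y2 = y1 + factor * L * math.sin(ang)
            c2 = _alpha_centroid(s2)
            off1 = (int(round(y1 - c1[0])), int(round(x1 - c1[1])))
            off2 = (int(round(y2 - c2[0])), int(round(x2 - c2[1])))
            if _masks_touch(m1, off1, m2, off2):
                placed = (x2, y2)
                break
        if placed is None:  # pragma: no cover - factor 0.10 always touches
            placed = (x1, y1)
        off1_, gx1, gy1 = place(s1, x1, y1)
        off2_, gx2, gy2 = place(s2, *placed)
        group = pair_idx + 1
        records.append(
            GroundTruthRecord(fly_id, gx1, gy1, sexes[fly_id], v1, group)
        )
        records.append(
            GroundTruthRecord(fly_id + 1, gx2, gy2, sexes[fly_id + 1], v2, group)
        )
        anchors.extend([(x1, y1), placed])
        fly_id += 2

    # isolated flies
    while fly_id < spec.n_flies:
        x, y = sample_position()
        sprite, view = make_sprite(sexes[fly_id])
        off, gx, gy = place(sprite, x, y)
        single_info.append((sprite[..., 3] > 0.5, off, gx, gy))
        records.append(GroundTruthRecord(fly_id, gx, gy, sexes[fly_id], view, None))
        anchors.append((x, y))
        fly_id += 1

    _render_stains(spec, rng, canvas, single_info, L, sample_position)

    noisy = canvas.gray + rng.normal(0.0, NOISE_SD, canvas.gray.shape)
    arr8 = np.clip(np.rint(noisy * 255.0), 0, 255).astype(np.uint8)
    pixels = np.repeat(arr8[:, :, None], 3, axis=2)
    return PlateImage(pixels), records


def _stain_mask(rng: np.random.Generator, L: float) -> np.ndarray:
    """Irregular blob: a short random walk of overlapping disks."""
    side = int(math.ceil(1.6 * L))
    mask = np.zeros((side, side), dtype=bool)
    r0 = 0.17 * L
    y, x = side / 2.0, side / 2.0
    for _ in range(6):
        rr, cc = draw.disk((y, x), r0 * (0.7 + 0.6 * rng.random()), shape=mask.shape)
        mask[rr, cc] = True
        ang = rng.uniform(0.0, 2 * math.pi)
        y += 0.22 * L * math.cos(ang)
        x += 0.22 * L * math.sin(ang)
        y = min(max(y, r0), side - r0)
        x = min(max(x, r0), side - r0)
    return mask


def _paint_stain(canvas: _Canvas, mask: np.ndarray, top: int, left: int) -> None:
    h, w = mask.shape
    region = slice(top, top + h), slice(left, left + w)
    free = mask & ~canvas.fg_mask[region]  # never repaint fly pixels
    canvas.gray[region][free] = STAIN_GRAY
    canvas.fg_mask[region][free] = True


def _render_stains(spec, rng, canvas, single_info, L, sample_position) -> None:
    for i in range(spec.n_stains):
        mask = _stain_mask(rng, L)
        cy, cx = ndimage.center_of_mass(mask)
        if spec.stain_touching_fly and i == 0 and single_info:
            fmask, foff, fx, fy = single_info[int(rng.integers(len(single_info)))]
            ang = rng.uniform(0.0, 2 * math.pi)
            for factor in (0.6, 0.5, 0.4, 0.3, 0.2):
                x = fx + factor * L * math.cos(ang)
                y = fy + factor * L * math.sin(ang)
                top = int(round(y - cy))
                left = int(round(x - cx))
                if _masks_touch(mask, (top, left), fmask, foff):
                    break
        else:
            x, y = sample_position()
            top = int(round(y - cy))
            left = int(round(x - cx))
        top = min(max(top, 0), canvas.gray.shape[0] - mask.shape[0])
        left = min(max(left, 0), canvas.gray.shape[1] - mask.shape[1])
        _paint_stain(canvas, mask, top, left)


# ---------------------------------------------------------------------------
# crop datasets
# ---------------------------------------------------------------------------


def make_crop_dataset(
    n_per_sex: int, crop_px: int = 32, seed: int = 0
) -> list[LabeledCrop]:
    """Generate a balanced set of single-fly crops for classifier training.

    Each crop holds one near-centered fly on plate background with
    sensor-like noise, at a uniformly random orientation — matching the
    statistics of crops extracted from plate detections, where flies land
    at arbitrary angles.
    """
    if n_per_sex < 1:
        raise ValueError("n_per_sex must be >= 1")
    if crop_px < MIN_CROP_PX:
        raise ValueError(
            f"crop_px={crop_px} too small for the dimorphic markers; "
            f"minimum is {MIN_CROP_PX}"
        )
    rng = np.random.default_rng(seed)
    crops: list[LabeledCrop] = []
    for label in (MALE, FEMALE):
        for i in range(n_per_sex):
            length = 0.42 * crop_px * (0.92 + 0.16 * rng.random())
            view = DORSAL if rng.random() < 0.8 else LATERAL
            sprite = render_fly_sprite(label, view, length, rng)
            rotated = _rotate_sprite(sprite, rng.uniform(0.0, 360.0))
            canvas = _Canvas(crop_px, crop_px)
            cy, cx = _alpha_centroid(rotated)
            jitter = 0.03 * crop_px
            top = int(round(crop_px / 2 + rng.uniform(-jitter, jitter) - cy))
            left = int(round(crop_px / 2 + rng.uniform(-jitter, jitter) - cx))
            top = min(max(top, 0), crop_px - rotated.shape[0])
            left = min(max(left, 0), crop_px - rotated.shape[1])
            canvas.composite(rotated, top, left)
            noisy = canvas.gray + rng.normal(0.0, NOISE_SD, canvas.gray.shape)
            arr8 = np.clip(np.rint(noisy * 255.0), 0, 255).astype(np.uint8)
            crops.append(
                LabeledCrop(
                    pixels=np.repeat(arr8[:, :, None], 3, axis=2),
                    label=label,
                    origin_id=f"synthetic:{label}:{i}",
                    augmented=False,
                )
            )
    return crops


# ---------------------------------------------------------------------------
# ground-truth serialization
# ---------------------------------------------------------------------------

_GT_HEADER = ["fly_id", "centroid_x", "centroid_y", "sex", "view", "touching_group"]


def write_ground_truth_csv(records: list[GroundTruthRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_GT_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.fly_id,
                    f"{r.centroid_x:.3f}",
                    f"{r.centroid_y:.3f}",
                    r.sex,
                    r.view,
                    "" if r.touching_group is None else r.touching_group,
                ]
            )


def read_ground_truth_csv(path: str | Path) -> list[GroundTruthRecord]:
    records = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                GroundTruthRecord(
                    fly_id=int(row["fly_id"]),
                    centroid_x=float(row["centroid_x"]),
                    centroid_y=float(row["centroid_y"]),
                    sex=row["sex"],
                    view=row["view"],
                    touching_group=(
                        int(row["touching_group"]) if row["touching_group"] else None
                    ),
                )
            )
    return records


def write_ground_truth_json(records: list[GroundTruthRecord], path: str | Path) -> None:
    doc = [
        {
            "fly_id": r.fly_id,
            "centroid_x": round(r.centroid_x, 3),
            "centroid_y": round(r.centroid_y, 3),
            "sex": r.sex,
            "view": r.view,
            "touching_group": r.touching_group,
        }
        for r in records
    ]
    Path(path).write_text(json.dumps(doc, indent=2))
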