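"""Labeled crop datasets: class balancing by rotation and sex-balanced splitting.

Field datasets of sexed fly crops are typically skewed (females are detected
more often than males).  Rather than discarding majority-class images, the
minority class is topped up with copies rotated by a quarter turn — a
label-preserving augmentation for round-symmetric imaging — until the two
classes are equal.  Splitting then stratifies by sex so that train, validation
and test partitions each contain exactly as many males as females.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

MALE = "male"
FEMALE = "female"
SEX_LABELS = (MALE, FEMALE)


@dataclass(eq=False)
class LabeledCrop:
    """A square RGB crop of one fly with its sex label.

    ``pixels`` is a ``(side, side, 3)`` uint8 array.  ``augmented`` marks
    rotation copies created by :func:`balance_by_rotation`.
    """

    pixels: np.ndarray
    label: str
    origin_id: str | None = None
    augmented: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[0] != px.shape[1] or px.shape[2] != 3:
            raise ValueError(f"crop must be square RGB, got shape {px.shape}")
        if self.label not in SEX_LABELS:
            raise ValueError(f"label must be one of {SEX_LABELS}, got {self.label!r}")
        self.pixels = px

    @property
    def side(self) -> int:
        return int(self.pixels.shape[0])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LabeledCrop)
            and self.label == other.label
            and self.origin_id == other.origin_id
            and self.augmented == other.augmented
            and np.array_equal(self.pixels, other.pixels)
        )


@dataclass(frozen=True)
class SplitSpec:
    """Fractions for the train/validation/test partition (must sum to 1)."""

    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(f <= 0 for f in fracs):
            raise ValueError(f"split fractions must be positive, got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fracs)}")


@dataclass
class DatasetSplit:
    train: list[LabeledCrop] = field(default_factory=list)
    val: list[LabeledCrop] = field(default_factory=list)
    test: list[LabeledCrop] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {"train": len(self.train), "val": len(self.val), "test": len(self.test)}


def _counts_by_label(crops: list[LabeledCrop]) -> dict[str, int]:
    counts = {lab: 0 for lab in SEX_LABELS}
    for c in crops:
        counts[c.label] += 1
    return counts


def balance_by_rotation(crops: list[LabeledCrop], seed: int = 0) -> list[LabeledCrop]:
    """Equalize class counts by adding quarter-turn-rotated minority copies.

    Minority-class crops are duplicated with a rotation of 90° clockwise or
    counterclockwise (chosen uniformly, seeded) until both classes have the
    majority count.  Originals are untouched; the copies carry
    ``augmented=True``.  Balanced input is returned unchanged (the identity).
    """
    counts = _counts_by_label(crops)
    for lab in SEX_LABELS:
        if counts[lab] == 0:
            raise ValueError(f"cannot balance: class {lab!r} is absent from the input")
    deficit = abs(counts[MALE] - counts[FEMALE])
    if deficit == 0:
        return list(crops)
    minority = MALE if counts[MALE] < counts[FEMALE] else FEMALE
    pool = [c for c in crops if c.label == minority]
    rng = np.random.default_rng(seed)
    out = list(crops)
    for i in range(deficit):
        src = pool[i % len(pool)]
        # np.rot90 k=1 is counterclockwise, k=3 clockwise; both stay in the label class
        k = 1 if rng.random() < 0.5 else 3
        rotated = np.ascontiguousarray(np.rot90(src.pixels, k=k))
        out.append(
            LabeledCrop(
                pixels=rotated,
                label=src.label,
                origin_id=(f"{src.origin_id}+rot" if src.origin_id else None),
                augmented=True,
            )
        )
    return out


def split_balanced(crops: list[LabeledCrop], spec: SplitSpec) -> DatasetSplit:
    """Partition a class-balanced crop set into sex-balanced train/val/test.

    Per class of size ``C``: ``val = floor(val_frac * C)``,
    ``test = floor(test_frac * C)`` and the remainder goes to train, so the
    partition is exhaustive and each part contains the same number of males
    and females.  Shuffling within each class is seeded.
    """
    counts = _counts_by_label(crops)
    if counts[MALE] != counts[FEMALE]:
        raise ValueError(
            f"input is not class-balanced ({counts}); run balance_by_rotation first"
        )
    rng = np.random.default_rng(spec.seed)
    split = DatasetSplit()
    for lab in SEX_LABELS:
        members = [c for c in crops if c.label == lab]
        order = rng.permutation(len(members))
        members = [members[i] for i in order]
        c = len(members)
        n_val = int(np.floor(spec.val_frac * c))
        n_test = int(np.floor(spec.test_frac * c))
        n_train = c - n_val - n_test
        split.train.extend(members[:n_train])
        split.val.extend(members[n_train : n_train + n_val])
        split.test.extend(members[n_train + n_val :])
    return split


def save_crop_dir(crops: list[LabeledCrop], out_dir: str | Path) -> Path:
    """Write crops as PNG files plus a ``labels.csv`` manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "labels.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "augmented"])
        for i, crop in enumerate(crops):
            name = f"crop_{i:06d}.png"
            Image.fromarray(crop.pixels).save(out / name)
            writer.writerow([name, crop.label, int(crop.augmented)])
    return manifest


def load_crop_dir(crop_dir: str | Path) -> list[LabeledCrop]:
    crop_dir = Path(crop_dir)
    manifest = crop_dir / "labels.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no labels.csv manifest in {crop_dir}")
    crops: list[LabeledCrop] = []
    with manifest.open(newline="") as fh:
        for row in csv.DictReader(fh):
            with Image.open(crop_dir / row["filename"]) as im:
                px = np.asarray(im.convert("RGB"), dtype=np.uint8)
            crops.append(
                LabeledCrop(
                    pixels=px,
                    label=row["label"],
                    origin_id=row["filename"],
                    augmented=bool(int(row["augmented"])),
                )
            )
    return crops
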