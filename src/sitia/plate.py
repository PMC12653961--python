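"""Plate-image container shared by every pipeline stage.

Coordinates are 0-based pixel centers with the origin at the top-left corner,
x increasing rightward and y downward; every module in the package uses this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class PlateImage:
    """An RGB raster of the anesthesia plate.

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` uint8 array.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB array, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        if px.shape[0] == 0 or px.shape[1] == 0:
            raise ValueError("image must be non-empty")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def gray(self) -> np.ndarray:
        """Luminance image as float in [0, 1]."""
        from skimage.color import rgb2gray

        return rgb2gray(self.pixels)

    def to_png(self, path: str | Path) -> None:
        Image.fromarray(self.pixels).save(Path(path), format="PNG")

    @classmethod
    def from_png(cls, path: str | Path) -> "PlateImage":
        with Image.open(Path(path)) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
        return cls(arr)
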