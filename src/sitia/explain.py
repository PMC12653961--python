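"""RISE saliency maps for black-box explanation of the sex classifier.

Randomized Input Sampling for Explanation: the model is probed with many
randomly masked versions of a crop; each pixel's saliency is the average of
the masks covering it weighted by the model's score (softmax probability of
the target class) on the masked input.  Masks preserving the features the
model relies on score high, so the weighted average highlights them.

Masks are the standard RISE construction: a low-resolution binary grid (each
cell kept with probability ``keep_prob``) upsampled bilinearly to image size
with a uniform random sub-cell shift, giving smooth masks with values in
[0, 1].  Everything is seeded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from skimage.transform import resize

from sitia.classifier.nn import Cnn6, softmax
from sitia.classifier.training import LABEL_INDEX


@dataclass(frozen=True)
class RiseConfig:
    n_masks: int = 10000
    grid_cells: int = 7
    keep_prob: float = 0.5
    seed: int = 0
    batch_size: int = 256

    def __post_init__(self) -> None:
        if self.n_masks < 1:
            raise ValueError("n_masks must be >= 1")
        if not 0.0 < self.keep_prob < 1.0:
            raise ValueError("keep_prob must be in (0, 1)")
        if self.grid_cells < 2:
            raise ValueError("grid_cells must be >= 2")


@dataclass
class Heatmap:
    """Per-pixel saliency in [0, 1] (max exactly 1 unless the map is flat).

    ``raw_values`` keeps the score-weighted mask average before min-max
    normalization; for a constant-score model it is flat up to mask-sampling
    noise, which normalization would otherwise amplify to full range.
    """

    values: np.ndarray
    target_label: str
    raw_values: np.ndarray | None = None

    def save(self, path: str | Path, config: RiseConfig | None = None) -> None:
        """Write as 16-bit PNG plus a JSON sidecar."""
        path = Path(path)
        arr = np.clip(self.values, 0.0, 1.0)
        Image.fromarray((arr * 65535.0).round().astype(np.uint16)).save(path)
        sidecar = {"target_label": self.target_label}
        if config is not None:
            sidecar["config"] = {
                "n_masks": config.n_masks,
                "grid_cells": config.grid_cells,
                "keep_prob": config.keep_prob,
                "seed": config.seed,
            }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def generate_masks(cfg: RiseConfig, image_side: int) -> np.ndarray:
    """Soft masks of shape (n_masks, image_side, image_side), values in [0, 1]."""
    rng = np.random.default_rng(cfg.seed)
    g = cfg.grid_cells
    cell = int(math.ceil(image_side / g))
    up = (g + 1) * cell
    grids = rng.random((cfg.n_masks, g, g)) < cfg.keep_prob
    shifts = rng.integers(0, cell, size=(cfg.n_masks, 2))
    masks = np.empty((cfg.n_masks, image_side, image_side))
    for i in range(cfg.n_masks):
        big = resize(
            grids[i].astype(np.float64), (up, up), order=1, anti_aliasing=False
        )
        dy, dx = shifts[i]
        masks[i] = big[dy : dy + image_side, dx : dx + image_side]
    return masks


def rise_heatmap(
    model: Cnn6,
    crop: np.ndarray,
    target_label: str,
    cfg: RiseConfig,
) -> Heatmap:
    """Score-weighted mask average, min-max normalized to [0, 1].

    Raw saliency is ``sum_i score_i * mask_i / (n_masks * keep_prob)`` where
    ``score_i`` is the model's softmax probability for ``target_label`` on
    the masked crop.
    """
    if target_label not in LABEL_INDEX:
        raise ValueError(f"unknown label {target_label!r}")
    px = np.asarray(crop)
    if px.dtype == np.uint8:
        px = px.astype(np.float64) / 255.0
    side = model.spec.input_side_px
    if px.shape != (side, side, 3):
        raise ValueError(
            f"crop shape {px.shape} does not match model input ({side}, {side}, 3)"
        )
    masks = generate_masks(cfg, side)
    target = LABEL_INDEX[target_label]
    sal = np.zeros((side, side))
    for start in range(0, cfg.n_masks, cfg.batch_size):
        batch = masks[start : start + cfg.batch_size]
        masked = px[None] * batch[:, :, :, None]
        scores = softmax(model.forward(masked))[:, target]
        sal += np.tensordot(scores, batch, axes=(0, 0))
    sal /= cfg.n_masks * cfg.keep_prob
    raw = sal.copy()
    lo, hi = sal.min(), sal.max()
    if hi > lo:
        sal = (sal - lo) / (hi - lo)
    else:
        sal = np.zeros_like(sal)
    return Heatmap(values=sal, target_label=target_label, raw_values=raw)


def overlay_heatmap(
    crop: np.ndarray, heatmap: Heatmap, alpha: float = 0.5, cmap: str = "jet"
) -> np.ndarray:
    """Alpha-blend the colormapped heatmap over the crop; returns uint8 RGB."""
    px = np.asarray(crop)
    if px.dtype != np.uint8:
        px = np.clip(px * 255.0, 0, 255).astype(np.uint8)
    if px.shape[:2] != heatmap.values.shape:
        raise ValueError(
            f"crop {px.shape[:2]} and heatmap {heatmap.values.shape} sizes differ"
        )
    colors = colormaps[cmap](np.clip(heatmap.values, 0.0, 1.0))[..., :3]
    blended = (1 - alpha) * (px.astype(np.float64) / 255.0) + alpha * colors
    return np.clip(blended * 255.0, 0, 255).astype(np.uint8)
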