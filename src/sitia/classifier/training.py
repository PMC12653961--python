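"""Training loop, prediction and evaluation for the six-layer sex classifier.

Training is from scratch (no pretraining), fully seeded: weight init, epoch
shuffling and batch order all derive from the config seed, so identical runs
produce identical accuracy curves.  The weights from the epoch with the best
validation accuracy are retained.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from sitia.classifier.data import FEMALE, MALE, DatasetSplit, LabeledCrop
from sitia.classifier.nn import Adam, Cnn6, Cnn6Spec, softmax

LABEL_INDEX = {MALE: 0, FEMALE: 1}
INDEX_LABEL = {v: k for k, v in LABEL_INDEX.items()}


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    early_plateau_epoch: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def canonical_resize(pixels: np.ndarray, side: int) -> np.ndarray:
    """Resize an RGB crop to the model input side, scaled to [0, 1] floats."""
    px = np.asarray(pixels)
    if px.dtype == np.uint8:
        px = px.astype(np.float64) / 255.0
    if px.shape[0] == side and px.shape[1] == side:
        return px
    return resize(px, (side, side, 3), order=1, anti_aliasing=px.shape[0] > side)


def crops_to_arrays(crops: list[LabeledCrop], side: int):
    x = np.stack([canonical_resize(c.pixels, side) for c in crops])
    y = np.array([LABEL_INDEX[c.label] for c in crops], dtype=np.int64)
    return x, y


def train_from_scratch(
    model: Cnn6, split: DatasetSplit, cfg: TrainingConfig
) -> tuple[Cnn6, pd.DataFrame]:
    """Train on the split's train partition, monitor the validation partition.

    Returns the model carrying the best-validation-epoch weights, and a frame
    with columns ``epoch``, ``train_acc``, ``val_acc`` (train accuracy is the
    running accuracy over the epoch's minibatches).  If
    ``early_plateau_epoch`` is set, training stops once the validation
    accuracy has not improved for that many epochs.
    """
    if not split.train:
        raise ValueError("train partition is empty")
    side = model.spec.input_side_px
    x_train, y_train = crops_to_arrays(split.train, side)
    x_val, y_val = (
        crops_to_arrays(split.val, side) if split.val else (None, None)
    )
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(lr=cfg.learning_rate)
    n = x_train.shape[0]
    best_val = -1.0
    best_weights = model.get_weights()
    best_epoch = 0
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits, _cache = model.forward(xb, want_cache=True)
            correct += int((logits.argmax(axis=1) == yb).sum())
            _loss, grads = model.loss_and_gradients(xb, yb)
            opt.step(model.params, grads)
        train_acc = correct / n
        if x_val is not None:
            val_probs = model.predict_proba(x_val)
            val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        else:
            val_acc = float("nan")
        rows.append({"epoch": epoch, "train_acc": train_acc, "val_acc": val_acc})
        if x_val is not None and val_acc > best_val:
            best_val = val_acc
            best_weights = model.get_weights()
            best_epoch = epoch
        if (
            cfg.early_plateau_epoch is not None
            and x_val is not None
            and epoch - best_epoch >= cfg.early_plateau_epoch
        ):
            break
    if x_val is not None:
        model.set_weights(best_weights)
    return model, pd.DataFrame(rows)


def predict_sex(model: Cnn6, crop: np.ndarray | LabeledCrop) -> tuple[str, float]:
    """Label one crop; returns (label, winning softmax probability).

    The crop must already match the model input side; use
    :func:`canonical_resize` to bring arbitrary crops to that side.
    """
    px = crop.pixels if isinstance(crop, LabeledCrop) else np.asarray(crop)
    side = model.spec.input_side_px
    if px.ndim != 3 or px.shape[0] != side or px.shape[1] != side or px.shape[2] != 3:
        raise ValueError(
            f"crop shape {px.shape} does not match model input ({side}, {side}, 3)"
        )
    if px.dtype == np.uint8:
        px = px.astype(np.float64) / 255.0
    probs = softmax(model.forward(px[None]))[0]
    idx = int(probs.argmax())
    return INDEX_LABEL[idx], float(probs[idx])


@dataclass
class EvalResult:
    """Confusion matrix and derived metrics; rows true, cols predicted (male, female)."""

    confusion: np.ndarray
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]

    @classmethod
    def from_confusion(cls, confusion: np.ndarray) -> "EvalResult":
        cm = np.asarray(confusion, dtype=np.int64)
        if cm.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")
        total = cm.sum()
        acc = float(np.trace(cm) / total) if total else float("nan")
        precision, recall = {}, {}
        for lab, i in LABEL_INDEX.items():
            col = cm[:, i].sum()
            row = cm[i, :].sum()
            precision[lab] = float(cm[i, i] / col) if col else float("nan")
            recall[lab] = float(cm[i, i] / row) if row else float("nan")
        return cls(confusion=cm, accuracy=acc, precision=precision, recall=recall)

    @property
    def n_evaluated(self) -> int:
        return int(self.confusion.sum())


def evaluate(model: Cnn6, crops: list[LabeledCrop]) -> EvalResult:
    """Confusion matrix, accuracy, per-class precision/recall on labeled crops."""
    if not crops:
        raise ValueError("cannot evaluate on an empty crop set")
    x, y = crops_to_arrays(crops, model.spec.input_side_px)
    pred = model.predict_proba(x).argmax(axis=1)
    cm = np.zeros((2, 2), dtype=np.int64)
    for t, p in zip(y, pred):
        cm[t, p] += 1
    return EvalResult.from_confusion(cm)


def save_model(model: Cnn6, out_dir: str | Path, extra: dict | None = None) -> Path:
    """Write weights (.npz) with a JSON sidecar carrying the architecture spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "weights.npz", **model.params)
    sidecar = {"cnn6_spec": asdict(model.spec)}
    if extra:
        sidecar.update(extra)
    (out / "model.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_model(model_dir: str | Path) -> Cnn6:
    model_dir = Path(model_dir)
    sidecar = json.loads((model_dir / "model.json").read_text())
    spec_dict = dict(sidecar["cnn6_spec"])
    spec_dict["conv_channels"] = tuple(spec_dict["conv_channels"])
    model = Cnn6(spec=Cnn6Spec(**spec_dict))
    with np.load(model_dir / "weights.npz") as data:
        model.set_weights({k: data[k] for k in data.files})
    return model
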