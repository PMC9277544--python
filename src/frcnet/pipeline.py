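"""Training, inference and evaluation orchestration over directory datasets.

The dataset layout is the one the synthetic generator writes (and the reader
contract for real releases such as Kvasir-SEG): ``images/NNNN.png`` RGB
frames, ``masks/NNNN.png`` 8-bit 0/255 masks with matching names, and an
optional ``manifest.json``.

Checkpoints are numpy archives carrying the named weight arrays plus a JSON
echo of the model configuration and seed, so a checkpoint alone is enough to
rebuild the network bit-for-bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .estimator import FRCNetSegmenter
from .metrics import MetricConfig, MetricReport, evaluate
from .network import FRCNet, ModelConfig, count_parameters, PARAM_BUDGET

__all__ = ["TrainConfig", "RunRecord", "train", "predict", "evaluate_dataset",
           "audit_params", "save_checkpoint", "load_checkpoint", "load_pairs"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol. The defaults are the published full-scale
    protocol (Adam 1e-3, batch 4, 512x512, 80 epochs); desk-scale runs
    override ``input_size`` and ``epochs``."""

    lr: float = 1e-3
    batch_size: int = 4
    epochs: int = 80
    input_size: int = 512
    optimizer: str = "adam"
    augment: bool = True
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.input_size % 32:
            raise ValueError("input_size must be a multiple of 32")


@dataclass
class RunRecord:
    """Bookkeeping for one training run."""

    train_loss: list[float]
    val_mdice: list[float]
    best_epoch: int
    best_val_mdice: float
    wall_seconds: float
    model_config: dict
    train_config: dict
    seed: int
    checkpoint: str
    val_report: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def _resize_image(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if img.shape[:2] == size:
        return img
    return _sk_resize(img, size, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def _resize_mask(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if mask.shape[:2] == size:
        return mask
    out = _sk_resize(mask.astype(np.float64), size, order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(mask.dtype)


def load_pairs(data_dir, input_size: int | None = None
               ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load name-matched image/mask pairs as (N, 3, S, S) / (N, 1, S, S)
    arrays in [0, 1] / {0, 1}. Raises on orphan files, naming each."""
    data_dir = Path(data_dir)
    img_dir, mask_dir = data_dir / "images", data_dir / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"expected {img_dir} and {mask_dir}")
    img_names = {p.name for p in img_dir.glob("*.png")}
    mask_names = {p.name for p in mask_dir.glob("*.png")}
    orphans = sorted(img_names ^ mask_names)
    if orphans:
        raise ValueError(f"unpaired image/mask files: {orphans}")
    if not img_names:
        raise ValueError(f"no PNG pairs found under {data_dir}")
    names = sorted(img_names)
    images, masks = [], []
    for name in names:
        img = np.asarray(Image.open(img_dir / name).convert("RGB"),
                         dtype=np.float32) / 255.0
        mask = (np.asarray(Image.open(mask_dir / name).convert("L")) > 127
                ).astype(np.uint8)
        if input_size is not None:
            img = _resize_image(img, (input_size, input_size)).astype(np.float32)
            mask = _resize_mask(mask, (input_size, input_size))
        images.append(np.moveaxis(img, -1, 0))
        masks.append(mask[None, :, :])
    return np.stack(images), np.stack(masks), names


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: FRCNet) -> None:
    state = {f"weights/{k}": v for k, v in model.state_dict().items()}
    meta = json.dumps({"model_config": model.config.to_dict(),
                       "seed": model.config.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> FRCNet:
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        state = {k[len("weights/"):]: archive[k]
                 for k in archive.files if k.startswith("weights/")}
    model = FRCNet(ModelConfig.from_dict(meta["model_config"]))
    model.load_state_dict(state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def train(model_cfg: ModelConfig, train_cfg: TrainConfig, data_dir,
          out_dir, metric_cfg: MetricConfig = MetricConfig(),
          verbose: int = 0) -> RunRecord:
    """Fit the network on a directory dataset and write the best-validation
    checkpoint plus a JSON run record under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X, y, _ = load_pairs(data_dir, input_size=train_cfg.input_size)

    t0 = time.time()
    est = FRCNetSegmenter(
        variant=model_cfg.variant, encoder_widths=model_cfg.encoder_widths,
        lr=train_cfg.lr, batch_size=train_cfg.batch_size,
        epochs=train_cfg.epochs, augment=train_cfg.augment,
        seed=train_cfg.seed, verbose=verbose)
    est.fit(X, y)
    wall = time.time() - t0

    ckpt_path = out_dir / "checkpoint.npz"
    save_checkpoint(ckpt_path, est.model_)

    # full metric report on the held-out validation images
    val_report = {}
    if len(est.val_indices_):
        probs = est.predict_proba(X[est.val_indices_])
        report = evaluate(probs[:, 0], y[est.val_indices_, 0], metric_cfg)
        val_report = report.to_dict(include_per_image=False)

    record = RunRecord(
        train_loss=est.history_["train_loss"],
        val_mdice=est.history_["val_mdice"],
        best_epoch=est.best_epoch_,
        best_val_mdice=est.val_mdice_,
        wall_seconds=wall,
        model_config=model_cfg.to_dict(),
        train_config=asdict(train_cfg),
        seed=train_cfg.seed,
        checkpoint=str(ckpt_path),
        val_report=val_report,
    )
    record.to_json(out_dir / "run_record.json")
    return record


def predict(checkpoint, images_dir, out_dir, threshold: float = 0.5) -> list[str]:
    """Segment every PNG under ``images_dir``.

    Writes per image a 16-bit probability map (``*_prob.png``) and a 0/255
    binary mask (``*_mask.png``) at the original resolution; the network runs
    at the nearest multiple-of-32 size and the probability map is resized
    back bilinearly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = load_checkpoint(checkpoint)
    images_dir = Path(images_dir)
    names = sorted(p.name for p in images_dir.glob("*.png"))
    if not names:
        raise ValueError(f"no PNG images under {images_dir}")
    written = []
    for name in names:
        img = np.asarray(Image.open(images_dir / name).convert("RGB"),
                         dtype=np.float32) / 255.0
        h, w = img.shape[:2]
        if h < 32 or w < 32:
            raise ValueError(f"{name}: image side below 32 pixels ({h}x{w})")
        hs, ws = -(-h // 32) * 32, -(-w // 32) * 32
        net_in = _resize_image(img, (hs, ws)).astype(np.float32)
        prob = model.predict_proba(np.moveaxis(net_in, -1, 0)[None])[0, 0]
        prob = _resize_image(prob, (h, w))
        stem = Path(name).stem
        Image.fromarray((prob * 65535.0).round().astype(np.uint16)
                        ).save(out_dir / f"{stem}_prob.png")
        Image.fromarray(((prob >= threshold) * 255).astype(np.uint8)
                        ).save(out_dir / f"{stem}_mask.png")
        written.append(stem)
    return written


def _load_gray_unit(path) -> np.ndarray:
    img = Image.open(path)
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    peak = 65535.0 if arr.max() > 255 else 255.0
    return arr / peak


def evaluate_dataset(pred_dir, gt_dir, metric_cfg: MetricConfig = MetricConfig(),
                     report_path=None) -> MetricReport:
    """Evaluate name-matched predictions against ground-truth masks.

    Predictions may be probability maps (``*_prob.png``, 16-bit) or binary
    masks; ground truths are 0/255 PNGs under ``gt_dir``.
    """
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    gt_names = sorted(p.name for p in gt_dir.glob("*.png"))
    if not gt_names:
        raise ValueError(f"no ground-truth masks under {gt_dir}")
    preds, gts = [], []
    for name in gt_names:
        stem = Path(name).stem
        candidates = [pred_dir / f"{stem}_prob.png", pred_dir / f"{stem}_mask.png",
                      pred_dir / name]
        path = next((c for c in candidates if c.exists()), None)
        if path is None:
            raise ValueError(f"no prediction found for ground truth {name!r}")
        preds.append(_load_gray_unit(path))
        gts.append(np.asarray(Image.open(gt_dir / name).convert("L")) > 127)
    report = evaluate(preds, gts, metric_cfg)
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
    return report


def audit_params(model_cfg: ModelConfig) -> dict:
    """Parameter audit: total and per-module counts, in raw units and
    millions; ``passed`` is the published 0.78 M budget check for the full
    variant (always reported, only binding for variant='full')."""
    model = FRCNet(model_cfg)
    total = count_parameters(model)
    per_module = {}
    for name, sub in model._modules.items():
        per_module[name] = sub.num_parameters()
    return {
        "variant": model_cfg.variant,
        "total": total,
        "total_millions": round(total / 1e6, 2),
        "budget": PARAM_BUDGET,
        "passed": bool(total <= PARAM_BUDGET),
        "per_module": per_module,
    }
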