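"""Training, evaluation and detection orchestration.

The training protocol mirrors the reference detector recipe: Adam, a
constant learning rate, fixed batch size, square inputs, with the box
loss (PIoU or CIoU), snake convolutions and the fusion neck togglable
as independent ablation flags.  The full-scale preset trains 100
epochs at 640x640 with learning rate 0.01 and batch 16; the tiny
preset (64x64, narrow widths, learning rate 0.001) exists for CPU-only
smoke runs and is what the test-suite uses.

Everything is seeded: parameter initialization, data order and the
synthetic data itself, so a run is reproducible bit-for-bit from its
config snapshot.  Checkpoints are numpy .npz archives carrying the
parameter/buffer state plus a JSON config snapshot.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .autograd import Tensor
from .boxgeom import CLASS_INDEX, CLASS_NAMES, BoundingBox, PIoUConfig
from .data_io import LabeledScene, read_labelme, read_manifest, save_image, write_labelme
from .detmetrics import EvalReport, evaluate_detections, regression_errors
from .mff_net import (Detector, DetectorConfig, build_detector, compute_loss,
                      decode_predictions)
from .nn import Adam

__all__ = [
    "TrainConfig", "RunRecord", "train", "evaluate", "detect",
    "save_checkpoint", "load_checkpoint", "full_train_config",
    "tiny_train_config",
]

log = logging.getLogger("svbdete")


@dataclass
class TrainConfig:
    """Training hyperparameters and ablation flags."""

    epochs: int = 100
    optimizer: str = "adam"
    learning_rate: float = 0.01
    batch_size: int = 16
    input_size: int = 640
    width: str = "default"
    depth: int = 1
    loss: str = "piou"                   # {"piou", "ciou"}
    piou_penalty_mode: str = "corner"
    piou_loss_form: str = "corrected"
    piou_lambda: float = 1.3
    use_dsconv: bool = True
    use_mff: bool = True
    augment_flips: bool = False          # random horizontal flips
    classes: tuple = CLASS_NAMES         # classes to train on, in order
    seed: int = 0
    device: str = "cpu"
    score_threshold: float = 0.25
    nms_iou: float = 0.45

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.input_size) <= 0 \
                or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.device != "cpu":
            raise ValueError("only device='cpu' is supported")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(
            input_size=(self.input_size, self.input_size),
            num_classes=len(self.classes),
            width=self.width,
            depth=self.depth,
            use_dsconv=self.use_dsconv,
            use_mff=self.use_mff,
            loss=self.loss,
            piou=PIoUConfig(lambda_=self.piou_lambda,
                            penalty_mode=self.piou_penalty_mode,
                            loss_form=self.piou_loss_form),
            seed=self.seed,
        )


def full_train_config(**overrides) -> TrainConfig:
    """The full-scale recipe: 100 epochs, Adam, lr 0.01, batch 16, 640px."""
    return replace(TrainConfig(), **overrides)


def tiny_train_config(**overrides) -> TrainConfig:
    """CPU smoke recipe: 64px tiny-width model on the small-bundle class.

    Uses a gentler learning rate than the full recipe (2e-3 rather
    than 0.01) — the tiny model at batch 8 diverges at the full rate —
    and 20 epochs, enough for the easy synthetic preset to converge.
    """
    cfg = TrainConfig(epochs=20, learning_rate=2e-3, batch_size=8,
                      input_size=64, width="tiny", classes=("small",))
    return replace(cfg, **overrides)


@dataclass
class RunRecord:
    config: dict
    epoch_losses: list = field(default_factory=list)
    val_report: dict | None = None
    checkpoint_path: str | None = None
    version: str = __version__
    wall_time_s: float = 0.0


# -- data plumbing ------------------------------------------------------

def _scene_gt(scene: LabeledScene, classes) -> list[BoundingBox]:
    """Filter and re-index gt boxes to the training class list."""
    keep = {CLASS_INDEX[c]: i for i, c in enumerate(classes)}
    return [BoundingBox(b.x1, b.y1, b.x2, b.y2, class_id=keep[b.class_id])
            for b in scene.boxes if b.class_id in keep]


def load_split(manifest_path, split: str, classes=CLASS_NAMES):
    """Load (image array, gt boxes) pairs for one manifest split."""
    manifest_path = Path(manifest_path)
    doc = read_manifest(manifest_path)
    root = manifest_path.parent
    items = []
    for stem in doc["split"][split]:
        scene = read_labelme(root / "images" / f"{stem}.json")
        items.append((scene.image, _scene_gt(scene, classes)))
    if not items:
        raise ValueError(f"empty split {split!r} in {manifest_path}")
    return items


def _flip_horizontal(image: np.ndarray, gts: list[BoundingBox]):
    w = image.shape[1]
    flipped = [BoundingBox(w - b.x2, b.y1, w - b.x1, b.y2, b.class_id,
                           b.confidence) for b in gts]
    return np.ascontiguousarray(image[:, ::-1]), flipped


def _to_batch(images) -> Tensor:
    arr = np.stack([im.astype(np.float32) / 255.0 for im in images])
    return Tensor(arr.transpose(0, 3, 1, 2))


# -- checkpoints --------------------------------------------------------

def save_checkpoint(model: Detector, cfg: TrainConfig, path) -> None:
    state = model.state_dict()
    state["config_json"] = np.array(json.dumps(asdict(cfg)))
    np.savez(path, **state)


def load_checkpoint(path) -> tuple[Detector, TrainConfig]:
    with np.load(path, allow_pickle=False) as data:
        state = {k: data[k] for k in data.files}
    cfg_doc = json.loads(str(state.pop("config_json")))
    cfg_doc["classes"] = tuple(cfg_doc["classes"])
    cfg = TrainConfig(**cfg_doc)
    model = build_detector(cfg.detector_config())
    model.load_state_dict(state)
    model.eval()
    return model, cfg


# -- training -----------------------------------------------------------

def train(cfg: TrainConfig, manifest_path, out_dir=None,
          val_every: int = 0) -> RunRecord:
    """Run the training loop on a dataset manifest.

    Returns a :class:`RunRecord` with per-epoch mean losses, the final
    validation report, and the checkpoint path (when ``out_dir`` is
    given).  Aborts with diagnostics if the loss goes non-finite.
    """
    t0 = time.time()
    items = load_split(manifest_path, "train", cfg.classes)
    det_cfg = cfg.detector_config()
    model = build_detector(det_cfg)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    record = RunRecord(config=asdict(cfg))
    log.info("training %d scenes for %d epochs (%d params)",
             len(items), cfg.epochs, model.num_parameters())
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(items))
        losses = []
        for start in range(0, len(items), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            images = [items[i][0] for i in sel]
            gts = [items[i][1] for i in sel]
            if cfg.augment_flips:
                images = list(images)
                gts = list(gts)
                for k in range(len(images)):
                    if rng.random() < 0.5:
                        images[k], gts[k] = _flip_horizontal(images[k], gts[k])
            batch = _to_batch(images)
            raws = model(batch)
            loss, parts = compute_loss(raws, gts, det_cfg)
            if not np.isfinite(parts["total"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}: "
                    f"{parts}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.apply_constraints()
            losses.append(parts["total"])
        record.epoch_losses.append(float(np.mean(losses)))
        log.info("epoch %d/%d loss %.4f", epoch + 1, cfg.epochs,
                 record.epoch_losses[-1])
        if val_every and (epoch + 1) % val_every == 0:
            rep = evaluate(model, manifest_path, "val", cfg)
            log.info("epoch %d val mAP@.5 %.3f", epoch + 1, rep.map50)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt = out_dir / "model.npz"
        save_checkpoint(model, cfg, ckpt)
        record.checkpoint_path = str(ckpt)
    try:
        rep = evaluate(model, manifest_path, "val", cfg)
        record.val_report = json.loads(rep.to_json())
    except ValueError:
        log.warning("no validation split; skipping final evaluation")
    record.wall_time_s = time.time() - t0
    return record


def _predict_scene(model: Detector, image: np.ndarray, cfg: TrainConfig):
    raws = model(_to_batch([image]))
    return decode_predictions(raws, score_threshold=cfg.score_threshold,
                              nms_iou=cfg.nms_iou,
                              input_size=image.shape[:2])


def evaluate(model_or_ckpt, manifest_path, split: str,
             cfg: TrainConfig | None = None,
             score_threshold: float = 0.05) -> EvalReport:
    """Evaluate a model (or checkpoint path) on a manifest split.

    Pools detections over the split for P/R/AP/mAP, and adds per-image
    small-bundle count and total-area errors (MAPE/RMSE) plus
    class-mean Dice/IoU region scores.  Candidates are collected at a
    low confidence threshold (AP sweeps the ranking, so recall must not
    be truncated up front); precision/recall and the count errors are
    still reported at the config's operating threshold.
    """
    if isinstance(model_or_ckpt, (str, Path)):
        model, cfg = load_checkpoint(model_or_ckpt)
    else:
        model = model_or_ckpt
        if cfg is None:
            raise ValueError("cfg required when passing a model instance")
    model.eval()
    items = load_split(manifest_path, split, cfg.classes)
    eval_cfg = replace(cfg, score_threshold=min(score_threshold,
                                                cfg.score_threshold))
    all_preds, all_gts = [], []
    counts_a, counts_p, areas_a, areas_p = [], [], [], []
    small_id = cfg.classes.index("small") if "small" in cfg.classes else None
    image_size = items[0][0].shape[:2]
    offset = 0.0
    for image, gts in items:
        preds = _predict_scene(model, image, eval_cfg)
        # offset each image into its own coordinate slab so pooled
        # cross-image IoUs are zero
        all_preds += [b.translated(0.0, offset) for b in preds]
        all_gts += [b.translated(0.0, offset) for b in gts]
        offset += image.shape[0] + 64.0
        operating = [b for b in preds if b.confidence >= cfg.score_threshold]
        if small_id is not None:
            counts_a.append(sum(1 for b in gts if b.class_id == small_id))
            counts_p.append(sum(1 for b in operating
                                if b.class_id == small_id))
            areas_a.append(sum(b.area for b in gts if b.class_id == small_id))
            areas_p.append(sum(b.area for b in operating
                               if b.class_id == small_id))
    report = evaluate_detections(
        all_preds, all_gts,
        image_size=(int(offset), image_size[1]),
        class_names=cfg.classes)
    # precision/recall at the operating threshold (AP used all candidates)
    from .detmetrics import match_detections, precision_recall
    for cid, name in enumerate(cfg.classes):
        if name not in report.per_class:
            continue
        preds_c = [b for b in all_preds if b.class_id == cid
                   and b.confidence >= cfg.score_threshold]
        gts_c = [b for b in all_gts if b.class_id == cid]
        p, r = precision_recall(match_detections(preds_c, gts_c, 0.5))
        report.per_class[name]["precision"] = p
        report.per_class[name]["recall"] = r
    if small_id is not None:
        report.count_mape, report.count_rmse = regression_errors(
            counts_a, counts_p)
        report.area_mape, report.area_rmse = regression_errors(
            areas_a, areas_p)
    return report


def _draw_overlay(image: np.ndarray, boxes) -> np.ndarray:
    colors = {0: (255, 80, 80), 1: (80, 160, 255), 2: (255, 220, 60),
              3: (120, 255, 120)}
    out = image.copy()
    h, w = out.shape[:2]
    for b in boxes:
        x1, y1 = max(0, int(b.x1)), max(0, int(b.y1))
        x2, y2 = min(w - 1, int(b.x2)), min(h - 1, int(b.y2))
        col = colors.get(b.class_id, (255, 255, 255))
        out[y1, x1:x2 + 1] = col
        out[y2, x1:x2 + 1] = col
        out[y1:y2 + 1, x1] = col
        out[y1:y2 + 1, x2] = col
    return out


def detect(ckpt_path, image_paths, out_dir, score_threshold: float | None = None):
    """Run detection on images; write LabelMe JSON and an overlay per input.

    Unreadable images are reported and skipped.  Returns the list of
    written JSON paths.
    """
    from .data_io import load_image

    model, cfg = load_checkpoint(ckpt_path)
    if score_threshold is not None:
        cfg = replace(cfg, score_threshold=score_threshold)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for path in image_paths:
        path = Path(path)
        try:
            image = load_image(path)
        except Exception as exc:           # per-file failure, keep going
            log.error("cannot read %s: %s", path, exc)
            continue
        preds = _predict_scene(model, image, cfg)
        # map class ids back to the global label set
        remap = [CLASS_INDEX[c] for c in cfg.classes]
        preds = [BoundingBox(b.x1, b.y1, b.x2, b.y2,
                             class_id=remap[b.class_id],
                             confidence=b.confidence) for b in preds]
        scene = LabeledScene(image=image, image_path=str(path), boxes=preds)
        json_path = out_dir / f"{path.stem}_pred.json"
        write_labelme(scene, json_path)
        save_image(_draw_overlay(image, preds), out_dir / f"{path.stem}_overlay.png")
        written.append(json_path)
        log.info("%s: %d detections", path.name, len(preds))
    return written
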