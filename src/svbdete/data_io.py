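"""Annotation and image I/O plus deterministic dataset splitting.

Scenes are stored the way the source micrograph datasets are: one TIFF
(or PNG/JPEG) image per section with a LabelMe-dialect JSON carrying
polygon or rectangle shapes over the four classes — small vascular
bundles ("small"), large vascular bundles ("big"), the cavity ("in")
and the stem perimeter ("out").  Polygons are reduced to their
axis-aligned bounding boxes (the detector and every reported metric are
box-level); the raw vertices are kept for provenance.

A YOLO-style txt bridge (class index + normalized centre/size per
line) is provided for training pipelines, with the class order fixed
as small=0, big=1, in=2, out=3 and recorded in the dataset manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .boxgeom import CLASS_INDEX, CLASS_NAMES, BoundingBox

__all__ = [
    "LabeledScene", "DatasetSplit", "read_labelme", "write_labelme",
    "write_yolo_labels", "read_yolo_labels", "split_dataset",
    "load_image", "save_image", "write_manifest", "read_manifest",
]


@dataclass
class LabeledScene:
    """One image plus its annotation set."""

    image: np.ndarray | None
    image_path: str
    boxes: list[BoundingBox] = field(default_factory=list)
    source_polygons: list | None = None

    @property
    def image_size(self) -> tuple[int, int]:
        """(height, width) of the image."""
        if self.image is None:
            raise ValueError(f"image not loaded for {self.image_path}")
        return self.image.shape[0], self.image.shape[1]


@dataclass
class DatasetSplit:
    train: list[str]
    val: list[str]
    test: list[str]


def load_image(path) -> np.ndarray:
    """Load TIFF/PNG/JPEG as a (H, W, 3) uint8 array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(str(path))
    else:
        from PIL import Image
        arr = np.asarray(Image.open(str(path)))
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.shape[2] > 3:
        arr = arr[:, :, :3]
    return arr


def save_image(arr: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(str(path), arr)
    else:
        from PIL import Image
        Image.fromarray(arr).save(str(path))


def _normalize_label(label: str, allow_unknown: bool = False) -> int | None:
    norm = label.strip().lower()
    if norm in CLASS_INDEX:
        return CLASS_INDEX[norm]
    if allow_unknown:
        return None
    raise ValueError(f"unknown annotation label {label!r}; "
                     f"expected one of {CLASS_NAMES}")


def read_labelme(json_path, load_image_data: bool = True,
                 allow_unknown_labels: bool = False) -> LabeledScene:
    """Read a LabelMe-dialect JSON annotation file.

    Rectangle shapes are taken directly; polygon shapes are converted
    to their min/max envelope.  Labels are case-normalized; unknown
    labels raise unless ``allow_unknown_labels`` is set (then they are
    skipped).
    """
    json_path = Path(json_path)
    try:
        doc = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed LabelMe JSON at {json_path}: {exc}") from exc
    image_rel = doc.get("imagePath", json_path.with_suffix(".tif").name)
    image_path = json_path.parent / image_rel
    boxes, polys = [], []
    for shape in doc.get("shapes", []):
        cid = _normalize_label(shape["label"], allow_unknown_labels)
        if cid is None:
            continue
        pts = np.asarray(shape["points"], dtype=float)
        x1, y1 = pts.min(axis=0)
        x2, y2 = pts.max(axis=0)
        boxes.append(BoundingBox(float(x1), float(y1), float(x2), float(y2),
                                 class_id=cid))
        polys.append(pts.tolist())
    image = None
    if load_image_data:
        if image_path.exists():
            image = load_image(image_path)
        else:
            warnings.warn(f"image file missing: {image_path}; deferring load",
                          stacklevel=2)
    return LabeledScene(image=image, image_path=str(image_path),
                        boxes=boxes, source_polygons=polys)


def write_labelme(scene: LabeledScene, json_path,
                  image_size: tuple[int, int] | None = None) -> None:
    """Write boxes (and confidences, when present) as LabelMe rectangles."""
    h, w = image_size if image_size is not None else scene.image_size
    shapes = []
    for b in scene.boxes:
        shape = {
            "label": b.class_name,
            "points": [[b.x1, b.y1], [b.x2, b.y2]],
            "shape_type": "rectangle",
            "group_id": None,
            "flags": {},
        }
        if b.confidence is not None:
            shape["description"] = f"confidence={b.confidence:.4f}"
        shapes.append(shape)
    doc = {
        "version": "5.2.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": Path(scene.image_path).name,
        "imageData": None,
        "imageHeight": h,
        "imageWidth": w,
    }
    Path(json_path).write_text(json.dumps(doc, indent=2))


def write_yolo_labels(scene: LabeledScene, out_path,
                      image_size: tuple[int, int] | None = None) -> None:
    """One line per box: ``class xc yc w h`` normalized to [0, 1].

    Boxes exceeding the image bounds are clipped with a warning.
    """
    h, w = image_size if image_size is not None else scene.image_size
    lines = []
    for b in scene.boxes:
        x1, y1 = max(0.0, b.x1), max(0.0, b.y1)
        x2, y2 = min(float(w), b.x2), min(float(h), b.y2)
        if (x1, y1, x2, y2) != (b.x1, b.y1, b.x2, b.y2):
            warnings.warn(f"clipping out-of-bounds box {b.as_tuple()}",
                          stacklevel=2)
        if x2 <= x1 or y2 <= y1:
            continue
        xc, yc = (x1 + x2) / (2 * w), (y1 + y2) / (2 * h)
        bw, bh = (x2 - x1) / w, (y2 - y1) / h
        lines.append(f"{b.class_id} {xc:.6f} {yc:.6f} {bw:.6f} {bh:.6f}")
    Path(out_path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path, image_size: tuple[int, int]) -> list[BoundingBox]:
    h, w = image_size
    boxes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        cid, xc, yc, bw, bh = line.split()
        cid = int(cid)
        xc, yc, bw, bh = (float(xc) * w, float(yc) * h,
                          float(bw) * w, float(bh) * h)
        boxes.append(BoundingBox(xc - bw / 2, yc - bh / 2,
                                 xc + bw / 2, yc + bh / 2, class_id=cid))
    return boxes


def split_dataset(scene_ids, ratios=(8, 1, 1), seed: int = 0) -> DatasetSplit:
    """Seeded shuffle then contiguous slicing at the given ratios.

    Train and validation sizes are floored; the remainder goes to the
    test set (1091 scenes at 8:1:1 gives 872/109/110).
    """
    ids = list(scene_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 scenes to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    total = sum(ratios)
    n_train = int(len(ids) * ratios[0] / total)
    n_val = int(len(ids) * ratios[1] / total)
    return DatasetSplit(train=shuffled[:n_train],
                        val=shuffled[n_train:n_train + n_val],
                        test=shuffled[n_train + n_val:])


def write_manifest(path, split: DatasetSplit, seed: int,
                   image_size: int, extra: dict | None = None) -> None:
    doc = {
        "classes": {name: i for i, name in enumerate(CLASS_NAMES)},
        "seed": seed,
        "image_size": image_size,
        "split": {"train": split.train, "val": split.val, "test": split.test},
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
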