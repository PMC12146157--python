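"""Synthetic stem-cross-section micrographs with exact box annotations.

Real sections show a bright tissue disk (the stem, annotated "out")
around a central cavity ("in"), a peripheral ring of tiny vascular
bundles ("small") and an inner band of larger bundles ("big") — dense,
blurry-edged and low-contrast.  The generator reproduces that layout
with elliptical bundles placed on concentric annuli (rejection-sampled
against overlap), then degrades the render in a fixed order: Gaussian
blur, a multiplicative illumination gradient, additive texture noise,
and contrast compression toward mid-grey.  Degradations never move
geometry, so every emitted box tightly bounds its rendered ellipse.

Default per-image bundle counts are Poisson with means 28.28 (small)
and 30.88 (big), the per-image rates of the annotated micrograph corpus
the generator emulates (30854 small and 33692 big boxes over 1091
images).  Radii are stated in pixels at a 640-pixel reference frame and
scale linearly with image size.

Everything is driven by one integer seed: a fixed seed yields a
byte-identical image and an identical box list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .boxgeom import CLASS_INDEX, BoundingBox
from .data_io import (LabeledScene, save_image, split_dataset,
                      write_labelme, write_manifest, write_yolo_labels)

__all__ = [
    "SceneConfig", "GroundTruthScene", "generate_scene", "write_dataset",
    "realistic_config", "easy_config",
]

_REF_SIZE = 640.0


@dataclass
class SceneConfig:
    """Generation parameters; lengths in pixels at the 640 reference."""

    image_size: int = 640
    stem_radius_range: tuple = (0.38, 0.45)      # fraction of image size
    cavity_radius_fraction: float = 0.35         # fraction of stem radius
    n_small_mean: float = 28.28                  # Poisson mean per image
    n_big_mean: float = 30.88
    n_small_max: int | None = None               # truncate the Poisson draw
    n_big_max: int | None = None
    small_radius_range: tuple = (3.0, 8.0)       # px at 640
    big_radius_range: tuple = (8.0, 16.0)
    small_band: tuple = (0.84, 0.96)             # fraction of stem radius
    big_band: tuple = (0.52, 0.78)
    aspect_range: tuple = (0.6, 1.0)             # ellipse minor/major ratio
    max_overlap: float = 0.15                    # allowed circle overlap
    contrast_level: float = 0.55                 # (0, 1]; 1 = no compression
    blur_sigma: float = 1.5                      # px at 640
    illumination_gradient: float = 0.15          # multiplicative amplitude
    background_texture: float = 0.03             # additive noise sigma
    seed: int = 0

    def __post_init__(self):
        if not (self.small_radius_range[0] < self.big_radius_range[0]
                and self.small_radius_range[1] <= self.big_radius_range[1]):
            raise ValueError("small radii must be below big radii")
        if not 0 < self.contrast_level <= 1:
            raise ValueError("contrast_level must lie in (0, 1]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")

    @property
    def scale(self) -> float:
        return self.image_size / _REF_SIZE


def realistic_config(image_size: int = 640, seed: int = 0) -> SceneConfig:
    """Dense, tiny, low-contrast scenes matching the emulated corpus."""
    return SceneConfig(image_size=image_size, seed=seed)


def easy_config(image_size: int = 64, seed: int = 0) -> SceneConfig:
    """High-contrast sparse scenes for CPU smoke training.

    Bundles are larger relative to the frame (box area well above
    100 px^2 at 640^2), there is no blur, and large bundles are sparse.
    """
    return SceneConfig(
        image_size=image_size,
        stem_radius_range=(0.42, 0.47),
        cavity_radius_fraction=0.18,
        n_small_mean=5.0,
        n_big_mean=1.0,
        n_small_max=8,
        n_big_max=2,
        small_radius_range=(0.055 * _REF_SIZE, 0.080 * _REF_SIZE),
        big_radius_range=(0.090 * _REF_SIZE, 0.115 * _REF_SIZE),
        small_band=(0.40, 0.95),
        big_band=(0.28, 0.60),
        aspect_range=(0.8, 1.0),
        max_overlap=0.0,
        contrast_level=1.0,
        blur_sigma=0.0,
        illumination_gradient=0.05,
        background_texture=0.01,
        seed=seed,
    )


@dataclass
class GroundTruthScene:
    image: np.ndarray                    # (H, W, 3) uint8
    boxes: list                          # BoundingBox, all four classes
    log: dict = field(default_factory=dict)

    @property
    def boxes_by_class(self) -> dict:
        out: dict = {}
        for b in self.boxes:
            out.setdefault(b.class_name, []).append(b)
        return out


class PackingError(RuntimeError):
    """Raised when the requested bundles cannot fit in their annulus."""


def _ellipse_bbox(cx, cy, a, b, theta):
    rx = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    ry = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    return cx - rx, cy - ry, cx + rx, cy + ry


def _place_bundles(rng, n, radius_range, band, cfg: SceneConfig,
                   stem_c, stem_r, cavity_r, placed, label):
    """Rejection-sample n non-overlapping ellipses in an annulus band."""
    s = cfg.scale
    new = []
    for k in range(n):
        for attempt in range(400):
            a = rng.uniform(*radius_range) * s
            aspect = rng.uniform(*cfg.aspect_range)
            b = a * aspect
            theta = rng.uniform(0, np.pi)
            rb = a  # bounding-circle radius
            lo = max(band[0] * stem_r, cavity_r + rb + 1.0)
            hi = min(band[1] * stem_r, stem_r - rb - 1.0)
            if hi <= lo:
                continue
            rad = rng.uniform(lo, hi)
            ang = rng.uniform(0, 2 * np.pi)
            cx = stem_c[0] + rad * np.cos(ang)
            cy = stem_c[1] + rad * np.sin(ang)
            ok = True
            for (ox, oy, orb) in placed:
                if np.hypot(cx - ox, cy - oy) < (rb + orb) * (1 - cfg.max_overlap):
                    ok = False
                    break
            if ok:
                placed.append((cx, cy, rb))
                new.append((cx, cy, a, b, theta))
                break
        else:
            raise PackingError(
                f"could not place {label} bundle {k + 1}/{n}: the "
                f"annulus band {band} of stem radius {stem_r:.1f} is full")
    return new


def _render_ellipses(canvas, xs, ys, ellipses, value):
    for (cx, cy, a, b, theta) in ellipses:
        x1, y1, x2, y2 = _ellipse_bbox(cx, cy, a, b, theta)
        j1, j2 = max(0, int(x1) - 1), min(canvas.shape[1], int(x2) + 2)
        i1, i2 = max(0, int(y1) - 1), min(canvas.shape[0], int(y2) + 2)
        if j2 <= j1 or i2 <= i1:
            continue
        dx = xs[i1:i2, j1:j2] - cx
        dy = ys[i1:i2, j1:j2] - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        patch = canvas[i1:i2, j1:j2]
        patch[inside] = value


def generate_scene(cfg: SceneConfig) -> GroundTruthScene:
    """Render one section and return it with exact ground-truth boxes."""
    rng = np.random.default_rng(cfg.seed)
    S = cfg.image_size
    s = cfg.scale

    # geometry ---------------------------------------------------------
    stem_r = rng.uniform(*cfg.stem_radius_range) * S
    stem_c = (S / 2 + rng.uniform(-0.02, 0.02) * S,
              S / 2 + rng.uniform(-0.02, 0.02) * S)
    cavity_r = cfg.cavity_radius_fraction * stem_r
    n_small = int(rng.poisson(cfg.n_small_mean))
    n_big = int(rng.poisson(cfg.n_big_mean))
    if cfg.n_small_max is not None:
        n_small = min(n_small, cfg.n_small_max)
    if cfg.n_big_max is not None:
        n_big = min(n_big, cfg.n_big_max)

    placed: list = []
    big = _place_bundles(rng, n_big, cfg.big_radius_range, cfg.big_band,
                         cfg, stem_c, stem_r, cavity_r, placed, "big")
    small = _place_bundles(rng, n_small, cfg.small_radius_range,
                           cfg.small_band, cfg, stem_c, stem_r, cavity_r,
                           placed, "small")

    # render -----------------------------------------------------------
    ys, xs = np.mgrid[0:S, 0:S].astype(np.float64) + 0.5
    img = np.full((S, S), 0.30)
    rr = np.hypot(xs - stem_c[0], ys - stem_c[1])
    img[rr <= stem_r] = 0.55
    img[rr <= cavity_r] = 0.18
    _render_ellipses(img, xs, ys, big, 0.40)
    _render_ellipses(img, xs, ys, small, 0.85)

    # degrade: blur -> illumination -> noise -> contrast ---------------
    if cfg.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=cfg.blur_sigma * s)
    if cfg.illumination_gradient > 0:
        phi = rng.uniform(0, 2 * np.pi)
        ramp = ((xs - S / 2) * np.cos(phi) + (ys - S / 2) * np.sin(phi)) / S
        img = img * (1.0 + cfg.illumination_gradient * 2.0 * ramp)
    if cfg.background_texture > 0:
        img = img + rng.normal(0.0, cfg.background_texture, size=img.shape)
    img = 0.5 + cfg.contrast_level * (img - 0.5)
    img8 = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    img3 = np.repeat(img8[:, :, None], 3, axis=2)

    # exact boxes from the geometry -------------------------------------
    boxes = []
    for (cx, cy, a, b, theta) in small:
        x1, y1, x2, y2 = _ellipse_bbox(cx, cy, a, b, theta)
        boxes.append(BoundingBox(x1, y1, x2, y2, CLASS_INDEX["small"]))
    for (cx, cy, a, b, theta) in big:
        x1, y1, x2, y2 = _ellipse_bbox(cx, cy, a, b, theta)
        boxes.append(BoundingBox(x1, y1, x2, y2, CLASS_INDEX["big"]))
    boxes.append(BoundingBox(stem_c[0] - cavity_r, stem_c[1] - cavity_r,
                             stem_c[0] + cavity_r, stem_c[1] + cavity_r,
                             CLASS_INDEX["in"]))
    boxes.append(BoundingBox(stem_c[0] - stem_r, stem_c[1] - stem_r,
                             stem_c[0] + stem_r, stem_c[1] + stem_r,
                             CLASS_INDEX["out"]))
    log = {
        "seed": cfg.seed,
        "stem_center": stem_c,
        "stem_radius": stem_r,
        "cavity_radius": cavity_r,
        "n_small": n_small,
        "n_big": n_big,
        "small": small,
        "big": big,
    }
    return GroundTruthScene(image=img3, boxes=boxes, log=log)


def write_dataset(n_scenes: int, cfg: SceneConfig, out_dir,
                  difficulty: str | None = None,
                  ratios=(8, 1, 1)) -> Path:
    """Write TIFF images, LabelMe JSON, YOLO labels and a split manifest.

    ``difficulty`` optionally overrides cfg with a named preset
    ("easy" or "realistic") at cfg.image_size and cfg.seed.  Returns
    the manifest path.
    """
    if difficulty == "easy":
        cfg = easy_config(image_size=cfg.image_size, seed=cfg.seed)
    elif difficulty == "realistic":
        cfg = replace(realistic_config(), image_size=cfg.image_size,
                      seed=cfg.seed)
    elif difficulty is not None:
        raise ValueError(f"unknown difficulty {difficulty!r}")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)
    ids = []
    for i in range(n_scenes):
        scene_seed = (cfg.seed * 100003 + i) % (2 ** 31)
        scene = generate_scene(replace(cfg, seed=scene_seed))
        stem = f"scene_{i:04d}"
        ids.append(stem)
        img_path = out / "images" / f"{stem}.tif"
        save_image(scene.image, img_path)
        ls = LabeledScene(image=scene.image, image_path=str(img_path),
                          boxes=scene.boxes)
        write_labelme(ls, out / "images" / f"{stem}.json")
        write_yolo_labels(ls, out / "labels" / f"{stem}.txt")
    split = split_dataset(ids, ratios=ratios, seed=cfg.seed)
    manifest = out / "manifest.yaml"
    write_manifest(manifest, split, seed=cfg.seed, image_size=cfg.image_size)
    return manifest
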