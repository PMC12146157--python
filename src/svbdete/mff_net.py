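"""Detector assembly: serpentine backbone, multi-scale fusion neck, heads.

The backbone is a stride-2 convolution cascade whose stages are C2f
blocks (serpentine-kernel variants when the snake-convolution flag is
on), emitting pyramid levels P2/P3/P4/P5 at strides 4/8/16/32.

The multi-scale feature-fusion (MFF) neck extends the usual FPN+PAN
wiring in two ways: the top-down path continues one level further down
to stride 4 (upsample modules F4, F3, F2 fused with P4, P3, P2), and
the bottom-up path re-descends through T2, T4, T5 (fused with F3, F4
and P5).  A fourth detection head at stride 4 consumes the F2 level, so
objects a few pixels wide land on a grid fine enough to separate them.
With the MFF flag off the neck reduces to the standard three-head
FPN+PAN baseline at strides 8/16/32.

Heads are anchor-free: each grid cell predicts four edge distances
(left/top/right/bottom, softplus-activated and scaled by the stride)
plus per-class logits.  Ground truth is routed to a head by box size
and to the cell containing the box centre.  The box regression loss is
either CIoU or PIoU (see :mod:`svbdete.boxgeom`); classification is
binary cross-entropy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concatenate, maximum, minimum, upsample_nearest2x
from .boxgeom import BoundingBox, PIoUConfig
from .dsconv import FeatureMap
from .nn import C2f, Conv2d, ConvBlock, Module

__all__ = [
    "DetectorConfig", "RawPrediction", "Detector", "build_detector",
    "UpsampleFuse", "DownsampleFuse", "upsample_fuse", "downsample_fuse",
    "assign_targets", "compute_loss", "decode_predictions",
]

#: per-stage channel widths (stem, P2, P3, P4, P5)
WIDTH_PRESETS = {
    "tiny": (8, 16, 24, 32, 32),
    "small": (16, 32, 48, 64, 64),
    "default": (32, 64, 128, 256, 256),
}


@dataclass
class DetectorConfig:
    """Architecture and loss configuration.

    ``use_dsconv``, ``use_mff`` and ``loss`` span the ablation space:
    snake kernels in the backbone on/off, the extra fusion paths and
    stride-4 head on/off, and PIoU vs CIoU box regression.
    """

    input_size: tuple = (64, 64)            # (H, W), divisible by 32
    num_classes: int = 4
    width: str = "tiny"
    depth: int = 1                          # bottlenecks per C2f stage
    use_dsconv: bool = True
    use_mff: bool = True
    loss: str = "piou"                      # {"piou", "ciou"}
    piou: PIoUConfig = field(default_factory=lambda: PIoUConfig(
        penalty_mode="corner", loss_form="corrected"))
    box_weight: float = 5.0
    cls_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.input_size
        if h % 32 or w % 32:
            raise ValueError(f"input size must be divisible by 32, got {h}x{w}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.loss not in ("piou", "ciou"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @property
    def widths(self):
        if isinstance(self.width, str):
            return WIDTH_PRESETS[self.width]
        return tuple(self.width)

    @property
    def head_strides(self):
        return (4, 8, 16, 32) if self.use_mff else (8, 16, 32)


@dataclass
class RawPrediction:
    """One head's raw output grid plus its stride."""

    stride: int
    output: Tensor          # (N, 4 + num_classes, H/s, W/s)

    @property
    def grid_size(self):
        return self.output.shape[-2:]


class UpsampleFuse(Module):
    """Nearest 2x upsample of the deep map, concatenate with the shallow
    map (order: upsampled-deep first), then a C2f mixing block."""

    def __init__(self, deep_ch, shallow_ch, out_ch, n=1, rng=None):
        super().__init__()
        self.mix = C2f(deep_ch + shallow_ch, out_ch, n=n, rng=rng)

    @staticmethod
    def fuse(deep: Tensor, shallow: Tensor) -> Tensor:
        return concatenate([upsample_nearest2x(deep), shallow], axis=1)

    def forward(self, deep: Tensor, shallow: Tensor) -> Tensor:
        return self.mix(self.fuse(deep, shallow))

    __call__ = forward


class DownsampleFuse(Module):
    """Stride-2 convolution of the current map, concatenate with the
    lateral map, then a C2f mixing block.  ``mode="add"`` fuses by
    element-wise addition instead of concatenation (the channel counts
    must then match)."""

    def __init__(self, cur_ch, lat_ch, out_ch, n=1, mode="concat", rng=None):
        super().__init__()
        if mode not in ("concat", "add"):
            raise ValueError(f"unknown fusion mode {mode!r}")
        self.mode = mode
        self.down = ConvBlock(cur_ch, cur_ch if mode == "concat" else lat_ch,
                              k=3, stride=2, rng=rng)
        in_ch = cur_ch + lat_ch if mode == "concat" else lat_ch
        self.mix = C2f(in_ch, out_ch, n=n, rng=rng)

    def forward(self, current: Tensor, lateral: Tensor) -> Tensor:
        d = self.down(current)
        if self.mode == "concat":
            fused = concatenate([d, lateral], axis=1)
        else:
            fused = d + lateral
        return self.mix(fused)

    __call__ = forward


def upsample_fuse(deep: FeatureMap, shallow: FeatureMap,
                  module: UpsampleFuse) -> FeatureMap:
    """Functional wrapper with the stride contract enforced."""
    if deep.stride != 2 * shallow.stride:
        raise ValueError(f"deep stride {deep.stride} must be twice the "
                         f"shallow stride {shallow.stride}")
    y = module(Tensor(deep.values[None]), Tensor(shallow.values[None]))
    return FeatureMap(y.data[0], stride=shallow.stride)


def downsample_fuse(current: FeatureMap, lateral: FeatureMap,
                    module: DownsampleFuse) -> FeatureMap:
    if lateral.stride != 2 * current.stride:
        raise ValueError(f"lateral stride {lateral.stride} must be twice "
                         f"the current stride {current.stride}")
    y = module(Tensor(current.values[None]), Tensor(lateral.values[None]))
    return FeatureMap(y.data[0], stride=lateral.stride)


class Head(Module):
    def __init__(self, ch, num_classes, rng=None):
        super().__init__()
        self.stem = ConvBlock(ch, ch, 3, rng=rng)
        self.out = Conv2d(ch, 4 + num_classes, k=1, rng=rng)
        # bias the class logits low so early training is not swamped by
        # background false positives
        self.out.bias.data[4:] = -4.0

    def forward(self, x):
        return self.out(self.stem(x))

    __call__ = forward


class Detector(Module):
    """Backbone + neck + heads; forward maps an image batch to one raw
    prediction per head."""

    def __init__(self, cfg: DetectorConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w0, w1, w2, w3, w4 = cfg.widths
        n = cfg.depth
        sn = cfg.use_dsconv

        self.stem = ConvBlock(3, w0, 3, stride=2, rng=rng)
        self.down1 = ConvBlock(w0, w1, 3, stride=2, rng=rng)
        self.stage1 = C2f(w1, w1, n=n, snake=sn, rng=rng)
        self.down2 = ConvBlock(w1, w2, 3, stride=2, rng=rng)
        self.stage2 = C2f(w2, w2, n=n, snake=sn, rng=rng)
        self.down3 = ConvBlock(w2, w3, 3, stride=2, rng=rng)
        self.stage3 = C2f(w3, w3, n=n, snake=sn, rng=rng)
        self.down4 = ConvBlock(w3, w4, 3, stride=2, rng=rng)
        self.stage4 = C2f(w4, w4, n=n, snake=sn, rng=rng)

        self.f4 = UpsampleFuse(w4, w3, w3, n=n, rng=rng)
        self.f3 = UpsampleFuse(w3, w2, w2, n=n, rng=rng)
        if cfg.use_mff:
            self.f2 = UpsampleFuse(w2, w1, w1, n=n, rng=rng)
            self.t2 = DownsampleFuse(w1, w2, w2, n=n, rng=rng)
            self.t4 = DownsampleFuse(w2, w3, w3, n=n, rng=rng)
            self.t5 = DownsampleFuse(w3, w4, w4, n=n, rng=rng)
            head_chs = (w1, w2, w3, w4)
        else:
            self.n4 = DownsampleFuse(w2, w3, w3, n=n, rng=rng)
            self.n5 = DownsampleFuse(w3, w4, w4, n=n, rng=rng)
            head_chs = (w2, w3, w4)
        self.heads = [Head(c, cfg.num_classes, rng=rng) for c in head_chs]

    # -- graph ---------------------------------------------------------
    @property
    def head_strides(self):
        return self.cfg.head_strides

    def graph_nodes(self):
        """Names of the neck levels present, for topology checks."""
        base = ["P2", "P3", "P4", "P5", "F3", "F4"]
        if self.cfg.use_mff:
            return base + ["F2", "T2", "T4", "T5"]
        return base + ["N4", "N5"]

    def forward(self, x: Tensor) -> list[RawPrediction]:
        h, w = x.shape[-2:]
        if h % 32 or w % 32:
            raise ValueError(f"input size must be divisible by 32, got {h}x{w}")
        p1 = self.stem(x)
        p2 = self.stage1(self.down1(p1))
        p3 = self.stage2(self.down2(p2))
        p4 = self.stage3(self.down3(p3))
        p5 = self.stage4(self.down4(p4))

        f4 = self.f4(p5, p4)
        f3 = self.f3(f4, p3)
        if self.cfg.use_mff:
            f2 = self.f2(f3, p2)
            t2 = self.t2(f2, f3)
            t4 = self.t4(t2, f4)
            t5 = self.t5(t4, p5)
            feats = (f2, t2, t4, t5)
        else:
            n4 = self.n4(f3, f4)
            n5 = self.n5(n4, p5)
            feats = (f3, n4, n5)
        return [RawPrediction(stride=s, output=head(f))
                for s, head, f in zip(self.head_strides, self.heads, feats)]

    __call__ = forward


def build_detector(cfg: DetectorConfig) -> Detector:
    """Construct the detector for a configuration (ablation flags included)."""
    return Detector(cfg)


# -- target assignment --------------------------------------------------

def _route_level(box: BoundingBox, strides) -> int:
    """Scale routing: boxes up to ~2x the finest stride go to the finest
    head; each doubling of extent moves one level up."""
    m = max(box.width, box.height)
    lvl = int(math.floor(math.log2(max(m, 1e-6) / strides[0])))
    return int(np.clip(lvl, 0, len(strides) - 1))


def assign_targets(gts: list[BoundingBox], strides, input_size):
    """Map ground-truth boxes to (head, cell) positives.

    Each box is routed to one head by size; positives are the grid cell
    containing the box centre plus its two nearest neighbour cells (the
    adjacent cell on the side the centre leans toward, per axis), which
    densifies the supervision for tiny grids.  Boxes whose centre falls
    outside the image are skipped with a warning.  Returns, per head,
    index arrays (i, j), the target box array (P, 4) and the class
    array (P,).
    """
    h, w = input_size
    per_head = [{"ij": [], "boxes": [], "cls": []} for _ in strides]
    for b in gts:
        cx, cy = b.center
        if not (0 <= cx < w and 0 <= cy < h):
            warnings.warn(f"gt box centred outside the image skipped: "
                          f"{b.as_tuple()}", stacklevel=2)
            continue
        lvl = _route_level(b, strides)
        s = strides[lvl]
        gh, gw = h // s, w // s
        i = min(int(cy // s), gh - 1)
        j = min(int(cx // s), gw - 1)
        dj = 1 if (cx / s - j) > 0.5 else -1
        di = 1 if (cy / s - i) > 0.5 else -1
        cells = {(i, j)}
        if 0 <= j + dj < gw:
            cells.add((i, j + dj))
        if 0 <= i + di < gh:
            cells.add((i + di, j))
        for cell in sorted(cells):
            per_head[lvl]["ij"].append(cell)
            per_head[lvl]["boxes"].append(b.as_tuple())
            per_head[lvl]["cls"].append(b.class_id)
    out = []
    for d in per_head:
        ij = np.array(d["ij"], dtype=int).reshape(-1, 2)
        out.append({
            "i": ij[:, 0], "j": ij[:, 1],
            "boxes": np.array(d["boxes"], dtype=np.float32).reshape(-1, 4),
            "cls": np.array(d["cls"], dtype=int),
        })
    return out


# -- differentiable box losses -----------------------------------------

def _iou_tensor(px1, py1, px2, py2, gx1, gy1, gx2, gy2):
    ix = maximum(minimum(px2, gx2) - maximum(px1, gx1), 0.0)
    iy = maximum(minimum(py2, gy2) - maximum(py1, gy1), 0.0)
    inter = ix * iy
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    return inter / (area_p + area_g - inter + 1e-9)


def piou_loss_tensor(pred, gt, cfg: PIoUConfig):
    """Vectorized PIoU on decoded boxes: pred (P,4) Tensor, gt (P,4) array."""
    px1, py1, px2, py2 = (pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3])
    gx1, gy1, gx2, gy2 = (gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3])
    i = _iou_tensor(px1, py1, px2, py2, gx1, gy1, gx2, gy2)
    wg = gt[:, 2] - gt[:, 0]
    hg = gt[:, 3] - gt[:, 1]
    if cfg.penalty_mode == "corner":
        dw = (px1 - gx1).abs() + (px2 - gx2).abs()
        dh = (py1 - gy1).abs() + (py2 - gy2).abs()
    else:
        pw, ph = px2 - px1, py2 - py1
        dw = (pw - wg).abs() + (pw + wg).abs()
        dh = (ph - hg).abs() + (ph + hg).abs()
    p = (dw / wg + dh / hg) * 0.25
    expP2 = (-(p * p)).exp()
    q = expP2 if cfg.q_form == "exp_neg_P2" else (-p).exp()
    u = q * cfg.lambda_
    pref = u * 3.0 * (-(u * u)).exp()
    if cfg.loss_form == "corrected":
        factor = (1.0 - i) + (1.0 - expP2)
    else:
        factor = 1.0 - i - expP2
    return pref * factor


def ciou_loss_tensor(pred, gt):
    """Vectorized CIoU; the aspect trade-off alpha is treated as a
    constant in the gradient, the usual convention."""
    px1, py1, px2, py2 = (pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3])
    gx1, gy1, gx2, gy2 = (gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3])
    i = _iou_tensor(px1, py1, px2, py2, gx1, gy1, gx2, gy2)
    rho2 = (((px1 + px2) - (gx1 + gx2)) * 0.5) ** 2.0 \
        + (((py1 + py2) - (gy1 + gy2)) * 0.5) ** 2.0
    cw = maximum(px2, gx2) - minimum(px1, gx1)
    ch = maximum(py2, gy2) - minimum(py1, gy1)
    c2 = cw * cw + ch * ch + 1e-9
    wg, hg = gt[:, 2] - gt[:, 0], gt[:, 3] - gt[:, 1]
    v = ((np.arctan(wg / hg) - ((px2 - px1) / (py2 - py1 + 1e-9)).arctan()) ** 2.0) \
        * (4.0 / math.pi ** 2)
    alpha = v.data / ((1.0 - i.data) + v.data + 1e-9)   # detached
    return 1.0 - i + rho2 / c2 + Tensor(alpha) * v


def _bce_with_logits(x: Tensor, target: np.ndarray) -> Tensor:
    # max(x,0) - x*t + log(1 + exp(-|x|)), elementwise and stable
    return maximum(x, 0.0) - x * target + (((x.abs() * -1.0).exp()) + 1.0).log()


def compute_loss(raws: list[RawPrediction], gt_batch: list[list[BoundingBox]],
                 cfg: DetectorConfig):
    """Total training loss for a batch.

    Returns (loss Tensor, dict of float components).  Box loss (CIoU or
    PIoU per cfg) is averaged over positive cells; classification BCE is
    summed over every cell and normalized by the positive count.
    """
    h, w = raws[0].output.shape[-2] * raws[0].stride, \
        raws[0].output.shape[-1] * raws[0].stride
    strides = [r.stride for r in raws]
    n_img = raws[0].output.shape[0]
    assigns = [assign_targets(gt_batch[n], strides, (h, w))
               for n in range(n_img)]
    box_terms = []
    cls_terms = []
    total_pos = 0
    for hi, raw in enumerate(raws):
        gh, gw = raw.grid_size
        cls_target = np.zeros((n_img, cfg.num_classes, gh, gw), dtype=np.float32)
        n_idx, i_idx, j_idx, boxes = [], [], [], []
        for n in range(n_img):
            assigned = assigns[n][hi]
            for k in range(len(assigned["cls"])):
                n_idx.append(n)
                i_idx.append(assigned["i"][k])
                j_idx.append(assigned["j"][k])
                boxes.append(assigned["boxes"][k])
                cls_target[n, assigned["cls"][k], assigned["i"][k],
                           assigned["j"][k]] = 1.0
        cls_logits = raw.output[:, 4:]
        cls_terms.append(_bce_with_logits(cls_logits, cls_target).sum())
        if n_idx:
            total_pos += len(n_idx)
            n_a = np.array(n_idx)
            i_a = np.array(i_idx)
            j_a = np.array(j_idx)
            t = raw.output[n_a, :4, i_a, j_a]        # (P, 4) raw ltrb
            ltrb = t.softplus() * float(raw.stride)
            cxs = (j_a + 0.5) * raw.stride
            cys = (i_a + 0.5) * raw.stride
            px1 = cxs - ltrb[:, 0]
            py1 = cys - ltrb[:, 1]
            px2 = cxs + ltrb[:, 2]
            py2 = cys + ltrb[:, 3]
            pred = concatenate([p.reshape(-1, 1) for p in (px1, py1, px2, py2)],
                               axis=1)
            gt_arr = np.stack(boxes).astype(np.float32)
            if cfg.loss == "ciou":
                box_terms.append(ciou_loss_tensor(pred, gt_arr).sum())
            else:
                box_terms.append(piou_loss_tensor(pred, gt_arr, cfg.piou).sum())
    denom = float(max(total_pos, 1))
    cls_loss = cls_terms[0]
    for t in cls_terms[1:]:
        cls_loss = cls_loss + t
    cls_loss = cls_loss * (cfg.cls_weight / denom)
    if box_terms:
        box_loss = box_terms[0]
        for t in box_terms[1:]:
            box_loss = box_loss + t
        box_loss = box_loss * (cfg.box_weight / denom)
        total = box_loss + cls_loss
        parts = {"box": float(box_loss.data), "cls": float(cls_loss.data)}
    else:
        total = cls_loss
        parts = {"box": 0.0, "cls": float(cls_loss.data)}
    parts["total"] = float(total.data)
    parts["num_pos"] = total_pos
    return total, parts


# -- decoding -----------------------------------------------------------

def _nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list[int]:
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for oi in order:
        if suppressed[oi]:
            continue
        keep.append(int(oi))
        x1 = np.maximum(boxes[oi, 0], boxes[:, 0])
        y1 = np.maximum(boxes[oi, 1], boxes[:, 1])
        x2 = np.minimum(boxes[oi, 2], boxes[:, 2])
        y2 = np.minimum(boxes[oi, 3], boxes[:, 3])
        inter = np.maximum(x2 - x1, 0) * np.maximum(y2 - y1, 0)
        area = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
        iou = inter / (area[oi] + area - inter + 1e-9)
        suppressed |= iou > iou_thr
    return keep


def decode_predictions(raws: list[RawPrediction], score_threshold: float = 0.25,
                       nms_iou: float = 0.45,
                       input_size=None) -> list[BoundingBox]:
    """Decode raw head grids into confidence-sorted boxes.

    Grid offsets become image-space boxes, per-class NMS suppresses
    duplicates, and boxes are clipped to the image bounds.
    """
    if not 0.0 <= score_threshold <= 1.0 or not 0.0 <= nms_iou <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    if input_size is None:
        input_size = (raws[0].grid_size[0] * raws[0].stride,
                      raws[0].grid_size[1] * raws[0].stride)
    h, w = input_size
    all_boxes, all_scores, all_cls = [], [], []
    for raw in raws:
        data = raw.output.data if isinstance(raw.output, Tensor) else raw.output
        if data.shape[0] != 1:
            raise ValueError("decode one image at a time")
        d = data[0]
        gh, gw = d.shape[-2:]
        ltrb = np.logaddexp(0.0, d[:4]) * raw.stride   # softplus
        scores = 1.0 / (1.0 + np.exp(-d[4:]))
        jj, ii = np.meshgrid(np.arange(gw), np.arange(gh))
        cx = (jj + 0.5) * raw.stride
        cy = (ii + 0.5) * raw.stride
        x1 = cx - ltrb[0]
        y1 = cy - ltrb[1]
        x2 = cx + ltrb[2]
        y2 = cy + ltrb[3]
        for cid in range(scores.shape[0]):
            mask = scores[cid] >= score_threshold
            if not mask.any():
                continue
            all_boxes.append(np.stack([x1[mask], y1[mask], x2[mask], y2[mask]],
                                      axis=1))
            all_scores.append(scores[cid][mask])
            all_cls.append(np.full(mask.sum(), cid))
    if not all_boxes:
        return []
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    cls = np.concatenate(all_cls)
    result = []
    for cid in np.unique(cls):
        sel = cls == cid
        b, s = boxes[sel], scores[sel]
        for k in _nms(b, s, nms_iou):
            x1 = float(np.clip(b[k, 0], 0, w))
            y1 = float(np.clip(b[k, 1], 0, h))
            x2 = float(np.clip(b[k, 2], 0, w))
            y2 = float(np.clip(b[k, 3], 0, h))
            if x2 <= x1 or y2 <= y1:
                continue
            result.append(BoundingBox(x1, y1, x2, y2, class_id=int(cid),
                                      confidence=float(s[k])))
    result.sort(key=lambda bb: -bb.confidence)
    return result
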