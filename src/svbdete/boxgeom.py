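"""Axis-aligned box geometry and bounding-box regression losses.

Implements plain IoU, the CIoU loss (the YOLOv8 default, with the
standard arctan aspect-ratio penalty), and the PIoU loss with a
size/corner penalty P and the focusing prefactor 3u*exp(-u^2), u = λq.

The PIoU formulation circulates in two inconsistent variants, so both
axes of ambiguity are exposed as configuration:

* ``penalty_mode``: "printed" builds P from width/height sums and
  differences only (translation-invariant); "corner" builds it from the
  four corner-coordinate distances, which is what a corner-distance
  penalty is usually meant to be.
* ``loss_form``: "printed" uses the factor (1 - IoU - exp(-P^2)),
  which is negative at perfect overlap; "corrected" uses
  (1 - IoU) + (1 - exp(-P^2)), which is zero exactly at perfect
  overlap and is the form suitable for training.
* ``q_form``: the focusing factor q, either exp(-P^2) (default) or
  exp(-P).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CLASS_NAMES", "CLASS_INDEX", "BoundingBox", "PIoUConfig", "CIoUTerms",
    "iou", "ciou_terms", "ciou_loss", "piou_penalty", "piou_loss",
]

#: Annotation classes: small vascular bundles, large vascular bundles,
#: the central cavity and the stem perimeter.  Index order is fixed.
CLASS_NAMES = ("small", "big", "in", "out")
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


class DegenerateBoxError(ValueError):
    """A box with non-positive width or height."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in continuous pixel coordinates.

    Origin is the top-left corner, x grows rightward, y downward.
    ``class_id`` is an index into :data:`CLASS_NAMES`; ``confidence``
    is present on predictions and ``None`` on ground truth.
    """

    x1: float
    y1: float
    x2: float
    y2: float
    class_id: int = 0
    confidence: float | None = None

    def __post_init__(self):
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise DegenerateBoxError(
                f"box must have positive extent, got ({self.x1}, {self.y1},"
                f" {self.x2}, {self.y2})")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.class_id]

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)

    def translated(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x1 + dx, self.y1 + dy, self.x2 + dx,
                           self.y2 + dy, self.class_id, self.confidence)


@dataclass(frozen=True)
class PIoUConfig:
    """Configuration of the PIoU loss; see the module docstring.

    ``lambda_`` is the weight on the penalty term inside the focusing
    factor.  The defaults follow the loss exactly as printed; the
    corrected/corner combination is the recommended training setting.
    """

    lambda_: float = 1.3
    penalty_mode: str = "printed"     # {"printed", "corner"}
    loss_form: str = "printed"        # {"printed", "corrected"}
    q_form: str = "exp_neg_P2"        # {"exp_neg_P2", "exp_neg_P"}

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError(f"lambda_ must be > 0, got {self.lambda_}")
        if self.penalty_mode not in ("printed", "corner"):
            raise ValueError(f"unknown penalty_mode {self.penalty_mode!r}")
        if self.loss_form not in ("printed", "corrected"):
            raise ValueError(f"unknown loss_form {self.loss_form!r}")
        if self.q_form not in ("exp_neg_P2", "exp_neg_P"):
            raise ValueError(f"unknown q_form {self.q_form!r}")


@dataclass(frozen=True)
class CIoUTerms:
    """The individual terms of the CIoU loss, for inspection."""

    iou: float
    center_dist_sq: float
    enclosing_diag_sq: float
    v: float
    alpha: float

    @property
    def loss(self) -> float:
        return (1.0 - self.iou
                + self.center_dist_sq / self.enclosing_diag_sq
                + self.alpha * self.v)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1]."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def ciou_terms(pred: BoundingBox, gt: BoundingBox) -> CIoUTerms:
    i = iou(pred, gt)
    (pcx, pcy), (gcx, gcy) = pred.center, gt.center
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    cw = max(pred.x2, gt.x2) - min(pred.x1, gt.x1)
    ch = max(pred.y2, gt.y2) - min(pred.y1, gt.y1)
    c2 = cw * cw + ch * ch
    v = (4.0 / math.pi ** 2) * (math.atan(gt.width / gt.height)
                                - math.atan(pred.width / pred.height)) ** 2
    denom = (1.0 - i) + v
    alpha = 0.0 if denom == 0.0 else v / denom
    return CIoUTerms(iou=i, center_dist_sq=rho2, enclosing_diag_sq=c2,
                     v=v, alpha=alpha)


def ciou_loss(pred: BoundingBox, gt: BoundingBox) -> float:
    """Complete-IoU loss: 1 - IoU + rho^2/c^2 + alpha*v.

    ``rho`` is the centre distance, ``c`` the diagonal of the smallest
    enclosing axis-aligned box, ``v`` the arctan aspect-ratio penalty
    and ``alpha = v / ((1 - IoU) + v)`` (0 at the 0/0 corner case).
    """
    return ciou_terms(pred, gt).loss


def piou_penalty(pred: BoundingBox, gt: BoundingBox,
                 mode: str = "printed") -> float:
    """The PIoU penalty P >= 0.

    mode="printed": d_w1 = |w1 - w2|, d_w2 = |w1 + w2| and likewise for
    heights — a pure size comparison, invariant to translation.
    mode="corner": d_w1 = |x1_pred - x1_gt|, d_w2 = |x2_pred - x2_gt|
    and likewise for y — distances between matching corner coordinates.
    Both are then combined as P = ((d_w1 + d_w2)/w_gt + (d_h1 + d_h2)/h_gt)/4.
    """
    if mode == "printed":
        dw1 = abs(pred.width - gt.width)
        dw2 = abs(pred.width + gt.width)
        dh1 = abs(pred.height - gt.height)
        dh2 = abs(pred.height + gt.height)
    elif mode == "corner":
        dw1 = abs(pred.x1 - gt.x1)
        dw2 = abs(pred.x2 - gt.x2)
        dh1 = abs(pred.y1 - gt.y1)
        dh2 = abs(pred.y2 - gt.y2)
    else:
        raise ValueError(f"unknown penalty mode {mode!r}")
    return 0.25 * ((dw1 + dw2) / gt.width + (dh1 + dh2) / gt.height)


def piou_loss(pred: BoundingBox, gt: BoundingBox,
              cfg: PIoUConfig | None = None) -> float:
    """PIoU loss: 3*(λq)*exp(-(λq)^2) * overlap factor.

    The overlap factor is (1 - IoU - exp(-P^2)) in the printed form —
    note this is negative at perfect overlap — or
    (1 - IoU) + (1 - exp(-P^2)) in the corrected form, which vanishes
    iff IoU = 1 and P = 0.
    """
    cfg = cfg or PIoUConfig()
    p = piou_penalty(pred, gt, mode=cfg.penalty_mode)
    i = iou(pred, gt)
    if cfg.q_form == "exp_neg_P2":
        q = math.exp(-p * p)
    else:
        q = math.exp(-p)
    u = cfg.lambda_ * q
    prefactor = 3.0 * u * math.exp(-u * u)
    if cfg.loss_form == "printed":
        factor = 1.0 - i - math.exp(-p * p)
    else:
        factor = (1.0 - i) + (1.0 - math.exp(-p * p))
    return prefactor * factor
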