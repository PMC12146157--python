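"""Dynamic snake convolution: quantized kernels and serpentine sampling.

The operator has two independent ingredients:

* **Vector-quantized kernels.**  Floating-point weights are linearly
  mapped, block by block, onto a signed b-bit integer grid.  Two fitted
  affine corrections undo the quantization error: a kernel distribution
  shift (KDS: scale ``ξ`` and bias ``ξ_s`` per block of ``BLK``
  weights) and a channel distribution shift (CDS: scale ``φ`` and bias
  ``φ_s`` per output channel), both obtained by closed-form least
  squares so the dequantized kernel approximates the original tensor.

* **Serpentine sampling.**  The k taps of a 1-D kernel are spread along
  one image axis and each tap is displaced perpendicular to it by a
  learnable offset Δy, so the kernel can bend along curved structures.
  Tap c of a horizontal kernel centred at (x_i, y_i) samples
  (x_i + c, y_i + Δy_c); fractional positions are resolved by bilinear
  interpolation with zero padding.

This module is the functional, numpy-only surface; the trainable layer
lives in :mod:`svbdete.nn` and is cross-checked against this path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuantSpec", "SnakeKernelSpec", "FeatureMap",
    "quantize_vqk", "quantization_scales", "fit_kds", "fit_cds",
    "snake_sample_positions", "dsconv_apply", "C2fDSConvBlock",
    "c2f_dsconv_forward",
]


@dataclass
class QuantSpec:
    """Quantization parameters: bit width, block size and fitted shifts."""

    bits: int = 8
    block_size: int = 64
    kds_scale: np.ndarray | None = None   # ξ, one per block
    kds_bias: np.ndarray | None = None    # ξ_s, one per block
    cds_scale: np.ndarray | None = None   # φ, one per output channel
    cds_bias: np.ndarray | None = None    # φ_s, one per output channel

    def __post_init__(self):
        if self.bits < 2:
            raise ValueError(f"bits must be >= 2, got {self.bits}")
        if self.block_size < 1:
            raise ValueError(f"block_size must be >= 1, got {self.block_size}")

    @property
    def qmin(self) -> int:
        return -(2 ** (self.bits - 1))

    @property
    def qmax(self) -> int:
        return 2 ** (self.bits - 1) - 1


@dataclass
class SnakeKernelSpec:
    """A k-tap serpentine kernel: axis, per-tap offsets and clamp."""

    kernel_size: int = 3
    offsets: np.ndarray | None = None
    axis: str = "horizontal"
    offset_clamp: float = 1.0

    def __post_init__(self):
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.axis not in ("horizontal", "vertical"):
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.offset_clamp < 0:
            raise ValueError("offset_clamp must be >= 0")
        if self.offsets is None:
            self.offsets = np.zeros(self.kernel_size)
        self.offsets = np.clip(np.asarray(self.offsets, dtype=float),
                               -self.offset_clamp, self.offset_clamp)
        if self.offsets.shape != (self.kernel_size,):
            raise ValueError("offsets must have one entry per tap")

    @property
    def taps(self) -> np.ndarray:
        h = (self.kernel_size - 1) // 2
        return np.arange(-h, h + 1)


@dataclass
class FeatureMap:
    """A (channel, row, column) activation grid at a given stride."""

    values: np.ndarray
    stride: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("FeatureMap values must be 3-D (C, H, W)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap values must be finite")


# -- quantization -------------------------------------------------------

def _blocks(flat: np.ndarray, block_size: int):
    for start in range(0, flat.size, block_size):
        yield start, flat[start:start + block_size]


def quantization_scales(weights, spec: QuantSpec) -> np.ndarray:
    """Per-block linear-mapping scale: max|w| / (2^(b-1) - 1).

    The symmetric choice keeps every rounded value on the admissible
    grid without clamping distortion, so the mapping error stays within
    half a step.  All-zero blocks use a scale of 1.
    """
    flat = np.asarray(weights, dtype=float).ravel()
    scales = []
    for _, blk in _blocks(flat, spec.block_size):
        m = np.max(np.abs(blk))
        scales.append(m / (2 ** (spec.bits - 1) - 1) if m > 0 else 1.0)
    return np.asarray(scales)


def quantize_vqk(weights, spec: QuantSpec) -> np.ndarray:
    """Map weights block-wise onto the signed integer grid of ``spec.bits``.

    Each block is divided by its linear-mapping scale, rounded half to
    even, and clamped to [-2^(b-1), 2^(b-1)-1].  All-zero blocks use a
    scale of 1.  Returns integers in the shape of ``weights``.
    """
    w = np.asarray(weights, dtype=float)
    flat = w.ravel()
    out = np.empty_like(flat)
    scales = quantization_scales(flat, spec)
    for bi, (start, blk) in enumerate(_blocks(flat, spec.block_size)):
        q = np.rint(blk / scales[bi])          # round half to even
        out[start:start + blk.size] = np.clip(q, spec.qmin, spec.qmax)
    return out.astype(np.int64).reshape(w.shape)


def fit_kds(original, quantized, block_size: int):
    """Closed-form least-squares dequantization fit, per block.

    For each block the scale is the minimizer of
    Σ_i (w_q,i * ξ - w_i)^2, i.e. ξ = Σ w_q w / Σ w_q^2, and the bias
    ξ_s is the mean residual after scaling.  Blocks with Σ w_q^2 = 0
    fall back to ξ = 1, ξ_s = mean(w).
    """
    w = np.asarray(original, dtype=float).ravel()
    wq = np.asarray(quantized, dtype=float).ravel()
    if w.shape != wq.shape:
        raise ValueError("original and quantized must have the same length")
    xis, biases = [], []
    for start, blk in _blocks(w, block_size):
        qblk = wq[start:start + blk.size]
        denom = float(np.sum(qblk * qblk))
        if denom == 0.0:
            xi = 1.0
            bias = float(np.mean(blk))
        else:
            xi = float(np.sum(qblk * blk) / denom)
            bias = float(np.mean(blk - xi * qblk))
        xis.append(xi)
        biases.append(bias)
    return np.asarray(xis), np.asarray(biases)


def fit_cds(original: np.ndarray, reconstructed: np.ndarray):
    """Per-output-channel affine correction, same least-squares recipe.

    ``original`` and ``reconstructed`` have the output channel as the
    leading axis; returns (φ, φ_s) arrays of length C_out.
    """
    co = original.shape[0]
    w = original.reshape(co, -1).astype(float)
    r = reconstructed.reshape(co, -1).astype(float)
    denom = np.sum(r * r, axis=1)
    phi = np.where(denom > 0, np.sum(r * w, axis=1) / np.where(denom > 0, denom, 1.0), 1.0)
    phi_s = np.mean(w - phi[:, None] * r, axis=1)
    return phi, phi_s


def dequantize(quantized, spec: QuantSpec, kds_scale, kds_bias) -> np.ndarray:
    """Reconstruct weights: w ≈ ξ * w_q + ξ_s, block by block."""
    wq = np.asarray(quantized, dtype=float)
    flat = wq.ravel()
    out = np.empty_like(flat)
    for bi, (start, blk) in enumerate(_blocks(flat, spec.block_size)):
        out[start:start + blk.size] = kds_scale[bi] * blk + kds_bias[bi]
    return out.reshape(wq.shape)


def effective_weights(weights: np.ndarray, spec: QuantSpec) -> np.ndarray:
    """Quantize-and-correct: VQK -> KDS per block -> CDS per channel.

    Fills the fitted shifts into ``spec`` in place and returns the
    corrected kernel tensor (same shape as ``weights``, leading axis
    treated as the output channel).
    """
    w = np.asarray(weights, dtype=float)
    wq = quantize_vqk(w, spec)
    xi, xi_s = fit_kds(w, wq, spec.block_size)
    recon = dequantize(wq, spec, xi, xi_s)
    phi, phi_s = fit_cds(w, recon)
    spec.kds_scale, spec.kds_bias = xi, xi_s
    spec.cds_scale, spec.cds_bias = phi, phi_s
    shape = [w.shape[0]] + [1] * (w.ndim - 1)
    return phi.reshape(shape) * recon + phi_s.reshape(shape)


# -- serpentine sampling ------------------------------------------------

def snake_sample_positions(center, spec: SnakeKernelSpec):
    """Sample positions of every tap for a kernel centred at ``center``.

    Horizontal kernels spread taps in x and offset in y; vertical
    kernels swap the roles.  Positions may be fractional.
    """
    x, y = center
    positions = []
    for c, dy in zip(spec.taps, spec.offsets):
        if spec.axis == "horizontal":
            positions.append((x + c, y + dy))
        else:
            positions.append((x + dy, y + c))
    return positions


def _bilinear_shift(x: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """out(i, j) = x(i+dy, j+dx) with bilinear interpolation, zero pad."""
    iy, fy = int(np.floor(dy)), dy - np.floor(dy)
    ix, fx = int(np.floor(dx)), dx - np.floor(dx)
    out = np.zeros_like(x)
    for (oy, oxx, wgt) in (
        (iy, ix, (1 - fy) * (1 - fx)),
        (iy, ix + 1, (1 - fy) * fx),
        (iy + 1, ix, fy * (1 - fx)),
        (iy + 1, ix + 1, fy * fx),
    ):
        if wgt == 0.0:
            continue
        out += wgt * _int_shift(x, oy, oxx)
    return out


def _int_shift(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    H, W = a.shape[-2:]
    out = np.zeros_like(a)
    ys = slice(max(0, dy), min(H, H + dy))
    yd = slice(max(0, -dy), min(H, H - dy))
    xs = slice(max(0, dx), min(W, W + dx))
    xd = slice(max(0, -dx), min(W, W - dx))
    if ys.start < ys.stop and xs.start < xs.stop:
        out[..., yd, xd] = a[..., ys, xs]
    return out


def dsconv_apply(inp, weights, spec: SnakeKernelSpec,
                 quant: QuantSpec | None = None):
    """Apply a serpentine convolution to a (C, H, W) grid.

    ``weights`` has shape (C_out, C_in, k).  Each tap samples the input
    at its snake position via bilinear interpolation with zero padding.
    With ``quant`` given, the kernel is first vector-quantized and
    corrected by the fitted KDS/CDS shifts.
    """
    fm = inp if isinstance(inp, FeatureMap) else FeatureMap(np.asarray(inp))
    x = fm.values.astype(np.float64)
    w = np.asarray(weights, dtype=float)
    if w.ndim != 3:
        raise ValueError("weights must be (C_out, C_in, k)")
    co, ci, k = w.shape
    if ci != x.shape[0]:
        raise ValueError(f"channel mismatch: input {x.shape[0]}, kernel {ci}")
    if k != spec.kernel_size:
        raise ValueError("kernel width does not match spec.kernel_size")
    if quant is not None:
        w = effective_weights(w, quant)
    out = np.zeros((co, x.shape[1], x.shape[2]))
    for idx, (c, dy) in enumerate(zip(spec.taps, spec.offsets)):
        if spec.axis == "horizontal":
            samp = _bilinear_shift(x, dy, float(c))
        else:
            samp = _bilinear_shift(x, float(c), dy)
        out += np.einsum("oc,chw->ohw", w[:, :, idx], samp)
    result = FeatureMap(out.astype(np.float32), stride=fm.stride)
    return result if isinstance(inp, FeatureMap) else result.values


# -- C2f block with serpentine convolutions -----------------------------

class C2fDSConvBlock:
    """Functional wrapper over the trainable C2f block with snake kernels.

    Splits channels, runs ``n`` serpentine bottlenecks, concatenates
    every intermediate and projects back — with all bottleneck and
    channel-adjust convolutions as snake instances.  Spatial size is
    preserved (stride 1).
    """

    def __init__(self, cin: int, cout: int, n: int = 1, seed: int = 0):
        from .nn import C2f
        self.cin, self.cout, self.n = cin, cout, n
        self.block = C2f(cin, cout, n=n, snake=True,
                         rng=np.random.default_rng(seed))
        self.block.eval()

    def num_parameters(self) -> int:
        return self.block.num_parameters()

    def __call__(self, fm: FeatureMap) -> FeatureMap:
        from .autograd import Tensor
        if fm.values.shape[0] != self.cin:
            raise ValueError(
                f"expected {self.cin} input channels, got {fm.values.shape[0]}")
        x = Tensor(fm.values[None])
        y = self.block(x)
        return FeatureMap(y.data[0], stride=fm.stride)


def c2f_dsconv_forward(inp: FeatureMap, block: C2fDSConvBlock) -> FeatureMap:
    """Run a :class:`C2fDSConvBlock` on one feature map."""
    return block(inp)
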