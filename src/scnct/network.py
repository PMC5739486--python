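"""Stacked competitive network: multi-scale maxout convolution blocks.

A competitive block convolves its input with filters at several kernel
scales (e.g. 1x1, 3x3, 5x5), applies ReLU to each scale's response, and
combines them by element-wise maximum across scales, per pixel and per
filter index.  Blocks use same-padding everywhere so the maps of all
scales stay spatially aligned and the network is fully convolutional:
any image size works at inference.

The network stacks ``depth`` such blocks; hidden blocks carry
``filters`` channels and the final block outputs the single-channel
denoised image.  By default the final block's per-scale responses stay
linear (no terminal ReLU) so the output layer keeps a signed gradient.

Everything here is plain NumPy.  Arrays are channel-first:
features ``(batch, channels, height, width)``, weights
``(out_filters, in_channels, k, k)``.  The backward passes are written
by hand (im2col convolutions); they power the training module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SCNArchitecture",
    "CompetitiveBlockParams",
    "SCNModel",
    "competitive_block_forward",
    "scn_forward",
    "scn_loss",
    "conv2d_same",
    "save_checkpoint",
    "load_checkpoint",
]


class ModelDefinitionError(ValueError):
    pass


# ----------------------------------------------------------------------
# convolution primitives (same padding, cross-correlation convention)
# ----------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, N, H, W) -> contiguous (C*k*k, N*H*W) patch matrix with zero
    same-padding.  The batch axis folds into the GEMM column axis, so one
    BLAS call evaluates the convolution for the whole batch."""
    c, n, h, w = x.shape
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((c, k, k, n, h, w), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            cols[:, di, dj] = xp[:, :, di:di + h, dj:dj + w]
    return cols.reshape(c * k * k, n * h * w)


def _conv_cnhw(x, w, b=None):
    """Convolution in the internal (C, N, H, W) layout; w is (F, C, k, k)."""
    c, n, h, wd = x.shape
    f, _c, k, _k = w.shape
    cols = x.reshape(c, n * h * wd) if k == 1 else _im2col(x, k)
    out = w.reshape(f, -1) @ cols
    if b is not None:
        out += b[:, None]
    return out.reshape(f, n, h, wd)


def _conv_cnhw_backward(x, w, dout, cols=None):
    """Gradients of _conv_cnhw; pass the forward ``cols`` to skip a rebuild."""
    c, n, h, wd = x.shape
    f = w.shape[0]
    k = w.shape[2]
    if cols is None:
        cols = x.reshape(c, n * h * wd) if k == 1 else _im2col(x, k)
    dmat = dout.reshape(f, n * h * wd)
    dw = (dmat @ cols.T).reshape(f, c, k, k)
    db = dmat.sum(axis=1)
    w_flip = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx = _conv_cnhw(dout, w_flip)
    return dx, dw, db


def conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None
                ) -> np.ndarray:
    """Same-size 2-D convolution (correlation) of an (N, C, H, W) batch."""
    n, c, h, wd = x.shape
    f, c2, k, k2 = w.shape
    if c != c2 or k != k2:
        raise ModelDefinitionError(
            f"weight shape {w.shape} incompatible with input {x.shape}"
        )
    out = _conv_cnhw(np.ascontiguousarray(x.transpose(1, 0, 2, 3)), w, b)
    return np.ascontiguousarray(out.transpose(1, 0, 2, 3))


# ----------------------------------------------------------------------
# model containers
# ----------------------------------------------------------------------

@dataclass
class CompetitiveBlockParams:
    """Per-scale weights W^k (out, in, k, k) and biases b^k (out,)."""

    weights: dict[int, np.ndarray]
    biases: dict[int, np.ndarray]

    def __post_init__(self):
        if not self.weights:
            raise ModelDefinitionError("block needs at least one scale")
        if set(self.weights) != set(self.biases):
            raise ModelDefinitionError("weights/biases scale sets differ")
        shapes = {k: w.shape for k, w in self.weights.items()}
        outs = {s[0] for s in shapes.values()}
        ins = {s[1] for s in shapes.values()}
        if len(outs) != 1 or len(ins) != 1:
            raise ModelDefinitionError(
                f"all scales must share in/out channel counts, got {shapes}"
            )
        for k, w in self.weights.items():
            if k % 2 != 1 or k < 1:
                raise ModelDefinitionError(f"kernel size must be odd >= 1, got {k}")
            if w.shape[2:] != (k, k):
                raise ModelDefinitionError(
                    f"scale {k} weight has spatial shape {w.shape[2:]}"
                )
            if self.biases[k].shape != (w.shape[0],):
                raise ModelDefinitionError(f"scale {k} bias shape mismatch")

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(sorted(self.weights))

    @property
    def in_channels(self) -> int:
        return next(iter(self.weights.values())).shape[1]

    @property
    def out_channels(self) -> int:
        return next(iter(self.weights.values())).shape[0]

    def n_parameters(self) -> int:
        return sum(w.size + b.size
                   for w, b in zip(self.weights.values(), self.biases.values()))


@dataclass(frozen=True)
class SCNArchitecture:
    """Descriptor: depth, kernel-scale set, hidden filter count.

    ``depth`` counts competitive blocks; the paper-style default network
    uses 96 filters and scales (1, 3, 5).  ``residual`` adds the input
    back to the network output (off by default: the stacked model maps
    the low-dose image to the normal-dose image directly).
    """

    depth: int = 5
    scales: tuple[int, ...] = (1, 3, 5)
    filters: int = 96
    in_channels: int = 1
    final_relu: bool = False
    residual: bool = False

    def __post_init__(self):
        if self.depth < 1:
            raise ModelDefinitionError("depth must be >= 1")
        if not self.scales:
            raise ModelDefinitionError("scale set must be non-empty")
        for k in self.scales:
            if k % 2 != 1 or k < 1:
                raise ModelDefinitionError(f"kernel sizes must be odd >= 1: {k}")
        if self.filters < 1:
            raise ModelDefinitionError("filters must be >= 1")
        object.__setattr__(self, "scales", tuple(sorted(self.scales)))

    def block_channels(self) -> list[tuple[int, int]]:
        """(in, out) channels per block; the last block outputs 1 channel."""
        chans = []
        c_in = self.in_channels
        for i in range(self.depth):
            c_out = 1 if i == self.depth - 1 else self.filters
            chans.append((c_in, c_out))
            c_in = c_out
        return chans

    def n_parameters(self) -> int:
        """Closed form: sum over blocks and scales of (C_in*k^2 + 1)*C_out."""
        return sum(
            (ci * k * k + 1) * co
            for ci, co in self.block_channels()
            for k in self.scales
        )

    def to_json(self) -> str:
        return json.dumps({
            "depth": self.depth, "scales": list(self.scales),
            "filters": self.filters, "in_channels": self.in_channels,
            "final_relu": self.final_relu, "residual": self.residual,
        })

    @classmethod
    def from_json(cls, text: str) -> "SCNArchitecture":
        d = json.loads(text)
        d["scales"] = tuple(d["scales"])
        return cls(**d)


@dataclass
class SCNModel:
    arch: SCNArchitecture
    blocks: list[CompetitiveBlockParams]

    def __post_init__(self):
        chans = self.arch.block_channels()
        if len(self.blocks) != self.arch.depth:
            raise ModelDefinitionError(
                f"{len(self.blocks)} blocks for depth {self.arch.depth}"
            )
        for i, (blk, (ci, co)) in enumerate(zip(self.blocks, chans)):
            if blk.in_channels != ci or blk.out_channels != co:
                raise ModelDefinitionError(
                    f"block {i} channels ({blk.in_channels}->{blk.out_channels})"
                    f" do not chain, expected {ci}->{co}"
                )
            if blk.scales != self.arch.scales:
                raise ModelDefinitionError(
                    f"block {i} scales {blk.scales} != {self.arch.scales}"
                )

    @classmethod
    def initialize(cls, arch: SCNArchitecture, rng: np.random.Generator,
                   init_std: float = 0.01) -> "SCNModel":
        """Zero-mean Gaussian weights (std ``init_std``), zero biases."""
        blocks = []
        for ci, co in arch.block_channels():
            w = {k: rng.normal(0.0, init_std, size=(co, ci, k, k))
                 for k in arch.scales}
            b = {k: np.zeros(co) for k in arch.scales}
            blocks.append(CompetitiveBlockParams(w, b))
        return cls(arch, blocks)

    def n_parameters(self) -> int:
        return sum(b.n_parameters() for b in self.blocks)

    def weight_sq_norm(self) -> float:
        """Total squared Frobenius norm of all convolution weights."""
        return float(sum((w ** 2).sum()
                         for blk in self.blocks for w in blk.weights.values()))

    def parameters(self):
        """Flat list of (block_idx, scale, 'W'|'b', array) views."""
        out = []
        for i, blk in enumerate(self.blocks):
            for k in blk.scales:
                out.append((i, k, "W", blk.weights[k]))
                out.append((i, k, "b", blk.biases[k]))
        return out

    def copy(self) -> "SCNModel":
        return SCNModel(self.arch, [
            CompetitiveBlockParams(
                {k: blk.weights[k].copy() for k in blk.scales},
                {k: blk.biases[k].copy() for k in blk.scales},
            ) for blk in self.blocks
        ])

    def astype(self, dtype) -> "SCNModel":
        return SCNModel(self.arch, [
            CompetitiveBlockParams(
                {k: blk.weights[k].astype(dtype) for k in blk.scales},
                {k: blk.biases[k].astype(dtype) for k in blk.scales},
            ) for blk in self.blocks
        ])


# ----------------------------------------------------------------------
# forward / backward
# ----------------------------------------------------------------------

def _stack_scales(blk: CompetitiveBlockParams, dtype):
    """Embed every scale's kernel at the centre of a k_max x k_max kernel.

    A k x k same-padded convolution equals the k_max x k_max same-padded
    convolution of the centre-embedded kernel, so one GEMM evaluates all
    scales at once.  Returns (W_stacked (S*F, C, kmax, kmax), b_stacked).
    """
    scales = blk.scales
    kmax = scales[-1]
    f = blk.out_channels
    c = blk.in_channels
    w = np.zeros((len(scales) * f, c, kmax, kmax), dtype=dtype)
    b = np.empty(len(scales) * f, dtype=dtype)
    for s_idx, k in enumerate(scales):
        off = (kmax - k) // 2
        w[s_idx * f:(s_idx + 1) * f, :, off:off + k, off:off + k] = \
            blk.weights[k]
        b[s_idx * f:(s_idx + 1) * f] = blk.biases[k]
    return w, b


def _block_forward(x, blk: CompetitiveBlockParams, relu: bool):
    """Forward in (C, N, H, W) layout.

    Returns (out, cache); the cache keeps the im2col matrix for backprop.
    """
    _c, n, h, wd = x.shape
    f = blk.out_channels
    s = len(blk.scales)
    kmax = blk.scales[-1]
    w_st, b_st = _stack_scales(blk, x.dtype)
    cols = x.reshape(_c, n * h * wd) if kmax == 1 else _im2col(x, kmax)
    z = w_st.reshape(s * f, -1) @ cols                   # (S*F, N*H*W)
    z += b_st[:, None]
    z = z.reshape(s, f, n, h, wd)
    if relu:
        np.maximum(z, 0.0, out=z)
    out = z.max(axis=0)                                  # (F, N, H, W)
    winner = z.argmax(axis=0).astype(np.uint8)           # ties -> lowest scale
    return out, (x.shape, cols, winner, out, relu)


def _block_backward(dout, blk: CompetitiveBlockParams, cache,
                    need_dx: bool = True):
    x_shape, cols, winner, out, relu = cache
    c, n, h, wd = x_shape
    f = blk.out_channels
    s = len(blk.scales)
    kmax = blk.scales[-1]
    if relu:
        dout = dout * (out > 0)
    # route the gradient to the winning scale of each (pixel, filter)
    dz = np.zeros((s, f, n, h, wd), dtype=dout.dtype)
    scale_idx = np.arange(s, dtype=np.uint8)[:, None, None, None, None]
    np.copyto(dz, dout[None], where=(winner[None] == scale_idx))
    dmat = dz.reshape(s * f, n * h * wd)
    dw_st = (dmat @ cols.T).reshape(s * f, c, kmax, kmax)
    db_st = dmat.sum(axis=1)
    grads = {}
    for s_idx, k in enumerate(blk.scales):
        off = (kmax - k) // 2
        grads[k] = (
            dw_st[s_idx * f:(s_idx + 1) * f, :, off:off + k, off:off + k],
            db_st[s_idx * f:(s_idx + 1) * f],
        )
    if not need_dx:
        return None, grads
    # input gradient: convolve dz with the flipped, channel-transposed stack
    w_st, _ = _stack_scales(blk, dout.dtype)
    w_flip = np.ascontiguousarray(
        w_st[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx = _conv_cnhw(dmat.reshape(s * f, n, h, wd), w_flip)
    return dx, grads


def competitive_block_forward(a_prev: np.ndarray,
                              params: CompetitiveBlockParams,
                              relu: bool = True) -> np.ndarray:
    """Forward pass of one competitive block on an (H, W, C) feature map.

    Each scale k computes ReLU(conv_k(a_prev) + b_k) with same-size
    output; the block output is their element-wise maximum.  Output is
    (H, W, C_out) with the input's spatial size.
    """
    a_prev = np.asarray(a_prev, dtype=np.float64)
    if a_prev.ndim == 2:
        a_prev = a_prev[:, :, None]
    if a_prev.shape[2] != params.in_channels:
        raise ModelDefinitionError(
            f"input has {a_prev.shape[2]} channels, block expects "
            f"{params.in_channels}"
        )
    x = np.ascontiguousarray(a_prev.transpose(2, 0, 1))[:, None]
    out, _ = _block_forward(x, params, relu)
    return np.ascontiguousarray(out[:, 0].transpose(1, 2, 0))


def _model_forward(x, model: SCNModel, want_cache: bool = False):
    """(N, C, H, W) batch forward; optionally keep caches for backprop.

    Internally runs in the (C, N, H, W) layout; returns (N, C, H, W).
    """
    a = np.ascontiguousarray(x.transpose(1, 0, 2, 3))
    x0 = a
    caches = []
    last = model.arch.depth - 1
    for i, blk in enumerate(model.blocks):
        relu = True if i < last else model.arch.final_relu
        a, cache = _block_forward(a, blk, relu)
        if not np.all(np.isfinite(a)):
            raise FloatingPointError(f"non-finite activations in block {i}")
        caches.append(cache if want_cache else None)
    if model.arch.residual:
        a = a + x0
    out = np.ascontiguousarray(a.transpose(1, 0, 2, 3))
    return (out, caches) if want_cache else out


def _model_backward_cnhw(dout_cnhw, model: SCNModel, caches):
    """Backprop from a (C, N, H, W) output gradient; grads per block.

    The first block's input gradient is never needed and is skipped.
    """
    grads = [None] * len(model.blocks)
    da = dout_cnhw
    for i in range(len(model.blocks) - 1, -1, -1):
        da, grads[i] = _block_backward(da, model.blocks[i], caches[i],
                                       need_dx=(i > 0))
    return grads


def _model_backward(dout, model: SCNModel, caches):
    """Backprop through the stacked blocks from an (N, C, H, W) output
    gradient; returns grads per block."""
    return _model_backward_cnhw(
        np.ascontiguousarray(dout.transpose(1, 0, 2, 3)), model, caches)


def scn_forward(x: np.ndarray, model: SCNModel) -> np.ndarray:
    """Denoise an (H, W) or (H, W, 1) image through the stacked network."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
    if x.shape[2] != model.arch.in_channels:
        raise ModelDefinitionError(
            f"input has {x.shape[2]} channels, model expects "
            f"{model.arch.in_channels}"
        )
    out = _model_forward(x.transpose(2, 0, 1)[None], model)[0].transpose(1, 2, 0)
    return out[:, :, 0] if squeeze else out


def scn_loss(pred: np.ndarray, target: np.ndarray, model: SCNModel,
             alpha: float = 0.0) -> float:
    """Squared-error data term plus weight decay.

    Data term: squared L2 norm of (target - pred), summed over pixels and
    channels, averaged over the batch axis when present.  Penalty:
    alpha times the total squared Frobenius norm of all convolution
    weights (biases excluded).
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    diff = target - pred
    if diff.ndim == 4:  # (batch, channels, H, W)
        data = (diff.reshape(diff.shape[0], -1) ** 2).sum(axis=1).mean()
    else:  # a single image, any layout
        data = (diff ** 2).sum()
    return float(data + alpha * model.weight_sq_norm())


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(path, model: SCNModel, extra: dict | None = None) -> None:
    """Single-file .npz checkpoint with the architecture descriptor embedded."""
    arrays = {"__arch__": np.frombuffer(model.arch.to_json().encode(), dtype=np.uint8)}
    if extra:
        arrays["__extra__"] = np.frombuffer(
            json.dumps(extra).encode(), dtype=np.uint8)
    for i, blk in enumerate(model.blocks):
        for k in blk.scales:
            arrays[f"block{i}_k{k}_W"] = blk.weights[k]
            arrays[f"block{i}_k{k}_b"] = blk.biases[k]
    np.savez(path, **arrays)


def load_checkpoint(path) -> SCNModel:
    """Load a checkpoint; refuses descriptor/weight mismatches."""
    with np.load(path) as data:
        arch = SCNArchitecture.from_json(bytes(data["__arch__"]).decode())
        blocks = []
        for i, (ci, co) in enumerate(arch.block_channels()):
            w, b = {}, {}
            for k in arch.scales:
                try:
                    w[k] = data[f"block{i}_k{k}_W"]
                    b[k] = data[f"block{i}_k{k}_b"]
                except KeyError as e:
                    raise ModelDefinitionError(
                        f"checkpoint missing arrays for block {i} scale {k}"
                    ) from e
                if w[k].shape != (co, ci, k, k):
                    raise ModelDefinitionError(
                        f"checkpoint block {i} scale {k} shape {w[k].shape}"
                        f" != descriptor {(co, ci, k, k)}"
                    )
            blocks.append(CompetitiveBlockParams(w, b))
    return SCNModel(arch, blocks)
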