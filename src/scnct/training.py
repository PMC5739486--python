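"""Patch datasets, optimizers, greedy pretraining and supervised fine-tuning.

The training regimen mirrors classic stacked-network practice: weights
start from zero-mean Gaussians (std 0.01); the hidden blocks can first be
pretrained greedily, each with a throwaway linear reconstruction head
that regresses the block's own input (a per-block autoencoder on the
low-dose patches); the whole network is then fine-tuned end to end on
paired low-dose/normal-dose patches by Adam first and plain SGD after,
under a stepped learning-rate decay from ``lr_init`` toward ``lr_final``.

Full-scale defaults (patch 100, stride 4, lr 1e-2 -> 1e-5) match the
reference regimen; the toy profile used by the tests overrides sizes, not
the procedure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .network import (
    SCNModel, _model_forward, _model_backward,
    _block_forward, _block_backward, _conv_cnhw, _conv_cnhw_backward,
)
from .metrics import psnr

__all__ = ["TrainConfig", "PatchSet", "extract_patches", "build_patchset",
           "pretrain_blocks", "fine_tune", "TrainLogRow"]


@dataclass(frozen=True)
class TrainConfig:
    patch_size: int = 100
    stride: int = 4
    lr_init: float = 1e-2
    lr_final: float = 1e-5
    alpha: float = 1e-6           # weight decay coefficient
    epochs: int = 30
    batch_size: int = 32
    adam_fraction: float = 0.5    # Adam -> SGD handover point
    init_std: float = 0.01
    pretrain: str = "none"        # none | greedy
    pretrain_epochs: int = 3
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lr_final <= self.lr_init):
            raise ValueError("need 0 < lr_final <= lr_init")
        if self.patch_size < 1 or self.stride < 1:
            raise ValueError("patch_size and stride must be >= 1")
        if self.pretrain not in ("none", "greedy"):
            raise ValueError(f"pretrain must be none|greedy, got {self.pretrain}")
        if not (0.0 <= self.adam_fraction <= 1.0):
            raise ValueError("adam_fraction must be in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def lr_at(self, epoch: int) -> float:
        """Step decay x0.1 at evenly spaced milestones from lr_init to
        lr_final; the last segment runs at lr_final."""
        n_steps = int(round(np.log10(self.lr_init / self.lr_final)))
        if n_steps == 0 or self.epochs <= 1:
            return self.lr_init
        seg = self.epochs / (n_steps + 1)
        passed = min(int(epoch // seg), n_steps)
        return self.lr_init * 10.0 ** (-passed)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrainConfig":
        return cls(**json.loads(text))


@dataclass
class PatchSet:
    """Pixel-aligned low-dose/normal-dose patch pairs with provenance."""

    ld: np.ndarray                  # (T, ps, ps)
    nd: np.ndarray                  # (T, ps, ps)
    provenance: list[tuple[str, int, int]]  # (source image id, row, col)

    def __post_init__(self):
        if self.ld.shape != self.nd.shape:
            raise ValueError("ld/nd patch arrays differ in shape")
        if len(self.provenance) != self.ld.shape[0]:
            raise ValueError("provenance length mismatch")

    def __len__(self) -> int:
        return self.ld.shape[0]

    def source_ids(self) -> set[str]:
        return {p[0] for p in self.provenance}

    @staticmethod
    def concatenate(sets: list["PatchSet"]) -> "PatchSet":
        return PatchSet(
            np.concatenate([s.ld for s in sets]),
            np.concatenate([s.nd for s in sets]),
            [p for s in sets for p in s.provenance],
        )


def extract_patches(ld: np.ndarray, nd: np.ndarray, cfg: TrainConfig,
                    image_id: str = "img") -> PatchSet:
    """All fully-inside patches at offsets (r*stride, c*stride), row-major.

    Count per axis is floor((N - patch_size)/stride) + 1.
    """
    ld = np.asarray(ld, dtype=np.float64)
    nd = np.asarray(nd, dtype=np.float64)
    if ld.shape != nd.shape or ld.ndim != 2:
        raise ValueError("ld and nd must be 2-D images of the same shape")
    ps, st = cfg.patch_size, cfg.stride
    h, w = ld.shape
    if ps > h or ps > w:
        raise ValueError(f"patch {ps} larger than image {ld.shape}")
    rows = range(0, h - ps + 1, st)
    cols = range(0, w - ps + 1, st)
    lds, nds, prov = [], [], []
    for r in rows:
        for c in cols:
            lds.append(ld[r:r + ps, c:c + ps])
            nds.append(nd[r:r + ps, c:c + ps])
            prov.append((image_id, r, c))
    return PatchSet(np.stack(lds), np.stack(nds), prov)


def build_patchset(pairs, cfg: TrainConfig, ids=None) -> PatchSet:
    """Extract and pool patches from a list of (ld, nd) image pairs."""
    sets = []
    for idx, (ld, nd) in enumerate(pairs):
        image_id = ids[idx] if ids is not None else f"img{idx:04d}"
        sets.append(extract_patches(ld, nd, cfg, image_id))
    return PatchSet.concatenate(sets)


# ----------------------------------------------------------------------
# optimizers (operate on the model's flat parameter list, in place)
# ----------------------------------------------------------------------

class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def step(self, params, grads, lr):
        for p, g in zip(params, grads):
            p -= lr * g


def _flat_params(model: SCNModel):
    return [arr for *_n, arr in model.parameters()]


def _loss_and_grads(model: SCNModel, xb, yb, alpha):
    """Mean-over-batch, sum-over-pixels squared error + weight decay.

    Returns (loss, flat gradient list matching model.parameters()).
    """
    out, caches = _model_forward(xb, model, want_cache=True)
    diff = out - yb
    n = xb.shape[0]
    data = float((diff.reshape(n, -1) ** 2).sum(axis=1).mean())
    dout = (2.0 / n) * diff
    # with a residual skip d(out)/d(net) is still the identity
    block_grads = _model_backward(dout, model, caches)
    loss = data + alpha * model.weight_sq_norm()
    flat = []
    for i, blk in enumerate(model.blocks):
        for k in blk.scales:
            dw, db = block_grads[i][k]
            flat.append(dw + 2.0 * alpha * blk.weights[k])
            flat.append(db)
    return loss, flat


@dataclass
class TrainLogRow:
    epoch: int
    phase: str
    lr: float
    train_loss: float
    val_psnr: float


def _as_batches(ld, nd, batch_size, order):
    for start in range(0, len(order), batch_size):
        sel = order[start:start + batch_size]
        yield ld[sel][:, None, :, :], nd[sel][:, None, :, :]


def pretrain_blocks(patches: PatchSet, model: SCNModel,
                    cfg: TrainConfig, return_log: bool = False):
    """Greedy layer-wise pretraining of the first depth-1 blocks.

    Block i is trained, with a temporary linear 3x3 reconstruction head,
    to reproduce its own input features (squared error, Adam); the head
    is then discarded and the block's output feeds block i+1.  The final
    block keeps its random initialization.  Uses the low-dose patches
    only.  A depth-1 model is returned untouched.
    """
    model = model.astype(patches.ld.dtype)
    depth = model.arch.depth
    log: list[tuple[int, float, float]] = []  # (block, first loss, last loss)
    if depth <= 1:
        return (model, log) if return_log else model
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    # internal (C, N, H, W) layout; a_0 = the LDCT patches
    feats = np.ascontiguousarray(patches.ld[None, :, :, :])
    for i in range(depth - 1):
        blk = model.blocks[i]
        c_in = blk.in_channels
        head_w = rng.normal(0.0, cfg.init_std,
                            size=(c_in, blk.out_channels, 3, 3))
        head_b = np.zeros(c_in)
        if feats.dtype != np.float64:
            head_w = head_w.astype(feats.dtype)
            head_b = head_b.astype(feats.dtype)
        params = [blk.weights[k] for k in blk.scales] + \
                 [blk.biases[k] for k in blk.scales] + [head_w, head_b]
        opt = _Adam(params)
        order_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 1000 + i]))
        lr = min(cfg.lr_init, 1e-3)
        first_loss = last_loss = np.nan
        for _epoch in range(cfg.pretrain_epochs):
            order = order_rng.permutation(feats.shape[1])
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                xb = np.ascontiguousarray(feats[:, sel])
                out, cache = _block_forward(xb, blk, relu=True)
                rec = _conv_cnhw(out, head_w, head_b)
                diff = rec - xb
                n = xb.shape[1]
                if not np.all(np.isfinite(diff)):
                    raise FloatingPointError(
                        f"pretraining diverged at block {i}")
                last_loss = float((diff ** 2).sum() / n)
                if np.isnan(first_loss):
                    first_loss = last_loss
                drec = (2.0 / n) * diff
                dout, dhw, dhb = _conv_cnhw_backward(out, head_w, drec)
                _dx, bgrads = _block_backward(dout, blk, cache)
                grads = [bgrads[k][0] for k in blk.scales] + \
                        [bgrads[k][1] for k in blk.scales] + [dhw, dhb]
                opt.step(params, grads, lr)
        log.append((i, first_loss, last_loss))
        # freeze: push features through the trained block (in batches)
        outs = []
        for start in range(0, feats.shape[1], 256):
            outs.append(_block_forward(feats[:, start:start + 256], blk, True)[0])
        feats = np.concatenate(outs, axis=1)
    return (model, log) if return_log else model


def fine_tune(patches: PatchSet, model: SCNModel, cfg: TrainConfig,
              val_patches: PatchSet | None = None
              ) -> tuple[SCNModel, list[TrainLogRow]]:
    """End-to-end supervised training: Adam phase then SGD phase.

    Minimizes the squared-error + weight-decay objective over patch
    pairs; logs per-epoch training loss and validation PSNR, and returns
    the best-validation checkpoint (the final model when no validation
    set is given).
    """
    model = model.astype(patches.ld.dtype)  # compute dtype follows the data
    params = _flat_params(model)
    adam = _Adam(params)
    sgd = _SGD()
    n_adam = int(round(cfg.adam_fraction * cfg.epochs))
    order_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 42]))
    log: list[TrainLogRow] = []
    best = (-np.inf, model.copy())
    for epoch in range(cfg.epochs):
        phase = "adam" if epoch < n_adam else "sgd"
        opt = adam if phase == "adam" else sgd
        lr = cfg.lr_at(epoch)
        order = order_rng.permutation(len(patches))
        total, nb = 0.0, 0
        for xb, yb in _as_batches(patches.ld, patches.nd, cfg.batch_size, order):
            loss, grads = _loss_and_grads(model, xb, yb, cfg.alpha)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {nb}")
            opt.step(params, grads, lr)
            total += loss
            nb += 1
        val = _validation_psnr(model, val_patches) if val_patches is not None \
            else np.nan
        log.append(TrainLogRow(epoch, phase, lr, total / max(nb, 1), val))
        if val_patches is not None and val > best[0]:
            best = (val, model.copy())
    final = best[1] if val_patches is not None and np.isfinite(best[0]) else model
    return final, log


def _validation_psnr(model: SCNModel, val: PatchSet, chunk: int = 128) -> float:
    """PSNR of the model output vs the clean patches, pooled over pixels."""
    se, npx = 0.0, 0
    for start in range(0, len(val), chunk):
        xb = val.ld[start:start + chunk][:, None]
        yb = val.nd[start:start + chunk][:, None]
        out = _model_forward(xb, model)
        se += float(((out - yb) ** 2).sum())
        npx += out.size
    mse = se / npx
    return float(10.0 * np.log10(1.0 / mse)) if mse > 0 else np.inf
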