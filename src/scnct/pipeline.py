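"""End-to-end orchestration: dataset fabrication, training, evaluation.

A run executes simulate -> reconstruct -> split -> patch -> (pretrain)
-> fine-tune -> evaluate.  Both members of every training pair pass
through reconstruction: the normal-dose image is the FBP of the
noiseless sinogram and the low-dose image the FBP of the Poisson-
corrupted one, so the network learns reconstruction-domain noise, not
raster-vs-reconstruction bias.  All images of a dataset share one fixed
affine map to [0, 1] (min/max of the normal-dose set).

Architecture variants for the ablation harness:

    cnn3 -> scales {3}        cnn5 -> scales {5}
    scn2 -> {1, 3}   scn3 -> {1, 3, 5}   scn4 -> {1, 3, 5, 7}

Single-scale variants can be widened to match a reference variant's
trainable-parameter budget.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import random_phantom_spec, generate_phantom, AttenuationImage
from .forward import FanBeamGeometry, siddon_project, simulate_counts, \
    counts_to_sinogram
from .fbp import ReconGrid, fbp_reconstruct
from .network import SCNArchitecture, SCNModel, scn_forward, save_checkpoint
from .training import TrainConfig, build_patchset, pretrain_blocks, fine_tune
from .metrics import evaluate_images, EvalReport

__all__ = [
    "VARIANT_SCALES", "variant_architecture", "matched_filters",
    "PairedSlice", "PairedDataset", "make_dataset", "split_dataset",
    "ExperimentConfig", "run_experiment", "toy_experiment_config",
]

log = logging.getLogger("scnct")

VARIANT_SCALES = {
    "cnn3": (3,),
    "cnn5": (5,),
    "scn2": (1, 3),
    "scn3": (1, 3, 5),
    "scn4": (1, 3, 5, 7),
}


def matched_filters(scales, depth: int, reference: SCNArchitecture) -> int:
    """Hidden-filter count making a variant's parameter count closest to
    the reference architecture's (matched capacity for fair ablations)."""
    target = reference.n_parameters()
    best, best_gap = 1, float("inf")
    for f in range(1, 4 * reference.filters + 8):
        n = SCNArchitecture(depth=depth, scales=tuple(scales), filters=f,
                            in_channels=reference.in_channels).n_parameters()
        gap = abs(n - target)
        if gap < best_gap:
            best, best_gap = f, gap
    return best


def variant_architecture(variant: str, depth: int, filters: int,
                         match_to: SCNArchitecture | None = None
                         ) -> SCNArchitecture:
    if variant not in VARIANT_SCALES:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(VARIANT_SCALES)}"
        )
    scales = VARIANT_SCALES[variant]
    if match_to is not None:
        filters = matched_filters(scales, depth, match_to)
    return SCNArchitecture(depth=depth, scales=scales, filters=filters)


# ----------------------------------------------------------------------
# dataset fabrication
# ----------------------------------------------------------------------

@dataclass
class PairedSlice:
    image_id: str
    ndct: np.ndarray      # normalized [0, 1]
    ldct: np.ndarray      # same affine map as ndct
    b0: float


@dataclass
class PairedDataset:
    slices: list[PairedSlice]
    norm_lo: float
    norm_hi: float
    geometry: FanBeamGeometry
    grid_n: int
    fov_mm: float

    def ids(self) -> list[str]:
        return [s.image_id for s in self.slices]

    def provenance_hash(self) -> str:
        h = hashlib.sha256()
        for s in self.slices:
            h.update(s.image_id.encode())
            h.update(np.ascontiguousarray(s.ndct).tobytes())
            h.update(np.ascontiguousarray(s.ldct).tobytes())
        return h.hexdigest()[:16]


def simulate_pair(phantom_img, geom: FanBeamGeometry, grid: ReconGrid,
                  b0: float, seed: int, r_mean: float = 0.0,
                  window: str = "hann"):
    """One slice through the full chain; returns (ndct, ldct) raw
    attenuation reconstructions (not yet normalized)."""
    sino = siddon_project(phantom_img, geom)
    ndct = fbp_reconstruct(sino, grid, window=window)
    counts = simulate_counts(sino, b0=b0, r_mean=r_mean, seed=seed)
    noisy = counts_to_sinogram(counts)
    ldct = fbp_reconstruct(noisy, grid, window=window)
    return ndct, ldct


def make_dataset(n_images: int, geom: FanBeamGeometry, grid_n: int,
                 fov_mm: float, b0_levels, seed: int,
                 window: str = "hann", id_prefix: str = "img",
                 r_mean: float = 0.0,
                 partial_volume_px: float = 0.7) -> PairedDataset:
    """Fabricate paired normal-/low-dose slices from random phantoms.

    Noise levels cycle through ``b0_levels`` (mixed-level training when
    several are given).  All randomness derives from ``seed``.

    ``partial_volume_px`` applies a small Gaussian blur (in pixels) to the
    rasterized phantom before projection, emulating the partial-volume
    smoothness of real CT slices; pixel-sharp raster edges would otherwise
    fill the reconstructions with Gibbs ringing no real scanner shows.
    Set 0 to disable.
    """
    b0_levels = [float(b) for b in np.atleast_1d(b0_levels)]
    grid = ReconGrid(grid_n, fov_mm)
    ss = np.random.SeedSequence(seed)
    spec_rng = np.random.default_rng(ss.spawn(1)[0])
    noise_seeds = ss.generate_state(n_images) % (2**31 - 1)
    raw = []
    for i in range(n_images):
        spec = random_phantom_spec(spec_rng, grid_n=grid_n, fov_mm=fov_mm)
        img = generate_phantom(spec)
        if partial_volume_px > 0:
            img = AttenuationImage(
                gaussian_filter(img.values, partial_volume_px),
                img.pixel_size_mm)
        b0 = b0_levels[i % len(b0_levels)]
        ndct, ldct = simulate_pair(img, geom, grid, b0,
                                   int(noise_seeds[i]), r_mean, window)
        raw.append((f"{id_prefix}{i:04d}", ndct.values, ldct.values, b0))
    lo = min(float(n.min()) for _i, n, _l, _b in raw)
    hi = max(float(n.max()) for _i, n, _l, _b in raw)
    if hi <= lo:
        hi = lo + 1.0
    slices = [
        PairedSlice(i, (n - lo) / (hi - lo), (l - lo) / (hi - lo), b)
        for i, n, l, b in raw
    ]
    return PairedDataset(slices, lo, hi, geom, grid_n, fov_mm)


def split_dataset(ds: PairedDataset, val_fraction: float, seed: int
                  ) -> tuple[list[PairedSlice], list[PairedSlice]]:
    """Image-level train/validation split; returns (train, val)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    n = len(ds.slices)
    n_val = max(1, int(round(val_fraction * n))) if val_fraction > 0 else 0
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(ds.slices) if i not in val_idx]
    val = [s for i, s in enumerate(ds.slices) if i in val_idx]
    assert {s.image_id for s in train}.isdisjoint({s.image_id for s in val})
    return train, val


# ----------------------------------------------------------------------
# experiment harness
# ----------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    variant: str = "scn3"
    depth: int = 3
    filters: int = 16
    match_budget_to: str | None = None   # e.g. "scn3": match that variant's size
    n_train_images: int = 41
    n_test_images: int = 6
    grid_n: int = 64
    fov_mm: float = 200.0
    geometry: FanBeamGeometry = field(default_factory=FanBeamGeometry)
    b0_levels: tuple[float, ...] = (1e5,)
    r_mean: float = 0.0
    partial_volume_px: float = 0.7
    fbp_window: str = "hann"
    train: TrainConfig = field(default_factory=TrainConfig)
    out_dir: str | None = None
    seed: int = 0

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = self.geometry.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = FanBeamGeometry.from_dict(d["geometry"])
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "b0_levels" in d:
            d["b0_levels"] = tuple(d["b0_levels"])
        return cls(**d)


def toy_experiment_config(variant: str = "scn3", seed: int = 0,
                          out_dir: str | None = None) -> ExperimentConfig:
    """The documented toy profile: 64x64 phantoms, depth-3 16-filter
    networks, b0 = 1e5, ~2000 patches of 16x16, 30 epochs, Adam -> SGD."""
    return ExperimentConfig(
        variant=variant, depth=3, filters=16,
        match_budget_to="scn3" if variant in ("cnn3", "cnn5") else None,
        n_train_images=41, n_test_images=6, grid_n=64, fov_mm=200.0,
        geometry=FanBeamGeometry(n_bins=512, n_views=128),
        b0_levels=(1e5,),
        train=TrainConfig(patch_size=16, stride=8, lr_init=3e-3,
                          lr_final=3e-5, alpha=1e-6, epochs=30,
                          batch_size=16, seed=seed),
        out_dir=out_dir, seed=seed,
    )


@dataclass
class ExperimentResult:
    config: dict
    model: SCNModel
    report: EvalReport            # denoised vs NDCT on held-out images
    baseline: EvalReport          # LDCT vs NDCT on the same images
    train_log: list
    provenance: dict


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Execute the full pipeline and (optionally) persist every stage."""
    t0 = time.time()
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        train_ds = make_dataset(
            cfg.n_train_images, cfg.geometry, cfg.grid_n, cfg.fov_mm,
            cfg.b0_levels, seed=cfg.seed, window=cfg.fbp_window,
            id_prefix="train", r_mean=cfg.r_mean,
            partial_volume_px=cfg.partial_volume_px)
        # held-out phantoms come from an independent seed stream -> unseen specs
        test_ds = make_dataset(
            cfg.n_test_images, cfg.geometry, cfg.grid_n, cfg.fov_mm,
            cfg.b0_levels, seed=cfg.seed + 10_000, window=cfg.fbp_window,
            id_prefix="test", r_mean=cfg.r_mean,
            partial_volume_px=cfg.partial_volume_px)
        log.info("simulated %d train + %d test slices in %.1fs",
                 cfg.n_train_images, cfg.n_test_images, time.time() - t0)

        stage = "split"
        train_slices, val_slices = split_dataset(
            train_ds, cfg.train.val_fraction, cfg.seed)
        train_ids = {s.image_id for s in train_slices}
        test_ids = {s.image_id for s in test_ds.slices}
        if not train_ids.isdisjoint(test_ids):
            raise RuntimeError("train/test source images overlap")

        stage = "patch"
        patches = build_patchset([(s.ldct, s.ndct) for s in train_slices],
                                 cfg.train, ids=[s.image_id for s in train_slices])
        val_patches = build_patchset([(s.ldct, s.ndct) for s in val_slices],
                                     cfg.train, ids=[s.image_id for s in val_slices]) \
            if val_slices else None
        # single precision is plenty for SGD on unit-range patches
        patches.ld = patches.ld.astype(np.float32)
        patches.nd = patches.nd.astype(np.float32)
        if val_patches is not None:
            val_patches.ld = val_patches.ld.astype(np.float32)
            val_patches.nd = val_patches.nd.astype(np.float32)
        if val_patches is not None:
            assert patches.source_ids().isdisjoint(val_patches.source_ids())

        stage = "init"
        match_to = None
        if cfg.match_budget_to:
            match_to = SCNArchitecture(
                depth=cfg.depth, scales=VARIANT_SCALES[cfg.match_budget_to],
                filters=cfg.filters)
        arch = variant_architecture(cfg.variant, cfg.depth, cfg.filters,
                                    match_to=match_to)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 5]))
        model = SCNModel.initialize(arch, rng, init_std=cfg.train.init_std)

        stage = "pretrain"
        if cfg.train.pretrain == "greedy":
            model = pretrain_blocks(patches, model, cfg.train)

        stage = "fine_tune"
        model, train_log = fine_tune(patches, model, cfg.train, val_patches)

        stage = "evaluate"
        denoised = [scn_forward(s.ldct, model) for s in test_ds.slices]
        refs = [s.ndct for s in test_ds.slices]
        report = evaluate_images(denoised, refs, image_ids=test_ds.ids())
        baseline = evaluate_images([s.ldct for s in test_ds.slices], refs,
                                   image_ids=test_ds.ids())
    except Exception:
        log.exception("experiment failed at stage %r", stage)
        if out:
            (out / "FAILED").write_text(stage)
        raise

    provenance = {
        "train_hash": train_ds.provenance_hash(),
        "test_hash": test_ds.provenance_hash(),
        "n_patches": len(patches),
        "n_parameters": model.n_parameters(),
        "variant": cfg.variant,
        "scales": list(arch.scales),
        "filters": arch.filters,
        "elapsed_s": round(time.time() - t0, 1),
    }
    result = ExperimentResult(cfg.resolved(), model, report, baseline,
                              train_log, provenance)
    if out:
        _persist(out, cfg, result)
    return result


def _persist(out: Path, cfg: ExperimentConfig, res: ExperimentResult) -> None:
    (out / "config.json").write_text(json.dumps(res.config, indent=2))
    (out / "provenance.json").write_text(json.dumps(res.provenance, indent=2))
    save_checkpoint(out / "model.npz", res.model)
    with open(out / "train_log.csv", "w", newline="") as f:
        wr = csv.writer(f)
        wr.writerow(["epoch", "phase", "lr", "train_loss", "val_psnr"])
        for row in res.train_log:
            wr.writerow([row.epoch, row.phase, row.lr,
                         row.train_loss, row.val_psnr])
    for name, rep in (("report", res.report), ("baseline", res.baseline)):
        with open(out / f"{name}.csv", "w", newline="") as f:
            wr = csv.DictWriter(
                f, fieldnames=["image_id", "psnr_db", "rmse", "ssim"])
            wr.writeheader()
            for r in rep.to_rows():
                wr.writerow(r)
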