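"""Image-quality metrics: PSNR, RMSE, SSIM, with ROI support.

All images are expected on the unit range ([0, 1] after the dataset's
fixed affine normalization), so ``peak`` defaults to 1.0 everywhere.
SSIM is the canonical single-scale formulation: 11x11 Gaussian window
with sigma 1.5, C1 = (0.01 * peak)^2, C2 = (0.03 * peak)^2, averaged over
the local similarity map (delegated to scikit-image with exactly those
settings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["psnr", "rmse", "ssim", "Roi", "EvalReport", "evaluate_images"]


def _check_pair(x, ref):
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {ref.shape}")
    return x, ref


def rmse(x: np.ndarray, ref: np.ndarray) -> float:
    """Root mean squared error."""
    x, ref = _check_pair(x, ref)
    return float(np.sqrt(np.mean((x - ref) ** 2)))


def psnr(x: np.ndarray, ref: np.ndarray, peak: float = 1.0) -> float:
    """10*log10(peak^2 / MSE) in dB; +inf when the images are identical."""
    if not peak > 0:
        raise ValueError(f"peak must be > 0, got {peak}")
    x, ref = _check_pair(x, ref)
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0.0:
        return math.inf
    return float(10.0 * np.log10(peak**2 / mse))


def ssim(x: np.ndarray, ref: np.ndarray, peak: float = 1.0) -> float:
    """Mean structural similarity over the local 11x11 Gaussian-window map."""
    if not peak > 0:
        raise ValueError(f"peak must be > 0, got {peak}")
    x, ref = _check_pair(x, ref)
    if min(x.shape) < 11:
        raise ValueError(
            f"image {x.shape} smaller than the 11x11 SSIM window; "
            "use a larger image or a custom window"
        )
    return float(structural_similarity(
        x, ref, data_range=peak, gaussian_weights=True, sigma=1.5,
        win_size=11, use_sample_covariance=False, K1=0.01, K2=0.03,
    ))


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest: half-open row/column ranges."""

    row0: int
    row1: int
    col0: int
    col1: int
    name: str = ""

    def crop(self, img: np.ndarray) -> np.ndarray:
        if not (0 <= self.row0 < self.row1 <= img.shape[0]
                and 0 <= self.col0 < self.col1 <= img.shape[1]):
            raise ValueError(f"ROI {self} outside image {img.shape}")
        return img[self.row0:self.row1, self.col0:self.col1]


@dataclass
class EvalReport:
    """Per-image metric rows plus aggregate mean/std over images."""

    image_ids: list[str]
    psnr_db: list[float]
    rmse: list[float]
    ssim: list[float]
    roi: Roi | None = None

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """(mean, std) per metric, over per-image values (ddof=0)."""
        out = {}
        for name, vals in (("psnr_db", self.psnr_db), ("rmse", self.rmse),
                           ("ssim", self.ssim)):
            a = np.asarray(vals, dtype=np.float64)
            out[name] = (float(a.mean()), float(a.std()))
        return out

    def to_rows(self) -> list[dict]:
        return [
            {"image_id": i, "psnr_db": p, "rmse": r, "ssim": s}
            for i, p, r, s in zip(self.image_ids, self.psnr_db,
                                  self.rmse, self.ssim)
        ]


def evaluate_images(preds, refs, image_ids=None, peak: float = 1.0,
                    roi: Roi | None = None) -> EvalReport:
    """Evaluate paired image lists; ROI (when given) crops both inputs."""
    preds = list(preds)
    refs = list(refs)
    if len(preds) != len(refs):
        raise ValueError("pred/ref lists differ in length")
    if image_ids is None:
        image_ids = [f"img{i:04d}" for i in range(len(preds))]
    rows_p, rows_r, rows_s = [], [], []
    for x, ref in zip(preds, refs):
        if roi is not None:
            x, ref = roi.crop(np.asarray(x)), roi.crop(np.asarray(ref))
        rows_p.append(psnr(x, ref, peak))
        rows_r.append(rmse(x, ref))
        rows_s.append(ssim(x, ref, peak))
    return EvalReport(list(image_ids), rows_p, rows_r, rows_s, roi)
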