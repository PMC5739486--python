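"""Portable on-disk containers.

Float images and sinograms are stored as .npy (32-bit float) with an
optional JSON sidecar for geometry/metadata; 8/16-bit PNG export with
explicit windowing is provided for visualization only.  Grayscale PNG/
TIFF and (read-only) DICOM slices can be imported as float images.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import imageio.v3 as iio

from .forward import FanBeamGeometry, Sinogram
from .phantom import AttenuationImage

__all__ = [
    "save_image", "load_image", "save_sinogram", "load_sinogram",
    "export_png", "read_slice",
]


def save_image(path, image: AttenuationImage) -> None:
    path = Path(path)
    np.save(path, image.values.astype(np.float32))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"pixel_size_mm": image.pixel_size_mm}))


def load_image(path) -> AttenuationImage:
    path = Path(path)
    vals = np.load(path).astype(np.float64)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return AttenuationImage(vals, float(meta.get("pixel_size_mm", 1.0)))


def save_sinogram(path, sino: Sinogram) -> None:
    path = Path(path)
    np.save(path, sino.values.astype(np.float32))
    path.with_suffix(".json").write_text(json.dumps({
        "geometry": sino.geometry.to_dict(), "noisy": sino.noisy,
    }))


def load_sinogram(path) -> Sinogram:
    path = Path(path)
    vals = np.load(path).astype(np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Sinogram(vals, FanBeamGeometry.from_dict(meta["geometry"]),
                    noisy=bool(meta["noisy"]))


def export_png(path, values: np.ndarray, window: tuple[float, float],
               bits: int = 8) -> None:
    """Window [lo, hi] -> full integer range; values outside are clipped."""
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"window must satisfy hi > lo, got {window}")
    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    x = (np.asarray(values, dtype=np.float64) - lo) / (hi - lo)
    np.clip(x, 0.0, 1.0, out=x)
    dtype = np.uint8 if bits == 8 else np.uint16
    iio.imwrite(Path(path), (x * (2**bits - 1)).round().astype(dtype))


def read_slice(path, pixel_size_mm: float | None = None) -> AttenuationImage:
    """Import a user-supplied grayscale slice (PNG/TIFF/NPY/DICOM) as a
    float image; integer formats are rescaled to [0, 1]."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        vals = np.load(path).astype(np.float64)
        psz = pixel_size_mm or 1.0
    elif suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        vals = ds.pixel_array.astype(np.float64)
        vals -= vals.min()
        if vals.max() > 0:
            vals /= vals.max()
        psz = pixel_size_mm or float(getattr(ds, "PixelSpacing", [1.0])[0])
    else:
        vals = np.asarray(iio.imread(path), dtype=np.float64)
        if vals.ndim == 3:
            vals = vals.mean(axis=2)
        info = np.iinfo(iio.imread(path).dtype) if np.issubdtype(
            iio.imread(path).dtype, np.integer) else None
        if info is not None:
            vals /= info.max
        psz = pixel_size_mm or 1.0
    return AttenuationImage(vals, psz)
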