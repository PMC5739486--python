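import numpy as np
import pytest

from scnct.forward import FanBeamGeometry, ray_endpoints
from scnct.phantom import AttenuationImage, generate_phantom, uniform_disk


def dense_ray_integral(values: np.ndarray, fov_mm: float,
                       p0: tuple[float, float], p1: tuple[float, float],
                       n_steps_per_pixel: int = 1000) -> float:
    """Independent line-integral oracle: midpoint Riemann sum along the
    segment p0 -> p1 with a step far below the pixel size, looking up the
    raster value at each sample (same pixel-center convention).

    Deliberately naive and algorithm-independent of the Siddon walk.
    """
    n = values.shape[0]
    pix = fov_mm / n
    half = fov_mm / 2.0
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.hypot(*(p1 - p0)))
    step = pix / n_steps_per_pixel
    m = max(int(np.ceil(length / step)), 1)
    t = (np.arange(m) + 0.5) / m
    xs = p0[0] + t * (p1[0] - p0[0])
    ys = p0[1] + t * (p1[1] - p0[1])
    j = np.floor((xs + half) / pix).astype(np.int64)
    i = np.floor((half - ys) / pix).astype(np.int64)
    ok = (i >= 0) & (i < n) & (j >= 0) & (j < n)
    vals = np.zeros(m)
    vals[ok] = values[i[ok], j[ok]]
    return float(vals.sum() * (length / m))


def dense_oracle_sinogram(image: AttenuationImage, geom: FanBeamGeometry,
                          n_steps_per_pixel: int = 1000) -> np.ndarray:
    src_x, src_y, det_x, det_y = ray_endpoints(geom)
    out = np.zeros((geom.n_views, geom.n_bins))
    for v in range(geom.n_views):
        for b in range(geom.n_bins):
            out[v, b] = dense_ray_integral(
                image.values, image.fov_mm,
                (src_x[v], src_y[v]), (det_x[v, b], det_y[v, b]),
                n_steps_per_pixel,
            )
    return out


@pytest.fixture(scope="session")
def small_geom() -> FanBeamGeometry:
    """Reduced ray count for oracle comparisons (coverage unchanged)."""
    return FanBeamGeometry(n_bins=64, n_views=32)


@pytest.fixture(scope="session")
def disk_image() -> AttenuationImage:
    return generate_phantom(uniform_disk())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
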