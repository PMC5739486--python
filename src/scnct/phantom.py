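"""Synthetic 2-D attenuation phantoms.

Phantoms are compositions of constant-attenuation ellipses on a square
grid and stand in for normal-dose CT slices.  All continuous coordinates
are in millimetres with the origin at the image centre, x pointing right
and y pointing up; array element (0, 0) is the top-left pixel.  A pixel
belongs to an ellipse iff its centre does (no anti-aliasing), which makes
line-integral and area oracles exact against the same raster.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "AttenuationImage",
    "generate_phantom",
    "random_phantom_spec",
    "uniform_disk",
    "two_disk_pair",
    "shepp_logan_like",
]

#: soft-tissue linear attenuation around 60-70 keV, mm^-1
MU_WATER = 0.02


class PhantomError(ValueError):
    """Invalid phantom specification."""


@dataclass(frozen=True)
class Ellipse:
    """One constant-attenuation ellipse.

    ``delta_mu`` is added (mm^-1) to every pixel whose centre lies inside;
    negative deltas carve hypodense structures out of the background.
    """

    center_x_mm: float
    center_y_mm: float
    axis_a_mm: float
    axis_b_mm: float
    angle_deg: float = 0.0
    delta_mu: float = 0.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Membership mask for points (x, y) in mm."""
        t = np.deg2rad(self.angle_deg)
        dx = x - self.center_x_mm
        dy = y - self.center_y_mm
        u = dx * np.cos(t) + dy * np.sin(t)
        v = -dx * np.sin(t) + dy * np.cos(t)
        return (u / self.axis_a_mm) ** 2 + (v / self.axis_b_mm) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_n: int = 256
    fov_mm: float = 200.0
    ellipses: tuple[Ellipse, ...] = ()
    background_mu: float = 0.0

    def __post_init__(self):
        if self.grid_n < 16:
            raise PhantomError(f"grid_n must be >= 16, got {self.grid_n}")
        if not self.fov_mm > 0:
            raise PhantomError(f"fov_mm must be > 0, got {self.fov_mm}")
        if self.background_mu < 0:
            raise PhantomError(
                f"background_mu must be >= 0, got {self.background_mu}"
            )
        for e in self.ellipses:
            if e.axis_a_mm <= 0 or e.axis_b_mm <= 0:
                raise PhantomError(f"ellipse axes must be > 0, got {e}")
        object.__setattr__(self, "ellipses", tuple(self.ellipses))

    # -- JSON round trip ------------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["ellipses"] = [dataclasses.asdict(e) for e in self.ellipses]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["ellipses"] = tuple(Ellipse(**e) for e in d.get("ellipses", ()))
        return cls(**d)


@dataclass
class AttenuationImage:
    """Non-negative linear-attenuation map (mm^-1) with physical pixel size."""

    values: np.ndarray
    pixel_size_mm: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise PhantomError(f"values must be square 2-D, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise PhantomError("attenuation values must be finite")
        if self.values.min() < 0:
            raise PhantomError("attenuation values must be >= 0")
        if not self.pixel_size_mm > 0:
            raise PhantomError("pixel_size_mm must be > 0")

    @property
    def grid_n(self) -> int:
        return self.values.shape[0]

    @property
    def fov_mm(self) -> float:
        return self.grid_n * self.pixel_size_mm

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) mm coordinates of every pixel centre, shape (n, n)."""
        return pixel_center_grid(self.grid_n, self.fov_mm)


def pixel_center_grid(grid_n: int, fov_mm: float) -> tuple[np.ndarray, np.ndarray]:
    p = fov_mm / grid_n
    idx = np.arange(grid_n)
    x = (idx - (grid_n - 1) / 2.0) * p
    y = ((grid_n - 1) / 2.0 - idx) * p
    xx, yy = np.meshgrid(x, y)
    return xx, yy


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> AttenuationImage:
    """Rasterize a phantom spec onto its grid.

    Deterministic for a fixed spec; ``seed`` only matters for specs built
    by :func:`random_phantom_spec` (randomness lives in spec construction,
    so rasterization itself never consumes the seed).  Overlapping deltas
    accumulate; the result is clipped at zero.
    """
    xx, yy = pixel_center_grid(spec.grid_n, spec.fov_mm)
    img = np.full((spec.grid_n, spec.grid_n), spec.background_mu, dtype=np.float64)
    for e in spec.ellipses:
        img[e.contains(xx, yy)] += e.delta_mu
    np.clip(img, 0.0, None, out=img)
    return AttenuationImage(img, spec.fov_mm / spec.grid_n)


# ----------------------------------------------------------------------
# named catalog — stable test anchors
# ----------------------------------------------------------------------

def uniform_disk(grid_n: int = 256, fov_mm: float = 200.0,
                 radius_mm: float = 50.0, mu: float = MU_WATER) -> PhantomSpec:
    """Centred disk of uniform attenuation on a zero background."""
    return PhantomSpec(
        grid_n=grid_n, fov_mm=fov_mm,
        ellipses=(Ellipse(0.0, 0.0, radius_mm, radius_mm, 0.0, mu),),
    )


def two_disk_pair(grid_n: int = 256, fov_mm: float = 200.0) -> PhantomSpec:
    """Water body with a hyper- and a hypodense insert (contrast pair)."""
    return PhantomSpec(
        grid_n=grid_n, fov_mm=fov_mm,
        ellipses=(
            Ellipse(0.0, 0.0, 80.0, 80.0, 0.0, MU_WATER),
            Ellipse(-30.0, 0.0, 15.0, 15.0, 0.0, +0.008),
            Ellipse(30.0, 0.0, 15.0, 15.0, 0.0, -0.008),
        ),
    )


def shepp_logan_like(grid_n: int = 256, fov_mm: float = 200.0) -> PhantomSpec:
    """Head-like ellipse set: skull shell, brain, ventricles, small lesions.

    Inspired by the classic head phantom but parameterized in mm and in
    attenuation deltas rather than display intensities.
    """
    return PhantomSpec(
        grid_n=grid_n, fov_mm=fov_mm,
        ellipses=(
            Ellipse(0.0, 0.0, 69.0, 92.0, 0.0, 0.040),      # skull
            Ellipse(0.0, -1.8, 66.2, 87.4, 0.0, -0.020),    # brain interior
            Ellipse(22.0, 0.0, 11.0, 31.0, -18.0, -0.004),  # right ventricle
            Ellipse(-22.0, 0.0, 16.0, 41.0, 18.0, -0.004),  # left ventricle
            Ellipse(0.0, 35.0, 21.0, 25.0, 0.0, 0.002),
            Ellipse(0.0, 10.0, 4.6, 4.6, 0.0, 0.002),
            Ellipse(0.0, -10.0, 4.6, 4.6, 0.0, 0.002),
            Ellipse(-8.0, -60.5, 4.6, 2.3, 0.0, 0.002),
            Ellipse(0.0, -60.5, 2.3, 2.3, 0.0, 0.002),
            Ellipse(6.0, -60.5, 2.3, 4.6, 0.0, 0.002),
        ),
    )


def random_phantom_spec(rng: np.random.Generator, grid_n: int = 256,
                        fov_mm: float = 200.0) -> PhantomSpec:
    """Draw a random abdomen-like phantom.

    An elliptical soft-tissue body nearly filling the field of view
    (patients are scanned with a tight FOV), a few low-contrast internal
    structures, a vertebra-like dense insert in the posterior half, and
    up to two further bone-like disks.  The long attenuation paths
    through body and bone give realistically photon-starved rays at the
    low-dose blank-scan levels, which is what makes the reconstructed
    low-dose images noisy and streaky.  Used to build training/testing
    image sets.
    """
    half = fov_mm / 2.0
    body_a = rng.uniform(0.85, 0.98) * half
    body_b = rng.uniform(0.80, 0.95) * half
    body_angle = rng.uniform(0.0, 180.0)
    ellipses = [Ellipse(0.0, 0.0, body_a, body_b, body_angle, 0.022)]
    n_soft = rng.integers(2, 6)
    for _ in range(n_soft):
        a = rng.uniform(0.06, 0.30) * half
        b = rng.uniform(0.06, 0.30) * half
        r = rng.uniform(0.0, 0.50) * min(body_a, body_b)
        t = rng.uniform(0.0, 2 * np.pi)
        delta = rng.uniform(0.002, 0.008) * rng.choice([-1.0, 1.0])
        ellipses.append(
            Ellipse(r * np.cos(t), r * np.sin(t), a, b,
                    rng.uniform(0.0, 180.0), delta)
        )
    ellipses.append(  # vertebral body
        Ellipse(rng.uniform(-10.0, 10.0), rng.uniform(-0.55, -0.35) * fov_mm / 2,
                rng.uniform(12.0, 18.0), rng.uniform(12.0, 18.0), 0.0, 0.05)
    )
    for _ in range(rng.integers(0, 3)):
        a = rng.uniform(0.04, 0.09) * half
        r = rng.uniform(0.40, 0.75) * min(body_a, body_b)
        t = rng.uniform(0.0, 2 * np.pi)
        ellipses.append(
            Ellipse(r * np.cos(t), r * np.sin(t), a, a, 0.0, +0.040)
        )
    return PhantomSpec(grid_n=grid_n, fov_mm=fov_mm, ellipses=tuple(ellipses))
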