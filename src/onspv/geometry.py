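"""Reference frames and geometric primitives shared across the model.

Three spaces are used throughout:

* **visual field** — polar coordinates (rho in degrees of visual angle,
  theta in radians) centered on the fixation point;
* **retina** — polar coordinates (rho in mm, theta in radians) centered on
  the fovea; the model is built for the left eye, with +x pointing nasally
  and +y superiorly (a right eye mirrors x);
* **optic-nerve cross-section** — polar coordinates (rho in mm, theta in
  radians) centered on the nerve axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NerveGeometry",
    "RetinaGeometry",
    "SceneGeometry",
    "DiscEllipse",
    "polar_to_xy",
    "xy_to_polar",
]


def polar_to_xy(rho, theta):
    """Convert polar coordinates to Cartesian (vectorized)."""
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return rho * np.cos(theta), rho * np.sin(theta)


def xy_to_polar(x, y):
    """Convert Cartesian coordinates to polar with theta in [0, 2*pi)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.hypot(x, y), np.mod(np.arctan2(y, x), 2.0 * np.pi)


@dataclass(frozen=True)
class NerveGeometry:
    """Circular optic-nerve cross-section centered at the origin.

    Parameters
    ----------
    radius_mm : float
        Radius of the nerve section (default 2.5 mm).
    eye_side : str
        ``"left"`` (reference frame of the model) or ``"right"`` (mirrored x).
    """

    radius_mm: float = 2.5
    eye_side: str = "left"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("nerve radius must be positive")
        if self.eye_side not in ("left", "right"):
            raise ValueError("eye_side must be 'left' or 'right'")


@dataclass(frozen=True)
class DiscEllipse:
    """Optic-disc ellipse in the retinal plane (mm), void of RGC somas."""

    center_x_mm: float = 4.0   # nasal of the fovea (left eye: +x)
    center_y_mm: float = 0.0
    axis_vertical_mm: float = 1.77
    axis_horizontal_mm: float = 1.88

    @property
    def semi_x(self) -> float:
        return 0.5 * self.axis_horizontal_mm

    @property
    def semi_y(self) -> float:
        return 0.5 * self.axis_vertical_mm

    def contains(self, x, y, margin: float = 0.0):
        """Points strictly inside the ellipse grown by ``margin`` mm."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        u = (x - self.center_x_mm) / (self.semi_x + margin)
        v = (y - self.center_y_mm) / (self.semi_y + margin)
        return u * u + v * v < 1.0

    def ray_crossings(self, theta: float):
        """Radii at which the ray at angle ``theta`` crosses the ellipse.

        Returns ``None`` when the ray misses the ellipse, else ``(r0, r1)``
        with ``0 <= r0 < r1`` delimiting the interior segment.
        """
        c, s = np.cos(theta), np.sin(theta)
        a, b = self.semi_x, self.semi_y
        # ((r c - cx)/a)^2 + ((r s - cy)/b)^2 = 1
        A = (c / a) ** 2 + (s / b) ** 2
        B = -2.0 * (c * self.center_x_mm / a**2 + s * self.center_y_mm / b**2)
        C = (self.center_x_mm / a) ** 2 + (self.center_y_mm / b) ** 2 - 1.0
        disc = B * B - 4.0 * A * C
        if disc <= 0:
            return None
        sq = np.sqrt(disc)
        r0 = (-B - sq) / (2 * A)
        r1 = (-B + sq) / (2 * A)
        if r1 <= 0:
            return None
        return max(r0, 0.0), r1


@dataclass(frozen=True)
class RetinaGeometry:
    """Retinal disc of maximum modeled eccentricity with the optic-disc void.

    ``max_eccentricity_mm`` (R_RET) defaults to 21 mm, the extent of the
    packaged density profiles; it is a modeling choice, not a measurement.
    """

    max_eccentricity_mm: float = 21.0
    disc: DiscEllipse = field(default_factory=DiscEllipse)
    mm_per_degree: float = 0.29  # retinal magnification used to map mm <-> deg

    def __post_init__(self):
        if self.max_eccentricity_mm <= 0:
            raise ValueError("max eccentricity must be positive")
        if self.mm_per_degree <= 0:
            raise ValueError("mm_per_degree must be positive")
        # disc ellipse must sit fully inside the modeled retina
        reach = np.hypot(self.disc.center_x_mm, self.disc.center_y_mm)
        reach += max(self.disc.semi_x, self.disc.semi_y)
        if reach >= self.max_eccentricity_mm:
            raise ValueError("optic-disc ellipse extends beyond the modeled retina")

    def mm_to_deg(self, rho_mm):
        return np.asarray(rho_mm, dtype=float) / self.mm_per_degree

    def deg_to_mm(self, rho_deg):
        return np.asarray(rho_deg, dtype=float) * self.mm_per_degree


@dataclass(frozen=True)
class SceneGeometry:
    """Raster geometry of a scene or percept.

    The visual-field center maps to the raster center and the degree-to-pixel
    mapping is linear per axis (planar screen, small-angle approximation).
    """

    width: int = 640
    height: int = 480
    fov_x_deg: float = 90.0
    fov_y_deg: float = 65.0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("raster dimensions must be positive")
        if self.fov_x_deg <= 0 or self.fov_y_deg <= 0:
            raise ValueError("fields of view must be positive")

    @property
    def px_per_deg_x(self) -> float:
        return self.width / self.fov_x_deg

    @property
    def px_per_deg_y(self) -> float:
        return self.height / self.fov_y_deg

    def deg_to_px(self, x_deg, y_deg):
        """Visual-field degrees -> raster pixel coordinates (col, row).

        +x degrees to the right, +y degrees upward; row index grows downward.
        """
        col = (np.asarray(x_deg, dtype=float) + self.fov_x_deg / 2) * self.px_per_deg_x - 0.5
        row = (self.fov_y_deg / 2 - np.asarray(y_deg, dtype=float)) * self.px_per_deg_y - 0.5
        return col, row
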