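"""Image <-> firing-rate conversion through Gaussian receptive-field images.

Each RGC owns a receptive-field (RF) image: a bivariate Gaussian centered at
its visual-field position with standard deviation equal to its RF radius.
Encoding a scene multiplies it pixel-wise with each RF image and sums,
yielding one firing rate per cell; the Gaussian is scaled so a uniformly
white scene drives a cell whose RF lies inside the field of view at exactly
``fr_max`` (default 300 Hz, the ceiling of the biophysical fiber model).
Percept reconstruction is the adjoint operation: a linear combination of RF
images weighted by firing rates, normalized by the RF coverage of the
living population so that full-rate patterns render white.

The model is deliberately linear and static: no center-surround antagonism,
no output nonlinearity, no temporal dynamics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import SceneGeometry
from .rgc_population import RGCPopulation

__all__ = [
    "VisualScene",
    "Percept",
    "FiringPattern",
    "ReceptiveFieldImage",
    "make_rf_image",
    "RFStack",
    "build_rf_stack",
    "encode",
    "reconstruct",
]

TRUNCATE_SIGMA = 4.0  # Gaussian support cut; the discarded mass is < 4e-4


@dataclass
class VisualScene:
    """Grayscale raster in [0, 1] with its field-of-view geometry."""

    data: np.ndarray
    geometry: SceneGeometry = field(default_factory=SceneGeometry)

    def __post_init__(self):
        self.data = np.clip(np.asarray(self.data, dtype=float), 0.0, 1.0)
        if self.data.shape != (self.geometry.height, self.geometry.width):
            raise ValueError("raster shape does not match geometry")

    @classmethod
    def uniform(cls, level: float, geometry: SceneGeometry | None = None) -> "VisualScene":
        geometry = geometry or SceneGeometry()
        return cls(np.full((geometry.height, geometry.width), level), geometry)

    def to_png(self, path: str | Path) -> None:
        path = Path(path)
        img = Image.fromarray(np.round(self.data * 255).astype(np.uint8), mode="L")
        img.save(path)
        sidecar = {
            "width": self.geometry.width,
            "height": self.geometry.height,
            "fov_x_deg": self.geometry.fov_x_deg,
            "fov_y_deg": self.geometry.fov_y_deg,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_png(cls, path: str | Path) -> "VisualScene":
        path = Path(path)
        data = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            sc = json.loads(sidecar.read_text())
            geometry = SceneGeometry(
                width=sc["width"], height=sc["height"],
                fov_x_deg=sc["fov_x_deg"], fov_y_deg=sc["fov_y_deg"],
            )
        else:
            geometry = SceneGeometry(width=data.shape[1], height=data.shape[0])
        return cls(data, geometry)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.data, delimiter=",")

    @classmethod
    def from_csv(cls, path: str | Path, geometry: SceneGeometry | None = None) -> "VisualScene":
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        if geometry is None:
            geometry = SceneGeometry(width=data.shape[1], height=data.shape[0])
        return cls(data, geometry)


class Percept(VisualScene):
    """Reconstructed perception raster; carries normalization metadata."""

    def __init__(self, data, geometry=None, meta: dict | None = None):
        super().__init__(data, geometry or SceneGeometry())
        self.meta = meta or {}


@dataclass
class FiringPattern:
    """Per-cell firing rates (Hz), ids implicit by array index."""

    rates: np.ndarray
    fr_max: float = 300.0

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("firing rates must be non-negative")


@dataclass
class ReceptiveFieldImage:
    """Dense RF weight raster for a single cell (mainly for inspection)."""

    weights: np.ndarray
    center_deg: tuple[float, float]
    sigma_deg: float
    scale: float  # Hz per unit Gaussian mass


class RFStack:
    """Sparse per-cell Gaussian windows for fast encode/reconstruct.

    For cell i the stack stores the raster window intersecting the image and
    the Gaussian weights on it, pre-multiplied so that
    ``sum(full window weights) = fr_max`` (full = untruncated by the FOV).
    """

    def __init__(self, geometry: SceneGeometry, fr_max: float):
        self.geometry = geometry
        self.fr_max = fr_max
        self.windows: list[tuple[int, int, int, int] | None] = []
        self.weights: list[np.ndarray | None] = []

    @property
    def n(self) -> int:
        return len(self.windows)

    def add(self, window, weights) -> None:
        self.windows.append(window)
        self.weights.append(weights)

    def encode(self, scene: np.ndarray) -> np.ndarray:
        rates = np.zeros(self.n)
        for i, (win, w) in enumerate(zip(self.windows, self.weights)):
            if win is None:
                continue
            r0, r1, c0, c1 = win
            rates[i] = float(np.sum(scene[r0:r1, c0:c1] * w))
        return rates

    def accumulate(self, coeffs: np.ndarray, out: np.ndarray) -> None:
        for i, (win, w) in enumerate(zip(self.windows, self.weights)):
            if win is None or coeffs[i] == 0.0:
                continue
            r0, r1, c0, c1 = win
            out[r0:r1, c0:c1] += coeffs[i] * w

    def coverage(self, alive: np.ndarray) -> np.ndarray:
        cov = np.zeros((self.geometry.height, self.geometry.width))
        self.accumulate(np.where(alive, self.fr_max, 0.0), cov)
        return cov


def _gaussian_window(geometry: SceneGeometry, x_deg, y_deg, sigma_deg, fr_max):
    """Window bounds and scaled weights for one cell; None if off-raster."""
    cx, cy = geometry.deg_to_px(x_deg, y_deg)
    sx = sigma_deg * geometry.px_per_deg_x
    sy = sigma_deg * geometry.px_per_deg_y
    if min(sx, sy) < 0.5:
        warnings.warn("receptive field below half a pixel; clamped")
        sx, sy = max(sx, 0.5), max(sy, 0.5)
    hx = int(np.ceil(TRUNCATE_SIGMA * sx))
    hy = int(np.ceil(TRUNCATE_SIGMA * sy))
    # full (possibly off-raster) window used for calibration
    c0f, c1f = int(np.floor(cx)) - hx, int(np.floor(cx)) + hx + 1
    r0f, r1f = int(np.floor(cy)) - hy, int(np.floor(cy)) + hy + 1
    cols = np.arange(c0f, c1f)
    rows = np.arange(r0f, r1f)
    gx = np.exp(-0.5 * ((cols - cx) / sx) ** 2)
    gy = np.exp(-0.5 * ((rows - cy) / sy) ** 2)
    full = np.outer(gy, gx)
    norm = full.sum()
    if norm <= 0:
        return None, None
    scale = fr_max / norm
    r0, r1 = max(r0f, 0), min(r1f, geometry.height)
    c0, c1 = max(c0f, 0), min(c1f, geometry.width)
    if r0 >= r1 or c0 >= c1:
        return None, None
    w = full[r0 - r0f : r1 - r0f, c0 - c0f : c1 - c0f] * scale
    return (r0, r1, c0, c1), w


def make_rf_image(
    x_deg: float,
    y_deg: float,
    sigma_deg: float,
    geometry: SceneGeometry,
    fr_max: float = 300.0,
) -> ReceptiveFieldImage:
    """Dense RF image of a single cell on the full raster.

    Calibrated against the untruncated Gaussian mass, so weights of a cell
    whose RF lies inside the FOV sum to ``fr_max``; a cell outside the FOV
    gets an all-zero raster.
    """
    win, w = _gaussian_window(geometry, x_deg, y_deg, sigma_deg, fr_max)
    weights = np.zeros((geometry.height, geometry.width))
    scale = fr_max
    if win is not None:
        r0, r1, c0, c1 = win
        weights[r0:r1, c0:c1] = w
    return ReceptiveFieldImage(
        weights=weights, center_deg=(x_deg, y_deg), sigma_deg=sigma_deg, scale=scale
    )


def build_rf_stack(
    pop: RGCPopulation, geometry: SceneGeometry | None = None, fr_max: float = 300.0
) -> RFStack:
    """Build the sparse RF windows for every cell of the population."""
    geometry = geometry or SceneGeometry()
    stack = RFStack(geometry, fr_max)
    xy = pop.rf_xy_deg()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-cell sub-pixel clamp is routine at scale
        for i in range(pop.n):
            win, w = _gaussian_window(geometry, xy[i, 0], xy[i, 1], pop.sigma_rf_deg[i], fr_max)
            stack.add(win, w)
    return stack


def encode(
    scene: VisualScene, pop: RGCPopulation, stack: RFStack | None = None
) -> FiringPattern:
    """Firing rates FR_i = sum_pixels scene * RF_i (linear in the scene)."""
    if stack is None:
        stack = build_rf_stack(pop, scene.geometry)
    if stack.n != pop.n:
        raise ValueError("RF stack does not match population size")
    if (scene.geometry.height, scene.geometry.width) != (
        stack.geometry.height,
        stack.geometry.width,
    ):
        raise ValueError("scene geometry does not match RF stack")
    return FiringPattern(rates=stack.encode(scene.data), fr_max=stack.fr_max)


def reconstruct(
    fr: FiringPattern,
    pop: RGCPopulation,
    geometry: SceneGeometry | None = None,
    stack: RFStack | None = None,
    coverage_floor: float = 1e-6,
) -> Percept:
    """Percept proportional to sum_i FR_i * RF_i over living cells.

    Normalization divides by the pixelwise RF coverage of the living
    population at full rate, so an all-max pattern renders white wherever
    coverage is non-negligible; pixels with coverage below
    ``coverage_floor * max coverage`` are rendered black.
    """
    if fr.rates.size != pop.n:
        raise ValueError("firing pattern does not match population size")
    if fr.rates.size == 0:
        raise ValueError("empty firing pattern")
    geometry = geometry or SceneGeometry()
    if stack is None:
        stack = build_rf_stack(pop, geometry, fr.fr_max)
    num = np.zeros((geometry.height, geometry.width))
    stack.accumulate(np.where(pop.alive, fr.rates, 0.0), num)
    cov = stack.coverage(pop.alive)
    floor = coverage_floor * cov.max() if cov.max() > 0 else np.inf
    data = np.where(cov >= floor, num / np.maximum(cov, 1e-300), 0.0)
    return Percept(
        np.clip(data, 0.0, 1.0),
        geometry,
        meta={"coverage_floor": coverage_floor, "fr_max": fr.fr_max},
    )
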