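"""Simplified visual stimuli: depth-coded instance scenes and moving blocks.

Real acquisition pipelines segment an RGB-D capture into per-object masks
and assign each instance a gray level coding its distance (near = white,
far = black). This module implements that depth-to-gray coding for
externally supplied masks and, for self-contained experiments, synthesizes
instance scenes (rectangles and ellipses at distinct depths and sizes) and
dynamic scenes (gray blocks translating horizontally), together with the
ground truth needed for task scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import VisualScene
from .geometry import SceneGeometry

__all__ = [
    "DepthGrayMap",
    "InstanceScene",
    "DynamicScene",
    "depth_to_gray",
    "colorize_instances",
    "generate_static_fixture",
    "generate_dynamic_fixture",
]

_SETTING_RANGES = {"table": (0.3, 1.5), "indoor": (0.5, 5.0), "outdoor": (1.5, 16.0)}
_SETTING_LABELS = {
    "table": ["cup", "bottle", "plate"],
    "indoor": ["chair", "lamp", "bin"],
    "outdoor": ["car", "tree", "bench"],
}


@dataclass(frozen=True)
class DepthGrayMap:
    """Depth (m) to gray level [0, 1] coding for a viewing setting.

    ``table`` and ``indoor`` use the linear law
    I = (d_min - d)/(d_max - d_min) + 1; ``outdoor`` the quadratic law
    I = a d^2 + b with a = 1/(d_min^2 - d_max^2), b = -d_max^2 a / ...
    chosen so that both laws give I(d_min) = 1 and I(d_max) = 0. Values are
    clipped to [0, 1] outside the range.
    """

    setting: str = "table"
    d_min: float | None = None
    d_max: float | None = None

    def __post_init__(self):
        if self.setting not in _SETTING_RANGES:
            raise ValueError(f"unknown setting {self.setting!r}")
        lo, hi = _SETTING_RANGES[self.setting]
        object.__setattr__(self, "d_min", self.d_min if self.d_min is not None else lo)
        object.__setattr__(self, "d_max", self.d_max if self.d_max is not None else hi)
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be below d_max")

    def gray(self, d) -> np.ndarray:
        return depth_to_gray(d, self)


def depth_to_gray(d, dg_map: DepthGrayMap) -> np.ndarray:
    """Gray level of an instance at depth ``d`` meters."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("depth must be positive")
    lo, hi = dg_map.d_min, dg_map.d_max
    if dg_map.setting == "outdoor":
        a = 1.0 / (lo**2 - hi**2)
        b = -(hi**2) / (lo**2 - hi**2)
        gray = a * d**2 + b
    else:
        gray = (lo - d) / (hi - lo) + 1.0
    return np.clip(gray, 0.0, 1.0)


@dataclass
class InstanceScene:
    """Per-instance binary masks and mean depths on a black background."""

    masks: np.ndarray  # (k, H, W) bool
    depths_m: np.ndarray  # (k,)
    geometry: SceneGeometry = field(default_factory=SceneGeometry)

    def __post_init__(self):
        self.masks = np.asarray(self.masks, dtype=bool)
        self.depths_m = np.atleast_1d(np.asarray(self.depths_m, dtype=float))
        if self.masks.ndim != 3:
            self.masks = self.masks.reshape((0, self.geometry.height, self.geometry.width))
        if self.masks.shape[0] != self.depths_m.size:
            raise ValueError("one depth per mask required")
        if self.masks.shape[1:] != (self.geometry.height, self.geometry.width):
            raise ValueError("mask shape does not match geometry")
        if np.any(self.depths_m <= 0):
            raise ValueError("depths must be positive")

    @property
    def n_instances(self) -> int:
        return self.masks.shape[0]


def colorize_instances(scene: InstanceScene, dg_map: DepthGrayMap) -> VisualScene:
    """Paint each mask with its depth-coded gray; nearer instances on top."""
    canvas = np.zeros((scene.geometry.height, scene.geometry.width))
    order = np.argsort(scene.depths_m)[::-1]  # far first, near painted last
    for k in order:
        canvas[scene.masks[k]] = depth_to_gray(scene.depths_m[k], dg_map)
    return VisualScene(canvas, scene.geometry)


def _distinct_uniform(rng, lo, hi, n, min_sep_frac=0.05):
    """n values in (lo, hi), pairwise separated by a fraction of the range."""
    sep = (hi - lo) * min_sep_frac
    vals: list[float] = []
    while len(vals) < n:
        v = rng.uniform(lo + sep, hi - sep)
        if all(abs(v - u) > sep for u in vals):
            vals.append(v)
    return np.array(vals)


def generate_static_fixture(
    n_objects: int,
    setting: str = "table",
    seed: int = 0,
    geometry: SceneGeometry | None = None,
) -> tuple[InstanceScene, dict]:
    """Synthetic instance scene with recorded ground truth.

    Objects are axis-aligned rectangles or ellipses with pairwise-distinct
    depths (drawn inside the setting's range) and distinct pixel areas. The
    ground truth carries the object count, the distance ordering (indices
    by increasing depth), the size ordering (by decreasing area) and a label
    per object, as needed by the task-scoring module.
    """
    if n_objects < 0:
        raise ValueError("n_objects must be >= 0")
    geometry = geometry or SceneGeometry()
    rng = np.random.default_rng(seed)
    H, W = geometry.height, geometry.width
    dg = DepthGrayMap(setting=setting)
    depths = _distinct_uniform(rng, dg.d_min, dg.d_max, n_objects)
    masks = np.zeros((n_objects, H, W), dtype=bool)
    labels = []
    areas = np.zeros(n_objects)
    for k in range(n_objects):
        for _ in range(100):
            h = int(rng.uniform(0.10, 0.35) * H)
            w = int(rng.uniform(0.10, 0.35) * W)
            r0 = int(rng.uniform(0, H - h))
            c0 = int(rng.uniform(0, W - w))
            mask = np.zeros((H, W), dtype=bool)
            if rng.random() < 0.5:
                mask[r0 : r0 + h, c0 : c0 + w] = True
            else:
                rr, cc = np.mgrid[0:H, 0:W]
                cy, cx = r0 + h / 2, c0 + w / 2
                mask[((rr - cy) / (h / 2)) ** 2 + ((cc - cx) / (w / 2)) ** 2 <= 1.0] = True
            area = mask.sum()
            if all(abs(area - a) > 0.02 * H * W for a in areas[:k]):
                masks[k] = mask
                areas[k] = area
                break
        labels.append(_SETTING_LABELS[setting][int(rng.integers(3))])
    scene = InstanceScene(masks=masks, depths_m=depths, geometry=geometry)
    truth = {
        "count": n_objects,
        "distance_order": np.argsort(depths).tolist(),  # nearest first
        "size_order": np.argsort(-areas).tolist(),      # largest first
        "labels": labels,
        "setting": setting,
        "seed": seed,
    }
    return scene, truth


@dataclass
class DynamicScene:
    """Frame sequence of gray blocks translating horizontally."""

    frames: np.ndarray  # (T, H, W)
    geometry: SceneGeometry
    fps: float
    truth: dict

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def scene(self, t: int) -> VisualScene:
        return VisualScene(self.frames[t], self.geometry)


def generate_dynamic_fixture(
    n_blocks: int,
    seed: int = 0,
    geometry: SceneGeometry | None = None,
    duration_s: float = 3.0,
    fps: float = 30.0,
) -> DynamicScene:
    """Moving-block video: blocks of distinct sizes, grays and velocities.

    Each block travels horizontally at constant speed and is guaranteed to
    be visible in at least one frame (start positions are drawn so the
    trajectory crosses the raster during the clip).
    """
    if n_blocks < 0:
        raise ValueError("n_blocks must be >= 0")
    geometry = geometry or SceneGeometry()
    rng = np.random.default_rng(seed)
    H, W = geometry.height, geometry.width
    n_frames = int(round(duration_s * fps))
    frames = np.zeros((n_frames, H, W))
    blocks = []
    for k in range(n_blocks):
        h = int(rng.uniform(0.10, 0.30) * H)
        w = int(rng.uniform(0.10, 0.30) * W)
        gray = rng.uniform(0.3, 1.0)
        speed = rng.uniform(0.5, 2.0) * W / n_frames  # px per frame
        direction = 1 if rng.random() < 0.5 else -1
        row = int(rng.uniform(0, H - h))
        # anchor the trajectory on-screen at a random frame: guarantees the
        # block is fully visible at least once during the clip
        t_anchor = int(rng.integers(n_frames))
        x_anchor = rng.uniform(0, W - w)
        x0 = x_anchor - speed * direction * t_anchor
        blocks.append((h, w, gray, speed * direction, row, x0))
    for t in range(n_frames):
        for h, w, gray, v, row, x0 in blocks:
            x = int(round(x0 + v * t))
            c0, c1 = max(x, 0), min(x + w, W)
            if c0 < c1:
                frames[t, row : row + h, c0:c1] = np.maximum(
                    frames[t, row : row + h, c0:c1], gray
                )
    seen = set()
    for t in range(n_frames):
        for k, (h, w, gray, v, row, x0) in enumerate(blocks):
            x = int(round(x0 + v * t))
            if max(x, 0) < min(x + w, W):
                seen.add(k)
    truth = {"count": n_blocks, "visible_blocks": len(seen), "seed": seed}
    return DynamicScene(frames=np.clip(frames, 0, 1), geometry=geometry, fps=fps, truth=truth)
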