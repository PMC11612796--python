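"""Electrode grids, fiber-to-cell assignment and the partition stimulation rule.

An electrode array is abstracted as a tiling of rectangular cells with one
stimulation site at each cell center. Optic-nerve arrays tile the square
circumscribed to the nerve cross-section; the retinal (epiretinal) array is
a 6x10 rectangular tiling with the device's inter-electrode spacing. The
best-elicitable stimulation pattern follows the geometric partition rule:
within each cell, all fibers receive the cell's maximum natural firing rate
when at least a threshold fraction (default 30%) of them are active, and
zero otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import FiringPattern, Percept, RFStack, VisualScene, encode, reconstruct
from .geometry import NerveGeometry
from .rgc_population import RGCPopulation

__all__ = [
    "ElectrodeGrid",
    "StimRule",
    "make_regular_grid",
    "make_reduced_grid",
    "make_argus_grid",
    "assign",
    "apply_partition_rule",
    "best_perception",
]


@dataclass
class ElectrodeGrid:
    """Set of rectangular cells with a site at each center.

    ``rects`` holds (x0, y0, x1, y1) per site in mm; membership is half-open
    ([x0, x1) x [y0, y1)) so that every point belongs to at most one cell.
    """

    space: str  # "nerve" or "retina"
    centers: np.ndarray  # (n, 2) mm
    rects: np.ndarray    # (n, 4) mm
    active: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.space not in ("nerve", "retina"):
            raise ValueError("space must be 'nerve' or 'retina'")
        self.centers = np.asarray(self.centers, dtype=float)
        self.rects = np.asarray(self.rects, dtype=float)
        if self.active is None:
            self.active = np.ones(len(self.centers), dtype=bool)
        self.active = np.asarray(self.active, dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.centers)

    def with_active(self, active: np.ndarray) -> "ElectrodeGrid":
        return ElectrodeGrid(self.space, self.centers.copy(), self.rects.copy(), np.asarray(active, bool))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "space": self.space,
                    "centers": self.centers.tolist(),
                    "rects": self.rects.tolist(),
                    "active": self.active.astype(int).tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ElectrodeGrid":
        d = json.loads(Path(path).read_text())
        return cls(
            d["space"],
            np.array(d["centers"], float),
            np.array(d["rects"], float),
            np.array(d["active"], bool),
        )


@dataclass(frozen=True)
class StimRule:
    """Partition rule parameters: activity threshold over fibers with FR > 0."""

    activity_threshold: float = 0.30

    def __post_init__(self):
        if not (0.0 < self.activity_threshold <= 1.0):
            raise ValueError("activity_threshold must be in (0, 1]")


def _tile(x0: float, y0: float, nx: int, ny: int, side: float, space: str) -> ElectrodeGrid:
    rects, centers = [], []
    for iy in range(ny):
        for ix in range(nx):
            rx0, ry0 = x0 + ix * side, y0 + iy * side
            rects.append((rx0, ry0, rx0 + side, ry0 + side))
            centers.append((rx0 + side / 2, ry0 + side / 2))
    return ElectrodeGrid(space, np.array(centers), np.array(rects))


def make_regular_grid(n_side: int, geometry: NerveGeometry | None = None) -> ElectrodeGrid:
    """n x n equal cells tiling the square circumscribed to the nerve section."""
    if n_side < 1:
        raise ValueError("n_side must be >= 1")
    geometry = geometry or NerveGeometry()
    R = geometry.radius_mm
    side = 2.0 * R / n_side
    return _tile(-R, -R, n_side, n_side, side, "nerve")


def make_reduced_grid(geometry: NerveGeometry | None = None) -> ElectrodeGrid:
    """14x14 nerve grid with its central 8x8 block merged into 4x4 big cells.

    Merging 2x2 sub-grids of the 14x14 tiling into single sites exploits the
    foveal magnification at the nerve center: 196 - 64 + 16 = 148 sites.
    """
    geometry = geometry or NerveGeometry()
    base = make_regular_grid(14, geometry)
    R = geometry.radius_mm
    side = 2.0 * R / 14
    lo, hi = 3, 11  # central 8x8 block: row/col indices 3..10
    rects, centers = [], []
    for i in range(196):
        iy, ix = divmod(i, 14)
        if lo <= ix < hi and lo <= iy < hi:
            continue
        rects.append(base.rects[i])
        centers.append(base.centers[i])
    for by in range(4):
        for bx in range(4):
            x0 = -R + (lo + 2 * bx) * side
            y0 = -R + (lo + 2 * by) * side
            rects.append((x0, y0, x0 + 2 * side, y0 + 2 * side))
            centers.append((x0 + side, y0 + side))
    return ElectrodeGrid("nerve", np.array(centers), np.array(rects))


def make_argus_grid(
    spacing_mm: float = 0.525,
    rows: int = 6,
    cols: int = 10,
    center_offset_mm: tuple[float, float] = (0.0, 0.0),
) -> ElectrodeGrid:
    """Epiretinal 6x10 rectangular array with device-like spacing.

    The cell side equals the inter-electrode distance; the default 0.525 mm
    comes from device literature and is configurable.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    ox, oy = center_offset_mm
    x0 = ox - cols * spacing_mm / 2
    y0 = oy - rows * spacing_mm / 2
    return _tile(x0, y0, cols, rows, spacing_mm, "retina")


def assign(pop: RGCPopulation, grid: ElectrodeGrid) -> np.ndarray:
    """Cell index per record (-1 when outside every cell).

    Nerve grids partition fiber positions; retinal grids partition soma
    positions (epiretinal abstraction, no axon-of-passage stimulation).
    """
    xy = pop.fiber_xy() if grid.space == "nerve" else pop.soma_xy()
    out = np.full(pop.n, -1, dtype=int)
    for c in range(grid.n_sites):
        x0, y0, x1, y1 = grid.rects[c]
        m = (xy[:, 0] >= x0) & (xy[:, 0] < x1) & (xy[:, 1] >= y0) & (xy[:, 1] < y1)
        out[m] = c
    return out


def cell_commands(
    natural: FiringPattern, assignment: np.ndarray, rule: StimRule, grid: ElectrodeGrid
) -> np.ndarray:
    """Per-cell stimulation command under the partition rule.

    A cell's command is the maximum natural rate among its fibers if the
    fraction of active fibers (FR > 0) reaches the threshold, else zero;
    broken (inactive) sites always command zero.
    """
    commands = np.zeros(grid.n_sites)
    for c in range(grid.n_sites):
        if not grid.active[c]:
            continue
        m = assignment == c
        if not np.any(m):
            continue
        r = natural.rates[m]
        if np.mean(r > 0) >= rule.activity_threshold:
            commands[c] = r.max()
    return commands


def apply_partition_rule(
    natural: FiringPattern,
    assignment: np.ndarray,
    rule: StimRule | None = None,
    grid: ElectrodeGrid | None = None,
) -> FiringPattern:
    """Impose the per-cell partition rule on a natural firing pattern.

    Unassigned fibers (outside every cell) are set to zero: they cannot be
    reached by any electrode.
    """
    rule = rule or StimRule()
    if grid is None:
        raise ValueError("grid is required")
    if natural.rates.size != assignment.size:
        raise ValueError("pattern and assignment sizes differ")
    commands = cell_commands(natural, assignment, rule, grid)
    rates = np.zeros_like(natural.rates)
    assigned = assignment >= 0
    rates[assigned] = commands[assignment[assigned]]
    return FiringPattern(rates=rates, fr_max=natural.fr_max)


def best_perception(
    scene: VisualScene,
    pop: RGCPopulation,
    grid: ElectrodeGrid,
    rule: StimRule | None = None,
    stack: RFStack | None = None,
) -> Percept:
    """Best elicitable percept: encode, partition-stimulate, reconstruct."""
    natural = encode(scene, pop, stack)
    assignment = assign(pop, grid)
    stimulated = apply_partition_rule(natural, assignment, rule or StimRule(), grid)
    return reconstruct(stimulated, pop, scene.geometry, stack)
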