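"""Non-ideality models: fiber shuffling, broken electrodes, fiber death.

All operators act on copies; soma and receptive-field coordinates are never
touched. Shuffles permute fiber positions only, degeneration and
encapsulation flag fibers as dead (excluded from percept reconstruction),
and broken sites silence their cells through the partition rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .electrodes import ElectrodeGrid, StimRule, assign, cell_commands
from .encoding import FiringPattern
from .geometry import NerveGeometry
from .rgc_population import RGCPopulation

__all__ = [
    "ShuffleSpec",
    "UnitGrid",
    "DegenerationScenario",
    "mean_pairwise_distance",
    "local_shuffle",
    "global_shuffle",
    "correct_global_shuffle",
    "stimulate_shuffled",
    "disable_sites",
    "encapsulation_depletion",
    "degenerate_fibers",
]


def mean_pairwise_distance(xy: np.ndarray, chunk: int = 256) -> float:
    """Exact mean Euclidean distance over all unordered pairs (chunked)."""
    n = xy.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    total = 0.0
    for a in range(0, n, chunk):
        block = xy[a : a + chunk]
        d = np.sqrt(
            (block[:, None, 0] - xy[None, :, 0]) ** 2
            + (block[:, None, 1] - xy[None, :, 1]) ** 2
        )
        total += d.sum()
    return total / (n * (n - 1))  # self-distances are zero; full double sum


@dataclass
class ShuffleSpec:
    """Local-shuffle parameters.

    ``sigma_mm`` is the Gaussian scale of the swap-partner kernel
    w_ij = exp(-d_ij^2 / (2 sigma^2)); ``n_swaps`` the number of swap
    operations. Defaults (None) follow the reference prescription:
    sigma = mean pairwise fiber distance / 5 and n_swaps = round(n / 5).
    """

    sigma_mm: float | None = None
    n_swaps: int | None = None
    seed: int = 0

    def resolved(self, pop: RGCPopulation) -> tuple[float, int]:
        sigma = self.sigma_mm
        if sigma is None:
            sigma = mean_pairwise_distance(pop.fiber_xy()) / 5.0
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        n_swaps = self.n_swaps if self.n_swaps is not None else int(round(pop.n / 5))
        if n_swaps < 0:
            raise ValueError("n_swaps must be >= 0")
        return sigma, n_swaps


def _remember_original(pop: RGCPopulation) -> np.ndarray:
    if pop.fiber_xy_original is not None:
        return pop.fiber_xy_original.copy()
    return pop.fiber_xy()


def local_shuffle(pop: RGCPopulation, spec: ShuffleSpec | None = None) -> RGCPopulation:
    """Swap fiber positions between Gaussian-near pairs.

    Each swap draws fiber i uniformly and its partner j with probability
    proportional to exp(-d_ij^2 / (2 sigma^2)); the two fibers exchange nerve
    coordinates while keeping their somas and receptive fields.
    """
    spec = spec or ShuffleSpec()
    sigma, n_swaps = spec.resolved(pop)
    rng = np.random.default_rng(spec.seed)
    original = _remember_original(pop)
    xy = pop.fiber_xy()
    perm = np.arange(pop.n)  # perm[i]: whose coordinates fiber i now holds
    inv_two_sigma2 = 1.0 / (2.0 * sigma * sigma)
    for _ in range(n_swaps):
        i = int(rng.integers(pop.n))
        d2 = (xy[:, 0] - xy[i, 0]) ** 2 + (xy[:, 1] - xy[i, 1]) ** 2
        w = np.exp(-d2 * inv_two_sigma2)
        w[i] = 0.0
        s = w.sum()
        if s <= 0:
            continue
        j = int(rng.choice(pop.n, p=w / s))
        xy[[i, j]] = xy[[j, i]]
        perm[[i, j]] = perm[[j, i]]
    out = pop.copy(
        rho_fiber_mm=pop.rho_fiber_mm[perm],
        theta_fiber=pop.theta_fiber[perm],
        fiber_xy_original=original,
    )
    out.config["local_shuffle"] = {"sigma_mm": sigma, "n_swaps": n_swaps, "seed": spec.seed}
    return out


@dataclass(frozen=True)
class UnitGrid:
    """6x6 (by default) square units tiling the square inscribed in the nerve."""

    nerve: NerveGeometry
    n_side: int = 6

    @property
    def side(self) -> float:
        return self.nerve.radius_mm * np.sqrt(2.0) / self.n_side

    @property
    def half_extent(self) -> float:
        return self.nerve.radius_mm / np.sqrt(2.0)

    @property
    def n_units(self) -> int:
        return self.n_side * self.n_side

    def centers(self) -> np.ndarray:
        lo = -self.half_extent
        c = lo + (np.arange(self.n_side) + 0.5) * self.side
        gx, gy = np.meshgrid(c, c)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def unit_of(self, xy: np.ndarray) -> np.ndarray:
        """Unit index per point; -1 outside the inscribed square."""
        lo, hi = -self.half_extent, self.half_extent
        ix = np.floor((xy[:, 0] - lo) / self.side).astype(int)
        iy = np.floor((xy[:, 1] - lo) / self.side).astype(int)
        inside = (xy[:, 0] >= lo) & (xy[:, 0] < hi) & (xy[:, 1] >= lo) & (xy[:, 1] < hi)
        ix = np.clip(ix, 0, self.n_side - 1)
        iy = np.clip(iy, 0, self.n_side - 1)
        return np.where(inside, iy * self.n_side + ix, -1)


def global_shuffle(
    pop: RGCPopulation,
    units: UnitGrid | None = None,
    seed: int = 0,
    n_swaps: int | None = None,
) -> RGCPopulation:
    """Swap whole square units of the nerve section.

    Unit pairs are drawn with the same Gaussian kernel as the local shuffle,
    on unit-center distances with sigma = mean pairwise center distance / 5;
    the number of swaps defaults to the nearest integer to n_units / 5.
    Fibers move rigidly with their unit (translation by the center
    difference), so the within-unit arrangement — and, the units being
    equal-sized, the overall uniformity — is preserved.
    """
    units = units or UnitGrid(pop.nerve)
    centers = units.centers()
    sigma = mean_pairwise_distance(centers) / 5.0
    if n_swaps is None:
        n_swaps = int(round(units.n_units / 5))
    rng = np.random.default_rng(seed)
    original = _remember_original(pop)
    xy = pop.fiber_xy()
    inv_two_sigma2 = 1.0 / (2.0 * sigma * sigma)
    for _ in range(n_swaps):
        i = int(rng.integers(units.n_units))
        d2 = ((centers - centers[i]) ** 2).sum(axis=1)
        w = np.exp(-d2 * inv_two_sigma2)
        w[i] = 0.0
        j = int(rng.choice(units.n_units, p=w / w.sum()))
        unit = units.unit_of(xy)
        mi, mj = unit == i, unit == j
        shift = centers[j] - centers[i]
        xy[mi] += shift
        xy[mj] -= shift
    moved = np.any(xy != pop.fiber_xy(), axis=1)
    rho = np.where(moved, np.hypot(xy[:, 0], xy[:, 1]), pop.rho_fiber_mm)
    theta = np.where(
        moved, np.mod(np.arctan2(xy[:, 1], xy[:, 0]), 2 * np.pi), pop.theta_fiber
    )
    out = pop.copy(rho_fiber_mm=rho, theta_fiber=theta, fiber_xy_original=original)
    out.config["global_shuffle"] = {"sigma_mm": sigma, "n_swaps": n_swaps, "seed": seed}
    return out


def correct_global_shuffle(pop: RGCPopulation, grid: ElectrodeGrid) -> np.ndarray:
    """Site remapping that partially undoes a global shuffle.

    Each site votes over the fibers it now controls: the pre-shuffle cell
    most represented among them (majority, lowest cell id on ties) is the
    RGC group this contact is actually targeting, so the site is remapped to
    deliver that cell's intended command. Without a shuffle the mapping is
    the identity; a whole-unit swap aligned with the cell tiling is undone
    exactly; in general, unit and cell boundaries do not coincide and the
    correction stays partial by construction.

    Returns ``site_map`` with ``site_map[s]`` = index of the cell whose
    intended command site ``s`` should deliver.
    """
    if pop.fiber_xy_original is None:
        return np.arange(grid.n_sites)
    current_cell = assign(pop, grid)
    ox, oy = pop.fiber_xy_original.T
    ideal = pop.copy(
        rho_fiber_mm=np.hypot(ox, oy),
        theta_fiber=np.mod(np.arctan2(oy, ox), 2 * np.pi),
    )
    original_cell = assign(ideal, grid)
    site_map = np.arange(grid.n_sites)
    for s in range(grid.n_sites):
        m = (current_cell == s) & (original_cell >= 0)
        if not np.any(m):
            continue
        counts = np.bincount(original_cell[m], minlength=grid.n_sites)
        site_map[s] = int(np.argmax(counts))  # lowest cell id on ties
    return site_map


def stimulate_shuffled(
    natural: FiringPattern,
    pop: RGCPopulation,
    grid: ElectrodeGrid,
    rule: StimRule | None = None,
    site_map: np.ndarray | None = None,
    correction: str | None = None,
) -> FiringPattern:
    """Firing pattern delivered to a shuffled population.

    The per-cell commands are designed on the idealized (pre-shuffle)
    retinotopy; each fiber then receives the command of the cell it
    physically sits in. Two corrections are available once the contacts
    targeting each RGC group have been identified:

    * ``site_map`` (from :func:`correct_global_shuffle`): each site delivers
      the command of the majority pre-shuffle cell of its current fibers;
    * ``correction="least_squares"``: each site delivers the available
      command closest to the mean intended rate of its current fibers,
      which minimizes the squared rate error a single shared command can
      achieve. This is the default corrected path: unit and cell boundaries
      rarely align, so most cells hold fibers of mixed origin and a
      plurality vote can serve the minority badly.

    Both are exact for a whole-unit swap aligned with the cell tiling and
    both remain partial in general.
    """
    rule = rule or StimRule()
    if pop.fiber_xy_original is not None:
        ox, oy = pop.fiber_xy_original.T
        ideal = pop.copy(
            rho_fiber_mm=np.hypot(ox, oy),
            theta_fiber=np.mod(np.arctan2(oy, ox), 2 * np.pi),
        )
    else:
        ideal = pop
    original_cell = assign(ideal, grid)
    commands = cell_commands(natural, original_cell, rule, grid)
    current = assign(pop, grid)
    if correction == "least_squares":
        intended = np.where(original_cell >= 0, commands[np.maximum(original_cell, 0)], 0.0)
        candidates = np.unique(np.append(commands, 0.0))
        site_cmd = commands.copy()
        for s in range(grid.n_sites):
            m = current == s
            if np.any(m):
                site_cmd[s] = candidates[np.argmin(np.abs(candidates - intended[m].mean()))]
        commands = site_cmd
    elif site_map is not None:
        commands = commands[site_map]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    rates = np.zeros_like(natural.rates)
    assigned = current >= 0
    rates[assigned] = commands[current[assigned]]
    return FiringPattern(rates=rates, fr_max=natural.fr_max)


def disable_sites(grid: ElectrodeGrid, fraction: float = 0.10, seed: int = 0) -> ElectrodeGrid:
    """Flag round(fraction * n_sites) sites inactive, chosen uniformly."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_broken = int(round(fraction * grid.n_sites))
    rng = np.random.default_rng(seed)
    broken = rng.choice(grid.n_sites, size=n_broken, replace=False)
    active = grid.active.copy()
    active[broken] = False
    return grid.with_active(active)


def encapsulation_depletion(
    pop: RGCPopulation, grid: ElectrodeGrid, radius_um: float
) -> RGCPopulation:
    """Kill fibers within ``radius_um`` of any site center (fibrotic sheath)."""
    if radius_um < 0:
        raise ValueError("radius must be non-negative")
    out = pop.copy()
    if radius_um == 0:
        return out
    xy = pop.fiber_xy() if grid.space == "nerve" else pop.soma_xy()
    r_mm = radius_um / 1000.0
    dead = np.zeros(pop.n, dtype=bool)
    for c in range(grid.n_sites):
        d = np.hypot(xy[:, 0] - grid.centers[c, 0], xy[:, 1] - grid.centers[c, 1])
        dead |= d <= r_mm
    out.dead = out.dead | dead
    return out


@dataclass(frozen=True)
class DegenerationScenario:
    """Spatial fiber-death model.

    ``uniform`` kills with constant probability k0; ``foveal`` with
    k1 / (1 + exp(rho - 0.35 R_RET)) (sigmoid favoring central somas);
    ``peripheral`` with the mirrored sigmoid. The constant is solved so the
    mean death probability over the population equals ``target_fraction``.
    """

    kind: str = "uniform"
    target_fraction: float = 0.5
    seed: int = 0
    use_rf_eccentricity: bool = False

    def __post_init__(self):
        if self.kind not in ("uniform", "foveal", "peripheral"):
            raise ValueError("kind must be uniform, foveal or peripheral")
        if not (0.0 < self.target_fraction < 1.0):
            raise ValueError("target_fraction must be in (0, 1)")

    def base_probability(self, rho: np.ndarray, r_ret: float) -> np.ndarray:
        if self.kind == "uniform":
            return np.ones_like(rho)
        mid = 0.35 * r_ret
        if self.kind == "foveal":
            return 1.0 / (1.0 + np.exp(rho - mid))
        return 1.0 / (1.0 + np.exp(mid - rho))


def _solve_scale(base: np.ndarray, target: float) -> float:
    """Monotone bisection on k so that mean(clip(k * base, 0, 1)) = target."""
    achievable = np.mean(base > 0)
    if achievable < target - 1e-12:
        raise ValueError(
            f"target fraction {target} unreachable; at most {achievable:.3f} with this profile"
        )
    lo, hi = 0.0, 1.0
    while np.mean(np.minimum(hi * base, 1.0)) < target:
        hi *= 2.0
        if hi > 1e12:
            raise FloatingPointError("degeneration scale did not bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(np.minimum(mid * base, 1.0)) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-12 * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


def degenerate_fibers(pop: RGCPopulation, scenario: DegenerationScenario) -> RGCPopulation:
    """Flag fibers dead by Bernoulli draws from the scenario's probability."""
    rho = pop.rho_rf_deg if scenario.use_rf_eccentricity else pop.rho_soma_mm
    r_ret = pop.retina.max_eccentricity_mm
    base = scenario.base_probability(np.asarray(rho, float), r_ret)
    k = _solve_scale(base, scenario.target_fraction)
    p = np.minimum(k * base, 1.0)
    rng = np.random.default_rng(scenario.seed)
    draws = rng.random(pop.n) < p
    out = pop.copy()
    out.dead = out.dead | draws
    out.config["degeneration"] = {
        "kind": scenario.kind,
        "target_fraction": scenario.target_fraction,
        "k": float(k),
        "seed": scenario.seed,
    }
    return out
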