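"""Retinotopic population of retinal ganglion cells across three spaces.

Every modeled RGC carries linked coordinates in the visual field (receptive
field center and radius), the retina (soma) and the optic-nerve cross
section (fiber). Fibers are placed from uniform seed pairs, somas by 2-D
inverse-transform sampling of the soma density, and receptive fields by the
cumulative-count displacement that accounts for the foveal displacement
zone (somas pushed eccentrically away from their receptive fields).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .density import (
    ConditionalSampler,
    DensityField,
    build_conditional_sampler,
    build_corrected_density,
    build_density_field,
)
from .geometry import NerveGeometry, RetinaGeometry, polar_to_xy, xy_to_polar

__all__ = [
    "sample_seed_pairs",
    "fibers_from_seeds",
    "somas_from_seeds",
    "CumulativeCounts",
    "displace_receptive_fields",
    "rf_radius",
    "RGCPopulation",
    "build_population",
    "check_retinotopy",
    "map_circular_patch",
]


def sample_seed_pairs(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` seed pairs (u_rho, u_theta), each uniform and strictly in (0, 1)."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((2, n))
    while np.any(u == 0.0):  # open interval; probability ~0 but guaranteed
        z = u == 0.0
        u[z] = rng.random(int(z.sum()))
    return u[0], u[1]


def fibers_from_seeds(
    u_rho: np.ndarray,
    u_theta: np.ndarray,
    geometry: NerveGeometry,
    radial_map: str = "area_uniform",
) -> tuple[np.ndarray, np.ndarray]:
    """Place fibers in the nerve section from uniform seeds.

    ``area_uniform`` (default) uses rho = R*sqrt(u), which is uniform per
    unit area of the section; ``as_printed`` uses the linear map rho = R*u.
    Both are monotone in u_rho, so radial retinotopy is preserved either way.
    """
    u_rho = np.asarray(u_rho, dtype=float)
    theta = 2.0 * np.pi * np.asarray(u_theta, dtype=float)
    if radial_map == "area_uniform":
        rho = geometry.radius_mm * np.sqrt(u_rho)
    elif radial_map == "as_printed":
        rho = geometry.radius_mm * u_rho
    else:
        raise ValueError(f"unknown radial_map {radial_map!r}")
    return rho, theta


def somas_from_seeds(
    u_rho: np.ndarray,
    u_theta: np.ndarray,
    sampler: ConditionalSampler,
    retina: RetinaGeometry | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Place somas by 2-D inverse-transform sampling of the target density."""
    rho, theta = sampler.sample(u_rho, u_theta)
    if retina is not None:
        x, y = polar_to_xy(rho, theta)
        inside = retina.disc.contains(x, y)
        if np.any(inside):  # the corrected density makes this unreachable
            raise RuntimeError(f"{int(inside.sum())} somas landed inside the optic disc")
    return rho, theta


def _mix_rows(table: np.ndarray, j: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return (1 - lam)[:, None] * table[j] + lam[:, None] * table[j + 1]


@dataclass(frozen=True)
class CumulativeCounts:
    """Paired cumulative count functions CC_soma and CC_RF per meridian.

    ``cc_soma(rho', theta)`` counts somas with the same theta and rho < rho'
    (per unit angle); ``cc_rf`` counts receptive fields. Outside the foveal
    displacement zone the two coincide; inside it, receptive-field density
    is concentrated centrally so CC_RF >= CC_soma and the displacement map
    pulls RF centers inward relative to their somas.
    """

    rho: np.ndarray               # (n_rho,), mm
    theta_ext: np.ndarray         # (n_theta + 1,), wrapped
    cc_soma: np.ndarray           # (n_theta + 1, n_rho)
    cc_rf: np.ndarray             # (n_theta + 1, n_rho)

    @classmethod
    def from_density(
        cls,
        density: DensityField,
        displacement_zone_mm: float = 4.0,
        rf_scale_mm: float = 1.2,
    ) -> "CumulativeCounts":
        """Default pair: CC_soma integrates the soma density radially; inside
        the displacement zone CC_RF integrates a centrally-peaked exponential
        RF-density profile normalized so both counts agree at the zone edge."""
        wrapped = density._wrapped() * density.rho[None, :]
        drho = np.diff(density.rho)
        cc_soma = np.zeros_like(wrapped)
        cc_soma[:, 1:] = np.cumsum(0.5 * (wrapped[:, 1:] + wrapped[:, :-1]) * drho, axis=1)
        s = rf_scale_mm
        # closed-form int_0^rho exp(-r/s) r dr
        inner = s * s * (1.0 - np.exp(-density.rho / s) * (1.0 + density.rho / s))
        dz = displacement_zone_mm
        inner_dz = s * s * (1.0 - np.exp(-dz / s) * (1.0 + dz / s))
        cdz = np.array([np.interp(dz, density.rho, row) for row in cc_soma])
        amp = cdz / inner_dz
        cc_rf = np.where(
            density.rho[None, :] <= dz, amp[:, None] * inner[None, :], cc_soma
        )
        theta_ext = np.append(density.theta, 2.0 * np.pi)
        return cls(rho=density.rho, theta_ext=theta_ext, cc_soma=cc_soma, cc_rf=cc_rf)

    @classmethod
    def from_tables(cls, rho: np.ndarray, cc_soma: np.ndarray, cc_rf: np.ndarray) -> "CumulativeCounts":
        """Meridian-independent pair from user tables (e.g. digitized data)."""
        rho = np.asarray(rho, dtype=float)
        cc_soma = np.asarray(cc_soma, dtype=float)
        cc_rf = np.asarray(cc_rf, dtype=float)
        for name, cc in (("cc_soma", cc_soma), ("cc_rf", cc_rf)):
            if cc[0] != 0 or np.any(np.diff(cc) < 0):
                raise ValueError(f"{name} must start at 0 and be non-decreasing")
        theta_ext = np.array([0.0, 2.0 * np.pi])
        return cls(
            rho=rho,
            theta_ext=theta_ext,
            cc_soma=np.vstack([cc_soma, cc_soma]),
            cc_rf=np.vstack([cc_rf, cc_rf]),
        )

    def _columns(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = np.mod(np.asarray(theta, dtype=float), 2.0 * np.pi)
        dtheta = self.theta_ext[1] - self.theta_ext[0]
        n_col = self.theta_ext.size - 1
        j = np.minimum(np.floor(theta / dtheta).astype(int), n_col - 1)
        lam = theta / dtheta - j
        return j, lam

    def soma_count_at(self, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
        j, lam = self._columns(theta)
        rows = _mix_rows(self.cc_soma, j, lam)
        return _interp_each(self.rho, rows, np.asarray(rho, dtype=float))

    def rf_count_at(self, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
        j, lam = self._columns(theta)
        rows = _mix_rows(self.cc_rf, j, lam)
        return _interp_each(self.rho, rows, np.asarray(rho, dtype=float))

    def displace(self, rho_soma: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Solve CC_RF(rho, theta) = CC_soma(rho_soma, theta) for rho.

        The root is found exactly on the piecewise-linear tabulation (the
        interpolated CC_RF is monotone non-decreasing per meridian).
        """
        rho_soma = np.asarray(rho_soma, dtype=float)
        j, lam = self._columns(theta)
        target = self.soma_count_at(rho_soma, theta)
        rows = _mix_rows(self.cc_rf, j, lam)
        if np.any(target > rows[:, -1] * (1 + 1e-12) + 1e-12):
            bad = int(np.argmax(target - rows[:, -1]))
            raise ValueError(f"no displacement root in domain for record {bad}")
        k = np.clip((rows < target[:, None]).sum(axis=1), 1, self.rho.size - 1)
        idx = np.arange(rho_soma.size)
        c0, c1 = rows[idx, k - 1], rows[idx, k]
        frac = np.where(c1 > c0, (target - c0) / np.maximum(c1 - c0, 1e-300), 0.0)
        return self.rho[k - 1] + np.clip(frac, 0.0, 1.0) * (self.rho[k] - self.rho[k - 1])


def _interp_each(x: np.ndarray, rows: np.ndarray, xq: np.ndarray) -> np.ndarray:
    xq = np.clip(xq, x[0], x[-1])
    k = np.clip(np.searchsorted(x, xq), 1, x.size - 1)
    w = (xq - x[k - 1]) / (x[k] - x[k - 1])
    idx = np.arange(rows.shape[0])
    return (1 - w) * rows[idx, k - 1] + w * rows[idx, k]


def displace_receptive_fields(
    rho_soma: np.ndarray, theta_soma: np.ndarray, cc: CumulativeCounts
) -> tuple[np.ndarray, np.ndarray]:
    """Receptive-field centers from soma positions: theta is preserved and
    rho solves the cumulative-count matching equation."""
    return cc.displace(rho_soma, theta_soma), np.asarray(theta_soma, dtype=float)


def rf_radius(
    rho_rf_deg: np.ndarray,
    slope: float = 0.01,
    intercept: float = 0.05,
    min_sigma_deg: float = 0.01,
) -> np.ndarray:
    """Receptive-field radius (deg) as a linear function of eccentricity (deg)."""
    rho_rf_deg = np.asarray(rho_rf_deg, dtype=float)
    sigma = intercept + slope * rho_rf_deg
    if np.any(sigma <= 0):
        warnings.warn("non-positive receptive-field radius clamped to minimum")
    return np.maximum(sigma, min_sigma_deg)


@dataclass
class RGCPopulation:
    """Linked per-cell coordinates in visual field, retina and nerve section.

    Record ids are implicit and dense (0..n-1, array index). ``dead`` flags
    fibers excluded from percept reconstruction. When a shuffle has been
    applied, ``fiber_xy_original`` retains the pre-shuffle fiber positions
    (used by the shuffle-correction procedure).
    """

    rho_rf_deg: np.ndarray
    theta_rf: np.ndarray
    sigma_rf_deg: np.ndarray
    rho_soma_mm: np.ndarray
    theta_soma: np.ndarray
    rho_fiber_mm: np.ndarray
    theta_fiber: np.ndarray
    dead: np.ndarray
    nerve: NerveGeometry = field(default_factory=NerveGeometry)
    retina: RetinaGeometry = field(default_factory=RetinaGeometry)
    seed: int | None = None
    config: dict = field(default_factory=dict)
    fiber_xy_original: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.rho_rf_deg.size

    @property
    def alive(self) -> np.ndarray:
        return ~self.dead

    def fiber_xy(self) -> np.ndarray:
        x, y = polar_to_xy(self.rho_fiber_mm, self.theta_fiber)
        return np.column_stack([x, y])

    def soma_xy(self) -> np.ndarray:
        x, y = polar_to_xy(self.rho_soma_mm, self.theta_soma)
        return np.column_stack([x, y])

    def rf_xy_deg(self) -> np.ndarray:
        x, y = polar_to_xy(self.rho_rf_deg, self.theta_rf)
        return np.column_stack([x, y])

    def copy(self, **overrides) -> "RGCPopulation":
        fields = dict(
            rho_rf_deg=self.rho_rf_deg.copy(),
            theta_rf=self.theta_rf.copy(),
            sigma_rf_deg=self.sigma_rf_deg.copy(),
            rho_soma_mm=self.rho_soma_mm.copy(),
            theta_soma=self.theta_soma.copy(),
            rho_fiber_mm=self.rho_fiber_mm.copy(),
            theta_fiber=self.theta_fiber.copy(),
            dead=self.dead.copy(),
            nerve=self.nerve,
            retina=self.retina,
            seed=self.seed,
            config=dict(self.config),
            fiber_xy_original=None
            if self.fiber_xy_original is None
            else self.fiber_xy_original.copy(),
        )
        fields.update(overrides)
        return RGCPopulation(**fields)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(
            {
                "id": np.arange(self.n),
                "rho_RF_deg": self.rho_rf_deg,
                "theta_RF_rad": self.theta_rf,
                "sigma_RF_deg": self.sigma_rf_deg,
                "rho_soma_mm": self.rho_soma_mm,
                "theta_soma_rad": self.theta_soma,
                "rho_fiber_mm": self.rho_fiber_mm,
                "theta_fiber_rad": self.theta_fiber,
                "dead_flag": self.dead.astype(int),
            }
        )
        df.to_csv(path, index=False)
        sidecar = {
            "seed": self.seed,
            "config": self.config,
            "nerve": {"radius_mm": self.nerve.radius_mm, "eye_side": self.nerve.eye_side},
            "retina": {
                "max_eccentricity_mm": self.retina.max_eccentricity_mm,
                "mm_per_degree": self.retina.mm_per_degree,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RGCPopulation":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = path.with_suffix(".json")
        seed, config = None, {}
        nerve, retina = NerveGeometry(), RetinaGeometry()
        if sidecar_path.exists():
            sc = json.loads(sidecar_path.read_text())
            seed, config = sc.get("seed"), sc.get("config", {})
            nerve = NerveGeometry(**sc.get("nerve", {}))
            ret = sc.get("retina", {})
            retina = RetinaGeometry(
                max_eccentricity_mm=ret.get("max_eccentricity_mm", 21.0),
                mm_per_degree=ret.get("mm_per_degree", 0.29),
            )
        return cls(
            rho_rf_deg=df["rho_RF_deg"].to_numpy(float),
            theta_rf=df["theta_RF_rad"].to_numpy(float),
            sigma_rf_deg=df["sigma_RF_deg"].to_numpy(float),
            rho_soma_mm=df["rho_soma_mm"].to_numpy(float),
            theta_soma=df["theta_soma_rad"].to_numpy(float),
            rho_fiber_mm=df["rho_fiber_mm"].to_numpy(float),
            theta_fiber=df["theta_fiber_rad"].to_numpy(float),
            dead=df["dead_flag"].to_numpy(bool),
            nerve=nerve,
            retina=retina,
            seed=seed,
            config=config,
        )


def build_population(
    n: int = 10000,
    seed: int = 0,
    *,
    nerve: NerveGeometry | None = None,
    retina: RetinaGeometry | None = None,
    density: DensityField | None = None,
    cc: CumulativeCounts | None = None,
    radial_map: str = "area_uniform",
    species_mode: bool = False,
    fiber_density: DensityField | None = None,
    sigma_slope: float = 0.01,
    sigma_intercept: float = 0.05,
    sigma_min_deg: float = 0.01,
) -> RGCPopulation:
    """Generate a full population from a single stream of seed pairs.

    All three coordinate sets of each cell derive from the same (u_rho,
    u_theta) pair, which is what ties the spaces retinotopically. With
    ``species_mode`` the soma and receptive-field coordinates are taken to
    be identical (no cumulative-count data available for that species); with
    ``fiber_density`` the nerve section is populated by inverse-transform
    sampling of an inhomogeneous axon density instead of the uniform map.
    """
    nerve = nerve or NerveGeometry()
    retina = retina or RetinaGeometry()
    u_rho, u_theta = sample_seed_pairs(n, seed)

    if fiber_density is not None:
        if fiber_density.rho[-1] > nerve.radius_mm + 1e-9:
            raise ValueError("fiber density extends beyond the nerve section")
        fiber_sampler = build_conditional_sampler(fiber_density)
        rho_fiber, theta_fiber = fiber_sampler.sample(u_rho, u_theta)
    else:
        rho_fiber, theta_fiber = fibers_from_seeds(u_rho, u_theta, nerve, radial_map)

    raw = density if density is not None else build_density_field(
        max_eccentricity_mm=retina.max_eccentricity_mm
    )
    if raw.rho[-1] < retina.max_eccentricity_mm - 1e-9:
        raise ValueError("density grid does not cover the modeled retina")
    corrected = build_corrected_density(raw, retina)
    sampler = build_conditional_sampler(corrected)
    rho_soma, theta_soma = somas_from_seeds(u_rho, u_theta, sampler, retina)

    if species_mode:
        rho_rf, theta_rf = rho_soma.copy(), theta_soma.copy()
    else:
        cc = cc or CumulativeCounts.from_density(raw)
        rho_rf_mm, theta_rf = displace_receptive_fields(rho_soma, theta_soma, cc)
        rho_rf = retina.mm_to_deg(rho_rf_mm)

    sigma = rf_radius(rho_rf, sigma_slope, sigma_intercept, sigma_min_deg)
    if nerve.eye_side == "right":  # mirror x: theta -> pi - theta
        theta_fiber = np.mod(np.pi - theta_fiber, 2 * np.pi)
        theta_soma = np.mod(np.pi - theta_soma, 2 * np.pi)
        theta_rf = np.mod(np.pi - theta_rf, 2 * np.pi)

    return RGCPopulation(
        rho_rf_deg=rho_rf,
        theta_rf=theta_rf,
        sigma_rf_deg=sigma,
        rho_soma_mm=rho_soma,
        theta_soma=theta_soma,
        rho_fiber_mm=rho_fiber,
        theta_fiber=theta_fiber,
        dead=np.zeros(n, dtype=bool),
        nerve=nerve,
        retina=retina,
        seed=seed,
        config={
            "n": n,
            "radial_map": radial_map if fiber_density is None else "inhomogeneous",
            "species_mode": species_mode,
            "sigma_slope_deg_per_deg": sigma_slope,
            "sigma_intercept_deg": sigma_intercept,
            "sigma_min_deg": sigma_min_deg,
        },
    )


def check_retinotopy(pop: RGCPopulation, n_sectors: int = 12) -> dict:
    """Rank-correlation report of retinotopic order between retina and nerve.

    Radial order is assessed with Kendall's tau between soma and fiber
    eccentricities within each angular sector of the nerve section (narrow
    sectors approximate a common meridian); angular order with a single tau
    between soma and fiber angles.
    """
    edges = np.linspace(0.0, 2.0 * np.pi, n_sectors + 1)
    sector = np.clip(np.searchsorted(edges, pop.theta_fiber, side="right") - 1, 0, n_sectors - 1)
    radial = np.full(n_sectors, np.nan)
    for s in range(n_sectors):
        m = sector == s
        if m.sum() >= 2:
            radial[s] = stats.kendalltau(pop.rho_soma_mm[m], pop.rho_fiber_mm[m]).statistic
    angular = stats.kendalltau(pop.theta_soma, pop.theta_fiber).statistic
    return {
        "radial_tau_per_sector": radial,
        "radial_tau_mean": float(np.nanmean(radial)),
        "angular_tau": float(angular),
    }


def map_circular_patch(
    pop: RGCPopulation, space: str, center: tuple[float, float], radius: float
) -> dict:
    """Select the records whose coordinate in ``space`` lies inside a disc.

    ``center`` is Cartesian in the units of the space (degrees for
    ``visual_field``, mm otherwise). Returns the member ids together with
    their coordinates in all three spaces, ready for deformation plots.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    coords = {
        "visual_field": pop.rf_xy_deg(),
        "retina": pop.soma_xy(),
        "nerve": pop.fiber_xy(),
    }
    if space not in coords:
        raise ValueError(f"unknown space {space!r}")
    xy = coords[space]
    d = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
    ids = np.flatnonzero(d <= radius)
    return {
        "ids": ids,
        "visual_field_deg": coords["visual_field"][ids],
        "retina_mm": coords["retina"][ids],
        "nerve_mm": coords["nerve"][ids],
    }
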