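"""RGC soma density fields and 2-D inverse-transform sampling.

The soma density d(rho, theta) [cells/mm^2] is represented on a polar grid
over the retina. The packaged default is a parametric stand-in built from
four tabulated radial profiles (nasal, temporal, superior and inferior
meridians) interpolated log-linearly in angle; the CSV profiles are editable
so that digitized histological data can be substituted.

Sampling follows the textbook 2-D inverse transform: normalize the density
into a joint PDF f(rho, theta) (with the Jacobian rho), marginalize to get
the angular CDF F_theta, and for each sampled angle invert the conditional
radial CDF F_{rho|theta}.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np

from .geometry import RetinaGeometry

__all__ = [
    "MERIDIAN_ANGLES",
    "load_meridian_profiles",
    "build_density_field",
    "build_corrected_density",
    "build_conditional_sampler",
    "DensityField",
    "ConditionalSampler",
]

# Meridian angles in the left-eye retinal frame (+x nasal, +y superior).
MERIDIAN_ANGLES = {
    "nasal": 0.0,
    "superior": np.pi / 2,
    "temporal": np.pi,
    "inferior": 3 * np.pi / 2,
}

_DENSITY_FLOOR = 1e-12


def load_meridian_profiles(paths: dict[str, str] | None = None) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Load per-meridian radial density profiles.

    Parameters
    ----------
    paths : dict, optional
        Mapping meridian name -> CSV path with columns
        ``eccentricity_mm, density_cells_per_mm2``. When omitted, the
        packaged parametric profiles are used.
    """
    profiles = {}
    for name in MERIDIAN_ANGLES:
        if paths is not None:
            raw = np.loadtxt(paths[name], delimiter=",", skiprows=1)
        else:
            ref = importlib.resources.files("onspv.data") / f"density_{name}.csv"
            with importlib.resources.as_file(ref) as p:
                raw = np.loadtxt(p, delimiter=",", skiprows=1)
        ecc, dens = raw[:, 0], raw[:, 1]
        if np.any(dens < 0):
            raise ValueError(f"negative density in profile '{name}'")
        if np.any(np.diff(ecc) <= 0):
            raise ValueError(f"eccentricities must be increasing in profile '{name}'")
        profiles[name] = (ecc, dens)
    return profiles


@dataclass(frozen=True)
class DensityField:
    """Density d(rho, theta) tabulated on a polar grid.

    Attributes
    ----------
    rho : (n_rho,) array, mm, increasing from 0.
    theta : (n_theta,) array, radians, uniform on [0, 2*pi) without endpoint.
    values : (n_theta, n_rho) array, cells/mm^2.
    """

    rho: np.ndarray
    theta: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (self.theta.size, self.rho.size):
            raise ValueError("values shape must be (n_theta, n_rho)")
        if np.any(self.values < 0):
            raise ValueError("density must be non-negative")

    @property
    def dtheta(self) -> float:
        return 2.0 * np.pi / self.theta.size

    def _wrapped(self) -> np.ndarray:
        """Values with the first column appended at theta = 2*pi."""
        return np.vstack([self.values, self.values[:1]])

    def total_mass(self) -> float:
        """Integral of d * rho over the polar domain (total cell count)."""
        col = np.trapezoid(self.values * self.rho[None, :], self.rho, axis=1)
        col = np.append(col, col[0])
        th = np.append(self.theta, 2.0 * np.pi)
        return float(np.trapezoid(col, th))

    def at(self, rho, theta) -> np.ndarray:
        """Bilinear interpolation, periodic in theta, clipped in rho."""
        rho = np.clip(np.asarray(rho, dtype=float), self.rho[0], self.rho[-1])
        theta = np.mod(np.asarray(theta, dtype=float), 2.0 * np.pi)
        j = np.floor(theta / self.dtheta).astype(int) % self.theta.size
        lam = theta / self.dtheta - np.floor(theta / self.dtheta)
        jn = (j + 1) % self.theta.size
        i = np.clip(np.searchsorted(self.rho, rho) - 1, 0, self.rho.size - 2)
        w = (rho - self.rho[i]) / (self.rho[i + 1] - self.rho[i])
        v00 = self.values[j, i]
        v01 = self.values[j, i + 1]
        v10 = self.values[jn, i]
        v11 = self.values[jn, i + 1]
        return (1 - lam) * ((1 - w) * v00 + w * v01) + lam * ((1 - w) * v10 + w * v11)


def build_density_field(
    profiles: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    *,
    max_eccentricity_mm: float = 21.0,
    n_rho: int = 421,
    n_theta: int = 256,
) -> DensityField:
    """Tabulate the meridian profiles on a polar grid.

    Angular interpolation is log-linear between adjacent meridians, matching
    the roughly exponential angular variation of retinal cell densities.
    """
    if profiles is None:
        profiles = load_meridian_profiles()
    rho = np.linspace(0.0, max_eccentricity_mm, n_rho)
    theta = np.arange(n_theta) * 2.0 * np.pi / n_theta

    order = sorted(MERIDIAN_ANGLES.items(), key=lambda kv: kv[1])
    angles = np.array([a for _, a in order])
    logd = []
    for name, _ in order:
        ecc, dens = profiles[name]
        if ecc[-1] < max_eccentricity_mm - 1e-9:
            raise ValueError(f"profile '{name}' does not reach the modeled eccentricity")
        d = np.interp(rho, ecc, dens)
        logd.append(np.log(np.maximum(d, _DENSITY_FLOOR)))
    logd = np.array(logd)  # (4, n_rho)

    # periodic log-linear interpolation in angle
    values = np.empty((n_theta, rho.size))
    ext_angles = np.append(angles, angles[0] + 2 * np.pi)
    ext_logd = np.vstack([logd, logd[:1]])
    for j, th in enumerate(theta):
        k = np.searchsorted(ext_angles, th, side="right") - 1
        k = min(max(k, 0), len(angles) - 1)
        w = (th - ext_angles[k]) / (ext_angles[k + 1] - ext_angles[k])
        values[j] = np.exp((1 - w) * ext_logd[k] + w * ext_logd[k + 1])
    values[values <= 2 * _DENSITY_FLOOR] = 0.0
    return DensityField(rho=rho, theta=theta, values=values)


def build_corrected_density(raw: DensityField, retina: RetinaGeometry) -> DensityField:
    """Zero the density inside the optic-disc ellipse and renormalize later.

    The zeroed region is dilated by roughly one grid cell so that the
    piecewise-linear sampler can never place a soma strictly inside the
    ellipse (absolute void, not just a statistical one).
    """
    rho_g, theta_g = np.meshgrid(raw.rho, raw.theta)
    x = rho_g * np.cos(theta_g)
    y = rho_g * np.sin(theta_g)
    drho = raw.rho[1] - raw.rho[0] if raw.rho.size > 1 else 0.0
    margin = 2.0 * (drho + rho_g * raw.dtheta)
    disc = retina.disc
    u = (x - disc.center_x_mm) / (disc.semi_x + margin)
    v = (y - disc.center_y_mm) / (disc.semi_y + margin)
    inside = u * u + v * v < 1.0
    values = np.where(inside, 0.0, raw.values)
    if not np.any(values > 0):
        raise ValueError("corrected density is identically zero")
    return replace(raw, values=values)


@dataclass(frozen=True)
class ConditionalSampler:
    """Inverse-transform sampler for a tabulated polar density.

    ``F_theta`` is the marginal angular CDF on the wrapped theta grid;
    ``cond_cum[j]`` is the unnormalized conditional cumulative
    ``int_0^rho d(r, theta_j) r dr`` per column.
    """

    density: DensityField
    theta_ext: np.ndarray        # (n_theta + 1,)
    F_theta: np.ndarray          # (n_theta + 1,) from 0 to 1
    cond_cum: np.ndarray         # (n_theta + 1, n_rho)
    col_mass: np.ndarray         # (n_theta + 1,)

    def sample(self, u_rho: np.ndarray, u_theta: np.ndarray, chunk: int = 20000):
        """Map uniform seed pairs to (rho, theta) samples.

        theta = F_theta^{-1}(u_theta);  rho = F_{rho|theta}^{-1}(u_rho).
        """
        u_rho = np.asarray(u_rho, dtype=float)
        u_theta = np.asarray(u_theta, dtype=float)
        theta = np.interp(u_theta, self.F_theta, self.theta_ext)
        rho = np.empty_like(theta)
        dtheta = self.density.dtheta
        n_theta = self.density.theta.size
        grid_rho = self.density.rho
        for a in range(0, theta.size, chunk):
            b = min(a + chunk, theta.size)
            th = theta[a:b]
            j = np.minimum(np.floor(th / dtheta).astype(int), n_theta - 1)
            lam = th / dtheta - j
            cum = (1 - lam)[:, None] * self.cond_cum[j] + lam[:, None] * self.cond_cum[j + 1]
            mass = (1 - lam) * self.col_mass[j] + lam * self.col_mass[j + 1]
            if np.any(mass <= 0):
                raise FloatingPointError("conditional CDF has zero mass; density too sparse")
            t = u_rho[a:b] * mass
            k = np.clip((cum < t[:, None]).sum(axis=1), 1, grid_rho.size - 1)
            rows = np.arange(b - a)
            c0 = cum[rows, k - 1]
            c1 = cum[rows, k]
            frac = np.where(c1 > c0, (t - c0) / np.maximum(c1 - c0, 1e-300), 0.0)
            rho[a:b] = grid_rho[k - 1] + np.clip(frac, 0.0, 1.0) * (grid_rho[k] - grid_rho[k - 1])
        return rho, theta

    def bin_probabilities(self, rho_edges: np.ndarray, theta_edges: np.ndarray, n_sub: int = 16) -> np.ndarray:
        """Exact bin probabilities of the discretized target density.

        Used as the expected side of goodness-of-fit checks; integrates the
        tabulated density (not the sampler's random path) over polar bins.
        """
        rho_edges = np.asarray(rho_edges, dtype=float)
        theta_edges = np.asarray(theta_edges, dtype=float)
        dtheta = self.density.dtheta
        n_theta = self.density.theta.size
        P = np.zeros((theta_edges.size - 1, rho_edges.size - 1))
        # fine angular quadrature: n_sub midpoints per tabulated column interval
        fine = []
        for j in range(n_theta):
            base = j * dtheta
            fine.extend(base + (np.arange(n_sub) + 0.5) * dtheta / n_sub)
        fine = np.array(fine)
        w_theta = dtheta / n_sub
        j = np.minimum(np.floor(fine / dtheta).astype(int), n_theta - 1)
        lam = fine / dtheta - j
        # piecewise-constant marginal density of the sampler over each column interval
        interval_mass = np.diff(self.F_theta)
        f_th = interval_mass[j] / dtheta
        cum = (1 - lam)[:, None] * self.cond_cum[j] + lam[:, None] * self.cond_cum[j + 1]
        mass = (1 - lam) * self.col_mass[j] + lam * self.col_mass[j + 1]
        # conditional CDF evaluated at the requested rho edges
        Fr = np.empty((fine.size, rho_edges.size))
        for e, re in enumerate(rho_edges):
            Fr[:, e] = _interp_rows(self.density.rho, cum, re) / mass
        tb = np.clip(np.searchsorted(theta_edges, np.mod(fine, 2 * np.pi), side="right") - 1, 0, theta_edges.size - 2)
        contrib = f_th[:, None] * np.diff(Fr, axis=1) * w_theta
        np.add.at(P, tb, contrib)
        return P


def _interp_rows(x: np.ndarray, ys: np.ndarray, xq: float) -> np.ndarray:
    """np.interp of a scalar query against many rows sharing the same x."""
    xq = float(np.clip(xq, x[0], x[-1]))
    k = int(np.clip(np.searchsorted(x, xq), 1, x.size - 1))
    w = (xq - x[k - 1]) / (x[k] - x[k - 1])
    return (1 - w) * ys[:, k - 1] + w * ys[:, k]


def build_conditional_sampler(density: DensityField) -> ConditionalSampler:
    """Build marginal and conditional CDFs from a tabulated density."""
    wrapped = density._wrapped()  # (n_theta + 1, n_rho)
    integrand = wrapped * density.rho[None, :]
    drho = np.diff(density.rho)
    cond_cum = np.zeros_like(integrand)
    cond_cum[:, 1:] = np.cumsum(0.5 * (integrand[:, 1:] + integrand[:, :-1]) * drho, axis=1)
    col_mass = cond_cum[:, -1]
    if np.any(~np.isfinite(col_mass)) or col_mass.max() <= 0:
        raise FloatingPointError("quadrature of the density failed")
    theta_ext = np.append(density.theta, 2.0 * np.pi)
    F = np.zeros(theta_ext.size)
    F[1:] = np.cumsum(0.5 * (col_mass[1:] + col_mass[:-1]) * np.diff(theta_ext))
    F /= F[-1]
    return ConditionalSampler(
        density=density, theta_ext=theta_ext, F_theta=F, cond_cum=cond_cum, col_mass=col_mass
    )
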