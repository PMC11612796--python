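"""Multi-compartment optic-nerve fiber under extracellular sinusoidal drive.

A myelinated fiber is modeled as alternating Ranvier nodes (active membrane:
transient sodium with gates m/h, A-type potassium with gates a/b, persistent
sodium with gate p, and leak) and passive internodes, threaded along z at a
transverse position taken from the nerve cross-section. Stimulation sites
are isotropic point current sources in an infinite homogeneous anisotropic
medium; the extracellular potential at each compartment is the lead-field
matrix times the per-site sinusoidal currents. The cable equation is
integrated with a backward-Euler (implicit) voltage update and exponential
gate updates, which tolerates the stiffness of nodal kinetics at the
default 0.1 ms step. Spikes are local maxima of the recording-node
potential above an absolute threshold (default +10 mV) separated by at
least 1 ms.

Membrane constants other than the gate kinetics (conductance densities,
reversal potentials, capacitances, axial resistivity, medium
conductivities) are configuration defaults in the range used by myelinated
fiber models of this class; every simulation records them in its result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .electrodes import ElectrodeGrid
from .encoding import FiringPattern
from .rgc_population import RGCPopulation

try:  # optional acceleration; the pure-numpy path is semantically identical
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def _njit(f=None, **kw):
        if f is None:
            return lambda g: g
        return f


__all__ = [
    "ChannelParams",
    "FiberModel",
    "StimProtocol",
    "LeadField",
    "SimResult",
    "gate_rates",
    "steady_gates",
    "ionic_currents",
    "build_lead_field",
    "stimulus_currents",
    "simulate_fiber",
    "population_firing_rates",
]


@dataclass(frozen=True)
class ChannelParams:
    """Membrane parameters. Conductances mS/cm^2, potentials mV, C muF/cm^2."""

    g_A: float = 100.0
    g_Na: float = 400.0
    g_P: float = 2.5
    g_l: float = 10.0
    E_K: float = -90.0
    E_Na: float = 50.0
    E_L: float = -70.0
    c_node: float = 2.0
    c_myelin: float = 0.05
    g_myelin: float = 0.05
    axial_resistivity_ohm_cm: float = 70.0
    rate_scale: float = 1.0          # temperature factor on all gate rates
    v_rest: float = -70.0
    spike_threshold_mv: float = 10.0  # absolute potential, not deviation
    persistent_na_driving: str = "sodium"  # or "as_printed" (no driving term)

    def __post_init__(self):
        for name in ("g_A", "g_Na", "g_P", "g_l", "c_node", "c_myelin", "g_myelin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def balanced_leak_reversal(self) -> float:
        """Leak reversal that makes v_rest an exact equilibrium of the node.

        With gates at their steady state, the sum of nodal ionic currents at
        rest is absorbed into the leak battery so the unstimulated fiber
        stays quiescent by construction.
        """
        g = steady_gates(self.v_rest)
        i_a, i_na, i_p, _ = ionic_currents(self.v_rest, g, self)
        if self.g_l <= 0:
            return self.E_L
        return self.v_rest + (i_a + i_na + i_p) / self.g_l


@dataclass(frozen=True)
class FiberModel:
    """Geometry of one myelinated fiber along z (transverse position in mm)."""

    diameter_um: float = 1.0
    n_nodes: int = 31
    node_length_um: float = 1.0
    internode_length_um: float | None = None  # default: 100 x diameter
    recording_node: int = 26  # 1-based
    xy_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if not (1 <= self.recording_node <= self.n_nodes):
            raise ValueError("recording node out of range")

    @property
    def internode_um(self) -> float:
        return (
            self.internode_length_um
            if self.internode_length_um is not None
            else 100.0 * self.diameter_um
        )

    @property
    def n_comp(self) -> int:
        return 2 * self.n_nodes - 1

    @property
    def recording_comp(self) -> int:
        return 2 * (self.recording_node - 1)

    def compartment_lengths_um(self) -> np.ndarray:
        lengths = np.empty(self.n_comp)
        lengths[::2] = self.node_length_um
        lengths[1::2] = self.internode_um
        return lengths

    def compartment_z_mm(self) -> np.ndarray:
        lengths = self.compartment_lengths_um()
        ends = np.cumsum(lengths)
        centers = (ends - lengths / 2.0) / 1000.0
        return centers - centers.mean()  # site plane z=0 at fiber mid-length


@dataclass
class StimProtocol:
    """Per-site sinusoid i_j(t) = A_j sin(2 pi f_j t)."""

    amplitudes_uA: np.ndarray
    frequencies_hz: np.ndarray
    duration_ms: float = 1000.0
    dt_ms: float = 0.1

    def __post_init__(self):
        self.amplitudes_uA = np.atleast_1d(np.asarray(self.amplitudes_uA, float))
        self.frequencies_hz = np.atleast_1d(np.asarray(self.frequencies_hz, float))
        if self.amplitudes_uA.shape != self.frequencies_hz.shape:
            raise ValueError("amplitudes and frequencies must align")
        if np.any(self.frequencies_hz < 0):
            raise ValueError("frequencies must be non-negative")
        if self.duration_ms <= 0 or self.dt_ms <= 0:
            raise ValueError("duration and dt must be positive")

    @property
    def n_sites(self) -> int:
        return self.amplitudes_uA.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "site_id": np.arange(self.n_sites),
                "amplitude_uA": self.amplitudes_uA,
                "frequency_Hz": self.frequencies_hz,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, duration_ms: float = 1000.0, dt_ms: float = 0.1) -> "StimProtocol":
        df = pd.read_csv(path).sort_values("site_id")
        return cls(
            amplitudes_uA=df["amplitude_uA"].to_numpy(float),
            frequencies_hz=df["frequency_Hz"].to_numpy(float),
            duration_ms=duration_ms,
            dt_ms=dt_ms,
        )


@dataclass(frozen=True)
class LeadField:
    """Potential per unit current (kOhm) from each site at each compartment."""

    matrix_kohm: np.ndarray  # (n_comp, n_sites)
    sigma_xy_s_per_m: float
    sigma_z_s_per_m: float


@dataclass
class SimResult:
    t_ms: np.ndarray
    v_rec_mv: np.ndarray
    spike_times_ms: np.ndarray
    firing_rate_hz: float
    params: ChannelParams = field(default=None)


# ---------------------------------------------------------------- kinetics

@_njit
def _lin_over_expm1(x, s):
    """x / (1 - exp(-x/s)) with the removable singularity at x = 0."""
    out = x / -np.expm1(-x / s)
    small = np.abs(x) < 1e-6
    return np.where(small, s + 0.5 * x, out)


@_njit
def _rates(V, q):
    """All ten gate rate functions (1/ms) at membrane potential V (mV).

    The input is clamped to +-500 mV: rates saturate there, which keeps the
    exponentials finite when an electrode sits very close to a compartment.
    """
    V = np.minimum(np.maximum(V, -500.0), 500.0)
    aa = q * 0.015 * _lin_over_expm1(V + 90.0, 10.0)
    ba = q * 0.25 * np.exp(-(V + 30.0) / 10.0)
    ab = q * 0.04 * np.exp(-(V + 65.0) / 20.0)
    bb = q * 60.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    am = q * 0.45 * _lin_over_expm1(V + 37.0, 10.0)
    bm = q * 15.0 * np.exp(-(V + 62.0) / 18.0)
    ah = q * 0.16 * np.exp(-(V + 67.0) / 20.0)
    bh = q * 2.4 / (1.0 + np.exp(-(V + 37.0) / 10.0))
    ap = q * 0.0151 * _lin_over_expm1(V + 19.0, 10.2)
    bp = q * 0.000379 * _lin_over_expm1(-(V + 26.0), 10.0)
    return aa, ba, ab, bb, am, bm, ah, bh, ap, bp


def gate_rates(V, rate_scale: float = 1.0) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Opening/closing rates (alpha, beta) of the five gates a, b, m, h, p."""
    arr = np.atleast_1d(np.asarray(V, dtype=float))
    with np.errstate(over="ignore"):
        out = _rates(arr, float(rate_scale))
    if np.ndim(V) == 0:
        out = tuple(float(o[0]) for o in out)
    aa, ba, ab, bb, am, bm, ah, bh, ap, bp = out
    return {"a": (aa, ba), "b": (ab, bb), "m": (am, bm), "h": (ah, bh), "p": (ap, bp)}


def steady_gates(V, rate_scale: float = 1.0) -> dict[str, np.ndarray]:
    """Steady-state gate values alpha / (alpha + beta)."""
    r = gate_rates(V, rate_scale)
    return {k: a / (a + b) for k, (a, b) in r.items()}


def ionic_currents(V, gates: dict, params: ChannelParams):
    """Nodal current densities (muA/cm^2): I_A, I_Na, I_P, I_L.

    The persistent sodium current is g_P * p^3 * (V - E_Na) by default; the
    ``as_printed`` option drops the driving-force factor for audit purposes.
    """
    V = np.asarray(V, dtype=float)
    a, b, m, h, p = (np.asarray(gates[k], dtype=float) for k in "abmhp")
    i_a = params.g_A * a**3 * b * (V - params.E_K)
    i_na = params.g_Na * m**3 * h * (V - params.E_Na)
    if params.persistent_na_driving == "sodium":
        i_p = params.g_P * p**3 * (V - params.E_Na)
    else:
        i_p = params.g_P * p**3
    i_l = params.g_l * (V - params.E_L)
    return i_a, i_na, i_p, i_l


# ------------------------------------------------------------- lead field

def build_lead_field(
    points_mm: np.ndarray,
    sites_mm: np.ndarray,
    sigma_xy: float = 0.08,
    sigma_z: float = 0.5,
    as_printed: bool = False,
) -> np.ndarray:
    """Anisotropic point-source lead field, kOhm per (point, site).

    l = 1 / (4 pi sqrt(sigma_xy sigma_z (dx^2 + dy^2) + sigma_xy^2 dz^2))
    with distances in meters and conductivities in S/m; the isotropic limit
    is 1 / (4 pi sigma d). ``as_printed`` omits the square root (an audit
    mode; dimensionally inconsistent and not used by the simulator).
    """
    pts = np.atleast_2d(np.asarray(points_mm, float)) * 1e-3
    sts = np.atleast_2d(np.asarray(sites_mm, float)) * 1e-3
    dx = pts[:, None, 0] - sts[None, :, 0]
    dy = pts[:, None, 1] - sts[None, :, 1]
    dz = pts[:, None, 2] - sts[None, :, 2]
    arg = sigma_xy * sigma_z * (dx**2 + dy**2) + sigma_xy**2 * dz**2
    if np.any(arg <= 0):
        raise ZeroDivisionError("stimulation site coincides with a fiber compartment")
    denom = 4.0 * np.pi * (arg if as_printed else np.sqrt(arg))
    return 1.0 / denom / 1000.0  # Ohm -> kOhm


def stimulus_currents(protocol: StimProtocol, t_ms) -> np.ndarray:
    """Per-site currents i_j(t) = A_j sin(2 pi f_j t), t in ms, f in Hz."""
    t = np.asarray(t_ms, dtype=float)
    phase = 2.0 * np.pi * protocol.frequencies_hz * t[..., None] / 1000.0
    return protocol.amplitudes_uA * np.sin(phase)


# -------------------------------------------------------------- integrator

@_njit
def _integrate_core(
    coef,        # (nf, ncomp, nq) mV amplitude per frequency group
    omega,       # (nq,) rad/ms
    nsteps,
    dt,
    Cdt,         # (ncomp,) muF/ms == mS
    gax,         # (ncomp-1,) mS axial conductances
    g_pass,      # (ncomp,) mS passive membrane (internodes; 0 at nodes)
    e_pass,
    gNa_abs, gA_abs, gP_abs, gl_abs,   # mS per node
    e_na, e_k, e_l,
    p_driving_na,  # 1 if persistent Na uses (V - E_Na), 0 for as-printed
    q,
    v0,
    rec_idx,
):
    nf, ncomp, nq = coef.shape
    nnode = (ncomp + 1) // 2
    vrec = np.empty((nf, nsteps + 1))
    V = np.full((nf, ncomp), v0)
    v0a = np.full((nf, nnode), v0)
    aa, ba, ab, bb, am, bm, ah, bh, ap, bp = _rates(v0a, q)
    a = aa / (aa + ba)
    b = ab / (ab + bb)
    m = am / (am + bm)
    h = ah / (ah + bh)
    p = ap / (ap + bp)
    vrec[:, 0] = v0
    for step in range(1, nsteps + 1):
        t = step * dt
        ve = np.zeros((nf, ncomp))
        for iq in range(nq):
            ve += coef[:, :, iq] * np.sin(omega[iq] * t)
        Vn = V[:, ::2].copy()
        aa, ba, ab, bb, am, bm, ah, bh, ap, bp = _rates(Vn, q)
        a = _gate_step(a, aa, ba, dt)
        b = _gate_step(b, ab, bb, dt)
        m = _gate_step(m, am, bm, dt)
        h = _gate_step(h, ah, bh, dt)
        p = _gate_step(p, ap, bp, dt)
        gna = gNa_abs * m**3 * h
        gka = gA_abs * a**3 * b
        gp = gP_abs * p**3
        gmemb = np.zeros((nf, ncomp))
        ge = np.zeros((nf, ncomp))
        if p_driving_na == 1:
            gmemb[:, ::2] = gna + gka + gp + gl_abs
            ge[:, ::2] = gna * e_na + gka * e_k + gp * e_na + gl_abs * e_l
        else:
            gmemb[:, ::2] = gna + gka + gl_abs
            ge[:, ::2] = gna * e_na + gka * e_k + gl_abs * e_l - gp
        gmemb += g_pass
        ge += g_pass * e_pass
        rhs = Cdt * V + ge
        rhs[:, 1:] += gax * (ve[:, :-1] - ve[:, 1:])
        rhs[:, :-1] += gax * (ve[:, 1:] - ve[:, :-1])
        diag = Cdt + gmemb
        diag[:, 1:] += gax
        diag[:, :-1] += gax
        # Thomas solve of the tridiagonal system (vectorized over fibers)
        cp = np.empty((nf, ncomp - 1))
        dp = np.empty((nf, ncomp))
        cp[:, 0] = -gax[0] / diag[:, 0]
        dp[:, 0] = rhs[:, 0] / diag[:, 0]
        for k in range(1, ncomp):
            denom = diag[:, k] + gax[k - 1] * cp[:, k - 1]
            if k < ncomp - 1:
                cp[:, k] = -gax[k] / denom
            dp[:, k] = (rhs[:, k] + gax[k - 1] * dp[:, k - 1]) / denom
        V[:, ncomp - 1] = dp[:, ncomp - 1]
        for k in range(ncomp - 2, -1, -1):
            V[:, k] = dp[:, k] - cp[:, k] * V[:, k + 1]
        vrec[:, step] = V[:, rec_idx]
    return vrec


@_njit
def _gate_step(x, alpha, beta, dt):
    """Exponential (exact for frozen V) update of a first-order gate."""
    tot = alpha + beta
    xinf = alpha / tot
    return xinf + (x - xinf) * np.exp(-dt * tot)


def _absolute_params(fiber: FiberModel, params: ChannelParams):
    """Per-compartment absolute capacitances (muF) and conductances (mS)."""
    lengths_cm = fiber.compartment_lengths_um() * 1e-4
    d_cm = fiber.diameter_um * 1e-4
    areas = np.pi * d_cm * lengths_cm
    C = np.empty(fiber.n_comp)
    C[::2] = params.c_node * areas[::2]
    C[1::2] = params.c_myelin * areas[1::2]
    g_pass = np.zeros(fiber.n_comp)
    g_pass[1::2] = params.g_myelin * areas[1::2]
    cross = np.pi * d_cm**2 / 4.0
    seg = 0.5 * (lengths_cm[:-1] + lengths_cm[1:])
    gax = 1000.0 * cross / (params.axial_resistivity_ohm_cm * seg)  # S -> mS
    node_area = areas[0]
    return C, g_pass, gax, node_area


def _simulate_batch(
    xy_mm: np.ndarray,
    fiber: FiberModel,
    sites_xyz_mm: np.ndarray,
    protocol: StimProtocol,
    params: ChannelParams,
    sigma_xy: float = 0.08,
    sigma_z: float = 0.5,
) -> np.ndarray:
    """Membrane trace at the recording node for a batch of fiber positions."""
    xy_mm = np.atleast_2d(xy_mm)
    nf = xy_mm.shape[0]
    z = fiber.compartment_z_mm()
    ncomp = fiber.n_comp
    # lead field per fiber, collapsed by frequency group into mV coefficients
    freqs, inv = np.unique(protocol.frequencies_hz, return_inverse=True)
    nq = freqs.size
    coef = np.zeros((nf, ncomp, nq))
    for f in range(nf):
        pts = np.column_stack(
            [np.full(ncomp, xy_mm[f, 0]), np.full(ncomp, xy_mm[f, 1]), z]
        )
        lead = build_lead_field(pts, sites_xyz_mm, sigma_xy, sigma_z)  # kOhm
        for j in range(protocol.n_sites):
            coef[f, :, inv[j]] += lead[:, j] * protocol.amplitudes_uA[j]
    omega = 2.0 * np.pi * freqs / 1000.0
    C, g_pass, gax, node_area = _absolute_params(fiber, params)
    nsteps = int(round(protocol.duration_ms / protocol.dt_ms))
    with np.errstate(over="ignore"):
        vrec = _integrate_core(
            coef,
            omega,
            nsteps,
            protocol.dt_ms,
            C / protocol.dt_ms,
            gax,
            g_pass,
            params.v_rest,
            params.g_Na * node_area,
            params.g_A * node_area,
            params.g_P * node_area,
            params.g_l * node_area,
            params.E_Na,
            params.E_K,
            params.balanced_leak_reversal(),
            1 if params.persistent_na_driving == "sodium" else 0,
            params.rate_scale,
            params.v_rest,
            fiber.recording_comp,
        )
    if not np.all(np.isfinite(vrec)):
        raise FloatingPointError("integration diverged; try a smaller dt")
    return vrec


def _detect_spikes(v: np.ndarray, dt_ms: float, threshold_mv: float) -> np.ndarray:
    """Local maxima above the absolute threshold, merged within 1 ms."""
    distance = max(1, int(round(1.0 / dt_ms)))
    peaks, _ = find_peaks(v, height=threshold_mv, distance=distance)
    return peaks * dt_ms


def simulate_fiber(
    fiber: FiberModel,
    sites_xyz_mm: np.ndarray,
    protocol: StimProtocol,
    params: ChannelParams | None = None,
    sigma_xy: float = 0.08,
    sigma_z: float = 0.5,
) -> SimResult:
    """Simulate one fiber and return trace, spike times and firing rate."""
    params = params or ChannelParams()
    vrec = _simulate_batch(
        np.array([fiber.xy_mm]), fiber, np.atleast_2d(sites_xyz_mm), protocol, params,
        sigma_xy, sigma_z,
    )[0]
    t = np.arange(vrec.size) * protocol.dt_ms
    spikes = _detect_spikes(vrec, protocol.dt_ms, params.spike_threshold_mv)
    fr = 1000.0 * spikes.size / protocol.duration_ms
    return SimResult(t_ms=t, v_rec_mv=vrec, spike_times_ms=spikes, firing_rate_hz=fr, params=params)


def population_firing_rates(
    pop: RGCPopulation,
    grid: ElectrodeGrid,
    protocol: StimProtocol,
    params: ChannelParams | None = None,
    fiber_template: FiberModel | None = None,
    subsample: int | None = None,
    seed: int = 0,
    batch: int = 64,
    sigma_xy: float = 0.08,
    sigma_z: float = 0.5,
) -> tuple[FiringPattern, np.ndarray]:
    """Biophysical firing rates over (a subsample of) the population.

    Sites are point sources at the grid cell centers in the z = 0 plane at
    fiber mid-length. Each fiber is simulated independently; dead fibers and
    fibers outside the subsample get zero. Returns the firing pattern and
    the simulated record ids.
    """
    if protocol.n_sites != grid.n_sites:
        raise ValueError("protocol sites must match grid sites")
    params = params or ChannelParams()
    fiber_template = fiber_template or FiberModel()
    rng = np.random.default_rng(seed)
    candidates = np.flatnonzero(pop.alive)
    if subsample is not None and subsample < candidates.size:
        candidates = np.sort(rng.choice(candidates, size=subsample, replace=False))
    sites = np.column_stack([grid.centers, np.zeros(grid.n_sites)])
    xy = pop.fiber_xy()[candidates]
    rates = np.zeros(pop.n)
    for a in range(0, candidates.size, batch):
        ids = candidates[a : a + batch]
        vrec = _simulate_batch(
            xy[a : a + batch], fiber_template, sites, protocol, params, sigma_xy, sigma_z
        )
        for row, i in enumerate(ids):
            spikes = _detect_spikes(vrec[row], protocol.dt_ms, params.spike_threshold_mv)
            rates[i] = 1000.0 * spikes.size / protocol.duration_ms
    return FiringPattern(rates=rates, fr_max=300.0), candidates
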