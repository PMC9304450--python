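"""Rheology, lumped outlet model, wall traction, and WSS-derived biomarkers.

Implements the Carreau--Yasuda shear-thinning viscosity, the three-element
(RCR) Windkessel outlet ODE, a Robin-type wall traction, and the wall-shear
derived indices: time-averaged wall shear stress (TAWSS), oscillatory shear
index (OSI), peak Reynolds number, and Womersley number.

Units: Pa, mm, s, mm^3/s internally; cP and mmHg are converted at I/O.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "CP_TO_PAS",
    "MMHG_TO_PA",
    "BLOOD_DENSITY",
    "MU_AVG",
    "CarreauYasudaParams",
    "WindkesselParams",
    "WindkesselResult",
    "FlowWaveform",
    "WSSTimeSeries",
    "FieldSummary",
    "carreau_yasuda_viscosity",
    "windkessel_pressure",
    "equivalent_windkessel",
    "robin_traction",
    "tawss",
    "osi",
    "field_summary",
    "reynolds_max",
    "womersley",
]

logger = logging.getLogger(__name__)

CP_TO_PAS = 1e-3
MMHG_TO_PA = 133.322

#: Default blood density, kg/m^3.
BLOOD_DENSITY = 1027.0
#: Default cycle/shear-averaged blood viscosity, Pa*s (3.35 cP).
MU_AVG = 3.35e-3

REGIONS = ("ascending", "arch", "descending")


@dataclass(frozen=True)
class CarreauYasudaParams:
    """Five-parameter shear-thinning viscosity law.

    Defaults correspond to healthy blood: zero-shear plateau 11 cP,
    infinite-shear plateau 2 cP, time constant 1.5 s, transition exponent
    0.2, power-law index 0.71.
    """

    eta_inf: float = 2.0 * CP_TO_PAS
    eta_0: float = 11.0 * CP_TO_PAS
    lambda_cy: float = 1.5
    a: float = 0.2
    n: float = 0.71

    def __post_init__(self) -> None:
        if not self.eta_0 > self.eta_inf > 0:
            raise ValueError("need eta_0 > eta_inf > 0")
        if self.lambda_cy <= 0 or self.a <= 0:
            raise ValueError("lambda_cy and a must be positive")
        if not 0 < self.n <= 1:
            raise ValueError(f"power-law index n={self.n} outside (0, 1]")


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element (proximal R, compliance C, distal R) outlet model.

    Resistances in Pa*s/mm^3, compliance in mm^3/Pa.
    """

    r_p: float
    c_wk: float
    r_d: float
    outlet_name: str = "outlet"

    def __post_init__(self) -> None:
        if self.r_p <= 0 or self.c_wk <= 0 or self.r_d <= 0:
            raise ValueError("Windkessel parameters must all be positive")


@dataclass
class FlowWaveform:
    """Periodic flow-rate waveform over one cardiac cycle.

    ``times`` span [0, period] with q(0) == q(period) within tolerance.
    Flow in mm^3/s.
    """

    times: np.ndarray
    q: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.q.shape:
            raise ValueError("times and q must be 1-D arrays of equal length")
        if len(self.times) < 4:
            raise ValueError("need at least 4 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(self.times[0]) > 1e-12:
            raise ValueError("times must start at 0")
        if abs(self.times[-1] - self.period) > 1e-9 * max(1.0, self.period):
            raise ValueError("times must end at the period")
        scale = max(1.0, float(np.max(np.abs(self.q))))
        if abs(self.q[0] - self.q[-1]) > 1e-6 * scale:
            raise ValueError("waveform is not periodic: q(0) != q(T)")

    @property
    def mean_flow(self) -> float:
        return float(np.trapezoid(self.q, self.times) / self.period)

    @property
    def stroke_volume(self) -> float:
        """Integral of Q over one period, mm^3."""
        return float(np.trapezoid(self.q, self.times))


@dataclass
class WindkesselResult:
    times: np.ndarray          # final cycle, starting at 0
    pressure: np.ndarray       # Pa
    periodicity_residual: float  # |p(0) - p(T)| on the final cycle, Pa
    n_cycles_run: int
    converged: bool

    @property
    def p_max(self) -> float:
        return float(np.max(self.pressure))

    @property
    def p_mean(self) -> float:
        return float(np.trapezoid(self.pressure, self.times)
                     / (self.times[-1] - self.times[0]))


@dataclass
class WSSTimeSeries:
    """Per-node wall-shear-stress vectors over one cardiac cycle.

    ``tau`` has shape (n_times, n_nodes, 3) in Pa; ``points`` (n_nodes, 3)
    in mm.  ``regions`` optionally labels each node ascending/arch/descending.
    """

    points: np.ndarray
    times: np.ndarray
    tau: np.ndarray
    triangles: np.ndarray | None = None
    regions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n_nodes, 3)")
        if self.tau.shape != (len(self.times), len(self.points), 3):
            raise ValueError(
                f"tau shape {self.tau.shape} != (n_times, n_nodes, 3)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.tau)):
            raise ValueError("tau contains non-finite values")
        if self.regions is not None:
            self.regions = np.asarray(self.regions, dtype=object)
            if len(self.regions) != len(self.points):
                raise ValueError("one region label per node required")

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    def region_mask(self, region: str) -> np.ndarray:
        if self.regions is None:
            raise ValueError("series carries no region labels")
        return np.asarray([r == region for r in self.regions])


@dataclass(frozen=True)
class FieldSummary:
    statistic: str      # "min" | "mean" | "max"
    value: float
    region: str = "all"


def carreau_yasuda_viscosity(shear_rate,
                             params: CarreauYasudaParams | None = None):
    """Apparent viscosity (Pa*s) at the given shear rate (1/s).

    ``eta = eta_inf + (eta_0 - eta_inf) * (1 + (lambda*g)^a)^((n-1)/a)``.
    Monotone non-increasing, bounded in [eta_inf, eta_0].
    """
    p = params or CarreauYasudaParams()
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    eta = p.eta_inf + (p.eta_0 - p.eta_inf) * (
        1.0 + (p.lambda_cy * g) ** p.a) ** ((p.n - 1.0) / p.a)
    return eta if eta.shape else float(eta)


def windkessel_pressure(waveform: FlowWaveform, params: WindkesselParams,
                        n_cycles: int = 10, p_init: float = 0.0,
                        n_steps_per_cycle: int = 1000,
                        tol_pa: float = 0.1) -> WindkesselResult:
    """Integrate the RCR outlet ODE and return the final cardiac cycle.

    ``dp/dt + p/(Rd C) = Q (1 + Rp/Rd)/C + Rp dQ/dt`` is advanced with the
    A-stable implicit trapezoidal rule on a uniform grid; dQ/dt comes from a
    periodic cubic spline of the waveform.  Cycles repeat until the maximum
    cycle-to-cycle pressure change falls below ``tol_pa`` or ``n_cycles``
    is reached.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    big_t = waveform.period
    # periodic spline requires exact endpoint match
    q_vals = waveform.q.copy()
    q_vals[-1] = q_vals[0]
    spline = CubicSpline(waveform.times, q_vals, bc_type="periodic")
    dspline = spline.derivative()

    tau_rc = params.r_d * params.c_wk
    gain = (1.0 + params.r_p / params.r_d) / params.c_wk

    t_grid = np.linspace(0.0, big_t, n_steps_per_cycle + 1)
    q_grid = spline(t_grid)
    dq_grid = dspline(t_grid)
    f_grid = gain * q_grid + params.r_p * dq_grid  # forcing term
    dt = big_t / n_steps_per_cycle
    a = dt / (2.0 * tau_rc)

    p = float(p_init)
    prev_cycle = None
    converged = False
    cycles_run = 0
    for cyc in range(n_cycles):
        cycle = np.empty(n_steps_per_cycle + 1)
        cycle[0] = p
        for k in range(n_steps_per_cycle):
            p = (p * (1.0 - a) + 0.5 * dt * (f_grid[k] + f_grid[k + 1])) \
                / (1.0 + a)
            cycle[k + 1] = p
        cycles_run = cyc + 1
        if prev_cycle is not None and np.max(np.abs(cycle - prev_cycle)) < tol_pa:
            prev_cycle = cycle
            converged = True
            break
        prev_cycle = cycle

    residual = float(abs(prev_cycle[0] - prev_cycle[-1]))
    return WindkesselResult(times=t_grid, pressure=prev_cycle,
                            periodicity_residual=residual,
                            n_cycles_run=cycles_run, converged=converged)


def equivalent_windkessel(outlets: list[WindkesselParams],
                          name: str = "equivalent") -> WindkesselParams:
    """Parallel-equivalent RCR of several outlets (resistances combine in
    parallel, compliances add).  Approximate: a parallel bank of RCRs is not
    exactly an RCR, but the low-frequency behavior matches."""
    if not outlets:
        raise ValueError("need at least one outlet")
    r_p = 1.0 / sum(1.0 / o.r_p for o in outlets)
    r_d = 1.0 / sum(1.0 / o.r_d for o in outlets)
    c_wk = sum(o.c_wk for o in outlets)
    return WindkesselParams(r_p=r_p, c_wk=c_wk, r_d=r_d, outlet_name=name)


def robin_traction(u, dudt, normal, k_s: float = 1e7, c_s: float = 1e4,
                   p_0: float = 0.0) -> np.ndarray:
    """Robin-type wall traction ``-k_s u - c_s du/dt - p_0 n`` (Pa).

    ``u`` in m, ``dudt`` in m/s, ``normal`` must be unit length.  Defaults
    ``k_s = 1e7``, ``c_s = 1e4``, ``p_0 = 0`` model perivascular support.
    """
    u = np.asarray(u, dtype=float)
    dudt = np.asarray(dudt, dtype=float)
    n = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("normal must have unit length")
    return -k_s * u - c_s * dudt - p_0 * n


def _check_series(series: WSSTimeSeries) -> None:
    if len(series.times) < 3:
        raise ValueError("need at least 3 time samples")


def tawss(series: WSSTimeSeries) -> np.ndarray:
    """Per-node time-averaged wall shear stress, Pa.

    Trapezoidal average of |tau| over the supplied cycle.
    """
    _check_series(series)
    mag = np.linalg.norm(series.tau, axis=2)  # (n_times, n_nodes)
    span = series.times[-1] - series.times[0]
    return np.trapezoid(mag, series.times, axis=0) / span


def osi(series: WSSTimeSeries) -> np.ndarray:
    """Per-node oscillatory shear index in [0, 0.5].

    ``OSI = 0.5 * (1 - |int tau dt| / int |tau| dt)``; 0 means the WSS
    vector never changes direction, 0.5 a fully symmetric reversal.  Nodes
    with identically zero WSS return 0 by convention.
    """
    _check_series(series)
    vec_int = np.trapezoid(series.tau, series.times, axis=0)  # (n_nodes, 3)
    mag_int = np.trapezoid(np.linalg.norm(series.tau, axis=2),
                           series.times, axis=0)
    num = np.linalg.norm(vec_int, axis=1)
    out = np.zeros_like(mag_int)
    nz = mag_int > 0
    if np.any(~nz):
        logger.info("OSI: %d node(s) with zero WSS set to 0", int((~nz).sum()))
    out[nz] = 0.5 * (1.0 - num[nz] / mag_int[nz])
    return np.clip(out, 0.0, 0.5)


def field_summary(values, statistic: str, region_mask=None,
                  weights=None, region: str = "all") -> FieldSummary:
    """Min/mean/max of a per-node scalar field, optionally masked.

    The mean is unweighted by default; pass per-node ``weights`` (e.g.
    nodal areas) for a weighted mean.
    """
    vals = np.asarray(values, dtype=float)
    if region_mask is not None:
        mask = np.asarray(region_mask, dtype=bool)
        vals = vals[mask]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("empty node selection")
    if statistic == "min":
        v = float(np.min(vals))
    elif statistic == "max":
        v = float(np.max(vals))
    elif statistic == "mean":
        if weights is not None:
            v = float(np.average(vals, weights=weights))
        else:
            v = float(np.mean(vals))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return FieldSummary(statistic=statistic, value=v, region=region)


def reynolds_max(v_max: float, d_max: float, rho: float = BLOOD_DENSITY,
                 mu_avg: float = MU_AVG) -> float:
    """Peak Reynolds number ``rho * V * D / mu`` (SI inputs: m/s, m)."""
    if v_max <= 0 or d_max <= 0 or rho <= 0 or mu_avg <= 0:
        raise ValueError("all Reynolds inputs must be positive")
    return rho * v_max * d_max / mu_avg


def womersley(d: float, period: float, rho: float = BLOOD_DENSITY,
              mu: float = MU_AVG) -> float:
    """Womersley number ``(d/2) * sqrt(2 pi rho / (T mu))`` (SI inputs).

    Radius-based convention with angular frequency ``2 pi / T``.
    """
    if d <= 0 or period <= 0 or rho <= 0 or mu <= 0:
        raise ValueError("all Womersley inputs must be positive")
    return (d / 2.0) * math.sqrt(2.0 * math.pi * rho / (period * mu))
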