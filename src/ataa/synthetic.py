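"""Synthetic-data generators with known ground truth.

Each generator emulates one of the pipeline's upstream inputs -- biaxial
myograph tables, wall-shear-stress fields on a surface mesh, tortuous
vessel centerlines (optionally voxelized to axial mask stacks), inflow
waveforms, and censored lifespan cohorts -- and records the quantities a
downstream stage should recover in a ground-truth sidecar.  All draws come
from a single seeded generator per invocation, so a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import (
    BiaxialSample,
    HGOParams,
    MMHG_TO_MPA,
    cauchy_stresses,
    loaded_outer_diameter,
)
from .datasets import BIOMARKER_RANGES, DELTA_RANGES
from .geometry import Centerline, MaskStack
from .hemodynamics import REGIONS, FlowWaveform, WSSTimeSeries
from .stats import CohortTable

__all__ = [
    "GeneratorConfig",
    "gen_biaxial",
    "gen_wss_field",
    "gen_vessel",
    "voxelize_centerline",
    "gen_inflow",
    "gen_cohort",
    "inline_wss_truth",
]

#: six-protocol sweep definitions: (protocol_id, kind, held value)
_INFLATION_STRETCHES = (1.3, 1.4, 1.5)
_EXTENSION_PRESSURES = (50.0, 100.0, 150.0)
_INFLATION_PMAX = 175.0  # mmHg

#: regional wall-shear presets tuned so whole-field summaries fall inside
#: the observed cohort ranges (cohort-emulation mode)
COHORT_WSS_AMPLITUDE = {"ascending": 0.6, "arch": 2.0, "descending": 12.0}
COHORT_WSS_OSC_FRACTION = {"ascending": 0.7, "arch": 0.65, "descending": 0.95}


@dataclass
class GeneratorConfig:
    """Shared knobs for the cohort-level generators."""

    seed: int = 0
    cohort_size: int = 10
    hgo_truth: HGOParams = field(
        default_factory=lambda: HGOParams.from_degrees(1.0, 0.5, 2.0, 0.15, 40.0))
    noise_stress_mpa: float = 0.0
    noise_geometry_mm: float = 0.0
    period_s: float = 0.1
    tobit_beta0: float = 14.0
    tobit_beta1: float = 40.0
    tobit_sigma: float = 3.0
    censor_level: float = 25.0
    predictor: str = "OSI_mean"

    def __post_init__(self) -> None:
        if self.noise_stress_mpa < 0 or self.noise_geometry_mm < 0:
            raise ValueError("noise levels must be non-negative")
        if self.tobit_sigma <= 0:
            raise ValueError("tobit_sigma must be positive")


# -- biaxial -----------------------------------------------------------------

def gen_biaxial(truth: HGOParams,
                unloaded_outer_diameter_mm: float = 1.2,
                unloaded_thickness_mm: float = 0.15,
                noise_sd_mpa: float = 0.0,
                n_per_protocol: int = 15,
                seed: int = 0) -> tuple[BiaxialSample, dict]:
    """Emit the six standard loading protocols from known wall parameters.

    Inflation protocols sweep 0--175 mmHg at axial stretches 1.3/1.4/1.5,
    solving thin-wall equilibrium for the circumferential stretch; axial
    protocols sweep stretch 1.3--1.5 at 50/100/150 mmHg.  Emitted stresses
    are the model's own Cauchy stresses plus optional i.i.d. Gaussian
    noise, so a perfect fit exists by construction.
    """
    rng = np.random.default_rng(seed)
    lam_t_all, lam_z_all, pid_all = [], [], []

    for lam_z in _INFLATION_STRETCHES:
        pid = f"inflation_{lam_z}"
        for p_mmhg in np.linspace(0.0, _INFLATION_PMAX, n_per_protocol):
            try:
                lam_t, _ = loaded_outer_diameter(
                    truth, p_mmhg, lam_z,
                    unloaded_outer_diameter_mm, unloaded_thickness_mm)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"equilibrium failed in protocol {pid}: {exc}") from exc
            lam_t_all.append(lam_t)
            lam_z_all.append(lam_z)
            pid_all.append(pid)

    for p_mmhg in _EXTENSION_PRESSURES:
        pid = f"extension_{int(p_mmhg)}"
        for lam_z in np.linspace(1.3, 1.5, n_per_protocol):
            try:
                lam_t, _ = loaded_outer_diameter(
                    truth, p_mmhg, lam_z,
                    unloaded_outer_diameter_mm, unloaded_thickness_mm)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"equilibrium failed in protocol {pid}: {exc}") from exc
            lam_t_all.append(lam_t)
            lam_z_all.append(lam_z)
            pid_all.append(pid)

    lam_t_arr = np.asarray(lam_t_all)
    lam_z_arr = np.asarray(lam_z_all)
    sig_t, sig_z = cauchy_stresses(truth, lam_t_arr, lam_z_arr)
    if noise_sd_mpa > 0:
        sig_t = sig_t + rng.normal(0.0, noise_sd_mpa, sig_t.shape)
        sig_z = sig_z + rng.normal(0.0, noise_sd_mpa, sig_z.shape)

    sample = BiaxialSample(
        lambda_theta=lam_t_arr, lambda_z=lam_z_arr,
        sigma_theta=sig_t, sigma_z=sig_z,
        protocol_id=np.asarray(pid_all, dtype=object),
        unloaded_outer_diameter_mm=unloaded_outer_diameter_mm,
        unloaded_thickness_mm=unloaded_thickness_mm,
    )
    sidecar = {
        "generator": "gen_biaxial",
        "seed": seed,
        "truth_params": truth.to_dict(),
        "noise_sd_mpa": noise_sd_mpa,
        "unloaded_outer_diameter_mm": unloaded_outer_diameter_mm,
        "unloaded_thickness_mm": unloaded_thickness_mm,
    }
    return sample, sidecar


# -- WSS fields --------------------------------------------------------------

def inline_wss_truth(amplitude: float, osc_fraction: float) -> tuple[float, float]:
    """Closed-form (TAWSS, OSI) for the in-line surrogate signal
    ``tau(t) = A * [(1 - f) + f cos(2 pi t / T)] e``.

    For ``f <= 1/2`` the signal never reverses: TAWSS = A (1 - f), OSI = 0.
    For ``f > 1/2`` the magnitude average follows from the piecewise
    integral of ``|m + f cos(theta)|`` with ``m = 1 - f``.
    """
    a, f = amplitude, osc_fraction
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"oscillatory fraction {f} outside [0, 1]")
    m = 1.0 - f
    if a == 0.0 or (f == 0.0 and m == 0.0):
        return 0.0, 0.0
    if f <= 0.5:
        return a * m, 0.0
    theta_c = math.acos(-m / f)
    mean_abs = (2.0 / math.pi) * (m * theta_c + f * math.sin(theta_c)) - m
    tawss_v = a * mean_abs
    osi_v = 0.5 * (1.0 - m / mean_abs)
    return tawss_v, osi_v


def _tube_mesh(n_axial: int, n_circ: int, radius_mm: float,
               length_mm: float):
    """Straight triangulated tube along z with region labels by thirds."""
    zs = np.linspace(0.0, length_mm, n_axial)
    angs = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    pts = np.empty((n_axial * n_circ, 3))
    regions = np.empty(n_axial * n_circ, dtype=object)
    circumferential = np.empty((n_axial * n_circ, 3))
    for i, z in enumerate(zs):
        frac = i / max(n_axial - 1, 1)
        region = REGIONS[min(int(frac * 3), 2)]
        for j, ang in enumerate(angs):
            idx = i * n_circ + j
            pts[idx] = (radius_mm * np.cos(ang), radius_mm * np.sin(ang), z)
            regions[idx] = region
            circumferential[idx] = (-np.sin(ang), np.cos(ang), 0.0)
    tris = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = a + n_circ
            d = b + n_circ
            tris.append((a, b, c))
            tris.append((b, d, c))
    return pts, np.asarray(tris), regions, circumferential


def gen_wss_field(n_axial: int = 24, n_circ: int = 12, n_times: int = 64,
                  period: float = 0.1, radius_mm: float = 0.75,
                  length_mm: float = 20.0,
                  amplitude: dict[str, float] | None = None,
                  osc_fraction: dict[str, float] | None = None,
                  g_fraction: float = 0.0,
                  amplitude_jitter: float = 0.10,
                  osc_jitter: float = 0.02,
                  seed: int = 0) -> tuple[WSSTimeSeries, dict]:
    """Tubular WSS surrogate with controllable oscillatory content.

    Per node, ``tau(t) = A [(1-f) + f cos(2 pi t/T)] e_ax
    + A g sin(2 pi t/T) e_circ`` where the axial/circumferential unit
    vectors follow the tube.  Regional amplitude and oscillatory-fraction
    presets default to cohort-emulation values.  The sidecar records
    per-node TAWSS/OSI ground truth: closed form when ``g = 0``, dense
    quadrature (65_536 samples) otherwise.
    """
    if n_times < 8:
        raise ValueError("need n_times >= 8")
    amp_by_region = dict(COHORT_WSS_AMPLITUDE if amplitude is None else amplitude)
    f_by_region = dict(COHORT_WSS_OSC_FRACTION if osc_fraction is None
                       else osc_fraction)
    for reg, f in f_by_region.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"oscillatory fraction {f} for {reg} outside [0,1]")

    rng = np.random.default_rng(seed)
    pts, tris, regions, e_circ = _tube_mesh(n_axial, n_circ, radius_mm,
                                            length_mm)
    n_nodes = len(pts)
    e_ax = np.tile([0.0, 0.0, 1.0], (n_nodes, 1))

    amps = np.array([amp_by_region[r] for r in regions])
    amps = amps * (1.0 + amplitude_jitter * rng.uniform(-1, 1, n_nodes))
    fracs = np.array([f_by_region[r] for r in regions])
    fracs = np.clip(fracs + osc_jitter * rng.uniform(-1, 1, n_nodes), 0.0, 1.0)

    times = np.linspace(0.0, period, n_times)
    phase = np.cos(2.0 * np.pi * times / period)          # (n_times,)
    quad = np.sin(2.0 * np.pi * times / period)

    steady = amps * (1.0 - fracs)                          # (n_nodes,)
    osc = amps * fracs
    tau = (steady[None, :, None] + osc[None, :, None] * phase[:, None, None]) \
        * e_ax[None, :, :]
    if g_fraction:
        tau = tau + (amps * g_fraction)[None, :, None] \
            * quad[:, None, None] * e_circ[None, :, :]

    series = WSSTimeSeries(points=pts, times=times, tau=tau,
                           triangles=tris, regions=regions)

    if g_fraction == 0.0:
        truth = [inline_wss_truth(a, f) for a, f in zip(amps, fracs)]
        tawss_truth = np.array([t for t, _ in truth])
        osi_truth = np.array([o for _, o in truth])
        truth_kind = "closed_form"
    else:
        tt = np.linspace(0.0, period, 65_536)
        ph = np.cos(2.0 * np.pi * tt / period)
        qd = np.sin(2.0 * np.pi * tt / period)
        ax_comp = steady[:, None] + osc[:, None] * ph[None, :]
        circ_comp = (amps * g_fraction)[:, None] * qd[None, :]
        mag = np.hypot(ax_comp, circ_comp)
        int_mag = np.trapezoid(mag, tt, axis=1)
        int_ax = np.trapezoid(ax_comp, tt, axis=1)
        int_circ = np.trapezoid(circ_comp, tt, axis=1)
        tawss_truth = int_mag / period
        num = np.hypot(int_ax, int_circ)
        osi_truth = np.where(int_mag > 0,
                             0.5 * (1.0 - num / np.where(int_mag > 0,
                                                         int_mag, 1.0)),
                             0.0)
        truth_kind = "dense_quadrature"

    sidecar = {
        "generator": "gen_wss_field",
        "seed": seed,
        "period_s": period,
        "truth_kind": truth_kind,
        "tawss_truth_pa": tawss_truth,
        "osi_truth": osi_truth,
        "amplitude_by_region": amp_by_region,
        "osc_fraction_by_region": f_by_region,
        "g_fraction": g_fraction,
    }
    return series, sidecar


# -- vessel geometry ---------------------------------------------------------

def gen_vessel(tortuosity_amplitude: float = 1.75,
               bulge_peak_mm: float = 3.0,
               n_points: int = 200,
               base_diameter_mm: float = 1.4,
               length_mm: float = 20.0,
               bulge_center: float = 0.25,
               bulge_width: float = 0.06,
               noise_mm: float = 0.0,
               seed: int = 0) -> tuple[Centerline, dict]:
    """Sinusoidally perturbed, z-monotone vessel with a Gaussian bulge.

    The curve is ``(A sin(4 pi s), A/2 sin(6 pi s + 1), L s)`` for
    ``s in [0, 1]``; the diameter profile is the base value plus a Gaussian
    bump peaking at ``bulge_peak_mm``.  Sidecar ground truth (AL, GL, ATI,
    D_max) comes from a 100_001-point refinement of the same curve.
    """
    if n_points < 2 or length_mm <= 0 or base_diameter_mm <= 0:
        raise ValueError("positive dimensions required")
    if bulge_peak_mm < base_diameter_mm:
        raise ValueError("bulge peak must be >= base diameter")

    rng = np.random.default_rng(seed)
    amp = tortuosity_amplitude

    def curve(s: np.ndarray) -> np.ndarray:
        return np.column_stack([
            amp * np.sin(4.0 * np.pi * s),
            0.5 * amp * np.sin(6.0 * np.pi * s + 1.0),
            length_mm * s,
        ])

    def diam(s: np.ndarray) -> np.ndarray:
        return base_diameter_mm + (bulge_peak_mm - base_diameter_mm) \
            * np.exp(-0.5 * ((s - bulge_center) / bulge_width) ** 2)

    s = np.linspace(0.0, 1.0, n_points)
    pts = curve(s)
    if noise_mm > 0:
        pts = pts + rng.normal(0.0, noise_mm, pts.shape)
        if np.any(np.diff(pts[:, 2]) <= 0):
            raise ValueError("noise made the centerline non-monotone in z; "
                             "reduce noise_mm")
    regions = np.empty(n_points, dtype=object)
    for i in range(n_points):
        regions[i] = REGIONS[min(int(s[i] * 3), 2)]
    cl = Centerline(points=pts, diameters=diam(s), regions=regions)

    s_fine = np.linspace(0.0, 1.0, 100_001)
    pts_fine = curve(s_fine)
    al = float(np.linalg.norm(np.diff(pts_fine, axis=0), axis=1).sum())
    gl = float(np.linalg.norm(pts_fine[-1] - pts_fine[0]))
    sidecar = {
        "generator": "gen_vessel",
        "seed": seed,
        "al_mm": al,
        "gl_mm": gl,
        "ati": (al / gl - 1.0) * 100.0,
        "d_max_mm": float(np.max(diam(s_fine))),
        "tortuosity_amplitude": tortuosity_amplitude,
        "bulge_peak_mm": bulge_peak_mm,
    }
    return cl, sidecar


def voxelize_centerline(cl: Centerline,
                        pixel_size_mm: float = 0.1875,
                        slice_thickness_mm: float = 0.5,
                        margin_mm: float = 2.0) -> MaskStack:
    """Rasterize a z-monotone tubular vessel into binary axial slices.

    Each slice takes the in-plane disc of the locally interpolated
    centerline point and diameter (default spacing emulates a
    187.5 x 187.5 x 500 um^3 acquisition).
    """
    z = cl.points[:, 2]
    if np.any(np.diff(z) <= 0):
        raise ValueError("voxelization requires a z-monotone centerline")
    x, y, d = cl.points[:, 0], cl.points[:, 1], cl.diameters
    r_max = d.max() / 2.0
    x_lo = x.min() - r_max - margin_mm
    y_lo = y.min() - r_max - margin_mm
    nx = int(np.ceil((x.max() + r_max + margin_mm - x_lo) / pixel_size_mm)) + 1
    ny = int(np.ceil((y.max() + r_max + margin_mm - y_lo) / pixel_size_mm)) + 1
    n_slices = int(np.floor(z.max() / slice_thickness_mm)) + 1

    xs = x_lo + np.arange(nx) * pixel_size_mm
    ys = y_lo + np.arange(ny) * pixel_size_mm
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)

    data = np.zeros((n_slices, ny, nx), dtype=bool)
    for k in range(n_slices):
        zk = k * slice_thickness_mm
        if zk < z[0] or zk > z[-1]:
            continue
        cx = np.interp(zk, z, x)
        cy = np.interp(zk, z, y)
        rk = np.interp(zk, z, d) / 2.0
        data[k] = (gx - cx) ** 2 + (gy - cy) ** 2 <= rk**2
    stack = MaskStack(data=data, pixel_size_mm=pixel_size_mm,
                      slice_thickness_mm=slice_thickness_mm)
    # shift so voxel-center coordinates reproduce physical x/y positions
    # is not needed downstream (tortuosity is translation invariant)
    return stack


# -- inflow ------------------------------------------------------------------

def gen_inflow(period: float = 0.1, peak_flow: float = 800.0,
               systole_fraction: float = 0.35, baseline_flow: float = 20.0,
               n_samples: int = 201) -> FlowWaveform:
    """Smooth periodic inflow: squared-half-sine systolic ejection over a
    small diastolic plateau (C1-continuous, q(0) = q(T))."""
    if not 0.0 < systole_fraction < 1.0:
        raise ValueError("systole fraction must be in (0, 1)")
    if peak_flow <= baseline_flow:
        raise ValueError("peak flow must exceed baseline flow")
    t = np.linspace(0.0, period, n_samples)
    ts = systole_fraction * period
    q = np.full_like(t, baseline_flow)
    sy = t <= ts
    q[sy] = baseline_flow + (peak_flow - baseline_flow) \
        * np.sin(np.pi * t[sy] / ts) ** 2
    return FlowWaveform(times=t, q=q, period=period)


# -- cohorts -----------------------------------------------------------------

def gen_cohort(config: GeneratorConfig
               ) -> tuple[CohortTable, CohortTable, dict]:
    """Two-timepoint synthetic cohort with a known lifespan model.

    Six-month biomarkers are drawn uniformly within the observed cohort
    ranges; two-month values differ by signed draws from the observed
    change ranges.  Latent lifespan is
    ``beta0 + beta1 * predictor + N(0, sigma)`` and is right-censored at
    the censor level.  Returns (two-month table, six-month table, truth
    sidecar).
    """
    rng = np.random.default_rng(config.seed)
    n = config.cohort_size
    ids = [f"S{i:03d}" for i in range(n)]

    six = {"subject_id": ids}
    for name, (lo, hi) in BIOMARKER_RANGES.items():
        six[name] = rng.uniform(lo, hi, n)
    two = {"subject_id": ids}
    for name, (lo, hi) in BIOMARKER_RANGES.items():
        if name in DELTA_RANGES:
            dlo, dhi = DELTA_RANGES[name]
            delta = rng.uniform(dlo, dhi, n) * rng.choice([-1.0, 1.0], n)
            two[name] = np.maximum(np.asarray(six[name]) - delta,
                                   0.05 * np.asarray(six[name]))
        else:
            two[name] = np.asarray(six[name]).copy()

    x = np.asarray(six[config.predictor], dtype=float)
    latent = config.tobit_beta0 + config.tobit_beta1 * x \
        + rng.normal(0.0, config.tobit_sigma, n)
    lifespan = np.minimum(latent, config.censor_level)
    censored = latent >= config.censor_level

    def table(cols: dict) -> CohortTable:
        df = pd.DataFrame(cols)
        df["lifespan_months"] = lifespan
        df["censored"] = censored
        return CohortTable(df, censor_level=config.censor_level)

    sidecar = {
        "generator": "gen_cohort",
        "seed": config.seed,
        "predictor": config.predictor,
        "beta0": config.tobit_beta0,
        "beta1": config.tobit_beta1,
        "sigma": config.tobit_sigma,
        "censor_level": config.censor_level,
        "n_censored": int(censored.sum()),
        "latent_lifespan": latent,
    }
    return table(two), table(six), sidecar
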