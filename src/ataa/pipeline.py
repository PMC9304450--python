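"""Per-subject biomarker assembly, correlation analysis, and the
material/rheology sensitivity harness.

`run_biomarkers` turns raw per-subject inputs (WSS bundle, centerline,
shared inflow waveform and outlet parameters) into one biomarker row per
subject.  `run_correlations` joins biomarkers with lifespans and emits the
signed pseudo-r-squared map plus per-biomarker scatter data.
`run_sensitivity` perturbs the wall parameters and rheology on a
reduced-order synthetic surrogate and reports biomarkers normalized by the
baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constitutive import HGOParams, loaded_outer_diameter
from .hemodynamics import (
    BLOOD_DENSITY,
    MMHG_TO_PA,
    MU_AVG,
    CarreauYasudaParams,
    FlowWaveform,
    WindkesselParams,
    carreau_yasuda_viscosity,
    equivalent_windkessel,
    field_summary,
    osi,
    reynolds_max,
    tawss,
    windkessel_pressure,
    womersley,
)
from .geometry import max_diameter, tortuosity_index
from .stats import CohortTable, correlation_map
from . import io as ataa_io
from .synthetic import gen_wss_field

__all__ = [
    "SubjectInputs",
    "RunConfig",
    "run_biomarkers",
    "run_correlations",
    "run_sensitivity",
    "BIOMARKER_COLUMNS",
]

logger = logging.getLogger(__name__)

BIOMARKER_COLUMNS = [
    "P_max", "vMs_max", "Re_max", "OSI_min", "OSI_mean",
    "TAWSS_mean", "TAWSS_max", "TAWSS_min", "Wo", "ATI", "D_max",
]

#: near-wall shear rate (1/s) used to pick the effective viscosity in the
#: rheology comparison
REFERENCE_WALL_SHEAR_RATE = 350.0


@dataclass
class SubjectInputs:
    subject_id: str
    wss_dir: str | Path
    centerline_csv: str | Path
    timepoint: str = "6mo"
    vms_max_kpa: float | None = None


@dataclass
class RunConfig:
    subjects: list[SubjectInputs]
    waveform_csv: str | Path
    windkessel_json: str | Path
    out_dir: str | Path = "."
    seed: int = 0
    sensitivity_factors: tuple[float, ...] = (0.5, 0.75, 1.25, 1.5)
    rheologies: tuple[str, ...] = ("carreau_yasuda", "newtonian")

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.sensitivity_factors):
            raise ValueError("sensitivity factors must be positive")
        for p in (self.waveform_csv, self.windkessel_json):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _subject_row(sub: SubjectInputs, waveform: FlowWaveform,
                 rho: float, mu_avg: float) -> dict:
    series = ataa_io.read_wss_bundle(sub.wss_dir)
    cl = ataa_io.read_centerline_csv(sub.centerline_csv)

    tawss_field = tawss(series)
    osi_field = osi(series)
    row = {
        "subject_id": sub.subject_id,
        "timepoint": sub.timepoint,
        "TAWSS_mean": field_summary(tawss_field, "mean").value,
        "TAWSS_max": field_summary(tawss_field, "max").value,
        "TAWSS_min": field_summary(tawss_field, "min").value,
        "OSI_mean": field_summary(osi_field, "mean").value,
        "OSI_min": field_summary(osi_field, "min").value,
        "ATI": tortuosity_index(cl),
        "D_max": max_diameter(cl),
        "vMs_max": sub.vms_max_kpa if sub.vms_max_kpa is not None else np.nan,
    }
    d_max_m = row["D_max"] * 1e-3
    d_mean_m = float(np.mean(cl.diameters)) * 1e-3
    q_peak = float(np.max(waveform.q)) * 1e-9          # mm^3/s -> m^3/s
    v_max = q_peak / (math.pi * (d_mean_m / 2.0) ** 2)  # m/s
    row["Re_max"] = reynolds_max(v_max, d_max_m, rho=rho, mu_avg=mu_avg)
    row["Wo"] = womersley(d_max_m, waveform.period, rho=rho, mu=mu_avg)
    return row


def run_biomarkers(config: RunConfig, rho: float = BLOOD_DENSITY,
                   mu_avg: float = MU_AVG
                   ) -> tuple[pd.DataFrame, list[dict]]:
    """One biomarker row per subject per timepoint.

    Subject failures are collected and reported, never abort the cohort.
    Returns ``(table, failures)``.
    """
    waveform = ataa_io.read_waveform(config.waveform_csv)
    outlets = ataa_io.read_windkessel_json(config.windkessel_json)
    wk_eq = equivalent_windkessel(list(outlets.values()))
    wk = windkessel_pressure(waveform, wk_eq, n_cycles=20)
    p_max_mmhg = wk.p_max / MMHG_TO_PA

    rows, failures = [], []
    for sub in config.subjects:
        try:
            row = _subject_row(sub, waveform, rho, mu_avg)
            row["P_max"] = p_max_mmhg
            rows.append(row)
        except Exception as exc:
            logger.error("subject %s failed: %s", sub.subject_id, exc)
            failures.append({"subject_id": sub.subject_id, "error": str(exc)})

    cols = ["subject_id", "timepoint"] + BIOMARKER_COLUMNS
    if not rows:
        logger.warning("empty cohort: no biomarker rows produced")
        return pd.DataFrame(columns=cols), failures
    df = pd.DataFrame(rows)[cols]
    return df, failures


def run_correlations(table: CohortTable, variables: list[str] | None = None,
                     out_dir: str | Path | None = None,
                     pseudo_r2_method: str = "mckelvey_zavoina",
                     seed: int | None = None):
    """Correlation map plus per-biomarker scatter data with the censored
    fit line and the censoring cut-off level."""
    cmap = correlation_map(table, variables=variables,
                           pseudo_r2_method=pseudo_r2_method)
    scatters = {}
    for var in (variables or table.biomarker_columns):
        cell = cmap.manifest["cells"][f"{var}|LS"]
        sc = pd.DataFrame({
            "subject_id": table.df[table.subject_col],
            var: table.df[var],
            "lifespan_months": table.df[table.lifespan_col],
            "censored": table.df[table.censored_col].astype(int),
        })
        sc["fit_intercept"] = cell["beta"][0]
        sc["fit_slope"] = cell["beta"][1]
        sc["censor_level"] = table.censor_level
        scatters[var] = sc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ataa_io.write_csv(cmap.signed(), out / "correlation_map.csv",
                          seed=seed, index=True)
        (out / "correlation_manifest.json").write_text(cmap.manifest_json())
        for var, sc in scatters.items():
            safe = var.replace("/", "_")
            ataa_io.write_csv(sc, out / f"scatter_{safe}.csv", seed=seed)
    return cmap, scatters


def _surrogate_biomarkers(params: HGOParams, waveform: FlowWaveform,
                          outlets: list[WindkesselParams],
                          mu_eff: float,
                          unloaded_outer_diameter_mm: float,
                          unloaded_thickness_mm: float,
                          lambda_z: float,
                          wss_seed: int,
                          rho: float = BLOOD_DENSITY) -> dict:
    """Reduced-order biomarker vector coupling wall stiffness to the
    pressurized geometry.

    The systolic diameter comes from thin-wall equilibrium at the
    Windkessel peak pressure; wall shear scales as
    ``mu * Q / D^3`` (fully developed flow), so TAWSS statistics are
    rescaled from a fixed reference field.  OSI is shear-scale invariant
    and P_max is wall-independent in this surrogate.
    """
    wk_eq = equivalent_windkessel(outlets)
    wk = windkessel_pressure(waveform, wk_eq, n_cycles=20)
    p_max_mmhg = wk.p_max / MMHG_TO_PA
    _, d_sys_mm = loaded_outer_diameter(
        params, p_max_mmhg, lambda_z,
        unloaded_outer_diameter_mm, unloaded_thickness_mm)
    d_m = d_sys_mm * 1e-3
    q_peak = float(np.max(waveform.q)) * 1e-9
    v_max = q_peak / (math.pi * (d_m / 2.0) ** 2)

    series, sidecar = gen_wss_field(seed=wss_seed, period=waveform.period)
    tawss_field = np.asarray(sidecar["tawss_truth_pa"])
    osi_field = np.asarray(sidecar["osi_truth"])
    mu_ref = carreau_yasuda_viscosity(REFERENCE_WALL_SHEAR_RATE)
    d_ref_mm = unloaded_outer_diameter_mm * 1.4  # nominal reference state
    wss_scale = (mu_eff / mu_ref) * (d_ref_mm / d_sys_mm) ** 3
    tawss_field = tawss_field * wss_scale

    return {
        "P_max": p_max_mmhg,
        "Re_max": reynolds_max(v_max, d_m, rho=rho, mu_avg=mu_eff),
        "OSI_min": field_summary(osi_field, "min").value,
        "OSI_mean": field_summary(osi_field, "mean").value,
        "TAWSS_mean": field_summary(tawss_field, "mean").value,
        "TAWSS_max": field_summary(tawss_field, "max").value,
        "TAWSS_min": field_summary(tawss_field, "min").value,
        "Wo": womersley(d_m, waveform.period, rho=rho, mu=mu_eff),
        "D_max": d_sys_mm,
    }


def run_sensitivity(baseline: HGOParams, waveform: FlowWaveform,
                    outlets: list[WindkesselParams],
                    factors: tuple[float, ...] = (0.5, 0.75, 1.25, 1.5),
                    parameters: tuple[str, ...] = ("c", "k1"),
                    rheologies: tuple[str, ...] = ("newtonian",),
                    unloaded_outer_diameter_mm: float = 1.2,
                    unloaded_thickness_mm: float = 0.15,
                    lambda_z: float = 1.0,
                    seed: int = 0,
                    cy_params: CarreauYasudaParams | None = None
                    ) -> pd.DataFrame:
    """Normalized sensitivity table on the synthetic surrogate.

    One row per (parameter, factor) plus one per alternative rheology;
    every biomarker is reported as value / baseline value.  Perturbations
    producing invalid parameters are skipped with a log entry.
    """
    mu_cy = float(carreau_yasuda_viscosity(REFERENCE_WALL_SHEAR_RATE,
                                           cy_params))

    def evaluate(params: HGOParams, mu_eff: float) -> dict:
        return _surrogate_biomarkers(
            params, waveform, outlets, mu_eff,
            unloaded_outer_diameter_mm, unloaded_thickness_mm, lambda_z,
            wss_seed=seed)

    base_vals = evaluate(baseline, mu_cy)
    rows = [{"parameter": "baseline", "factor": 1.0,
             **{k: 1.0 for k in base_vals}}]

    for pname in parameters:
        for fac in factors:
            kwargs = baseline.to_dict()
            new = {
                "c": kwargs["c_mpa"], "k1": kwargs["k1_mpa"],
                "k2": kwargs["k2"], "kappa": kwargs["kappa"],
                "gamma": kwargs["gamma_rad"],
            }
            new[pname] = new[pname] * fac
            try:
                perturbed = HGOParams(new["c"], new["k1"], new["k2"],
                                      new["kappa"], new["gamma"],
                                      kappa_max=baseline.kappa_max)
                vals = evaluate(perturbed, mu_cy)
            except (ValueError, RuntimeError) as exc:
                logger.warning("skipping %s x %g: %s", pname, fac, exc)
                continue
            rows.append({"parameter": pname, "factor": fac,
                         **{k: v / base_vals[k] for k, v in vals.items()}})

    for rheo in rheologies:
        if rheo == "carreau_yasuda":
            continue  # the baseline
        if rheo != "newtonian":
            logger.warning("unknown rheology %r skipped", rheo)
            continue
        vals = evaluate(baseline, MU_AVG)
        rows.append({"parameter": "rheology_newtonian", "factor": 1.0,
                     **{k: v / base_vals[k] for k, v in vals.items()}})

    return pd.DataFrame(rows)
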