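"""Plain-text I/O for the formats shared across modules.

All tabular artifacts are CSV (with an optional ``#``-prefixed provenance
header line), sidecars and parameter sets are JSON.  WSS time series use a
two-file CSV bundle (``mesh.csv`` + ``wss.csv`` long format).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constitutive import BiaxialSample
from .geometry import Centerline
from .hemodynamics import FlowWaveform, WindkesselParams, WSSTimeSeries

__all__ = [
    "provenance_header",
    "write_csv",
    "read_biaxial_csv",
    "write_biaxial_csv",
    "read_centerline_csv",
    "write_centerline_csv",
    "read_wss_bundle",
    "write_wss_bundle",
    "read_waveform",
    "write_waveform",
    "read_windkessel_json",
    "write_windkessel_json",
    "write_sidecar",
    "read_sidecar",
]


def provenance_header(seed=None, config=None) -> str:
    parts = [f"tool=ataa-{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        parts.append(f"config_sha={digest}")
    return "# " + " ".join(parts)


def write_csv(df: pd.DataFrame, path, seed=None, config=None,
              index: bool = False) -> None:
    """Write a CSV with a leading provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config) + "\n")
        df.to_csv(fh, index=index)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# -- biaxial -----------------------------------------------------------------

def write_biaxial_csv(sample: BiaxialSample, path, seed=None) -> None:
    df = pd.DataFrame({
        "protocol_id": sample.protocol_id,
        "lambda_theta": sample.lambda_theta,
        "lambda_z": sample.lambda_z,
        "sigma_theta_mpa": sample.sigma_theta,
        "sigma_z_mpa": sample.sigma_z,
    })
    write_csv(df, path, seed=seed)
    if sample.unloaded_outer_diameter_mm is not None:
        write_sidecar(Path(path).with_suffix(".geometry.json"), {
            "unloaded_outer_diameter_mm": sample.unloaded_outer_diameter_mm,
            "unloaded_thickness_mm": sample.unloaded_thickness_mm,
        })


def read_biaxial_csv(path) -> BiaxialSample:
    df = _read_csv(path)
    geom_path = Path(path).with_suffix(".geometry.json")
    d_out = h = None
    if geom_path.exists():
        geom = read_sidecar(geom_path)
        d_out = geom.get("unloaded_outer_diameter_mm")
        h = geom.get("unloaded_thickness_mm")
    return BiaxialSample(
        lambda_theta=df["lambda_theta"].to_numpy(),
        lambda_z=df["lambda_z"].to_numpy(),
        sigma_theta=df["sigma_theta_mpa"].to_numpy(),
        sigma_z=df["sigma_z_mpa"].to_numpy(),
        protocol_id=df["protocol_id"].to_numpy(dtype=object),
        unloaded_outer_diameter_mm=d_out,
        unloaded_thickness_mm=h,
    )


# -- centerline --------------------------------------------------------------

def write_centerline_csv(cl: Centerline, path, seed=None) -> None:
    df = pd.DataFrame({
        "point_index": np.arange(len(cl)),
        "x_mm": cl.points[:, 0],
        "y_mm": cl.points[:, 1],
        "z_mm": cl.points[:, 2],
        "diameter_mm": cl.diameters,
        "region": cl.regions if cl.regions is not None else "",
    })
    write_csv(df, path, seed=seed)


def read_centerline_csv(path) -> Centerline:
    df = _read_csv(path).sort_values("point_index")
    regions = None
    if "region" in df.columns and df["region"].notna().any() \
            and (df["region"].astype(str) != "").any():
        regions = df["region"].to_numpy(dtype=object)
    return Centerline(
        points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        diameters=df["diameter_mm"].to_numpy(),
        regions=regions,
    )


# -- WSS bundle --------------------------------------------------------------

def write_wss_bundle(series: WSSTimeSeries, directory, seed=None) -> None:
    """Write ``mesh.csv`` (node table) and ``wss.csv`` (long format)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mesh = pd.DataFrame({
        "node_id": np.arange(series.n_nodes),
        "x": series.points[:, 0],
        "y": series.points[:, 1],
        "z": series.points[:, 2],
        "region": (series.regions if series.regions is not None else ""),
    })
    write_csv(mesh, directory / "mesh.csv", seed=seed)
    n_t, n_n = len(series.times), series.n_nodes
    long = pd.DataFrame({
        "node_id": np.tile(np.arange(n_n), n_t),
        "time_s": np.repeat(series.times, n_n),
        "tx": series.tau[:, :, 0].ravel(),
        "ty": series.tau[:, :, 1].ravel(),
        "tz": series.tau[:, :, 2].ravel(),
    })
    write_csv(long, directory / "wss.csv", seed=seed)


def read_wss_bundle(directory) -> WSSTimeSeries:
    directory = Path(directory)
    mesh = _read_csv(directory / "mesh.csv").sort_values("node_id")
    long = _read_csv(directory / "wss.csv")
    times = np.sort(long["time_s"].unique())
    n_n = len(mesh)
    tau = np.empty((len(times), n_n, 3))
    long = long.sort_values(["time_s", "node_id"])
    for k, t in enumerate(times):
        rows = long[long["time_s"] == t]
        if len(rows) != n_n:
            raise ValueError(f"timestep {t} has {len(rows)} rows, "
                             f"expected {n_n}")
        tau[k] = rows[["tx", "ty", "tz"]].to_numpy()
    regions = None
    if "region" in mesh.columns and (mesh["region"].astype(str) != "").any():
        regions = mesh["region"].to_numpy(dtype=object)
    return WSSTimeSeries(points=mesh[["x", "y", "z"]].to_numpy(),
                         times=times, tau=tau, regions=regions)


# -- waveform / windkessel ---------------------------------------------------

def write_waveform(waveform: FlowWaveform, path, seed=None) -> None:
    df = pd.DataFrame({"time_s": waveform.times, "q_mm3_per_s": waveform.q})
    write_csv(df, path, seed=seed)
    write_sidecar(Path(path).with_suffix(".json"),
                  {"period_s": waveform.period})


def read_waveform(path) -> FlowWaveform:
    df = _read_csv(path)
    meta = read_sidecar(Path(path).with_suffix(".json"))
    return FlowWaveform(times=df["time_s"].to_numpy(),
                        q=df["q_mm3_per_s"].to_numpy(),
                        period=float(meta["period_s"]))


def write_windkessel_json(params: dict[str, WindkesselParams], path) -> None:
    payload = {name: {"r_p": p.r_p, "c_wk": p.c_wk, "r_d": p.r_d}
               for name, p in params.items()}
    write_sidecar(path, payload)


def read_windkessel_json(path) -> dict[str, WindkesselParams]:
    raw = read_sidecar(path)
    return {name: WindkesselParams(outlet_name=name, **vals)
            for name, vals in raw.items()}


# -- sidecars ----------------------------------------------------------------

def write_sidecar(path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
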