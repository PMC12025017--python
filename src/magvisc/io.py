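"""File formats and configuration.

CSV carries sweeps, standards and traces (6 significant digits, for humans);
JSON carries calibration models, TEG parameters and comparisons (full double
precision, for round-trips). Frequencies are serialized in Hz and amplitudes
in V. The structured config is TOML with [sensor], [coil] and [liquid]
tables whose keys carry explicit unit suffixes (ls_m, I_AC_A, ...); missing
keys fall back to the package defaults.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationModel, CalibrationPoint
from .coagulation import CoagulationRun, DampingTrace, TEGTrace
from .physics import (
    DEFAULTS,
    CoilDrive,
    Liquid,
    SensorElement,
    SweepCurve,
    default_coil,
    default_sensor,
)

__all__ = [
    "load_config",
    "read_sweep_csv",
    "write_sweep_csv",
    "read_run_csv",
    "write_run_csv",
    "read_standards_csv",
    "write_calibration_json",
    "read_calibration_json",
    "write_damping_trace_csv",
    "write_teg_trace_csv",
    "write_params_json",
    "file_sha256",
]

log = logging.getLogger("magvisc")

_CSV_FLOAT_FMT = "%.6g"


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None = None) -> tuple[SensorElement, CoilDrive, Liquid]:
    """Load sensor/coil/liquid from a TOML config; defaults fill the gaps."""
    raw: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        log.info("config %s (sha256 %s)", path, file_sha256(path)[:12])

    sensor_keys = {
        "ls_m": "ls", "ws_m": "ws", "hs_m": "hs", "rho_s_kg_m3": "rho_s",
        "E_pa": "E", "D0_kg_m_s": "D0", "lambda_s": "lambda_s",
        "M_s_a_m": "M_s", "M_DC_a_m": "M_DC", "chi_AC": "chi_AC",
    }
    coil_keys = {
        "N": "N", "lc_m": "lc", "Ac_m2": "Ac", "km": "km",
        "I_AC_A": "I_AC", "I_bias_A": "I_bias",
        "sweep_start_hz": "sweep_start", "sweep_stop_hz": "sweep_stop",
        "sweep_step_hz": "sweep_step",
    }
    sensor_over = {
        dest: raw.get("sensor", {})[k]
        for k, dest in sensor_keys.items()
        if k in raw.get("sensor", {})
    }
    coil_over = {
        dest: raw.get("coil", {})[k]
        for k, dest in coil_keys.items()
        if k in raw.get("coil", {})
    }
    # A [drive] table is accepted as an alias for the coil's drive settings.
    for k, dest in coil_keys.items():
        if k in raw.get("drive", {}):
            coil_over[dest] = raw["drive"][k]
    liquid_tab = raw.get("liquid", {})
    liquid = Liquid(
        eta_L=liquid_tab.get("eta_pa_s", DEFAULTS["liquid"]["eta_pa_s"]),
        rho_L=liquid_tab.get("rho_kg_m3", DEFAULTS["liquid"]["rho_kg_m3"]),
    )
    return default_sensor(**sensor_over), default_coil(**coil_over), liquid


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def write_sweep_csv(sweep: SweepCurve, path: str | Path) -> None:
    df = pd.DataFrame({"frequency_hz": sweep.freqs, "amplitude_v": sweep.amps})
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FMT)


def read_sweep_csv(path: str | Path, t: float | None = None) -> SweepCurve:
    df = pd.read_csv(path)
    for col in ("frequency_hz", "amplitude_v"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return SweepCurve(
        freqs=df["frequency_hz"].to_numpy(),
        amps=df["amplitude_v"].to_numpy(),
        t=t,
        meta={"source": str(path)},
    )


def write_run_csv(sweeps: list[SweepCurve], path: str | Path) -> None:
    """Long-format run: columns time_s, frequency_hz, amplitude_v."""
    frames = [
        pd.DataFrame(
            {"time_s": s.t, "frequency_hz": s.freqs, "amplitude_v": s.amps}
        )
        for s in sweeps
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_CSV_FLOAT_FMT
    )


def read_run_csv(path: str | Path) -> list[SweepCurve]:
    df = pd.read_csv(path)
    for col in ("time_s", "frequency_hz", "amplitude_v"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    sweeps = []
    for t, grp in df.groupby("time_s", sort=True):
        sweeps.append(
            SweepCurve(
                freqs=grp["frequency_hz"].to_numpy(),
                amps=grp["amplitude_v"].to_numpy(),
                t=float(t),
                meta={"source": str(path)},
            )
        )
    return sweeps


# ---------------------------------------------------------------------------
# Standards and calibration model
# ---------------------------------------------------------------------------

def read_standards_csv(path: str | Path) -> list[CalibrationPoint]:
    """Viscosity standards: label, viscosity_pa_s, density_kg_m3,
    resonant_amplitude_v; repeated labels are replicates whose amplitudes are
    averaged before inversion."""
    df = pd.read_csv(path)
    required = ("label", "viscosity_pa_s", "density_kg_m3", "resonant_amplitude_v")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = df.index[df["resonant_amplitude_v"] <= 0]
    if len(bad):
        raise ValueError(f"{path}: non-positive amplitude at data line {bad[0] + 2}")
    points = []
    for label, grp in df.groupby("label", sort=False):
        amps = grp["resonant_amplitude_v"].to_numpy(dtype=float)
        vdv = float(np.sqrt(grp["viscosity_pa_s"].iloc[0] * grp["density_kg_m3"].iloc[0]))
        points.append(
            CalibrationPoint(
                vdv=vdv,
                u_r=float(amps.mean()),
                u_r_sd=float(amps.std(ddof=1)) if len(amps) > 1 else 0.0,
                n_rep=len(amps),
                label=str(label),
            )
        )
    return points


def write_calibration_json(
    model: CalibrationModel, path: str | Path, source: str | Path | None = None
) -> None:
    payload = model.to_dict()
    payload["provenance"] = {
        "package_version": __version__,
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "input_file": str(source) if source else None,
        "input_sha256": file_sha256(source) if source else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_calibration_json(path: str | Path) -> CalibrationModel:
    return CalibrationModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Traces and parameters
# ---------------------------------------------------------------------------

def write_damping_trace_csv(trace: DampingTrace, path: str | Path) -> None:
    pd.DataFrame({"time_min": trace.t, "x": trace.x}).to_csv(
        path, index=False, float_format=_CSV_FLOAT_FMT
    )


def write_teg_trace_csv(trace: TEGTrace, path: str | Path) -> None:
    pd.DataFrame({"time_min": trace.t, "amplitude_mm": trace.amplitude}).to_csv(
        path, index=False, float_format=_CSV_FLOAT_FMT
    )


def write_params_json(params: dict, path: str | Path, **extra) -> None:
    """TEG parameters with missing values as JSON nulls, never 0."""
    payload = {
        "R_min": params.get("R_time"),
        "K_min": params.get("K_time"),
        "alpha_deg": params.get("alpha_angle"),
        "MA_mm": params.get("MA"),
    }
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
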