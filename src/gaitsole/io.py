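"""Readers, writers and run configuration.

All on-disk formats are plain text: recordings and staircases are CSV,
calibrations/metrics/sidecars are JSON, scenario configuration is YAML.
Every writer stamps its output (or its JSON sidecar) with a hash of the
parameters that produced it, so a run can be re-identified and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import FsrCalibration, PiezoCalibration, StaircaseRecording
from .insole_sim import InsoleRecording

__all__ = [
    "config_hash",
    "read_recording",
    "write_recording",
    "read_staircase",
    "write_staircase",
    "write_calibration",
    "read_calibration",
    "load_run_config",
]

RECORDING_COLUMNS = ["time_s"] + [f"ch{i:02d}" for i in range(16)]


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable parameter object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_recording(rec: InsoleRecording, path) -> Path:
    """Write a recording as CSV (time_s, ch00..ch15) plus a JSON sidecar.

    Time is stored at microsecond precision and codes as integers, so a
    write/read round trip is lossless and byte-stable for a fixed seed.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(RECORDING_COLUMNS) + "\n")
        for t, row in zip(rec.time, rec.channels):
            fh.write(f"{t:.6f}," + ",".join(str(int(c)) for c in row) + "\n")
    meta = {
        "foot": rec.foot,
        "sampling_rate": rec.sampling_rate,
        **rec.metadata,
    }
    meta["config_hash"] = config_hash(meta)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_recording(path, adc_bits: int = 10) -> InsoleRecording:
    """Read and validate a recording CSV (+ sidecar if present).

    Raises ``ValueError`` naming the offending row on a malformed header,
    non-monotone time, or codes outside the ADC range.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != RECORDING_COLUMNS:
        raise ValueError(
            f"{path.name}: expected columns {RECORDING_COLUMNS}, got {list(df.columns)}"
        )
    time = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(time) <= 0)
    if bad.size:
        raise ValueError(f"{path.name}: time not strictly increasing at row {bad[0] + 1}")
    codes = df[RECORDING_COLUMNS[1:]].to_numpy()
    meta: dict = {}
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        adc_bits = int(meta.get("bits", adc_bits))
    max_code = 2**adc_bits - 1
    rows, cols = np.nonzero((codes < 0) | (codes > max_code))
    if rows.size:
        raise ValueError(
            f"{path.name}: code {codes[rows[0], cols[0]]} out of range "
            f"[0, {max_code}] at row {rows[0]}"
        )
    return InsoleRecording(
        foot=meta.get("foot", "unknown"),
        time=time,
        channels=codes,
        sampling_rate=float(meta.get("sampling_rate", 60.0)),
        metadata=meta,
    )


def write_staircase(rec: StaircaseRecording, path) -> Path:
    """Write a calibration session CSV: time_s, loadcell_units, sensor_volts."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s,loadcell_units,sensor_volts\n")
        for t, w, v in zip(rec.time, rec.reference_weight, rec.sensor_voltage):
            fh.write(f"{t:.6f},{w:.6f},{v:.9f}\n")
    return path


def read_staircase(path) -> StaircaseRecording:
    df = pd.read_csv(path)
    expected = ["time_s", "loadcell_units", "sensor_volts"]
    if list(df.columns) != expected:
        raise ValueError(f"{Path(path).name}: expected columns {expected}")
    return StaircaseRecording(
        time=df["time_s"].to_numpy(dtype=float),
        reference_weight=df["loadcell_units"].to_numpy(dtype=float),
        sensor_voltage=df["sensor_volts"].to_numpy(dtype=float),
    )


def write_calibration(cal: FsrCalibration | PiezoCalibration, path) -> Path:
    """Serialize a fitted calibration model as JSON."""
    if isinstance(cal, FsrCalibration):
        doc = {
            "sensor_type": "fsr",
            "model": "power_law",
            "params": {"a": cal.coefficient_a, "b": cal.exponent_b},
            "phase": cal.phase,
            "fit_r2": cal.fit_r2,
            "hysteresis_metric": cal.hysteresis_metric,
            "units": {"weight": "g", "resistance": "kohm"},
        }
    else:
        doc = {
            "sensor_type": "piezo",
            "model": "linear",
            "params": {"m": cal.slope_m, "c": cal.intercept_c},
            "fit_r2": cal.fit_r2,
            "units": {"weight": "kg", "voltage": "V"},
        }
    doc["config_hash"] = config_hash(doc)
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=lambda x: None)
        fh.write("\n")
    return path


def read_calibration(path) -> FsrCalibration | PiezoCalibration:
    doc = json.loads(Path(path).read_text())
    if doc["model"] == "power_law":
        return FsrCalibration(
            coefficient_a=doc["params"]["a"],
            exponent_b=doc["params"]["b"],
            phase=doc.get("phase", "offloading"),
            fit_r2=doc.get("fit_r2") or float("nan"),
            hysteresis_metric=doc.get("hysteresis_metric") or float("nan"),
        )
    if doc["model"] == "linear":
        return PiezoCalibration(
            slope_m=doc["params"]["m"],
            intercept_c=doc["params"]["c"],
            fit_r2=doc.get("fit_r2") or float("nan"),
        )
    raise ValueError(f"unknown calibration model {doc['model']!r}")


_RUNCONFIG_SCHEMA: dict = {
    "scenario": {
        "profile": {
            "body_weight",
            "stance_duration",
            "stride_duration",
            "peak_ratio",
            "valley_ratio",
            "cadence_jitter_sd",
        },
        "fsr_preset": None,
        "n_cycles": None,
    },
    "chain": None,
    "calibration": None,
    "pipeline": {"zero_threshold", "min_samples", "discard_edges", "n_points"},
    "seed": None,
    "log_level": None,
}


def load_run_config(path) -> dict:
    """Load and schema-validate a YAML run configuration.

    Unknown keys at any validated level are rejected so typos fail loudly
    rather than silently falling back to defaults.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError("run config must be a YAML mapping")
    _validate_keys(doc, _RUNCONFIG_SCHEMA, "config")
    return doc


def _validate_keys(doc: dict, schema, where: str) -> None:
    for key, val in doc.items():
        if key not in schema:
            raise ValueError(f"unknown key {key!r} in {where}")
        sub = schema[key]
        if isinstance(sub, dict) and isinstance(val, dict):
            _validate_keys(val, sub, f"{where}.{key}")
        elif isinstance(sub, set) and isinstance(val, dict):
            extra = set(val) - sub
            if extra:
                raise ValueError(f"unknown keys {sorted(extra)} in {where}.{key}")
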