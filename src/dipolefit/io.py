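"""Reading and writing recordings, sensor layouts and run configurations.

The native on-disk form of a recording is plain text: a signals CSV (one row
per sensor, one column per sample), a sensor position file (``label x y z``
in cm), and a JSON sidecar holding the head model, seeds and — for synthetic
data — the ground truth with its propagation draws.  All floats are written
with 17 significant digits, so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .forward_model import (
    DipoleParameters,
    EEGRecording,
    SimulationTruth,
)
from .head_geometry import HeadModel, SensorArray

__all__ = [
    "signal_paths",
    "write_recording",
    "read_recording",
    "write_sensors",
    "read_sensors",
    "load_config",
]

_FMT = "%.17g"


def signal_paths(prefix: str | Path) -> dict[str, Path]:
    prefix = Path(prefix)
    return {
        "signals": prefix.with_name(prefix.name + ".signals.csv"),
        "sensors": prefix.with_name(prefix.name + ".sensors.txt"),
        "meta": prefix.with_name(prefix.name + ".meta.json"),
    }


def write_sensors(sensors: SensorArray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# montage: {sensors.montage_name}\n")
        fh.write("# columns: label x y z (cm, head frame)\n")
        for label, pos in zip(sensors.labels, sensors.positions):
            fh.write(f"{label} {_FMT % pos[0]} {_FMT % pos[1]} {_FMT % pos[2]}\n")


def read_sensors(path: str | Path) -> SensorArray:
    labels, rows, montage = [], [], "custom"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("# montage:"):
                montage = line.split(":", 1)[1].strip()
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'label x y z'")
            labels.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
    return SensorArray(
        positions=np.array(rows), montage_name=montage, labels=tuple(labels)
    )


def _truth_to_json(truth: SimulationTruth) -> dict:
    return {
        "dipoles": [
            {
                "location": d.location.tolist(),
                "orientation": d.orientation.tolist(),
                "strength": d.strength,
            }
            for d in truth.dipoles
        ],
        "conductivity": truth.conductivity.tolist(),
        "attenuation": truth.attenuation.tolist(),
        "noiseless": truth.noiseless.tolist(),
        "sigma": truth.sigma,
    }


def _truth_from_json(obj: dict) -> SimulationTruth:
    return SimulationTruth(
        dipoles=tuple(
            DipoleParameters(d["location"], d["orientation"], d["strength"])
            for d in obj["dipoles"]
        ),
        conductivity=np.array(obj["conductivity"], dtype=float),
        attenuation=np.array(obj["attenuation"], dtype=float),
        noiseless=np.array(obj["noiseless"], dtype=float),
        sigma=float(obj["sigma"]),
    )


def write_recording(recording: EEGRecording, prefix: str | Path) -> dict[str, Path]:
    """Write signals CSV + sensor file + JSON sidecar; returns the paths."""
    paths = signal_paths(prefix)
    paths["signals"].parent.mkdir(parents=True, exist_ok=True)
    with open(paths["signals"], "w") as fh:
        n = recording.n_samples
        fh.write("label," + ",".join(f"t{k}" for k in range(n)) + "\n")
        for label, row in zip(recording.sensors.labels, recording.signals):
            fh.write(label + "," + ",".join(_FMT % v for v in row) + "\n")
    write_sensors(recording.sensors, paths["sensors"])
    meta = {
        "units": "uV",
        "head": {
            "radius_cm": recording.head.radius_cm,
            "conductivity_low": recording.head.conductivity_low,
            "conductivity_high": recording.head.conductivity_high,
        },
        "seed": recording.seed if isinstance(recording.seed, int) else None,
        "sample_rate": recording.sample_rate,
        "n_samples": recording.n_samples,
        "truth": _truth_to_json(recording.truth) if recording.truth else None,
    }
    with open(paths["meta"], "w") as fh:
        json.dump(meta, fh, indent=1)
    return paths


def read_recording(
    signals: str | Path,
    sensors: str | Path | None = None,
    meta: str | Path | None = None,
) -> EEGRecording:
    """Read a recording written by :func:`write_recording`.

    ``sensors``/``meta`` default to the sibling files of the signals CSV.
    The sidecar is required (it carries the head model); the sensor file row
    count must match the CSV.
    """
    signals = Path(signals)
    stem = signals.name.removesuffix(".signals.csv")
    sensors = Path(sensors) if sensors else signals.with_name(stem + ".sensors.txt")
    meta = Path(meta) if meta else signals.with_name(stem + ".meta.json")
    if not meta.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {meta}")
    sensor_array = read_sensors(sensors)
    rows = []
    with open(signals) as fh:
        header = fh.readline()
        if not header.startswith("label,"):
            raise ValueError(f"{signals}:1: expected a 'label,t0,...' header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(",")
            vals = []
            for col, cell in enumerate(cells[1:], start=2):
                try:
                    vals.append(float(cell))
                except ValueError as exc:
                    raise ValueError(
                        f"{signals}: non-numeric value at row {lineno}, column {col}"
                    ) from exc
            rows.append(vals)
    data = np.array(rows, dtype=float)
    if data.shape[0] != sensor_array.n_sensors:
        raise ValueError(
            f"{signals}: {data.shape[0]} signal rows but "
            f"{sensor_array.n_sensors} sensors in {sensors}"
        )
    with open(meta) as fh:
        info = json.load(fh)
    head = HeadModel(
        radius_cm=info["head"]["radius_cm"],
        conductivity_low=info["head"]["conductivity_low"],
        conductivity_high=info["head"]["conductivity_high"],
    )
    truth = _truth_from_json(info["truth"]) if info.get("truth") else None
    return EEGRecording(
        signals=data,
        sensors=sensor_array,
        head=head,
        truth=truth,
        sample_rate=info.get("sample_rate"),
        seed=info.get("seed"),
    )


# ---------------------------------------------------------------------------
# run configuration

_SCHEMA = {
    "head": {"radius_cm", "conductivity"},
    "sensors": {"montage", "count", "seed"},
    "dipoles": None,  # "table1" or a list of dipole dicts
    "simulation": {"n_samples", "target_snr", "sigma", "seed"},
    "solver": {
        "mode",
        "max_iterations",
        "multistart",
        "seed",
        "s_max",
        "initial_guess",
    },
    "sweep": {
        "sensor_counts",
        "sample_counts",
        "n_repeats",
        "target_snr",
        "noise_sigma",
        "base_seed",
        "mode",
        "fit_jointly",
    },
}


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    for key, val in cfg.items():
        if key not in _SCHEMA:
            raise ValueError(f"{path}: unknown config section {key!r}")
        allowed = _SCHEMA[key]
        if allowed is not None:
            if not isinstance(val, dict):
                raise ValueError(f"{path}: section {key!r} must be a mapping")
            unknown = set(val) - allowed
            if unknown:
                raise ValueError(
                    f"{path}: unknown keys in section {key!r}: {sorted(unknown)}"
                )
    return cfg
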