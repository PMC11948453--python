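"""File formats and run configuration.

Traces travel either as flat little-endian float32 binaries (current in
nA) with a JSON sidecar header, or inside an HDF5 container; event tables
and spike-in series as CSV; run configuration as YAML/JSON validated
against the dataclass schema (unknown keys are rejected).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .detect import TranslocationEvent
from .simulate import IonTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_trace_hdf5",
    "read_trace_hdf5",
    "write_events_csv",
    "read_events_csv",
    "RunConfig",
    "load_config",
    "config_hash",
]

EVENT_CSV_HEADER = (
    "# porecount event table v1; start_idx/end_idx are 0-based half-open "
    "sample indices; currents in nA; dwell in microseconds\n"
)


def write_trace(path, trace: IonTrace) -> None:
    """Write samples as little-endian float32 with a JSON sidecar header."""
    path = Path(path)
    trace.samples.astype("<f4").tofile(path)
    header = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "voltage_mV": trace.voltage_mV,
        "units": "nA",
        "dtype": "<f4",
        "n_samples": int(trace.samples.size),
        "source": trace.source,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))


def read_trace(path) -> IonTrace:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar header {sidecar}")
    header = json.loads(sidecar.read_text())
    for key in ("sampling_rate_hz", "units", "n_samples"):
        if key not in header:
            raise ValueError(f"sidecar header missing {key!r}")
    if header["units"] != "nA":
        raise ValueError(f"unsupported current units {header['units']!r}")
    if header["sampling_rate_hz"] <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    samples = np.fromfile(path, dtype=header.get("dtype", "<f4"))
    if samples.size != header["n_samples"]:
        raise ValueError(
            f"truncated payload: {samples.size} samples, header says {header['n_samples']}"
        )
    return IonTrace(samples.astype(np.float64), header["sampling_rate_hz"],
                    header.get("voltage_mV", 0.0), source=str(path))


def write_trace_hdf5(path, trace: IonTrace) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("current_nA", data=trace.samples.astype("<f4"))
        ds.attrs["sampling_rate_hz"] = trace.sampling_rate_hz
        ds.attrs["voltage_mV"] = trace.voltage_mV
        ds.attrs["units"] = "nA"


def read_trace_hdf5(path) -> IonTrace:
    with h5py.File(path, "r") as fh:
        if "current_nA" not in fh:
            raise ValueError("HDF5 container lacks a 'current_nA' dataset")
        ds = fh["current_nA"]
        return IonTrace(np.asarray(ds, dtype=np.float64),
                        float(ds.attrs["sampling_rate_hz"]),
                        float(ds.attrs.get("voltage_mV", 0.0)), source=str(path))


def write_events_csv(path, events) -> None:
    """Write an event table (list of TranslocationEvent or DataFrame) to CSV."""
    from .detect import events_to_frame

    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    with open(path, "w") as fh:
        fh.write(EVENT_CSV_HEADER)
        df.to_csv(fh, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class DetectConfig:
    window_s: float = 0.05
    k_sigma: float = 6.0
    min_dur_us: float = 20.0
    max_dur_us: float = 100_000.0
    edge_frac: float = 0.1


@dataclass
class SimulateConfig:
    duration_s: float = 2.0
    event_rate_hz: float = 50.0
    open_pore_current_nA: float = 10.0
    baseline_noise_sd_nA: float = 0.03
    sampling_rate_hz: float = 500_000.0
    voltage_mV: float = 150.0
    class_mixture: dict = field(default_factory=lambda: {"fragment": 0.5, "mtDNA": 0.5})


@dataclass
class ClassifyConfig:
    kernel_scale: float = 2.0
    box_constraint: float = 1.0
    n_folds: int = 5
    train_events_per_class: int = 500


@dataclass
class OpticalConfig:
    k_rms: float = 10.0
    min_frames: int = 1
    pre_window_ms: float = 5.0
    post_window_ms: float = 1.0


@dataclass
class RunConfig:
    """Full pipeline configuration; one global seed drives every stage."""

    seed: int = 0
    schema_version: int = 1
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    optical: OpticalConfig = field(default_factory=OpticalConfig)


def _from_dict(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        sub = {"simulate": SimulateConfig, "detect": DetectConfig,
               "classify": ClassifyConfig, "optical": OpticalConfig}.get(key)
        kwargs[key] = _from_dict(sub, value) if sub and isinstance(value, dict) else value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return _from_dict(RunConfig, data)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration (recorded in outputs)."""
    canon = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
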