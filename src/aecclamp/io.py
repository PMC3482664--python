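"""File formats: traces, kernels, reports, run configuration.

Traces and kernels are delimited text (tab-separated, commented
``# key = value`` header) chosen for diffability; an HDF5 container is
available for large runs (``.h5`` suffix).  Calibration reports are
JSON.  Run configuration is YAML with strict schema validation (unknown
keys rejected).  Every artifact written by a run embeds the
configuration hash and seed so the run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibration import CalibrationReport
from .errors import InvalidArgumentError, ParseError
from .kernels import Kernel, NoiseProtocol, SeparationResult
from .rig import RCParams, RigConfig, SimulationRecord, SpikeGenParams

__all__ = [
    "Trace",
    "read_trace",
    "write_trace",
    "read_kernel",
    "write_kernel",
    "report_to_dict",
    "write_report",
    "RunConfig",
    "read_config",
    "write_config",
    "config_hash",
]

_FLOAT_FMT = "%.17g"  # full double precision for lossless round trips


@dataclass
class Trace:
    """Timestamped current/voltage series plus free-form extra columns."""

    t: np.ndarray  # ms, strictly increasing
    I: np.ndarray  # nA
    V: np.ndarray  # mV
    extras: dict = field(default_factory=dict)  # name -> ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if not (len(self.t) == len(self.I) == len(self.V)):
            raise InvalidArgumentError("t, I, V must have equal lengths")
        bad = np.flatnonzero(np.diff(self.t) <= 0)
        if len(bad):
            raise ParseError(
                f"timestamps not strictly increasing at row {int(bad[0]) + 1}"
            )
        for k, v in self.extras.items():
            v = np.asarray(v, dtype=float)
            if len(v) != len(self.t):
                raise InvalidArgumentError(f"extra column {k!r} has wrong length")
            self.extras[k] = v


_BASE_COLS = ("t_ms", "I_nA", "V_mV")


def write_trace(trace: Trace, path) -> None:
    """Write a trace; text (TSV + header) by default, HDF5 for ``.h5``."""
    path = Path(path)
    cols = list(_BASE_COLS) + list(trace.extras)
    data = np.column_stack(
        [trace.t, trace.I, trace.V] + [trace.extras[k] for k in trace.extras]
    )
    if path.suffix == ".h5":
        import h5py

        with h5py.File(path, "w") as f:
            for name, col in zip(cols, data.T):
                f.create_dataset(name, data=col)
            for k, v in trace.meta.items():
                f.attrs[k] = v
        return
    with open(path, "w") as f:
        f.write("# aecclamp trace v1\n")
        f.write("# units: t=ms I=nA V=mV\n")
        for k, v in sorted(trace.meta.items()):
            f.write(f"# {k} = {v}\n")
        f.write("\t".join(cols) + "\n")
        np.savetxt(f, data, fmt=_FLOAT_FMT, delimiter="\t")


def read_trace(path) -> Trace:
    """Read a trace written by :func:`write_trace` (text or HDF5)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such trace file: {path}")
    if path.suffix == ".h5":
        import h5py

        with h5py.File(path, "r") as f:
            cols = {name: f[name][:] for name in f}
            meta = dict(f.attrs)
        return _trace_from_columns(cols, meta, path)
    meta: dict = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as f:
        for lineno, line in enumerate(f, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            if header is None:
                header = line.split("\t")
                continue
            try:
                rows.append([float(x) for x in line.split("\t")])
            except ValueError as exc:
                raise ParseError(f"{path}: bad value at row {lineno}: {exc}") from exc
    if header is None or not rows:
        raise ParseError(f"{path}: no data rows")
    arr = np.array(rows)
    if arr.shape[1] != len(header):
        raise ParseError(f"{path}: column count mismatch with header")
    cols = {name: arr[:, k] for k, name in enumerate(header)}
    return _trace_from_columns(cols, meta, path)


def _trace_from_columns(cols: dict, meta: dict, path) -> Trace:
    for required in _BASE_COLS:
        if required not in cols:
            raise ParseError(
                f"{path}: missing column {required!r} (units must be ms/nA/mV)"
            )
    extras = {k: v for k, v in cols.items() if k not in _BASE_COLS}
    return Trace(
        t=cols["t_ms"], I=cols["I_nA"], V=cols["V_mV"], extras=extras, meta=meta
    )


def record_to_trace(record: SimulationRecord, meta: dict | None = None) -> Trace:
    """View a closed-loop record as a trace (extra columns preserved)."""
    return Trace(
        t=record.t,
        I=record.I_injected,
        V=record.V_raw,
        extras={
            "dt_ms": record.dt,
            "V_control_mV": record.V_control,
            "V_comp_mV": record.V_comp,
            "Ve_true_mV": record.Ve_true,
            "Ve_est_mV": record.Ve_est,
        },
        meta=meta or {},
    )


def write_kernel(kernel: Kernel, path) -> None:
    """Two-column text file: bin start (ms) and bin mass (MΩ)."""
    path = Path(path)
    starts = np.arange(len(kernel.masses)) * kernel.bin_width
    with open(path, "w") as f:
        f.write("# aecclamp kernel v1\n")
        f.write(f"# label = {kernel.label}\n")
        f.write(f"# bin_width_ms = {kernel.bin_width!r}\n")
        f.write("bin_start_ms\tmass_MOhm\n")
        np.savetxt(f, np.column_stack([starts, kernel.masses]), fmt=_FLOAT_FMT, delimiter="\t")


def read_kernel(path) -> Kernel:
    path = Path(path)
    label = "full"
    bin_width = None
    rows = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("label"):
                    label = body.partition("=")[2].strip()
                elif body.startswith("bin_width_ms"):
                    bin_width = float(body.partition("=")[2])
                continue
            if line.startswith("bin_start_ms"):
                continue
            parts = line.split("\t")
            rows.append(float(parts[1]))
    if bin_width is None:
        raise ParseError(f"{path}: missing bin_width_ms header")
    if not rows:
        raise ParseError(f"{path}: no kernel bins")
    return Kernel(bin_width=bin_width, masses=np.array(rows), label=label)


# -- reports ----------------------------------------------------------------


def _separation_to_dict(sep: SeparationResult) -> dict:
    return {
        "R_e_MOhm": sep.R_e,
        "tau_e_ms": sep.tau_e,
        "R_m_MOhm": sep.R_m,
        "tau_m_ms": sep.tau_m,
        "iterations": sep.iterations,
        "converged": sep.converged,
        "warnings": list(sep.warnings),
        "electrode_kernel": {
            "bin_width_ms": sep.electrode_kernel.bin_width,
            "masses_MOhm": sep.electrode_kernel.masses.tolist(),
        },
        "membrane_kernel": {
            "bin_width_ms": sep.membrane_kernel.bin_width,
            "masses_MOhm": sep.membrane_kernel.masses.tolist(),
        },
    }


def report_to_dict(report: CalibrationReport) -> dict:
    """JSON-serializable dictionary of a calibration report."""

    def stats(s):
        if s is None:
            return None
        return {
            "mean_R_MOhm": s.mean_R,
            "sd_R_MOhm": s.sd_R,
            "cv": s.cv,
            "tau_e_ms": s.tau_e,
            "per_level": [[i, r] for i, r in s.per_level],
        }

    return {
        "electrode_in_bath": stats(report.electrode_in_bath),
        "electrode_in_cell": stats(report.electrode_in_cell),
        "membrane": {
            "R_m_MOhm": report.membrane.R_m,
            "tau_m_ms": report.membrane.tau_m,
            "sd_R_m_MOhm": report.membrane.sd_R_m,
            "sd_tau_m_ms": report.membrane.sd_tau_m,
        },
        "separation": _separation_to_dict(report.separation),
        "applicability": {
            "linearity_pass": report.applicability.linearity_pass,
            "speed_pass": report.applicability.speed_pass,
            "ratio_pass": report.applicability.ratio_pass,
        },
        "spike_count": report.spike_count,
        "artifact_range_mV": list(report.artifact_range),
        "protocol": dataclasses.asdict(report.protocol),
        "full_kernel_ms": report.full_kernel_ms,
        "electrode_kernel_ms": report.electrode_kernel_ms,
        "offset_mV": report.offset,
        "cross_check_ok": report.cross_check_ok,
        "warnings": list(report.warnings),
        "thresholds": dict(report.thresholds),
    }


def write_report(report: CalibrationReport, path, extra_meta: dict | None = None) -> None:
    d = report_to_dict(report)
    if extra_meta:
        d["meta"] = extra_meta
    with open(path, "w") as f:
        json.dump(d, f, indent=2, sort_keys=True)
        f.write("\n")


# -- run configuration ------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    rig: RigConfig = field(default_factory=RigConfig)
    spikegen: SpikeGenParams = field(default_factory=SpikeGenParams)
    protocol: NoiseProtocol = field(default_factory=NoiseProtocol)
    mode: str = "aec"  # none | bridge | bridge+capneut | aec
    gap_conductance: float = 500.0  # nS
    duration: float = 500.0  # ms
    full_kernel_ms: float | None = None
    electrode_kernel_ms: float | None = None
    bridge_R: float | None = None  # MΩ, defaults to the true electrode R
    bridge_lag: float = 0.2  # ms
    log_level: str = "INFO"

    _MODES = ("none", "bridge", "bridge+capneut", "aec")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise InvalidArgumentError(
                f"mode must be one of {self._MODES}, got {self.mode!r}"
            )


def _dataclass_from(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ParseError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


def read_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "rig" in kwargs:
        rigd = dict(kwargs["rig"])
        for key in ("electrode", "membrane", "control_electrode"):
            if key in rigd and rigd[key] is not None:
                rigd[key] = _dataclass_from(RCParams, rigd[key], f"rig.{key}")
        kwargs["rig"] = _dataclass_from(RigConfig, rigd, "rig")
    if "spikegen" in kwargs:
        sg = dict(kwargs["spikegen"])
        if "spike_times" in sg:
            sg["spike_times"] = tuple(sg["spike_times"])
        kwargs["spikegen"] = _dataclass_from(SpikeGenParams, sg, "spikegen")
    if "protocol" in kwargs:
        kwargs["protocol"] = _dataclass_from(NoiseProtocol, kwargs["protocol"], "protocol")
    return RunConfig(**kwargs)


def _config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["spikegen"]["spike_times"] = list(d["spikegen"]["spike_times"])
    return d


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_config_to_dict(cfg), f, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash identifying a configuration."""
    blob = json.dumps(_config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
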