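"""Plain-text readers and writers for the pipeline's tabular inputs.

Trace tables are delimited text (CSV) with explicit column names; jump
protocols and calibrations travel in YAML sidecars; fit results and ground
truth are JSON.  Images use TIFF/PNG via tifffile / imageio elsewhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .frap import FRAPTrace
from .tjump import JumpProtocol, RelaxationTrace, TemperatureCalibration

__all__ = [
    "write_trace_csv", "read_trace_csv", "write_protocol_yaml",
    "read_protocol_yaml", "read_calibration_yaml", "write_frap_csv",
    "read_frap_csv", "write_json",
]


def write_trace_csv(trace: RelaxationTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.time, "donor": trace.donor,
                       "acceptor": trace.acceptor})
    df.attrs = {}
    header = (f"# pre_jump_T={trace.pre_jump_T}\n"
              f"# post_jump_T={trace.post_jump_T}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_trace_csv(path) -> RelaxationTrace:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
            body_start = i + 1
        else:
            break
    from io import StringIO
    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return RelaxationTrace(time=df["time_s"].to_numpy(),
                           donor=df["donor"].to_numpy(),
                           acceptor=df["acceptor"].to_numpy(),
                           pre_jump_T=meta.get("pre_jump_T", np.nan),
                           post_jump_T=meta.get("post_jump_T", np.nan))


def write_protocol_yaml(protocol: JumpProtocol, path) -> None:
    data = {"target_temperatures": [float(t) for t in protocol.target_temperatures],
            "start_temperature": float(protocol.start_temperature),
            "dwell_per_jump": float(protocol.dwell_per_jump)}
    Path(path).write_text(yaml.safe_dump(data))


def read_protocol_yaml(path) -> JumpProtocol:
    data = yaml.safe_load(Path(path).read_text())
    return JumpProtocol(target_temperatures=tuple(data["target_temperatures"]),
                        start_temperature=data["start_temperature"],
                        dwell_per_jump=data.get("dwell_per_jump", 25.0))


def read_calibration_yaml(path) -> TemperatureCalibration:
    """Calibration from either explicit (f_ref, t_ref, sensitivity) or pairs."""
    data = yaml.safe_load(Path(path).read_text())
    if "pairs" in data:
        f = [p["fluorescence"] for p in data["pairs"]]
        t = [p["temperature"] for p in data["pairs"]]
        return TemperatureCalibration.from_pairs(f, t)
    return TemperatureCalibration(f_ref=data["f_ref"], t_ref=data["t_ref"],
                                  sensitivity=data["sensitivity"])


def write_frap_csv(trace: FRAPTrace, path) -> None:
    cols = {"time_s": trace.time, "roi": trace.roi_intensity}
    if trace.reference_intensity is not None:
        cols["reference"] = trace.reference_intensity
    with open(path, "w") as fh:
        fh.write(f"# bleach_index={trace.bleach_index}\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_frap_csv(path, bleach_index: int | None = None) -> FRAPTrace:
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if bleach_index is None:
            bleach_index = int(first.split("=")[1])
    if bleach_index is None:
        raise ValueError("bleach_index required (no header in file)")
    df = pd.read_csv(path, skiprows=skip)
    ref = df["reference"].to_numpy() if "reference" in df else None
    return FRAPTrace(time=df["time_s"].to_numpy(), roi_intensity=df["roi"].to_numpy(),
                     bleach_index=bleach_index, reference_intensity=ref)


def write_json(obj: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
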