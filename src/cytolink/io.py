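"""CSV and config-file plumbing.

Flow-cytometry events arrive as CSV exported from FCS files with linear
forward/side scatter and a log-amplified fluorescence channel;
microscopy records are per-cell CSVs with volume and intensity columns
whose names the config supplies.  The workflow config is a plain
``Key: value`` text file; blocks separated by blank lines each describe
one data file, and a calibration is performed per value of ``Dox``
(the induction label identifying which populations were measured by
both techniques).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

__all__ = [
    "WorkflowConfig",
    "parse_config",
    "read_flow_csv",
    "read_micro_csv",
    "write_truth_sidecar",
]

_PURPOSES = ("Calibration", "Measurement")
_METHODS = ("FACS", "Microscopy")


@dataclasses.dataclass(frozen=True)
class WorkflowConfig:
    """One config block: what a data file is and how to read it."""

    purpose: str
    method: str
    dox: float
    intensity: str
    volume: str
    file: str

    def __post_init__(self) -> None:
        if self.purpose not in _PURPOSES:
            raise ValueError(f"Purpose must be one of {_PURPOSES}, got {self.purpose!r}")
        if self.method not in _METHODS:
            raise ValueError(f"Method must be one of {_METHODS}, got {self.method!r}")


def parse_config(path_or_text: str | Path) -> list[WorkflowConfig]:
    """Parse the key:value workflow config into a list of blocks.

    Recognized keys: Purpose, Method, Dox, Intensity, Volume, File.
    Blocks are separated by blank lines; '#' starts a comment line.
    """
    p = Path(path_or_text)
    text = p.read_text() if p.exists() else str(path_or_text)
    blocks: list[dict] = []
    current: dict = {}
    for line in text.splitlines() + [""]:
        line = line.strip()
        if not line:
            if current:
                blocks.append(current)
                current = {}
            continue
        if line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, _, value = line.partition(":")
        current[key.strip().lower()] = value.strip()
    out = []
    for b in blocks:
        missing = {"purpose", "method", "dox", "intensity", "volume", "file"} - set(b)
        if missing:
            raise ValueError(f"config block missing keys: {sorted(missing)}")
        out.append(
            WorkflowConfig(
                purpose=b["purpose"],
                method=b["method"],
                dox=float(b["dox"]),
                intensity=b["intensity"],
                volume=b["volume"],
                file=b["file"],
            )
        )
    return out


def read_flow_csv(
    path: str | Path, f0: str = "F0", f1: str = "F1", f2: str = "F2"
) -> pd.DataFrame:
    """Read a flow-event CSV, renaming channels to F0/F1/F2."""
    df = pd.read_csv(path)
    for col in (f0, f1, f2):
        if col not in df.columns:
            raise ValueError(f"flow CSV {path} lacks column {col!r}")
    return df.rename(columns={f0: "F0", f1: "F1", f2: "F2"})


def read_micro_csv(
    path: str | Path, intensity: str = "intensity", volume: str = "volume"
) -> pd.DataFrame:
    """Read a microscopy per-cell CSV, renaming to intensity/volume."""
    df = pd.read_csv(path)
    for col in (intensity, volume):
        if col not in df.columns:
            raise ValueError(f"microscopy CSV {path} lacks column {col!r}")
    return df.rename(columns={intensity: "intensity", volume: "volume"})


def write_truth_sidecar(truth, path: str | Path) -> None:
    """Write a dataclass's fields as a plain key:value text sidecar."""
    lines = []
    for f in dataclasses.fields(truth):
        v = getattr(truth, f.name)
        if dataclasses.is_dataclass(v):
            for g in dataclasses.fields(v):
                lines.append(f"{f.name}.{g.name}: {getattr(v, g.name)}")
        else:
            lines.append(f"{f.name}: {v}")
    Path(path).write_text("\n".join(lines) + "\n")
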