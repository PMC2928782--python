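"""Scatter gating of flow-cytometry events.

Trypsinized suspensions contain debris and dead cells alongside the vital
cells that the paired microscopy sample represents.  In the forward-
versus side-scatter plane (F0 proportional to cell cross-section, F1 to
granularity) the vital cells form an elongated cloud.  A line through the
cloud is fitted by no-intercept regression of F1 on F0, and two cuts
perpendicular to that line bound the band of vital cells: events are kept
when their signed projection onto the line's unit direction falls inside
the band.  Cut placement is parameterized by projection quantiles, a
reproducible surrogate for placing the cuts by eye.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "ScatterGate",
    "fit_scatter_axis",
    "project_events",
    "choose_cuts",
    "gate_events",
    "flag_events",
]

#: default projection-quantile band bounding the vital-cell region
DEFAULT_BAND = (0.02, 0.98)


@dataclasses.dataclass(frozen=True)
class ScatterGate:
    """No-intercept scatter axis plus perpendicular cut positions.

    ``slope`` is the F1-on-F0 regression slope; ``t_low``/``t_high`` bound
    the signed projection of (F0, F1) onto the unit vector along the line.
    """

    slope: float
    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("gate slope must be finite")
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be below t_high")


def _scatter(events: pd.DataFrame, f0: str, f1: str):
    x = np.asarray(events[f0], dtype=float)
    y = np.asarray(events[f1], dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("scatter channels must be non-negative")
    return x, y


def fit_scatter_axis(events: pd.DataFrame, f0: str = "F0", f1: str = "F1") -> float:
    """No-intercept regression slope s = sum(F0*F1) / sum(F0^2).

    Minimizes sum (F1 - s*F0)^2; events with F0 = 0 contribute nothing.
    """
    x, y = _scatter(events, f0, f1)
    if np.count_nonzero(x > 0) < 2:
        raise ValueError("need at least two events with F0 > 0")
    denom = float(x @ x)
    if denom == 0.0:
        raise ValueError("all forward-scatter values are zero")
    return float(x @ y) / denom


def project_events(
    events: pd.DataFrame, slope: float, f0: str = "F0", f1: str = "F1"
) -> np.ndarray:
    """Signed projection of (F0, F1) onto the unit vector (1, slope)/|.|."""
    x, y = _scatter(events, f0, f1)
    return (x + slope * y) / np.hypot(1.0, slope)


def choose_cuts(
    events: pd.DataFrame,
    slope: float,
    keep_band: tuple[float, float] = DEFAULT_BAND,
    f0: str = "F0",
    f1: str = "F1",
) -> ScatterGate:
    """Place the perpendicular cuts at projection quantiles of all events."""
    lo, hi = keep_band
    if not (0 <= lo < hi <= 1):
        raise ValueError("keep_band must satisfy 0 <= low < high <= 1")
    if len(events) == 0:
        raise ValueError("empty event list")
    t = project_events(events, slope, f0, f1)
    t_low, t_high = np.quantile(t, [lo, hi])
    return ScatterGate(slope=slope, t_low=float(t_low), t_high=float(t_high))


def gate_events(
    events: pd.DataFrame, gate: ScatterGate, f0: str = "F0", f1: str = "F1"
) -> pd.DataFrame:
    """Return the subset of events whose projection lies in [t_low, t_high]."""
    t = project_events(events, gate.slope, f0, f1)
    keep = (t >= gate.t_low) & (t <= gate.t_high)
    return events.loc[keep].copy()


def flag_events(
    events: pd.DataFrame,
    gate: ScatterGate,
    column: str = "in_gate",
    f0: str = "F0",
    f1: str = "F1",
) -> pd.DataFrame:
    """Copy of the event table with a boolean gate-membership column added.

    Keeping failed events flagged rather than deleted preserves an audit
    trail of what the gate removed.
    """
    t = project_events(events, gate.slope, f0, f1)
    out = events.copy()
    out[column] = (t >= gate.t_low) & (t <= gate.t_high)
    return out
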