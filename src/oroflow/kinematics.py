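"""Skeletal kinematic traces (gape, hyoid depression, opercula abduction)
and the phase-wise ordering of their peaks.

All traces are computed from locator trajectories expressed in the
anatomical frame, so they are invariant to whole-body motion.  During the
intake the canonical expansion wave runs anterior-to-posterior (peak gape,
then peak hyoid depression, then peak opercula abduction); during reverse
flow the wave — and hence the peak order — is inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phases import PhaseInterval, PhaseTable

__all__ = [
    "KinematicTrace",
    "gape_trace",
    "hyoid_depression_trace",
    "opercula_abduction_trace",
    "peak_sequence",
    "INTAKE_ORDER",
    "RF_ORDER",
]

INTAKE_ORDER = ("gape", "hyoid_depression", "opercula_abduction")
RF_ORDER = tuple(reversed(INTAKE_ORDER))


@dataclass
class KinematicTrace:
    """A skeletal excursion time series in mm (NaN where locators are missing)."""

    variable: str
    values: np.ndarray
    frame_rate: float
    rest_reference: float = 0.0
    peak_times: dict = field(default_factory=dict)  # phase label -> peak time (s)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) / self.frame_rate

    def peak_in(self, iv: PhaseInterval) -> tuple[float, float] | None:
        """(peak_time, peak_value) of the maximum inside a phase, or None."""
        t = self.times
        mask = (t >= iv.start_time - 1e-12) & (t <= iv.end_time + 1e-12)
        mask &= np.isfinite(self.values)
        if not mask.any():
            return None
        idx = np.flatnonzero(mask)
        best = idx[np.argmax(self.values[idx])]
        return float(t[best]), float(self.values[best])


def _rest_mean(series: np.ndarray, frame_rate: float, rest_window: tuple[float, float]) -> float:
    t0, t1 = rest_window
    t = np.arange(series.shape[0]) / frame_rate
    mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12) & np.isfinite(series)
    if not mask.any():
        raise ValueError(f"empty rest window [{t0}, {t1}] s")
    return float(series[mask].mean())


def gape_trace(
    upper_jaw_tip: np.ndarray, lower_jaw_tip: np.ndarray, frame_rate: float
) -> KinematicTrace:
    """Per-frame 3D Euclidean distance between the jaw-tip locators (mm)."""
    upper = np.asarray(upper_jaw_tip, dtype=float)
    lower = np.asarray(lower_jaw_tip, dtype=float)
    if upper.shape != lower.shape:
        raise ValueError("jaw-tip series must have the same shape")
    values = np.linalg.norm(upper - lower, axis=1)
    if not np.isfinite(values).any():
        raise ValueError("jaw-tip series have no overlapping valid frames")
    return KinematicTrace("gape", values, frame_rate)


def hyoid_depression_trace(
    hyoid_tip: np.ndarray,
    frame_rate: float,
    rest_window: tuple[float, float],
) -> KinematicTrace:
    """Ventral excursion of the hyoid tip: rest mean y minus y(t), in mm.

    Positive values mean depression below the resting posture; the rest
    posture is the mean over ``rest_window`` (conventionally the approach
    phase, before any buccal expansion).
    """
    y = np.asarray(hyoid_tip, dtype=float)[:, 1]
    rest = _rest_mean(y, frame_rate, rest_window)
    return KinematicTrace("hyoid_depression", rest - y, frame_rate, rest_reference=rest)


def opercula_abduction_trace(
    operculum_tip: np.ndarray,
    frame_rate: float,
    rest_window: tuple[float, float],
) -> KinematicTrace:
    """Lateral excursion of the operculum tip: |z(t)| minus rest mean |z|, mm."""
    z = np.abs(np.asarray(operculum_tip, dtype=float)[:, 2])
    rest = _rest_mean(z, frame_rate, rest_window)
    return KinematicTrace("opercula_abduction", z - rest, frame_rate, rest_reference=rest)


def peak_sequence(
    traces: dict[str, KinematicTrace] | list[KinematicTrace],
    pt: PhaseTable,
    phase: str,
    which: int = 0,
) -> dict:
    """Order the kinematic peaks inside one phase window.

    Returns ``{"order": [(variable, peak_time), ...] sorted by time,
    "label": intake_like | rf_like | other}``.  ``intake_like`` means the
    gape → hyoid → opercula sequence; ``rf_like`` its inversion.  Variables
    whose trace is fully missing inside the phase are omitted and force the
    label to ``other``.
    """
    if isinstance(traces, dict):
        trace_list = list(traces.values())
    else:
        trace_list = list(traces)
    ivs = pt.of_label(phase)
    if not ivs:
        raise ValueError(f"phase {phase!r} not present in table")
    iv = ivs[which]

    peaks: list[tuple[str, float]] = []
    omitted: list[str] = []
    for tr in trace_list:
        found = tr.peak_in(iv)
        if found is None:
            omitted.append(tr.variable)
        else:
            peaks.append((tr.variable, found[0]))
            tr.peak_times[phase] = found[0]
    peaks.sort(key=lambda p: p[1])
    order = tuple(v for v, _ in peaks)
    if omitted or len(order) < 3:
        label = "other"
    elif order == INTAKE_ORDER:
        label = "intake_like"
    elif order == RF_ORDER:
        label = "rf_like"
    else:
        label = "other"
    return {
        "phase": phase,
        "interval": (iv.start_time, iv.end_time),
        "order": peaks,
        "omitted": omitted,
        "label": label,
    }
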