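"""Velocity computation and automatic feeding-phase segmentation.

A suction-feeding sequence is segmented from the anteroposterior (x)
velocity of the water tracers, expressed in the anatomical frame, into:

* ``approach`` — slow posterior drift before capture (the fish closing in);
* ``intake``   — the single high-magnitude posterior pulse of food capture;
* ``stasis``   — near-zero flow;
* ``rf``       — reverse flow, anteriorly directed handling flow (v > 0);
* ``bf``       — backflow, a slower intake-like posterior handling flow.

Frames whose velocity falls inside the asymmetric dead band of
(-4.5, +2) cm/s are treated as stagnant and discarded from phase
assignment, so a phase boundary is precisely a dead-band crossing of the
mean water-tracer velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .trajectories import MM_PER_CM, TrajectorySet

__all__ = [
    "SegmentationConfig",
    "VelocitySeries",
    "PhaseInterval",
    "PhaseTable",
    "smooth_positions",
    "compute_velocity",
    "aggregate_water_velocity",
    "segment_phases",
    "transition_periodicity",
]


@dataclass
class SegmentationConfig:
    """Thresholds and filtering parameters for phase segmentation.

    The dead band (-4.5, +2 cm/s) is asymmetric because posterior drift at
    the approach speed (~3-4 cm/s) must not register as flow while even weak
    anterior flow is meaningful.
    """

    dead_band_low: float = -4.5   # cm/s
    dead_band_high: float = 2.0   # cm/s
    min_phase_duration: float = 0.02  # s
    intake_fraction: float = 0.5
    smoothing_cutoff: float = 25.0    # Hz, zero-phase low-pass before differentiation
    boundary_cutoff: float | None = 15.0  # Hz, extra velocity smoothing for boundary detection (None: off)

    def __post_init__(self) -> None:
        if not (self.dead_band_low < 0 < self.dead_band_high):
            raise ValueError("dead band must straddle zero (low < 0 < high)")
        if self.min_phase_duration <= 0:
            raise ValueError("min_phase_duration must be > 0")
        if not (0 < self.intake_fraction <= 1):
            raise ValueError("intake_fraction must be in (0, 1]")


@dataclass
class VelocitySeries:
    """Per-frame 3-component velocity (cm/s, anatomical frame)."""

    values: np.ndarray          # (n, 3) cm/s; NaN where invalid
    valid: np.ndarray           # (n,) bool
    frame_rate: float
    sd: np.ndarray | None = None  # cross-tracer SD of the x component

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def x(self) -> np.ndarray:
        """Anteroposterior component (posterior flow is negative)."""
        return self.values[:, 0]


@dataclass
class PhaseInterval:
    label: str  # approach | intake | stasis | rf | bf
    start_time: float
    end_time: float
    peak_ap_velocity: float  # cm/s, signed


@dataclass
class PhaseTable:
    """Ordered, non-overlapping labelled intervals covering a sequence."""

    intervals: list[PhaseInterval] = field(default_factory=list)
    all_stasis: bool = False  # warning flag: nothing exceeded the dead band

    def __post_init__(self) -> None:
        labels = {"approach", "intake", "stasis", "rf", "bf"}
        prev_end = -np.inf
        for iv in self.intervals:
            if iv.label not in labels:
                raise ValueError(f"unknown phase label {iv.label!r}")
            if iv.start_time < prev_end - 1e-12:
                raise ValueError("phase intervals must be ordered and non-overlapping")
            prev_end = iv.end_time
        if sum(iv.label == "intake" for iv in self.intervals) > 1:
            raise ValueError("at most one intake per capture event")

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def of_label(self, label: str) -> list[PhaseInterval]:
        return [iv for iv in self.intervals if iv.label == label]

    def intake(self) -> PhaseInterval:
        ivs = self.of_label("intake")
        if not ivs:
            raise ValueError("no intake phase in table")
        return ivs[0]

    def records(self) -> list[dict]:
        return [
            {
                "label": iv.label,
                "start_time": iv.start_time,
                "end_time": iv.end_time,
                "peak_ap_velocity": iv.peak_ap_velocity,
            }
            for iv in self.intervals
        ]


# ---------------------------------------------------------------------------
# smoothing and differentiation
# ---------------------------------------------------------------------------

def smooth_positions(
    positions: np.ndarray, frame_rate: float, cutoff: float = 25.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a (n, k) position series.

    Applied independently to each contiguous valid run; runs too short for
    the filter's padding are returned unfiltered.  NaN samples stay NaN.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    squeeze = positions is not None and np.asarray(positions).ndim == 1
    if squeeze:
        pos = np.asarray(positions, dtype=float)[:, None]
    out = pos.copy()
    if cutoff <= 0 or cutoff >= frame_rate / 2:
        return out[:, 0] if squeeze else out
    sos = signal.butter(order, cutoff, fs=frame_rate, output="sos")
    # pad over ~3 filter time constants with odd extension: linear trends are
    # continued exactly, so constant-velocity segments filter transient-free
    padlen = max(3 * (2 * order + 1), int(3 * frame_rate / cutoff))
    valid = ~np.isnan(pos).any(axis=1)
    for start, stop in _runs(valid):
        n_seg = stop - start
        if n_seg > 3 * (2 * order + 1):
            out[start:stop] = signal.sosfiltfilt(
                sos, pos[start:stop], axis=0, padtype="odd",
                padlen=min(padlen, n_seg - 1),
            )
    return out[:, 0] if squeeze else out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return list(zip(idx[::2], idx[1::2]))


def compute_velocity(
    path: np.ndarray,
    frame_rate: float,
    config: SegmentationConfig | None = None,
) -> VelocitySeries:
    """Differentiate a (n, 3) anatomical position series (mm) into cm/s.

    Positions are low-pass smoothed (zero-phase) before central finite
    differences; frames adjacent to gaps are flagged invalid because the
    central difference there straddles missing data.
    """
    config = config or SegmentationConfig()
    path = np.asarray(path, dtype=float)
    valid = ~np.isnan(path).any(axis=1)
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid frames to compute velocity")
    smoothed = smooth_positions(path, frame_rate, config.smoothing_cutoff)
    vel = np.full_like(path, np.nan)
    vel_valid = np.zeros(path.shape[0], dtype=bool)
    for start, stop in _runs(valid):
        if stop - start < 3:
            continue
        seg = smoothed[start:stop]
        v = np.gradient(seg, axis=0) * frame_rate / MM_PER_CM  # mm/frame -> cm/s
        vel[start:stop] = v
        vel_valid[start:stop] = True
        vel_valid[start] = vel_valid[stop - 1] = False  # gap-adjacent frames
    return VelocitySeries(values=vel, valid=vel_valid, frame_rate=frame_rate)


def aggregate_water_velocity(
    ts: TrajectorySet, config: SegmentationConfig | None = None
) -> VelocitySeries:
    """Mean (and SD) velocity across all valid water tracers, per frame."""
    config = config or SegmentationConfig()
    names = ts.tracks_of_kind("water_tracer")
    if not names:
        raise ValueError("TrajectorySet contains no water tracers")
    per_tracer = []
    for name in names:
        try:
            per_tracer.append(compute_velocity(ts.points[name], ts.frame_rate, config))
        except ValueError:
            continue
    if not per_tracer:
        raise ValueError("no water tracer has enough valid frames")
    stack = np.stack([vs.values for vs in per_tracer])      # (m, n, 3)
    vmask = np.stack([vs.valid for vs in per_tracer])       # (m, n)
    stack = np.where(vmask[:, :, None], stack, np.nan)
    count = vmask.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd_x = np.nanstd(stack[:, :, 0], axis=0, ddof=1)
    valid = count >= 1
    mean[~valid] = np.nan
    sd_x[count < 2] = 0.0
    sd_x[~valid] = np.nan
    return VelocitySeries(
        values=mean, valid=valid, frame_rate=ts.frame_rate, sd=sd_x
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_phases(vs: VelocitySeries, config: SegmentationConfig | None = None) -> PhaseTable:
    """Label a sequence with approach/intake/stasis/rf/bf phases.

    Frames are classified posterior (v < dead_band_low), anterior
    (v > dead_band_high) or stagnant; dead-band-exceeding runs shorter than
    ``min_phase_duration`` are discarded as noise and same-direction runs
    separated by sub-threshold stagnant slivers are merged.  The first
    posterior run whose peak speed reaches ``intake_fraction`` of the global
    posterior maximum is the intake; the pre-intake span is the approach when
    its mean velocity is posterior; later anterior runs are rf, posterior
    runs bf; everything else is stasis.
    """
    config = config or SegmentationConfig()
    v = vs.x.copy()
    n = vs.n_frames
    times = vs.times
    dt = 1.0 / vs.frame_rate
    min_frames = max(1, int(round(config.min_phase_duration * vs.frame_rate)))

    # boundary detection runs on an additionally smoothed copy: the phase
    # dynamics live below ~3 Hz, and velocity noise at the full 25 Hz
    # bandwidth is correlated over ~half the filter period, so it cannot be
    # averaged away locally — it must be filtered out before thresholding
    if config.boundary_cutoff is None:
        v_det = v.copy()
    else:
        v_det = smooth_positions(v, vs.frame_rate, config.boundary_cutoff)
    v_det[~vs.valid] = np.nan

    post = vs.valid & (v_det < config.dead_band_low)
    ante = vs.valid & (v_det > config.dead_band_high)

    runs: list[dict] = []
    for sign, mask in (("posterior", post), ("anterior", ante)):
        for start, stop in _runs(mask):
            runs.append({"sign": sign, "start": int(start), "stop": int(stop)})
    # drop sub-duration runs (single-frame noise at 750 fps)
    runs = [r for r in runs if r["stop"] - r["start"] >= min_frames]
    # a genuine run must also exceed the dead band on the unfiltered
    # velocity: zero-phase filter ringing at step-like transitions can
    # otherwise fabricate small spurious excursions
    def _real(r: dict) -> bool:
        seg = v[r["start"]: r["stop"]]
        seg = seg[np.isfinite(seg)]
        if seg.size == 0:
            return False
        if r["sign"] == "posterior":
            return bool(seg.min() < config.dead_band_low)
        return bool(seg.max() > config.dead_band_high)

    runs = [r for r in runs if _real(r)]
    runs.sort(key=lambda r: r["start"])
    # merge same-direction runs separated by stagnant slivers shorter than
    # the minimum phase duration
    merged: list[dict] = []
    for r in runs:
        if (
            merged
            and merged[-1]["sign"] == r["sign"]
            and r["start"] - merged[-1]["stop"] < min_frames
        ):
            merged[-1]["stop"] = r["stop"]
        else:
            merged.append(dict(r))
    runs = merged

    if not any(r["sign"] == "posterior" for r in runs):
        peak = float(np.nanmin(v)) if np.isfinite(v).any() else 0.0
        table = PhaseTable(
            intervals=[PhaseInterval("stasis", float(times[0]), float(times[-1] + dt), peak)],
            all_stasis=True,
        )
        return table

    def run_peak(r: dict) -> float:
        seg = v[r["start"]: r["stop"]]
        seg = seg[np.isfinite(seg)]
        if seg.size == 0:
            return 0.0
        return float(seg.min() if r["sign"] == "posterior" else seg.max())

    post_runs = [r for r in runs if r["sign"] == "posterior"]
    global_peak_speed = max(-run_peak(r) for r in post_runs)
    intake_run = next(
        r for r in post_runs if -run_peak(r) >= config.intake_fraction * global_peak_speed
    )

    def refine(edge: int, threshold: float) -> float:
        """Sub-frame crossing time by an iterated local quadratic fit.

        Single-frame threshold crossings jitter by sigma_v / slope.  A short
        quadratic fit around the current edge estimate averages the noise
        down and follows the pulse curvature; re-centering the window on the
        solution removes the bias a noise-shifted raw edge would otherwise
        leave.  Solutions far from the raw edge are rejected (the local
        smoothness assumption broke, e.g. at a step-like transition).
        """
        w = 8  # frames
        center = min(edge, n - 1)
        t_star = float(edge * dt)
        for _ in range(3):
            lo, hi = max(0, center - w), min(n, center + w + 1)
            tt, vv = times[lo:hi], v_det[lo:hi]
            ok = np.isfinite(vv)
            if ok.sum() < 5:
                return float(edge * dt)
            coeffs = np.polyfit(tt[ok] - center * dt, vv[ok], 2)
            coeffs = coeffs.copy()
            coeffs[-1] -= threshold
            roots = np.roots(coeffs)
            roots = roots[np.isreal(roots)].real
            if roots.size == 0:
                return float(edge * dt)
            t_star = float(center * dt + roots[np.argmin(np.abs(roots))])
            new_center = min(max(int(round(t_star / dt)), 0), n - 1)
            if new_center == center:
                break
            center = new_center
            if abs(center - edge) > w:
                return float(edge * dt)
        if abs(t_star - edge * dt) > 2.5 * dt:
            return float(edge * dt)
        return float(t_star)

    for r in runs:
        thr = config.dead_band_low if r["sign"] == "posterior" else config.dead_band_high
        r["t0"] = refine(r["start"], thr)
        r["t1"] = refine(r["stop"], thr)
        if r["t1"] <= r["t0"]:  # degenerate refinement: keep the raw edges
            r["t0"], r["t1"] = float(r["start"] * dt), float(r["stop"] * dt)

    intervals: list[PhaseInterval] = []

    # approach: the span before the intake, when its mean drift is posterior
    pre = v[: intake_run["start"]]
    pre = pre[np.isfinite(pre)]
    cursor = 0.0
    if intake_run["start"] > 0:
        pre_label = "approach" if (pre.size and np.mean(pre) < 0) else "stasis"
        pre_peak = float(np.min(pre)) if pre.size else 0.0
        intervals.append(PhaseInterval(pre_label, 0.0, intake_run["t0"], pre_peak))
        cursor = intake_run["t0"]

    def stasis_peak(t0: float, t1: float) -> float:
        seg = v[int(np.ceil(t0 / dt)): int(t1 / dt)]
        seg = seg[np.isfinite(seg)]
        return float(seg[np.argmax(np.abs(seg))]) if seg.size else 0.0

    for r in runs:
        if r["stop"] <= intake_run["start"]:
            continue  # pre-intake excursions are folded into the approach
        t0 = max(r["t0"], cursor)
        gap = t0 - cursor
        if (
            intervals
            and intervals[-1].label in ("intake", "rf", "bf")
            and 0 < gap < config.min_phase_duration
        ):
            # stagnant sliver between two flow phases: split it at the middle
            t0 = 0.5 * (cursor + t0)
            intervals[-1].end_time = t0
        elif t0 > cursor + dt / 2:
            intervals.append(PhaseInterval("stasis", cursor, t0, stasis_peak(cursor, t0)))
        if r is intake_run:
            label = "intake"
        else:
            label = "rf" if r["sign"] == "anterior" else "bf"
        intervals.append(PhaseInterval(label, t0, r["t1"], run_peak(r)))
        cursor = r["t1"]
    t_end = float(n * dt)
    if cursor < t_end - dt / 2:
        intervals.append(PhaseInterval("stasis", cursor, t_end, stasis_peak(cursor, t_end)))

    return PhaseTable(intervals=intervals)


def transition_periodicity(pt: PhaseTable) -> dict:
    """Mean/SD of intervals between successive rf<->bf flow reversals.

    A reversal event is the onset of each rf or bf phase; the paper's
    periodicity (0.58 s carp, 0.40 s tilapia) is the mean spacing of these
    events.
    """
    events = [
        (iv.start_time, iv.label) for iv in pt.intervals if iv.label in ("rf", "bf")
    ]
    # keep only actual alternations (an rf followed by rf is one event)
    times = []
    last_label = None
    for t, lab in events:
        if lab != last_label:
            times.append(t)
            last_label = lab
    if len(times) < 2:
        raise ValueError("need at least 2 rf/bf transitions to estimate periodicity")
    gaps = np.diff(times)
    return {
        "mean": float(np.mean(gaps)),
        "sd": float(np.std(gaps, ddof=1)) if gaps.size > 1 else 0.0,
        "n": int(gaps.size),
    }
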