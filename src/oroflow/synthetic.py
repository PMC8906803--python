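"""Seeded synthetic feeding sequences, drop tests, and on-disk fixtures.

The generator emulates what the biplanar X-ray recordings deliver to the
pipeline: world-frame trajectories of cranial bone markers, skeletal
locators, ~15 water tracers and one food tracer at 750 frames/s with
+-0.1 mm isotropic measurement noise, together with the ground truth the
recordings cannot provide — the exact phase boundaries, kinematic peak
times and tracer classes.

The anteroposterior velocity program is built from raised-cosine pulses:
an approach plateau, one high-magnitude intake pulse, stasis, then
``n_cycles`` alternating reverse-flow / backflow pulses.  Phase boundaries
are the analytic dead-band crossings (-4.5 / +2 cm/s) of the pre-noise
program, and each pulse is widened so that the crossing-to-crossing
duration equals the preset's phase duration — the program's knots therefore
coincide with the ground-truth boundaries by construction.

Species presets carry the published trial statistics (approach speed,
intake peak and duration, handling peak, rf/bf periodicity) as their means;
the printed between-trial SDs ship with the presets and are applied when
``between_trial_sd_scale`` > 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .frames import AnatomicalLandmarks
from .phases import PhaseInterval, PhaseTable
from .physics import particle_relaxation_time, settling_velocity
from .trajectories import (
    FluidProperties,
    TracerSpec,
    TrajectorySet,
    read_trajectories,
    write_trajectories,
)

__all__ = [
    "SpeciesPreset",
    "SyntheticWorld",
    "CARP",
    "TILAPIA",
    "get_preset",
    "generate_feeding_sequence",
    "generate_drop_test",
    "write_fixture",
    "regenerate_fixture",
]


@dataclass
class SpeciesPreset:
    """Trial-level parameters of a synthetic feeding sequence.

    Speeds in cm/s, durations in s, lengths in mm.  The ``*_sd`` fields are
    between-trial variabilities (only used when sampling trial parameters).
    """

    name: str
    approach_speed: float
    approach_speed_sd: float
    intake_peak: float
    intake_peak_sd: float
    intake_duration: float
    intake_duration_sd: float
    handling_peak: float
    handling_peak_sd: float
    rf_bf_period: float
    rf_bf_period_sd: float
    n_water_tracers: int = 15
    noise_sd: float = 0.1            # mm, isotropic measurement noise
    frame_rate: float = 750.0
    cavity_length: float = 65.0      # mm (buccopharyngeal cavity, x)
    cavity_halfwidth: float = 20.0   # mm (z)
    # kinematic peak positions as fractions of the phase duration
    gape_peak_frac: float = 0.35
    hyoid_peak_frac: float = 0.55
    operc_peak_frac: float = 0.75

    def __post_init__(self) -> None:
        for name in ("approach_speed", "intake_peak", "intake_duration",
                     "handling_peak", "rf_bf_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SpeciesPreset.{name} must be > 0")
        if self.n_water_tracers < 1:
            raise ValueError("n_water_tracers must be >= 1")


CARP = SpeciesPreset(
    name="carp",
    approach_speed=3.9, approach_speed_sd=2.5,
    intake_peak=92.1, intake_peak_sd=59.0,
    intake_duration=0.26, intake_duration_sd=0.04,
    handling_peak=32.9, handling_peak_sd=11.0,
    rf_bf_period=0.58, rf_bf_period_sd=0.12,
)

TILAPIA = SpeciesPreset(
    name="tilapia",
    approach_speed=3.3, approach_speed_sd=1.3,
    intake_peak=97.8, intake_peak_sd=23.0,
    intake_duration=0.27, intake_duration_sd=0.08,
    handling_peak=24.7, handling_peak_sd=12.0,
    rf_bf_period=0.40, rf_bf_period_sd=0.05,
)


def get_preset(name: str) -> SpeciesPreset:
    presets = {"carp": CARP, "tilapia": TILAPIA}
    if name not in presets:
        raise ValueError(f"unknown preset {name!r} (have {sorted(presets)})")
    return presets[name]


@dataclass
class SyntheticWorld:
    """A generated sequence plus the ground truth behind it."""

    trajectories: TrajectorySet          # world frame, noisy
    phase_table: PhaseTable              # ground-truth boundaries (pre-noise)
    kinematic_peaks: dict                # phase -> {variable: peak time (s)}
    tracer_labels: dict                  # track name -> kind
    marker_reference: dict               # bone-marker name -> bone-model coords
    landmarks: AnatomicalLandmarks
    ap_velocity_truth: np.ndarray        # pre-noise water x-velocity (cm/s)
    preset: SpeciesPreset = None
    seed: int = 0
    n_cycles: int = 0
    flow_pattern_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# velocity program
# ---------------------------------------------------------------------------

DEAD_LOW = 4.5   # cm/s, posterior threshold magnitude
DEAD_HIGH = 2.0  # cm/s, anterior threshold


def _intake_half_width(preset: SpeciesPreset) -> tuple[float, float, float]:
    """Half-pulse duration H and crossing fractions (tau1, tau2).

    Entry half ramps the speed from the approach plateau to the peak, exit
    half from the peak back to zero; H is chosen so the time between the
    posterior dead-band crossings equals the preset intake duration.
    """
    base, peak = preset.approach_speed, preset.intake_peak
    if base >= DEAD_LOW:
        raise ValueError("approach speed must lie inside the dead band")
    q1 = (DEAD_LOW - base) / (peak - base)
    tau1 = np.arccos(1.0 - 2.0 * q1) / np.pi
    q2 = DEAD_LOW / peak
    tau2 = np.arccos(2.0 * q2 - 1.0) / np.pi
    H = preset.intake_duration / (1.0 - tau1 + tau2)
    return H, tau1, tau2


def _pulse_crossing_offset(amplitude: float, threshold: float, width: float) -> float:
    """Time after onset at which a raised-cosine pulse crosses a threshold."""
    theta = np.arccos(1.0 - 2.0 * threshold / amplitude)
    return width * theta / (2.0 * np.pi)


@dataclass
class _Program:
    """Piecewise anteroposterior velocity program with analytic crossings."""

    preset: SpeciesPreset
    n_cycles: int
    approach_duration: float = 0.5
    stasis_duration: float = 0.3
    tail_duration: float = 0.2
    rf_amp_frac: float = 0.8  # rf peak as a fraction of the handling peak

    def __post_init__(self) -> None:
        p = self.preset
        self.H, self.tau1, self.tau2 = _intake_half_width(p)
        self.t_intake_on = self.approach_duration
        self.t_peak = self.t_intake_on + self.H
        self.t_intake_off = self.t_intake_on + 2.0 * self.H
        self.intake_cross_in = self.t_intake_on + self.tau1 * self.H
        self.intake_cross_out = self.t_peak + self.tau2 * self.H
        self.handling_start = self.t_intake_off + self.stasis_duration
        P = p.rf_bf_period
        self.pulse_width = 0.6 * P
        self.rf_amp = self.rf_amp_frac * p.handling_peak
        self.bf_amp = p.handling_peak
        self.rf_onsets = [self.handling_start + 2 * k * P for k in range(self.n_cycles)]
        self.bf_onsets = [self.handling_start + (2 * k + 1) * P for k in range(self.n_cycles)]
        self.total_time = (
            self.handling_start + 2 * self.n_cycles * P + self.tail_duration
            if self.n_cycles
            else self.t_intake_off + self.stasis_duration + self.tail_duration
        )

    def velocity(self, t: np.ndarray) -> np.ndarray:
        """Water-tracer anteroposterior velocity (cm/s) at times t."""
        p = self.preset
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        # approach plateau
        v[t < self.t_intake_on] = -p.approach_speed
        # intake entry half: plateau -> peak
        m = (t >= self.t_intake_on) & (t < self.t_peak)
        tau = (t[m] - self.t_intake_on) / self.H
        v[m] = -(p.approach_speed + (p.intake_peak - p.approach_speed)
                 * 0.5 * (1.0 - np.cos(np.pi * tau)))
        # intake exit half: peak -> 0
        m = (t >= self.t_peak) & (t < self.t_intake_off)
        tau = (t[m] - self.t_peak) / self.H
        v[m] = -p.intake_peak * 0.5 * (1.0 + np.cos(np.pi * tau))
        # handling pulses
        for onsets, amp, sign in (
            (self.rf_onsets, self.rf_amp, +1.0),
            (self.bf_onsets, self.bf_amp, -1.0),
        ):
            for onset in onsets:
                m = (t >= onset) & (t < onset + self.pulse_width)
                tau = (t[m] - onset) / self.pulse_width
                v[m] += sign * amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))
        return v

    def phase_table(self) -> PhaseTable:
        p = self.preset
        ivs = [
            PhaseInterval("approach", 0.0, self.intake_cross_in, -p.approach_speed),
            PhaseInterval("intake", self.intake_cross_in, self.intake_cross_out,
                          -p.intake_peak),
        ]
        events = []
        d_rf = _pulse_crossing_offset(self.rf_amp, DEAD_HIGH, self.pulse_width)
        d_bf = _pulse_crossing_offset(self.bf_amp, DEAD_LOW, self.pulse_width)
        for onset in self.rf_onsets:
            events.append(("rf", onset + d_rf, onset + self.pulse_width - d_rf, self.rf_amp))
        for onset in self.bf_onsets:
            events.append(("bf", onset + d_bf, onset + self.pulse_width - d_bf, -self.bf_amp))
        events.sort(key=lambda e: e[1])
        cursor = self.intake_cross_out
        for label, t0, t1, peak in events:
            if t0 > cursor:
                ivs.append(PhaseInterval("stasis", cursor, t0, 0.0))
            ivs.append(PhaseInterval(label, t0, t1, peak))
            cursor = t1
        if cursor < self.total_time:
            ivs.append(PhaseInterval("stasis", cursor, self.total_time, 0.0))
        return PhaseTable(intervals=ivs)


def _bump(t: np.ndarray, center: float, halfwidth: float, amplitude: float) -> np.ndarray:
    """Raised-cosine bump: amplitude at center, zero outside +-halfwidth."""
    out = np.zeros_like(t)
    m = np.abs(t - center) < halfwidth
    out[m] = amplitude * 0.5 * (1.0 + np.cos(np.pi * (t[m] - center) / halfwidth))
    return out


# ---------------------------------------------------------------------------
# feeding-sequence generator
# ---------------------------------------------------------------------------

def generate_feeding_sequence(
    preset: SpeciesPreset,
    n_cycles: int = 3,
    seed: int = 0,
    noise_sd: float | None = None,
    between_trial_sd_scale: float = 0.0,
    anterior_return_fraction: float = 0.0,
    posteromedial_fraction: float = 0.0,
) -> SyntheticWorld:
    """Generate one seeded synthetic feeding sequence.

    Water tracers share the preset's anteroposterior velocity program and
    diverge laterally (side-preserving S-curves toward the cavity walls);
    the food tracer stays midsagittal, more dorsal, and covers less ground.
    Bone markers advance at the approach speed and then hold; jaw, hyoid and
    operculum locators follow the canonical gape -> hyoid -> opercula peak
    order during the intake and its inversion during each reverse flow.
    Measurement noise (isotropic, SD ``noise_sd`` mm) is added to every
    sample; every ground truth is recorded pre-noise.

    ``anterior_return_fraction`` / ``posteromedial_fraction`` divert that
    fraction of the water tracers into central-jet return or crossflow-like
    medial sub-populations (defaults 0: plain diverging flow).
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if anterior_return_fraction + posteromedial_fraction > 1.0 + 1e-12:
        raise ValueError("sub-population fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = preset.noise_sd

    if between_trial_sd_scale > 0:
        s = between_trial_sd_scale
        preset = SpeciesPreset(
            **{
                **asdict(preset),
                "approach_speed": float(np.clip(
                    rng.normal(preset.approach_speed, s * preset.approach_speed_sd),
                    0.5, 0.9 * DEAD_LOW,
                )),
                "intake_peak": max(3 * DEAD_LOW, rng.normal(preset.intake_peak, s * preset.intake_peak_sd)),
                "intake_duration": max(0.08, rng.normal(preset.intake_duration, s * preset.intake_duration_sd)),
                "handling_peak": max(2 * DEAD_LOW, rng.normal(preset.handling_peak, s * preset.handling_peak_sd)),
                "rf_bf_period": max(0.2, rng.normal(preset.rf_bf_period, s * preset.rf_bf_period_sd)),
            }
        )

    prog = _Program(preset, n_cycles)
    fps = preset.frame_rate
    n = int(round(prog.total_time * fps))
    t = np.arange(n) / fps
    dt = 1.0 / fps

    v_truth = prog.velocity(t)                       # cm/s
    x_rel = np.concatenate([[0.0], np.cumsum(0.5 * (v_truth[1:] + v_truth[:-1]) * dt)]) * 10.0  # mm

    # cranium translation: advance at approach speed until the intake begins
    v_app_mm = preset.approach_speed * 10.0
    cran = np.zeros((n, 3))
    cran[:, 0] = v_app_mm * np.minimum(t, prog.intake_cross_in)

    # intake progress in [0, 1] (time-based, for the dorsoventral wiggles)
    prog_x = np.clip(
        (t - prog.t_intake_on) / (prog.t_intake_off - prog.t_intake_on), 0.0, 1.0
    )

    points: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    pattern_truth: dict[str, str] = {}

    n_w = preset.n_water_tracers
    n_ar = int(round(anterior_return_fraction * n_w))
    n_pm = int(round(posteromedial_fraction * n_w))
    mouth_x = preset.cavity_length  # aperture position on the anatomical x axis

    for i in range(n_w):
        name = f"water_{i:02d}"
        side = 1.0 if i % 2 == 0 else -1.0
        z0 = side * rng.uniform(1.0, 6.0)
        x0 = mouth_x + 5.0 + rng.uniform(0.0, 15.0)
        x_a = x0 + x_rel
        # lateral divergence is an intraoral phenomenon: it progresses with
        # the tracer's position inside the cavity, not with intake time
        prog_lat = np.clip((mouth_x - x_a) / preset.cavity_length, 0.0, 1.0)
        if i < n_ar:
            pattern = "anterior_return"
            # a brief anterior excursion late in the intake (central-jet return)
            v_extra = _bump(t, prog.t_peak + 0.7 * prog.H, 0.06, 22.0)
            x_a = x_a + np.concatenate(
                [[0.0], np.cumsum(0.5 * (v_extra[1:] + v_extra[:-1]) * dt)]
            ) * 10.0
            z_end = side * (preset.cavity_halfwidth * 0.5)
        elif i < n_ar + n_pm:
            pattern = "posteromedial"
            z_end = side * 0.5  # swings out and returns toward the midline
        else:
            pattern = "posterior"
            z_end = side * (6.0 + 1.5 * abs(z0) + rng.normal(0.0, 0.5))
        pattern_truth[name] = pattern
        if pattern == "posteromedial":
            # swing toward the wall mid-cavity, return near the midline by the end
            swing = side * (0.6 * preset.cavity_halfwidth)
            z_a = z0 + (swing - z0) * np.sin(np.pi * prog_lat) ** 2 \
                + (z_end - z0) * prog_lat ** 3
        else:
            z_a = z0 + (z_end - z0) * 0.5 * (1.0 - np.cos(np.pi * prog_lat))
        y_a = rng.uniform(-6.0, 0.0) + 1.5 * np.sin(np.pi * prog_x) * rng.uniform(0.3, 1.0)
        path = np.column_stack([x_a, np.full(n, 0.0) + y_a, z_a])
        points[name] = path + cran
        kinds[name] = "water_tracer"

    # food tracer: midsagittal, dorsal, attenuated displacement
    v_food = np.where(t < prog.intake_cross_in, v_truth, 0.6 * v_truth)
    xf = mouth_x + 8.0 + np.concatenate(
        [[0.0], np.cumsum(0.5 * (v_food[1:] + v_food[:-1]) * dt)]
    ) * 10.0
    food = np.column_stack([xf, np.full(n, 6.0), np.zeros(n)])
    points["food_00"] = food + cran
    kinds["food_00"] = "food_tracer"

    # neurocranium bone markers (rigid, identity orientation)
    marker_reference = {
        "neuro_m1": np.array([10.0, 20.0, 0.0]),
        "neuro_m2": np.array([30.0, 26.0, 5.0]),
        "neuro_m3": np.array([24.0, 16.0, -6.0]),
        "neuro_m4": np.array([42.0, 30.0, 2.0]),
    }
    for mname, ref in marker_reference.items():
        points[mname] = ref[None, :] + cran
        kinds[mname] = "bone_marker"

    # skeletal locators and their ground-truth peaks
    peaks: dict[str, dict[str, float]] = {}
    D = prog.intake_cross_out - prog.intake_cross_in
    gape = np.full(n, 2.0)
    hyoid_exc = np.zeros(n)
    operc_exc = np.zeros(n)

    def add_wave(t0: float, dur: float, order: tuple, amp_scale: float, key: str | None):
        fracs = {
            "gape": preset.gape_peak_frac,
            "hyoid_depression": preset.hyoid_peak_frac,
            "opercula_abduction": preset.operc_peak_frac,
        }
        times = {}
        for var in ("gape", "hyoid_depression", "opercula_abduction"):
            frac = fracs[var] if order == "forward" else 1.0 - fracs[var]
            tp = t0 + frac * dur
            times[var] = tp
            w = 0.30 * dur
            if var == "gape":
                gape[:] += _bump(t, tp, w, 8.0 * amp_scale)
            elif var == "hyoid_depression":
                hyoid_exc[:] += _bump(t, tp, w, 6.0 * amp_scale)
            else:
                operc_exc[:] += _bump(t, tp, w, 4.0 * amp_scale)
        if key is not None:
            peaks[key] = times

    add_wave(prog.intake_cross_in, D, "forward", 1.0, "intake")
    d_rf = _pulse_crossing_offset(prog.rf_amp, DEAD_HIGH, prog.pulse_width)
    d_bf = _pulse_crossing_offset(prog.bf_amp, DEAD_LOW, prog.pulse_width)
    for k, onset in enumerate(prog.rf_onsets):
        t0, t1 = onset + d_rf, onset + prog.pulse_width - d_rf
        add_wave(t0, t1 - t0, "reverse", 0.6, "rf" if k == 0 else f"rf_{k}")
    for k, onset in enumerate(prog.bf_onsets):
        t0, t1 = onset + d_bf, onset + prog.pulse_width - d_bf
        add_wave(t0, t1 - t0, "forward", 0.4, "bf" if k == 0 else f"bf_{k}")

    upper = np.column_stack([np.full(n, mouth_x), np.full(n, 10.0), np.zeros(n)])
    lower = upper.copy()
    lower[:, 1] -= gape
    hyoid = np.column_stack([np.full(n, 30.0), -15.0 - hyoid_exc, np.zeros(n)])
    operc = np.column_stack([np.full(n, 15.0), np.full(n, 0.0), 18.0 + operc_exc])
    for lname, arr in (
        ("upper_jaw", upper), ("lower_jaw", lower), ("hyoid", hyoid), ("operculum", operc)
    ):
        points[lname] = arr + cran
        kinds[lname] = "locator"

    # measurement noise, applied to every sample of every track
    if noise_sd > 0:
        for name in points:
            points[name] = points[name] + rng.normal(0.0, noise_sd, size=(n, 3))

    landmarks = AnatomicalLandmarks(
        origin=np.zeros(3),
        x_axis_pair=(np.zeros(3), np.array([10.0, 0.0, 0.0])),
        y_hint=np.array([0.0, 10.0, 0.0]),
    )
    ts = TrajectorySet(
        frame_rate=fps,
        points=points,
        track_kind=kinds,
        coordinate_frame="world",
    )
    return SyntheticWorld(
        trajectories=ts,
        phase_table=prog.phase_table(),
        kinematic_peaks=peaks,
        tracer_labels={k: v for k, v in kinds.items() if v.endswith("_tracer")},
        marker_reference=marker_reference,
        landmarks=landmarks,
        ap_velocity_truth=v_truth,
        preset=preset,
        seed=seed,
        n_cycles=n_cycles,
        flow_pattern_truth=pattern_truth,
    )


# ---------------------------------------------------------------------------
# drop tests
# ---------------------------------------------------------------------------

def generate_drop_test(
    spec: TracerSpec,
    fluid: FluidProperties | None = None,
    duration: float = 2.0,
    frame_rate: float = 50.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Vertical drop-test record (m, + up) of one tracer released at rest.

    The velocity relaxes as v(t) = v_t (1 - exp(-t / tau)) with the Stokes
    terminal velocity v_t for the spec and the added-mass response time tau;
    positions integrate that in closed form.  ``noise_sd`` is in mm (the
    tracking resolution), converted to metres internally.
    """
    fluid = fluid or FluidProperties()
    rng = np.random.default_rng(seed)
    tau = particle_relaxation_time(spec, fluid)
    if duration < 5.0 * tau:
        raise ValueError(
            f"duration {duration} s is not >> relaxation time {tau:.3f} s"
        )
    v_up = -settling_velocity(spec.density, fluid, spec.diameter)  # + up
    t = np.arange(int(round(duration * frame_rate))) / frame_rate
    y = v_up * (t - tau * (1.0 - np.exp(-t / tau)))
    return y + rng.normal(0.0, noise_sd * 1e-3, size=y.shape)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def write_fixture(world: SyntheticWorld, directory: str | Path) -> None:
    """Write a complete on-disk fixture: trajectories (xmalab_3d dialect),
    ground-truth phase table, peak times, tracer labels, and the generating
    configuration.  Regenerating from the stored config reproduces the files
    byte-identically."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_trajectories(world.trajectories, directory / "trajectories.csv")

    import pandas as pd

    pd.DataFrame(world.phase_table.records()).to_csv(
        directory / "phases.csv", index=False, float_format="%.9g"
    )
    with open(directory / "peaks.json", "w") as fh:
        json.dump(world.kinematic_peaks, fh, indent=1)
    pd.DataFrame(
        [{"track": k, "kind": v} for k, v in sorted(world.tracer_labels.items())]
    ).to_csv(directory / "labels.csv", index=False)
    config = {
        "preset": asdict(world.preset),
        "n_cycles": world.n_cycles,
        "seed": world.seed,
        "landmarks": {
            "origin": world.landmarks.origin.tolist(),
            "x_axis_pair": [p.tolist() for p in world.landmarks.x_axis_pair],
            "y_hint": world.landmarks.y_hint.tolist(),
        },
        "marker_reference": {k: v.tolist() for k, v in world.marker_reference.items()},
    }
    with open(directory / "config.json", "w") as fh:
        json.dump(config, fh, indent=1)


def regenerate_fixture(directory: str | Path, out_directory: str | Path) -> SyntheticWorld:
    """Rebuild a fixture from its stored config (determinism check)."""
    directory = Path(directory)
    with open(directory / "config.json") as fh:
        config = json.load(fh)
    preset = SpeciesPreset(**config["preset"])
    world = generate_feeding_sequence(
        preset, n_cycles=config["n_cycles"], seed=config["seed"]
    )
    write_fixture(world, out_directory)
    return world


def load_fixture_trajectories(directory: str | Path) -> TrajectorySet:
    return read_trajectories(Path(directory) / "trajectories.csv")
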