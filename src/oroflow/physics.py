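"""Tracer-fidelity physics: Stokes density estimation and a reduced-order
suction-flow particle simulation.

Two questions are answered here.  First, how dense is a tracer?  A sphere
dropped in still water reaches a terminal velocity where Stokes drag
balances its net buoyant weight, so

    rho_tracer = 18 * mu * v_settle / (g * d^2) + rho_water

with ``v_settle`` positive when sinking.  Second, does a tracer of that
density faithfully follow an unsteady suction flow?  The full moving-mesh
CFD of that question is replaced by a closed-form flow model — a
hemispherical sink converging on the mouth aperture outside, plug flow
inside a cylindrical cavity, with the aperture speed from a quasi-steady
Bernoulli closure of the imposed suction-pressure profile — and a reduced
Maxey-Riley force balance on the particle (Stokes drag, buoyancy/weight,
added mass, fluid pressure-gradient force; Basset history and Faxen terms
neglected).  Comparing the particle path against the pure-fluid pathline
from the same release point yields the fidelity metrics: velocity lag and
overshoot, gravity-direction path deviation, and total path separation.

All quantities in this module are SI (m, s, kg, Pa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectories import FluidProperties, TracerSpec

__all__ = [
    "SuctionModel",
    "SimulationResult",
    "FidelityReport",
    "stokes_density",
    "settling_velocity",
    "terminal_velocity",
    "NonTerminalError",
    "simulate_suction",
    "fidelity_metrics",
    "fidelity_of",
    "default_release_points",
    "cube_to_sphere_volume_ratio",
    "particle_relaxation_time",
]


# ---------------------------------------------------------------------------
# Stokes density
# ---------------------------------------------------------------------------

def stokes_density(
    v_settle: float, fluid: FluidProperties | None = None, d: float = 1.4e-3
) -> float:
    """Tracer density (kg/m^3) from its terminal settling velocity.

    ``v_settle`` is positive when the tracer sinks (so a rising tracer gives
    a density below the fluid's).  Warns when the particle Reynolds number
    exceeds 1, where the Stokes drag law starts to degrade.
    """
    fluid = fluid or FluidProperties()
    if d <= 0:
        raise ValueError("tracer diameter must be > 0")
    re = fluid.density * abs(v_settle) * d / fluid.dynamic_viscosity
    if re > 1.0:
        warnings.warn(
            f"particle Reynolds number {re:.2f} > 1: Stokes law is only advisory",
            stacklevel=2,
        )
    return (
        18.0 * fluid.dynamic_viscosity * v_settle / (fluid.gravity * d**2)
        + fluid.density
    )


def settling_velocity(
    density: float, fluid: FluidProperties | None = None, d: float = 1.4e-3
) -> float:
    """Inverse of :func:`stokes_density`: terminal settling speed (+ down)."""
    fluid = fluid or FluidProperties()
    return (density - fluid.density) * fluid.gravity * d**2 / (18.0 * fluid.dynamic_viscosity)


def particle_relaxation_time(
    spec: TracerSpec, fluid: FluidProperties | None = None
) -> float:
    """Stokes response time including added mass: (rho_p + rho_f/2) d^2 / 18 mu."""
    fluid = fluid or FluidProperties()
    return (
        (spec.density + 0.5 * fluid.density)
        * spec.diameter**2
        / (18.0 * fluid.dynamic_viscosity)
    )


class NonTerminalError(RuntimeError):
    """The drop-test record never settled onto a steady terminal velocity."""


def terminal_velocity(
    drop_path: np.ndarray,
    frame_rate: float,
    drift_rel_tol: float = 0.15,
    drift_abs_tol: float = 1e-3,
) -> dict:
    """Terminal velocity from a 1D vertical drop-test record (m, + up).

    The slope of the final 50 % of the record gives ``v_terminal`` (m/s,
    positive = rising); the drift check compares the slopes of the two
    halves of that tail and raises :class:`NonTerminalError` when they
    disagree beyond tolerance (the record is still relaxing).
    ``fit_quality`` is the residual SD of the tail fit (m).
    """
    y = np.asarray(drop_path, dtype=float).ravel()
    ok = np.isfinite(y)
    if ok.sum() < 8:
        raise ValueError("drop-test record too short")
    t = np.arange(y.shape[0]) / frame_rate
    t, y = t[ok], y[ok]
    tail = slice(y.shape[0] // 2, None)
    tt, yy = t[tail], y[tail]
    slope, intercept = np.polyfit(tt, yy, 1)
    half = tt.shape[0] // 2
    s1 = np.polyfit(tt[:half], yy[:half], 1)[0]
    s2 = np.polyfit(tt[half:], yy[half:], 1)[0]
    drift = abs(s2 - s1)
    if drift > max(drift_rel_tol * abs(slope), drift_abs_tol):
        raise NonTerminalError(
            f"tail slope drifts by {drift:.2e} m/s (first half {s1:.2e}, "
            f"second half {s2:.2e}): record has not reached terminal velocity"
        )
    resid = yy - (slope * tt + intercept)
    return {"v_terminal": float(slope), "fit_quality": float(np.std(resid))}


def cube_to_sphere_volume_ratio(cube_edge: float = 2e-3, diameter: float = 1.4e-3) -> float:
    """Volume of a cube over the volume of a sphere (how much smaller the
    1.4-mm spherical tracers are than 2-mm cubic ones)."""
    sphere = (np.pi / 6.0) * diameter**3
    return cube_edge**3 / sphere


# ---------------------------------------------------------------------------
# reduced-order suction flow
# ---------------------------------------------------------------------------

@dataclass
class SuctionModel:
    """Cylindrical-cavity suction with a sinusoidal pressure ramp.

    The cavity (length 40 mm, radius 10 mm) opens at the origin toward +x;
    suction pressure follows a raised-cosine (sin^2) ramp to
    ``-pressure_amplitude`` over ``ramp_time`` and is then held at the peak.
    The aperture speed follows the quasi-steady orifice estimate
    u = sqrt(2 |p| / rho) — an analytic sine in time, peaking at ~2 m/s for
    2 kPa, the order of measured intake flows.

    The flow field is separable, ``u(x, t) = u_ap(t) * F(x)``, with a smooth
    (C^1) spatial shape: outside the mouth a sink displaced one radius
    behind the aperture (so off-axis pathlines enter the cavity off-axis
    instead of collapsing onto the sink point), inside a radially tapered
    plug flow, blended over an entrance region of one cavity radius.
    Smoothness matters: a neutrally buoyant particle follows the fluid
    pathline exactly only when the field has no velocity discontinuities.
    """

    cavity_length: float = 0.040   # m
    cavity_radius: float = 0.010   # m
    pressure_amplitude: float = 2000.0  # Pa (suction magnitude)
    ramp_time: float = 0.020       # s
    total_time: float = 0.100      # s
    time_step: float = 1.25e-4     # s
    fluid: FluidProperties = field(default_factory=FluidProperties)
    gravity_direction: tuple = (0.0, -1.0, 0.0)
    domain_radius: float = 0.30    # m, integration stops beyond this

    def __post_init__(self) -> None:
        for name in ("cavity_length", "cavity_radius", "ramp_time", "total_time", "time_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SuctionModel.{name} must be > 0")
        if self.time_step > self.ramp_time / 10.0:
            raise ValueError("time_step must be <= ramp_time / 10")
        if self.cavity_radius >= self.cavity_length:
            raise ValueError("cavity_radius must be < cavity_length")
        g = np.asarray(self.gravity_direction, dtype=float)
        self.gravity_direction = tuple(g / np.linalg.norm(g))

    # -- forcing -------------------------------------------------------------

    def pressure(self, t: float) -> float:
        """Suction pressure p(t) <= 0 (Pa): raised-cosine ramp, then hold."""
        if t <= 0:
            return 0.0
        if t >= self.ramp_time:
            return -self.pressure_amplitude
        return -self.pressure_amplitude * np.sin(np.pi * t / (2.0 * self.ramp_time)) ** 2

    def aperture_speed(self, t: float) -> float:
        """Plug-flow speed inside the cavity (m/s, >= 0)."""
        u_max = np.sqrt(2.0 * self.pressure_amplitude / self.fluid.density)
        if t <= 0:
            return 0.0
        if t >= self.ramp_time:
            return float(u_max)
        return float(u_max * np.sin(np.pi * t / (2.0 * self.ramp_time)))

    def aperture_speed_derivative(self, t: float) -> float:
        """d u_ap / dt, analytic (right limit at t = 0)."""
        if t < 0 or t >= self.ramp_time:
            return 0.0
        u_max = np.sqrt(2.0 * self.pressure_amplitude / self.fluid.density)
        w = np.pi / (2.0 * self.ramp_time)
        return float(u_max * w * np.cos(w * t))

    def shape(self, pos: np.ndarray) -> np.ndarray:
        """Spatial shape F(x) of the separable field u = u_ap(t) * F(x)."""
        R, L = self.cavity_radius, self.cavity_length
        x = pos[0]
        if x <= -L:
            return np.zeros(3)
        r_rad = np.hypot(pos[1], pos[2])
        # plug component with a C^1 radial taper at the cavity wall
        if r_rad <= 0.8 * R:
            taper = 1.0
        elif r_rad >= R:
            taper = 0.0
        else:
            taper = 0.5 * (1.0 + np.cos(np.pi * (r_rad - 0.8 * R) / (0.2 * R)))
        plug = np.array([-taper, 0.0, 0.0])
        # entrance blend weight: pure sink beyond x = +R/2, pure plug below -R/2
        if x >= 0.5 * R:
            w = 1.0
        elif x <= -0.5 * R:
            w = 0.0
        else:
            w = 0.5 * (1.0 + np.sin(np.pi * x / R))
        if w == 0.0:
            return plug
        # sink displaced one radius behind the aperture, normalised so the
        # on-axis speed at the aperture equals the plug speed
        d_vec = pos - np.array([-R, 0.0, 0.0])
        d = np.linalg.norm(d_vec)
        sink = -(R**2 / d**2) * d_vec / d
        return w * sink + (1.0 - w) * plug

    def fluid_velocity(self, pos: np.ndarray, t: float) -> np.ndarray:
        """Flow velocity (m/s) at a point and time."""
        u_ap = self.aperture_speed(t)
        if u_ap == 0.0:
            return np.zeros(3)
        return u_ap * self.shape(pos)

    def material_derivative(self, pos: np.ndarray, t: float, h_x: float = 1e-6) -> np.ndarray:
        """Du/Dt = u_ap'(t) F + u_ap^2 (F . grad) F, gradient by central
        spatial differences (the time dependence is handled analytically)."""
        u_ap = self.aperture_speed(t)
        F = self.shape(pos)
        out = self.aperture_speed_derivative(t) * F
        if u_ap != 0.0:
            adv = np.zeros(3)
            for i in range(3):
                e = np.zeros(3)
                e[i] = h_x
                adv += F[i] * (self.shape(pos + e) - self.shape(pos - e))
            out = out + u_ap**2 * adv / (2.0 * h_x)
        return out


@dataclass
class SimulationResult:
    """Particle path, matched fluid pathline, and sampled fluid velocities."""

    times: np.ndarray
    particle_position: np.ndarray    # (n_p, 3) m
    particle_velocity: np.ndarray    # (n_p, 3) m/s
    fluid_position: np.ndarray       # (n_f, 3) m — the pure-fluid pathline
    fluid_velocity_at_particle: np.ndarray  # (n_p, 3) m/s
    particle_status: str             # completed | reached_base | exited_domain
    fluid_status: str
    model: SuctionModel | None = None
    spec: TracerSpec | None = None


@dataclass
class FidelityReport:
    """Tracking-fidelity metrics, all non-negative by construction.

    max_lag
        Largest shortfall of particle speed below local fluid speed while
        the forcing accelerates (m/s).
    max_overshoot
        Largest excess of particle speed over fluid speed while the forcing
        decelerates (m/s).
    gravity_deviation
        Largest displacement of the particle from the matched fluid-pathline
        point along the gravity direction (m).
    path_separation
        Largest pointwise 3D distance between the two paths (m).
    """

    max_lag: float
    max_overshoot: float
    gravity_deviation: float
    path_separation: float

    def __post_init__(self) -> None:
        for name in ("max_lag", "max_overshoot", "gravity_deviation", "path_separation"):
            if getattr(self, name) < 0:
                raise ValueError(f"FidelityReport.{name} must be >= 0")


def default_release_points(model: SuctionModel | None = None) -> list[np.ndarray]:
    """The two canonical release points: 5 mm ahead of the aperture on-axis,
    and 5 mm ahead + 5 mm off-axis (both configurable by the caller)."""
    return [np.array([0.005, 0.0, 0.0]), np.array([0.005, 0.0, 0.005])]


def _integrate(
    model: SuctionModel,
    deriv,
    state0: np.ndarray,
) -> tuple[np.ndarray, str]:
    """RK4 with early termination at the cavity base or the domain edge."""
    dt = model.time_step
    n_steps = int(round(model.total_time / dt))
    states = [state0.copy()]
    status = "completed"
    y = state0.copy()
    for k in range(n_steps):
        t = k * dt
        k1 = deriv(y, t)
        k2 = deriv(y + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = deriv(y + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = deriv(y + dt * k3, t + dt)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        pos = y[:3]
        states.append(y.copy())
        if pos[0] <= -model.cavity_length:
            status = "reached_base"
            break
        if np.linalg.norm(pos) > model.domain_radius:
            status = "exited_domain"
            break
    return np.array(states), status


def simulate_suction(
    model: SuctionModel,
    spec: TracerSpec,
    release_point: np.ndarray | None = None,
    schiller_naumann: bool = False,
) -> SimulationResult:
    """Advect one tracer and the matching fluid parcel through the suction.

    The particle obeys the reduced Maxey-Riley balance

        (rho_p + rho_f/2) dv/dt = (3/2) rho_f Du/Dt
                                  + (rho_p - rho_f) g
                                  + (18 mu / d^2) phi (u - v)

    with ``phi = 1`` (Stokes) or the Schiller-Naumann correction
    ``1 + 0.15 Re^0.687`` when requested.  The fluid pathline integrates
    ``dx/dt = u(x, t)`` from the same release point.
    """
    if spec.density <= 0:
        raise ValueError("tracer density must be > 0")
    rp = (
        default_release_points(model)[0]
        if release_point is None
        else np.asarray(release_point, dtype=float)
    )
    if rp[0] <= 0:
        raise ValueError("release point must lie in the inflow half-space (x > 0)")

    fluid = model.fluid
    rho_p, rho_f = spec.density, fluid.density
    mu = fluid.dynamic_viscosity
    d = spec.diameter
    g_vec = fluid.gravity * np.asarray(model.gravity_direction)
    inert = rho_p + 0.5 * rho_f
    drag0 = 18.0 * mu / d**2

    def particle_deriv(state: np.ndarray, t: float) -> np.ndarray:
        pos, vel = state[:3], state[3:]
        u = model.fluid_velocity(pos, t)
        dudt = model.material_derivative(pos, t)
        slip = u - vel
        phi = 1.0
        if schiller_naumann:
            re = rho_f * np.linalg.norm(slip) * d / mu
            phi = 1.0 + 0.15 * re**0.687
        acc = (1.5 * rho_f * dudt + (rho_p - rho_f) * g_vec + drag0 * phi * slip) / inert
        return np.concatenate([vel, acc])

    def fluid_deriv(state: np.ndarray, t: float) -> np.ndarray:
        return model.fluid_velocity(state[:3], t)

    p_states, p_status = _integrate(
        model, particle_deriv, np.concatenate([rp, np.zeros(3)])
    )
    f_states, f_status = _integrate(model, fluid_deriv, rp.copy())

    dt = model.time_step
    times = np.arange(p_states.shape[0]) * dt
    u_at_p = np.array(
        [model.fluid_velocity(p_states[i, :3], i * dt) for i in range(p_states.shape[0])]
    )
    return SimulationResult(
        times=times,
        particle_position=p_states[:, :3],
        particle_velocity=p_states[:, 3:],
        fluid_position=f_states,
        fluid_velocity_at_particle=u_at_p,
        particle_status=p_status,
        fluid_status=f_status,
        model=model,
        spec=spec,
    )


def fidelity_metrics(
    particle_path: np.ndarray,
    fluid_pathline: np.ndarray,
    fluid_velocity_at_particle: np.ndarray,
    time_step: float = 1.25e-4,
    gravity_direction: tuple = (0.0, -1.0, 0.0),
    particle_velocity: np.ndarray | None = None,
) -> FidelityReport:
    """Compare a particle path against its matched fluid pathline.

    Paths must share the time grid; when one terminates early the comparison
    runs over the common prefix.  Lag is evaluated while the local fluid
    speed is increasing, overshoot while it is decreasing; both are clamped
    at zero (signed extrema are available from the raw arrays).
    """
    p = np.asarray(particle_path, dtype=float)
    f = np.asarray(fluid_pathline, dtype=float)
    u = np.asarray(fluid_velocity_at_particle, dtype=float)
    if p.size == 0 or f.size == 0:
        raise ValueError("empty path")
    n = min(p.shape[0], f.shape[0], u.shape[0])
    p, f, u = p[:n], f[:n], u[:n]
    if particle_velocity is not None:
        v = np.asarray(particle_velocity, dtype=float)[:n]
    else:
        v = np.gradient(p, time_step, axis=0)

    su = np.linalg.norm(u, axis=1)
    sp = np.linalg.norm(v, axis=1)
    dsu = np.gradient(su, time_step)
    # near-zero fluid speed means the flow is off or a path has left the
    # flow region (e.g. reached the cavity base): no meaningful slip there
    moving = su > 0.02 * su.max()
    accel = (dsu > 1e-9) & moving
    decel = (dsu < -1e-9) & moving
    diff = su - sp
    max_lag = float(max(0.0, diff[accel].max())) if accel.any() else 0.0
    max_overshoot = float(max(0.0, (-diff[decel]).max())) if decel.any() else 0.0

    ghat = np.asarray(gravity_direction, dtype=float)
    ghat = ghat / np.linalg.norm(ghat)
    delta = p - f
    gravity_dev = float(max(0.0, (delta @ ghat).max()))
    separation = float(np.linalg.norm(delta, axis=1).max())
    return FidelityReport(
        max_lag=max_lag,
        max_overshoot=max_overshoot,
        gravity_deviation=gravity_dev,
        path_separation=separation,
    )


def fidelity_of(result: SimulationResult) -> FidelityReport:
    """Convenience wrapper: fidelity metrics straight from a simulation.

    The sample on which a path terminated (base reached / domain left) is
    excluded — it lies beyond the flow region being compared.
    """
    n = min(result.particle_position.shape[0], result.fluid_position.shape[0])
    if n > 4 and (result.particle_status != "completed" or result.fluid_status != "completed"):
        n -= 1
    return fidelity_metrics(
        result.particle_position[:n],
        result.fluid_position[:n],
        result.fluid_velocity_at_particle[:n],
        time_step=float(result.times[1] - result.times[0]) if result.times.size > 1 else 1.25e-4,
        gravity_direction=result.model.gravity_direction if result.model else (0.0, -1.0, 0.0),
        particle_velocity=result.particle_velocity[:n],
    )
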