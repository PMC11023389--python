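"""Task-dynamical affordance analysis of targeted throwing.

The affordance of a target "to be hit" is formalised as the set of release
parameter combinations (angle, speed, height) whose projectile motion
intercepts the target face.  A tennis ball launched at speed v, elevation
angle theta from height h follows

    x'' = -(k/m) * |v| * vx,      y'' = -g - (k/m) * |v| * vy,

with quadratic drag k = 0.5 * rho * C_d * A.  Sweeping a grid of release
parameters and recording hit/miss yields an affordance map; the drag-free
closed form serves as an independent oracle for the integrator.

The analysis is two-dimensional (sagittal plane): the release parameters
carry no lateral component, so the target's 1.2 m width is not binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "ReleaseParameters",
    "TargetSpec",
    "Environment",
    "AffordanceMap",
    "simulate_flight",
    "hit_test",
    "affordance_map",
    "closed_form_range",
    "closed_form_height_at",
]

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class ReleaseParameters:
    """Ball state at the moment it leaves the hand.

    angle : degrees above horizontal, in (-90, 90]
    speed : m/s, >= 0
    height : m above the floor, > 0
    """

    angle: float
    speed: float
    height: float

    def __post_init__(self):
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if not -90 < self.angle <= 90:
            raise ValueError("angle must be in (-90, 90] degrees")
        if self.height <= 0:
            raise ValueError("height must be positive")

    @property
    def velocity(self) -> tuple:
        a = math.radians(self.angle)
        return self.speed * math.cos(a), self.speed * math.sin(a)


@dataclass(frozen=True)
class TargetSpec:
    """Vertical square target; the study used 1.2 m x 1.2 m, centre 1.5 m up."""

    distance: float
    width: float = 1.2
    height: float = 1.2
    centre_height: float = 1.5

    def __post_init__(self):
        if min(self.distance, self.width, self.height, self.centre_height) <= 0:
            raise ValueError("target dimensions must be positive")


@dataclass(frozen=True)
class Environment:
    """Ball and medium constants. Defaults: ITF regulation tennis ball,
    sea-level air, C_d = 0.55 (typical measured tennis-ball value)."""

    g: float = GRAVITY
    air_density: float = 1.225
    drag_coefficient: float = 0.55
    ball_mass: float = 0.0577
    ball_diameter: float = 0.067

    def __post_init__(self):
        if self.g <= 0 or self.ball_mass <= 0 or self.drag_coefficient < 0:
            raise ValueError("invalid environment constants")

    @property
    def drag_factor(self) -> float:
        """k/m with k = 0.5 * rho * C_d * A (1/m)."""
        area = math.pi * (self.ball_diameter / 2) ** 2
        return 0.5 * self.air_density * self.drag_coefficient * area / self.ball_mass


@dataclass
class FlightTrajectory:
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray


def _deriv(state: np.ndarray, km: float, g: float) -> np.ndarray:
    x, y, vx, vy = state
    v = math.hypot(vx, vy)
    return np.array([vx, vy, -km * v * vx, -g - km * v * vy])


def rk4_step(state: np.ndarray, dt: float, km: float, g: float) -> np.ndarray:
    """One classical Runge-Kutta step of the drag-flight dynamics.

    ``dt`` may be negative (backward continuation of the same solution).
    """
    k1 = _deriv(state, km, g)
    k2 = _deriv(state + 0.5 * dt * k1, km, g)
    k3 = _deriv(state + 0.5 * dt * k2, km, g)
    k4 = _deriv(state + dt * k3, km, g)
    return state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_flight(
    release: ReleaseParameters,
    env: Environment = Environment(),
    dt: float = 0.001,
    x_max: float = 20.0,
    t_max: float = 10.0,
) -> FlightTrajectory:
    """Integrate the drag-affected ballistic flight by fixed-step RK4.

    Starts at (0, release.height); terminates once x > x_max, the ball
    reaches the floor (y < 0), or t_max elapses.  Fixed step keeps the
    result bit-reproducible.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    km, g = env.drag_factor, env.g
    vx0, vy0 = release.velocity
    state = np.array([0.0, release.height, vx0, vy0])
    out = [state.copy()]
    t = 0.0
    times = [0.0]
    while state[0] <= x_max and state[1] >= 0 and t < t_max:
        state = rk4_step(state, dt, km, g)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"flight diverged at t={t:.4f}s: {state}")
        t += dt
        times.append(t)
        out.append(state.copy())
    arr = np.array(out)
    return FlightTrajectory(
        t=np.array(times), x=arr[:, 0], y=arr[:, 1], vx=arr[:, 2], vy=arr[:, 3]
    )


def hit_test(
    traj: FlightTrajectory, target: TargetSpec, inclusive: bool = True
):
    """Did the flight intercept the target plane within its vertical extent?

    Interpolates y linearly at x = target.distance.  Returns
    ``(hit, y_at_plane, reason)``; ``y_at_plane`` is NaN when the ball never
    reaches the plane (reason "short").  A ball crossing exactly at the target
    edge counts as a hit when ``inclusive`` (the default).
    """
    x, y = traj.x, traj.y
    beyond = np.nonzero(x >= target.distance)[0]
    if beyond.size == 0:
        return False, float("nan"), "short"
    j = beyond[0]
    if j == 0:
        y_at = y[0]
    else:
        frac = (target.distance - x[j - 1]) / (x[j] - x[j - 1])
        y_at = y[j - 1] + frac * (y[j] - y[j - 1])
    if y_at < 0:
        return False, float(y_at), "short"
    err = abs(y_at - target.centre_height)
    half = target.height / 2
    # small absolute slack so an exactly-on-the-edge crossing is not decided
    # by floating-point rounding
    hit = err <= half + 1e-12 if inclusive else err < half - 1e-12
    reason = "hit" if hit else ("high" if y_at > target.centre_height else "low")
    return bool(hit), float(y_at), reason


@dataclass
class AffordanceMap:
    """Hit/miss grid over (angle, speed) at a fixed release height."""

    angle_grid: np.ndarray
    speed_grid: np.ndarray
    height: float
    hits: np.ndarray
    target: TargetSpec
    env: Environment = field(default_factory=Environment)

    @property
    def hit_count(self) -> int:
        return int(self.hits.sum())

    def speed_interval(self, angle_index: int):
        """(min, max) hit speed at one angle, or None if no hit."""
        row = np.nonzero(self.hits[angle_index])[0]
        if row.size == 0:
            return None
        return float(self.speed_grid[row[0]]), float(self.speed_grid[row[-1]])

    def to_frame(self):
        import pandas as pd

        aa, ss = np.meshgrid(self.angle_grid, self.speed_grid, indexing="ij")
        return pd.DataFrame(
            {
                "angle": aa.ravel(),
                "speed": ss.ravel(),
                "height": self.height,
                "hit": self.hits.ravel().astype(int),
            }
        )


def affordance_map(
    angle_grid,
    speed_grid,
    height: float,
    env: Environment = Environment(),
    target: TargetSpec = TargetSpec(distance=10.0),
    dt: float = 0.001,
) -> AffordanceMap:
    """Sweep release-parameter combinations and record hits.

    ``hits[i, j]`` is the outcome for ``angle_grid[i]``, ``speed_grid[j]``.
    """
    angle_grid = np.asarray(angle_grid, float)
    speed_grid = np.asarray(speed_grid, float)
    if angle_grid.size == 0 or speed_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(np.diff(angle_grid) <= 0) or np.any(np.diff(speed_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    hits = np.zeros((angle_grid.size, speed_grid.size), dtype=bool)
    x_max = target.distance + 1.0
    for i, ang in enumerate(angle_grid):
        for j, spd in enumerate(speed_grid):
            traj = simulate_flight(
                ReleaseParameters(angle=ang, speed=spd, height=height),
                env,
                dt=dt,
                x_max=x_max,
            )
            hits[i, j] = hit_test(traj, target)[0]
    return AffordanceMap(angle_grid, speed_grid, height, hits, target, env)


def closed_form_height_at(
    distance: float, speed: float, angle: float, release_height: float, g: float = GRAVITY
) -> float:
    """Drag-free ball height when it crosses the vertical plane at ``distance``.

    y(d) = h + d tan(theta) - g d^2 / (2 v^2 cos^2 theta); NaN if the plane is
    unreachable (vertical or zero-speed throw).
    """
    th = math.radians(angle)
    c = math.cos(th)
    if speed <= 0 or c <= 0:
        return float("nan")
    return release_height + distance * math.tan(th) - g * distance**2 / (
        2 * speed**2 * c**2
    )


def closed_form_range(
    speed: float,
    angle: float,
    release_height: float,
    g: float = GRAVITY,
    target_height: float = None,
):
    """Drag-free horizontal distance at which the ball descends to
    ``target_height`` (default: the floor, y=0). None if never reached."""
    if speed <= 0:
        raise ValueError("speed must be positive")
    y_ref = 0.0 if target_height is None else target_height
    th = math.radians(angle)
    vx = speed * math.cos(th)
    vy = speed * math.sin(th)
    # solve h + vy t - g t^2 / 2 = y_ref for the larger root
    disc = vy**2 + 2 * g * (release_height - y_ref)
    if disc < 0:
        return None
    t = (vy + math.sqrt(disc)) / g
    if t <= 0:
        return None
    return vx * t
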