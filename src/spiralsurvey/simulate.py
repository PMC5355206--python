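"""Camera-trajectory simulation for spiral, lawnmower and spoke surveys.

Generates time-stamped camera pose sequences (planar position, altitude,
heading) sampled at the camera frame period under constant path speed.
The spiral pattern follows the involute of a circle exactly, using the
closed-form arc-length inversion alpha(t) = sqrt(2 s t / R); the lawnmower
("mow the lawn") pattern is a boustrophedon of parallel legs joined by
semicircular end turns, with optional coverage-hole injection; spokes are
straight passes over the survey center.  A seeded AR(1) disturbance model
emulates swell and current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .design import CameraModel, DrumLine, involute_xy

__all__ = [
    "FLAG_MAIN",
    "FLAG_TURN",
    "FLAG_SPOKE",
    "CameraPose",
    "Trajectory",
    "DisturbanceModel",
    "LawnHole",
    "LawnSpec",
    "spiral_trajectory",
    "lawn_trajectory",
    "spoke_passes",
    "apply_disturbance",
    "concatenate",
]

FLAG_MAIN = "main"
FLAG_TURN = "turn"
FLAG_SPOKE = "spoke"


@dataclass(frozen=True)
class CameraPose:
    """A single camera exposure: time, planar position, altitude, heading."""

    t: float
    x: float
    y: float
    altitude: float
    heading: float
    flag: str = FLAG_MAIN


@dataclass
class Trajectory:
    """An ordered, time-stamped sequence of camera poses.

    Column arrays share one length; times are strictly increasing and
    altitudes positive.  ``flags`` marks each pose as part of a survey leg
    (``main``), an end turn (``turn``) or a spoke pass (``spoke``), so
    evaluation can include or exclude non-leg frames.  ``metadata`` records
    pattern type, parameters and seeds sufficient to reproduce the run.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    altitude: np.ndarray
    heading: np.ndarray
    flags: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = [self.t, self.x, self.y, self.altitude, self.heading, self.flags]
        n = len(self.t)
        if any(len(a) != n for a in arrays):
            raise ValueError("trajectory columns must share one length")
        if n == 0:
            raise ValueError("trajectory must contain at least one pose")
        if np.any(np.diff(self.t) <= 0.0):
            raise ValueError("pose times must be strictly increasing")
        if np.any(self.altitude <= 0.0):
            raise ValueError("altitudes must be positive")

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i: int) -> CameraPose:
        return CameraPose(
            t=float(self.t[i]),
            x=float(self.x[i]),
            y=float(self.y[i]),
            altitude=float(self.altitude[i]),
            heading=float(self.heading[i]),
            flag=str(self.flags[i]),
        )

    def positions(self) -> np.ndarray:
        """(n, 2) array of planar positions."""
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class DisturbanceModel:
    """Seeded AR(1) swell/current disturbance.

    ``sigma_cross`` and ``sigma_altitude`` are the stationary standard
    deviations (meters) of the cross-track and altitude perturbations;
    ``correlation_rho`` is the frame-to-frame AR(1) coefficient in [0, 1).
    Zero sigmas reproduce the ideal path exactly.  For spiral trajectories
    the taut line prevents outward motion, so the cross-track (radial)
    perturbation is applied inward only.
    """

    sigma_cross: float = 0.1
    sigma_altitude: float = 0.05
    correlation_rho: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_cross < 0.0 or self.sigma_altitude < 0.0:
            raise ValueError("sigmas must be non-negative")
        if not 0.0 <= self.correlation_rho < 1.0:
            raise ValueError("correlation_rho must lie in [0, 1)")

    def is_null(self) -> bool:
        return self.sigma_cross == 0.0 and self.sigma_altitude == 0.0


@dataclass(frozen=True)
class LawnHole:
    """A coverage defect on one lawnmower leg.

    The hole spans along-leg distances in the half-open interval
    ``(start, end]`` on leg ``leg_index``.  If ``drop_frames`` is true the
    poses inside the interval are removed (camera failed to record /
    swimmer cut the corner); otherwise the path is laterally displaced by
    ``lateral_offset`` meters over the interval.
    """

    leg_index: int
    start: float
    end: float
    drop_frames: bool = True
    lateral_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0.0 or self.end <= self.start:
            raise ValueError("hole interval must satisfy 0 <= start < end")


@dataclass(frozen=True)
class LawnSpec:
    """Geometry of a boustrophedon survey: legs, spacing and defects."""

    leg_length: float
    spacing: float
    n_legs: int
    holes: tuple = ()

    def __post_init__(self) -> None:
        if self.leg_length <= 0.0:
            raise ValueError("leg_length must be positive")
        if self.spacing <= 0.0:
            raise ValueError("spacing must be positive")
        if self.n_legs < 1:
            raise ValueError("need at least one leg")
        for hole in self.holes:
            if not 0 <= hole.leg_index < self.n_legs:
                raise ValueError(f"hole leg index {hole.leg_index} out of range")
            if hole.end > self.leg_length:
                raise ValueError("hole interval extends beyond the leg")


# ---------------------------------------------------------------------------
# Spiral
# ---------------------------------------------------------------------------

def spiral_trajectory(
    drum: DrumLine,
    camera: CameraModel,
    speed: float,
    altitude: float,
    disturbance: DisturbanceModel | None = None,
) -> Trajectory:
    """Simulate a spiral survey: the involute swum at constant path speed.

    Frames are emitted at the camera frame period from t = 0 until the
    line is fully unwound at t_M = M^2 / (2 R s); the unwound angle at
    time t is alpha(t) = sqrt(2 s t / R), the exact inversion of the
    involute arc length L = R alpha^2 / 2.  Headings are tangent to the
    path (for the involute the tangent direction angle equals alpha,
    modulo 2 pi).  The frame count is floor(t_M / T) + 1.
    """
    if speed <= 0.0:
        raise ValueError("speed must be positive")
    if altitude <= 0.0:
        raise ValueError("altitude must be positive")
    R, M = drum.drum_radius, drum.line_length
    T = camera.frame_period
    t_total = M * M / (2.0 * R * speed)
    if t_total < T:
        raise ValueError(
            "degenerate drum/line: the line unwinds in less than one frame period"
        )
    n_frames = int(math.floor(t_total / T)) + 1
    t = np.arange(n_frames, dtype=float) * T
    alpha = np.sqrt(2.0 * speed * t / R)
    x, y = involute_xy(drum, alpha)
    heading = np.mod(alpha, 2.0 * math.pi)
    traj = Trajectory(
        t=t,
        x=x,
        y=y,
        altitude=np.full(n_frames, float(altitude)),
        heading=heading,
        flags=np.full(n_frames, FLAG_MAIN, dtype=object),
        metadata={
            "pattern": "spiral",
            "drum_radius_m": R,
            "line_length_m": M,
            "speed_m_s": speed,
            "altitude_m": altitude,
            "frame_period_s": T,
            "beta_across_rad": camera.beta_across,
            "beta_along_rad": camera.beta_along,
            "duration_s": t_total,
        },
    )
    if disturbance is not None:
        traj = apply_disturbance(traj, disturbance)
    return traj


# ---------------------------------------------------------------------------
# Lawnmower
# ---------------------------------------------------------------------------

def _lawn_geometry(spec: LawnSpec):
    """Per-segment (length, kind, leg index) list for the boustrophedon path.

    Legs run along y (alternating direction), leg i at x = i * spacing,
    joined by semicircular turns of radius spacing / 2.
    """
    turn_len = math.pi * spec.spacing / 2.0
    segments = []
    for leg in range(spec.n_legs):
        segments.append((spec.leg_length, "leg", leg))
        if leg < spec.n_legs - 1:
            segments.append((turn_len, "turn", leg))
    return segments


def lawn_trajectory(
    spec: LawnSpec,
    camera: CameraModel,
    speed: float,
    altitude: float,
    disturbance: DisturbanceModel | None = None,
) -> Trajectory:
    """Simulate a "mow the lawn" survey sampled at the frame period.

    Parallel legs (along y, spaced ``spec.spacing`` apart in x) are joined
    by semicircular end turns swum at the same speed; poses emitted during
    turns are flagged ``turn``.  Hole injection per ``spec.holes`` either
    drops the frames inside the along-leg interval or displaces them
    laterally.
    """
    if speed <= 0.0 or altitude <= 0.0:
        raise ValueError("speed and altitude must be positive")
    segments = _lawn_geometry(spec)
    seg_len = np.array([s[0] for s in segments])
    bounds = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = bounds[-1]
    T = camera.frame_period
    step = speed * T
    n_frames = int(math.floor(total / step)) + 1
    d = np.arange(n_frames, dtype=float) * step

    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    hs = np.empty(n_frames)
    flags = np.empty(n_frames, dtype=object)
    keep = np.ones(n_frames, dtype=bool)
    half = spec.spacing / 2.0

    # Segment of each sample (right-open intervals; final point -> last segment)
    seg_idx = np.minimum(np.searchsorted(bounds, d, side="right") - 1, len(segments) - 1)
    for i in range(n_frames):
        k = seg_idx[i]
        length, kind, leg = segments[k]
        u = d[i] - bounds[k]  # distance into this segment
        upward = leg % 2 == 0
        if kind == "leg":
            x = leg * spec.spacing
            y = u if upward else spec.leg_length - u
            h = math.pi / 2.0 if upward else -math.pi / 2.0
            for hole in spec.holes:
                if hole.leg_index == leg and hole.start < u <= hole.end:
                    if hole.drop_frames:
                        keep[i] = False
                    else:
                        x += hole.lateral_offset
            xs[i], ys[i], hs[i] = x, y, h
            flags[i] = FLAG_MAIN
        else:
            # Semicircular turn from the end of leg `leg` to the start of leg+1
            cx = leg * spec.spacing + half
            cy = spec.leg_length if upward else 0.0
            theta = u / half  # swept angle, 0..pi
            if upward:  # top turn: CW from west to east of the center
                xs[i] = cx - half * math.cos(theta)
                ys[i] = cy + half * math.sin(theta)
                hs[i] = math.pi / 2.0 - theta
            else:  # bottom turn: CCW below
                xs[i] = cx - half * math.cos(theta)
                ys[i] = cy - half * math.sin(theta)
                hs[i] = -math.pi / 2.0 + theta
            flags[i] = FLAG_TURN
    hs = np.mod(hs, 2.0 * math.pi)

    t = np.arange(n_frames, dtype=float) * T
    traj = Trajectory(
        t=t[keep],
        x=xs[keep],
        y=ys[keep],
        altitude=np.full(int(keep.sum()), float(altitude)),
        heading=hs[keep],
        flags=flags[keep],
        metadata={
            "pattern": "lawn",
            "leg_length_m": spec.leg_length,
            "spacing_m": spec.spacing,
            "n_legs": spec.n_legs,
            "n_holes": len(spec.holes),
            "speed_m_s": speed,
            "altitude_m": altitude,
            "frame_period_s": T,
            "beta_across_rad": camera.beta_across,
            "beta_along_rad": camera.beta_along,
        },
    )
    if disturbance is not None:
        traj = apply_disturbance(traj, disturbance)
    return traj


# ---------------------------------------------------------------------------
# Spokes
# ---------------------------------------------------------------------------

def spoke_passes(
    center: tuple[float, float],
    n_passes: int,
    length: float,
    camera: CameraModel,
    speed: float,
    altitude: float,
    start_time: float = 0.0,
) -> Trajectory:
    """Straight passes over the survey center at evenly spaced orientations.

    Pass k runs through ``center`` at orientation k * pi / n_passes, each
    of the given total length, sampled at the frame period.  Times continue
    monotonically across passes so the result can be concatenated with a
    spiral trajectory.
    """
    if n_passes < 1:
        raise ValueError("need at least one pass")
    if length <= 0.0 or speed <= 0.0 or altitude <= 0.0:
        raise ValueError("length, speed and altitude must be positive")
    T = camera.frame_period
    step = speed * T
    n_per = int(math.floor(length / step)) + 1
    cx, cy = center
    ts, xs, ys, hds = [], [], [], []
    t0 = start_time
    for k in range(n_passes):
        theta = k * math.pi / n_passes
        ux, uy = math.cos(theta), math.sin(theta)
        d = np.arange(n_per) * step - length / 2.0
        ts.append(t0 + np.arange(n_per) * T)
        xs.append(cx + d * ux)
        ys.append(cy + d * uy)
        hds.append(np.full(n_per, theta))
        t0 = ts[-1][-1] + T
    n = n_passes * n_per
    return Trajectory(
        t=np.concatenate(ts),
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        altitude=np.full(n, float(altitude)),
        heading=np.concatenate(hds),
        flags=np.full(n, FLAG_SPOKE, dtype=object),
        metadata={
            "pattern": "spokes",
            "n_passes": n_passes,
            "pass_length_m": length,
            "speed_m_s": speed,
            "altitude_m": altitude,
            "frame_period_s": T,
        },
    )


def concatenate(first: Trajectory, second: Trajectory) -> Trajectory:
    """Join two trajectories in time, shifting the second if needed.

    If the second trajectory starts at or before the end of the first, its
    times are shifted so it begins one frame interval after the first ends.
    """
    dt = np.min(np.diff(second.t)) if len(second) > 1 else 1.0
    shift = 0.0
    if second.t[0] <= first.t[-1]:
        shift = first.t[-1] + dt - second.t[0]
    meta = dict(first.metadata)
    meta["appended"] = second.metadata.get("pattern", "unknown")
    return Trajectory(
        t=np.concatenate([first.t, second.t + shift]),
        x=np.concatenate([first.x, second.x]),
        y=np.concatenate([first.y, second.y]),
        altitude=np.concatenate([first.altitude, second.altitude]),
        heading=np.concatenate([first.heading, second.heading]),
        flags=np.concatenate([first.flags, second.flags]),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Disturbance
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with sd ``sigma`` and coefficient ``rho``."""
    if sigma == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sigma)
    innov = rng.normal(0.0, sigma * math.sqrt(1.0 - rho * rho), size=n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + innov[i - 1]
    return e


def apply_disturbance(traj: Trajectory, model: DisturbanceModel) -> Trajectory:
    """Perturb a trajectory with seeded, autocorrelated swell/current noise.

    Cross-track positions receive an AR(1) offset along the local left
    normal of the heading; altitudes receive an independent AR(1) offset
    (floored at 1 cm).  For spiral trajectories the line is taut, so the
    perturbation is applied radially inward only: the perturbed radius
    never exceeds the ideal (taut-line) radius.  Zero sigmas return the
    trajectory unchanged.
    """
    if model.is_null():
        out = replace(traj)
        out.metadata = dict(traj.metadata)
        return out
    rng = np.random.default_rng(model.seed)
    n = len(traj)
    e_cross = _ar1(rng, n, model.sigma_cross, model.correlation_rho)
    e_alt = _ar1(rng, n, model.sigma_altitude, model.correlation_rho)

    if traj.metadata.get("pattern") == "spiral":
        # Taut line: radial displacement inward only.
        r = np.hypot(traj.x, traj.y)
        shrink = np.clip(r - np.abs(e_cross), 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(r > 0.0, shrink / r, 1.0)
        x = traj.x * scale
        y = traj.y * scale
    else:
        x = traj.x - np.sin(traj.heading) * e_cross
        y = traj.y + np.cos(traj.heading) * e_cross

    meta = dict(traj.metadata)
    meta["disturbance"] = {
        "sigma_cross_m": model.sigma_cross,
        "sigma_altitude_m": model.sigma_altitude,
        "correlation_rho": model.correlation_rho,
        "seed": model.seed,
    }
    return Trajectory(
        t=traj.t.copy(),
        x=x,
        y=y,
        altitude=np.maximum(traj.altitude + e_alt, 0.01),
        heading=traj.heading.copy(),
        flags=traj.flags.copy(),
        metadata=meta,
    )
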