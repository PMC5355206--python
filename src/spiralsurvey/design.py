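"""Closed-form survey design mathematics.

Everything a survey designer needs before getting in the water: camera
ground footprints, the overlap-driven speed and trackline-spacing solvers,
the geometry of the involute of a circle traced by a line unwinding from a
fixed drum, and the derived path length, unwind angle, duration and area of
a spiral survey.  Also provides the grid evaluations behind design contour
charts (footprint over altitude x field of view; path length over drum
diameter x survey area).

Angles are radians throughout this module; the CLI converts from degrees.
The coordinate frame is a right-handed x-y plane in meters with the drum
pole at the origin; the involute starts at (R, 0) and unwinds
counter-clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraModel",
    "DrumLine",
    "SurveyDesign",
    "InvolutePoint",
    "DesignGrid",
    "footprint",
    "design_speed",
    "track_spacing",
    "involute_point",
    "involute_xy",
    "path_length",
    "max_radius",
    "total_unwind_angle",
    "unwind_revolutions",
    "survey_time",
    "survey_area",
    "drum_radius_for_spacing",
    "footprint_grid",
    "footprint_altitude_band",
    "pathlength_grid",
    "plan_survey",
]


@dataclass(frozen=True)
class CameraModel:
    """Down-looking camera: angular fields of view and frame period.

    Parameters
    ----------
    beta_across : float
        Angular field of view across track (perpendicular to the direction
        of travel), radians, in (0, pi).
    beta_along : float
        Angular field of view along track, radians, in (0, pi).
    frame_period : float
        Time between consecutive frames, seconds, > 0.
    """

    beta_across: float
    beta_along: float
    frame_period: float

    def __post_init__(self) -> None:
        for name in ("beta_across", "beta_along"):
            beta = getattr(self, name)
            if not 0.0 < beta < math.pi:
                raise ValueError(f"{name} must lie in (0, pi), got {beta}")
        if self.frame_period <= 0.0:
            raise ValueError(f"frame_period must be positive, got {self.frame_period}")


@dataclass(frozen=True)
class DrumLine:
    """Drum radius R and guide-line length M defining the involute.

    Line thickness is assumed negligible: the drum radius does not change
    as the line unwinds.
    """

    drum_radius: float
    line_length: float

    def __post_init__(self) -> None:
        if self.drum_radius <= 0.0:
            raise ValueError(f"drum_radius must be positive, got {self.drum_radius}")
        if self.line_length <= 0.0:
            raise ValueError(f"line_length must be positive, got {self.line_length}")

    @classmethod
    def from_diameter(cls, diameter: float, line_length: float) -> "DrumLine":
        return cls(drum_radius=diameter / 2.0, line_length=line_length)


@dataclass(frozen=True)
class SurveyDesign:
    """A resolved survey design: altitude, views per point, speed, spacings."""

    altitude: float
    views_n: float
    speed: float
    spacing_across: float
    spacing_along: float

    def __post_init__(self) -> None:
        if self.altitude <= 0.0:
            raise ValueError("altitude must be positive")
        if self.views_n < 1.0:
            raise ValueError("views_n must be >= 1")
        if self.speed <= 0.0:
            raise ValueError("speed must be positive")
        if self.spacing_across <= 0.0 or self.spacing_along <= 0.0:
            raise ValueError("spacings must be positive")


@dataclass(frozen=True)
class InvolutePoint:
    """A point on the involute of a circle, in polar and Cartesian form.

    ``alpha`` is the unwound angle along the drum circumference; the tip of
    the taut line sits at radius r = R*sqrt(1 + alpha^2) and polar angle
    phi = alpha - arctan(alpha).
    """

    alpha: float
    radius: float
    angle: float
    x: float
    y: float


@dataclass(frozen=True)
class DesignGrid:
    """A matrix of a derived design quantity over two parameter axes.

    ``values[i, j]`` corresponds to ``axis1[i]`` and ``axis2[j]``.  Invalid
    cells (e.g. a requested survey area smaller than the drum disc) hold
    NaN.  Contour extraction and plotting are left to the caller.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray
    axis1_label: str = ""
    axis2_label: str = ""
    value_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.axis1), len(self.axis2)):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({len(self.axis1)}, {len(self.axis2)})"
            )


# ---------------------------------------------------------------------------
# Footprint and overlap-driven design solvers
# ---------------------------------------------------------------------------

def footprint(h, beta):
    """Ground footprint b = 2 h tan(beta/2) of a down-looking camera.

    Parameters
    ----------
    h : float or array
        Altitude above the seafloor, meters, > 0.
    beta : float or array
        Angular field of view, radians, in (0, pi).
    """
    h = np.asarray(h, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(h <= 0.0):
        raise ValueError("altitude must be positive")
    if np.any(beta <= 0.0) or np.any(beta >= math.pi):
        raise ValueError("field of view must lie in (0, pi)")
    out = 2.0 * h * np.tan(beta / 2.0)
    return out if out.ndim else float(out)


def design_speed(b_along: float, n: float, T: float) -> float:
    """Survey speed s = b_along / (n T) giving n views of each point.

    ``b_along`` is the along-track footprint, ``n`` the desired number of
    views of each scene point (may be non-integer) and ``T`` the frame
    period in seconds.
    """
    if b_along <= 0.0 or n <= 0.0 or T <= 0.0:
        raise ValueError("b_along, n and T must all be positive")
    return b_along / (n * T)


def track_spacing(b_across: float, n: float) -> float:
    """Trackline spacing across track, b_across / n, for n views."""
    if b_across <= 0.0:
        raise ValueError("b_across must be positive")
    if n < 1.0:
        raise ValueError("fewer than one view per point is meaningless")
    return b_across / n


# ---------------------------------------------------------------------------
# Involute geometry
# ---------------------------------------------------------------------------

def involute_xy(drum: DrumLine, alpha):
    """Cartesian coordinates of the involute tip at unwound angle(s) alpha.

    Pole at the origin, start at (R, 0), counter-clockwise unwinding:
    x = R (cos a + a sin a), y = R (sin a - a cos a).
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0.0):
        raise ValueError("alpha must be non-negative")
    R = drum.drum_radius
    x = R * (np.cos(alpha) + alpha * np.sin(alpha))
    y = R * (np.sin(alpha) - alpha * np.cos(alpha))
    return x, y


def involute_point(drum: DrumLine, alpha: float) -> InvolutePoint:
    """Evaluate the involute at unwound angle alpha (radians, >= 0).

    Returns polar coordinates r = R*sqrt(1+alpha^2), phi = alpha - arctan
    alpha, plus the Cartesian conversion x = r cos(phi), y = r sin(phi).
    In the large-alpha limit, successive revolutions (phi increasing by
    2*pi) are spaced by the drum circumference 2*pi*R.
    """
    if alpha < 0.0:
        raise ValueError("alpha must be non-negative")
    R = drum.drum_radius
    r = R * math.sqrt(1.0 + alpha * alpha)
    phi = alpha - math.atan(alpha)
    return InvolutePoint(
        alpha=alpha, radius=r, angle=phi, x=r * math.cos(phi), y=r * math.sin(phi)
    )


def path_length(drum: DrumLine, alpha: float) -> float:
    """Arc length of the involute from 0 to alpha: L = R alpha^2 / 2."""
    if alpha < 0.0:
        raise ValueError("alpha must be non-negative")
    return 0.5 * drum.drum_radius * alpha * alpha


def max_radius(drum: DrumLine) -> float:
    """Maximum survey radius sqrt(M^2 + R^2) with the line fully unwound."""
    return math.hypot(drum.line_length, drum.drum_radius)


def total_unwind_angle(drum: DrumLine) -> float:
    """Total unwound angle alpha_M = M / R when the line leaves the drum.

    Algebraically identical to sqrt((r_M / R)^2 - 1) with
    r_M = sqrt(M^2 + R^2).
    """
    return drum.line_length / drum.drum_radius


def unwind_revolutions(drum: DrumLine) -> float:
    """Number of drum revolutions to fully unwind: alpha_M / (2 pi)."""
    return total_unwind_angle(drum) / (2.0 * math.pi)


def survey_time(drum: DrumLine, speed: float) -> float:
    """Time to swim the full spiral at constant speed: M^2 / (2 R s)."""
    if speed <= 0.0:
        raise ValueError("speed must be positive")
    M, R = drum.line_length, drum.drum_radius
    return M * M / (2.0 * R * speed)


def survey_area(drum: DrumLine) -> float:
    """Approximate surveyed area: the disc of the maximum radius, pi (M^2 + R^2)."""
    M, R = drum.line_length, drum.drum_radius
    return math.pi * (M * M + R * R)


def drum_radius_for_spacing(spacing: float) -> float:
    """Drum radius whose circumference gives the requested revolution spacing.

    Successive revolutions of the involute are spaced (asymptotically) by
    the drum circumference, so R = spacing / (2 pi).
    """
    if spacing <= 0.0:
        raise ValueError("spacing must be positive")
    return spacing / (2.0 * math.pi)


# ---------------------------------------------------------------------------
# Design grids (contour-chart inputs)
# ---------------------------------------------------------------------------

def footprint_grid(h_values, beta_values) -> DesignGrid:
    """Footprint b(h, beta) over a grid of altitudes and fields of view.

    ``values[i, j] = footprint(h_values[i], beta_values[j])``.
    """
    h = np.asarray(h_values, dtype=float)
    beta = np.asarray(beta_values, dtype=float)
    if h.ndim != 1 or beta.ndim != 1 or len(h) == 0 or len(beta) == 0:
        raise ValueError("axis ranges must be non-empty 1-D sequences")
    if np.any(np.diff(h) <= 0) or np.any(np.diff(beta) <= 0):
        raise ValueError("axis ranges must be strictly increasing")
    values = footprint(h[:, None], beta[None, :])
    return DesignGrid(
        axis1=h,
        axis2=beta,
        values=np.asarray(values),
        axis1_label="altitude_m",
        axis2_label="beta_rad",
        value_label="footprint_m",
    )


def footprint_altitude_band(h: float, beta: float, delta: float = 0.5):
    """Footprint at (h - delta, h, h + delta): the altitude range bar.

    Quantifies how a +/- delta altitude excursion moves the footprint.
    """
    if delta < 0.0 or h - delta <= 0.0:
        raise ValueError("band must stay at positive altitude")
    return tuple(footprint(hh, beta) for hh in (h - delta, h, h + delta))


def pathlength_grid(diameter_values, area_values) -> DesignGrid:
    """Spiral path length over drum diameter x desired survey area.

    For each cell, the line length M making the full-unwind disc match the
    requested area A is M = sqrt(A/pi - R^2) with R = d/2; the path length
    is then M^2 / (2 R).  Cells where A < pi R^2 (area smaller than the
    drum disc) are invalid and hold NaN.
    """
    d = np.asarray(diameter_values, dtype=float)
    A = np.asarray(area_values, dtype=float)
    if d.ndim != 1 or A.ndim != 1 or len(d) == 0 or len(A) == 0:
        raise ValueError("axis ranges must be non-empty 1-D sequences")
    if np.any(d <= 0) or np.any(A <= 0):
        raise ValueError("diameters and areas must be positive")
    if np.any(np.diff(d) <= 0) or np.any(np.diff(A) <= 0):
        raise ValueError("axis ranges must be strictly increasing")
    R = d[:, None] / 2.0
    M_sq = A[None, :] / math.pi - R * R
    with np.errstate(invalid="ignore"):
        values = np.where(M_sq >= 0.0, M_sq / (2.0 * R), np.nan)
    return DesignGrid(
        axis1=d,
        axis2=A,
        values=values,
        axis1_label="drum_diameter_m",
        axis2_label="survey_area_m2",
        value_label="path_length_m",
    )


# ---------------------------------------------------------------------------
# End-to-end design summary
# ---------------------------------------------------------------------------

def plan_survey(
    camera: CameraModel,
    drum: DrumLine,
    altitude: float,
    views_n: float,
    speed: float | None = None,
) -> dict:
    """Resolve a full spiral survey design and return a summary dict.

    If ``speed`` is omitted it is derived from the along-track overlap
    requirement (n views at the camera's frame period).  The summary
    contains the footprints, design speed, trackline spacing, revolution
    spacing set by the drum, number of revolutions, path length, duration
    and approximate area.
    """
    b_across = footprint(altitude, camera.beta_across)
    b_along = footprint(altitude, camera.beta_along)
    s = design_speed(b_along, views_n, camera.frame_period) if speed is None else speed
    if s <= 0.0:
        raise ValueError("speed must be positive")
    design = SurveyDesign(
        altitude=altitude,
        views_n=views_n,
        speed=s,
        spacing_across=track_spacing(b_across, views_n),
        spacing_along=s * camera.frame_period,
    )
    return {
        "altitude_m": altitude,
        "views_n": views_n,
        "footprint_across_m": b_across,
        "footprint_along_m": b_along,
        "footprint_area_m2": b_across * b_along,
        "speed_m_s": design.speed,
        "spacing_across_m": design.spacing_across,
        "spacing_along_m": design.spacing_along,
        "revolution_spacing_m": 2.0 * math.pi * drum.drum_radius,
        "revolutions": unwind_revolutions(drum),
        "path_length_m": path_length(drum, total_unwind_angle(drum)),
        "duration_s": survey_time(drum, design.speed),
        "max_radius_m": max_radius(drum),
        "area_m2": survey_area(drum),
        "design": design,
    }
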