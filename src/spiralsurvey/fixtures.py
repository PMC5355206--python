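"""Deterministic paired spiral / lawnmower test scenarios.

Generates, from a single seed, the four trajectories used throughout the
test suite and the worked examples: an ideal spiral at the reference
design (42 deg / 34 deg camera at 2 Hz, 2 m altitude, 6 m line on a
0.16 m drum, 0.3 m/s), a swell-disturbed variant, an ideal lawnmower
survey of matching swath area at the 0.51 m design spacing, and the same
lawn with two frame-drop coverage holes wider than the along-track
footprint.  Regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .design import CameraModel, DrumLine
from .io import write_pose_table
from .simulate import DisturbanceModel, LawnHole, LawnSpec, Trajectory, lawn_trajectory, spiral_trajectory

__all__ = ["FixtureSet", "reference_camera", "reference_drum", "generate_fixtures"]

#: Names of the generated trajectories, in generation order.
FIXTURE_NAMES = ("spiral_ideal", "spiral_disturbed", "lawn_ideal", "lawn_holes")


def reference_camera() -> CameraModel:
    """The reference imaging configuration: 42/34 degree FOV at 2 Hz."""
    return CameraModel(
        beta_across=math.radians(42.0),
        beta_along=math.radians(34.0),
        frame_period=0.5,
    )


def reference_drum() -> DrumLine:
    """The reference drum and line: 0.16 m diameter drum, 6 m line."""
    return DrumLine.from_diameter(0.16, 6.0)


@dataclass
class FixtureSet:
    """Named trajectories plus the seeds that produced them."""

    trajectories: dict
    seed: int

    def __getitem__(self, name: str) -> Trajectory:
        return self.trajectories[name]


def generate_fixtures(seed: int = 0, outdir=None) -> FixtureSet:
    """Build the paired spiral/lawn scenario set (optionally writing CSVs).

    The lawn matches the spiral's ~113 m^2 swath: 21 legs of 11.1 m at the
    0.51 m across-track design spacing.  The holed variant injects two
    coverage holes, each a 2.5 m frame-drop stretch spanning two adjacent
    legs — wider than the 1.22 m along-track footprint in both directions,
    so the void cannot be bridged laterally by a neighboring leg and
    nearby cameras on opposite sides must link around it.
    """
    camera = reference_camera()
    drum = reference_drum()
    speed, altitude = 0.3, 2.0

    spiral = spiral_trajectory(drum, camera, speed=speed, altitude=altitude)
    disturbed = spiral_trajectory(
        drum,
        camera,
        speed=speed,
        altitude=altitude,
        disturbance=DisturbanceModel(
            sigma_cross=0.1, sigma_altitude=0.05, correlation_rho=0.9,
            seed=(seed * 7919 + 1) % (2**31),
        ),
    )

    lawn_spec = LawnSpec(leg_length=11.1, spacing=0.51, n_legs=21)
    lawn = lawn_trajectory(lawn_spec, camera, speed=speed, altitude=altitude)
    holed_spec = LawnSpec(
        leg_length=11.1,
        spacing=0.51,
        n_legs=21,
        holes=(
            # hole 1: legs 5-6, y in (3.0, 5.5]; leg 5 runs downward so its
            # along-leg interval is mirrored (u = leg_length - y)
            LawnHole(leg_index=5, start=5.6, end=8.1, drop_frames=True),
            LawnHole(leg_index=6, start=3.0, end=5.5, drop_frames=True),
            # hole 2: legs 13-14, y in (6.0, 8.5]
            LawnHole(leg_index=13, start=2.6, end=5.1, drop_frames=True),
            LawnHole(leg_index=14, start=6.0, end=8.5, drop_frames=True),
        ),
    )
    lawn_holes = lawn_trajectory(holed_spec, camera, speed=speed, altitude=altitude)

    trajectories = {
        "spiral_ideal": spiral,
        "spiral_disturbed": disturbed,
        "lawn_ideal": lawn,
        "lawn_holes": lawn_holes,
    }
    for name, traj in trajectories.items():
        traj.metadata["fixture"] = name
        traj.metadata["seed"] = seed

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, traj in trajectories.items():
            write_pose_table(traj, outdir / f"{name}.csv")

    return FixtureSet(trajectories=trajectories, seed=seed)
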