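"""Configuration and file formats: run configs, pose tables, reports.

Pose tables are plain CSV with a commented header carrying a schema
version and the trajectory metadata, so a written table round-trips into
an equivalent :class:`~spiralsurvey.simulate.Trajectory`.  Run configs are
YAML (JSON is valid YAML and accepted too) with angles in degrees at the
interface; they are converted to radians on load.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import CameraModel, DrumLine
from .network import DEFAULT_LINK_THRESHOLD, CoverageReport
from .simulate import DisturbanceModel, Trajectory

__all__ = [
    "POSE_SCHEMA_VERSION",
    "RunConfig",
    "write_pose_table",
    "read_pose_table",
    "write_report",
    "read_report",
    "write_histogram_csv",
    "load_config",
    "save_config",
]

POSE_SCHEMA_VERSION = 1
POSE_COLUMNS = ["frame_index", "t_s", "x_m", "y_m", "altitude_m", "heading_rad", "flag"]


def write_pose_table(trajectory: Trajectory, path) -> None:
    """Write a trajectory as CSV with metadata in leading ``#`` comments."""
    path = Path(path)
    meta = {"schema_version": POSE_SCHEMA_VERSION, **trajectory.metadata}
    frame = pd.DataFrame(
        {
            "frame_index": np.arange(len(trajectory)),
            "t_s": trajectory.t,
            "x_m": trajectory.x,
            "y_m": trajectory.y,
            "altitude_m": trajectory.altitude,
            "heading_rad": trajectory.heading,
            "flag": trajectory.flags,
        }
    )
    with path.open("w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        frame.to_csv(fh, index=False, float_format="%.9f")


def read_pose_table(path) -> Trajectory:
    """Read a pose-table CSV (with or without the metadata comment)."""
    path = Path(path)
    meta = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                meta = json.loads(first.lstrip("# ").strip())
            except json.JSONDecodeError:
                meta = {}
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in POSE_COLUMNS if c not in frame.columns and c != "flag"]
    if missing:
        raise ValueError(f"pose table {path} missing columns: {missing}")
    flags = (
        frame["flag"].astype(str).to_numpy(dtype=object)
        if "flag" in frame.columns
        else np.full(len(frame), "main", dtype=object)
    )
    return Trajectory(
        t=frame["t_s"].to_numpy(float),
        x=frame["x_m"].to_numpy(float),
        y=frame["y_m"].to_numpy(float),
        altitude=frame["altitude_m"].to_numpy(float),
        heading=frame["heading_rad"].to_numpy(float),
        flags=flags,
        metadata=meta,
    )


def write_report(report: CoverageReport, path) -> None:
    """Write a coverage report as JSON (schema-versioned)."""
    payload = {"schema_version": POSE_SCHEMA_VERSION, **report.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path) -> CoverageReport:
    payload = json.loads(Path(path).read_text())
    return CoverageReport(
        median_link_length=payload["median_link_length_m"],
        neighborhood_radius=payload["neighborhood_radius_m"],
        path_length_counts={
            int(k): v for k, v in payload["path_length_counts"].items()
        },
        normalized_histogram={
            int(k): v for k, v in payload["normalized_histogram"].items()
        },
        unreachable_pairs=payload["unreachable_pairs"],
        n_cameras=payload["n_cameras"],
        n_links=payload["n_links"],
        per_camera=None,
    )


def write_histogram_csv(report: CoverageReport, path) -> None:
    """Write the normalized path-length histogram as two-column CSV."""
    frame = pd.DataFrame(
        {
            "path_length_links": list(report.normalized_histogram),
            "fraction": list(report.normalized_histogram.values()),
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parsed run configuration with domain objects resolved.

    Angles are degrees in the file and radians in the objects.
    """

    camera: CameraModel
    drum: DrumLine
    altitude: float
    views_n: float
    speed: float | None
    link_threshold: float
    disturbance: DisturbanceModel | None
    raw: dict

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            cam = data["camera"]
            camera = CameraModel(
                beta_across=math.radians(cam["beta_across_deg"]),
                beta_along=math.radians(cam["beta_along_deg"]),
                frame_period=cam["frame_period_s"],
            )
            dr = data["drum"]
            drum = DrumLine.from_diameter(dr["diameter_m"], dr["line_length_m"])
            des = data["design"]
            altitude = des["altitude_m"]
            views_n = des["views_n"]
        except KeyError as exc:
            raise ValueError(f"config missing required key: {exc}") from exc
        dist = None
        sim = data.get("simulation", {})
        if "disturbance" in sim:
            d = sim["disturbance"]
            dist = DisturbanceModel(
                sigma_cross=d.get("sigma_cross_m", 0.1),
                sigma_altitude=d.get("sigma_altitude_m", 0.05),
                correlation_rho=d.get("correlation_rho", 0.9),
                seed=d.get("seed", 0),
            )
        return cls(
            camera=camera,
            drum=drum,
            altitude=altitude,
            views_n=views_n,
            speed=data.get("speed_m_s"),
            link_threshold=data.get("evaluation", {}).get(
                "link_threshold", DEFAULT_LINK_THRESHOLD
            ),
            disturbance=dist,
            raw=data,
        )


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON) run configuration file."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfig.from_dict(data)


def save_config(data: dict, path) -> None:
    """Write a configuration mapping as YAML."""
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
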