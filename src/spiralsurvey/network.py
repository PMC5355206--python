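"""Photogrammetric link graph and the survey-consistency metric.

Cameras are nodes; an undirected edge links two cameras whose ground
footprints overlap by at least a threshold fraction — a geometric proxy
for a matchable image pair.  Survey quality is scored by a connectivity
metric: take the median Euclidean length of the direct links, define a
circular neighborhood of radius twice that median, and for every ordered
pair of cameras within that distance record the unweighted shortest-path
length in links between them.  A well-designed survey concentrates the
pooled histogram at one and two links; coverage holes force long detours
(three or more links) or leave nearby pairs unreachable.  Because the
neighborhood radius is derived from the link lengths themselves, the
normalized histogram is invariant to uniform geometric scaling of the
survey (footprint size / imaging altitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree
from shapely.affinity import rotate, translate
from shapely.geometry import Polygon, box

from .design import CameraModel, footprint
from .simulate import CameraPose, Trajectory

__all__ = [
    "DEFAULT_LINK_THRESHOLD",
    "CoverageReport",
    "footprint_polygon",
    "overlap_fraction",
    "build_link_graph",
    "coverage_metric",
    "compare_surveys",
]

#: Minimum footprint-overlap fraction for a pair of images to count as a
#: photogrammetric link (a plausible lower bound for feature matching).
DEFAULT_LINK_THRESHOLD = 0.15


def footprint_polygon(pose: CameraPose, camera: CameraModel) -> Polygon:
    """Ground footprint of one pose: an oriented rectangle.

    Centered at the pose's planar position; the along-track side (length
    ``footprint(altitude, beta_along)``) is aligned with the heading and
    the across-track side perpendicular to it.  Rotating the heading by pi
    leaves the rectangle unchanged.
    """
    if pose.altitude <= 0.0:
        raise ValueError("altitude must be positive")
    half_along = footprint(pose.altitude, camera.beta_along) / 2.0
    half_across = footprint(pose.altitude, camera.beta_across) / 2.0
    rect = box(-half_along, -half_across, half_along, half_across)
    rect = rotate(rect, pose.heading, origin=(0, 0), use_radians=True)
    return translate(rect, pose.x, pose.y)


def overlap_fraction(a: Polygon, b: Polygon) -> float:
    """Footprint overlap: intersection area over the smaller footprint's area.

    Symmetric, in [0, 1]; normalizing by the smaller area keeps the
    fraction meaningful when the two frames were taken at different
    altitudes.
    """
    min_area = min(a.area, b.area)
    if min_area <= 0.0:
        raise ValueError("degenerate footprint polygon (zero area)")
    return a.intersection(b).area / min_area


def build_link_graph(
    trajectory: Trajectory,
    camera: CameraModel,
    link_threshold: float = DEFAULT_LINK_THRESHOLD,
    candidate_radius: float | None = None,
    include_flags: set[str] | None = None,
) -> nx.Graph:
    """Build the photogrammetric link graph of a trajectory.

    Nodes are frame indices with a ``pos`` attribute; an edge joins every
    pair of poses whose footprint overlap fraction reaches
    ``link_threshold``, carrying ``overlap`` and ``length`` (Euclidean
    distance between camera positions).  Candidate pairs are pre-pruned
    with a k-d tree at ``candidate_radius`` (default: the sum of the two
    largest footprint half-diagonals, beyond which overlap is impossible);
    the result is independent of the pruning.

    ``include_flags`` restricts the graph to poses with those flags (e.g.
    drop ``turn`` frames); default is all poses.
    """
    if len(trajectory) < 2:
        raise ValueError("need at least two poses to build a link graph")
    if not 0.0 < link_threshold <= 1.0:
        raise ValueError("link_threshold must lie in (0, 1]")

    if include_flags is None:
        idx = np.arange(len(trajectory))
    else:
        idx = np.flatnonzero(np.isin(trajectory.flags, list(include_flags)))
        if len(idx) < 2:
            raise ValueError("fewer than two poses match include_flags")

    polys = [footprint_polygon(trajectory[int(i)], camera) for i in idx]
    pos = trajectory.positions()[idx]

    if candidate_radius is None:
        h_max = float(np.max(trajectory.altitude[idx]))
        diag = math.hypot(
            footprint(h_max, camera.beta_across), footprint(h_max, camera.beta_along)
        )
        candidate_radius = diag  # two half-diagonals

    graph = nx.Graph()
    for k, i in enumerate(idx):
        graph.add_node(int(i), pos=(float(pos[k, 0]), float(pos[k, 1])))

    tree = cKDTree(pos)
    for k, l in tree.query_pairs(candidate_radius):
        frac = overlap_fraction(polys[k], polys[l])
        if frac >= link_threshold:
            graph.add_edge(
                int(idx[k]),
                int(idx[l]),
                overlap=frac,
                length=float(np.hypot(*(pos[k] - pos[l]))),
            )
    graph.graph["link_threshold"] = link_threshold
    return graph


@dataclass
class CoverageReport:
    """Survey-consistency metric output.

    ``path_length_counts`` pools, over all ordered camera pairs closer
    than ``neighborhood_radius`` (= 2 x median direct-link length), the
    shortest-path length in links between them; ``normalized_histogram``
    divides by the number of reachable pairs.  Pairs with no connecting
    path are counted in ``unreachable_pairs`` rather than binned.
    """

    median_link_length: float
    neighborhood_radius: float
    path_length_counts: dict
    normalized_histogram: dict
    unreachable_pairs: int
    n_cameras: int
    n_links: int
    per_camera: pd.DataFrame = field(repr=False, default=None)

    def mass(self, lengths) -> float:
        """Total normalized mass in the given path-length bins."""
        return float(sum(self.normalized_histogram.get(int(k), 0.0) for k in lengths))

    def max_path_length(self) -> int:
        return max(self.path_length_counts) if self.path_length_counts else 0

    def to_dict(self) -> dict:
        return {
            "median_link_length_m": self.median_link_length,
            "neighborhood_radius_m": self.neighborhood_radius,
            "path_length_counts": {str(k): v for k, v in self.path_length_counts.items()},
            "normalized_histogram": {
                str(k): v for k, v in self.normalized_histogram.items()
            },
            "unreachable_pairs": self.unreachable_pairs,
            "n_cameras": self.n_cameras,
            "n_links": self.n_links,
        }


def coverage_metric(graph: nx.Graph) -> CoverageReport:
    """Score a link graph with the shortest-path-in-links neighborhood metric.

    Computes the median Euclidean length of the direct links (midpoint of
    the two central values for an even count); the neighborhood radius is
    twice that.  For every ordered pair (i, j), i != j, of cameras whose
    planar separation is at most the radius, the unweighted shortest-path
    length in links from i to j is recorded; lengths are pooled into
    counts and a histogram normalized over the reachable pairs.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("link graph has no edges; median link length undefined")

    lengths = np.array([d["length"] for _, _, d in graph.edges(data=True)])
    median = float(np.median(lengths))
    radius = 2.0 * median

    nodes = list(graph.nodes)
    pos = np.array([graph.nodes[n]["pos"] for n in nodes])
    n = len(nodes)
    node_index = {u: i for i, u in enumerate(nodes)}

    rows, cols = [], []
    for u, v in graph.edges:
        rows += [node_index[u], node_index[v]]
        cols += [node_index[v], node_index[u]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    hops = shortest_path(adj, method="D", unweighted=True, directed=False)

    tree = cKDTree(pos)
    pairs = tree.query_pairs(radius, output_type="ndarray")  # unordered i<j

    counts: dict[int, int] = {}
    unreachable = 0
    neigh = np.zeros(n, dtype=int)
    unreach_per = np.zeros(n, dtype=int)
    for i, j in pairs:
        neigh[i] += 1
        neigh[j] += 1
        d = hops[i, j]
        if math.isinf(d):
            unreachable += 2  # both ordered directions
            unreach_per[i] += 1
            unreach_per[j] += 1
        else:
            counts[int(d)] = counts.get(int(d), 0) + 2

    reachable = sum(counts.values())
    histogram = (
        {k: c / reachable for k, c in sorted(counts.items())} if reachable else {}
    )
    per_camera = pd.DataFrame(
        {
            "node": nodes,
            "degree": [graph.degree[u] for u in nodes],
            "n_neighbors": neigh,
            "n_unreachable": unreach_per,
        }
    )
    return CoverageReport(
        median_link_length=median,
        neighborhood_radius=radius,
        path_length_counts=dict(sorted(counts.items())),
        normalized_histogram=histogram,
        unreachable_pairs=unreachable,
        n_cameras=n,
        n_links=graph.number_of_edges(),
        per_camera=per_camera,
    )


def compare_surveys(a: CoverageReport, b: CoverageReport) -> dict:
    """Contrast two coverage reports by their histogram mass split.

    Reports the normalized mass at one-and-two-link paths (direct and
    near-direct connectivity), the tail mass at three or more links
    (detours around coverage holes), their differences (a minus b), and
    each survey's maximum observed path length.
    """
    out = {}
    for name, rep in (("a", a), ("b", b)):
        low = rep.mass([1, 2])
        out[name] = {
            "mass_1_2": low,
            "tail_mass": 1.0 - low if rep.normalized_histogram else 0.0,
            "max_path_length": rep.max_path_length(),
            "unreachable_pairs": rep.unreachable_pairs,
        }
    out["difference"] = {
        "mass_1_2": out["a"]["mass_1_2"] - out["b"]["mass_1_2"],
        "tail_mass": out["a"]["tail_mass"] - out["b"]["tail_mass"],
    }
    return out
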