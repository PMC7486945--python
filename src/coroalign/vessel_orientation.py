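"""Per-segment vessel orientation angles and their depth-resolved summaries.

A vessel-vector V_v joins the start and end node of each skeleton segment.
Its *helical angle* is the elevation out of the local circumferential–
radial (g1–g3) plane:

    α_H = 90° − arccos(V_v · g2 / |V_v|),

so 0° is circumferential and ±90° runs apex→base.  Its *projection angle*
is the orientation of the tangent-plane projection V_p = g1 × (V_v × g1)
relative to the circumferential axis g3, folded to the axial range
(−90°, 90°] so it is directly comparable to 2D nuclei orientations.

One local frame is computed per segment, anchored at the segment's
arc-length midpoint; segment start/end order is arbitrary, so every
statistic treats angles axially (α ≡ α + 180°).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular_stats import (
    AngularSample,
    axial_mean,
    fit_sample,
    fold_axial_deg,
)
from .geometry import (
    DegenerateFrameError,
    LocalFrame,
    SurfaceIndex,
    build_frame,
    unit,
)
from .io_core import DepthProfile, SkeletonGraph, SurfaceCloud, logger

__all__ = [
    "VesselVector",
    "LocalAngleField",
    "ExcludedSegmentError",
    "helical_angle",
    "projection_angle",
    "analyze_segments",
    "depth_profile",
    "local_angle_field",
    "normalize_depth",
]

#: segments with |V_p|/|V_v| below this are radial — projection undefined
PROJECTION_TOL = 1e-6


class ExcludedSegmentError(ValueError):
    """Segment cannot contribute an angle (zero-length or radial vector)."""


@dataclass
class VesselVector:
    """Orientation data for one included segment."""

    segment_id: int
    v_v: np.ndarray          # start→end node vector, μm
    depth_um: float
    length_um: float         # polyline length
    helical_deg: float
    projection_deg: float
    midpoint_um: np.ndarray


@dataclass
class LocalAngleField:
    """Per-segment mean helical angle over an axis-aligned 3D window."""

    segment_ids: np.ndarray
    mean_deg: np.ndarray
    window_um: tuple[float, float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"segment_id": self.segment_ids, "mean_angle_deg": self.mean_deg}
        )


def helical_angle(v_v: np.ndarray, frame: LocalFrame) -> float:
    """Elevation of V_v from the g1–g3 plane toward g2, degrees in [−90, 90].

    Segment start/end order is arbitrary, so V_v is first mapped to the
    hemisphere with non-negative circumferential (g3) component (positive
    apex→base component on the boundary): the elevation of an undirected
    line is then single-valued and invariant under direction reversal.
    """
    v_v = np.asarray(v_v, float)
    norm = np.linalg.norm(v_v)
    if norm == 0:
        raise ExcludedSegmentError("zero-length vessel vector")
    c3 = float(np.dot(v_v, frame.g3))
    if c3 < 0 or (c3 == 0 and float(np.dot(v_v, frame.g2)) < 0):
        v_v = -v_v
    c = np.clip(float(np.dot(v_v, frame.g2)) / norm, -1.0, 1.0)
    return 90.0 - float(np.degrees(np.arccos(c)))


def projection_angle(v_v: np.ndarray, frame: LocalFrame) -> float:
    """Axial orientation of the tangent-plane projection of V_v.

    V_p = g1 × (V_v × g1) removes the radial component; the returned angle
    is measured from g3 toward g2 and folded to (−90°, 90°].  A vessel
    running along g1 has no tangent projection and is excluded.
    """
    v_v = np.asarray(v_v, float)
    norm = np.linalg.norm(v_v)
    if norm == 0:
        raise ExcludedSegmentError("zero-length vessel vector")
    v_p = np.cross(frame.g1, np.cross(v_v, frame.g1))
    if np.linalg.norm(v_p) / norm < PROJECTION_TOL:
        raise ExcludedSegmentError("vessel vector is radial; projection undefined")
    ang = np.degrees(np.arctan2(float(np.dot(v_p, frame.g2)), float(np.dot(v_p, frame.g3))))
    return float(fold_axial_deg(ang))


def analyze_segments(
    graph: SkeletonGraph,
    surface: SurfaceCloud | SurfaceIndex,
    v_ab: np.ndarray,
    max_radius_um: float | None = None,
) -> tuple[list[VesselVector], dict[str, int]]:
    """Compute one frame and both angles per segment.

    Frames are anchored at segment midpoints.  Degenerate cases (zero
    depth, g1 parallel to the apex–base axis, zero-length or radial
    vessel-vectors) are excluded from the returned list; exclusion counts
    are logged and returned so they cannot silently bias the statistics.
    An optional radius cutoff excludes large vessels (off by default).
    """
    index = surface if isinstance(surface, SurfaceIndex) else SurfaceIndex(surface)
    v_ab_u = unit(np.asarray(v_ab, float))
    node_xyz = {int(i): xyz for i, xyz in zip(graph.node_ids, graph.node_xyz)}

    counts = {"included": 0, "degenerate_frame": 0, "zero_vector": 0,
              "radial": 0, "radius_cutoff": 0}
    mids = np.array([seg.midpoint for seg in graph.segments])
    dists, idxs = index.query(mids)

    vectors: list[VesselVector] = []
    for seg, mid, depth, si in zip(graph.segments, mids, dists, idxs):
        if max_radius_um is not None and seg.radii is not None:
            if float(np.mean(seg.radii)) > max_radius_um:
                counts["radius_cutoff"] += 1
                continue
        if depth == 0.0:
            counts["degenerate_frame"] += 1
            continue
        g1 = unit(index.points[si] - mid)
        try:
            g2, g3 = build_frame(g1, v_ab_u)
        except DegenerateFrameError:
            counts["degenerate_frame"] += 1
            continue
        frame = LocalFrame(g1=g1, g2=g2, g3=g3, depth_um=float(depth))
        v_v = node_xyz[seg.end_node] - node_xyz[seg.start_node]
        try:
            h = helical_angle(v_v, frame)
            p = projection_angle(v_v, frame)
        except ExcludedSegmentError as exc:
            key = "zero_vector" if "zero-length" in str(exc) else "radial"
            counts[key] += 1
            continue
        counts["included"] += 1
        vectors.append(
            VesselVector(
                segment_id=seg.segment_id,
                v_v=np.asarray(v_v, float),
                depth_um=float(depth),
                length_um=seg.length_um,
                helical_deg=h,
                projection_deg=p,
                midpoint_um=mid,
            )
        )
    excluded = sum(v for k, v in counts.items() if k != "included")
    if excluded:
        logger.info("analyze_segments: excluded %d segments (%s)", excluded, counts)
    return vectors, counts


def depth_profile(
    angles_deg: np.ndarray,
    depths_um: np.ndarray,
    half_width_um: float = 15.0,
    step_um: float = 5.0,
    min_bin_count: int = 10,
    lengths_um: np.ndarray | None = None,
) -> DepthProfile:
    """Moving-window depth profile of axial angles.

    At each evaluation depth (every ``step_um`` from the minimum to the
    maximum sample depth) the axial circular mean, least-squares von Mises
    concentration κ and standard uncertainty u are computed over all
    samples whose depth lies within ±``half_width_um``.  Bins with fewer
    than ``min_bin_count`` samples are reported with NaN statistics (never
    interpolated).  Each segment counts once; pass ``lengths_um`` for the
    optional length-weighted mode.
    """
    angles = np.asarray(angles_deg, float)
    depths = np.asarray(depths_um, float)
    if len(angles) == 0:
        raise ValueError("need at least one sample")
    lo, hi = float(depths.min()), float(depths.max())
    centers = np.arange(lo, hi + step_um / 2, step_um)
    if len(centers) == 0:
        centers = np.array([lo])

    mean = np.full(len(centers), np.nan)
    kappa = np.full(len(centers), np.nan)
    u = np.full(len(centers), np.nan)
    n = np.zeros(len(centers), dtype=int)
    for i, c in enumerate(centers):
        inside = np.abs(depths - c) <= half_width_um
        n[i] = int(inside.sum())
        if n[i] < max(min_bin_count, 1):
            continue
        w = lengths_um[inside] if lengths_um is not None else None
        fit = fit_sample(AngularSample(angles[inside], w))
        mean[i], kappa[i], u[i] = fit.mu_deg, fit.kappa, fit.u_deg
    return DepthProfile(depth=centers, mean_deg=mean, kappa=kappa, u_deg=u, n=n)


def local_angle_field(
    vectors: list[VesselVector],
    window_um: tuple[float, float, float] = (136.0, 136.0, 175.0),
) -> LocalAngleField:
    """Local mean helical angle per segment.

    For each segment, the axial circular mean of the helical angles of all
    segments whose midpoints fall inside the axis-aligned window (full
    extents ``window_um``) centred on its own midpoint.  The window always
    contains the segment itself, so the field is total.
    """
    if not vectors:
        raise ValueError("no vessel vectors")
    from scipy.spatial import cKDTree

    mids = np.array([v.midpoint_um for v in vectors])
    angles = np.array([v.helical_deg for v in vectors])
    half = np.asarray(window_um, float) / 2.0
    # scale axes so the box query becomes a Chebyshev ball of radius 1
    tree = cKDTree(mids / half)
    means = np.empty(len(vectors))
    for i, m in enumerate(mids):
        neighbors = tree.query_ball_point(m / half, 1.0, p=np.inf)
        mu, _ = axial_mean(AngularSample(angles[neighbors]))
        means[i] = mu
    return LocalAngleField(
        segment_ids=np.array([v.segment_id for v in vectors]),
        mean_deg=means,
        window_um=tuple(window_um),
    )


def normalize_depth(profile: DepthProfile, wall_bounds_um: tuple[float, float]) -> DepthProfile:
    """Affinely map profile depths onto the 0–1 wall fraction.

    ``wall_bounds_um`` are the shallowest and deepest segment depths in the
    region of interest; 0 is the vessel closest to the epicardium and 1 the
    closest to the endocardium.  Angles are unchanged.
    """
    lo, hi = wall_bounds_um
    if hi <= lo:
        raise ValueError("wall thickness must be positive")
    return DepthProfile(
        depth=(profile.depth - lo) / (hi - lo),
        mean_deg=profile.mean_deg.copy(),
        kappa=profile.kappa.copy(),
        u_deg=profile.u_deg.copy(),
        n=profile.n.copy(),
        normalized=True,
    )
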