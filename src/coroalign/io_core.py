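"""Core domain types and file I/O.

All internal coordinates and lengths are micrometres (μm), 0-based and
right-handed, with z increasing along the stack slice index.  Density
outputs are converted to mm-based units exactly once, at reporting time
(see :mod:`coroalign.density_and_stats`).

Skeleton dialect
----------------
A skeleton is stored as a directory of three delimited tables:

``nodes.csv``
    columns ``node_id, x_um, y_um, z_um``
``segments.csv``
    columns ``segment_id, start_node, end_node``
``points.csv``
    columns ``segment_id, point_index, x_um, y_um, z_um`` and optionally
    ``radius_um``; rows ordered by ``point_index`` within each segment.

Every segment's first/last point must coincide with its start/end node
coordinates (to 1e-6 μm), mirroring how auto-skeletonization tools export
vessel-points, -nodes and -segments.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("coroalign")

#: coincidence tolerance between segment end points and node coordinates (μm)
NODE_COINCIDENCE_TOL_UM = 1e-6


class FormatError(ValueError):
    """A file is structurally invalid (e.g. a required column is missing)."""


class IntegrityError(ValueError):
    """Tables are individually valid but mutually inconsistent."""


class ConfigurationError(ValueError):
    """Required configuration (e.g. voxel size) is absent."""


def setup_logging(level: int = logging.INFO) -> logging.Logger:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """One vessel centreline segment between two nodes."""

    segment_id: int
    start_node: int
    end_node: int
    #: ordered centreline points, shape (n, 3), μm; n >= 2
    points: np.ndarray
    #: optional per-point radius, shape (n,), μm
    radii: np.ndarray | None = None

    @property
    def length_um(self) -> float:
        """Polyline length: sum of inter-point Euclidean distances."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def midpoint(self) -> np.ndarray:
        """Arc-length midpoint of the polyline (interpolated)."""
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(d)])
        if s[-1] == 0.0:
            return self.points[0].astype(float)
        half = 0.5 * s[-1]
        i = int(np.searchsorted(s, half, side="right") - 1)
        i = min(i, len(d) - 1)
        t = (half - s[i]) / d[i] if d[i] > 0 else 0.0
        return (1 - t) * self.points[i] + t * self.points[i + 1]


@dataclass
class SkeletonGraph:
    """Vessel network as nodes, segments and ordered 3D points (μm)."""

    node_ids: np.ndarray          # (N,) int
    node_xyz: np.ndarray          # (N, 3) float, μm
    segments: list[Segment]

    def validate(self) -> None:
        ids, counts = np.unique(self.node_ids, return_counts=True)
        if np.any(counts > 1):
            raise IntegrityError(f"duplicate node ids: {ids[counts > 1].tolist()}")
        lookup = {int(i): xyz for i, xyz in zip(self.node_ids, self.node_xyz)}
        for seg in self.segments:
            if len(seg.points) < 2:
                raise IntegrityError(
                    f"segment {seg.segment_id} has {len(seg.points)} point(s); need >= 2"
                )
            for which, nid, pt in (
                ("start", seg.start_node, seg.points[0]),
                ("end", seg.end_node, seg.points[-1]),
            ):
                if nid not in lookup:
                    raise IntegrityError(
                        f"segment {seg.segment_id} references missing {which} node {nid}"
                    )
                if np.max(np.abs(lookup[nid] - pt)) > NODE_COINCIDENCE_TOL_UM:
                    raise IntegrityError(
                        f"segment {seg.segment_id} {which} point does not coincide "
                        f"with node {nid}"
                    )

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def total_length_um(self) -> float:
        return float(sum(s.length_um for s in self.segments))


@dataclass
class SurfaceCloud:
    """Points sampled on the epicardial surface, μm."""

    points: np.ndarray  # (M, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) == 0:
            raise ValueError("surface cloud must be a non-empty (M, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("surface cloud contains non-finite coordinates")


@dataclass
class ImageStack:
    """A voxel grid of intensities or binary labels.

    ``data`` is indexed ``[z, y, x]``; ``voxel_size`` is ``(dx, dy, dz)`` in
    μm and ``origin`` is the world coordinate (μm) of the centre of voxel
    ``[0, 0, 0]``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("stack must be a 3-D array with all dimensions >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def slice_depth_um(self, k: int) -> float:
        """World z coordinate (μm) of slice ``k``."""
        return self.origin[2] + k * self.voxel_size[2]


@dataclass
class AnalysisConfig:
    """Run parameters shared across the pipeline.

    The apex→base axis is identified manually on the specimen and supplied
    here as two 3D points; all orientation angles are measured relative to
    the unit vector between them.
    """

    apex_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    base_um: tuple[float, float, float] = (0.0, 0.0, 1.0)
    roi_um: tuple[float, float, float, float, float, float] | None = None
    #: half-width of the moving depth window (μm)
    depth_half_width_um: float = 15.0
    #: axis-aligned local-window extents for the per-vessel angle map (μm)
    local_window_um: tuple[float, float, float] = (136.0, 136.0, 175.0)
    #: angular mask increment for Fourier orientation analysis (degrees)
    mask_increment_deg: float = 5.0
    #: number of depth points profiles are resampled to before correlation
    resample_count: int = 200
    #: evaluation-depth step of the moving window (μm)
    depth_step_um: float = 5.0
    #: minimum segment count before a depth bin's mean is reported
    min_bin_count: int = 10
    #: voxel-size override (dx, dy, dz μm); always wins over file metadata
    voxel_size_um: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if np.allclose(self.apex_um, self.base_um):
            raise ValueError("apex and base points must differ")
        if self.depth_half_width_um <= 0 or any(w <= 0 for w in self.local_window_um):
            raise ValueError("window sizes must be > 0")

    @property
    def v_ab(self) -> np.ndarray:
        """Unit apex→base vector."""
        v = np.asarray(self.base_um, float) - np.asarray(self.apex_um, float)
        return v / np.linalg.norm(v)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("apex_um", "base_um", "local_window_um", "voxel_size_um", "roi_um"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)


@dataclass
class DepthProfile:
    """Depth-resolved axial orientation summary.

    One row per evaluation depth: the axial circular mean (degrees, in
    (−90, 90]), the fitted von Mises concentration κ, the standard
    uncertainty u (degrees) and the sample count n.  Bins with too few
    samples carry NaN statistics but keep their count.
    """

    depth: np.ndarray      # μm, or wall fraction if normalized
    mean_deg: np.ndarray
    kappa: np.ndarray
    u_deg: np.ndarray
    n: np.ndarray          # int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, float)
        self.mean_deg = np.asarray(self.mean_deg, float)
        self.kappa = np.asarray(self.kappa, float)
        self.u_deg = np.asarray(self.u_deg, float)
        self.n = np.asarray(self.n, int)
        if not np.all(np.diff(self.depth) > 0):
            raise ValueError("depth centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.depth)

    def valid(self) -> np.ndarray:
        """Boolean mask of bins with a defined mean."""
        return np.isfinite(self.mean_deg)


# ---------------------------------------------------------------------------
# Skeleton I/O
# ---------------------------------------------------------------------------

_NODE_COLS = ["node_id", "x_um", "y_um", "z_um"]
_SEGMENT_COLS = ["segment_id", "start_node", "end_node"]
_POINT_COLS = ["segment_id", "point_index", "x_um", "y_um", "z_um"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{table} is missing column(s): {missing}")


def read_skeleton(path: str | os.PathLike, dialect: str = "csv-tables") -> SkeletonGraph:
    """Read a skeleton graph from a three-table directory (see module docs)."""
    if dialect != "csv-tables":
        raise FormatError(f"unknown skeleton dialect {dialect!r}")
    root = Path(path)
    for name in ("nodes.csv", "segments.csv", "points.csv"):
        if not (root / name).is_file():
            raise FileNotFoundError(root / name)
    nodes = pd.read_csv(root / "nodes.csv")
    segs = pd.read_csv(root / "segments.csv")
    pts = pd.read_csv(root / "points.csv")
    _require_columns(nodes, _NODE_COLS, "nodes.csv")
    _require_columns(segs, _SEGMENT_COLS, "segments.csv")
    _require_columns(pts, _POINT_COLS, "points.csv")

    has_radius = "radius_um" in pts.columns
    by_segment = dict(iter(pts.sort_values(["segment_id", "point_index"]).groupby("segment_id")))
    segments = []
    for row in segs.itertuples(index=False):
        group = by_segment.get(row.segment_id)
        if group is None:
            raise IntegrityError(f"segment {row.segment_id} has no points")
        segments.append(
            Segment(
                segment_id=int(row.segment_id),
                start_node=int(row.start_node),
                end_node=int(row.end_node),
                points=group[["x_um", "y_um", "z_um"]].to_numpy(float),
                radii=group["radius_um"].to_numpy(float) if has_radius else None,
            )
        )
    graph = SkeletonGraph(
        node_ids=nodes["node_id"].to_numpy(int),
        node_xyz=nodes[["x_um", "y_um", "z_um"]].to_numpy(float),
        segments=segments,
    )
    graph.validate()
    return graph


def write_skeleton(graph: SkeletonGraph, path: str | os.PathLike) -> None:
    """Write a skeleton graph in the three-table directory dialect."""
    graph.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "node_id": graph.node_ids,
            "x_um": graph.node_xyz[:, 0],
            "y_um": graph.node_xyz[:, 1],
            "z_um": graph.node_xyz[:, 2],
        }
    ).to_csv(root / "nodes.csv", index=False)
    pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in graph.segments],
            "start_node": [s.start_node for s in graph.segments],
            "end_node": [s.end_node for s in graph.segments],
        }
    ).to_csv(root / "segments.csv", index=False)
    frames = []
    has_radius = any(s.radii is not None for s in graph.segments)
    for s in graph.segments:
        df = pd.DataFrame(s.points, columns=["x_um", "y_um", "z_um"])
        df.insert(0, "point_index", np.arange(len(df)))
        df.insert(0, "segment_id", s.segment_id)
        if has_radius:
            df["radius_um"] = s.radii if s.radii is not None else np.nan
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(root / "points.csv", index=False)


# ---------------------------------------------------------------------------
# Surface cloud I/O
# ---------------------------------------------------------------------------

def read_surface(path: str | os.PathLike) -> SurfaceCloud:
    df = pd.read_csv(path)
    _require_columns(df, ["x_um", "y_um", "z_um"], Path(path).name)
    return SurfaceCloud(df[["x_um", "y_um", "z_um"]].to_numpy(float))


def write_surface(surface: SurfaceCloud, path: str | os.PathLike) -> None:
    pd.DataFrame(surface.points, columns=["x_um", "y_um", "z_um"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Image stack I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: str | os.PathLike,
    voxel_size_um: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Voxel size comes from ImageJ-style metadata (XResolution/YResolution
    tags plus a z ``spacing`` entry); an explicit ``voxel_size_um`` override
    always wins, since the z pixel size of a confocal stack routinely
    depends on the sample rather than the file.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = _voxel_size_from_tiff(tif)
    if data.ndim == 2:
        data = data[None, :, :]
    if voxel_size_um is not None:
        size = tuple(float(v) for v in voxel_size_um)
    elif meta is not None:
        size = meta
    else:
        raise ConfigurationError(
            f"{path}: no voxel-size metadata and no voxel_size_um override"
        )
    return ImageStack(data=data, voxel_size=size)  # type: ignore[arg-type]


def _voxel_size_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        dx = xres[1] / xres[0]
        dy = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    ij = tif.imagej_metadata or {}
    dz = ij.get("spacing")
    if dz is None:
        return None
    return float(dx), float(dy), float(dz)


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as an ImageJ TIFF with voxel-size metadata."""
    dx, dy, dz = stack.voxel_size
    data = stack.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


# ---------------------------------------------------------------------------
# Profile I/O
# ---------------------------------------------------------------------------

_PROFILE_COLS = ["depth", "mean_angle_deg", "kappa", "u_deg", "n"]


def write_profile(profile: DepthProfile, path: str | os.PathLike) -> None:
    """Write a depth profile as a delimited table (6-decimal precision)."""
    if len(profile) == 0:
        raise ValueError("refusing to write an empty profile")
    df = pd.DataFrame(
        {
            "depth": profile.depth,
            "mean_angle_deg": profile.mean_deg,
            "kappa": profile.kappa,
            "u_deg": profile.u_deg,
            "n": profile.n,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_profile(path: str | os.PathLike, normalized: bool = False) -> DepthProfile:
    df = pd.read_csv(path)
    _require_columns(df, _PROFILE_COLS, Path(path).name)
    return DepthProfile(
        depth=df["depth"].to_numpy(float),
        mean_deg=df["mean_angle_deg"].to_numpy(float),
        kappa=df["kappa"].to_numpy(float),
        u_deg=df["u_deg"].to_numpy(float),
        n=df["n"].to_numpy(int),
        normalized=normalized,
    )
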