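"""Surface-anchored local reference frames.

Each vessel location gets an orthonormal triad anchored to the heart
surface: g1 points from the vessel location toward its nearest epicardial
surface point, g2 is the apex→base axis projected onto the local tangent
plane, and g3 = g2 × g1 is the circumferential direction.  The distance to
the nearest surface point is the location's depth in the wall.

The g3 = g2 × g1 operand order fixes the handedness of the frame and hence
the sign of helical angles; it is applied verbatim everywhere so signs stay
self-consistent across the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_core import ImageStack, SurfaceCloud, logger

__all__ = [
    "LocalFrame",
    "DegenerateFrameError",
    "EmptySurfaceError",
    "SurfaceIndex",
    "nearest_surface",
    "build_frame",
    "frame_at",
    "surface_from_labels",
    "unit",
]

ORTHO_TOL = 1e-9
#: |g1 · V_AB| above this is treated as parallel (tangent projection vanishes)
PARALLEL_TOL = 1e-9


class DegenerateFrameError(ValueError):
    """The local frame is undefined (zero depth, or g1 parallel to V_AB)."""


class EmptySurfaceError(ValueError):
    """No foreground voxels to extract a surface from."""


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize zero vector")
    return np.asarray(v, float) / n


@dataclass
class LocalFrame:
    """Orthonormal triad + depth at one vessel location."""

    g1: np.ndarray   # unit, toward nearest surface point
    g2: np.ndarray   # unit, apex→base projected on tangent plane
    g3: np.ndarray   # unit, circumferential (g2 × g1)
    depth_um: float

    def validate(self) -> None:
        for g in (self.g1, self.g2, self.g3):
            if abs(np.linalg.norm(g) - 1.0) > ORTHO_TOL:
                raise ValueError("frame vectors must be unit length")
        for a, b in ((self.g1, self.g2), (self.g1, self.g3), (self.g2, self.g3)):
            if abs(float(np.dot(a, b))) > ORTHO_TOL:
                raise ValueError("frame vectors must be pairwise orthogonal")
        if self.depth_um < 0:
            raise ValueError("depth must be >= 0")


class SurfaceIndex:
    """KD-tree over a surface cloud for sub-quadratic nearest-point queries.

    Distance ties are broken by the lowest surface-point index so repeated
    runs are deterministic.
    """

    _TIE_REL = 1e-9

    def __init__(self, surface: SurfaceCloud):
        self.points = surface.points
        self._tree = cKDTree(self.points)

    def query(self, xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest distances and surface-point indices for (n, 3) queries."""
        xyz = np.atleast_2d(np.asarray(xyz, float))
        dist, idx = self._tree.query(xyz, k=1)
        # resolve ties toward the lowest index
        for i, (d, p) in enumerate(zip(dist, xyz)):
            ball = self._tree.query_ball_point(p, d * (1 + self._TIE_REL) + 1e-12)
            if len(ball) > 1:
                cand = np.asarray(sorted(ball))
                dd = np.linalg.norm(self.points[cand] - p, axis=1)
                tied = cand[dd <= d * (1 + self._TIE_REL) + 1e-12]
                idx[i] = tied.min()
        return dist, idx


def nearest_surface(
    point_um: np.ndarray, surface: SurfaceCloud | SurfaceIndex
) -> tuple[float, np.ndarray]:
    """Depth and surface-normal-ward direction for one vessel point.

    The depth is the smallest Euclidean distance between the vessel point
    and any surface point; g1 is the unit vector from the vessel point
    toward that nearest surface point.  A zero distance leaves g1 undefined
    and raises :class:`DegenerateFrameError`.
    """
    index = surface if isinstance(surface, SurfaceIndex) else SurfaceIndex(surface)
    dist, idx = index.query(np.asarray(point_um, float))
    depth = float(dist[0])
    if depth == 0.0:
        raise DegenerateFrameError("vessel point coincides with a surface point")
    g1 = unit(index.points[idx[0]] - np.asarray(point_um, float))
    return depth, g1


def build_frame(g1: np.ndarray, v_ab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complete the triad from g1 and the apex→base axis.

    g2 = normalize(g1 × (V_AB × g1)) — the apex→base direction with its g1
    component removed; g3 = g2 × g1.  Raises when g1 is (numerically)
    parallel to V_AB, since the tangent projection then vanishes.
    """
    g1 = np.asarray(g1, float)
    v_ab = np.asarray(v_ab, float)
    g2_raw = np.cross(g1, np.cross(v_ab, g1))
    norm = np.linalg.norm(g2_raw)
    if norm < PARALLEL_TOL or abs(float(np.dot(g1, v_ab))) > 1 - 1e-9:
        raise DegenerateFrameError("g1 is parallel to the apex-base axis")
    g2 = g2_raw / norm
    g3 = np.cross(g2, g1)
    g3 = g3 / np.linalg.norm(g3)
    return g2, g3


def frame_at(
    point_um: np.ndarray,
    surface: SurfaceCloud | SurfaceIndex,
    v_ab: np.ndarray,
) -> LocalFrame:
    """Full local frame (g1, g2, g3, depth) at one vessel location."""
    depth, g1 = nearest_surface(point_um, surface)
    g2, g3 = build_frame(g1, unit(v_ab))
    frame = LocalFrame(g1=g1, g2=g2, g3=g3, depth_um=depth)
    frame.validate()
    return frame


def surface_from_labels(stack: ImageStack, threshold: float) -> SurfaceCloud:
    """Extract the outer boundary of a thresholded stack as a surface cloud.

    Foreground voxels with at least one 6-connected background (or
    out-of-bounds) neighbour are boundary voxels; their world-coordinate
    centres form the cloud.  This stands in for surface extraction from
    low-magnification nuclei-counterstain images.
    """
    fg = stack.data > threshold
    if not fg.any():
        raise EmptySurfaceError("thresholded stack has no foreground")
    interior = ndimage.binary_erosion(fg, structure=ndimage.generate_binary_structure(3, 1))
    boundary = fg & ~interior
    zz, yy, xx = np.nonzero(boundary)
    dx, dy, dz = stack.voxel_size
    ox, oy, oz = stack.origin
    pts = np.column_stack([ox + xx * dx, oy + yy * dy, oz + zz * dz])
    logger.debug("surface_from_labels: %d boundary voxels", len(pts))
    return SurfaceCloud(pts)
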