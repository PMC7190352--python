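"""Projection of detected nuclei to a 2D analysis plane and distance measures.

Detected nuclei arrive as 3D point tables (µm). All downstream scoring works
in a 2D plane obtained by projecting along a chosen axis (for embryos, the
imaging Z axis). Distances are then planar Euclidean distances to the nearest
reference point (YSL nuclei in embryos, wounding-site spots in explants), and
are optionally expressed in *cell tiers* — multiples of the mean cell
diameter, i.e. approximate cell rows from the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError

logger = logging.getLogger("explantquant.geometry")

#: Required columns of a nucleus table (one row per detected nucleus).
NUCLEUS_COLUMNS = [
    "sample_id",
    "nucleus_id",
    "x_um",
    "y_um",
    "z_um",
    "ch_signal_mean",
    "ch_dapi_mean",
    "is_evl",
    "is_dividing",
]

#: Columns of a projected table.
PROJECTED_COLUMNS = ["nucleus_id", "u_um", "v_um"]


@dataclass
class ReferenceSet:
    """Labelled reference points for distance measurements.

    ``label`` is ``"ysl"`` (embryo margin) or ``"wound"`` (explant wounding
    site). ``recenter_point`` is the optional extra landmark used to
    re-position the wounding site at the origin of the analysis plane.
    """

    label: str
    sample_kind: str  # "embryo" | "explant"
    points: np.ndarray  # (n, 3) µm
    recenter_point: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) == 0:
            raise ValidationError("reference points must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("reference points must be finite")
        if self.sample_kind not in ("embryo", "explant"):
            raise ValidationError(f"unknown sample_kind: {self.sample_kind!r}")
        if self.recenter_point is not None:
            self.recenter_point = np.asarray(self.recenter_point, dtype=float).reshape(3)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValidationError("zero-length axis")
    return v / n


@dataclass(frozen=True)
class ProjectionFrame:
    """A 2D analysis plane: projection axis, origin and in-plane basis.

    The in-plane basis convention is Gram–Schmidt from the world X axis
    (falling back to Y when the axis is parallel to X), so (u, v) coordinates
    are reproducible, not just pairwise distances.
    """

    axis: np.ndarray
    origin: np.ndarray
    in_plane_basis: np.ndarray  # (2, 3), rows e_u and e_v

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float).reshape(3))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        basis = np.asarray(self.in_plane_basis, dtype=float).reshape(2, 3)
        object.__setattr__(self, "in_plane_basis", basis)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValidationError("projection axis must be a unit vector")
        gram = basis @ basis.T
        if not np.allclose(gram, np.eye(2), atol=1e-9):
            raise ValidationError("in-plane basis must be orthonormal")
        if np.max(np.abs(basis @ self.axis)) > 1e-9:
            raise ValidationError("in-plane basis must be orthogonal to the axis")

    @classmethod
    def from_axis(cls, axis, origin=(0.0, 0.0, 0.0)) -> "ProjectionFrame":
        """Build a frame from a projection direction by Gram–Schmidt."""
        a = _unit(axis)
        seed = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(seed, a)) > 1.0 - 1e-9:  # axis ∥ X → fall back to Y
            seed = np.array([0.0, 1.0, 0.0])
        e_u = _unit(seed - np.dot(seed, a) * a)
        e_v = np.cross(a, e_u)
        return cls(axis=a, origin=np.asarray(origin, dtype=float),
                   in_plane_basis=np.vstack([e_u, e_v]))


def project_points(points: np.ndarray, frame: ProjectionFrame) -> np.ndarray:
    """Project (n, 3) points into the frame's plane; returns (n, 2) (u, v)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, 3)
    return (pts - frame.origin) @ frame.in_plane_basis.T


def project_to_plane(nuclei: pd.DataFrame, frame: ProjectionFrame) -> pd.DataFrame:
    """Project a nucleus table along ``frame.axis``.

    Returns a projected table (nucleus_id, u_um, v_um) with one row per
    input nucleus.
    """
    if len(nuclei) == 0:
        raise ValidationError("cannot project an empty nucleus table")
    uv = project_points(nuclei[["x_um", "y_um", "z_um"]].to_numpy(), frame)
    return pd.DataFrame(
        {"nucleus_id": nuclei["nucleus_id"].to_numpy(), "u_um": uv[:, 0], "v_um": uv[:, 1]}
    )


@dataclass(frozen=True)
class RigidTransform2D:
    """p ↦ R (p - center), a rotation about ``center`` followed by moving
    ``center`` to the origin."""

    center: np.ndarray
    rotation: np.ndarray  # (2, 2)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.center) @ self.rotation.T


def wound_recenter_transform(wound_points_2d: np.ndarray,
                             recenter_point_2d: np.ndarray) -> RigidTransform2D:
    """Rigid transform placing the wound centroid at the origin, rotated so
    the direction wound-centroid → recenter-point maps onto the +u axis."""
    wound = np.atleast_2d(np.asarray(wound_points_2d, dtype=float))
    if len(wound) == 0:
        raise ValidationError("need at least one wound point")
    centroid = wound.mean(axis=0)
    d = np.asarray(recenter_point_2d, dtype=float) - centroid
    r = np.linalg.norm(d)
    if r < 1e-12:
        raise ValidationError(
            "recenter point coincides with the wound centroid; rotation undefined"
        )
    c, s = d / r
    # rotate by -angle(d): maps d onto +u
    rot = np.array([[c, s], [-s, c]])
    return RigidTransform2D(center=centroid, rotation=rot)


def recenter_on_wound(proj: pd.DataFrame, wound_points_2d: np.ndarray,
                      recenter_point_2d: np.ndarray) -> pd.DataFrame:
    """Re-position the wounding site at the centre of the analysis plane.

    Applies the rigid transform of :func:`wound_recenter_transform` to the
    projected table. Pairwise distances are preserved exactly.
    """
    t = wound_recenter_transform(wound_points_2d, recenter_point_2d)
    out = proj.copy()
    uv = t.apply(out[["u_um", "v_um"]].to_numpy())
    out["u_um"] = uv[:, 0]
    out["v_um"] = uv[:, 1]
    return out


def distance_to_reference(points_2d: np.ndarray, ref_points_2d: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance of each point to any reference point."""
    refs = np.atleast_2d(np.asarray(ref_points_2d, dtype=float))
    if len(refs) == 0:
        raise ValidationError("reference set is empty")
    pts = np.atleast_2d(np.asarray(points_2d, dtype=float))
    dist, _ = cKDTree(refs).query(pts)
    return dist


def to_cell_tiers(dist_um, cell_diameter_um: float):
    """Express a distance in cell tiers (multiples of the mean cell diameter).

    Tiers are continuous; flooring to integer tiers happens only when
    binning counts.
    """
    if not np.isfinite(cell_diameter_um) or cell_diameter_um <= 0:
        raise ValidationError("cell diameter must be positive")
    return np.asarray(dist_um, dtype=float) / cell_diameter_um


def measure_sample(nuclei: pd.DataFrame, refs: ReferenceSet, frame: ProjectionFrame,
                   cell_diameter_um: float):
    """Project a sample and measure nearest-reference distances and tiers.

    For explants (``refs.recenter_point`` set) the plane is re-centred on the
    wounding site first. Returns ``(projected_table, ref_points_2d)`` where
    the projected table carries ``dist_to_ref_um`` and ``tier`` columns and
    the reference points are in the same (possibly re-centred) plane.
    """
    proj = project_to_plane(nuclei, frame)
    refs_2d = project_points(refs.points, frame)
    if refs.recenter_point is not None:
        recenter_2d = project_points(refs.recenter_point, frame)[0]
        t = wound_recenter_transform(refs_2d, recenter_2d)
        uv = t.apply(proj[["u_um", "v_um"]].to_numpy())
        proj["u_um"], proj["v_um"] = uv[:, 0], uv[:, 1]
        refs_2d = t.apply(refs_2d)
    proj["dist_to_ref_um"] = distance_to_reference(
        proj[["u_um", "v_um"]].to_numpy(), refs_2d
    )
    proj["tier"] = to_cell_tiers(proj["dist_to_ref_um"].to_numpy(), cell_diameter_um)
    logger.info("stage=project n=%d ref=%s recentered=%s",
                len(proj), refs.label, refs.recenter_point is not None)
    return proj, refs_2d
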