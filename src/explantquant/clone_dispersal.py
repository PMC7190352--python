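"""Dispersal statistics for a labelled cell clone followed over time.

Two standard proxies for clone dispersion: the mean distance over all
unordered pairs of labelled nuclei, and the mean distance of each nucleus to
the clone's centre of mass. Both are computed per timepoint from 3D nuclear
coordinates; no tracking between timepoints is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import ValidationError


def _as_points(points, mode: str) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValidationError("points must be (n, 3)")
    if mode == "2d":
        return pts[:, :2]
    if mode != "3d":
        raise ValidationError(f"unknown mode: {mode!r}")
    return pts


@dataclass
class CloneTrack:
    """Per-timepoint 3D point sets for one labelled clone."""

    timepoints_min: np.ndarray  # strictly increasing, minutes
    points: list  # list of (n_i, 3) arrays, µm

    def __post_init__(self) -> None:
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        if len(self.timepoints_min) != len(self.points):
            raise ValidationError("one point set per timepoint required")
        if len(self.timepoints_min) == 0:
            raise ValidationError("track has no timepoints")
        if np.any(np.diff(self.timepoints_min) <= 0):
            raise ValidationError("timepoints must be strictly increasing")
        self.points = [np.asarray(p, dtype=float) for p in self.points]
        for i, p in enumerate(self.points):
            if p.ndim != 2 or p.shape[1] != 3 or len(p) < 2:
                raise ValidationError(
                    f"timepoint {self.timepoints_min[i]:g} min needs >=2 (n,3) points"
                )


def mean_pairwise_distance(points, mode: str = "3d") -> float:
    """Mean Euclidean distance over all unordered pairs of points (µm)."""
    pts = _as_points(points, mode)
    if len(pts) < 2:
        raise ValidationError("mean pairwise distance needs at least 2 points")
    return float(pdist(pts).mean())


def mean_centroid_distance(points, mode: str = "3d") -> float:
    """Mean distance of each point to the arithmetic centroid (µm)."""
    pts = _as_points(points, mode)
    if len(pts) == 0:
        raise ValidationError("mean centroid distance needs at least 1 point")
    return float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean())


def dispersal_timecourse(track: CloneTrack, mode: str = "3d") -> pd.DataFrame:
    """Both dispersal metrics per timepoint.

    Returns a DataFrame (timepoint_min, mean_pairwise_um, mean_centroid_um).
    """
    rows = []
    for t, pts in zip(track.timepoints_min, track.points):
        try:
            rows.append(
                {
                    "timepoint_min": t,
                    "mean_pairwise_um": mean_pairwise_distance(pts, mode),
                    "mean_centroid_um": mean_centroid_distance(pts, mode),
                }
            )
        except ValidationError as exc:  # pragma: no cover - guarded by CloneTrack
            raise ValidationError(f"timepoint {t:g} min: {exc}") from exc
    return pd.DataFrame(rows)
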