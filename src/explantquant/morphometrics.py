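"""Shape and expression-domain morphometrics for explants and embryos.

Explants are quantified from manually drawn 2D outlines (µm) plus named
landmark points: the extension tip, the pair of points at the base of the
extension (where curvature changes), cavity edges, and expression-domain
start/end positions along the back–tip axis. Operations cover circularity
(4πA/P²), extension classification and normalized extension length, batch
quality control, cavity localization, 10-bin binary expression profiles,
expression-domain areas with reduction classes, EVL reporter ROI intensity
and cell-size summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import ValidationError

logger = logging.getLogger("explantquant.morphometrics")


@dataclass
class Outline:
    """A closed, simple 2D polygon (µm). The last vertex must not repeat
    the first; closure is implicit."""

    vertices: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("outline vertices must be (n, 2)")
        if len(self.vertices) < 3:
            raise ValidationError("outline needs at least 3 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError("outline vertices must be finite")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValidationError("outline must be a simple polygon with positive area")
        self._polygon = poly

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area_um2(self) -> float:
        return float(self._polygon.area)

    @property
    def perimeter_um(self) -> float:
        return float(self._polygon.length)


@dataclass
class Cavity:
    """One fluid-filled cavity: its two edge points on the back–tip axis and
    its area, used to pick the biggest lumen."""

    edges: tuple  # (point_2d, point_2d)
    area_um2: float

    def __post_init__(self) -> None:
        a, b = self.edges
        self.edges = (np.asarray(a, dtype=float), np.asarray(b, dtype=float))
        if not np.isfinite(self.area_um2) or self.area_um2 <= 0:
            raise ValidationError("cavity area must be positive")


@dataclass
class Landmarks:
    """Named landmark points accompanying an outline."""

    tip: Optional[np.ndarray] = None
    back: Optional[np.ndarray] = None
    extension_base: Optional[tuple] = None  # pair of 2D points at the neck
    cavities: list = field(default_factory=list)  # list[Cavity]
    #: expression domains as (start, end) distances from the tip, µm
    domains_um: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tip is not None:
            self.tip = np.asarray(self.tip, dtype=float)
        if self.back is not None:
            self.back = np.asarray(self.back, dtype=float)
        if self.extension_base is not None:
            a, b = self.extension_base
            self.extension_base = (np.asarray(a, dtype=float), np.asarray(b, dtype=float))


def circularity(outline: Outline) -> float:
    """Circularity 4π·area/perimeter² of the outline, 1 for a circle.

    Clamped to ≤1 against the tiny overshoot a near-circular polygon can
    produce numerically. Invariant to scaling and rigid motion.
    """
    value = 4.0 * math.pi * outline.area_um2 / outline.perimeter_um**2
    return min(value, 1.0)


# Convexity-deficiency threshold of the automatic extension call. Convex
# outlines (circle, ellipse) have deficiency ~0; an extension neck is a
# reflex region that the convex hull closes.
AUTO_EXTENSION_DEFICIENCY = 1e-3


def classify_extension(outline: Outline, landmarks: Optional[Landmarks] = None,
                       mode: str = "manual") -> str:
    """Classify an explant as ``extended`` or ``not_extended``.

    The reference path is the operator's manual call: a sample is extended
    iff extension-base landmarks were supplied. ``mode="auto"`` is a
    heuristic fallback: extended iff the outline's convexity deficiency
    (1 - area/hull_area) exceeds a small threshold, i.e. the shape has a
    neck-like indentation.
    """
    if mode == "manual":
        extended = landmarks is not None and landmarks.extension_base is not None
    elif mode == "auto":
        hull = outline.polygon.convex_hull
        deficiency = 1.0 - outline.area_um2 / hull.area
        extended = deficiency > AUTO_EXTENSION_DEFICIENCY
    else:
        raise ValidationError(f"unknown mode: {mode!r}")
    return "extended" if extended else "not_extended"


def _axis_points(outline: Outline, landmarks: Landmarks):
    if landmarks.tip is None:
        raise ValidationError("tip landmark required")
    tip = landmarks.tip
    if landmarks.back is not None:
        back = landmarks.back
    else:
        # fall back to the outline vertex farthest from the tip
        d = np.linalg.norm(outline.vertices - tip, axis=1)
        back = outline.vertices[int(np.argmax(d))]
    return tip, back


def normalized_extension_length(outline: Outline, landmarks: Optional[Landmarks],
                                include_not_extended: bool = False) -> float:
    """Extension length from the tip to the extension base, normalized to
    the total back–tip length (segmented line through the base midpoint).

    Not-extended samples (no base landmarks) yield 0 when
    ``include_not_extended`` is set, otherwise an error.
    """
    extended = landmarks is not None and landmarks.extension_base is not None
    if not extended:
        if include_not_extended:
            return 0.0
        raise ValidationError(
            "extension-base landmarks missing; pass include_not_extended=True "
            "to score not-extended samples as 0"
        )
    tip, back = _axis_points(outline, landmarks)
    base_mid = (landmarks.extension_base[0] + landmarks.extension_base[1]) / 2.0
    ext = float(np.linalg.norm(tip - base_mid))
    total = ext + float(np.linalg.norm(base_mid - back))
    if total <= 0:
        raise ValidationError("degenerate back-tip axis")
    return ext / total


def batch_qc(control_extended_flags: Sequence[bool], min_fraction: float = 0.70) -> str:
    """Batch passes iff at least ``min_fraction`` of control explants are
    extended."""
    flags = list(control_extended_flags)
    if len(flags) == 0:
        raise ValidationError("empty control group")
    frac = sum(bool(f) for f in flags) / len(flags)
    verdict = "pass" if frac >= min_fraction else "fail"
    logger.info("stage=batch_qc extended=%d/%d verdict=%s", sum(map(bool, flags)),
                len(flags), verdict)
    return verdict


def cavity_position(outline: Outline, landmarks: Landmarks):
    """Normalized cavity location: (tip → nearest cavity edge,
    farthest cavity edge → back), both divided by the total back–tip length.

    With several cavities the biggest lumen is used.
    """
    if not landmarks.cavities:
        raise ValidationError("no cavity landmarks provided")
    tip, back = _axis_points(outline, landmarks)
    cavity = max(landmarks.cavities, key=lambda c: c.area_um2)
    total = float(np.linalg.norm(tip - back))
    if total <= 0:
        raise ValidationError("degenerate back-tip axis")
    d_tip = [float(np.linalg.norm(tip - e)) for e in cavity.edges]
    near = int(np.argmin(d_tip))
    far_edge = cavity.edges[1 - near]
    return d_tip[near] / total, float(np.linalg.norm(back - far_edge)) / total


def bin_domain(domains, total_length_um: float, n_bins: int = 10) -> np.ndarray:
    """Binary presence profile of expression domains along the tip→back axis.

    ``domains`` is one (start, end) pair or a list of pairs, each a distance
    from the tip in µm; multiple domains are OR-combined. Bins are half-open
    [i/n, (i+1)/n), the last closed; a bin scores 1 iff it intersects a
    normalized domain interval with positive length.
    """
    if total_length_um <= 0 or not np.isfinite(total_length_um):
        raise ValidationError("total length must be positive")
    if np.ndim(domains) == 1:
        domains = [domains]
    profile = np.zeros(n_bins, dtype=float)
    for start, end in domains:
        if not (0.0 <= start < end <= total_length_um):
            raise ValidationError(
                f"domain [{start}, {end}] must satisfy 0 <= start < end <= total"
            )
        lo, hi = start / total_length_um, end / total_length_um
        for i in range(n_bins):
            b_lo, b_hi = i / n_bins, (i + 1) / n_bins
            if min(hi, b_hi) - max(lo, b_lo) > 1e-12:
                profile[i] = 1.0
    return profile


def average_profiles(profiles: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of bin profiles (fractional presence per bin)."""
    if len(profiles) == 0:
        raise ValidationError("need at least one profile")
    arrs = [np.asarray(p, dtype=float) for p in profiles]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValidationError("profiles must all have the same length")
    stack = np.vstack(arrs)
    if np.any((stack < 0) | (stack > 1)):
        raise ValidationError("profile values must lie in [0, 1]")
    return stack.mean(axis=0)


def domain_area(outline: Outline) -> float:
    """Area of an expression-domain outline (µm², shoelace)."""
    return outline.area_um2


def classify_mesendoderm_area(area_um2: float, control_mean_area_um2: float,
                              egfp_detected: bool = True):
    """Mesendoderm-induction class from a reporter domain area.

    Returns ``(label, recorded_area)``: ``negative`` (area recorded as 0)
    when no reporter accumulation was detected, ``reduced`` when the area is
    more than 50% smaller than the control mean (strict), ``normal``
    otherwise.
    """
    if not np.isfinite(control_mean_area_um2) or control_mean_area_um2 <= 0:
        raise ValidationError("control mean area must be positive")
    if not egfp_detected:
        return "negative", 0.0
    if area_um2 < 0.5 * control_mean_area_um2:
        return "reduced", float(area_um2)
    return "normal", float(area_um2)


def evl_intensity(z_stack: np.ndarray, n_planes: int,
                  center_roi_area_um2: float = 400.90,
                  bg_roi_side_um: float = 24.91,
                  pixel_size_um: float = 1.0,
                  center=None, bg_origin=(0, 0)) -> float:
    """Background-subtracted EVL reporter intensity from a SUM projection.

    The first ``n_planes`` planes are SUM-projected; the mean over a square
    ROI of ``center_roi_area_um2`` centred on ``center`` (default: image
    centre) minus the mean over a square background ROI of side
    ``bg_roi_side_um`` anchored at ``bg_origin`` (row, col; placed outside
    the sample by the caller).
    """
    stack = np.asarray(z_stack, dtype=float)
    if stack.ndim != 3:
        raise ValidationError("z_stack must be (planes, y, x)")
    if n_planes < 1 or n_planes > stack.shape[0]:
        raise ValidationError(f"n_planes must be in [1, {stack.shape[0]}]")
    proj = stack[:n_planes].sum(axis=0)
    ny, nx = proj.shape

    side_px = max(1, int(round(math.sqrt(center_roi_area_um2) / pixel_size_um)))
    cy, cx = (ny // 2, nx // 2) if center is None else center
    y0, x0 = cy - side_px // 2, cx - side_px // 2
    if y0 < 0 or x0 < 0 or y0 + side_px > ny or x0 + side_px > nx:
        raise ValidationError("centre ROI exceeds image bounds")
    roi = proj[y0:y0 + side_px, x0:x0 + side_px]

    bg_px = max(1, int(round(bg_roi_side_um / pixel_size_um)))
    by, bx = bg_origin
    if by < 0 or bx < 0 or by + bg_px > ny or bx + bg_px > nx:
        raise ValidationError("background ROI exceeds image bounds")
    bg = proj[by:by + bg_px, bx:bx + bg_px]
    return float(roi.mean() - bg.mean())


def cell_diameter_summary(diameters_by_stage) -> pd.DataFrame:
    """Per-stage mean and s.d. of sampled cell diameters (µm).

    ``diameters_by_stage`` maps stage name → sequence of diameters. The s.d.
    is the sample standard deviation, 0 for a single measurement.
    """
    rows = []
    for stage, diams in diameters_by_stage.items():
        d = np.asarray(list(diams), dtype=float)
        if len(d) == 0:
            raise ValidationError(f"stage {stage!r} has no measurements")
        sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
        rows.append({"stage": stage, "mean_um": float(d.mean()), "sd_um": sd, "n": len(d)})
    return pd.DataFrame(rows)
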