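"""Synthetic microscopy point clouds, outlines and clone tracks.

The generators produce data with the geometric and intensity structure the
downstream analyses assume, so the whole pipeline can be exercised with no
external data and with ground truth available for every quantity:

* **Nuclei** are placed uniformly in a hemispherical cap (the blastoderm
  dome). The signal channel carries an exponentially decaying gradient from
  the reference structure — the margin ring of YSL nuclei at the cap rim
  (embryo) or a wounding-site disc at the base centre (explant) — with
  additive Gaussian noise. Both channels are attenuated multiplicatively per
  µm of imaging depth, so the DAPI ratio cancels the attenuation by
  construction. Reference points are laid out at several depth levels
  through the imaging volume, as detected reference spots are in a real
  stack; for the explant wound this keeps the projected 2D nearest-reference
  distance close to the true 3D distance that drives the gradient. The true
  3D distance of every nucleus to the nearest reference point is stored for
  test oracles.
* **Outlines** are circle, ellipse or pear polygons; the pear has an
  extension of exactly known normalized length, with tip and extension-base
  landmarks.
* **Clone tracks** start from a compact Gaussian seed cluster and disperse
  by an independent Gaussian random walk per cell.

All generators are deterministic given their config (one seeded generator
per call).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely import affinity
from shapely.geometry import Point, box
from shapely.geometry.polygon import orient
from shapely.ops import unary_union

from .clone_dispersal import CloneTrack
from .errors import ValidationError
from .geometry import NUCLEUS_COLUMNS, ReferenceSet
from .morphometrics import Landmarks, Outline


def _check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")


def _check_positive(name: str, value: float) -> None:
    _check_finite(name, value)
    if value <= 0:
        raise ValidationError(f"{name} must be > 0, got {value!r}")


def _check_fraction(name: str, value: float) -> None:
    _check_finite(name, value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SyntheticNucleiConfig:
    """Conditions for one synthetic sample.

    Defaults model a wildtype-like explant field: deep cells of ~20 µm at
    50% epiboly–shield stage, a ~250 µm dome, a signal gradient with 40 µm
    decay length and a 20:1 amplitude-to-noise ratio, and a counterstain
    attenuated by 0.1%/µm of depth.
    """

    sample_kind: str = "explant"  # "embryo" | "explant"
    n_nuclei: int = 800
    geometry_radius: float = 250.0  # µm
    cell_diameter: float = 20.0  # µm
    gradient_amplitude: float = 100.0  # a.u.
    gradient_decay_length: float = 40.0  # µm
    intensity_noise_sd: float = 5.0  # a.u.
    dapi_base: float = 200.0  # a.u.
    depth_attenuation_per_um: float = 1e-3  # fraction lost per µm depth
    evl_fraction: float = 0.10
    dividing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_kind not in ("embryo", "explant"):
            raise ValidationError(f"unknown sample_kind: {self.sample_kind!r}")
        if self.n_nuclei < 1:
            raise ValidationError("n_nuclei must be >= 1")
        for name in ("geometry_radius", "cell_diameter", "gradient_decay_length",
                     "dapi_base"):
            _check_positive(name, getattr(self, name))
        for name in ("gradient_amplitude", "intensity_noise_sd"):
            _check_finite(name, getattr(self, name))
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("evl_fraction", "dividing_fraction", "depth_attenuation_per_um"):
            _check_fraction(name, getattr(self, name))


def _reference_points(cfg: SyntheticNucleiConfig) -> np.ndarray:
    """Reference spots spanning the imaging depth.

    Embryo: rings of YSL nuclei at the cap rim, one ring per depth level.
    Explant: a filled wounding-site disc (radius = 2 cell diameters) at the
    base centre, repeated over depth levels.
    """
    R, dc = cfg.geometry_radius, cfg.cell_diameter
    z_levels = np.arange(0.0, 0.5 * R + 1e-9, dc / 2.0)
    pts = []
    if cfg.sample_kind == "embryo":
        for z in z_levels:
            rho = math.sqrt(max(R * R - z * z, 0.0))
            n_ring = max(12, int(round(2 * math.pi * rho / dc)))
            theta = np.linspace(0, 2 * math.pi, n_ring, endpoint=False)
            pts.append(np.column_stack(
                [rho * np.cos(theta), rho * np.sin(theta), np.full(n_ring, z)]))
    else:
        wound_radius = 2.0 * dc
        radii = np.arange(0.0, wound_radius + 1e-9, dc / 2.0)
        for z in z_levels:
            for r in radii:
                n_ring = 1 if r == 0 else max(6, int(round(2 * math.pi * r / (dc / 2.0))))
                theta = np.linspace(0, 2 * math.pi, n_ring, endpoint=False)
                pts.append(np.column_stack(
                    [r * np.cos(theta), r * np.sin(theta), np.full(n_ring, z)]))
    return np.vstack(pts)


def generate_nuclei(cfg: SyntheticNucleiConfig):
    """Generate one synthetic sample.

    Returns ``(nucleus_table, reference_set)``. The nucleus table follows the
    standard schema plus a ``true_dist_um`` column (3D distance to the
    nearest reference point, the distance that drives the gradient).
    """
    rng = np.random.default_rng(cfg.seed)
    R = cfg.geometry_radius

    # uniform in the hemisphere z >= 0
    direction = rng.standard_normal((cfg.n_nuclei, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = R * rng.random(cfg.n_nuclei) ** (1.0 / 3.0)
    pos = direction * radius[:, None]
    pos[:, 2] = np.abs(pos[:, 2])

    refs = _reference_points(cfg)
    true_dist, _ = cKDTree(refs).query(pos)

    depth = R - pos[:, 2]  # imaging from the dome top
    atten = (1.0 - cfg.depth_attenuation_per_um) ** depth
    signal = (cfg.gradient_amplitude * np.exp(-true_dist / cfg.gradient_decay_length)
              * atten + rng.normal(0.0, cfg.intensity_noise_sd, cfg.n_nuclei))
    dapi = cfg.dapi_base * atten + rng.normal(0.0, cfg.intensity_noise_sd, cfg.n_nuclei)

    # outermost shell (largest spherical radius) flagged EVL
    r_sph = np.linalg.norm(pos, axis=1)
    n_evl = int(round(cfg.evl_fraction * cfg.n_nuclei))
    is_evl = np.zeros(cfg.n_nuclei, dtype=bool)
    if n_evl > 0:
        is_evl[np.argsort(r_sph)[-n_evl:]] = True
    is_dividing = rng.random(cfg.n_nuclei) < cfg.dividing_fraction

    sample_id = f"{cfg.sample_kind}_s{cfg.seed}"
    tbl = pd.DataFrame(
        {
            "sample_id": sample_id,
            "nucleus_id": np.arange(cfg.n_nuclei, dtype=int),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
            "ch_signal_mean": signal,
            "ch_dapi_mean": dapi,
            "is_evl": is_evl,
            "is_dividing": is_dividing,
            "true_dist_um": true_dist,
        }
    )
    if cfg.sample_kind == "embryo":
        refset = ReferenceSet(label="ysl", sample_kind="embryo", points=refs)
    else:
        refset = ReferenceSet(label="wound", sample_kind="explant", points=refs,
                              recenter_point=np.array([R / 2.0, 0.0, 0.0]))
    return tbl, refset


@dataclass(frozen=True)
class SyntheticOutlineConfig:
    """Ground-truth outline shapes for the morphometrics benchmarks."""

    shape: str = "pear"  # "circle" | "ellipse" | "pear"
    total_length: float = 600.0  # µm, back-to-tip
    extension_fraction: float = 0.30  # of total length, pear only
    body_width: float = 540.0  # µm
    n_vertices: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "ellipse", "pear"):
            raise ValidationError(f"unknown shape: {self.shape!r}")
        _check_positive("total_length", self.total_length)
        _check_positive("body_width", self.body_width)
        _check_finite("extension_fraction", self.extension_fraction)
        if not 0.0 <= self.extension_fraction < 1.0:
            raise ValidationError("extension_fraction must be in [0, 1)")
        if self.n_vertices < 32:
            raise ValidationError("n_vertices must be >= 32")
        if self.shape == "pear" and self.extension_fraction > 0:
            base_x = (1.0 - self.extension_fraction) * self.total_length
            if not self.body_width / 2.0 < base_x < self.body_width:
                raise ValidationError(
                    "pear geometry requires body_width/2 < (1-f)*total_length "
                    "< body_width so the neck attaches on the forward half of "
                    "the body"
                )


def _resample_boundary(poly, n_vertices: int) -> np.ndarray:
    boundary = orient(poly, sign=1.0).exterior
    s = np.linspace(0.0, boundary.length, n_vertices, endpoint=False)
    return np.array([boundary.interpolate(d).coords[0] for d in s])


def generate_outline(cfg: SyntheticOutlineConfig):
    """Generate an outline with landmarks and its true extension fraction.

    The pear is body circle ∪ neck rectangle ∪ elliptical tip cap; the neck
    half-width equals the body-circle half-width at the extension base, so
    the boundary leaves the body exactly at the configured fraction and the
    landmark-based measurement recovers it up to vertex discretization.
    """
    L, W, f = cfg.total_length, cfg.body_width, cfg.extension_fraction
    quad = max(16, cfg.n_vertices // 4)
    if cfg.shape == "circle":
        poly = Point(L / 2.0, 0.0).buffer(L / 2.0, quad_segs=quad)
        landmarks = Landmarks(tip=(L, 0.0), back=(0.0, 0.0))
        true_f = 0.0
    elif cfg.shape == "ellipse" or f == 0.0:
        poly = affinity.scale(Point(L / 2.0, 0.0).buffer(1.0, quad_segs=quad),
                              L / 2.0, W / 2.0)
        landmarks = Landmarks(tip=(L, 0.0), back=(0.0, 0.0))
        true_f = 0.0
    else:
        r_b = W / 2.0
        base_x = (1.0 - f) * L
        h = math.sqrt(r_b * r_b - (base_x - r_b) ** 2)  # body half-width at base
        a = f * L / 2.0  # axial semi-axis of the tip cap
        parts = [Point(r_b, 0.0).buffer(r_b, quad_segs=quad),
                 box(base_x, -h, L - a, h),
                 affinity.scale(Point(L - a, 0.0).buffer(1.0, quad_segs=quad), a, h)]
        poly = unary_union(parts)
        landmarks = Landmarks(tip=(L, 0.0), back=(0.0, 0.0),
                              extension_base=((base_x, h), (base_x, -h)))
        true_f = f
    outline = Outline(_resample_boundary(poly, cfg.n_vertices))
    return outline, landmarks, true_f


@dataclass(frozen=True)
class CloneSimConfig:
    """Random-walk dispersal of a labelled clone.

    Defaults follow a 2 h acquisition sampled hourly from late sphere stage:
    ~25 labelled cells seeded as a compact cluster, dispersing with a 15 µm
    per-step displacement s.d.
    """

    n_cells: int = 25
    step_sd: float = 15.0  # µm per step
    n_timepoints: int = 3
    timestep: float = 60.0  # minutes
    seed: int = 0
    cluster_sd: float = 15.0  # µm, initial seed-cluster spread

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValidationError("n_cells must be >= 2")
        _check_finite("step_sd", self.step_sd)
        if self.step_sd < 0:
            raise ValidationError("step_sd must be >= 0")
        if self.n_timepoints < 1:
            raise ValidationError("n_timepoints must be >= 1")
        _check_positive("timestep", self.timestep)
        _check_positive("cluster_sd", self.cluster_sd)


def generate_clone_track(cfg: CloneSimConfig) -> CloneTrack:
    """Simulate a clone dispersing by independent Gaussian random walks."""
    rng = np.random.default_rng(cfg.seed)
    pos = rng.normal(0.0, cfg.cluster_sd, (cfg.n_cells, 3))
    points = [pos.copy()]
    for _ in range(cfg.n_timepoints - 1):
        pos = pos + rng.normal(0.0, cfg.step_sd, (cfg.n_cells, 3))
        points.append(pos.copy())
    timepoints = np.arange(cfg.n_timepoints) * cfg.timestep
    return CloneTrack(timepoints_min=timepoints, points=points)


def config_metadata(cfg) -> dict:
    """Serializable record of a generator config (seed included)."""
    return asdict(cfg)
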