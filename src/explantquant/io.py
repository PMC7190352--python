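"""File formats, configuration loading and logging setup.

CSV dialect everywhere: comma-separated, UTF-8, header required, '.'
decimal; units are µm and minutes, encoded in the column names. Landmarks,
configs and results are JSON/YAML.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .clone_dispersal import CloneTrack
from .errors import (
    DuplicateIdError,
    MissingColumnError,
    NonNumericColumnError,
    UnknownConfigKeyError,
    ValidationError,
)
from .geometry import NUCLEUS_COLUMNS, ReferenceSet
from .morphometrics import Cavity, Landmarks, Outline
from .signal_quant import QuantConfig, QuantResult
from .synthetic import CloneSimConfig, SyntheticNucleiConfig, SyntheticOutlineConfig

logger = logging.getLogger("explantquant")

_NUMERIC_NUCLEUS_COLUMNS = ["x_um", "y_um", "z_um", "ch_signal_mean", "ch_dapi_mean"]


def configure_logging(log_file: Optional[Path] = None, level: int = logging.INFO) -> None:
    """Structured log lines to stderr and, optionally, a run log file."""
    root = logging.getLogger("explantquant")
    root.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(name)s %(message)s")
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(fmt)
    root.handlers = [handler]
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        root.addHandler(fh)


def _check_numeric(df: pd.DataFrame, columns, what: str) -> None:
    for col in columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise NonNumericColumnError(f"{what} column {col!r} must be numeric")
        if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
            raise NonNumericColumnError(f"{what} column {col!r} has non-finite values")


def read_nucleus_table(path) -> pd.DataFrame:
    """Read a detected-nucleus table (CSV, coordinates in µm)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in NUCLEUS_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"nucleus table {path} is missing column(s): {', '.join(missing)}"
        )
    _check_numeric(df, _NUMERIC_NUCLEUS_COLUMNS, "nucleus table")
    if df["nucleus_id"].duplicated().any():
        dupes = df.loc[df["nucleus_id"].duplicated(), "nucleus_id"].unique()[:5]
        raise DuplicateIdError(f"duplicate nucleus_id values: {list(dupes)}")
    df["is_evl"] = df["is_evl"].astype(bool)
    df["is_dividing"] = df["is_dividing"].astype(bool)
    logger.info("stage=io read=nucleus_table path=%s rows=%d", path, len(df))
    return df


def write_nucleus_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_reference_set(refs: ReferenceSet, path) -> None:
    rows = pd.DataFrame(refs.points, columns=["x_um", "y_um", "z_um"])
    rows.insert(0, "point_kind", "reference")
    if refs.recenter_point is not None:
        extra = pd.DataFrame([["recenter", *refs.recenter_point]], columns=rows.columns)
        rows = pd.concat([rows, extra], ignore_index=True)
    rows.insert(0, "label", refs.label)
    rows.insert(1, "sample_kind", refs.sample_kind)
    rows.to_csv(path, index=False)


def read_reference_set(path) -> ReferenceSet:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["label", "sample_kind", "point_kind", "x_um", "y_um", "z_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"reference set {path} is missing column(s): {', '.join(missing)}"
        )
    _check_numeric(df, ["x_um", "y_um", "z_um"], "reference set")
    pts = df[df["point_kind"] == "reference"][["x_um", "y_um", "z_um"]].to_numpy()
    rec = df[df["point_kind"] == "recenter"][["x_um", "y_um", "z_um"]].to_numpy()
    return ReferenceSet(
        label=str(df["label"].iloc[0]),
        sample_kind=str(df["sample_kind"].iloc[0]),
        points=pts,
        recenter_point=rec[0] if len(rec) else None,
    )


def write_projected_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_projected_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("nucleus_id", "u_um", "v_um") if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"projected table {path} is missing column(s): {', '.join(missing)}"
        )
    return df


def write_outline(outline: Outline, path) -> None:
    pd.DataFrame(outline.vertices, columns=["x_um", "y_um"]).to_csv(path, index=False)


def read_outline(path) -> Outline:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("x_um", "y_um") if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"outline {path} is missing column(s): {', '.join(missing)}"
        )
    _check_numeric(df, ["x_um", "y_um"], "outline")
    return Outline(df[["x_um", "y_um"]].to_numpy())


def write_landmarks(landmarks: Landmarks, path) -> None:
    def pt(p):
        return None if p is None else [float(p[0]), float(p[1])]

    payload = {
        "tip": pt(landmarks.tip),
        "back": pt(landmarks.back),
        "extension_base": None if landmarks.extension_base is None
        else [pt(landmarks.extension_base[0]), pt(landmarks.extension_base[1])],
        "cavities": [
            {"edges": [pt(c.edges[0]), pt(c.edges[1])], "area_um2": float(c.area_um2)}
            for c in landmarks.cavities
        ],
        "domains_um": [[float(a), float(b)] for a, b in landmarks.domains_um],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_landmarks(path) -> Landmarks:
    payload = json.loads(Path(path).read_text())
    eb = payload.get("extension_base")
    return Landmarks(
        tip=payload.get("tip"),
        back=payload.get("back"),
        extension_base=None if eb is None else (eb[0], eb[1]),
        cavities=[Cavity(edges=(c["edges"][0], c["edges"][1]), area_um2=c["area_um2"])
                  for c in payload.get("cavities", [])],
        domains_um=[tuple(d) for d in payload.get("domains_um", [])],
    )


def write_clone_track(track: CloneTrack, path) -> None:
    rows = []
    for t, pts in zip(track.timepoints_min, track.points):
        for i, p in enumerate(pts):
            rows.append({"timepoint_min": t, "cell_id": i,
                         "x_um": p[0], "y_um": p[1], "z_um": p[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clone_track(path) -> CloneTrack:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["timepoint_min", "cell_id", "x_um", "y_um", "z_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"clone track {path} is missing column(s): {', '.join(missing)}"
        )
    _check_numeric(df, required, "clone track")
    times = np.sort(df["timepoint_min"].unique())
    points = [df[df["timepoint_min"] == t][["x_um", "y_um", "z_um"]].to_numpy()
              for t in times]
    return CloneTrack(timepoints_min=times, points=points)


def write_quant_result(result: QuantResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))


def _dataclass_from_mapping(cls, mapping: dict, where: str):
    """Build a config dataclass, rejecting unknown keys by name."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise UnknownConfigKeyError(
            f"unknown key(s) in {where}: {', '.join(unknown)}"
        )
    kwargs = dict(mapping)
    if cls is QuantConfig and "bg_band" in kwargs:
        kwargs["bg_band"] = tuple(kwargs["bg_band"])
    return cls(**kwargs)


def load_quant_config(mapping_or_path) -> QuantConfig:
    """QuantConfig from a YAML/JSON file or an in-memory mapping."""
    if isinstance(mapping_or_path, (str, Path)):
        mapping = yaml.safe_load(Path(mapping_or_path).read_text()) or {}
    else:
        mapping = dict(mapping_or_path)
    return _dataclass_from_mapping(QuantConfig, mapping, "quant config")


def load_nuclei_config(mapping: dict) -> SyntheticNucleiConfig:
    return _dataclass_from_mapping(SyntheticNucleiConfig, mapping, "nuclei config")


def load_outline_config(mapping: dict) -> SyntheticOutlineConfig:
    return _dataclass_from_mapping(SyntheticOutlineConfig, mapping, "outline config")


def load_clone_config(mapping: dict) -> CloneSimConfig:
    return _dataclass_from_mapping(CloneSimConfig, mapping, "clone config")
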