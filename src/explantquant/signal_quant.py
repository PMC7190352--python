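"""Nuclear signal scoring: pSMAD2/3-style positivity and β-catenin clustering.

The scoring chain mirrors a standard nuclear-immunostain quantification on
spot-detection output:

1. **Filter** — drop EVL, dividing and low-DAPI nuclei; keep nuclei within a
   100 µm imaging-depth window (anchored at the imaging-side z minimum of
   the retained nuclei) and within 150 µm of the reference structure.
2. **Background subtraction** — subtract the mean signal of nuclei in the
   120–150 µm distance band (the far field).
3. **DAPI ratio** — nuclei with non-positive background-subtracted signal
   are discarded; the remaining signal is divided by the DAPI mean to cancel
   depth-dependent attenuation.
4. **Positivity** — ratio strictly above 0.1.
5. **Bright subset** — the top 30% of positive nuclei by ratio.
6. **Domain classification** — present / strongly_reduced / absent from the
   bright count against a control mean (22 for explants, 81 for embryos);
   strongly_reduced at a 50% reduction.

β-catenin positives are summarized as counts per integer cell tier and as an
angular distribution about the wound→brightest-nuclei axis (circular mean
and mean resultant length R̄).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyBackgroundBandError, MissingColumnError, ValidationError
from .geometry import to_cell_tiers

logger = logging.getLogger("explantquant.signal_quant")


@dataclass(frozen=True)
class QuantConfig:
    """All scoring constants of the positivity chain (µm and dimensionless)."""

    z_window: float = 100.0  # µm of imaging depth retained
    max_dist: float = 150.0  # µm from the reference
    bg_band: tuple = (120.0, 150.0)  # µm, closed interval
    ratio_threshold: float = 0.1  # positive iff ratio strictly above
    bright_fraction: float = 0.30  # top fraction of positives kept as bright
    control_bright_mean: dict = field(
        default_factory=lambda: {"explant": 22.0, "embryo": 81.0}
    )
    reduction_fraction: float = 0.5  # strongly_reduced at <= this x control

    def __post_init__(self) -> None:
        if not 0.0 < self.bright_fraction <= 1.0:
            raise ValidationError("bright_fraction must be in (0, 1]")
        lo, hi = self.bg_band
        if not (0.0 <= lo < hi <= self.max_dist):
            raise ValidationError(
                "bg_band must satisfy 0 <= low < high <= max_dist"
            )
        for name in ("z_window", "max_dist", "ratio_threshold", "reduction_fraction"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.z_window <= 0 or self.max_dist <= 0:
            raise ValidationError("z_window and max_dist must be positive")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{what} is missing column(s): {', '.join(missing)}")


def filter_nuclei(tbl: pd.DataFrame, proj: pd.DataFrame, cfg: QuantConfig) -> pd.DataFrame:
    """Apply the exclusion filters and join the projected measurements.

    Drops, in order and each nucleus counted once: EVL-flagged, dividing,
    low-DAPI-flagged (optional ``is_low_dapi`` column), nuclei outside the
    ``z_window`` µm imaging-depth window anchored at the z minimum of the
    flag-passing nuclei, and nuclei farther than ``max_dist`` from the
    reference. Per-reason drop counts are logged and attached as
    ``result.attrs["drops"]``.
    """
    _require_columns(tbl, ["nucleus_id", "z_um", "is_evl", "is_dividing"], "nucleus table")
    _require_columns(proj, ["nucleus_id", "dist_to_ref_um"], "projected table")
    merged = tbl.merge(proj, on="nucleus_id", how="inner", validate="one_to_one")

    drops = {}
    keep = np.ones(len(merged), dtype=bool)
    for reason, mask in (
        ("evl", merged["is_evl"].to_numpy(dtype=bool)),
        ("dividing", merged["is_dividing"].to_numpy(dtype=bool)),
        ("low_dapi", merged["is_low_dapi"].to_numpy(dtype=bool)
         if "is_low_dapi" in merged.columns else np.zeros(len(merged), dtype=bool)),
    ):
        newly = keep & mask
        drops[reason] = int(newly.sum())
        keep &= ~mask

    z = merged["z_um"].to_numpy(dtype=float)
    if keep.any():
        z_min = z[keep].min()
        out_z = keep & (z > z_min + cfg.z_window)
    else:
        out_z = np.zeros(len(merged), dtype=bool)
    drops["z_window"] = int(out_z.sum())
    keep &= ~out_z

    far = keep & (merged["dist_to_ref_um"].to_numpy(dtype=float) > cfg.max_dist)
    drops["distance"] = int(far.sum())
    keep &= ~far

    result = merged[keep].reset_index(drop=True)
    result.attrs["drops"] = drops
    for reason, n in drops.items():
        logger.info("stage=filter reason=%s dropped=%d", reason, n)
    logger.info("stage=filter kept=%d of=%d", len(result), len(merged))
    return result


def subtract_background(tbl: pd.DataFrame, cfg: QuantConfig,
                        background: Optional[float] = None) -> pd.DataFrame:
    """Subtract the far-field background from the signal channel.

    The background is the mean raw signal of nuclei whose distance to the
    reference lies in the closed ``bg_band`` interval; an explicit
    ``background`` value overrides it (required when the band is empty).
    Adds a ``signal_bgsub`` column; the band mean of ``signal_bgsub`` is 0.
    """
    _require_columns(tbl, ["ch_signal_mean", "dist_to_ref_um"], "nucleus table")
    if background is None:
        lo, hi = cfg.bg_band
        d = tbl["dist_to_ref_um"].to_numpy(dtype=float)
        band = (d >= lo) & (d <= hi)
        if not band.any():
            raise EmptyBackgroundBandError(
                f"no nuclei in the background band [{lo}, {hi}] µm; widen the "
                "band or supply an explicit background value"
            )
        background = float(tbl.loc[band, "ch_signal_mean"].mean())
    out = tbl.copy()
    out["signal_bgsub"] = out["ch_signal_mean"] - background
    out.attrs["background"] = float(background)
    logger.info("stage=background value=%.4g", background)
    return out


def compute_ratio(tbl: pd.DataFrame) -> pd.DataFrame:
    """DAPI-normalized signal ratio for depth correction.

    Nuclei with non-positive background-subtracted signal, or with
    non-positive DAPI, are dropped (with logged counts) before positivity
    calling. Adds ``ratio`` (bgsub/DAPI) and ``ratio_raw`` (raw/DAPI, the
    depth-corrected profile before background subtraction, used for
    gradient fitting).
    """
    _require_columns(tbl, ["signal_bgsub", "ch_dapi_mean"], "nucleus table")
    dapi = tbl["ch_dapi_mean"].to_numpy(dtype=float)
    bgsub = tbl["signal_bgsub"].to_numpy(dtype=float)
    bad_dapi = dapi <= 0
    nonpos = ~bad_dapi & (bgsub <= 0)
    keep = ~(bad_dapi | nonpos)
    if bad_dapi.any():
        logger.info("stage=ratio reason=nonpositive_dapi dropped=%d", bad_dapi.sum())
    if nonpos.any():
        logger.info("stage=ratio reason=nonpositive_signal dropped=%d", nonpos.sum())
    out = tbl[keep].reset_index(drop=True)
    out["ratio"] = out["signal_bgsub"] / out["ch_dapi_mean"]
    out["ratio_raw"] = out["ch_signal_mean"] / out["ch_dapi_mean"]
    out.attrs["drops_ratio"] = {"nonpositive_dapi": int(bad_dapi.sum()),
                                "nonpositive_signal": int(nonpos.sum())}
    out.attrs.update(tbl.attrs)
    return out


def call_positive(tbl: pd.DataFrame, cfg: QuantConfig) -> pd.DataFrame:
    """Flag positive nuclei: ratio strictly above the threshold."""
    _require_columns(tbl, ["ratio"], "nucleus table")
    out = tbl.copy()
    out["is_positive"] = out["ratio"].to_numpy(dtype=float) > cfg.ratio_threshold
    return out


def percent_positive(tbl: pd.DataFrame) -> float:
    """Percentage of positive nuclei among the considered nuclei."""
    if len(tbl) == 0:
        raise ValidationError("percent_positive is undefined on an empty table")
    _require_columns(tbl, ["is_positive"], "nucleus table")
    return 100.0 * float(tbl["is_positive"].sum()) / len(tbl)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_brightest(tbl: pd.DataFrame, cfg: QuantConfig) -> pd.DataFrame:
    """The top ``bright_fraction`` of positive nuclei by ratio.

    k = max(1, round-half-up(fraction · n_positive)); empty when there are
    no positives. Ties are broken by nucleus_id for determinism.
    """
    _require_columns(tbl, ["ratio", "is_positive", "nucleus_id"], "nucleus table")
    pos = tbl[tbl["is_positive"]]
    if len(pos) == 0:
        return pos.iloc[0:0]
    k = max(1, _round_half_up(cfg.bright_fraction * len(pos)))
    ordered = pos.sort_values(["ratio", "nucleus_id"], ascending=[False, True],
                              kind="mergesort")
    return ordered.head(k).reset_index(drop=True)


def tier_profile(subset: pd.DataFrame, cell_diameter_um: Optional[float] = None):
    """Per-nucleus (tier, normalized intensity) plus per-integer-tier means.

    Intensities are normalized to the maximum ratio in the subset, mapping
    the profile to (0, 1]. Tiers are taken from the table's ``tier`` column,
    or recomputed from ``dist_to_ref_um`` when ``cell_diameter_um`` is given.
    Returns ``(per_nucleus, per_tier)`` DataFrames.
    """
    if len(subset) == 0:
        raise ValidationError("tier_profile needs a non-empty subset")
    _require_columns(subset, ["nucleus_id", "ratio"], "subset")
    if cell_diameter_um is not None:
        _require_columns(subset, ["dist_to_ref_um"], "subset")
        tiers = to_cell_tiers(subset["dist_to_ref_um"].to_numpy(), cell_diameter_um)
    else:
        _require_columns(subset, ["tier"], "subset")
        tiers = subset["tier"].to_numpy(dtype=float)
    ratio = subset["ratio"].to_numpy(dtype=float)
    norm = ratio / ratio.max()
    per_nucleus = pd.DataFrame(
        {"nucleus_id": subset["nucleus_id"].to_numpy(), "tier": tiers,
         "ratio": ratio, "norm_intensity": norm}
    )
    per_tier = (
        per_nucleus.assign(tier_bin=np.floor(tiers).astype(int))
        .groupby("tier_bin", as_index=False)
        .agg(mean_norm_intensity=("norm_intensity", "mean"), n=("nucleus_id", "size"))
    )
    return per_nucleus, per_tier


def fit_decay_length(dist_um, intensity, bin_width_um: Optional[float] = None,
                     min_bin_fraction: float = 0.05, min_bin_n: int = 3,
                     method: str = "loglinear") -> float:
    """Decay length λ of an exponential profile intensity ≈ A·exp(−d/λ).

    Pass *all* considered nuclei, noise and all — not a positivity-selected
    subset: selecting nuclei with positive (or supra-threshold) intensity
    truncates the noise distribution and flattens the apparent profile.
    Intended for the depth-corrected pre-subtraction profile
    (``ratio_raw``), which is exponential when the underlying gradient is;
    the background-subtracted ratio is exponential minus a constant and
    would bias the fit.

    ``method="loglinear"``: with ``bin_width_um`` the intensities are first
    averaged in distance bins and the fit runs on ln(bin mean) vs bin
    centre, over bins with at least ``min_bin_n`` nuclei and a mean of at
    least ``min_bin_fraction`` of the peak bin mean, weighted by the
    inverse log-variance; binning before taking logs averages the additive
    noise out. Without ``bin_width_um`` the fit is per-nucleus on positive
    intensities (appropriate only when noise is negligible).

    ``method="nls"``: per-nucleus nonlinear least squares of A·exp(−d/λ),
    which also uses the sub-noise far field and is the better-powered
    choice when few nuclei survive the filter chain (short decay lengths
    inside a thin imaging slab).
    """
    d = np.asarray(dist_um, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if method == "nls":
        if len(y) < 3:
            raise ValidationError("need at least 3 nuclei to fit a decay")
        from scipy.optimize import curve_fit

        p0 = (max(float(y.max()), 1e-6), max(float(d.max()) / 4.0, 1.0))
        try:
            popt, _ = curve_fit(lambda x, a, lam: a * np.exp(-x / lam), d, y,
                                p0=p0, maxfev=10000)
        except RuntimeError as exc:
            raise ValidationError(f"decay fit did not converge: {exc}") from exc
        if popt[1] <= 0:
            raise ValidationError("profile does not decay; decay length undefined")
        return float(popt[1])
    if method != "loglinear":
        raise ValidationError(f"unknown fit method: {method!r}")
    if bin_width_um is not None:
        if bin_width_um <= 0:
            raise ValidationError("bin width must be positive")
        idx = np.floor(d / bin_width_um).astype(int)
        centers, means, counts = [], [], []
        for b in np.unique(idx):
            sel = idx == b
            centers.append((b + 0.5) * bin_width_um)
            means.append(y[sel].mean())
            counts.append(sel.sum())
        centers, means = np.asarray(centers), np.asarray(means)
        counts = np.asarray(counts)
        ok = (counts >= min_bin_n) & (means > 0)
        if ok.any():
            ok &= means >= min_bin_fraction * means[ok].max()
        d, y = centers[ok], means[ok]
        # var(ln mean) ≈ sigma² / (n · mean²); weight by its inverse
        w = np.sqrt(counts[ok]) * means[ok]
    else:
        keep = y > 0
        d, y = d[keep], y[keep]
        w = None
    if len(y) < 3:
        raise ValidationError("need at least 3 positive intensities/bins to fit a decay")
    slope, _ = np.polyfit(d, np.log(y), 1, w=w)
    if slope >= 0:
        raise ValidationError("profile does not decay; decay length undefined")
    return -1.0 / slope


def classify_domain(n_bright: int, sample_kind: str, cfg: QuantConfig) -> str:
    """Classify a sample's signal domain from its bright-nucleus count.

    ``absent`` when no bright nuclei are detected; ``strongly_reduced`` when
    the count is at or below ``reduction_fraction`` of the control mean for
    the sample kind; ``present`` otherwise.
    """
    if n_bright < 0:
        raise ValidationError("n_bright must be >= 0")
    if sample_kind not in cfg.control_bright_mean:
        raise ValidationError(f"no control bright mean configured for {sample_kind!r}")
    if n_bright == 0:
        return "absent"
    if n_bright <= cfg.reduction_fraction * cfg.control_bright_mean[sample_kind]:
        return "strongly_reduced"
    return "present"


def bcat_counts_by_tier(dist_um, sampled_diameters_um) -> pd.Series:
    """Counts of positive nuclei per integer cell tier.

    The cell diameter is the mean of the sampled diameters (typically 10
    randomly measured cells per sample); tiers are floored for counting.
    """
    diams = np.asarray(list(sampled_diameters_um), dtype=float)
    if len(diams) == 0:
        raise ValidationError("need at least one sampled cell diameter")
    d = np.asarray(dist_um, dtype=float)
    if len(d) == 0:
        raise ValidationError("need at least one positive nucleus")
    tiers = np.floor(to_cell_tiers(d, float(diams.mean()))).astype(int)
    return pd.Series(tiers).value_counts().sort_index()


@dataclass
class AngularStats:
    """Angular distribution summary about a reference axis."""

    angles_deg: np.ndarray  # per-nucleus angle in (-180, 180]
    circular_mean_deg: float
    mean_resultant_length: float  # R̄ in [0, 1]; 1 = no dispersion


def angular_dispersion(points_2d, wound_centroid, bright_index) -> AngularStats:
    """Angles of positive nuclei about the wound → brightest-nuclei axis.

    The reference axis runs from the wound centroid to the centroid of the
    brightest nuclei (``bright_index``: boolean mask or integer indices into
    ``points_2d``); those nuclei are excluded from the angle set. Angles lie
    in (−180°, 180°]; the summary is the circular mean and the mean
    resultant length R̄ = |mean unit vector|.
    """
    pts = np.atleast_2d(np.asarray(points_2d, dtype=float))
    centroid = np.asarray(wound_centroid, dtype=float)
    bright = np.zeros(len(pts), dtype=bool)
    bright[np.asarray(bright_index)] = True
    if not bright.any():
        raise ValidationError("need at least one brightest nucleus to define the axis")
    axis = pts[bright].mean(axis=0) - centroid
    if np.linalg.norm(axis) < 1e-12:
        raise ValidationError("brightest-nuclei centroid coincides with the wound")
    rest = pts[~bright] - centroid
    lengths = np.linalg.norm(rest, axis=1)
    rest = rest[lengths > 1e-12]
    if len(rest) == 0:
        raise ValidationError(
            "all remaining positive nuclei coincide with the wound centroid"
        )
    axis_angle = math.atan2(axis[1], axis[0])
    raw = np.arctan2(rest[:, 1], rest[:, 0]) - axis_angle
    wrapped = np.angle(np.exp(1j * raw))  # (-pi, pi]
    wrapped[wrapped == -math.pi] = math.pi
    mean_vec = np.exp(1j * wrapped).mean()
    return AngularStats(
        angles_deg=np.degrees(wrapped),
        circular_mean_deg=math.degrees(np.angle(mean_vec)),
        mean_resultant_length=float(abs(mean_vec)),
    )


@dataclass
class QuantResult:
    """Summary of one sample's scoring chain."""

    sample_id: str
    sample_kind: str
    n_considered: int
    n_positive: int
    percent_positive: float
    n_bright: int
    bright_ids: list
    classification: str
    background: float
    drops: dict

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "sample_kind": self.sample_kind,
            "n_considered": self.n_considered,
            "n_positive": self.n_positive,
            "percent_positive": self.percent_positive,
            "n_bright": self.n_bright,
            "bright_ids": [int(i) for i in self.bright_ids],
            "classification": self.classification,
            "background": self.background,
            "drops": self.drops,
        }


def quantify_sample(tbl: pd.DataFrame, proj: pd.DataFrame, cfg: QuantConfig,
                    sample_kind: str, background: Optional[float] = None):
    """Run the full scoring chain on one sample.

    Returns ``(QuantResult, scored_table)`` where the scored table carries
    per-nucleus ratio, positivity, bright flag and tier.
    """
    sample_id = str(tbl["sample_id"].iloc[0]) if "sample_id" in tbl and len(tbl) else ""
    filtered = filter_nuclei(tbl, proj, cfg)
    drops = dict(filtered.attrs.get("drops", {}))
    if len(filtered) == 0:
        result = QuantResult(sample_id, sample_kind, 0, 0, 0.0, 0, [], "absent",
                             float("nan"), drops)
        return result, filtered
    bgsub = subtract_background(filtered, cfg, background=background)
    scored = call_positive(compute_ratio(bgsub), cfg)
    drops.update(scored.attrs.get("drops_ratio", {}))
    bright = select_brightest(scored, cfg)
    scored["is_bright"] = scored["nucleus_id"].isin(bright["nucleus_id"]).to_numpy()
    n_pos = int(scored["is_positive"].sum())
    pct = percent_positive(scored) if len(scored) else 0.0
    result = QuantResult(
        sample_id=sample_id,
        sample_kind=sample_kind,
        n_considered=len(scored),
        n_positive=n_pos,
        percent_positive=pct,
        n_bright=len(bright),
        bright_ids=list(bright["nucleus_id"]),
        classification=classify_domain(len(bright), sample_kind, cfg),
        background=float(bgsub.attrs["background"]),
        drops=drops,
    )
    logger.info("stage=quantify sample=%s considered=%d positive=%d bright=%d class=%s",
                sample_id, result.n_considered, n_pos, result.n_bright,
                result.classification)
    return result, scored
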