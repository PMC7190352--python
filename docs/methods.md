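# Methods

## Scope and data model

The pipeline consumes the *output* of nucleus spot detection, not images:
a nucleus table (one row per detected nucleus: `x_um, y_um, z_um`,
`ch_signal_mean`, `ch_dapi_mean`, QC flags `is_evl`, `is_dividing`,
optional `is_low_dapi`) plus a reference set (YSL-margin or wounding-site
points, with an optional re-centring landmark for explants). Morphometric
operations consume closed 2D outlines (µm) with named landmarks; clone
dispersal consumes per-timepoint 3D point sets. All lengths are µm, times
minutes; CSV is comma-separated UTF-8 with '.' decimals, and floats are
parsed round-trip exactly.

## Projection and distance measurement

Nuclei are projected along a user-chosen axis (embryos: the imaging Z
axis). The in-plane basis is fixed by Gram–Schmidt from the world X axis
(falling back to Y when the axis is parallel to X); only pairwise distances
and angles matter downstream, but a fixed convention makes the raw (u, v)
coordinates reproducible and testable. For explants the plane is re-centred
by the rigid map p ↦ R(p − c), where c is the wound centroid and R rotates
the direction c → recentre-landmark onto +u; a pure translation would give
identical distances — the rotation only standardizes orientation. The
distance of each nucleus is the planar Euclidean distance to the nearest
reference point (k-d tree; the test suite checks it against an exhaustive
double loop). Cell tiers are d/⟨cell diameter⟩, kept continuous; flooring
happens only when counting per tier.

## Nuclear signal scoring

The chain applies, in order:

1. flag filters (EVL, dividing, low-DAPI), each drop counted once under its
   first matching reason;
2. an imaging-depth window of `z_window` = 100 µm, anchored at the minimum
   z of the flag-passing nuclei (the imaging-side surface) — the anchor is
   a choice, since only the window's extent is standard;
3. a range filter `max_dist` = 150 µm from the reference (applied uniformly
   to pSMAD2/3-style and β-catenin-style channels; configurable);
4. background subtraction: mean raw signal of nuclei with distance in the
   closed band [120, 150] µm; an explicit background value can be supplied
   when the band is empty;
5. nuclei with non-positive background-subtracted signal or non-positive
   DAPI are dropped (logged);
6. ratio = background-subtracted signal / DAPI mean. Multiplying both
   channels by a common depth factor cancels here, which is the point of
   DAPI normalization;
7. positive ⇔ ratio strictly above `ratio_threshold` = 0.1;
8. bright subset: the k = max(1, round-half-up(0.30 · n_positive))
   highest-ratio positives, ties broken by nucleus id (the rounding rule
   and tie-break are conventions chosen for determinism);
9. classification from the bright count n against the control mean m (22
   explant / 81 embryo): absent if n = 0, strongly_reduced if
   n ≤ 0.5 · m (the boundary itself counts as reduced), present otherwise.

Tier profiles report per-nucleus (tier, ratio) with intensities normalized
to the per-sample maximum bright ratio, mapping profiles to (0, 1]; the
normalization constant is a convention and is stated here because other
choices (e.g. control-sample maximum) would rescale but not reorder
profiles.

Angular dispersion of β-catenin positives: the reference axis runs from
the wound centroid to the centroid of the flagged brightest nuclei (their
centroid, when several are flagged); those nuclei are excluded from the
angle set. Angles lie in (−180°, 180°]; the summary is the circular mean
and mean resultant length R̄ = |⟨e^{iθ}⟩| — per-nucleus angles are also
returned so any downstream dispersion definition can be computed.

### Decay-length estimation

`fit_decay_length` estimates λ of an exponential profile A·e^{−d/λ}. Two
estimators are provided, both to be fed *all* considered nuclei:

* **Binned log-linear** (`method="loglinear"`, with `bin_width_um`): bin
  means are computed first, then ln(mean) is regressed on bin centre,
  weighted by the inverse log-variance n·mean² and restricted to bins with
  ≥3 nuclei and a mean ≥5% of the peak bin. Averaging before the log is
  essential: fitting ln(intensity) of individually selected positive
  nuclei truncates the additive noise and flattens the apparent profile
  (overestimating λ by tens of percent in simulation).
* **Nonlinear least squares** (`method="nls"`): per-nucleus fit of
  A·e^{−d/λ}, which also uses the sub-noise far field. This is the
  better-powered choice when few nuclei survive the filter chain — with a
  20 µm decay inside the 100 µm slab the binned fit has only ~3 usable
  bins, and nls is used for the recovery benchmarks.

Both operate on the *pre-subtraction* depth-corrected ratio (raw
signal / DAPI): after background subtraction the profile is exponential
minus a constant, and a log-linear fit of that is misspecified whenever λ
is comparable to the background-band distance (a 80 µm decay would fit as
≈48 µm).

## Morphometrics

Circularity is 4πA/P² of the polygon (shapely area/perimeter), clamped to
≤1. The reference path for the extended / not-extended call is manual:
extension-base landmarks supplied ⇔ extended, mirroring the operator
decision the measurements are built on. The optional automatic mode is a
labelled heuristic: extended ⇔ convexity deficiency 1 − A/A_hull > 10⁻³
(convex outlines such as circles and ellipses score ~0; an extension neck
is a reflex region the hull closes). Normalized extension length is the
tip → base-midpoint distance divided by the segmented tip → base → back
length. Cavity location uses the largest-area cavity and normalizes the
tip→near-edge and far-edge→back distances by the tip→back length.
Expression domains are binned into 10 half-open windows [i/10, (i+1)/10)
(last closed) along the tip→back axis; a bin scores presence only for a
positive-length intersection, multiple domains are OR-combined, and
profiles are averaged element-wise. Mesendoderm-area classes: negative
(no reporter; area recorded as 0), reduced (area strictly below half the
control mean), normal. EVL reporter intensity SUM-projects n planes and
subtracts a background ROI mean from a centred square ROI of 400.90 µm²
(side √400.90 µm); the square shape and centroid placement are
conventions, as only relative intensities over time are interpreted.

## Synthetic data

The generator's defaults are the study conditions the analyses assume;
they were fixed once and are not tuned per experiment:

| parameter | default | rationale |
|---|---|---|
| cell_diameter | 20 µm | deep-cell size at 50% epiboly–shield |
| geometry_radius | 250 µm | blastoderm dome / explant scale |
| gradient_amplitude | 100 a.u. | arbitrary units; 20:1 vs noise |
| gradient_decay_length | 40 µm | ~2 cell tiers, a steep embryonic gradient |
| intensity_noise_sd | 5 a.u. | amplitude/noise = 20 |
| dapi_base | 200 a.u. | ratio at the reference ≈ 0.5, threshold 0.1 well inside |
| depth_attenuation_per_um | 10⁻³ | ~22% signal loss over a 250 µm dome |
| evl_fraction / dividing_fraction | 0.10 / 0.05 | typical detected fractions |

Nuclei are uniform in a hemispherical dome. The signal channel is
amplitude·e^{−d/λ} with d the **true 3D distance** to the nearest
reference point (stored per nucleus as `true_dist_um` for oracles), plus
Gaussian noise; both channels are attenuated by (1 − a)^depth, so the DAPI
ratio cancels attenuation by construction. Amplitude ≈ 0 emulates
signal-source-removed samples. References: embryos get margin rings at the
cap rim, explants a filled wounding-site disc (radius two cell diameters)
at the base centre; both are laid out at several depth levels through the
imaging volume, as detected reference spots are in a real stack. For the
explant this keeps the projected 2D nearest-reference distance within a
few µm of the 3D distance driving the gradient, so gradient recovery
through the projection chain measures the method, not a projection
artifact; for the embryo rim the 2D distance retains a depth-dependent
bias (a few tens of µm), which is why the recovery benchmarks use
explants. Outlines are noise-free circle/ellipse/pear polygons; the pear
is body circle ∪ neck rectangle ∪ elliptical tip cap with the neck
half-width equal to the body half-width at the base, making the configured
extension fraction exact by construction (valid when (1−f)·L lies strictly
between half and one body width). Clone tracks start from a Gaussian seed
cluster (sd 15 µm) and take independent Gaussian steps (sd 15 µm) per
hourly timepoint over 2 h.

What the generator does **not** emulate: segmentation errors and merged
nuclei, anisotropic PSF blur, non-exponential or patterned gradients,
tissue movement during acquisition, and intensity scales tied to any real
staining. Passing tests therefore demonstrate correctness of the
measurement chain under the stated geometric/noise model, not performance
on real microscopy data.

## Determinism and problem sizes

Every generator takes one seed and uses a single `numpy` Generator; the
batch pipeline derives per-sample seeds from the run seed, so fixed-seed
reruns are byte-identical. The benchmark sizes — 500 nuclei for recovery
runs, 1,500 nuclei per sample and 20 samples per condition for the
end-to-end contrast, 20 seeds per Monte-Carlo property — keep the full
suite and the acceptance script in the seconds range while leaving the
statistical checks well-powered.

## Known limitations

* The z-window anchor (surface minimum of retained nuclei) is one of
  several defensible readings of a "100 µm volume"; samples where the
  imaged surface is not the z-minimum need a pre-shifted z column.
* The automatic extension call is a convexity heuristic validated only on
  the synthetic shape family; the manual landmark path is authoritative.
* Embryo-mode projected distances inherit the real method's projection
  bias near a curved margin (see above); tier profiles for embryos are
  comparative, not absolute.
* `percent_positive` is relative to the nuclei that survive all filters
  including the positive-background-subtracted-signal requirement, so its
  denominator is condition-dependent in very low-signal samples.
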