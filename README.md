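# explantquant

Quantification of nuclear signalling readouts, shape morphometrics and cell
clone dispersal in zebrafish embryos and blastoderm explants, starting from
the point tables a spot-detection step exports (one row per detected
nucleus: 3D coordinates in µm plus per-channel mean intensities) — not from
raw images.

It is written for developmental biologists who score Nodal/TGFβ signalling
by nuclear pSMAD2/3, dorsal determinant activity by nuclear β-catenin, or
explant morphogenesis by outline measurements, and who want those manual
Fiji/Imaris measurement recipes as a reproducible, tested pipeline. A
synthetic-data module generates nucleus tables, outlines and clone tracks
with known ground truth, so every stage can be exercised and validated
without microscopy data.

## What it computes

**Projection and distances.** Detected nuclei are projected along a chosen
axis into a 2D analysis plane (for explants, re-centred on the wounding
site); each nucleus gets its planar Euclidean distance to the nearest
reference point (YSL nuclei in embryos, wounding-site spots in explants),
optionally expressed in *cell tiers* d/⟨cell diameter⟩.

**Nuclear signal scoring.** EVL, dividing and low-quality nuclei are
excluded; analysis is restricted to a 100 µm imaging-depth window and to
nuclei within 150 µm of the reference. The signal channel is
background-subtracted (mean intensity in the 120–150 µm band), divided by
the DAPI mean to cancel depth attenuation, and a nucleus is *positive* when
this ratio exceeds 0.1. The top 30% of positives by ratio are the *bright*
nuclei; their count against a control mean (22 per explant, 81 per embryo)
classifies the signalling domain as present, strongly reduced (≤50% of
control) or absent. β-catenin positives are summarized as counts per
integer cell tier and as an angular distribution about the
wound→brightest-nuclei axis (circular mean and mean resultant length
R̄ = |⟨e^{iθ}⟩|).

**Morphometrics.** Circularity 4πA/P² of an outline; extended /
not-extended classification with normalized extension length; the ≥70%
control-extension batch QC rule; cavity localization relative to the
biggest lumen; 10-bin binary expression profiles along the tip→back axis
and their averages; expression-domain areas with normal / reduced /
negative classes; SUM-projection ROI intensity for an EVL reporter;
per-stage cell-diameter summaries.

**Clone dispersal.** Mean pairwise distance and mean distance to the centre
of mass of a labelled clone, per timepoint.

## Worked example

```python
import numpy as np
from explantquant import (ProjectionFrame, QuantConfig, SyntheticNucleiConfig,
                          generate_nuclei, measure_sample, quantify_sample,
                          fit_decay_length, filter_nuclei)

cfg = SyntheticNucleiConfig(sample_kind="explant", n_nuclei=1500,
                            gradient_decay_length=40.0, seed=1)
nuclei, refs = generate_nuclei(cfg)
frame = ProjectionFrame.from_axis((0, 0, 1))
proj, _ = measure_sample(nuclei, refs, frame, cfg.cell_diameter)
result, scored = quantify_sample(nuclei, proj, QuantConfig(), "explant")
print(f"considered nuclei : {result.n_considered}")
print(f"positive nuclei   : {result.n_positive} ({result.percent_positive:.1f}%)")
print(f"bright nuclei     : {result.n_bright}")
print(f"classification    : {result.classification}")

filt = filter_nuclei(nuclei, proj, QuantConfig())
lam = fit_decay_length(filt["dist_to_ref_um"],
                       filt["ch_signal_mean"] / filt["ch_dapi_mean"], method="nls")
print(f"fitted decay len  : {lam:.1f} um (true 40.0)")
```

prints

```
considered nuclei : 366
positive nuclei   : 132 (36.1%)
bright nuclei     : 40
classification    : present
fitted decay len  : 40.3 um (true 40.0)
```

Of 1,500 simulated nuclei, 366 survive the exclusion filters (EVL,
dividing, depth window, 150 µm range); 36% of those are pSMAD2/3-like
positive, the 40 bright nuclei exceed half the explant control mean of 22,
so the signalling domain is *present*; and the exponential decay length of
the simulated gradient (40 µm) is recovered from the depth-corrected
intensity profile.

The same chain is available from the shell:

```bash
explantquant simulate --out-dir sim --seed 1
explantquant project --nuclei sim/nuclei.csv --references sim/references.csv \
    --out sim/proj.csv
explantquant quantify --nuclei sim/nuclei.csv --projected sim/proj.csv \
    --out-prefix sim/result
explantquant run-all --out-dir run --seed 1   # whole synthetic batch
```

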