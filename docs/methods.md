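# Methods

This note documents the models behind `thromboquant`: what the synthetic
generator emulates, how the measurement pipeline works, which defaults matter
and why, and what the validation does and does not demonstrate.

## The assay being modeled

Whole blood is perfused over collagen microspots (collagen I, III, IV) in a
parallel-plate flow chamber at a wall-shear rate of 150 s⁻¹ (venous regime,
6 min) or 1000–1600 s⁻¹ (arterial regime, 3.5 min), with or without an
inhibitor added to the blood.  Per microspot, two brightfield images and
three multicolor fluorescence images (annexin A5 for phosphatidylserine,
anti-CD62P for P-selectin, labeled fibrinogen for activated integrin
αIIbβ3) are captured on a 1360 × 1024-pixel camera.  Each condition is run
in duplicate with blood from at least three donors.

## Synthetic experiment generator

### Field model

A field is a binary object mask hierarchy on the pixel grid (default
1024 × 1360 at 0.2 µm/pixel, configurable):

- **Single platelets** — discs of radius 1–2 µm (diameter 2–4 µm) at uniform
  random positions.
- **Aggregates** — clusters of 8–40 discs scattered with a Gaussian spread
  around a center, merged by morphological closing.  A *compactness*
  parameter *c* ∈ [0, 1] controls contraction: scatter σ = 7 − 5.5 c µm and
  closing radius 0.3 + 3.2 c µm, which maps c ≈ 0.1 → component solidity
  ≈ 0.64 and c ≈ 0.9 → ≈ 0.91.
- **Multilayer cores** — the deepest pixels of each aggregate (by Euclidean
  distance transform), selected per component at the quantile that yields the
  target share of aggregate area.  These model regions more than one platelet
  thick.
- **Channel-positive subsets** — per fluorescence channel, the top-ranked
  pixels of a smoothed random field inside the platelet mask, cut at the
  exact target pixel count; positives are spatially coherent patches and by
  construction subsets of the platelet mask.

Masks are grown object-by-object until the target coverage is crossed, so
realized (pixel-counted) fractions land within one percentage point of the
targets; the *realized* fractions are stored as ground truth.  Single
platelets keep a 1 µm clearance from aggregates so that "isolated platelet"
and "aggregate" remain distinguishable concepts in the rendered image — the
same distinction the P2 measurement needs.

### Rendering

Brightfield: uniform background at 40 000 counts (16-bit), platelet
monolayer 12 000 counts darker, multilayer tier a further 8 000 counts
darker.  Fluorescence: background 800 counts, positives at 18 200.  The
object level map is blurred with a Gaussian of σ = 0.6 px (the diffraction
scale of a 60× oil objective at 0.2 µm/pixel), a ±3 % linear illumination
ramp multiplies the background, and i.i.d. Gaussian noise (default
σ = 1 500 counts, i.e. ⅛ of the monolayer contrast) is added.  Microscope
calibration (µm/pixel) and exposure levels are free configuration, as they
are instrument properties.

### Effect structure

Condition effects are multiplicative factors, per shear rate, on: platelet
seeding density (field coverage), aggregate share of platelet area,
multilayer share of aggregate area, and each channel's positive share.  The
control condition has all factors 1.  Donor variation is a lognormal
multiplier (default σ = 0.20) on seeding density drawn **once per donor**
and shared across all of that donor's conditions and runs — one blood sample
per donor — so it cancels in paired comparisons, exactly as the paired
design intends.  Per-field lognormal jitter (σ = 0.08) models field-to-field
biological variability within a run.  Baseline coverages per microspot and
shear regime (e.g. collagen I at high shear: 38 % platelet coverage, 55 %
aggregate share; collagen IV at low shear: 12 % and 28 %) encode the
potency order collagen I > III > IV and the denser, more contracted, more
activated thrombi of the arterial regime, with values in the middle of the
ranges the assay reports.  No fluid dynamics, adhesion kinetics, or receptor
signaling is simulated: shear dependence exists only through these factors.

## Measurement pipeline

### Coverage segmentation (P1, P6–P8)

Flat-field correction followed by Otsu thresholding, with dark-object
polarity for brightfield and bright-object polarity for fluorescence.  The
background surface is a Gaussian smooth (σ = 150 px) computed on a
16×-decimated grid (the background is smooth at that scale by definition,
so decimation changes nothing but cost).  Because the objects themselves
bias a plain smoothed background in densely covered fields, segmentation is
two-pass: after a first Otsu mask, the background is re-estimated from
non-object pixels only (normalized convolution) and the threshold is
recomputed.  This removes a coverage-dependent bias of about one percentage
point.

Degenerate images are guarded: a constant image yields an empty mask with a
warning, and an image whose Otsu split separates the classes by less than
`noise_k` (default 4) robust standard deviations of the background class —
the signature of thresholding pure noise — also yields an empty mask with a
warning.  Both guards, and the whole pipeline, are scale-equivariant: a gain
change (multiplying all intensities) leaves every mask unchanged.  A fixed
absolute threshold can replace Otsu per configuration.

### Aggregate segmentation (P2)

A connected platelet component is a multilayered aggregate when it exceeds
`min_aggregate_area` (default 20 µm², several platelet footprints) **and**
contains a multilayer core.  Core pixels are those whose corrected darkness
exceeds the monolayer reference level by a relative offset
(`multilayer_offset`, default 0.33, which places the cut at the midpoint of
the generator's monolayer/multilayer contrast where edge-blur bias cancels).
The monolayer reference is the 0.40 quantile of corrected intensity inside
the platelet mask: a low-but-not-minimal quantile sits on the single-layer
plateau, above edge-dimmed rim pixels, and — unlike the median — stays
anchored to the monolayer population even when multilayered regions cover
close to half the platelet area.  The core requirement is
max(2 µm², 5 % of component area); the proportional part keeps pixel noise
in large monolayer patches from fabricating cores.  The aggregate mask is a
subset of the platelet mask by construction, so P2 ≤ P1 always.

### Score rubric (P3–P5)

The assay's visual scoring against reference images is replaced by a
deterministic rubric over measurable features; the reference images
themselves are not available, so the rubric is an explicit stand-in
calibrated against the generator, not a claim about the original anchors.
Features per field: number of platelet components, largest component area
(µm²), aggregate area fraction of platelet area, multilayer area fraction
of platelet area, and the area-weighted mean solidity of aggregate
components above `min_aggregate_area` (restricting and weighting makes the
statistic insensitive to fragment populations).

- **Morphology P3 (0–5):** 0 below a platelet floor (P1 < 0.5 % SAC,
  "essential absence of platelets"); otherwise 1 plus one tier for each of:
  aggregates present with largest component ≥ 50 µm²; largest ≥ 400 µm²;
  multilayer fraction ≥ 0.15; solidity ≥ 0.80 (contracted).
- **Multilayer P4 (0–3):** tier ladder on multilayer area fraction at
  (0.04, 0.15, 0.25); forced 0 when there are no aggregates (so P2 = 0 ⇒
  P4 = 0).
- **Contraction P5 (0–3):** tier ladder on aggregate solidity at
  (0.60, 0.70, 0.80); 0 without aggregates.

All rules are monotone non-decreasing in every feature, ties at a cut-point
take the higher tier, and every cut-point lives in `RubricConfig`.  The
defaults were placed in the gaps between the feature distributions the
generator's baseline conditions produce, so that a field's intended tier
(computed from its true masks) and its measured tier (computed from
segmented masks) disagree only when a field lands within measurement error
(≲ 0.01 in the fractions) of a cut: in validation this keeps full-triple
agreement at about 95 % with no disagreement beyond one tier.

### Statistics

Per-image parameters are averaged per run (P1–P5 over brightfield images,
P6–P8 over fluorescence images; a parameter with no contributing image is
missing, never zero), then duplicate runs are averaged per donor.  Scaling
to 0–10 is an affine map of [min, max] across conditions (per microspot and
shear by default; pooled and fixed-range modes available — the fixed frames
are the assay's published observed ranges).  A constant vector scales to
all zeros with a warning, keeping "no signal anywhere" visually empty
rather than mid-scale.  Conditions are compared against control per donor
with a two-sided paired Student *t*-test on the **unscaled** per-donor
means (the *t* statistic is invariant to the affine scaling, so this choice
is presentation-neutral; it is pinned for definiteness).  All-zero
differences give t = 0, p = 1 by convention.  Subtraction heatmaps carry
the scaled delta, the p-value, and a significance flag at p < 0.05 (the
assay's conventional filter; no multiplicity correction by default,
Benjamini–Hochberg optional).  Non-significant cells keep their raw delta
in the exported table — masking is a rendering decision — so the deltas of
a condition always sum to the difference of cumulative scaled values.

### Peptide arithmetic

Peptide notation (`Ace-` prefix, `-OH`/`-NH2` suffix, internal whitespace
ignored, case-insensitive) is parsed into residues plus terminal chemistry.
Monoisotopic mass is the residue-mass sum plus one water; the residue table
is an atomic-composition sum over NIST isotope masses and is cross-checked
against an independent implementation in the tests.  Printed "theoretical"
masses in synthesis reports drop the decimal fraction, so comparison with
printed integers uses truncation (3102.56 Da → "3102 Da"); the printed
values for these peptides correspond to the unmodified linear chains, so
terminal modifications are excluded by default and added only on request
(acetyl +42.011 Da, amide −0.984 Da).  Substitution counts are Hamming
distances on equal-length sequences.

## Validation scale and what it shows

Ground-truth recovery runs on 50 full-size (1024 × 1360) fields at default
noise, spanning all microspots and both shear regimes; mean absolute
coverage errors are well under 1 percentage point for P1 and P6–P8 and
about 1 point for P2, against a 3-point acceptance bound.  The
shear-contrast study uses a deliberately scaled-down replicate design — 3
donors × 2 duplicate runs × collagen I × two shears × control/inhibitor,
2 brightfield + 1 fluorescence field per run, 256 × 340-px fields — chosen
to keep a 20-replicate batch tractable; an image-level null calibration
(100 two-control experiments) shows the paired test rejects at the nominal
5 %, so roughly one low-shear false positive per 20 replicates is the
expected behavior of a correct pipeline, not a defect.

Passing these checks shows the pipeline recovers the generator's geometry
and effect structure; it does not certify performance on real microscopy,
which differs in ways the generator does not model: out-of-focus light and
uneven staining, red-cell shadows and debris, platelet shape irregularity,
electronic fixed-pattern noise, and genuinely three-dimensional thrombi
whose height the two intensity tiers only caricature.  The rubric's
cut-points in particular are calibrated to this generator and would need
re-anchoring against reference images before use on real data.

## Numerical choices and edge cases

- Pixel grid is row-major, origin top-left, 0-based; masks are whole-pixel
  memberships.
- Determinism: every stochastic step derives from `numpy` Generators seeded
  from the design seed via `SeedSequence` spawning; a fixed seed reproduces
  experiments bit-identically, including written TIFF and CSV bytes.
- Tier ties take the higher tier; Otsu ties follow scikit-image.
- Empty platelet mask: features are zero, solidity undefined (`None`), and
  scores are (0, 0, 0) through the P1 floor.
- Fixed-frame scaling clips out-of-range values into [0, 10] with a warning.
- Paired tests require ≥ 2 donors and donor-aligned vectors; misalignment
  and missing values raise errors rather than silently dropping pairs.

## Known limitations

- P2's definition is operational (multilayer-cored components above an area
  cut); the assay's original semi-automated scripts involved manual steps
  that cannot be reproduced, so absolute P2 values are comparable within
  this pipeline, not across implementations.
- The two-tier intensity model cannot represent partial focal planes or
  more than two layers; P4 saturates accordingly.
- The generator's shear dependence is purely parametric; it cannot be used
  to study flow physics, only to validate the analysis chain.
- Score tiers 1–4 anchor to generator regimes, not to the assay's reference
  image set.
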