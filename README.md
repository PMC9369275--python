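# thromboquant

Multiparameter quantification of whole-blood thrombus formation under flow.

In microfluidic flow-chamber assays, citrated whole blood is perfused over
microspots of adhesive collagen (types I, III, IV) at a venous (150 s⁻¹) or
arterial (1000–1600 s⁻¹) wall-shear rate, and platelet deposition is imaged
by brightfield and three-channel fluorescence microscopy.  `thromboquant`
turns those images into the assay's eight standard parameters:

| | parameter | source | range |
|---|---|---|---|
| P1 | platelet adhesion (% SAC) | brightfield | 0–100 |
| P2 | platelet aggregate coverage (% SAC) | brightfield | 0–100, ≤ P1 |
| P3 | thrombus morphological score | brightfield | 0–5 |
| P4 | thrombus multilayer score | brightfield | 0–3 |
| P5 | thrombus contraction score | brightfield | 0–3 |
| P6 | phosphatidylserine exposure (% SAC) | annexin-A5 channel | 0–100 |
| P7 | P-selectin expression (% SAC) | anti-CD62P channel | 0–100 |
| P8 | fibrinogen binding (% SAC) | fibrinogen channel | 0–100 |

SAC is surface-area coverage: the percentage of the imaged field inside a
segmentation mask.  Coverage parameters come from flat-field-corrected Otsu
segmentation (dark objects in brightfield, bright positives in fluorescence);
the ordinal scores come from a deterministic rubric over morphological
features (aggregate size, multilayer area fraction, component solidity) that
replaces visual comparison against reference images, so scores depend only on
pixels.

On top of the per-image parameters the package implements the assay's
analysis hierarchy: the 2–3 images of a run are averaged, duplicate runs are
averaged to one parameter set per (donor, condition, microspot, shear); each
parameter is univariate normalized to 0–10 across conditions; conditions are
compared against vehicle control with a two-sided paired Student *t*-test per
donor; and results are rendered as cumulative bar plots and subtraction
heatmaps (scaled condition − control, masked where p ≥ 0.05, green =
decrease, red = increase).

Because thrombus images from donor blood cannot ship with a package, a
first-class synthetic-experiment generator (`thromboquant.synthetic`)
produces complete experiments — TIFF images, metadata, and exact pixel
ground truth — with the statistical structure the analysis assumes: donor
variation, duplicate runs, per-shear condition effects, and channel-positive
subregions.  The whole measurement pipeline is validated by recovering this
ground truth.

A small peptide module reproduces the sequence arithmetic of the inhibitor
peptides used with this assay (a GPR56 tethered-ligand mimic and two
CIB1-blocking αIIb cytoplasmic peptides): parsing of `Ace-…-OH` notation,
lengths, substitution counts, and theoretical monoisotopic masses.

## Worked example

Simulate a two-condition experiment with an inhibitor that halves platelet
deposition at arterial shear only, then analyze it:

```python
import thromboquant as tq
from thromboquant.pipeline import PipelineConfig, measure_runs
from thromboquant.stats import (
    average_images_to_run, average_runs_to_donor, subtraction_heatmap,
)

inhibitor = tq.ConditionSpec("inhibitor", {1000.0: {"seeding": 0.6}})
design = tq.ExperimentDesign(
    donors=3, duplicate_runs_per_condition=2,
    microspots=("collagen-I",), shear_rates=(1000.0, 150.0),
    conditions=(tq.ConditionSpec.control(), inhibitor),
    images_per_run_brightfield=2, images_per_run_fluorescence=1,
    field_size=(256, 340), seed=0,
)
per_image = measure_runs(tq.generate_experiment(design), PipelineConfig())
donors = average_runs_to_donor(average_images_to_run(per_image))
hm = subtraction_heatmap(donors, control="control")
print(hm[hm.parameter == "P1"][
    ["shear_rate", "condition", "delta", "p_value", "significant"]
].to_string(index=False))
```

```
 shear_rate condition  delta  p_value  significant
      150.0 inhibitor   10.0 0.946481        False
     1000.0 inhibitor  -10.0 0.023061         True
```

The inhibitor's platelet-adhesion delta is significant and negative at
1000 s⁻¹ (deposition reduced vs control) and non-significant at 150 s⁻¹ —
the shear-dependent signature this analysis is designed to expose.  With only
two conditions, dataset-mode scaling maps them to the ends of the 0–10 scale,
hence deltas of ±10.

The same pipeline runs from the shell on directories of TIFFs:

```sh
thromboquant simulate --outdir exp --seed 0
thromboquant run --metadata exp/metadata.csv --image-dir exp --outdir results
thromboquant peptide "Ace-LVLAMWKVGFFKRNRPP LEEDDEEGQ-OH"
```

## Layout

- `src/thromboquant/synthetic.py` — synthetic experiment generator + ground truth
- `src/thromboquant/metrics.py` — segmentation and coverage parameters (P1, P2, P6–P8)
- `src/thromboquant/scoring.py` — morphological score rubric (P3–P5)
- `src/thromboquant/stats.py` — averaging, scaling, paired tests, heatmaps
- `src/thromboquant/pipeline.py` — configuration, end-to-end runs, provenance
- `src/thromboquant/peptides.py` — peptide notation and mass arithmetic
- `src/thromboquant/cli.py` — `thromboquant` command-line interface
- `docs/methods.md` — models, defaults, calibration, and limitations
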