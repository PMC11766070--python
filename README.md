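# lesionwise

Component-based evaluation of multi-pathology brain-MRI segmentations.

Whole-volume overlap scores (Dice, sensitivity, precision) are the standard
way to report a segmentation model, but they are dominated by the largest
lesions: a model can score DSC 0.85 on an exam while missing every
clinically critical micro-abnormality. `lesionwise` evaluates a detection
mask against a ground-truth mask **per connected component** as well as per
volume, and profiles successes and failures by component volume, position
in the brain, and intensity contrast — the three factors a radiologist
reasons with.

It is aimed at people validating brain-lesion segmentation models (tumors,
strokes, multiple sclerosis, white-matter hyperintensities) who have
co-registered NIfTI volumes: a binary ground-truth mask, a binary detection
mask, a brain mask, a healthy white-matter reference region, and one or
more intensity modalities (e.g. FLAIR, T2, T1ce).

## The metrics

For detection set *A* and ground truth *B* (voxel sets):

```
DSC         = 2|A ∩ B| / (|A| + |B|)
sensitivity = TP / (TP + FN)
precision   = TP / (TP + FP)
```

For the lesion-wise analysis, connected components (26-neighborhood by
default) are extracted independently from both masks. Each component is
scored against the **union of the opposite-side components that overlap
it**, and classified on each side:

| category                      | rule               |
|-------------------------------|--------------------|
| Found GT / Good Detection     | DSC ≥ 0.5          |
| Partially Found / Good        | 0.05 ≤ DSC < 0.5   |
| Missed GT (FN) / Missed Detection (FP) | DSC < 0.05 |

Around this core the toolkit computes: category tables (count, % of
components, % of side volume), a DSC-threshold sweep (0.05…0.95, step
0.05), case-volume strata (<10, 10–100, >100 cm³), GT-vs-detected volume
correlation, per-component centroid offsets from the brain center with
half-brain asymmetry percentages, and per-modality intensity differences

```
ID = 100% × (mean intensity of component − mean intensity of healthy VOI)
            / (mean intensity of healthy VOI)
```

All offsets follow a fixed orientation convention (+X left, +Y anterior,
+Z superior); volumes are reoriented on load from their NIfTI affines.

Because real validation cohorts are rarely shareable, the package ships a
seeded phantom generator (`lesionwise.phantom_forge`) that builds complete
synthetic cases — multi-lesion masks, detections perturbed to requested
per-component DSC values, modality volumes with exact planned intensity
contrasts, and a healthy VOI — with a truth table for every planned
quantity, so the whole pipeline is testable end to end.

## Worked example

```python
from lesionwise import (
    EvaluationConfig, LesionSpec, PerturbationPlan, PhantomSpec,
    evaluate_cohort, generate_bundle,
)

spec = PhantomSpec(
    lesions=(
        LesionSpec(volume_mm3=5000, offset_mm=(10, 5, -8),
                   intensity_diffs={"flair": 40.0},
                   plan=PerturbationPlan(target_dsc=0.7)),
        LesionSpec(volume_mm3=300, offset_mm=(-15, -10, 12),
                   intensity_diffs={"flair": 30.0},
                   plan=PerturbationPlan(target_dsc=0.2)),
        LesionSpec(volume_mm3=50, offset_mm=(0, 20, 5),
                   intensity_diffs={"flair": 50.0},
                   plan=PerturbationPlan(drop=True)),
    ),
    modalities=("flair",),
    seed=11,
)
bundle, truth = generate_bundle(spec)
report = evaluate_cohort([bundle])

case = report.cases.iloc[0]
print(f"whole-volume DSC={case.dsc:.2f} sensitivity={case.sensitivity:.2f} "
      f"precision={case.precision:.2f}")
print(report.gt_categories[["n", "pct_components", "pct_volume"]].round(1))
```

prints

```
whole-volume DSC=0.67 sensitivity=0.51 precision=1.00
         n  pct_components  pct_volume
found    1            33.3        93.5
partial  1            33.3         5.6
missed   1            33.3         0.9
total    3           100.0       100.0
```

Read: the whole-volume DSC (0.67) looks mediocre, but the component view
explains it — the 5 cm³ lesion was found (per-component DSC 0.7, as
planned), the 300 mm³ lesion only partially (0.2), and the 50 mm³ lesion
was missed entirely; the missed lesion is 33% of the components yet only
0.9% of the abnormal volume. Precision is 1.0 because the detection was
generated as a subset of the truth (no spurious voxels). The per-component
table carries positions and intensity contrasts:

```
label  volume_mm3  dsc category  offset_x_mm  id_flair
    1       300.0  0.2  partial       -15.05      30.0
    2        50.0  0.0   missed        -0.18      50.0
    3      5000.0  0.7    found         9.95      40.0
```

## Command line

```sh
lesionwise phantom  --out cohort/ --cases 24 --seed 7     # synthetic cohort
lesionwise evaluate --manifest cohort/manifest.csv --out results/ --plots
lesionwise sweep    --manifest cohort/manifest.csv --out sweep.csv
lesionwise report   --json results/report.json --out rendered/
```

`evaluate` writes delimited-text tables (per-case metrics, cohort
statistics, category tables per side, threshold sweep, half-brain
asymmetries, axis histograms, volume-vs-intensity summaries), a
machine-readable `report.json`, and optional plots. Real cohorts use the
same manifest format: a header row `case_id,gt,detection,brain,voi,<modality...>`
with NIfTI paths per case.

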