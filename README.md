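# hypovol

Automated volumetry of a small, low-contrast midline brain structure
(a hypothalamus-like target) from T1-weighted MR volumes: slice-wise
encoder–decoder segmentation of the structure and of the intracranial
volume (ICV), volume quantification with head-size normalization,
IQR-based quality control, and group-level atrophy statistics.  The
whole pipeline runs end-to-end on built-in synthetic head phantoms with
known ground truth, so every stage — from training protocol to the
final unpaired test — is exercisable and checkable without patient
data.

**Who it is for:** neuroimaging researchers who want a transparent,
fully seeded reference implementation of the small-structure volumetry
workflow (segment → quantify → normalize → QC → compare groups), and a
phantom harness for validating each stage.

## The method

A 2-D U-topology network (configurable encoder style: plain
convolutional, residual, multi-branch, or depthwise-separable blocks,
each convolution followed by group normalization) is trained per
coronal slice with the loss

    L = CE(p, t) + (1 − J(p, t)),

the sum of categorical cross-entropy and the Jaccard loss computed from
the soft foreground overlap `J = |p∩t| / |p∪t|`.  Training uses Adam
(step 10⁻³, moment decays 0.9/0.999), batch size 4, up to 25 epochs
with early stopping once the validation loss has not improved for 10
consecutive epochs; the weights of the lowest-validation-loss epoch are
kept for prediction.

Per subject, the segmented structure volume `V` (foreground voxels ×
voxel volume, both hemispheres summed) is normalized to head size by

    V_norm = V / V_ICV × mean(V_ICV, controls),

quality-controlled per group with Tukey fences `[Q1 − 1.5·IQR,
Q3 + 1.5·IQR]` applied in a fixed cascade (empty segmentation → ICV
outlier → raw-volume outlier → normalized-volume outlier), and compared
across groups with a two-sided pooled-variance t-test.  Agreement with
ground truth is reported as Dice, IoU, precision, recall, the
95th-percentile Hausdorff distance (boundary distances in mm,
anisotropic spacing honored), and Bland–Altman mean difference ±1.96 SD
limits of agreement with approximate confidence intervals.

## Worked example

```python
import json
from hypovol.phantom import CohortSpec
from hypovol.pipeline import RunConfig, run_pipeline

config = RunConfig(
    cohort=CohortSpec(n_control=60, n_case=60, effect_fraction=0.10),
    seed=1)
rundir = run_pipeline(config, "runs/demo")
report = json.loads((rundir / "stats_report.json").read_text())
print(report["percent_difference"], report["unpaired_test"]["p_value"])
```

This simulates a 10% case-group volume reduction, trains both
segmenters on a separate labeled phantom cohort, segments the 120 study
subjects, and prints (one run on one CPU, ~1.5 minutes):

```
{'percent': 10.85, 'one_decimal': 10.9, 'nearest_int': 11} 4.5e-15
```

i.e. the pipeline recovers the ≈10% simulated case reduction in
normalized volume (the residual deviation from 10 is cohort sampling
noise, not segmentation bias) at overwhelming significance.  The
run directory also contains `metrics.csv` (per-subject Dice/HD95),
`cohort_results.csv` (volumes, QC status and reason per subject),
`qc_summary.json` (fences, acceptance rates) and `provenance.json`
(config hash and all derived stage seeds; a rerun with the same config
reproduces every output bit-exactly).

The same stages are available as CLI subcommands:

```bash
hypovol simulate --n-control 10 --n-case 10 --out cohort/
hypovol train    --data cohort/manifest.csv --task target --out model.npz
hypovol predict  --model model.npz --data cohort/manifest.csv --out pred.csv
hypovol evaluate --pred pred_target_masks --truth cohort/manifest.csv --out metrics.csv
hypovol quantify --target pred.csv --icv pred_icv.csv --out qc/
hypovol stats    --cohort qc/cohort_results.csv --out stats.json
hypovol run      --config run.yaml --out runs/full
```

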