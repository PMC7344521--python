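# spinemetry

A validation toolkit for wearable-sensor measurement of spinal mobility in
axial spondyloarthritis (axSpA).

Clinicians monitor axSpA with mobility metrology: conventional
tape-and-goniometer measures (summarized by the 0–10 BASMI), optical motion
capture in a laboratory, and — increasingly — portable inertial measurement
units (IMUs). Before an IMU system can stand in for the laboratory
reference, it must be validated on three fronts:

* **concurrent validity** — agreement of IMU ranges of motion with optical
  motion capture on the same movements: ICC(2,1) with 95% CI, Pearson r,
  RMSE, Bland–Altman bias and 95% limits of agreement, SEM = SD·√(1−ICC)
  and MDC = 1.96·SEM·√2;
* **discriminant validity** — separation of patients from matched healthy
  controls: unpaired Student/Welch t-tests per measure;
* **construct validity** — Pearson correlations of IMU measures and the
  composite 0–10 kinematic mobility index with conventional metrology and
  disease outcomes (BASDAI, BASFI, ASAS-HI, mSASSS, ...).

`spinemetry` implements the whole pipeline: a synthetic-data generator that
renders one shared ground-truth motion as a paired dual-sensor IMU recording
(12 Hz) and optical marker-pair recording (50 Hz); both kinematic processing
chains (reference zeroing, per-plane sensor subtraction, projected
marker-segment angles, linear upsampling to a common 100 Hz grid,
peak-to-peak ROM over three repetitions); the composite metrology indices;
and every agreement statistic, implemented from first principles. The
scientific details are in [docs/methods.md](docs/methods.md).

## Worked example

```python
from spinemetry import (default_cohort_spec, NoiseSpec, generate_cohort,
                        run_concurrent, run_discriminant)

spec = default_cohort_spec(n_per_group=20)       # published group means/SDs
noise = NoiseSpec(orientation_noise_sd=1.0)      # 1 deg white sensor noise
ds = generate_cohort(spec, noise=noise, seed=1)  # paired IMU + optical cohort

table = run_concurrent(ds).table                 # agreement, one row/measure
print(table[["measure", "n", "icc", "r", "rmse", "bias", "sem", "mdc"]].round(3))
```

```text
             measure  n   icc     r  rmse   bias   sem   mdc
   cervical_sagittal 40 0.984 0.995 2.965  2.519 2.084 5.777
    cervical_frontal 40 0.993 0.997 2.507  1.981 1.769 4.904
      cervical_axial 40 0.997 0.999 2.577  2.102 1.820 5.046
L1_absolute_sagittal 40 0.999 0.999 1.527  0.580 1.080 2.993
 L1_absolute_frontal 40 0.996 0.997 1.525  0.838 1.078 2.987
   L1_absolute_axial 40 0.997 0.998 1.581  0.786 1.118 3.098
     lumbar_sagittal 40 0.986 0.994 3.010  2.289 2.120 5.877
      lumbar_frontal 40 0.987 0.993 2.629  1.798 1.854 5.138
        lumbar_axial 40 0.919 0.968 3.262  2.605 2.247 6.229
     composite_index 40 0.962 0.993 0.284 -0.258 0.198 0.548
```

Each row compares the IMU-chain and optical-chain peak-to-peak range of one
regional movement across the 40 simulated subjects: at 1° sensor noise
agreement is excellent everywhere (ICC ≥ 0.92), the residual between-chain
bias of 1–3° reflects the upward bias of peak-picking on noisy samples, and
an MDC of ~3–6° is the smallest real change this measurement could detect in
an individual. The composite-index row is in 0–10 score units.

```python
d = run_discriminant(ds).table
print(d[["measure", "axSpA_mean", "control_mean", "p_display", "significant"]].head(3))
```

```text
           measure  axSpA_mean  control_mean p_display significant
 cervical_sagittal        92.0         104.7     0.011           *
  cervical_frontal        56.6          75.5     0.004          **
    cervical_axial       119.6         140.6     0.033           *
```

Patients move less in every region, and the composite index separates the
groups strongly (IUCOASMI 2.8 vs 1.5, p < 0.001 in this cohort).

The same workflow is available from the shell:

```bash
spinemetry simulate --seed 7 --out data/
spinemetry analyze  --data data/ --out analysis/
spinemetry validate concurrent   --data data/ --out reports/concurrent.csv
spinemetry validate discriminant --data data/ --out reports/groups.csv --ttest pooled
spinemetry validate construct    --data data/ --out reports/construct.json --format json
```

Datasets, ROM tables, scores and reports are plain CSV/JSON; a (config,
seed) pair reproduces every file byte for byte.

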