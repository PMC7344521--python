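# Methods

## The problem

Spinal mobility in axial spondyloarthritis (axSpA) is classically quantified
with tape-and-goniometer metrology (lateral spinal flexion, modified Schober,
tragus-to-wall, intermalleolar distance, cervical rotation, summarized by the
0–10 BASMI), by optical motion capture in a gait laboratory, and more
recently by wearable inertial measurement units (IMUs). Before an IMU system
can replace the laboratory reference it must be shown to be *valid*:
concurrently (does it agree with optical capture on the same movements?),
discriminantly (does it separate patients from healthy controls?) and in
construct (does it correlate with disease outcomes that mobility should
track?). `spinemetry` implements that entire validation pipeline — including
a synthetic-data generator, so every stage is testable without access to any
patient recording.

## Measurement model

Each instrumented region is observed by two sensors reporting absolute
orientation (roll, pitch, yaw, degrees). Anatomical planes map onto Euler
axes as sagittal→pitch, frontal→roll, axial→yaw. Processing is per-plane
angle subtraction:

* **cervical** angle = occiput sensor − T3 sensor,
* **lumbar** angle = upper-lumbar (L1/T12) sensor − sacral sensor,
* **L1-absolute (trunk)** angle = upper-lumbar sensor vs. the ground.

Both sensors are first re-referenced to the mean orientation of an initial
standing window (default 1 s), which removes constant mounting offsets
exactly. Angles are unwrapped (any inter-sample jump > 180° is treated as a
wrap-around) and kept in degrees end to end. Per-plane subtraction — rather
than full rotation-matrix composition — matches the per-plane outputs such
devices report and is exact for the planar motions the simulator produces; a
rotation-composition variant is deliberately out of scope.

The optical chain measures the signed angle of a two-marker segment
projected onto an anatomical plane. Lab frame: right-handed, z up, y
anterior, x lateral-right; sagittal = y–z plane, frontal = x–z, axial
(transverse) = x–y. The reference axis is vertical (z) for sagittal/frontal
and anterior (y) for axial; flexion / right-side / right-rotation are
positive. Samples whose projected segment length falls below 1 µm are
flagged and filled by interpolation; a trial fails if more than 5% of its
samples are degenerate.

The IMU stream is sampled at 12 Hz and the optical stream at 50 Hz; both
angle signals are brought onto a common 100 Hz grid by linear interpolation
(no extrapolation, overlap only) before ranges and curves are compared. The
range of motion (ROM) of a trial is the total peak-to-peak excursion
max − min. Repetitions are segmented by the scripted protocol timing carried
in the dataset's provenance; the default aggregation over the three
repetitions is **max** (maximal mobility, the clinical intent of metrology
indices), with **mean** available by configuration.

## Synthetic cohorts

### Movement waveform

A movement task is `n_reps` (default 3) repetitions of a raised-cosine
excursion to +`asymmetry`·ROM followed by one to −(1−`asymmetry`)·ROM
(default symmetric), each cycle 4 s, separated by 1 s rests, after a 1 s
standing lead-in. Each peak carries a 0.4 s hold, so the programmed
peak-to-peak range is attained *exactly* on any sampling grid with a step
below 0.4 s (both 12 Hz and 50 Hz qualify); this is what makes the
noise-free end-to-end recovery exact rather than merely close. Excursions
stay within ±90° per axis, away from orientation-representation
singularities.

### Cohort draws

Per group (axSpA, control) and per measure (3 regions × 3 planes), true ROMs
are drawn from normals truncated to [0°, 200°], with defaults equal to the
published group means and SDs of an axSpA validation cohort (n = 20 per
group). Draws are independent across measures; a subject's **latent mobility
factor** is then defined as their standardized mobility composite (mean of
the nine group z-scores, rescaled to unit variance). The pelvic share of
trunk motion is whatever the drawn L1-absolute range exceeds the lumbar
range by (floored at 0), rendered as a pelvic trajectory proportional to the
lumbar one so that ranges add exactly; the thoracic share under the cervical
region is zero by default. Outcome variables (BASDAI, BASFI, ASAS-HI, BAS-G,
ASDAS, mSASSS, and the five conventional metrology items) are generated as
`mean + sd·(ρ·z + √(1−ρ²)·ε)` with configurable target correlation ρ to the
latent factor, truncated to their clinical bounds by redrawing the
idiosyncratic term (falling back to clipping); mSASSS is rounded to an
integer in [0, 72]. Disease scores carry negative ρ (less mobile = more
burden); defaults follow the published correlation table of the composite
index. Because measures are drawn independently, cross-correlations *among*
kinematic measures are weaker than in real cohorts — a deliberate trade-off
that keeps cohort-level sampling behaviour exactly normal-theoretic.

### Sensor imperfections

Per recording and axis the IMU model adds: a constant mounting offset
(SD 2° default; removed exactly by reference zeroing), white orientation
noise per sample (SD 1° default), and a motion-proportional skin artifact
(amplitude 1° default): a scaled copy of the normalized true motion with a
random per-sensor gain in [−1, 1], mimicking soft-tissue movement that grows
with the movement itself. Optical markers receive isotropic Gaussian jitter
(SD 1 mm default) on every coordinate; over the default 150 mm segment this
is ≈ 0.5° of angle noise. All draws flow through one seeded generator:
a (config, seed) pair reproduces a dataset bit for bit.

What the generator does **not** emulate: multi-joint skeletal coupling,
gravity/accelerometer-level signal synthesis (orientation streams are
generated directly, as the devices report them), sensor drift, marker
occlusion/relabeling, and out-of-plane cross-talk. Passing tests therefore
demonstrate correctness of the processing and statistics under a controlled,
planar motion model — not robustness to every artifact of real recordings.

## Composite indices

Both 0–10 composite indices share one engine: each component value passes
through a monotone linear transform anchored at (`best_ref` → 0,
`worst_ref` → 10, clipped), and the index is the weighted average. The
kinematic index (optical variant and IMU variant differ only in where the
raw ranges come from) uses five components: cervical flexion (cervical
sagittal ROM), cervical rotation (cervical axial), lumbar flexion (lumbar
sagittal — the regional, not trunk, angle), lateral flexion (trunk frontal,
matching its shoulder-and-hip origin) and lumbar rotation (lumbar axial).
Its published weights and anchors come from a separate derivation study and
are **not** reproduced here; the shipped defaults (equal weights,
healthy/ankylosed reference anchors) are editable configuration, and no
acceptance property depends on them. The conventional index defaults encode
the published linear scoring functions, e.g. lateral flexion (21.1 − cm)/2.1
expressed as the anchor pair (21.1, 0.1).

## Statistics

All validity statistics are implemented from first principles (scipy
supplies only the t, F and normal distribution functions):

* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measurement: (MS_R − MS_E)/(MS_R + (k−1)MS_E + k(MS_C − MS_E)/n), with the
  standard F-based 95% CI for this form. Perfect agreement short-circuits to
  (1, (1, 1)).
* **Bland–Altman** — bias = mean(method1 − method2), limits of agreement
  bias ± 1.96·SD of the differences (sample SD, n−1 denominator).
* **SEM = SD_pooled·√(1−ICC)**, with SD_pooled defaulting to
  √((SD₁² + SD₂²)/2) across the two methods (the pooling choice is an
  explicit argument, since conventions differ); a sample ICC below 0 is
  floored at 0 here. **MDC = 1.96·SEM·√2**.
* **Unpaired t-tests** — pooled (Student) by default, Welch–Satterthwaite on
  request; identical results from raw data and from (n, mean, SD)
  summaries by construction, so printed group tables can be re-tested.
* **Pearson r** with the exact t-transform p-value; **OLS** with adjusted
  R² = 1 − (1−R²)(n−1)/(n−2).
* **Sample size for detecting a correlation** — smallest n with
  √(n−3)·(atanh r + r/(2(n−1))) ≥ z₁₋α/₂ + z_power, scanned upward from
  n = 4. The small-sample bias-correction term is included because it is the
  form standard power software evaluates (the uncorrected equation gives an
  answer one participant larger for r = 0.6 at α = 0.05, power 0.80).
* **Strength labels** — ICC: < 0.6 poor, 0.6–0.8 good, > 0.8 excellent;
  |r|: < 0.3 negligible, 0.3–0.7 weak-to-moderate, > 0.7 good. The middle
  band is closed at both ends; the sources phrase the boundaries ambiguously,
  so the tie-break is documented here and in the report metadata.
* p-values display at 3 decimals with a "<0.001" floor; machine-readable
  output keeps the raw value.

## Report shapes and determinism

`run_concurrent` emits one row per region × plane measure plus the composite
index (ICC + CI, r, RMSE over subject pairs, bias, LoA, SEM, MDC).
`run_discriminant` emits group mean (SD) and range per measure with the
t-test and significance stars. `run_construct` emits long-format correlation
rows against metrology and outcome anchors, restricted to the patient group
by default. CSV output uses fixed decimals (angles/cm 1, ICC/r/t 3, p with
floor); JSON keeps full precision with sorted keys — identical inputs give
byte-identical files.

## Problem sizes used by the test suite

Noise-free recovery uses 4–5 subjects per group (the check is exact, size
adds nothing); the noise Monte-Carlo uses the published cohort size (20
patients) over 100 seeds; the type-I-error study uses 1000 truth-level
cohorts of 20 + 20; ICC oracle checks use 1000 random tables with 3–12
subjects. Statistical tolerances follow sampling theory at those sizes
(e.g. coverage 95% ± 1% at 10⁴ draws).

## Known limitations

* Peak-to-peak ROM of a noisy signal is upward-biased (the maximum of signal
  plus noise exceeds the signal's maximum), and the bias grows with sampling
  density and noise level. Because the two chains run at 12 Hz and 50 Hz
  with different noise, their inflations differ, producing a systematic
  between-chain offset of several degrees at 2° orientation noise —
  consistent with the bias and the weaker lumbar agreement that real
  validation studies report for exactly this reason. Under those conditions
  the lumbar-sagittal ICC straddles 0.9.
* Repetition segmentation trusts the scripted protocol timing; event-based
  alignment is not implemented.
* The composite-index defaults are placeholders pending the published
  weights/anchors; absolute index values (not agreement between the two
  chains' indices) depend on them.
* Welch p-values are provided because several published group comparisons
  are only consistent with unequal-variance testing; reports always state
  the variant used.
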