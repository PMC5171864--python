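# finquant

Quantitative assessment of caudal-fin regeneration and de-novo bone
mineralization in adult zebrafish (*Danio rerio*), from paired
bright-field / fluorescence micrographs of alizarin-red-S-stained fins.

Zebrafish regrow an amputated caudal fin in under two weeks, which makes
the fin a standard screening system for compounds with regenerative or
mineralogenic (bone-forming) activity. Quantifying that process from
micrographs is noisy because fish stocks vary widely in size. `finquant`
implements a standardized measurement and analysis workflow for
researchers running such screens:

- **Histomorphometry.** From each image pair and a two-point annotation
  of the amputation plane, the package measures the regenerated area
  REG, the estimated and real mineralized areas EMA and RMA (RMA via an
  RGB colour threshold: green and blue bands 0–30, red from an
  autotuned minimum in 20–60 up to 255), the mean mineralized-ray width
  at the first intersegment joint proximal to the plane (RAY) and the
  stump width STU.
- **Size correction.** Inter-specimen variability is removed with the
  ratios REG/STU (regeneration) and RMA/RAY (mineralization); the
  dimensionless index (RMA/RAY)/(REG/STU) summarizes mineralogenic
  performance within the regenerate.
- **Biphasic phase model.** RMA/RAY as a function of REG/STU is fitted
  with a continuous two-segment (segmental) linear regression. The
  breakpoint X0 separates phase P1 (outgrowth without effective
  mineralization) from P2, where mineral grows linearly with
  regeneration. Within the 84–240 hpa screening window an ordinary
  regression of RMA/RAY on REG/STU is the *standard curve*: treated
  groups displaced **along** the curve are over/under-regenerated,
  groups displaced **off** it over/under-mineralized (unpaired t-tests,
  α = 0.05, Bonferroni over the two axes with direction replication
  across time points).
- **Intensity densitometry.** Within the mineralized area, the YUV luma
  histogram over the 15–254 spectrum acts as a proxy for mineral
  density/ray thickness; the low (15–29) and high (30–44) intensity
  classes are compared between groups to detect density effects that
  leave areas unchanged.
- **Statistics.** Pearson correlation, one-way ANOVA with Tukey's HSD,
  unpaired Student's t (pooled or Welch) and Grubbs' outlier test are
  implemented from their closed forms so the pipeline needs no external
  statistics application.
- **Synthetic fins.** Because no reference images are distributed, a
  generator renders structurally faithful fins (segmented, bifurcating
  bony rays; red mineral fluorescence; inter-ray tissue) and simulates
  longitudinal cohorts with known ground truth, so the entire pipeline
  is testable offline.

## Worked example

```python
import finquant as fq
from finquant.pipeline import measure_record
from finquant.phase_model import SegmentalRegression, StandardCurve

# Measure one synthetic fin against its known geometry
record, truth = fq.render_fin(fq.SyntheticFinSpec(seed=1))
row = measure_record(record)

# Fit the biphasic model on a simulated 60-fish time course
cohort = fq.simulate_cohort(fq.CohortSpec(seed=1))
print(SegmentalRegression.from_dataframe(cohort).fit().summary())
```

The measurement row for this fin contains (areas mm², lengths mm):

```
reg_mm2            0.8748      reg_over_stu_mm    0.6249
ema_mm2            0.6670      rma_over_ray_mm    7.2571
rma_mm2            0.2926      mineral_fraction   11.6136
ray_mm             0.0403      low_15_29          0.8682
stu_mm             1.4000      high_30_44         0.1318
```

REG/STU and RMA/RAY carry units of length (area over width), so the
mineral-fraction index is a dimensionless ratio, not a proportion — its
value depends on the number of rays summed into RMA. The segmental fit
prints:

```
Segmental linear regression (continuous two-segment)
  n observations      : 60
  breakpoint X0       : 0.6108
  P1 intercept (a)    : -0.0000
  P1 slope (b)        : 0.0000
  P2 slope (c)        : 0.3575
  SSE                 : 0.0317669
  SSE one-segment ref : 0.147064
  X0 identifiable     : True
  points in P1 / P2   : 12 / 48
```

i.e. mineralization becomes effective once REG/STU exceeds ≈ 0.61 mm
(the generating truth is 0.586), rises with slope 0.36 thereafter, and
the two-segment model clearly beats a single line.

## Command line

```sh
finquant simulate --out data/ --n 6 --seed 1     # synthetic image set
finquant measure  --manifest data/manifest.csv --out results/
finquant model    --measurements results/measurements.csv --out results/
finquant classify --measurements results/measurements.csv --out results/
finquant report   --manifest data/manifest.csv --out results/   # all-in-one
```

Inputs are TIFF/PNG image pairs listed in a manifest CSV (paths, plane
endpoints, distal side, mm/px calibration, time in hours
post-amputation, group, optional weight/length metadata, exposure).
Outputs are CSV tables, a JSON report and diagnostic plots.

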