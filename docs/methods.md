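# Methods

This note documents the models, measurement rules, numerical choices
and limitations of `finquant`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Measurement model

**Geometry.** Rasters use 0-based (row, col) coordinates with the origin
top-left. The amputation plane is a straight two-point annotation; the
`distal_side` label orients its normal. Each pixel is assigned to the
distal or proximal half-plane by the sign of its centre's distance to
the infinite line through the endpoints; pixels exactly on the line are
distal (an arbitrary but fixed convention). Curved amputation planes are
out of scope. Areas are measured in px² and converted with
`mm_per_px**2`; lengths with `mm_per_px`. A helper derives `mm_per_px`
from a ruled calibrator image (pixels counted across a stated span).

**Regenerate (REG).** The workflow this package standardizes traces REG
by hand; a manual outline polygon therefore always takes precedence.
The automatic default defines tissue as pixels whose BT.601 luminance is
below 0.9× the modal background luminance, estimated from the image
border frame (a well-framed micrograph shows only background at its
edge; estimating the mode over the whole image fails when tissue covers
more area than background). The regenerate is the largest 8-connected
tissue component distal to the plane, holes filled.

**Mineral (RMA).** Alizarin-red-positive pixels satisfy all three RGB
bands simultaneously: green and blue in [0, 30], red from a minimum up
to 255. The red minimum, expected in [20, 60], is autotuned per image as
Otsu's threshold of the red-channel histogram inside the distal region,
clamped to that range. The Otsu split is computed on the full 256-bin
histogram and taken at the midpoint of the between-class-variance
plateau, so a cleanly bimodal image thresholds midway between its modes;
this makes the choice deterministic and analyst-free. A manual
`ThresholdSpec` always wins. If no distal pixel reaches the search
floor, the threshold is flagged `no_signal` and RMA is 0. Restricting
the mask to the regenerate guarantees RMA ≤ REG.

**Tip polygon (EMA).** Mineral components smaller than 20 px are
discarded as speckle. Components are grouped into rays by overlap of
their projection intervals on the plane axis (tolerance 2 px): an
intersegment joint splits one anatomical ray into several connected
components, and treating each component as a ray would add spurious
"tips" at interior joint borders. Per ray, the tip is the pixel with
maximal plane distance (ties resolve toward the dorsal end). The EMA
polygon runs dorsal endpoint → tips ordered along the plane → ventral
endpoint, closing along the plane segment; its area is the shoelace
area. EMA includes inter-ray space by construction, so EMA ≥ RMA; it is
computed for comparability but never used in downstream corrections,
because RMA is the more sensitive measure.

**Ray widths (RAY).** For each ray proximal to the plane, pixels are
binned by integer distance from the plane; the first run of ≥ 2 empty
bins with mineral beyond it is the first intersegment joint, and the
width is the ray's extent along the plane axis in the last mineral bin
before the gap. This distance-profile walk is the discrete equivalent of
following the ray's medial axis for the quasi-parallel rays of this
anatomy, and is robust to skeleton spurs. Rays without a visible joint
are skipped with a warning; all measurable rays enter the RAY mean
(configurable upstream via manual widths, which take precedence).

**Corrected metrics.** REG/STU and RMA/RAY (both mm), and the
dimensionless index (RMA/RAY)/(REG/STU). RMA = 0 maps to RMA/RAY = 0
and index 0 — the pre-mineralization regime — regardless of RAY.
REG/WEI and REG/LEN are computed when weight/length metadata exist, for
comparisons of correction factors; REG/STU is the default everywhere
because STU comes from the same micrograph at no extra bench cost.

## Intensity densitometry

Staining intensity within the mineralized area proxies mineral density
or hemiray thickness. Luma is BT.601 (0.299 R + 0.587 G + 0.114 B),
the YUV convention of common imaging software; the coefficients are
configurable. Histograms cover the integer spectrum 15–254; pixels
below 15 (background) or at 255 are excluded, and by default
frequencies are normalized by the pixel count *inside the spectrum*
(normalizing by all mask pixels is available as an option). The low
(15–29) and high (30–44) classes summarize the distribution for group
tests. Comparisons across groups assume identical acquisition settings;
the pipeline refuses to pool records with differing recorded exposures
unless forced, and treats different exposure strata as separate.

## Phase model

RMA/RAY vs REG/STU is biphasic: P1 (wound closure, blastema, early
outgrowth; no effective mineralization), P2 (mineral area growing
linearly with regeneration), and a late P3 (mineralization continuing
after outgrowth plateaus) that falls beyond 240 hpa and is never fitted
— points beyond the window are excluded with a warning.

**Segmental regression.** The continuous two-segment model
y = a + b·x (x ≤ x0), y = a + b·x0 + c·(x − x0) (x > x0) is fitted by
profiling the breakpoint over every interior data abscissa and the
midpoints between consecutive abscissae, solving each profile by least
squares on the design [1, x, (x−x0)⁺], then refining the best candidate
by bounded scalar minimization between its bracketing candidates. Ties
break toward the smaller x0; each segment must keep ≥ 3 points.
Continuity at the breakpoint is imposed (the standard "segmental"
definition); a discontinuous variant is out of scope. The first-segment
slope b is left free by default — P1 looks flat but the data should say
so — with a `constrain_b0` option. When the two-segment SSE does not
improve on a single line the breakpoint is flagged unidentifiable. The
reference breakpoint X0 = 0.5860 from a 60-specimen fixed-sample time
course is kept as a package constant for plot overlays and as an
optional x0-based P2 gate; the primary screening gate is the 84–240 hpa
window.

**Standard curve and effect calls.** The P2 standard curve is the OLS
fit of RMA/RAY on REG/STU over control points inside the window
(≥ 10 required), with Pearson r and 95% prediction-band parameters
(the band flags single specimens only). `classify_effect` compares one
treated group to controls at one nominal time: dx is the mean REG/STU
difference (along-curve, regenerative axis), dy the mean difference in
residuals off the control curve (mineralogenic axis); both are tested
with unpaired pooled-variance t-tests and a shift is called only when
significant (α = 0.05). The pooled-variance test matches the two-group
default of classical biostatistics software; Welch is available.

**Group screening rule.** The exact significance rule behind a
"clearly shifted" group is a design decision. `classify_group` pools
each group's points over the window's assayed time points, tests each
shift axis at α/2 (Bonferroni over the two axes), and calls a shift only
when its direction also replicates at every individual time point. The
Bonferroni step bounds the familywise false-call probability of an
area-neutral treatment; the replication step mirrors the practice of
requiring an effect to reappear at each assayed stage and discards
significant-but-inconsistent displacements. A strict
all-time-points-significant combiner (`consensus_call`) is available as
a conservative alternative.

## Statistics

Statistics are computed from their closed forms; p-values come from
scipy's t, F and studentized-range distributions. Tukey's HSD uses the
Tukey–Kramer standard error for unequal group sizes. Degenerate inputs
follow documented limit conventions: identical ANOVA groups give
F = 0, p = 1; a zero-pooled-variance t-test gives p = 1 for equal
means and p = 0 otherwise. Grubbs' test is two-sided, applied once (no
iterative removal), flags at most one point, and resolves ties on the
extreme deviation to the first-encountered point; α = 0.05 throughout.

## Synthetic data

**Rendered fins.** The renderer draws a parabolic-dome regenerate above
a horizontal amputation plane on a light bright-field background, with
16 quasi-parallel rays (defaults: mean width 8 px, CV 8%) segmented by
4 px intersegment joints every 40 px, half of the rays bifurcating at
55% of their mineral height, and a segmented stump below the plane with
its first joint 12 px down. Fluorescence shows mineral as red pixels
whose luma is drawn from N(25, 4) (G, B < 30) over a dark noisy
background (σ = 5); bright-field tissue sits well below the luminance
threshold. The scale is 0.005 mm/px, putting the stump at 1.4 mm —
millimetre-scale adult fin anatomy. Ground truth (masks, per-ray tips,
first-joint widths, joint/bifurcation counts, luma parameters) is
recorded before noise; the recorded morphometrics are exactly the
measurements of the truth masks.

**Simulated cohorts.** The tabular simulator emulates the
cross-sectional reference design: 60 fish, 4 per time point, sampled
every 12 h from 24–144 hpa then every 24 h to 240 hpa. REG/STU follows
the saturating quadratic 2u − u² (u = (t−24)/216) scaled to 2.2 mm at
240 hpa; mineralization onsets at 36 hpa and RMA/RAY follows
0.35·(REG/STU − 0.586) in P2. Noise: multiplicative (CV 5%) on REG/STU
and additive Gaussian with σ = 5% of the P2 range on RMA/RAY;
un-mineralized records are exactly zero, as an empty threshold mask
measures. Inter-specimen size scales STU log-normally (default CV 20%)
and RAY with square-root coupling plus independent jitter — RAY tracks
body size only weakly. Treatment multipliers scale regeneration rate,
mineral fraction and staining luma; the reference profiles are
regeneration ×0.6 with fraction ×1.3 (retinoic-acid-like) and luma ×0.7
only (warfarin-like). Per-record intensity classes are sampled from the
record's luma distribution (2000 px). All randomness flows from one
seed through per-fish substreams, so cohorts reproduce record by
record.

The cohort's RMA/RAY scale is normalized to the P2 slope 0.35 rather
than matched to the 16-ray render scale (where RMA sums all rays and
RMA/RAY is an order of magnitude larger); every fit and classification
downstream is equivariant to that scale, and the render-backed route
carries its own exact ground truth.

**What the generator does not emulate.** Photorealistic texture,
staining chemistry artefacts (fixation shrinkage, vital-vs-fixed
differences), curved amputation planes, fluorescence flat-field
inhomogeneity, multi-fish scenes, or registration across time points.
Passing tests therefore demonstrate correctness of the measurement and
inference machinery under controlled imaging conditions, not robustness
to every real-world acquisition artefact — on real data the manual
overrides (outline, ray widths, red threshold) are the escape hatch the
workflow expects.

## Problem sizes and numerics

The validation suite uses 50 rendered fixtures for measurement
accuracy, 100 simulated cohorts (n = 60) for breakpoint recovery, 10⁴
null simulations (3 × 10) for ANOVA calibration and 100 simulated
screens (n = 10 per group at 120 and 168 hpa) for phenotype-call rates
— sizes at which the Monte-Carlo error of the reported rates is a few
percent while the whole suite runs in well under a minute on one core.
Least-squares solves use `numpy.linalg.lstsq`; the breakpoint refinement
uses bounded Brent minimization (xatol 10⁻⁶); 16-bit images are
rescaled to 8-bit with a warning because all thresholds are 8-bit
values.

## Known limitations

- Ray grouping by projection overlap assumes quasi-parallel rays; fins
  imaged with strongly fanned or crossing rays may merge neighbours.
  The merge tolerance and speckle floor are module constants.
- The joint detector needs the first proximal joint inside the imaged
  stump; rays amputated immediately distal to a joint can lose it to
  the 2 px minimum gap.
- EMA's proximal boundary is assumed to be the amputation-plane
  segment itself.
- Luma-based densitometry is relative; no absolute bone-mineral-density
  calibration is attempted, and classes from different exposure strata
  are never pooled silently.
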