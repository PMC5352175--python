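# Methods

## Scope and model

`dectgrade` reimplements a dual-energy-CT (DECT) radiomics workflow for
grading early-stage lung adenocarcinoma as a tested pipeline.  The
patient images behind the original cohort are not available, so every
stage is validated on synthetic data with known ground truth; printed
cohort-level statistics (per-grade feature means/SDs, the 19/65/7 grade
prevalence) parameterize the simulators.

## Three-material decomposition

A voxel acquired at 80/140 kVp is a point in the (HU_low, HU_high) plane.
The decomposition assumes:

* unenhanced tissue lies on the piecewise-linear locus through the fixed
  basis points of air (−1000, −1000), fat (−100, −80) and soft tissue
  (60, 50) — defaults chosen as plausible dual-energy behavior and fully
  configurable;
* iodine displaces a voxel along a fixed direction (slope 2.0 in the
  plane, i.e. twice the enhancement at 80 kV per HU at 140 kV), with
  30 HU of high-kV enhancement per unit concentration.

Each voxel is translated back along the iodine direction until it meets
the locus.  The signed travel, in high-kV HU, is the iodine channel; the
landing point's weighted average (0.6·low + 0.4·high, the ≈120-kV
convention) is the VNC value.  Design choices:

* **Interpolation rule.** The basis fixes points, not the curve between
  them; the air→fat→soft polyline is used.  When both segments intersect
  (possible near the fat vertex) the solution with the smaller |iodine|
  wins.
* **Beyond the endpoints.** Voxels whose projection parameter falls
  outside every segment (e.g. enhancing tissue denser than the
  soft-tissue point) are projected onto the nearest segment's *extension*
  rather than clamped to a vertex.  Extrapolation keeps the estimator
  linear, hence unbiased under symmetric noise; such voxels are counted
  (`n_outside_locus`) in the QC summary.
* **Negative iodine is retained** by default (`clip_iodine` optional) so
  noise stays symmetric for downstream statistics.
* **Identifiability.** Only voxels whose unenhanced composition lies *on*
  the locus are exactly recoverable; a general three-material interior
  mixture is not (the projection is a 1-D inverse of a 2-D plane).  The
  phantom generator therefore plants compositions on the locus, and the
  round-trip guarantee (relative error < 1e-9, noiseless) is stated for
  that class.  VNC values are reported in the weighted-average convention.

## Synthetic phantoms

A phantom is a sphere of radius r (default 12 mm in a 40³ grid at 1 mm
spacing) with a solid core of radius r·(1−ggo_fraction)^{1/3} — so the
ground-glass shell holds exactly `ggo_fraction` of the nodule volume —
on a lung background (−870 HU, with ground glass −600 HU and solid
40 HU as unenhanced targets).  Target HU values are mapped to locus
compositions by inverting the weighted average along the polyline, iodine
is added per a spatial spec (`uniform`, `radial` or `none`), and the two
energy channels are rendered through the forward model plus i.i.d.
Gaussian HU noise, independent between channels (default SD 5 HU — the
source protocol publishes no noise level, so this is a placeholder, not a
scanner calibration).  Noiseless iodine/VNC volumes are returned as
ground truth.  Not modeled: beam hardening, scatter, reconstruction
kernels, motion, lung anatomy.

## Feature battery

Per channel (VNC unprefixed, iodine `i-`, gradient `g-`): density
(mean HU + 1000)/1000 in g/cm³, mass = density × volume, population
skewness and **Pearson (non-excess) kurtosis** (the reference per-grade
kurtosis values cluster near 3), 75th/97.5th percentiles with linear
interpolation between order statistics, histogram uniformity and entropy
(bits) over fixed 1-HU-wide bins spanning [min, max], and the GLSZM
gray-level and size-zone nonuniformities after equal-width quantization
to 64 levels with full (26 in 3-D, 8 in 2-D) zone connectivity.  Bin
width, level count and thresholds are configurable; the defaults are
conventional choices — the source text states none of them.

Whole-tumor features: volume, maximal axial in-plane diameter (lung
window), the same diameter of the solid sub-mask (HU > −300 on the
enhanced weighted-average channel, a reproducible proxy for the visual
mediastinal-window reading), and a solidity class (non-solid ≤ 5% solid
voxels, solid ≥ 95%, part-solid in between).

**The `g-` channel is ambiguous in the source description** (verbally a
difference of non-contrast and iodine-map values, but with printed
magnitudes incompatible with a plain difference and a "gradient
variability" heading).  Both readings are implemented:
`g_mode="spatial"` (default) extracts features from the
gradient-magnitude image (spacing-corrected central differences, HU/mm)
of the VNC channel; `g_mode="diff"` reports feature-wise
i-value − plain-value.

Features that cannot be computed (moments of a numerically constant
channel, e.g. a zero-iodine phantom) are recorded as missing with a
reason rather than silently propagated as NaN.

## Reproducibility filter

Lin's CCC with population (1/n) moments; features below the 0.8 threshold
are excluded and every value is reported.  ICC(2,1) is provided for
completeness but the filter uses CCC.  In the synthetic pipeline the
retest pair is emulated as truth plus two independent measurement-error
draws at 10% of the pooled feature SD.

## Pathology grading

Comprehensive subtyping percentages (nominally multiples of 5%; finer
values warn but pass) are reduced to the predominant pattern with central
fibrosis disregarded.  AIS/MIA and lepidic-predominant tumors are grade
1, acinar/papillary grade 2, micropapillary/solid grade 3.  Exact
percentage ties — never defined in the source — break toward the more
aggressive pattern and are flagged.

## Grading model

Baseline-category multinomial logit, grade 1 reference, fit by
Newton-Raphson with step halving on internally standardized covariates
(relative log-likelihood tolerance 1e-10, 100 iterations) and reported on
the original scale (per-HU odds ratios).  Quasi-separation — diverging
coefficients with |linear predictor| > 30 — terminates iteration and is
flagged rather than failing, following common GLM practice; true
non-convergence raises (or is flagged inside selection/CV).  Wald
covariance comes from the Fisher information on the original design.

Stepwise selection uses the 2-df likelihood-ratio test per feature block
(one coefficient per non-reference class) at α = 0.05 for both insertion
and deletion — the source names the alpha but not the test; the LRT is
the standard multinomial choice.  Ties break toward earlier column
order; repetition of a visited state terminates.  VIF is computed as
1/(1−R²) from OLS of each feature on the rest; the screen flags > 10.
Within-patient correlation from multiple nodules is ignored, mirroring
the source analysis.  The sample-size helper implements
N = 4·z²·p(1−p)/D² exactly as printed (p = 0.65, z = 1.960, D = 0.20
gives 88).

## Evaluation

LOOCV refits the model n times.  Default mode `fixed-selection` reuses
the full-data stepwise set — mirroring the apparent original workflow and
therefore optimistically biased; `per-fold-selection` reruns selection
inside each fold and is provided as the honest alternative.  Both are
recorded in output metadata.  AUC is the midrank Mann-Whitney statistic;
its 95% CI uses DeLong's structural components.  Argmax classification
yields per-grade sensitivity/specificity/PPV/NPV with Wilson score CIs;
ratios with empty denominators (a never-predicted grade's PPV) are
reported as undefined with a reason, not as 0.

## What the synthetic tests do and do not show

The cohort simulator draws features from independent per-grade Gaussians
(no published covariances exist), so collinearity, heavy tails, outliers
and within-patient correlation of real radiomics tables are absent, and
class separation is optimistic.  Passing tests therefore demonstrate
*correctness of the computations* (closed forms, exhaustive GLSZM
labeling, parameter recovery within Wald error, stepwise type-I error
5% ± 2% and power > 95% at the stated effect sizes, AUC = Φ(d/√2) for
Gaussian separation) and *qualitative structure* (the grade-1 one-vs-rest
AUC exceeding the grade-3 AUC in most replicates, echoing that the rarest
grade is hardest to call) — not clinical performance.  Problem sizes in
the test suite (e.g. 1000 round-trip voxels, 500 GLSZM arrays, 200
null-selection replicates, 120 LOOCV cohorts) were chosen to make the
Monte-Carlo bands tight at interactive runtimes.

## Known limitations

* The decomposition is exact only for on-locus compositions (above);
  vendor VNC implementations are not emulated.
* The phantom noise level is a placeholder, not calibrated to any
  scanner.
* The `g-` channel definition remains ambiguous at the source; both
  implementations are provided but neither can be verified against the
  printed per-grade values without the original images.
* Diameters are center-to-center voxel distances; sub-voxel surface
  extent is not interpolated.
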