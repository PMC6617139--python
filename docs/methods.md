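# Methods

`octascreen` implements a quantitative OCT-angiography (OCTA) screening
pipeline for retinopathies: six vascular/foveal features are extracted
from en-face angiograms of the superficial (SCP) and deep (DCP) capillary
plexus, per-task optimal feature subsets are chosen by stepwise backward
elimination, and a hierarchy of linear SVMs classifies eyes as
control → disease → (diabetic vs. sickle-cell retinopathy) → severity
stage. Because no public image cohort accompanies the method, the package
ships a phantom generator that produces angiogram-like images with exact
geometric ground truth; all quantitative guarantees are stated — and
tested — against those phantoms and against closed-form oracles.

## Image model and preprocessing

An angiogram is a square scan with a known physical field of view
(default 6 mm at 304×304 px, 19.74 µm/px). Intensities are windowed to
[0, 1] from the observed min/max, then corrected for multiplicative
illumination bias, then re-windowed. The bias estimate is a least-squares
quadratic surface (6 coefficients): it reproduces linear and gently
curved ramps exactly and has no boundary bias, unlike a large smoothing
kernel whose support is truncated at the image border precisely where the
ramp matters most (at a 1.5 mm smoothing scale, half of a 6 mm field is
border-affected). Gaussian smoothing at a configurable physical scale
remains available (`method="gaussian"`). The background estimate is
floored at 5% of its median before division, and the corrected image is
re-windowed against its 99.5th percentile so a handful of floored pixels
cannot compress the intensity range. Contrast-limited equalization is
deliberately not applied by default; no parameters for it are
established.

## Vessel segmentation

Vesselness is the multi-scale Frangi (Hessian-eigenvalue) response at
scales {1, 2, 4, 8} px with bright-ridge polarity, covering capillaries
through arcade vessels at this pixel pitch. Binarization combines a local
mean threshold (31 px window, −0.02 offset) with a small absolute floor
(0.02) — the floor is needed because empty background has a local mean of
~0 and would otherwise pass the relative test — followed by removal of
objects under 20 px and closure of holes under 10 px. These values were
chosen so that a noise-free width-3 ridge is recovered at ≥95% of its
pixels with ≤2% background contamination, and they stay fixed everywhere.

The skeleton is the topology-preserving medial axis. The perimeter map
marks vessel pixels with a background 4-neighbor, with the image border
counting as background. Skeleton branches are obtained by deleting
junction pixels (≥3 skeleton 8-neighbors) and tracing the remaining
simple paths; branches shorter than 5 px are discarded.

Two lengths are attached to each branch. `geodesic_length` is the
classical 8-connected chain length (orthogonal step 1, diagonal √2).
For tortuosity we use `arc_length`, the length of the branch path after
an endpoint-pinned 5-point moving average: the raw chain metric
overestimates straight lines by 5.5% on average over orientations (8.2%
at 22.5°), which would floor the tortuosity of perfectly straight vessels
at ~1.05; the smoothed estimate is orientation-unbiased while leaving
genuinely curved paths intact (a rasterized semicircle still measures
π/2 within 2%). Pinning the endpoints guarantees arc ≥ chord, so
tortuosity never falls below 1.

## Local fractal dimension and vessel density

Each pixel receives the box-counting dimension of the vessel mask inside
a centered 16 px window: occupied-box counts N(s) over dyadic box sizes
s = 1…16, the least-squares slope of log N against log (1/s), divided
by 2. An empty window maps to 0, a filled window to exactly 2/2 = 1 and a
1-px line to 1/2, so the conventional vessel threshold of 0.7 sits
between "line-like" and "plate-like" neighborhoods. The implementation
slides globally aligned boxes (block-reduction plus a uniform filter),
which is within ±s/2 of perfectly centered windows and is validated
against a brute-force per-window box counter in the tests.

Vessel density (BVD) is the fraction of FD ≥ 0.7 pixels in three
concentric regions around the fovea — annuli of 0–1, 1–2 and 2–3 mm
radius (region diameters 2/4/6 mm), disjoint by default with a nested-disk
mode available — after excluding the segmented FAZ from both numerator
and denominator. The region center is the FAZ centroid when segmentation
succeeded, else the image center. The denominator is the region under
measurement, not the full frame: this keeps the three regional values on
a common scale and makes the FAZ exclusion meaningful.

## FAZ segmentation

The foveal avascular zone is segmented with a region-based (edge-free)
morphological active contour evolving on a Gaussian-smoothed vessel
density field (σ = 2 px) — capillary dropout gives weak edges, so
edge-free evolution is the robust choice. The contour starts as a 5 px
disk at the scan center (scans are macula-centered), runs on a 152 px
window around the seed in chunks of 50 iterations (max 300) with early
stopping at a fixed point, and the 4-connected component containing the
seed is kept. The reported boundary is a sub-pixel iso-contour of the
lightly smoothed (σ = 1) mask indicator, so the contour irregularity
index is not dominated by pixel staircase (a rasterized perimeter carries
a systematic ≈ +27% bias). A contour reaching the window border raises a
warning (an implausible FAZ). FAZ area follows the pixel-count
definition (count × pixel area, µm²); contour irregularity (FAZ-CI) is
polygon perimeter over the perimeter of the equal-area circle, both from
the same sub-pixel polygon, so a circle measures exactly 1.

The curvature-regularization and smoothing settings deliberately sit at
the light end: stronger smoothing (density σ = 4, curvature weight 2)
rounds genuine boundary lobes away and collapses the dynamic range of
FAZ-CI to a few parts in a thousand.

## The 13 features

Tortuosity (BVT), caliber (BVC) and perimeter index (VPI) are computed on
the SCP only; vessel density (3 regions) and the two FAZ features on both
layers — 13 scalars per eye. BVT is the unweighted mean of branch
arc/chord ratios (a length-weighted variant exists behind a flag).
BVC is vessel area over skeleton length; skeleton length counts
8-connected steps plus one per connected path, so an n-pixel straight
line measures n and a mask equal to its own skeleton yields exactly one
pixel pitch of caliber. Closed-loop branches (chord 0) are excluded from
BVT with a log entry.

## Statistics and feature selection

The univariate profile applies Shapiro-Wilk normality per group, then
t-test/one-way ANOVA for normal features and Mann-Whitney/Kruskal-Wallis
otherwise, Bonferroni-corrected across the 13 features, plus a Spearman
correlation matrix. Zero-variance groups force the nonparametric path.

Screening keeps features whose one-predictor logistic model (binomial,
or multinomial for 3-class staging) beats p < 0.15 by likelihood-ratio
test. Backward elimination starts from the screened set, repeatedly
removes the predictor with the largest Bonferroni-adjusted
likelihood-ratio p ≥ 0.10 (adjusted by the number of starting
candidates), refits, and stops when all remaining adjusted p < 0.10;
retained features are additionally reported against 0.05. P-values tied
within 0.01 are ordered by single-feature cross-validated accuracy, the
worse predictor leaving first. Without the Bonferroni adjustment the
procedure is not null-safe: the last survivor is the minimum of ~13
uniform p-values, below 0.10 with probability ≈ 75%, so pure noise would
"select" a feature in three runs out of four. With it, permuted-label
cohorts eliminate everything ≈ 90% of the time while 2-SD effects are
retained essentially always.

All logistic likelihoods come from ridge-stabilized fits (L2, C = 10⁴):
strong-effect cohorts routinely separate completely, where the
unpenalized MLE diverges and optimizer noise would scramble the
elimination order. The penalty is too weak to move p-values on ordinary
data. If every feature is eliminated, the single most accurate feature is
returned with an `all_eliminated` warning.

## Classification

Each stage is a linear SVM with class-balanced weights behind a
train-fold-only standardizer, evaluated by stratified, subject-grouped
5-fold cross-validation; metrics (sensitivity, specificity, accuracy, %)
come from the single pooled out-of-fold confusion matrix, with per-fold
accuracies logged. Multi-class staging uses one-vs-one voting for
prediction and macro-averaged one-vs-rest decision scores for AUC. The
ROC is swept over unique scores; its trapezoidal area equals the
tie-aware Mann-Whitney probability (verified to 1e-9 in tests). The
SVM's C defaults to 10: selection can legitimately retain a single
feature that separates classes by a gap much narrower than the
within-class spread, and at C = 1 the soft margin parks the boundary
inside the broader class (observed: 83% pooled accuracy at AUC 1.0);
C = 10 keeps the boundary in the gap while permuted-label cohorts stay at
chance (49.5%). Kernel and C remain configurable.

The hierarchy routes each eye through control-vs-disease, then DR-vs-SCR,
then the matching staging model; every input receives exactly one leaf
label. Stages are evaluated independently on their true sub-cohorts
(mirroring per-task reporting) and end-to-end with error propagation —
both are reported and labeled.

## Phantom generator

Phantoms emulate macula-centered en-face angiograms: vessels are
sinusoid-perturbed radial curves with closed-form arc and chord lengths
(tortuosity ground truth to quadrature precision), rendered at a given
caliber with soft edges; a parafoveal capillary ring follows the FAZ
boundary, as in real retinas, giving the avascular zone a physical rim;
the FAZ boundary itself is a circle perturbed by low-order harmonics with
amplitude `faz_irregularity`; multiplicative speckle (σ = 0.10) and a
lateral illumination ramp (±7.5%) complete the image. The DCP is rendered
from an independent sub-seed with 1.35× the vessels at 0.75× the caliber.
Vessel angles and start radii are stratified (grid plus jitter): a plexus
tiles its territory, and stratification keeps the per-region vessel count
proportional to `n_vessels` instead of Binomial-noisy. The wiggle
frequency is drawn narrowly (4.5–5.5 cycles) because true tortuosity
scales with (amplitude × frequency)²; a wide frequency band would make
frequency, not the amplitude dial, the dominant driver.

Disease cohorts are ordinal parameter ramps, not biophysical models:
with severity, tortuosity amplitude, caliber, FAZ radius and boundary
irregularity rise while vessel count falls; the sickle-cell branch pushes
tortuosity hardest (3.5/5.5 px vs. 1.0 control), the diabetic branch
vessel loss and FAZ growth. Within-group variation is lognormal
per-subject jitter (σ = 6%). Their only contract is the direction of
these trends and linear separability commensurate with a
proof-of-concept cohort; they are not calibrated to any clinical feature
distribution, so classifier performance on phantoms validates the
mechanics of the pipeline, not clinical accuracy.

What the phantoms do not emulate: projection artifacts between layers,
motion artifacts, patchy (non-ordinal) capillary dropout,
microaneurysms, true capillary meshes (curves only branch, never
anastomose beyond the parafoveal ring), and realistic speckle
correlation. Passing phantom tests therefore demonstrates correct
measurement and selection mechanics, not robustness to clinical
confounders.

## Validation protocol and problem sizes

The test suite checks, at fixed seeds chosen in advance:

* definitional ROC identities (perfect ranking → AUC 1; independent
  scores, 10⁴ per class → 0.5 ± 0.01);
* feature oracles (straight branch BVT = 1 exactly; semicircle π/2 ± 5%;
  square FAZ-CI = 2/√π ± 1%; fine circle 1 ± 0.5%; disk FAZ-A ± 2%;
  100×5 bar BVC ± 10%; 2:1 ellipse FAZ-CI against a dense-quadrature
  perimeter oracle, 1.0903);
* an independent brute-force box-count oracle for the FD map;
* segmentation recovery on noise-free geometry (ridge ≥95%/≤2%,
  FAZ Dice ≥ 0.95);
* monotonicity sweeps, 10 levels × 5 replicates each: Spearman ρ between
  the level and the per-level replicate mean exceeds 0.9 for tortuosity
  amplitude → BVT and vessel count → full-disk BVD, and 0.8 for boundary
  perturbation → FAZ-CI; the per-annulus BVD correlations are asserted at
  0.8 because the inner and outer rings saturate at the FD-classification
  ceiling for high counts;
* selector recovery over 50 seeds (2 informative + 11 noise features,
  2 SD effect, n = 60/class): both informative kept and ≤2 noise features
  in ≥90% of runs; permuted labels: everything eliminated in ≥80%;
* classifier ceiling/null (separable ≥99%; permuted 50 ± 5%) and the
  trapezoid/Mann-Whitney identity on 100 random instances;
* the full chain on a 6-group cohort of 20 eyes per group (240 images):
  per-stage cross-validated AUC > 0.9 and held-out phantom routing with
  ≥75% leaf accuracy. Routing errors concentrate on the mild-NPDR
  vs. control boundary, the clinically hard case by construction.

The replicate means are used in the sweeps because replicates exist to
stabilize each level's estimate; pooled per-replicate correlation mixes
within-level measurement noise into the rank statistic.

`scripts/acceptance.py` regenerates a cohort from a command-line seed and
recomputes the per-stage metrics, held-out routing accuracy, control-group
vessel/skeleton area fractions and the AUC anchors from scratch.

## Known limitations

* Measured absolute values carry segmentation bias: BVC under-reports
  caliber by roughly a third (the ridge filter recovers vessel cores, not
  full widths), FAZ-A runs ~15% below the generated area (the contour
  settles inside the capillary-ring rim). Monotone trends and ranks are
  faithful; absolute calibration would need a measured point-spread
  model.
* Under SCR-like tortuosity the measured BVC falls while the generated
  caliber rises, because wiggly skeletons are longer per unit area; the
  caliber dial and the tortuosity dial are not fully independent in the
  measurement.
* The active contour assumes a single central avascular zone; eccentric
  fixation or split FAZ are out of scope.
* Backward elimination with the Bonferroni gate is deliberately
  conservative and tends to retain minimal sets; redundant near-equal
  features are dropped in favor of the one with the better
  cross-validated accuracy.
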