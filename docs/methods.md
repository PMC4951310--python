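# Methods

`stromascope` quantifies the vascular, perivascular and fibroblast-stroma
compartments of dual-stained tumor tissue-microarray (TMA) cores and carries
the resulting per-case metric panel through a survival-analysis design.
Because no public image/clinical dataset accompanies this kind of assay, the
package ships a first-class synthetic bench — an image renderer and a cohort
simulator with exact ground truth — and every guarantee the test suite makes
is a statement about recovery of that ground truth.

## Stain model and separation

Pixels are modeled by Beer–Lambert attenuation: with white point `W` and
intensity `I`, the per-channel optical density is `OD = -log10(I/W)`, and the
ODs of the two chromogens add along fixed RGB absorbance directions
(`stains.VECTOR_RED` for CD34 / Vector Red, `stains.VECTOR_BLUE` for the
stroma marker / Vector Blue). Separation solves the per-pixel least-squares
projection onto the two stain vectors; negative coefficients are clipped to
zero. On noiseless renderings this inversion is exact up to 8-bit
quantization (about 1/(255·T·ln10) OD at transmittance `T`).

The default stain vectors match the synthetic renderer. For real slides they
are configuration, not constants: Vector Red / Vector Blue absorbance
vectors vary by batch and scanner and must be calibrated per deployment.
Automatic vector estimation (Macenko-style) is deliberately out of scope.

The tissue mask is `sum(OD) > floor` (default 0.05), opened once (to shed
isolated off-tissue noise speckle), closed, hole-filled, and reduced to the
largest connected component. Tumor area = mask pixel count × pixel area; an
empty mask flags the core as excluded. Whether lumina/glass inside the mask
should be subtracted from "total tumor area" is unknowable from the assay
description; the full filled mask is used.

## Vessel and perivascular metrics

A vessel is an 8-connected component of CD34 OD above threshold (default
0.15 OD) inside the tissue mask, with components below 20 µm² discarded.
Its lumen is the set of enclosed holes; lumen area is the hole pixel count ×
pixel area and lumen perimeter uses the 4-direction Crofton estimator
(`skimage.measure.perimeter_crofton`; the marching-squares estimator is
selectable, and the choice is fixed per run). On digitized discs of the
relevant radii the Crofton estimator is accurate to well under 1 %.
A solid CD34⁺ component is a collapsed vessel: lumen area and perimeter 0.
Whether collapsed vessels should enter the mean lumen area is ambiguous;
by default they are included (configurable).

The perivascular ring of a vessel is every pixel within `ring_width_um`
(default 10 µm, about one mural-cell layer) of the vessel component,
excluding all vessel components and their enclosed lumina, intersected with
the tissue mask. Pixels near two vessels are assigned to the nearer one,
ties to the lower label; the implementation scans labels in increasing order
with a strict-improvement distance update, which realizes exactly that tie
rule. Per-vessel perivascular intensity is the mean marker OD over the ring;
the core-level value is the unweighted mean over vessels. Vessels whose ring
is empty (degenerate ring width) are dropped from intensity metrics with a
warning.

Coverage calls use the 10 %-of-maximal-intensity rule: with `M` the maximal
detected ring intensity, a vessel is *covered* iff its ring mean OD is
strictly greater than `0.10·M`; equality counts as uncovered. The
perivascular fraction is the covered share. The scope of `M` is ambiguous in
the assay description; the default takes it across all cores of a marker in
the run (making calls comparable between cases), with per-core scope
selectable.

## Stroma metrics

Marker-positive area is every tissue pixel with marker OD above a pre-set
background threshold, cleaned in two passes at the calibration
0.5477 µm/px (the value at which 50 px² = 15 µm² and 20 px ≈ 11 µm):

1. positive 8-connected components of area ≤ 50 px are set negative
   ("up to" read boundary-inclusive);
2. negative 4-connected regions fully enclosed by positive area whose
   minimal bounding-box side is ≤ 20 px are set positive.

"20 square pixels" and "minimal linear dimension 11 µm" are mutually
inconsistent as a single rule; the default reads it as the bounding-box-side
test (matching the linear-dimension wording), with an area-≤ 20 px variant
selectable. Complementary connectivity (8 for foreground, 4 for holes)
avoids topological paradoxes. The pass is idempotent and agrees exactly
with a brute-force transcription of the rules (tested against an
independent `scipy.ndimage` oracle on random rasters, including the 50-px
and 20-px boundary cases).

Stroma fraction = cleaned positive pixels / tissue pixels; stroma intensity
= mean marker OD over the cleaned positive area. The background threshold
is always the configured value; `calibrate_background` only *suggests* one
(max of an Otsu split and background-mode + 3·1.4826·MAD over sample cores)
and is deterministic. Desmin cores are scored in the perivascular
compartment only. PDGFβR cores flagged as epithelial-positive (an input
annotation; automated epithelium detection is out of scope) lose their
stroma metrics, and exclusions are counted in the run log.

## Aggregation

Cores aggregate to one 13-metric vector per (case, site): each metric is
the unweighted mean (median selectable) over cores where it is non-missing;
vessel metrics pool the CD34 channel of all markers' cores. Multiple
metastatic blocks pool into a single "metastasis" site. Three site policies
build the flat analysis table: `primary_only`, `primary_else_metastasis`
(metastatic values substituted when primary tissue is missing), and
`paired_only` (cases with both sites, for the concordance analysis); row
counts always satisfy paired ≤ primary ≤ extended.

## Cohort statistics

* **Correlation**: Spearman with midrank ties and the two-tailed
  t-approximation, pairwise-complete deletion; flags at p < 0.05, p < 0.01,
  and the highlighted class |ρ| > 0.5 together with p < 0.01. A
  Benjamini–Hochberg column is emitted for transparency but flags follow
  raw p, matching the design being emulated (no multiplicity correction).
* **Concordance**: per-metric Spearman ρ between primary and metastatic
  values on paired cases; the p < 0.01 cut-off governs which metrics are
  carried into the extended-cohort survival analysis.
* **Dichotomization**: mean split (high ⇔ value > mean) or lowest quartile
  vs the rest (low ⇔ value ≤ type-7 first quartile). The quartile rule is
  rank-based and thus invariant under monotone transforms.
* **Survival**: Kaplan–Meier group medians (earliest t with S(t) ≤ 0.5) and
  the two-group log-rank test via `lifelines`; Cox proportional hazards
  with Efron tie handling (`lifelines`), Breslow selectable via
  `statsmodels` PHReg — the two libraries also cross-check each other in
  tests on tie-free data. The clinical design is age (continuous), FIGO
  stage (III, IV vs I+II), grade (2, 3 vs 1) and residual tumor (present vs
  none), with the dichotomized metric as the term of interest. Wald 95 %
  CIs and p-values are reported; a warning fires below 10 events per
  coefficient, and diverging or non-finite fits raise with a diagnostic.
* **Backward selection**: iteratively drop the least significant covariate
  (Wald p above 0.05, configurable), treating dummy blocks (stage, grade)
  as units judged by their smallest member p, until all remaining
  covariates are significant; reported as whether the metric term survives.
  The elimination criterion is a documented choice — the emulated design
  names backward selection without specifying threshold or test.
* **Associations**: Pearson chi-square without continuity correction of the
  high/low label against each clinical category; degenerate tables are
  missing, expected counts < 5 warn.

## Synthetic image generator

Each scene is a circular 0.6 mm tissue disc at 0.5477 µm/px (both
configurable) with a faint neutral tissue background rendered as 0.04 OD of
each stain. Vessels are non-overlapping annuli (overlap is forbidden so
ground truth counts are unambiguous): an empty lumen (OD 0), a CD34 wall
(default 1.0 OD, 3 µm), and a perivascular marker coat rendered 1 µm wider
than the measurement ring so the ring sits strictly inside it. Per-vessel
coat ODs are either given explicitly or drawn as a covered/uncovered
mixture (defaults U(0.3, 0.9) and U(0, 0.02)) at the target covered
fraction. Diffuse stroma is built from random discs (OD ≈ N(target, 0.05),
clipped ≥ 0.25) placed outside vessel halos until the *total*
marker-positive area — perivascular coats included, exactly as positivity
would be measured — reaches the target fraction; targets below the coat
footprint alone are unattainable and the ground truth records the realized
fraction. Noise is additive Gaussian in OD space (default sd 0.02),
truncated at zero, applied after ground truth is recorded. Identical
parameters and seed give byte-identical images.

What the renderer does **not** emulate: nuclei and epithelium texture,
stain gradients and edge artifacts, chromogen co-localization, scanner
formats, and any non-annular vessel morphology. Passing recovery tests
therefore demonstrates correctness of the measurement logic, not
performance on real histology; thresholds and stain vectors must be
re-calibrated for real slides.

## Cohort simulator

Clinical covariates follow the emulated cohort's structure: age ~
N(60, 11) truncated to [22, 84]; stage, grade and residual-tumor
frequencies from the published distribution among cases with known status;
tissue availability 91:47:48 (both sites : primary only : metastasis only)
out of 186. The 13 metrics get realistic marginals (log-normal for
densities, areas and intensities; Beta for fractions) coupled across sites
by a Gaussian copula whose latent correlation is `2·sin(π·ρ_s/6)`, so the
population Spearman coefficient equals the requested concordance (defaults
are the published paired-cohort coefficients).

Survival follows exponential proportional hazards: rate
`h0·exp(β·x)` with the covariate vector containing centered age, stage and
grade dummies, residual tumor, and the high/low indicator of a designated
prognostic metric (default: PDGFβR stroma fraction, mean split on the
site-resolved value). Default log-HRs are the published multivariate
estimates (metric HR 1.66). Censoring is exponential with no
administrative cap, so the censoring probability has the closed form
`c/(c+h)` per case and the analytic expectation used by the calibration
test is exact. The defaults `h0 = 0.002`, `c = 0.011` per month were chosen
from that identity to give ≈ 68 % events and median survival times of
roughly 20–30 months, the scale of the emulated cohort.

## Problem sizes and numerical choices

The test suite renders cores at the full 0.6 mm default for geometry
recovery (20 scenes) and smaller 200–350 µm discs for unit tests. The Cox
coverage check uses 3000 simulated 186-case cohorts — enough replicates
(MC sd ≈ 0.4 %) to statistically resolve its 93–97 % acceptance band —
with sequential seeds; measured coverage is ≈ 94 %. Concordance recovery
uses 100 replicates at 91 pairs. The demo runs a 186-case statistical
cohort but renders images for only a handful of cases, which keeps a full
end-to-end run in tens of seconds; all outputs are byte-reproducible from
(config, seed).

Known limitations: Wald CIs show the usual mild finite-sample optimism at
~130 events with 7 coefficients; the ring tie-break (lower label wins) is a
convention, not biology; the generator's positivity floor ties its
ground-truth stroma fraction to the default background threshold (0.15 OD),
so recovery tests at other thresholds must set both; and none of the
defaults substitute for calibration on real staining batches.
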