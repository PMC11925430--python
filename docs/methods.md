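# Methods

This note documents the models, numerical choices and limitations behind
`cranial_iip`. It is the design record for maintainers; the README covers
usage.

## Problem and pipeline

Chronic increased intracranial pressure (IIP) in young children remodels the
calvarial bones: bone density drops markedly while thickness changes are
smaller and phenotype-dependent. The package quantifies local calvarial
thickness (mm) and density (Hounsfield units, HU) from CT-like volumes,
adjusts the measurements for age, sex and acquisition resolution with a
normative linear model, contrasts craniosynostosis (CS) phenotype groups
(metopic MC, sagittal SC, unicoronal UCC, bicoronal BCC, Apert syndrome AS)
against normative and chronic-IIP references, and screens subjects with a
logistic risk classifier. Because presurgical pediatric CT datasets of this
kind are not publicly deposited, the package ships a first-class synthetic
data module: every stage is validated against analytic phantoms and
simulated cohorts with known ground truth.

## Preprocessing

Scans with in-plane spacing above 0.5 mm or slice thickness above 1.5 mm are
excluded (boundary inclusive: exactly 0.5/1.5 mm is kept, since the
exclusion rule is a strict "larger than"). Retained volumes are resampled to
a uniform 0.5 × 0.5 × 1.5 mm grid by trilinear interpolation. Out-of-grid
samples are filled with −1000 HU (air), the CT background convention. The
voxel-volume covariate `V` used by the regression is always the **original**
acquisition voxel volume (mm³), carried through resampling on the `Volume`
object: the model adjusts for acquisition resolution, not for the processed
grid.

## Calvaria segmentation and the location grid

Segmentation is classical — HU threshold (default 150), largest 26-connected
component, one-voxel morphological closing. This is deliberate: the
scientific content under test is the quantification and statistics, and for
phantoms (where bone is the only high-HU structure) a threshold segmenter is
exact up to rasterization. It is *not* adequate for real infant CT, where a
dedicated segmentation model plus manual review would be substituted.

The standardized anatomical representation is a fixed icosphere direction
grid (default 2562 directions, subdivision level 4) centred at the mask
centroid. Because the grid is identical for every subject, location `l` in
one subject corresponds to location `l` in every other — a deliberately
simple stand-in for suture-guided subject-specific correspondence. Bone
labels are assigned by azimuthal sector in a canonical frame (+x anterior,
+y left, +z superior): frontal within ±55° of anterior, parietal from 55° to
125°, occipital beyond, with left/right split at the midline. Canonical
great-circle suture bands (a coronal pair, a lambdoid pair, a midline
sagittal/metopic band; default width 2 mm) are labelled `suture` and
excluded from all bone summaries. Ray directions are mapped through the
volume's direction matrix, so a rigidly rotated scan with correct
orientation metadata yields identical maps (regression-tested with an exact
180° rotation).

**Thickness** at a location is the chord length of the centroid ray through
the bone mask: (outer crossing − inner crossing), sampled at half the
smallest voxel spacing with nearest-neighbour lookup. **Density** is the
mean HU of mask samples along that chord. Rays that miss the mask flag the
location invalid; invalid locations propagate as NaN and are excluded from
every average. Chord-length thickness was chosen over a
distance-transform/medial-surface definition because it is analytically
exact on the ellipsoidal phantoms (the phantom thickness field is defined
radially), giving a closed-form oracle. On a 70/74 mm spherical shell at the
default grid the measured mean is within 0.02 mm of 4.0 mm; the test bound
of 0.6 mm reflects the worst-case voxel-limited discretization (slices are
1.5 mm).

## Synthetic phantoms

Phantoms are ellipsoidal shells: the outer surface is an ellipsoid with
semi-axes `outer_radii`; bone occupies the radial band of width
`thickness_field(u)` inside it, with HU `density_field(u)`, both arbitrary
functions of surface direction `u`. Rasterization is voxel-centre based
(strict inner inequality, so a zero-thickness field produces an empty
shell); suture bands are carved as gap tissue (default 60 HU). Partial
volume is emulated by a Gaussian blur of configurable FWHM, noise as
additive i.i.d. Gaussian HU. Ground truth (thickness, density, label per
grid direction) is evaluated analytically *before* degradation. The geometry
is intentionally not anatomical — analytic ground truth is the point.

## Cohort simulation and the normative model

Each subject contributes per-region summaries for five bones
(frontal L/R, parietal L/R, occipital) plus the whole-calvaria mean. For a
region and measure the model is

```
Y = β0 + β1·Age + β2·Sex + β3·V + β4·IIP + β5·MC + β6·SC
      + β7·UCC + β8·BCC + β9·AS + ε,     ε ~ N(0, σ²)
```

with Age in years, Sex coded 1 male / 0 female, V the original voxel volume
in mm³, and six mutually exclusive group indicators (all zero = normative).
The simulator draws covariates per group from the published dataset
composition (sample sizes 1018/48/79/242/63/19/19 for
normative/IIP/MC/SC/UCC/BCC/AS — AS counted per scan; ages e.g.
3.08 ± 3.02 y normative, 0.39 ± 0.33 y nonsyndromic CS; sex ratios; voxel
volumes ≈ 0.06–0.105 ± SD mm³) and evaluates the linear predictor plus
Gaussian noise. Ages and voxel volumes are truncated at 0 (and 10⁻³ mm³);
with the study means the truncation mass is small and accepted as a
simplification.

Default group effects are the published magnitudes (e.g. global density:
IIP −163.73, MC −132.92, SC −149.60, UCC −130.96, BCC −131.84,
AS −196.47 HU; global thickness +0.04 to +0.50 mm). UCC frontal/parietal
effects are side-specific (fused side = left by default). Normative
baselines are not published; we chose realistic pediatric values (intercepts
2.4–2.8 mm and 620–700 HU; slopes +0.35 mm/y and +55 HU/y; small sex
offsets; voxel-volume slopes −0.5 mm/mm³ and −400 HU/mm³, the latter giving
a ≈40 HU partial-volume spread over the observed V range). Residual SDs are
likewise unpublished; treating the published "SD" columns as standard errors
of the mean difference implies residual SDs around 110–165 HU and
0.34–0.54 mm, so the defaults are **140 HU** and **0.4 mm**. These defaults
define the study conditions for all tests and were fixed once.

Fitting is ordinary least squares (statsmodels). Rank deficiency — most
commonly an absent group — raises an error naming the offending column
rather than silently dropping it. Adjusted measurements subtract the fitted
age, sex and voxel-volume effects only; group effects are retained. Group
contrasts are two-sided Welch t tests on adjusted values (the published
analysis reports t tests after adjustment; whether its p-values are Wald
coefficient tests or t tests on adjusted values is ambiguous — we chose the
latter and keep an internal-consistency test that the group-vs-normative
contrast agrees with the fitted group coefficient within its standard
error). The contrast "SD" column is the standard error of the mean
difference, √(s²ₐ/nₐ + s²ᵦ/nᵦ). Repeated AS scans enter as independent
observations, as a cross-sectional regression implies; prevalence can
optionally be computed per patient. No multiple-testing correction is
applied to the contrast tables; Bonferroni is used only for the risk
distribution comparisons.

## Risk classifier and operating points

Features are the adjusted densities of the whole calvaria plus the five
bones. The classifier is an L2-regularized logistic regression (default
C = 10⁴ — weak enough to be invisible on realistic cohorts, but keeping
separable inputs finite; the oracle-equivalence test disables it with
C = 10¹²). Operating points are chosen on **out-of-fold** probabilities from
stratified 10-fold cross-validation with a fixed shuffle seed, never on
resubstitution scores. Candidate thresholds are midpoints of consecutive
sorted unique scores, with "score ≥ threshold" counted positive. The Youden
threshold maximizes sensitivity + specificity − 1 (ties → smallest
threshold); the screening threshold is the smallest candidate with
specificity ≥ 0.95. `select_thresholds` raises when no candidate reaches
95% specificity; `fit_iip_classifier` degrades gracefully in that case
(Youden point kept, screening threshold NaN, warning logged), since small
overlapping samples can legitimately lack such a candidate. Prevalence is
100 × (count of scores ≥ threshold)/n per group and is monotone
non-increasing in the threshold by construction. Distribution comparisons
use two-sided Mann-Whitney U with Bonferroni multiplier m = number of pairs
actually tested (recorded in the output); the risk-age association is
tie-corrected Spearman rank correlation.

## What the synthetic study does and does not show

Passing tests demonstrate that the measurement chain is unbiased on shells
with known geometry, that the regression recovers designed effects at
published sample sizes, that the statistical operations agree with
independent brute-force oracles, and that when CS groups carry an IIP-like
density deficit the classifier assigns them elevated prevalence. They do
**not** show that the published patient-level numbers are reproduced: those
depend on non-public CT datasets, a pretrained segmentation network and a
subject-specific correspondence model that are out of scope here. Two
consequences worth flagging: the simulated risk-age correlation is ≈0
because adjusted features have no residual age coupling in the generator
(the published positive correlation reflects real-data structure); and
simulated probability thresholds sit much lower than the published 54%/73%
because the simulated class imbalance (1018 vs 48) shifts the probability
scale.

## Problem sizes and numerics

Default analyses run on the published cohort sizes (1488 records) and a
single 0.5 × 0.5 × 1.5 mm phantom (~11M voxels, a few seconds); tests use
smaller spheres (30 mm, 1 mm voxels) and scaled cohorts. Ray sampling uses
step = min(spacing)/2; phantom rasterization processes the volume in ~2M
voxel slabs to bound memory. All randomness flows through
`numpy.random.default_rng` seeds stored in the specs/designs, and every CLI
stage writes a manifest (config hash, seed, versions, SHA-256 per output)
sufficient to verify exact reproduction.

## Known limitations

- The sector-based bone labeling and canonical suture positions are fixed
  geometry, not detected anatomy; real calvaria would need suture detection.
- Chord-length thickness overestimates where the bone is oblique to the
  centroid ray (negligible for near-radial shells, real for skull base).
- The icosphere grid includes inferior directions that real calvaria do not
  cover; validity flags handle this, but region means are direction-weighted
  rather than area-weighted.
- Gaussian blur + additive Gaussian noise is a coarse model of CT physics
  (no beam hardening, no structured noise, no motion).
- The simulated cohort has no between-region residual correlation beyond the
  shared covariates, which likely makes the synthetic classification task
  easier than the clinical one.
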