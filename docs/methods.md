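# Methods

This note documents the models, defaults and numerical choices behind
`mifquant`, and what the synthetic tests do and do not demonstrate about
real whole-slide data.

## Pipeline model

The toolkit treats a multiplexed slide as a named 7-channel 2D image
(DAPI, autofluorescence, CD79a, CD38, Ki-67, CD19, CD138) with a physical
pixel size (default 0.325 µm/pixel, a 20x whole-slide scan). Analysis is a
fixed sequence of stages, each with logged parameters:

**Tissue detection.** The autofluorescence (AF) channel is Gaussian-blurred
(default sigma 4 px) and thresholded (Otsu by default; a constant channel
yields an empty mask rather than an arbitrary split). Connected components
below 500 px are dropped as non-tissue specks. Manual exclusions (folds,
staining artifacts, non-renal tissue) enter as GeoJSON polygons and are
subtracted. Rasterization includes exactly the pixels whose centers fall
strictly inside a polygon, so area arithmetic is exact and exclusion is
idempotent and monotone. Area is `true pixels x (pixel_size_um/1000)^2` mm².
Automatic detection of non-renal tissue is out of scope — that is a
pathologist's call and enters only through ROI files.

**Segmentation.** The built-in segmenter is deterministic and classical:
Gaussian smoothing of DAPI (sigma 1 px), Otsu foreground on
log1p(intensity), Euclidean distance transform, peaks at least
`min_peak_distance_px` (default 5) apart as seeds (numbered in (row, col)
scan order for platform stability), 4-connected watershed, removal of
components under `min_area_px` (default 20). The foreground threshold is
taken on the log scale because nuclear brightness is right-skewed; a
raw-scale Otsu can land above the dimmest nuclei and silently drop cells.
Nuclear labels are then expanded by `expand_radius_px` (default 2) to
approximate whole-cell regions without overlap; expansion claims background
pixels by exact Euclidean distance with ties to the smaller label id. The
segmenter is deliberately replaceable: any external instance-segmentation
tool's integer label mask can be loaded instead, and everything downstream
is source-agnostic. MFI is computed over the (optionally expanded) cell
region, and which compartment was used is logged.

**Features.** Per label: pixel count, unweighted pixel centroid (an
intensity-weighted centroid would couple geometry to staining), arithmetic
mean intensity per channel. Cells whose centroid pixel falls outside the
tissue mask are kept but flagged `in_tissue = False`; only in-tissue cells
are counted downstream, keeping the exclusion auditable.

**Gating.** Marker status is `MFI >= cutoff` — the boundary counts as
positive so threshold tests are deterministic. Cutoffs come from one of
three methods per marker: `manual`, `otsu`, or `gmm2` — a two-component
Gaussian mixture fit by EM (k-means initialisation, fixed seed) on
`log1p(MFI)`, with the cutoff at the equal-posterior boundary mapped back
to the intensity scale. Fluorescence intensities are approximately
lognormal, so the mixture is fit on the scale where its components are
near-Gaussian; fitting on the raw scale lets the wide positive component
drag the boundary into the negative tail. Thresholds are fit per slide by
default (staining intensity varies slide to slide); a fitted `ThresholdSet`
can be passed explicitly to share cutoffs across a cohort. Cells with AF
MFI at or above the AF cutoff are rejected before any gate is evaluated.

Gate definitions are data, not code: each gate is a (required-positive,
required-negative) marker pair, deliberately permissive about unmentioned
markers — a CD79a⁺/CD138⁻ cell is a B cell regardless of CD38 or Ki-67, so
activated and proliferating B cells are not lost. Consequences of the gate
algebra, enforced by property tests: `bona_fide_pb ⊆ permissive_pb`;
`b_cell` is disjoint from both ASC gates (CD138 appears with opposite
sign); a CD138⁺/CD38⁻ profile (renal tubular epithelium) receives no gate.

**Reporting.** Per slide: per-gate count, density (count / tissue area) and
fraction (100 x count / total cells). The total-cell denominator defaults
to AF-passing in-tissue cells (`denominator="af_pass"`); counting rejected
cells back into the denominator is a documented toggle (`"all"`), since
either convention is defensible and the choice is recorded in output
metadata. Cohorts aggregate cumulatively: counts, areas and totals are
summed, then densities, fractions and derived proportions are recomputed
from the sums. This count-weighted convention (rather than averaging
per-slide frequencies) is the one under which derived proportions follow
directly from raw cumulative counts; per-slide values are still emitted for
plotting. Derived proportions with a zero denominator are reported as
missing, never as 0. CSV output rounds percentages to 2 dp; JSON keeps
full precision; every output carries the config hash.

## Panel ordering

Sequential TSA multiplexing exposes each epitope to 0–n heat-elution cycles
depending on its position in the staining sequence. Given a measured
tolerance matrix `value[m, k]` (% change in thresholded MFI of marker `m`
at position `k` relative to position 1), the toolkit formalizes sequence
design as: maximize `Σ_m value[m, pos(m)]` over bijections `pos`, optionally
restricted to orders where consecutive positions alternate antibody host
species (mouse/rabbit) — the practical constraint when anti-mouse and
anti-rabbit secondaries alternate to avoid carry-over detection. The search
is exhaustive (n ≤ 8; 5-plex panels have 120 orders), with ties broken by
lexicographic marker order, and the unconstrained solution is certified
against `scipy.optimize.linear_sum_assignment`. On the bundled measured
matrix the two objectives differ (370.24 unconstrained vs 360.37
constrained) and only the constrained optimum matches the sequence the
panel actually uses — the host-alternation constraint is load-bearing, and
`constraint="none"` is exposed so other policies can be compared.

## Phantom generator

The phantom emulates exactly the features the pipeline must be sensitive
to, with fully known ground truth:

* **Cells** are uniform-intensity disks (radius 6 px): DAPI and Ki-67 on an
  inner nuclear disk (radius 4 px), membrane/cytoplasmic markers on the
  full disk. This is the simplest geometry that still distinguishes
  nuclear from whole-cell MFI extraction.
* **Intensities** per cell and channel are lognormal: median 1000 (positive)
  vs 100 (negative), log-sd 0.25 — non-negative, right-skewed, ~4 sigma of
  separation, so threshold recovery is near-perfect in the noiseless
  regime and degrades gracefully with noise.
* **Phenotypes**: `b_cell` (CD79a⁺/CD138⁻), `plasma_cell`
  (CD138⁺/CD38⁺/Ki-67⁻), `bona_fide_pb` (CD138⁺/CD38⁺/Ki-67⁺), `t_nk_like`
  (CD38⁺/Ki-67⁺ but CD79a⁻/CD138⁻ — the contaminant of the permissive PB
  gate), `other` (all negative). Anchor markers are deterministic so
  planted gate counts are exact; subfraction markers are Bernoulli at
  lymphoid-tissue-scale rates (CD19⁺ in 15% of B cells; CD79a⁺ in 88% of
  PCs and 84% of bona fide PBs), so subfraction reporting is exercised
  with realistic, seed-dependent proportions.
* **Tubules** are rings of nucleated epithelial cells (ring radius 22 px,
  8 cells) drawing CD138 from the positive and CD38 from the negative
  distribution — the planted renal confound; a correct pipeline assigns
  them no gate.
* **Artifacts** are larger blobs (radius 9 px) bright in AF and every
  marker; a correct pipeline rejects them on AF before gating.
* The **tissue bed** is a uniform AF plateau (median of the AF negative
  class) over an ellipse (or any polygon), so tissue detection has a sharp
  oracle. Placement is rejection sampling with per-object exclusion radii
  (cells at least `2r + 3` px apart) and an attempt cap; infeasible packing
  raises an explicit error naming the limiting class.
* **Bleed-through** is a global linear channel-mixing matrix applied after
  rendering (identity by default; the documented "bleed on" regime leaks
  2% between spectrally adjacent marker channels); **noise** is additive
  Gaussian (default sd 5, clipped at 0). Linear mixing lets tests probe the
  claim that thresholding alone absorbs realistic bleed — at these levels
  it does.

Fixed spec + seed gives bit-identical images and truth tables.

What the phantom does **not** emulate: optical PSF and focus variation,
scanner vignetting and stitching seams, intensity gradients within cells,
overlapping/3D nuclei, variable cell sizes and shapes, spatially structured
autofluorescence, or slide-to-slide staining drift. Exact phantom recovery
therefore validates the quantification logic (masking arithmetic,
segmentation bookkeeping, MFI extraction, gate algebra, denominators,
aggregation), not the image-quality robustness of any particular
segmenter or threshold on clinical material — on real slides, threshold
quality should be reviewed per slide (manual override is first-class) and
segmentation can be delegated to a dedicated instance-segmentation model
via the external label-mask path.

## Problem sizes and determinism

End-to-end checks run 2048 x 2048 px tiles (0.44 mm² of tissue) with 445
phenotype cells, 3 tubules and 5 artifacts, across 5 seeds in the test
suite and 3 seeds x 2 noise regimes in the acceptance script; unit tests
use 512 px tiles. All randomness flows through explicit integer seeds
(generator, mixture initialisation), watershed seeds are ordered
deterministically, and pipeline outputs are byte-identical across reruns.

## Known limitations

* The built-in segmenter assumes roughly convex, non-overlapping nuclei of
  broadly similar size; crowded clinical tissue is better served by an
  external segmentation model.
* `gmm2` assumes a marker's per-cell MFI distribution is two-component;
  markers with no positive population on a slide are degenerate and should
  be thresholded manually (a constant sample raises with that advice).
* Cohort "mean frequency" is defined as cumulative count / cumulative
  area; the alternative (mean of per-slide densities) is not computed at
  cohort level, though per-slide densities are emitted for it.
* The panel-ordering objective (max summed % retention, host alternation)
  is one formalization of a design practice that may also weigh factors
  this model does not see, e.g. fluorophore brightness pairing.
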