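# Methods

`epiquant` quantifies stratified squamous epithelium (the motivating
system is paired inner/outer foreskin sections from the same donor) from
multi-channel immunofluorescence rasters, and runs the paired
nonparametric inference that such within-subject designs call for.  This
note records the models, conventions and numerical choices, and what the
synthetic test bed does and does not establish about real tissue.

## Image model and units

A section is a set of named 2-D channels (nuclear counterstain, red
autofluorescence, far-red stain, blue stain, isotype control) with
intensities in arbitrary units (AU) scaled to [0, 1]; integer TIFFs are
rescaled by their dtype maximum on ingest.  Physical scale is a single
`pixel_size_um` (µm per pixel) carried on every section and mask; a JSON
sidecar, not TIFF tags, is the source of truth for it.  The helper
`convert_length(value_px, magnification, compression, camera_scale)`
implements µm = px · camera_scale / magnification / compression (a
composite compressed to 50% has compression 0.5, doubling the effective
µm per stored pixel); the acquisition chain is parameterized rather than
hard-coded because it varies per microscope.

## Segmentation

The epidermis is outlined from its red-channel autofluorescence: global
threshold (Otsu by default; any fixed AU value can be supplied), removal
of objects smaller than 500 µm² (the epidermis is one large structure),
then hole filling.  Empty foreground is an error, not an empty mask.
8-neighbour connectivity is used for every connected-component step in
the package.  Whether the stratum corneum (SC) autofluoresces is
tissue- and protocol-dependent; the synthetic generator exposes it as an
option and by default excludes the SC, so "epidermis" means the cellular
strata (SB–SG) and the SC is handled through its own outline mask.

Nuclei are connected components of the counterstain above a fixed
threshold (default 0.5 AU), kept if ≥ 5 µm² (single-pixel noise
rejection) and if their centroid lies inside the region of interest.
Touching nuclei merge into one detection — there is deliberately no
declumping/watershed step, a documented limitation that matters at high
nuclear density.

## Morphometry

Mean thickness of an outlined strip is area / Feret diameter, where the
Feret (maximum caliper) diameter closely approximates the strip length.
A mask is treated as a union of unit pixel squares: the Feret diameter
is the exact maximum pairwise distance over the corner points of its
boundary pixels, computed via the convex hull (pairwise max over hull
vertices).  Under this convention an axis-aligned w×h rectangle has
Feret √(w²+h²) exactly, so the thickness of a strip is w·h/√(w²+h²),
converging to the true height h with relative error ≤ h²/(2w²).  A
single-pixel mask therefore has Feret √2 · pixel size (its true caliper
width) rather than zero.  Disconnected masks are allowed — manual
outlines fragment — and the Feret spans the union's hull.

Parakeratosis is retained-SC-nuclei per millimetre: nucleus count in the
SC outline divided by the SC Feret diameter in mm.  Per-subject
summaries are medians over that subject's sections (even counts: mean of
the middle two); the expected design is 3–5 sections per site and a
warning is logged outside that range.

## Stain quantification

All four stain statistics are section-level summaries with *scalar*
isotype subtraction — the summary minus the same summary measured on the
matched isotype-control stain, floored at 0 (negative corrected values
are background-subtraction artifacts).  Subtraction is not pixelwise
because the baselines of interest are summary-level backgrounds.

* **Ki-67 fraction**: 100 · positive/total nuclei − baseline.
* **Coverage**: percent of epidermal pixels strictly above an AU
  threshold (Otsu within the mask by default, or fixed) − baseline.
* **Mean intensity**: summed epidermal fluorescence / epidermal pixel
  count (AU/pixel) − baseline.
* **Polarization**: Σ I(p)²·r(p) / N over epidermal pixels, with r(p)
  the distance in µm from the epidermal midpoint.  The midpoint is the
  intensity-independent centroid of the mask (a per-column midline
  variant is provided for long undulating strips).  Per-pixel
  normalization keeps sections of different sizes comparable and puts
  the score in AU/pixel.  The score is position-sensitive by design:
  it scales quadratically in a global intensity multiplier and strictly
  increases when intensity moves away from the midpoint, so membrane
  stain concentrated under the SC scores high while uniform cytosolic
  stain scores low.  (It borrows the name "angular second moment" but is
  unrelated to co-occurrence-matrix texture features.)

## Cell detection

Marker-positive cells are connected components of pixels above a
per-pixel AU threshold (0.03 for CD4 on the blue channel, 0.025 for CCR5
on far-red), assigned to a compartment by centroid membership, and kept
when the component area lies in the 10–33 µm² gate.  Densities are
cells/mm² of compartment area; the per-subject isotype-control density
is subtracted with a floor at 0.  Double positives are counted by
*optimal* one-to-one bipartite matching of CD4 and CCR5 centroids within
a 3 µm pairing radius (same-cell colocalization at 20× scale; greedy
matching can be suboptimal, so the assignment problem is solved
exactly).  The gate is applied at detection and the subtraction at
density level, since published backgrounds are densities.

Two caveats.  First, widening the area gate can only add detections,
but raising the intensity threshold is monotone only for well-separated
objects: on percolating noise a single out-of-gate cluster can split
into many in-gate fragments as the threshold rises.  Second, fixed AU
thresholds are meaningful only relative to a particular background
level; on noisy images the detection threshold must sit between the
background and the signal (the `detection_threshold` override), while
the area gate is unchanged.

## Synthetic test bed

The generator renders a horizontal epithelial strip — background, SC,
then SG/SS/SB, then dermis — with an optional sinusoidal undulation of
the basal boundary, reproducing the length ≫ thickness geometry the
area/Feret estimator assumes.  Band heights are strata fractions of a
72 px default epithelium on a 512 px strip at 1 µm/px (SC ≈ 11 µm, near
reported SC medians; the aspect ratio keeps the estimator's intrinsic
error ≈ 1%).  Nuclei are non-overlapping disks (radius 2.5 µm) placed
uniformly in the cellular strata at 2000/mm²; SC nuclei are placed per
mm of length as the parakeratosis truth.  Membrane stain is rendered as
thin borders of the nearest-nucleus (Voronoi) tessellation within a
stratum; cytosolic stain is a uniform fill.  Infiltrating cells are
disks of controlled area (rendered pixel area is the recorded truth) at
0.5 AU on their marker channels.  The isotype channel is pure background
level.  Noise is additive Gaussian clipped to [0, 1] (no Poisson/PSF
model).  All randomness flows from one explicit seed; identical spec and
seed reproduce bit-identical images.

Cohorts are generated at measurement level: each metric is log-normal
with a subject effect shared between sites (σ = 0.35), a site effect
(σ = 0.15) and section noise (σ = 0.10), anchored at outer-site medians
on the scale of published foreskin values (SC 19.9 µm, claudin-1
intensity 0.039 AU/px, epidermal CCR5 6.46 cells/mm², ...); the
dispersion split is chosen so the marginal log-IQR matches the reported
interquartile ranges.  Inner-vs-outer effects are multiplicative ratios;
`study_effects()` encodes the published directions and magnitudes
(SC ratio 0.8, claudin-1 intensity ×1.54, claudin-4 polarization ×0.32,
epidermal CCR5 ×3.3, IP-10 ×4, GM-CSF ×3, RANTES ×2, ...).  Analyte
panels draw per-subject inner/outer ratios log-normally (log-SD 1.0).
Hemoglobin contamination of epidermal explants is Bernoulli per subject
(default rate 0.15, matching 3 exclusions in 20); contaminated cultures
receive hemoglobin at or above LOD + 1 CI.  Image rendering per cohort
section is available and used for end-to-end runs at small n; the
statistical calibration studies use the measurement-level draws, whose
structure is exactly what the inference consumes.

What passing tests show — and do not.  Truth recovery on noise-free
renders verifies the estimators' arithmetic, not their behaviour on real
tissue: the generator has no uneven illumination, no spectral bleed, no
out-of-focus light, no nuclear declumping challenge, and its membrane/
cytosolic patterns are idealized.  Robustness at noise SD 0.05 probes
threshold stability, not acquisition artifacts.

## Inference

Paired inner-vs-outer comparisons use the Wilcoxon matched-pairs
signed-rank test.  Zero differences are dropped; tied |differences| get
mid-ranks.  For n ≤ 25 the two-sided p-value is exact: the distribution
of W⁺ over all 2ⁿ sign assignments is built by the subset-sum recursion
over (doubled) ranks, which handles ties exactly; beyond that a normal
approximation with tie-corrected variance is used.  The reported
statistic is W = min(W⁺, W⁻).  Analyte ratio-vs-1 tests run on
log(ratio) vs 0 — the symmetric, scale-invariant formulation for fold
changes.  (Testing r − 1 instead gives identical p-values when all
ratios lie on one side of 1, but can differ when they straddle it,
because the monotone transform preserves signs, not magnitude ranks.)

Multiplicity is controlled with the Benjamini-Hochberg step-up over a
*declared* family: adjusted p = min over higher ranks of p·m/rank,
capped at 1, where m is the declared family size (default: the number
of supplied p-values; m may exceed it when the study family is larger
than the batch at hand, e.g. m = 53).  Verdicts: adjusted p < 0.05
significant, < 0.10 trend.  With n = 17 pairs the exact test is
discrete, so under a global null the realized false-discovery
proportion sits below the nominal 5% — conservatism, not error.  Power
to flag a lone 20% effect in an m = 53 family is limited (rank-1 BH
needs raw p < 0.05/53); in a family containing the full set of
study-direction effects, the SC-thinning comparison is recovered as
significant in a clear majority of replicate cohorts.

The hemoglobin QC rule excludes epidermal explant cultures with
hemoglobin ≥ LOD + 1 CI (inclusive boundary); dermal cultures are
vascularized and pass through.

## Pipeline and reproducibility

`run_pipeline` wires simulate → segment → measure → summarize → QC →
family statistics and writes tidy CSVs plus a JSON report; every output
row carries the seed and a SHA-256 config hash, writes are atomic
(write-then-rename), and identical config + seed reproduce byte-identical
CSVs.  The default end-to-end run uses 6 subjects × 2 sites × 3
sections; calibration studies in the test suite use 17-subject
measurement-level cohorts with 300–1000 replicates.
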