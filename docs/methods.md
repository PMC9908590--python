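# Methods

## The annotation model

An annotation document describes one whole-slide image (WSI) by one
annotator in one phase. The *coarse* phase carries decision-layer class
regions and a free-text slide caption; the *fine* phase adds subtype labels,
reason-layer feature regions with terminology captions, and bundles. All
labels reference a three-level terminology tree: diagnosis **classes**
(adenocarcinoma, adenoma, normal) → decision **subtypes** (differentiation
grades, invasion/budding categories, adenoma grades) → **reason labels**
(morphological features). The bundled fixture carries the reference
vocabulary's shape — 3 classes, 12 subtypes and 77 reason labels, split
9 + 34 / 2 + 25 / 1 + 18 per class. Entries whose display names were not
available verbatim are explicit synthetic placeholders, marked
`[synthetic placeholder]` in the name; all count checks are data-driven
against whatever table is loaded, never hard-coded.

Validation enforces the structural invariants (unique region ids, ≥ 3
vertices and positive area per polygon, subtype-under-class and
reason-under-subtype lineage, bundle members existing and belonging to at
most one bundle, coarse-phase content restrictions) and reports stable
violation codes (`DANGLING_BUNDLE_MEMBER`, `LABEL_LINEAGE`, …) rather than
raising, so audits can enumerate problems. Free-text reason tags are legal:
any caption token that does not resolve in the tree is carried as
non-terminology text. Region ids are caller-supplied and never renumbered,
keeping diffs stable across audit rounds.

Serialization is deliberately boring: versioned JSON documents, TSV
terminology, GeoJSON (RFC 7946) polygon features with closed rings, JSON
Lines traces with a leading header record, CSV patch manifests. Writers fix
key order and float formatting so saving equal objects is byte-identical;
coordinates are level-0 integer pixels and non-integral floats are rejected
on import.

## Patch pipeline

Patches live on a regular grid at the slide's reference magnification
(default 256 px, 20×). Coordinates are 0-based, origin top-left, x right /
y down, and boxes are half-open, so at stride = patch size the grid
partitions the plane — every pixel belongs to exactly one patch.

**Tissue masking.** Foreground is the dark class of the Otsu split on a
Gaussian-smoothed (σ = 2) luminance image: tissue absorbs light, glass does
not. The Otsu operation itself takes a 256-bin histogram, maximizes
between-class variance over all splits "bins ≤ t vs > t", and returns the
smallest maximizer; a histogram with all mass in one bin is degenerate
(a blank slide yields an empty mask rather than an error). A patch is
*valid* when its tissue fraction is ≥ 0.5 (configurable; the protocol only
requires patches to come from foreground).

**Stain normalization (Macenko).** Intensities are converted to optical
density, OD = −log10((I + 1)/I₀) with I₀ = 255 and a +1 pseudo-count;
pixels whose OD is below β = 0.15 on all channels are background and
discarded (fewer than 100 usable pixels is an error). The two stain
directions are the α = 1 and 100 − α percentile angles of the OD cloud
projected on its top-2 singular plane; hematoxylin is the vector with the
larger blue-channel component. Reference concentrations are the 99th
percentile of the projected stain concentrations. Normalization rescales a
source image's concentrations by the target's reference concentrations and
recombines with the target's stain matrix. Slightly negative concentrations
(pixels in the angular tails beyond the percentile vectors) are kept by
default so that normalizing an image to its own model is the identity up to
quantization; a `clip_negative` flag restores the conventional behavior. A
nearly single-stain image makes the percentile angles collapse and is
flagged degenerate rather than silently fit.

**Labeling and sampling.** A patch inherits the label of the decision
region containing its center pixel; boundary points count as inside
(favoring lesion recall), and overlapping regions are resolved by a severity
priority, adenocarcinoma > adenoma > normal. Train/test splits are assigned
per slide so no slide contributes to both sides. Class targets are sampled
uniformly without replacement; normal-class patches can be restricted to
slides whose annotation contains no tumor region, so normal-looking tissue
on tumor slides never trains the normal class (the default posture; a flag
admits explicitly-labeled normal regions instead). Test slides are tiled
with stride = patch size, i.e. without overlap.

## Agreement protocol

Two documents for the same slide are compared at three levels:

1. **Slide** — the highest-priority class among each document's decision
   regions.
2. **Patch** — Cohen's κ over central-pixel labels on a shared grid,
   computed separately for class labels and subtype labels. Only patches
   labeled by at least one annotator enter; counting the both-background
   class would inflate agreement (a flag includes it). κ = (p_o − p_e)/(1 −
   p_e) with product-of-marginals chance agreement; when both raters use a
   single identical label, p_e = 1 and κ is defined as 1 with a degeneracy
   flag. Note that on effectively single-class slides p_e approaches p_o and
   κ is near zero even for high raw agreement — the observed agreement p_o
   is reported alongside for exactly this case.
3. **Pixel** — Dice per label on rasterized class maps at a 1/4 linear
   downsample (bounding memory); rasterization paints lower-priority classes
   first so overlaps resolve exactly as in patch labeling. Two empty masks
   score 1 by convention.

Captions are compared between reason regions matched greedily by descending
polygon IoU. Tokenization lowercases, treats commas as separators, strips
trailing periods and splits on whitespace; terminology ids are first
detokenized to their display names. BLEU_n is the clipped n-gram precision
(candidate counts clipped at the per-reference maximum); the composite score
is the brevity penalty exp(1 − r/c) (for c < r) times the geometric mean of
orders 1..4, with no smoothing by default — any zero precision zeroes the
score, and an identical pair scores exactly 1 provided the caption has at
least 4 tokens. An optional add-one smoothing exists for diagnostics only.

The audit diff matches regions greedily by descending IoU above 0.5;
unmatched old regions are removals, unmatched new ones additions, and
matched regions with differing labels or captions are modifications. The
classification report derives per-class recall and precision and overall
accuracy from a ground-truth-by-prediction confusion matrix; zero
denominators are reported as undefined, never as 0.

## Behavior traces

Dwell follows last-event-holds semantics: each field-of-view or
magnification event opens an interval closed by the next such event or the
final trace event; voice, pencil and edit events do not move the viewport
and do not close intervals. The viewport rectangle is screen size (default
1920×1080) divided by magnification, centered on the FOV center and clipped
to the slide. Intervals longer than 120 s are truncated as idle — an
unattended session would otherwise dominate the heat. The heatmap deposits
each interval's full dwell into every grid cell (default 256 px, aligned
with patches) its rectangle intersects, so total cell-heat equals
Σ dwell × covered-cell-count exactly — the conservation law the tests check.
Per-region dwell attributes each interval to the first document-order region
containing its center, keeping the attributed total ≤ the trace total under
overlaps.

## Lesion clustering

Abnormal patch predictions are integer grid points. DBSCAN with Euclidean
metric, eps = 1.5 grid units (making the 8-neighborhood adjacent) and
min_samples = 4 (suppressing isolated false positives) groups adjacent
abnormal patches into lesion clusters; the implementation processes points
in lexicographic scan order so border points reachable from two clusters
deterministically join the first, and cluster ids are canonicalized by each
cluster's smallest member, making the partition invariant under input
permutation. Supplying a normal-class point is a contract violation, not a
silent filter. Caption bags cap each cluster at a fixed size (64 for
training, 256 at test time in the motivating setup): larger clusters are
sampled uniformly without replacement, smaller ones kept whole or — in
training mode — resampled with replacement to exactly the bag size.

## Synthetic cohorts

The generator emulates the *structure* of an annotated H&E cohort, not its
biology: procedural textures (smooth eosin wash for normal, stained stripes
for adenoma, dense hematoxylin speckles for adenocarcinoma) mixed from two
reference stain vectors in OD space on a white background, so stain
estimation, masking and classification-by-texture all have signal; blob
polygons placed on a jittered grid so decision regions never overlap (which
makes the label-flip → agreement calculation exact); reason features nested
inside decision regions with caption lengths drawn as 1 + Poisson(mean − 1)
targeting 4.4 terms per caption, the typical density of fine-grain
colorectal reason captions (terms beyond a subtype's vocabulary become
free-text tags, which the dataset format explicitly permits); bundles over a
configurable fraction of feature groups; and traces whose FOV centers land
inside a lesion with a configurable bias (default 0.8), realizing the
observation that dwell concentrates on difficult regions. Defaults are six
512 px slides, two per class.

All randomness flows from a single seed through named substreams (images,
labels, traces, perturbation), so cohorts are byte-reproducible and each
artifact can be regenerated independently. The second-annotator model flips
each region's class label to a uniformly different class with probability f
(re-drawing subtype and reason labels under the new class to keep lineage
valid) and jitters polygon vertices by uniform integer offsets; its edit log
is ground truth for the audit diff.

What passing tests on these fixtures shows: the measurement machinery is
correct (metrics match independent oracles, planted parameters are
recovered, formats round-trip, pipelines are deterministic). What it does
not show: performance on real histology — no nuclei, no staining artifacts,
no scanner variation, no inter-observer ambiguity beyond the simple flip
model.

## Numerical and design choices

- Point-in-polygon uses area-topology semantics (shapely `covers`), with
  boundary inside; results are invariant under vertex-order reversal.
- Otsu ties break toward the smallest threshold; the uniform histogram
  yields t = 127.
- Macenko constants (I₀ = 255, β = 0.15, α = 1, +1 pseudo-count) are the
  standard published defaults, stated here because the method is otherwise
  only cited.
- Caption-pair matching uses IoU > 0 by default (any overlap can pair);
  the audit diff uses IoU ≥ 0.5 (a real correspondence).
- The acceptance script measures flip-rate recovery over 40 synthetic
  slides of 4 regions each — 160 independent flips — so the binomial
  uncertainty of the recovered agreement is about ±0.024 (1 s.d.).
- Desk-scale problem sizes throughout (512 px slides, 16–64 px grids) keep
  the full suite under half a minute while leaving every code path
  exercised.

## Known limitations

- No pyramidal/vendor slide reader is bundled; plain PNG/TIFF rasters are
  first-class, and real WSIs must be exported at the reference
  magnification first.
- Exactly two raters per comparison (Cohen's κ); no Fleiss' κ or
  significance tests on agreement.
- The BLEU brevity penalty uses the closest-length reference; with a single
  reference (the normal case here) this is just its length.
- Voice media are carried as opaque references; no audio handling.
- DBSCAN is exact and quadratic-ish in neighborhood construction — ample
  for per-slide patch counts, not tuned for multi-slide point clouds at
  once.
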