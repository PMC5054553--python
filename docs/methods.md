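# Methods

This note documents the models and procedures implemented in `ki67hotspot`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Working resolution and field geometry

All analysis runs at an eight-fold reduction of the scanner's full
resolution (0.38895 µm/px under a 20× lens), i.e. ≈ 3.11 µm/px. At this
scale a nucleus is a blurred disk of a few pixels — enough to localize, far
too little for per-nucleus morphometry — and a whole slide fits in memory.
The reference field of view is 1024 × 766 px at full resolution (the
rectangle equivalent in area to a 400× microscope field, ≈ 0.12 mm²); FOV
dimensions at any other resolution are rescaled and rounded to the nearest
integer per axis so that window counts are reproducible. All rectangles are
half-open, coordinates 0-based, and results are mapped back to level-0 pixel
space using the pyramid level's downsample factor.

Pyramidal slides are read through tifffile (SubIFD levels); plain PNG/TIFF
rasters are treated as level 0 with a user-supplied resolution. The level
whose downsample is closest to 8 is auto-selected (config
`working_downsample`).

## Specimen map

Black pixels (R = G = B = 0) mark non-scanned area and are excluded
outright. The B − R difference image separates the violet/pink tissue from
the white glass; Otsu's threshold is computed by exhaustive maximization of
between-class variance on a 256-bin histogram (ties broken toward the first
maximum, threshold reported as the upper edge of the last low-class bin).
Morphological closing with a disk (radius 6 by default; the accepted range
is 5–8), hole filling and removal of components below one-fiftieth of a FOV
follow. The area cut-off is a package choice — small enough that gaps
between tissue lobes survive, large enough that nuclei-scale holes close.

## Texture features and the artifact cascade

Hemorrhage/erythrocytes and tissue folds are removed by texture
classification rather than color thresholds, because their colors overlap
the legitimate stain colors.

**Unser features.** Eight statistics (mean, variance, homogeneity, contrast,
energy, correlation, cluster shade, cluster prominence) computed from
normalized histograms of pixel-pair sums and differences inside a circular
neighborhood Ω. Pairs pool the four unit displacements (0°, 45°, 90°, 135°),
which matches the rotation-robustness aim of the descriptor set. Gray levels
are quantized to 64 bins before histogramming. Two quantization details
matter:

* the grid is anchored at the plane minimum, so an image-wide intensity
  offset changes only the mean (exact offset invariance);
* the step is **fixed per plane identifier** (e.g. 100/64 for the 0–100
  luminance scale, 45000/64 for the composite plane) rather than derived
  from each image's range — otherwise features extracted from a small
  training patch and from a whole slide live in different units and the
  classifier silently fails. Values beyond the top bin saturate.

**Color planes.** Texture is computed on the composite plane
`u·512 + C` — u from CIE Luv (red–green chroma, the axis that separates
hemorrhage from tumour irrespective of how many immunopositive cells are
present) and C from CMYK — plus luminance L. The Luv conversion uses sRGB
companding with D65; the reference white is taken as the sRGB matrix applied
to (1, 1, 1) so the neutral axis maps exactly to u = v = 0. CMYK is the
naive conversion with the K = 1 → C = M = Y = 0 convention.

**Feature selection and SVMs.** Features are ranked by Fisher's linear
discriminant `(µ₁−µ₂)²/(σ₁²+σ₂²+ε)` (population variances, ε = 1e-12) on
the stage-1 problem and the top 8 of 16 are kept. Two Gaussian-kernel SVMs
form a cascade: tumour vs. hemorrhage on all tissue locations, then fold
detection only inside the area stage 1 called tumour (so the fold mask is a
subset of the stage-1 tumour region and the two artifact masks are disjoint
by construction). Hyperparameters come from a 3 × 3 grid (γ at
{0.1, 1, 10} × the median heuristic, C in {0.1, 1, 10}) evaluated on a
seeded 25% held-out split. Training patches are rendered single-class — they
never straddle a class boundary — because margin-region samples blur the
separating hyperplane; prediction uses a smaller neighborhood radius
(10 px) than training (12 px) for the same reason. Predictions on a
stride-10 grid are rasterized back by nearest-grid-point assignment; grid
points whose Ω exits the tissue mask are skipped (treated as tumour), not
padded.

Model persistence uses joblib (the standard mechanism for sklearn
estimators) with a JSON-serializable metadata dict (radii, planes, seed,
validation accuracies) carried inside the archive.

## Vessel-wall elimination

Brown-stained vessel walls would otherwise be segmented as immunopositive
cells. Two detectors run on the Y (CMYK) plane, where brown structures
contrast best, and their union (minus components smaller than a
15-px-diameter disk, 8-connected) is the vessel mask:

* **LBP branch** — wall-likeness = Y intensity gated by edge-like uniform
  rotation-invariant LBP codes (2–6 of 8 bits set at sampling radius 2),
  mean-filtered 5 × 5, thresholded at max(Otsu, 0.18), closed with a disk of
  radius 2.
* **CORF branch** — a simplified contour operator: the on-center
  difference-of-Gaussians (σ = 2 px, center at σ/2) is half-wave rectified
  and five collinear sub-fields spaced 2 px along each of 8 orientations are
  combined by a Gaussian-weighted geometric mean; the response is the
  maximum over orientations, thresholded at max(95th in-tissue quantile,
  0.02). The geometric mean makes the operator respond only where contrast
  persists along a line, which is what distinguishes a wall from a blob.

Both branches keep only elongated components (perimeter²/(4πA) ≥ 2), so
dense nuclei clusters — the very hot-spots being searched for — are not
flagged as vessels. Thin faint walls remain a genuinely hard case: raising
sensitivity starts consuming strongly stained cell clusters, so the
thresholds above favour specificity and are exposed in config. The stage can
be disabled entirely (`--no-vessel-removal`).

## Color-artifact handling

Small near-black artifacts (dust, ink) stretch the luminance range of a
field and destabilize anything computed from it. The cut-off operation clips
the lowest 5% of in-region luminance to the 5th percentile — a universal
value — and an artifact is *flagged* when the gap between the 5th percentile
and the minimum exceeds 10 L-units (uniform content leaves the plane
unchanged and unflagged).

In the pipeline the cut-off serves detection, not preprocessing of the
extraction plane: clipping at the 5th percentile of pixel values would
flatten the immunopositive wells themselves whenever immunopositive pixels
make up less than 5% of the region (at a Ki-67 index of a few percent the
5th percentile sits above the nucleus cores, and extraction collapses). The
operational artifact mask is therefore the genuinely near-black pixels
(L < 15, darker than any credible DAB nucleus), dilated by 2 px to cover
their blur halo, and removed from the analysis region; cell extraction then
runs on the unclipped luminance. The analysis region always satisfies
`analysis = tissue − hemorrhage − fold − vessel − artifact`, asserted per
run.

## Immunopositive-cell extraction

Global thresholds fail across slides because reaction intensity varies;
extended regional extrema adapt to the local background instead.
Immunopositive nuclei are extracted as the **extended regional minima of
depth ≥ h** of the luminance plane inside the analysis mask: the h-minima
reconstruction (erosion reconstruction of `plane + h` under `plane`,
8-connected) fills every depression shallower than h — background texture
and the pale hematoxylin-only nuclei, i.e. the non-immunoreactive region —
and the regional minima of the result are the DAB-dark wells. Two wells
merge when the barrier between them rises less than h above their floors,
which is precisely the behaviour that avoids the over-segmented areas an
extended-maxima formulation produces on merged cells. Each component is
reduced to its integer centroid (center of mass, .5 ties rounded toward
smaller coordinates). The marker count is non-increasing in h; h defaults to
20 on the 0–100 luminance scale, placing the cut between pale blue nuclei
(≈ 15–18 L below background after blur) and DAB-brown nuclei (≈ 40+ below).

Degenerate case: if no well of depth h exists, the reconstruction is flat
and every pixel is formally a regional minimum; a region covering the whole
mask is reported as "no extrema".

Pixels outside the mask are set brighter than everything inside, so minima
cannot leak across the mask boundary and the bright blurred glass halo at
the tissue edge is irrelevant (it is never a minimum — the reason the minima
formulation was chosen over recovering a "background plateau" of maxima,
which that halo fragments).

**Immunonegative pass.** The full-resolution counting algorithm that the
original workflow applies inside each selected field is out of scope here;
to still report a per-field Ki-67 index the package runs the same transform
a second time on a hematoxylin-dominant plane — the hematoxylin channel of
the Ruifrok–Johnston stain separation (`rgb2hed`), rescaled to a descending
0–100-like range (`100 − 300·OD`) — with h = 8. Components overlapping the
already-found positive region are dropped so no nucleus is counted twice.
The per-field index is `100 · pos/(pos + neg)` over markers inside the
field.

## Density map and gradual extinction

The density map counts markers in every candidate FOV window (integral
images; stride of half a FOV per axis; candidates with tumour coverage
below 0.5 are invalid). Selection is greedy with the penalty

    penalty = 1 − ρ · Σᵢ dᵢ^−0.5,   dᵢ = Euclidean distance to selected
                                         field i, in FOV widths

clamped below at zero and applied multiplicatively to the raw count. The
candidate with the maximal penalized score wins each round (ties: higher raw
count, then row-major grid order — fully deterministic); selection stops at
the field budget or when no candidate with a positive raw count remains.
Score-zero candidates remain selectable — with many strong regions the
penalty sum saturates well before 20 fields, and the raw-count tie-break
then orders the remainder. With ρ = 0 the algorithm reduces to plain greedy
top-k.

Parameter choices that the source material leaves open, fixed here:
ρ = 0.3; distances in FOV widths (pixel units would make ρ
resolution-dependent); the penalty read as a multiplicative factor; no hard
overlap exclusion (the penalty discourages it). Field budget:
`⌊area · 20/500⌋` below 500 FOV-equivalents of analysis area, else 20. For
low-compactness specimens ρ is scaled by `min(1, area/100 FOV, r_eff/6)`,
where `r_eff` is the largest inscribed-circle radius of the analysis mask
(distance transform) measured in radii of a circle with one FOV's area.

## Agreement statistics

Spearman's rho (average ranks for ties, large-sample t approximation for
the p-value; errors on constant series) and Bland-Altman analysis:
differences a − b against means (a + b)/2, bias ± 1.96·SD limits. Because
Ki-67 indices pile up near zero while the clinically relevant grade
boundaries are low, the log panel uses log₁₀(value + 0.1); the 0.1 offset
keeps index-0 cases representable and is configurable.

## Synthetic slides: what they emulate, and what passing means

The generator renders, at working resolution: pale violet tissue (one or
more ellipses) with mild per-pixel noise (σ 2.5 RGB) and smooth mottling;
anti-aliased nuclei disks of radius 2 px — DAB brown (91, 59, 29) and pale
hematoxylin blue (150, 155, 205), placed by rejection sampling with a
minimum separation and an explicit achieved-count report; optional dense
immunopositive clusters; hemorrhage patches (erythrocyte-red with fine
speckle); fold bands (darkened ×0.62 with crushed high-variance texture);
thin brown vessel-wall polylines; near-black artifact pixel clusters; a
final Gaussian blur of σ 0.8 px mimicking how few-pixel nuclei appear at
eight-fold reduction. Identical spec + seed give bit-identical images and
ground truth. The noise amplitudes were set so that the tissue-background
luminance variation stays below h while pale nuclei remain separable on the
hematoxylin plane — the regime the depth-based extraction assumes of real
slides.

What the generator does **not** emulate: scanner noise and compression,
stain batch variation, out-of-focus regions, nuclear pleomorphism,
overlapping/touching nuclei at high density, partial-thickness folds, and
the continuous color gradations of real hemorrhage margins. Passing tests
therefore demonstrate that each stage implements its specified computation
correctly and that the stages compose (artifact regions are excluded, dense
clusters win, diversity is enforced, runs are deterministic) — not that the
trained cascade or the fixed thresholds transfer to real slides, which
requires calibration on scanner data.

## Numerical choices and degenerate inputs

* Otsu: 256 bins over the data range; constant input is an error.
* Quantization saturates above 64 steps; constant planes map to bin 0.
* Reconstruction and component labelling are 8-connected throughout.
* Centroid ties (.5) round toward smaller coordinates.
* Empty tissue → empty masks and an empty field list with a warning, not an
  error; an empty candidate set warns likewise.
* The two independent artifact detectors may run in threads; their masks
  are combined by set union, so scheduling cannot change the result.
* All randomness (generator, SVM grid split) flows from explicit seeds;
  reruns are bit-identical.

## Problem sizes used by the test suite and acceptance run

Unit fixtures are 512² px slides (≈ 145k px tissue, ≈ 1200 nuclei);
end-to-end fixtures 1200 × 900 px; the large-specimen scenario is
4000 × 2400 px with a tissue ellipse of ≈ 546 FOV-equivalents, 43 dense
clusters of 55 cells each over 2000 scattered positive and 12000 negative
cells. These sizes keep a full suite run and the acceptance script in the
minutes range on a single CPU while exercising every stage at realistic
nuclear density.

## Known limitations

* Small or faint vessel walls below the elongation/response thresholds
  survive elimination; the trade-off constant is exposed, not hidden.
* The cascade is trained on rendered textures by default; real deployments
  should train on annotated patches (`ki67hotspot train`).
* The per-field Ki-67 index uses working-resolution marker counts, a
  substitute for full-resolution counting inside selected fields.
* Candidate grids are axis-aligned with half-FOV stride; a true local
  maximum straddling four windows can land slightly off-center.
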