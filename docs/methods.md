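# Methods

This note documents the models, parameter choices and numerical conventions
behind `hybridcyc`, and what the synthetic-data generator does and does not
emulate.

## The synthetic forward model

Each specimen is a population of cells of four classes — epithelial,
leukocyte, stromal, and hybrid — drawn i.i.d. with configured fractions.
Per-cell marker intensities are **log-normal** around a class-level (or, for
hybrids, subpopulation-level) log-mean with a common log-scale `log_sd`.
The log-normal is a standard model for multiplicative microscopy noise; no
distributional form is dictated by the assay itself, so the family and its
parameters are package choices, exposed in `PopulationConfig`.

Default intensity levels (arbitrary fluorescence units): background 50,
positively expressed marker 500 (10× contrast), DAPI 200, round-0
autofluorescence 20 with a 5× multiplier for the configured fraction
(default 2%) of autofluorescent cells. Default `log_sd` = 0.25. Class
signatures: epithelial cells express the epithelial cocktail
(ECAD/EpCAM/panCK) and cytokeratins; leukocytes express CD45; stromal cells
express αSMA and VIM; hybrids co-express CD45 and the epithelial cocktail.
Hybrid subpopulations add one elevated pair of phenotyping markers each;
disjoint pairs give near-equidistant mean vectors, which matters for elbow
behavior (below).

Rendering draws each cell as a circular nucleus (radius 4 px) inside a
circular cell body (radius 9 px) on a dark background: DAPI and
nucleus-compartment markers paint the nucleus, all other markers paint the
whole cell body uniformly, so every compartment mean of the noise-free
render equals the assigned intensity exactly — the identity the extraction
tests rely on. Cells are placed by dart-throwing Poisson-disk sampling with
minimum spacing 2× cell radius and a one-radius border margin; placement
failure raises rather than silently overlapping cells. Per-round rigid
drifts, an optional Gaussian PSF, Gaussian or Poisson noise, and a
`residual_signal_fraction` (incomplete signal erasure leaking the previous
round's marker into the same fluorophore channel of the next round) complete
the forward model. Coordinates are 0-based `(row, col) = (y, x)` with pixel
centers at integers.

**What the generator does not emulate:** tissue texture and autofluorescence
structure, non-circular morphology, 3-D optics, staining chemistry kinetics,
spectral bleed-through, and segmentation-induced doublets. Passing tests
therefore demonstrate the correctness of the analysis logic under a clean,
known forward model — not robustness to every artifact of real slides.

## Registration

"Feature-based" alignment is realized as **phase correlation** with
upsampled subpixel refinement (upsample factor 50) on the DAPI channel,
a deterministic, parameter-light choice. The model is translation-only;
slide-scan drift has no stated rotation component and rotation is out of
scope. Round 1 is the reference; one transform per round is applied to all
of its channels; out-of-frame pixels are zero-filled. Residual error on
integer shifts is zero to machine precision and well under the 0.5 px
contract on subpixel shifts.

## Segmentation

A classical stand-in with the same output contract as a deep-learning
segmenter: three aligned label masks with one consecutive label set.
Nuclei: Otsu threshold (configurable absolute threshold), Euclidean
distance transform smoothed with σ = 1 px, peak seeds with minimum
separation 3 px, watershed, then a size filter (default min area 20 px²).
Whole cells: `expand_labels` up to `max_expansion` (default 6 px) from the
nucleus; when a membrane channel is supplied, expansion is confined to the
membrane-positive footprint so cells stop at their stained body's edge.
Cytoplasm is the per-label set difference; a nucleus-filling cell yields an
empty cytoplasm (flagged, not an error). The single-cell table schema is
segmenter-agnostic so externally produced label TIFFs can be imported.

## QC rules

* **Edge/artifact exclusion**: cells whose centroid falls in a supplied
  binary exclusion region are dropped and logged.
* **Autofluorescence**: cells whose round-0 whole-cell mean strictly
  exceeds the per-specimen 99th percentile (or an absolute cutoff) are
  removed. The quantile rule is scale-free across specimens; the applied
  cutoff is recorded in the log. Re-applying the filter with the recorded
  cutoff is exactly idempotent; re-deriving a quantile on an
  already-filtered table would necessarily shift it, so idempotence is
  defined with respect to the recorded cutoff.
* **Poor segmentation**: area bounds and a solidity bound (default 0.8)
  remove implausible labels; cells touching a brighter neighbor's 1-px
  dilated mask are flagged (`touches_brighter_neighbor`) for optional
  exclusion rather than dropped.

Every removal carries a reason code; `rows_out = rows_in − removals` holds
by construction.

## Signal-to-background validation

Tissue mode uses a single representative ROI per staining condition and
divides the mean intensity of that condition's positive cells by the mean
of the imaging-strand-only control. Positive cells come from a numeric
rule (strictly above control mean + 3·SD) or from an anticipated-pattern
annotation; the synthetic validation specimens carry that annotation, which
is also the import path for manual annotations. Blood mode uses the
two-population model (cancer cells spiked into PBMCs, distinguished by an
Otsu split of **log** areas — sizes are multiplicative, and a raw-scale
split is biased toward the broader large-cell class): per ROI,
positive-population mean over negative-population mean, averaged over three
ROIs. Markers staining both populations are normalized to strand-only
cells instead. All ratios are invariant under global intensity rescaling.

## Gating

Thresholds are derived from an unstained control; the default rule is
**mean + 3·SD** per marker on whole-cell means, with quantile and absolute
alternatives. Positivity is a strict inequality; a missing intensity is a
negative call and is flagged. Thresholds are per-specimen-batch by default
(the control is matched to the staining batch); the rule and k are
configuration. A hybrid is CD45⁺ with a non-empty positive subset of
{ECAD, EpCAM, panCK}; the subset is recorded for provenance. Percentages
always use the post-QC cell count as denominator.

## Phenotyping

Z-scoring uses the population SD (ddof = 0) per marker over a pooled
tissue + blood hybrid scope, so both compartments share one scale;
zero-variance columns become zeros and are flagged. Missing values
(empty-cytoplasm markers) are imputed with the column median by default or
rejected under `missing="error"`. Each marker enters the matrix from its
configured phenotyping compartment (whole cell for all markers except
nuclear Ki67).

k-means is Lloyd's algorithm from k-means++ starts, best of 10 restarts by
WCSS, seeded for reproducibility; clustering runs separately per
compartment (distinct T- and B-numbered subpopulations), both scopes
configurable. The elbow rule selects the interior k maximizing the second
difference `WCSS(k−1) − 2·WCSS(k) + WCSS(k+1)` over a consecutive range
(default 1..8), ties to the smallest k. Two practical notes established
during design:

* The maximum-second-difference rule finds the *largest kink*; it recovers
  the true k reliably when the planted cluster centers are near-equidistant
  (a regular simplex), and can prefer a smaller k under strongly
  hierarchical geometries (e.g. four blobs at square corners). The
  generator's disjoint marker-pair subpopulations produce the simplex-like
  geometry.
* Pooled z-scoring shrinks the scale of markers that vary widely in the
  pooled set and inflates rare ones; subpopulation designs whose markers
  have comparable pooled prevalence keep cluster separations balanced.

Cluster labels T1..Tk / B1..Bk are assigned by descending cluster size
(ties: ascending internal id), making labeling deterministic. Profiles are
per-cluster mean z-vectors. For the tiny-n oracle check (n ≤ 8, k = 2
against exhaustive partition enumeration) 50 restarts are used: with 10
restarts a rare instance can stop in a local Lloyd minimum, and the check's
purpose is agreement with the global optimum.

## Concordance

Pearson r between every (tissue, blood) profile pair over the marker
dimension, computed on the stored z-scored profiles without
re-standardization. A constant profile yields a missing entry (flagged),
not an exception. "Conserved" pairs are those with r ≥ 0.7 — there is no
canonical cutoff for this, so the full matrix is always written and the
cutoff is configuration.

## The rare-population study design

The matched synthetic patient used by `scripts/acceptance.py` and the
end-to-end test has tissue n = 50,000 at hybrid fraction 0.008 and blood
n = 20,000 at 0.002, four tissue and three blood hybrid subpopulations with
the elevated VIM/αSMA (mesenchymal) phenotype planted in both compartments
at 1.6× the other subpopulations' elevation. For gated counts to equal
ground truth *exactly*, the probability of any background exceedance across
~7·10⁴ cells × 4 gating markers must be ≪ 1. For a log-normal background,
a mean + k·SD cutoff sits at ≈ k log-sigmas only in the small-σ limit (at
k = 3 the exceedance is ~0.3% regardless of σ — hundreds of false calls at
this scale), so this study uses `log_sd` = 0.08 with a mean + 7·SD gate,
putting the cutoff ≈ 5.6 log-sigmas out (exceedance ~10⁻⁸ per draw,
expected miscalls ≈ 0.002 per run). This is the study's definition of
"separable intensities"; the package-wide default gate remains mean + 3·SD.

## Problem sizes

Test and acceptance runs use desk-scale problems chosen to exercise each
contract: 50–500 cells for imaging stages (up to 1150² px frames),
50,000 + 20,000-cell tables for the rare-population study, 100 random
50×14 matrices for normalization invariants, 20-seed replicates for elbow
and ARI checks, and 50 random instances for the exhaustive k-means oracle.

## Known limitations

* Circular-geometry rendering means segmentation performance on real,
  irregular cells is not demonstrated here.
* No spillover/bleed-through compensation and no background subtraction
  beyond round-0 filtering.
* The elbow rule's known preference for large kinks (above) means k can be
  under-selected on strongly hierarchical data; a fixed k is accepted
  everywhere a selection is.
* Biological-fusion hybrids vs segmentation doublets cannot be
  distinguished computationally; doublets are not simulated.
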