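# Methods

## The model

DESI-MSI rasters a tissue section into a grid of pixels, each carrying a
centroided mass spectrum.  The analysis target here is a tissue with a
*linear* developmental axis: positions along one image axis (rows, with
row 0 at the root tip by convention) correspond to successive developmental
states.  The pipeline makes three modelling commitments:

* **Consensus channels.** The instrument reports the same chemical species
  at slightly different m/z in different pixels (relative jitter at the
  ppm scale).  All per-pixel peaks are therefore harmonized onto a
  consensus set of centers found on the region-wide *pseudobulk* spectrum
  (the sum of every peak in every sample pixel).  A center is an entry
  whose intensity is strictly maximal among all entries within
  ±(center·ppm/10⁶); equal-intensity ties resolve toward lower m/z.  This
  guarantees any two centers are separated by more than the window
  (measured at the lower center).
* **Background as an in-acquisition control.** Pixels outside the sample
  mask see the same solvent, substrate and electronic background as the
  sample; a channel is biological signal only if its sample intensity
  exceeds the background by a minimum fold.
* **One profile per channel.** A channel's spatial pattern is summarised
  by a maximum projection across the lateral axis.  The maximum (rather
  than the mean) is robust to the tissue occupying only part of each row
  and to cell-layer-restricted signals; the cost is sensitivity to single
  hot pixels, which the optional hot-pixel filter and the median smoothing
  of linescans both mitigate.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `window_ppm` | 2.5 | ppm | consensus window half-width, multiplicative about each center |
| `min_fold` | 1.5 | — | strict sample/background per-pixel mean enrichment threshold |
| `median_filter_width` | 3 | entries | running median on the pseudobulk before peak picking |
| `linescan filter_width` | 10 | pixels | running median on each normalized linescan |
| `pool tol` | 0.001 | Th | absolute tolerance for replicate pooling and group comparison |
| `annotate ppm_tol` | 5 | ppm | feature-to-theoretical-mass matching bound |
| `hot_pixel_k` | 5 | — | MAD multiplier; hot-pixel suppression is off by default |
| `k` (clusters) | user | — | always chosen by the user from the dendrogram |

2.5 ppm, 1.5-fold, 10-pixel smoothing, 0.001 Th pooling and ±5 ppm
annotation are the standard analysis settings for Orbitrap-class DESI data
of this kind; all are exposed as CLI flags because real studies vary them
(typically widening to 5 ppm or relaxing the fold to 1.1 to trade
stringency for feature count — both directions only ever grow the kept
set, a monotonicity the test suite asserts).

## Numerical and design choices

* **Where the median filter acts.**  The summed-spectrum median filter is
  used for consensus-center *detection* only.  Enrichment statistics
  (window sums on both the sample and background side) are computed on the
  raw pseudobulk.  Adjacent entries of the pseudobulk are jittered draws
  from different pixels, so a median over them is not mass-preserving: for
  channels whose intensity distribution across pixels is strongly skewed
  (tip-enriched patterns: a few bright rows, many near-zero rows) the
  filtered window sum underestimates total signal severalfold and would
  push genuinely enriched channels below the fold threshold.  Raw sums
  keep the measured fold equal to the true per-pixel mean ratio.
* **Per-pixel means for the fold.**  Sample and background window sums are
  divided by their region pixel counts before comparison, so unequal mask
  and background areas do not bias the fold (`background_normalize="sum"`
  provides the raw-sum comparison for cross-checking other
  implementations).  The threshold is a strict inequality: a fold of
  exactly `min_fold` is removed.  Zero background with positive sample is
  kept, with the fold recorded as infinity.
* **Assignment.**  Each observed entry within the window of at least one
  kept center is added to the nearest center (distance ties to the lower
  m/z center); out-of-window entries are dropped.  Assignment therefore
  conserves in-window intensity exactly, per pixel (asserted in tests).
* **Sparsity filter.**  Binary erosion of the per-channel presence image
  with a full 3×3 structuring element (8-connectivity), borders treated as
  zero; a channel is removed when the erosion is empty, i.e. when no
  nonzero pixel has a fully nonzero 8-neighbourhood.  Removed channels are
  retained in a separate list and stay exportable.
* **Median filters.**  Running medians use truncated windows at the
  sequence ends.  Even widths put the extra element on the leading
  (lower-index) side and take the lower median, so outputs are always
  drawn from the input values.
* **Normalization order.**  Linescans are normalized to max 1 first, then
  smoothed; no re-normalization afterwards, so a displayed maximum below 1
  indicates the peak was a narrow spike the median removed.
* **Clustering.**  Ward linkage on Euclidean distances between smoothed
  normalized linescans (`scipy.cluster.hierarchy.linkage`), cut to exactly
  `k` clusters with `cut_tree`; cluster ids are relabeled 1..k in order of
  first appearance along ascending channel m/z, making output deterministic
  and permutation-equivariant.  The tool prints the largest merge-height
  gap as a suggested `k` but never auto-selects: cluster count is a
  judgment made on the dendrogram.
* **Pooling rule.**  Greedy anchor-at-smallest grouping: a group opens at
  the smallest unassigned value v and absorbs every value ≤ v + tol, so a
  chain of values each within tol of its neighbour splits after the anchor
  window.  A transitive (single-linkage) mode is provided for comparison
  with implementations that chain; outputs are labeled with the mode.
  Group representatives are member means, reported to 4 decimals.
  Cross-group matching is best-pair-first greedy and one-to-one, so a
  feature is never counted as shared twice.
* **Atomic masses.**  Monoisotopic masses for C/H/N/O/P/S are hard-coded
  IUPAC values; [M−H]⁻ subtracts one proton mass (1.00727646 u).  The
  electron mass is folded into that convention — a sub-ppm effect at these
  masses, well inside the 5 ppm matching bound.
* **Auto-masking.**  Otsu's criterion evaluated exactly on the sorted TIC
  values (no histogram binning, so the threshold cannot fall inside an
  occupied bin), then the largest connected component.  Intended for
  synthetic and quick-look data; curated masks drawn on the sum projection
  remain the recommended input for real sections, and a supplied mask
  always bypasses auto-masking.

## The synthetic generator

`dimple.synthetic.generate_root_msi` emulates the data regimes the pipeline
must handle, with full ground truth: a tapering root-shaped mask
(narrow at the tip row, widening toward the mature end); planted channels
with Gaussian/logistic axial templates (tip-enriched, transition-zone,
bimodal, mature) plus uniform and lateral-stripe options; per-channel
sample-over-background folds drawn from 3–8; background-only channels 4×
stronger outside the mask; sparse channels present only at isolated,
mutually non-adjacent pixels; broadband noise entries (Poisson count per
pixel, uniform m/z kept ≥25 ppm from planted channels); optional hot
pixels (whole-spectrum ×30).  Intensity noise is multiplicative lognormal
(MSI intensities are positive and right-skewed), σ = 0.25 by default; m/z
jitter is Gaussian with σ = 1 ppm per entry.  The default raster is
100×24 pixels with 5 channels per pattern class, 5 background-only and 3
sparse channels — small enough that a full pipeline run takes about a
second, large enough that every filter has real work to do.

What it does **not** emulate: isotopologue and adduct structure, matrix
clusters, correlated (per-scan) mass drift, profile-mode peak shapes, and
intensity gradients from source instability.  Passing tests on this
generator therefore demonstrate the pipeline's logic — harmonization,
filtering, projection, clustering — not robustness to every artifact of
real acquisitions.

## Known limitations

* With 1 ppm per-entry jitter, a channel's pseudobulk cluster spans about
  ±3 ppm — wider than the 2.5 ppm window — so a secondary local maximum
  more than one window from the primary center can occasionally arise and,
  if the per-pixel assignments split between the two centers in a
  spatially dense way, survive the erosion filter as a duplicate channel.
  Across random seeds roughly a quarter of simulated runs keep one or two
  such duplicates (always within ~4 ppm of a genuine channel); the
  replicate-pooling step merges them back at the 0.001 Th tolerance.
  Smaller jitter or a wider window removes the effect.
* The background model assumes background pixels exist inside the raster;
  a mask covering the whole image is rejected.
* Consensus centers inherit the m/z of a single pseudobulk entry, so their
  accuracy is limited by the jitter of that entry (~1 ppm standard error
  at default settings) rather than by the window width.
* The per-row netCDF reader targets the generic ANDI-MS layout
  (`mass_values`/`intensity_values`/`scan_index`); converter-specific
  variants may need re-export through imzML.
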