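# Methods

`organoquant` packages the bespoke quantifications used around cerebral-organoid
assays: fluorescence-image quantification of lipid droplets and marker burden,
single-cell RNA-seq cell-level quality control and composition analysis,
region-identity signature scoring, differential-expression filtering, and
relative qPCR quantification by 2^-ddCt. Every stage is paired with a synthetic
generator that plants known ground truth, so the whole chain is testable
end-to-end without any external data.

## Droplet imaging pipeline

Lipid droplets in a neutral-lipid stain (LipidTOX) appear as bright, nearly
circular puncta over a dim background. The pipeline is:

1. **Constant-threshold binarization.** Foreground where pixel ≥ threshold.
   Thresholds are per-channel constants in the image's own intensity units;
   the shipped defaults (DAPI 250, LIPIDTOX/FILIPIN 350, MARKER 250) sit
   roughly halfway between the synthetic generator's background (100) and
   object amplitudes (400–600) and must be re-tuned for real acquisitions.
   The comparison is ≥, so a pixel exactly at threshold is foreground.
2. **Area filter.** 8-connected components with pixel area outside
   `[min_area_px2, max_area_px2]` (defaults 9–2500 px²) are removed. The lower
   bound rejects hot pixels; the upper bound rejects stain pools and debris.
3. **Circular Hough transform.** For each integer radius r in
   `[r_min, r_max]` (defaults 2–10 px), every boundary pixel of the mask
   votes for all candidate centers at distance r. Accumulator support is
   normalised by the discrete perimeter length, so a perfect disk scores ≈ 1.
   Candidates above `1 − sensitivity` (default sensitivity 0.85) survive;
   greedy non-maximum suppression enforces a minimum center separation of
   `r_min`. Center and radius are refined to subpixel precision by
   score-weighted centroids over the 3×3 accumulator neighbourhood and the
   adjacent radius planes. This is a from-scratch vote accumulator, not a
   re-implementation of any particular vendor tool; its contract is the
   detection-quality bound checked in the tests (≤ 1 px deviation from an
   exhaustive template-search oracle for clean disks), not bit compatibility.
4. **Circular-feature selection.** Hough accumulators produce low-score
   satellite candidates along the rim of every strong disk. Candidates are
   visited in descending score order and dropped when their circle intersects
   an already-kept circle (center distance below the sum of radii). The cost
   of this rule is that two droplets whose physical circles interpenetrate
   are reported as a single feature; at the non-overlapping droplet densities
   the generator emulates this trade-off is free, and it removes essentially
   all false positives.
5. **Watershed splitting.** A marker-seeded watershed on the negative
   Euclidean distance transform of the mask, restricted to foreground, with
   one marker per selected circle center (centers falling on background are
   dropped with a warning). Each labeled region is one droplet; areas,
   equivalent diameters and mean intensities are measured per region.

**Per-cell normalisation.** Droplet counts are divided by the DAPI nucleus
count of the same field. Nuclei are segmented by the same threshold + area
filter route, then split at the local maxima of the distance transform
(minimum peak separation 5 px by default) before counting. When a field has
no detected nucleus the per-cell count is NaN rather than zero.

**Intensity and area fraction.** Filipin (free cholesterol) intensity is the
whole-field arithmetic mean — segmentation-free, matching how such stains are
usually reported; a per-mask variant can be built from `binarize` if needed.
Immunomarker burden is |marker ≥ t_marker| / |DAPI ≥ t_dapi| in the same
field. Per-field values from one coverslip are averaged with
`field_average` (3 fields per coverslip by default), and the coverslip is
the replicate unit passed to the statistics.

### Watershed validity domain

For two overlapping equal disks of radius r at center separation s, the
distance-transform saddle at the neck has relief `r − sqrt(r² − (s/2)²)`.
When that relief falls below about one pixel the lattice distance transform
cannot represent the split and the watershed boundary wanders; with unequal
radii, the distance ridge is additionally not the perpendicular bisector, so
a nearest-marker comparison is only a valid reference for equal-radius
pairs. The partition tests therefore exercise equal-radius pairs with at
least 1.25 px of saddle relief; outside that regime the region count and
foreground coverage still hold exactly, but the exact boundary placement is
resolution-limited.

## Synthetic fluorescence fields

The generator plants circular droplets and nuclei with centers rejection-
sampled so each disk lies fully inside the field, and (by default) no two
disks intersect (separation at least r_i + r_j + 1); a disk that cannot be
placed after 500 attempts is skipped and logged, so the returned truth table
always lists exactly what is in the image. Droplet count is a Poisson draw
per nucleus with mean `droplets_per_cell_mean`. Pixels are
`background + amplitude·disk + N(0, noise_sd)` clipped at zero. Defaults —
256×256 px, 8 nuclei, 4 droplets/cell, radii 3–8 px, amplitude 600 over
background 100 with noise sd 20 — give the high-contrast punctate appearance
of a well-exposed confocal field. The generator does not model point-spread
blur, uneven illumination, or camera shot noise, so passing recovery tests
demonstrate correctness of the geometry pipeline, not robustness to real
optics; thresholds on real data must be set per experiment.

## Single-cell quantification

**QC metrics and filter.** Per cell: total UMI (column sum), detected genes
(nonzero count), mitochondrial percent (100 × mito counts / total; genes
matching the `MT-` symbol-prefix predicate by default). A cell is discarded
iff total UMI > 25,000, total UMI < 5,000, detected genes < 200, or
mitochondrial percent > 12 — all strict inequalities, so boundary-equal
cells are kept. The filter is idempotent by construction.

**Cellular detection rate.** The z-scaled number of detected genes per cell
(sample sd, n−1), used downstream as a covariate in hurdle-model
differential expression; the hurdle model itself is out of scope here.

**Composition.** Per-sample cell-type fractions (counts over the sample's
cell total; rows sum to 1), compared between two genotype groups per cell
type with a two-sided unpaired equal-variance Student's t test on the
per-sample fractions. The sample — a pooled dissociate of three organoids —
is the replicate unit, not the cell. Cell-type labels are an input from any
clustering; clustering is deliberately not part of this package.

**Signature scores.** Counts are normalised per cell to 10,000, log1p-
transformed, each signature gene z-scored across cells (zero-variance genes
dropped), and the score is the mean z over retained genes. This is the
simplest score consistent with "mean standardized expression of the set";
a control-bin module score (Seurat `AddModuleScore` style) differs mainly by
background subtraction and was not adopted as the default because it adds a
binning heuristic without changing the rank ordering the score is used for.
The cortical and hippocampal identity sets ship as data (13 symbols each).

**DEG filtering.** Records are (gene, log2FC, raw p). Bonferroni correction
is `min(1, p·n_tests)` with `n_tests` the number of genes tested in that
comparison; a gene is significant iff corrected p < 0.05 and |log2FC| >
0.25, both strict. The significant set is monotonically non-increasing in
`n_tests`.

**Two-group test.** A per-gene two-sided Wilcoxon rank-sum on log-normalised
expression, normal approximation with tie correction, implemented directly
so the degenerate all-tied case returns statistic 0 and p = 1 instead of
NaN. It exists to drive the synthetic DEG pipeline; it is not a stand-in
recommendation over a hurdle model for real data. The reported log2 fold
change is `log2((mean CP10K + 1) / (mean CP10K + 1))` between groups.

## Synthetic count matrices

Counts are negative binomial with mean m and dispersion α (variance
m + αm²; defaults m = 2, α = 0.1 — deep-ish coverage with moderate
overdispersion). A dedicated `MT-` block receives the type's configured
share of each cell's expected total, and planted DE genes have their mean
multiplied by 2^log2FC in the affected type. The generator draws each
gene independently: no gene–gene correlation, library-size variation beyond
NB noise, doublets or ambient RNA; recovery results therefore validate the
filter logic, not performance on real droplet data.

## qPCR quantification

Technical replicates are averaged on the Ct scale; ΔCt = Ct(gene) −
Ct(ACTB) per sample; ΔΔCt subtracts the arithmetic-mean ΔCt of the control
group for that gene; fold change = 2^−ΔΔCt with amplification efficiency
fixed at 2 (no standard-curve correction). By construction the control
group's geometric mean fold change is exactly 1. Group summaries are mean ±
SEM (sample sd / √n) with a two-sided unpaired equal-variance Student's t
test (df = n₁ + n₂ − 2); constant identical groups return t = 0, p = 1
rather than NaN. The Ct generator lowers the treated-group mean Ct by
log2(fold change) — one cycle per doubling of template — and adds Gaussian
cycle noise per technical measurement (default 0.1 cycles, 6 biological
samples per group, duplicate wells).

## Determinism and problem sizes

Every generator is a pure function of its config including the seed
(`numpy.random.default_rng`). Pipeline CSV outputs are written in sorted
key order, so a fixed-seed run is byte-reproducible and checksum-comparable.
The shipped verification workloads use 50 simulated fields for detection
recall, 260 disks for the Hough/oracle comparison, 200 overlapping-disk
pairs for the watershed partition, 10,000 cells for the QC filter oracle,
1,000 genes × 400 cells for DE recovery, and 200 seeds for the ddCt bias
estimate — sizes chosen so each estimate is stable to well within the
tolerance it is checked against.

## Known limitations

- No optics model in the image simulator (no PSF, no illumination field),
  and no z-stacks; the imaging pipeline is strictly 2-D.
- Default thresholds are calibrated to the synthetic generator's intensity
  scale and are configuration, not recommendations, for real images.
- Overlapping droplets are merged into one feature by the circular-feature
  selection rule (see above).
- The rank-sum DE test ignores the cellular detection rate covariate; CDR
  is computed and exported for use by an external hurdle model.
- Single-reference-gene ddCt with fixed efficiency 2; no multi-reference
  normalisation or primer-efficiency estimation.
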