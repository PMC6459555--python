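# Methods

This note documents the models, procedures, parameter choices, and known
limitations of `autoflux`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
external measurements.

## 1. Cell masking from an empty-field background model

Foreground ("cell") voxels are identified against a Gaussian background
model calibrated on a green-channel z-stack of an empty field. Both the
calibration stack and sample stacks are smoothed with the same Gaussian
kernel (default sigma (1, 2, 2) voxels in (z, y, x); the kernel itself is a
free choice — a mild anisotropic blur that suppresses shot noise without
erasing cell-scale structure). The model is Normal(mu, sigma) with mu, sigma
the sample mean and SD of the smoothed empty-field intensities (method of
moments, which for a Gaussian is also the MLE). A median/MAD option exists
for calibration fields suspected to contain debris, but is off by default
because the calibration field is cell-free by construction.

A voxel joins the mask when its upper-tail background probability is below
alpha = 1e-5. The test is one-sided and upper because fluorescence
foreground is strictly brighter than empty background. Per-voxel p-value
thresholding is mathematically identical to the closed-form cutoff

    I > mu + z_(1-alpha) * sigma,

and the implementation uses the cutoff; the equivalence is asserted by an
oracle test on 1e6 random voxels.

Mask cleanup:

* **Speck removal.** 3D connected components (26-connectivity) smaller
  than a volume gate are deleted. The gate is *strict*: a component of
  exactly the gate volume survives. The library default gate is 100,000
  voxels, sized for full-resolution confocal acquisitions; the bundled
  synthetic scale uses 2,000 voxels (a synthetic cell body is ~15,000
  voxels), which is the `RunConfig` default.
* **Out-of-focus plane filtering.** Each plane gets a three-feature
  vector: masked-voxel fraction, mean in-mask intensity, mean gradient
  magnitude. Two classifiers are available: a standardized-feature linear
  max-margin classifier (`LinearSVC`) trained on labeled synthetic planes,
  and a rule-based fallback that drops planes whose masked fraction is
  below 1e-3. The fallback is the pipeline default because it needs no
  training corpus; the trained classifier reaches >= 95% plane accuracy on
  held-out synthetic scenes in the test suite. The plane filter used in the
  original analyses this package descends from is specified only in prior
  literature, so our classifier is a declared replacement validated on
  synthetic ground truth, not a reproduction.

## 2. Nucleus and cell segmentation

**Nuclei** come from the DAPI channel. Each z-slice is thresholded at

    mode + t * (max - mode),   t = 0.5 by default,

with the mode estimated from a 256-bin histogram. This per-slice *relative*
threshold is scale-free and robust to axial intensity falloff; a blank
slice (max ≈ mode) contributes no foreground. The stacked binary volume is
split into objects by watershed on the inverted Euclidean distance
transform, seeded at distance-transform peaks at least `min_peak_distance`
(default 6) voxels apart; objects below `min_volume` (default 500) voxels
are discarded. The relative-threshold formula and watershed flavor are this
package's own definitions, validated against generator ground truth.

**Cells** are carved out of the cell mask by seeded watershed from the
nucleus labels: multi-source flooding at constant altitude, which
partitions the mask by geodesic distance to the nearest seed (ties resolved
by the deterministic flooding order, so runs are reproducible). Cell labels
equal their seed nucleus labels. Masked voxels unreachable from any seed
are reported, not silently assigned.

Post-processing: each cell is independently eroded by a 6-connected ball
(default radius 2 in-plane, 0 in z — anisotropy-aware, since the p-value
mask mostly over-extends laterally through the blurred cell edge), and
cells touching the lateral (row/column) field boundary are removed.
z-contact does not disqualify a cell: confocal stacks routinely truncate
cells axially, and "edge of the field" is a lateral notion. Per-label
erosion also shrinks shared boundaries, so labels can never merge; a cell
annihilated by erosion is dropped with a logged warning.

## 3. Puncta segmentation and object-based colocalization

Punctae (autophagosomal structures: diffraction-limited spots) are
segmented per channel by slice-wise Canny edge detection; closed contours
are filled per plane, planes are stacked, and 3D 26-connected components
become punctum candidates. Candidates outside a [4, 10,000]-voxel volume
gate (single-voxel noise; merged blobs) are discarded, and by default only
candidates whose centroid lies inside a segmented cell are retained.
Running Canny in 2D per plane and connecting in 3D afterwards avoids
anisotropic 3D gradients and matches the slice-wise style of segmentation
this pipeline descends from; a 3D-gradient mode is out of scope.

Canny thresholds are intentionally data-dependent ("empirically
determined"): the low/high thresholds can be given as quantiles of the
per-plane gradient magnitude (0.90/0.99 when no calibration exists) or as
absolute gradient values. For the bundled synthetic conditions the
absolute values 100/180 were determined empirically: they sit well above
the gradient of the diffuse cell-body edge (so the cell outline is never
traced and filled — which would swallow the punctae inside it) and well
below the spot-edge gradient. These are the `RunConfig` defaults.

Each punctum is assigned to the cell owning the plurality of its voxels
(ties to the smaller label; zero in-cell voxels means unassigned). A green
punctum counts as colocalized when it shares at least `min_overlap_vox`
(default 1) voxels with any red punctum, and symmetrically. Only
object-based counting is provided — no Pearson/Manders intensity
correlation, which measures a different thing. Per-cell fractions with a
zero denominator are reported as missing, never as zero.

## 4. Flux statistics from flow cytometry

Per-event Red:Green ratio = RFP/GFP; events with GFP <= 0 are excluded and
tallied. Summaries (median, quartiles, 10th/90th percentiles) use linear
("type 7") quantile interpolation, fixed and documented because the
upstream graphical software's rule is unspecified. Summaries require at
least 1,000 events. Normalization to a reference population (e.g. the
BafA1-treated minimal-flux state) divides every quantile by the reference
median and is order-preserving.

**Bimodal deconvolution** replaces interactive bifurcation gating with a
deterministic rule: the threshold on log10 ratio that minimizes the
two-class within-variance over a 256-bin histogram, found by exhaustive
scan (Otsu's criterion — "unbiased" in the sense of requiring no user
threshold). When the two modes are well separated the histogram has an
empty valley in which *every* boundary is exactly optimal; the gate takes
the middle of that tied plateau, which is both deterministic and the
robust choice. A population whose between-class variance fraction at the
optimum falls below 0.75 is flagged degenerate (effectively unimodal —
for a single Gaussian mode the optimal split captures only ~0.64 of the
variance, while separated modes approach 1). A two-component Gaussian
mixture could be fit instead, but EM adds seeds and restarts for no gain
at the separations of interest, so the variance scan is the default and
only built-in rule.

**Fold repression** maps a knockout's median ratio onto the interval
spanned by the autophagy-null reference (sgATG9A) and the unperturbed
control:

    fold repression = (ratio_gene - ratio_ATG9A) / (ratio_control - ratio_ATG9A)

It is 1 when the knockout looks like the control, 0 when it looks like the
null, affine-invariant in the medians, never clamped (out-of-range values
are flagged), and undefined (an error) when control and null medians
coincide.

## 5. Screen scoring

Reads are assigned to sgRNAs by anchored extraction: the first exact
occurrence of the vector sequence 5'-CACCG-3' is located and the following
20 nt are matched exactly against the library (unique 20-mers enforced).
Reads without anchor or without a library match are tallied separately.
No error correction or staggered-primer demultiplexing is attempted.

Counts are normalized by DESeq-style median-of-ratios size factors. The
per-gene enrichment score between the high and low Red:Green bins is

    score(gene) = mean over the gene's sgRNAs of log2((high + c)/(low + c)),  c = 0.5,

a deliberately simple stand-in with beta-score *semantics* (positive =
enriched in the high bin = flux suppressor for ratio-increasing
reporters); it is not an MLE and carries no FDR machinery. External
beta-score tables (gene-summary layout) can be ingested directly for the
downstream steps. Scores are averaged over the 2-4 replicates available
per reporter (a gene absent from some replicates is averaged over those
present, with n recorded), and each reporter column is then divided by its
reference-gene (ATG9A) score, making the reference row exactly 1.
Normalization happens after replicate averaging; the order is logged in
the table's provenance. A reference absent or zero in a column leaves that
column unnormalized and flagged rather than silently skipped.

## 6. Synthetic data: what it emulates, and what it does not

**Imaging scenes.** Cells are non-overlapping ellipsoids (lateral radius
r, axial semi-axis 0.4 r) centered mid-stack, placed by rejection sampling
with a 1,000-try cap that fails loudly; nuclei are concentric smaller
ellipsoids. Punctae are Gaussian spots (sigma 1 voxel, amplitude 300)
placed uniformly inside the cell body; a green punctum carries an exactly
coincident red partner with probability `coloc_fraction`, and independent
red punctae top the red rate up to its nominal value. Channels carry a
diffuse cell-body fill (25 intensity units) so masking has a realistic
foreground. The rendered signal is blurred with an anisotropic Gaussian
PSF (sigma (1.0, 0.6, 0.6) voxels, z > xy as in confocal optics; the one
physical voxel size anchoring our sense of scale, 83 x 83 x 438 nm, says
axial blur per *voxel* is mild, and the anisotropy is configurable), then
Poisson shot noise on signal plus additive Gaussian read noise (mean 100,
SD 10) is applied — camera statistics are never stated for the real data,
so both noise terms are toggleable. Spot amplitude 300 against read-noise
SD 10 gives an effective peak SNR ~ 9 after PSF blur.

Default scene scale: 16 x 384 x 384 voxel fields with 30 cells of radius
20 and 3 punctae per cell per channel. These sizes were chosen once so
that a full 20-scene recovery study runs in about a minute on one CPU
while keeping >= 10 resolution elements across a cell; they are the
conditions under which the recovery guarantees below are demonstrated.
The colocalization benchmark instead uses sparse fields (10 cells of
radius 32, 2.5 punctae/cell/channel), because object-overlap
colocalization has an irreducible accidental-overlap rate that scales
with punctum density — in real adherent cells punctae are far smaller
relative to the cell than any desk-scale raster can afford, and the
sparse condition keeps the accidental rate of the synthetic geometry
comparable to that regime (~3% per green punctum).

What the generator does *not* emulate: spectral bleed-through, Airy-disk
side lobes or any optics beyond a Gaussian PSF, illumination gradients,
intracellular texture, z-dependent attenuation, or clustered/vesicular
punctum substructure. Passing the recovery tests therefore demonstrates
the correctness and calibration of the *algorithms* under controlled
conditions, not performance on any particular microscope's data — on real
data the Canny thresholds and speck gate must be re-determined, exactly as
in the original workflow.

**Flow populations.** One or two log-normal Red:Green modes (fraction,
median, log10 SD per mode); GFP is drawn log-normally (median 1000,
log10 SD 0.2) and RFP = ratio x GFP, so the per-event ratio carries
exactly the mode's spread. Additive channel noise exists but defaults to
zero — measurement spread is folded into the mode log-SDs. Defaults
(n = 10,000 events; mode SD 0.1 dex) reflect the event counts and spreads
typical of the reporter assays.

**Sorted screens.** Each of n_sgRNA x coverage cells (coverage default
500) carries one sgRNA; knockout effects shift the cell's log2 ratio,
cell-to-cell spread is SD 1.0 in log2. The top and bottom thirds *of the
realized ratio distribution* are collected — sorting by realized ratio,
not by true effect, so misclassification noise is captured. Bin read
counts are multinomial over the bin's sgRNA composition at 300 reads/sgRNA
mean coverage (the 200-400 range of the real screens), with 2 replicates
by default. The generator does not model infection multiplicity, sgRNA
efficacy heterogeneity, PCR jackpotting, or growth effects during
expansion.

## 7. Numerical and determinism choices

* All randomness flows from `numpy.random.default_rng(seed)`; a pipeline
  run fans one root seed out to per-stage seeds through `SeedSequence`,
  so identical configs reproduce byte-identical CSV outputs (asserted in
  the test suite).
* Quantiles: linear interpolation everywhere.
* Watershed ties: resolved by the deterministic flooding order of the
  priority queue (insertion order at equal altitude).
* Puncta assignment ties: smaller cell label wins.
* Histogram mode estimation: 256 bins; ties resolved to the lowest bin.
* Degenerate inputs raise typed errors (`errors` module) rather than
  returning sentinel values: empty populations, zero-variance calibration
  fields, zero seeds, all-zero count samples, reference-median zero.

## 8. Known limitations

* The Canny thresholds, speck gate, and nucleus `min_volume` are
  scale-dependent and must be chosen per dataset; defaults target the
  bundled synthetic scale.
* Object-overlap colocalization has a density-dependent accidental
  component that is *part of the measurement*, in synthetic and real data
  alike; the benchmark quantifies it rather than subtracting it.
* The enrichment score is not a substitute for a proper MLE with FDR
  control when real screen inference is the goal; it exists to make the
  downstream averaging/normalization machinery testable end to end.
* FCS files are not parsed; flow input is per-event CSV.
* 2D-only imaging mode, cross-field cell tracking, and spillover
  compensation are out of scope.
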