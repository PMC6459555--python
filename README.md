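# autoflux

Quantitative analysis of autophagic flux, end to end: 3D puncta
segmentation and object-based colocalization from multi-channel confocal
z-stacks, tandem-fluorescent (RFP–GFP) reporter statistics from flow
cytometry, and gene scoring for FACS-sorted pooled CRISPR screens — with
ground-truthed synthetic generators for all three data kinds, so every
stage is testable without raw microscope or sequencing data.

## Who this is for

Labs measuring autophagy with tandem reporters (tfLC3 and tfReceptor
fusions: the RFP:GFP ratio rises when the fusion reaches the acidic
lysosome, because GFP is quenched there) and with puncta markers (LC3,
WIPI2), and labs post-processing FACS-binned CRISPR screen counts into
replicate-averaged, reference-normalized gene effect tables.

## The methods at the core

**Imaging.** Cell regions are found against an empty-field Gaussian
background model: a voxel is foreground when its upper-tail probability
under Normal(μ, σ) is below α = 10⁻⁵, equivalently I > μ + z₁₋ₐσ. After
debris (speck) removal and out-of-focus plane filtering, nuclei are
segmented from DAPI by per-slice relative thresholding + watershed, cells
by seeded watershed from nucleus labels, and punctae per channel by
slice-wise Canny edge detection with filled contours stacked into 3D
components. Colocalization is object-based: a green punctum counts as
colocalized iff it shares ≥ 1 voxel with a red punctum (and vice versa).

**Flow.** Per-event ratio R = RFP/GFP; summaries are median, inner
quartiles, and 10th/90th percentiles, optionally normalized to a reference
population's median (e.g. BafA1-treated cells, the minimal-flux state).
Bimodal knockout populations are split by a deterministic bifurcation
gate: the threshold on log₁₀R minimizing two-class within-variance over a
256-bin histogram (exhaustive scan). Knockout strength is summarized as

    fold repression = (R̃_gene − R̃_ATG9A) / (R̃_control − R̃_ATG9A)

with sgATG9A treated as the autophagy-null reference (score 0) and the
non-targeting control as 1.

**Screens.** Reads are assigned to guides by anchored extraction (first
exact 5′-CACCG-3′, then the next 20 nt matched exactly to the library),
counts are size-factor normalized (median-of-ratios), per-gene scores are
mean log₂((high+½)/(low+½)) over the gene's sgRNAs between the top- and
bottom-third Red:Green bins, averaged across 2–4 replicates, and every
reporter column is normalized by the ATG9A score so the reference row is
exactly 1. MAGeCK-layout count tables and gene-summary beta tables are
read directly; MAGeCK's estimator itself is not reimplemented.

See `docs/methods.md` for assumptions, parameter defaults, and limits.

## Worked example

```python
import dataclasses
from autoflux import synth, pipeline, flux

# a synthetic field: 30 cells, 79% of green punctae carry a red partner
spec = synth.SceneSpec(coloc_fraction=0.79, seed=7)
stacks, truth = synth.generate_scene(spec)
empty = synth.generate_empty_field(dataclasses.replace(spec, seed=8))

result = pipeline.run_image_pipeline(pipeline.RunConfig(), stacks, empty)
summary = result["table"].field_summary.iloc[0]
print(f"cells segmented:      {result['counts']['cells_surviving']} (true: {truth.n_cells()})")
print(f"green punctae:        {summary.total_green} (true: {(truth.puncta.channel == 'green').sum()})")
print(f"green overlapping red: {summary.total_green_overlapping}"
      f" -> fraction {summary.total_green_overlapping / summary.total_green:.2f}"
      f" (planted: {truth.realized_coloc_fraction():.2f})")

# a bimodal flow population and its unbiased gate
pop = synth.generate_flow_population(
    synth.FlowPopSpec(n_events=10_000, modes=((0.3, 1.0, 0.1), (0.7, 10.0, 0.1)), seed=9))
ratios, _ = flux.compute_ratios(flux.FlowPopulation(pop))
gate = flux.bifurcate(ratios)
print(f"bifurcation gate at ratio {gate.threshold:.2f}: "
      f"{gate.low_fraction:.0%} low / {gate.high_fraction:.0%} high")
print(f"fold repression (gene 4, null 2, control 10): {flux.fold_repression(4, 2, 10)[0]}")
```

prints

```
cells segmented:      30 (true: 30)
green punctae:        89 (true: 92)
green overlapping red: 75 -> fraction 0.84 (planted: 0.83)
bifurcation gate at ratio 3.12: 30% low / 70% high
fold repression (gene 4, null 2, control 10): 0.25
```

All 30 cells are recovered exactly; 89 of 92 planted green punctae are
detected (nearby spots occasionally merge), and the recovered overlap
fraction (0.84) tracks the planted one (0.83). The gate splits the
two flow modes at their planted 30/70 mixing fractions, and the fold
repression of a knockout with median ratio 4 between a null at 2 and a
control at 10 is (4−2)/(10−2) = 0.25.

The same stages are available from the shell:

```sh
autoflux simulate-scene --out scene/ --seed 7
autoflux mask    --green scene/green.tif --empty scene/empty.tif --out scene/mask.tif
autoflux segment --mask scene/mask.tif --blue scene/blue.tif --out scene/seg/
autoflux puncta  --green scene/green.tif --red scene/red.tif \
                 --cells scene/seg/cells.tif --out scene/puncta.csv
autoflux run-all --out run/ --seed 1     # imaging + flow + screen in one go
```

Every run writes its fully resolved configuration and per-stage object
counts next to its outputs; identical config + seed reproduces
byte-identical CSVs.

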