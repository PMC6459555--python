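"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the data the analysis consumes:

* :func:`generate_scene` / :func:`generate_empty_field` — multi-channel 3D
  confocal-like z-stacks: DAPI nuclei, diffuse cell-body reporter signal,
  and diffraction-limited punctae rendered as Gaussian spots, with a
  controlled cross-channel colocalization fraction, anisotropic PSF blur,
  and Poisson-Gaussian noise. A matching empty field supports background
  calibration.
* :func:`generate_flow_population` — per-event (RFP, GFP) intensities with
  one or two log-normal Red:Green modes, emulating tandem-reporter flow
  populations.
* :func:`simulate_sorted_screen` — a FACS-sorted pooled CRISPR screen: one
  sgRNA per cell, knockout effects shifting the cell's Red:Green ratio,
  sorting of the realized top/bottom ratio tertiles, and multinomial read
  counts at a controlled mean coverage per sgRNA.

All generators are deterministic given their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import InvalidSpecError, PlacementError, UnknownGeneError
from .screen import ScreenCounts
from .stacks import ImageStack, LabelVolume

# ---------------------------------------------------------------------------
# Scene generation


@dataclass
class SceneSpec:
    """Parameters of one synthetic imaging field.

    Geometry is in voxels with axis order (plane, row, column). Cells are
    ellipsoids (lateral radius ``cell_radius_vox``, axial semi-axis
    ``z_aspect`` times that) centered mid-stack, placed by rejection
    sampling so cell bodies never overlap; nuclei share the cell centers.
    ``coloc_fraction`` is the probability that a green punctum carries a
    coincident red partner. The axial PSF SD exceeds the lateral one by
    default, mimicking the elongated confocal PSF (physical voxels are
    anisotropic too; the only stated acquisition voxel in our anchor
    datasets is 83 x 83 x 438 nm, so z blur per voxel is mild).
    """

    field_shape: tuple[int, int, int] = (16, 384, 384)
    n_cells: int = 30
    nucleus_radius_vox: float = 9.0
    cell_radius_vox: float = 20.0
    puncta_per_cell_green: float = 3.0
    puncta_per_cell_red: float = 3.0
    coloc_fraction: float = 0.3
    puncta_radius_vox: float = 1.0
    psf_sigma_vox: tuple[float, float, float] = (1.0, 0.6, 0.6)
    bg_mean: float = 100.0
    bg_sd: float = 10.0
    signal_amplitude: float = 300.0
    cell_fill_amplitude: float = 25.0
    nucleus_amplitude: float = 150.0
    z_aspect: float = 0.4
    noise_model: str = "poisson_gaussian"  # poisson_gaussian | gaussian | none
    edge_margin_vox: float | None = None  # default: cell_radius + 10 (keeps cells off x/y borders)
    max_place_tries: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.field_shape) or len(self.field_shape) != 3:
            raise InvalidSpecError(f"field_shape must be 3 positive ints, got {self.field_shape}")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise InvalidSpecError("coloc_fraction must be in [0, 1]")
        for name in ("nucleus_radius_vox", "cell_radius_vox", "puncta_radius_vox"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be > 0")
        if self.puncta_per_cell_green < 0 or self.puncta_per_cell_red < 0:
            raise InvalidSpecError("puncta rates must be nonnegative")
        if self.noise_model not in ("poisson_gaussian", "gaussian", "none"):
            raise InvalidSpecError(f"unknown noise model {self.noise_model!r}")
        if self.bg_sd < 0 or self.bg_mean < 0:
            raise InvalidSpecError("background mean/SD must be nonnegative")

    @property
    def margin(self) -> float:
        return self.edge_margin_vox if self.edge_margin_vox is not None else self.cell_radius_vox + 10.0


@dataclass
class GroundTruth:
    """Everything the generator placed, for validating the pipeline.

    ``puncta`` has one row per punctum: punctum_id, cell_id, channel,
    z/y/x centroid, and partner_id (the colocalized punctum in the other
    channel, or -1). ``cells``/``nuclei`` are the true label volumes, with
    label k for cell k. ``in_focus_planes`` marks planes containing at
    least one true cell voxel.
    """

    cells: LabelVolume
    nuclei: LabelVolume
    puncta: pd.DataFrame
    cell_centers: np.ndarray  # (n_cells, 3) float (z, y, x)
    border_flags: np.ndarray  # (n_cells,) bool
    in_focus_planes: np.ndarray  # (nz,) bool
    spec: SceneSpec

    def n_cells(self) -> int:
        return len(self.cell_centers)

    def puncta_counts(self, channel: str) -> pd.Series:
        """True per-cell punctum count for one channel (all cells, zeros kept)."""
        sub = self.puncta[self.puncta["channel"] == channel]
        counts = sub.groupby("cell_id").size()
        return counts.reindex(range(1, self.n_cells() + 1), fill_value=0)

    def realized_coloc_fraction(self) -> float:
        """Fraction of true green punctae with a planted red partner."""
        green = self.puncta[self.puncta["channel"] == "green"]
        if len(green) == 0:
            return float("nan")
        return float((green["partner_id"] >= 0).mean())


def _apply_noise(signal: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise on signal photons + additive Gaussian read noise on top of the offset."""
    if spec.noise_model == "poisson_gaussian":
        out = rng.poisson(np.clip(signal, 0, None)).astype(np.float32)
    elif spec.noise_model == "gaussian":
        out = signal.astype(np.float32, copy=True)
    else:  # none
        return np.clip(signal + spec.bg_mean, 0, None).astype(np.float32)
    out += spec.bg_mean
    if spec.bg_sd > 0:
        out += rng.normal(0.0, spec.bg_sd, size=out.shape).astype(np.float32)
    return np.clip(out, 0, None)


def generate_empty_field(spec: SceneSpec) -> ImageStack:
    """Background-only green stack from the stated noise model (for calibration)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    signal = np.zeros(spec.field_shape, dtype=np.float32)
    return ImageStack(_apply_noise(signal, spec, rng), channel="green")


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping cell centers; loud failure at the retry cap."""
    nz, ny, nx = spec.field_shape
    m = spec.margin
    if ny - 2 * m <= 0 or nx - 2 * m <= 0:
        raise PlacementError(
            f"field {spec.field_shape} too small for margin {m:.0f} (cell radius {spec.cell_radius_vox})"
        )
    min_d2 = (2.0 * spec.cell_radius_vox + 2.0) ** 2
    centers: list[tuple[float, float, float]] = []
    for i in range(spec.n_cells):
        for _ in range(spec.max_place_tries):
            y = rng.uniform(m, ny - m)
            x = rng.uniform(m, nx - m)
            z = nz / 2.0 + rng.uniform(-1.0, 1.0)
            if all((y - cy) ** 2 + (x - cx) ** 2 >= min_d2 for _, cy, cx in centers):
                centers.append((z, y, x))
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{spec.n_cells} without body overlap "
                f"after {spec.max_place_tries} tries (min center distance "
                f"{2 * spec.cell_radius_vox + 2:.0f} vox in a "
                f"{ny - 2 * m:.0f}x{nx - 2 * m:.0f} placement region)"
            )
    return np.array(centers, dtype=float)


def _paint_ellipsoid(vol: np.ndarray, center, semi, value) -> None:
    """Set voxels inside an axis-aligned ellipsoid; bbox-local for speed."""
    cz, cy, cx = center
    az, ay, ax = semi
    z0, z1 = max(int(np.floor(cz - az)), 0), min(int(np.ceil(cz + az)) + 1, vol.shape[0])
    y0, y1 = max(int(np.floor(cy - ay)), 0), min(int(np.ceil(cy + ay)) + 1, vol.shape[1])
    x0, x1 = max(int(np.floor(cx - ax)), 0), min(int(np.ceil(cx + ax)) + 1, vol.shape[2])
    zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
    inside = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    vol[z0:z1, y0:y1, x0:x1][inside] = value


def _add_gaussian_spot(img: np.ndarray, center, sigma: float, amplitude: float) -> None:
    cz, cy, cx = center
    r = int(np.ceil(4 * sigma))
    z0, z1 = max(int(cz) - r, 0), min(int(cz) + r + 1, img.shape[0])
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, img.shape[1])
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, img.shape[2])
    zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
    d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    img[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(-0.5 * d2 / sigma**2)


def _sample_in_ellipsoid(rng, center, semi, shrink=0.85):
    """Uniform point inside the shrunken ellipsoid (keeps centroids interior)."""
    while True:
        u = rng.uniform(-1, 1, size=3)
        if (u**2).sum() <= 1.0:
            return center + u * np.asarray(semi) * shrink


def generate_scene(spec: SceneSpec):
    """Render one field; returns ``({channel: ImageStack}, GroundTruth)``.

    The blue channel carries nuclei; green and red carry diffuse cell-body
    signal plus their punctae. Colocalized green/red pairs share centroids
    exactly. Red punctae are the colocalized partners plus an independent
    Poisson(max(0, rate_red - p*rate_green)) count per cell, so the
    expected red total matches ``puncta_per_cell_red``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.field_shape
    centers = _place_centers(spec, rng)

    cell_semi = (spec.z_aspect * spec.cell_radius_vox, spec.cell_radius_vox, spec.cell_radius_vox)
    nuc_semi = (spec.z_aspect * spec.nucleus_radius_vox, spec.nucleus_radius_vox, spec.nucleus_radius_vox)

    cells_true = np.zeros(spec.field_shape, dtype=np.int32)
    nuclei_true = np.zeros(spec.field_shape, dtype=np.int32)
    for k, c in enumerate(centers, start=1):
        _paint_ellipsoid(cells_true, c, cell_semi, k)
    for k, c in enumerate(centers, start=1):
        _paint_ellipsoid(nuclei_true, c, nuc_semi, k)

    # puncta placement with exact colocalized partners
    red_only_rate = max(0.0, spec.puncta_per_cell_red - spec.coloc_fraction * spec.puncta_per_cell_green)
    rows = []
    pid = 0
    for k, c in enumerate(centers, start=1):
        n_green = rng.poisson(spec.puncta_per_cell_green)
        coloc = rng.random(n_green) < spec.coloc_fraction
        for j in range(n_green):
            pos = _sample_in_ellipsoid(rng, c, cell_semi)
            pid += 1
            gid = pid
            rows.append(dict(punctum_id=gid, cell_id=k, channel="green",
                             z=pos[0], y=pos[1], x=pos[2], partner_id=-1))
            if coloc[j]:
                pid += 1
                rows.append(dict(punctum_id=pid, cell_id=k, channel="red",
                                 z=pos[0], y=pos[1], x=pos[2], partner_id=gid))
                rows[-2]["partner_id"] = pid
        for _ in range(rng.poisson(red_only_rate)):
            pos = _sample_in_ellipsoid(rng, c, cell_semi)
            pid += 1
            rows.append(dict(punctum_id=pid, cell_id=k, channel="red",
                             z=pos[0], y=pos[1], x=pos[2], partner_id=-1))
    puncta = pd.DataFrame(
        rows, columns=["punctum_id", "cell_id", "channel", "z", "y", "x", "partner_id"]
    )

    # render noiseless signal per channel
    signal = {ch: np.zeros(spec.field_shape, dtype=np.float32) for ch in ("green", "red", "blue")}
    body = (cells_true > 0).astype(np.float32) * spec.cell_fill_amplitude
    signal["green"] += body
    signal["red"] += body
    signal["blue"] += (nuclei_true > 0).astype(np.float32) * spec.nucleus_amplitude
    for row in puncta.itertuples():
        _add_gaussian_spot(signal[row.channel], (row.z, row.y, row.x),
                           spec.puncta_radius_vox, spec.signal_amplitude)

    stacks = {}
    for ch in ("green", "red", "blue"):
        blurred = ndi.gaussian_filter(signal[ch], sigma=spec.psf_sigma_vox)
        stacks[ch] = ImageStack(_apply_noise(blurred, spec, rng), channel=ch)

    in_focus = np.array([(cells_true[z] > 0).any() for z in range(nz)])
    border = np.zeros(len(centers), dtype=bool)
    for k in range(1, len(centers) + 1):
        where = cells_true == k
        if where[:, 0, :].any() or where[:, -1, :].any() or where[:, :, 0].any() or where[:, :, -1].any():
            border[k - 1] = True

    truth = GroundTruth(
        cells=LabelVolume(cells_true, kind="cells"),
        nuclei=LabelVolume(nuclei_true, kind="nuclei"),
        puncta=puncta,
        cell_centers=centers,
        border_flags=border,
        in_focus_planes=in_focus,
        spec=spec,
    )
    return stacks, truth


def write_truth_csv(truth: GroundTruth, puncta_path, cells_path) -> None:
    """Persist truth: one row per punctum, and one per cell."""
    truth.puncta.to_csv(puncta_path, index=False)
    per_cell = pd.DataFrame(
        {
            "cell_id": range(1, truth.n_cells() + 1),
            "center_z": truth.cell_centers[:, 0],
            "center_y": truth.cell_centers[:, 1],
            "center_x": truth.cell_centers[:, 2],
            "n_green": truth.puncta_counts("green").to_numpy(),
            "n_red": truth.puncta_counts("red").to_numpy(),
            "border_flag": truth.border_flags,
        }
    )
    per_cell.to_csv(cells_path, index=False)


# ---------------------------------------------------------------------------
# Flow populations


@dataclass
class FlowPopSpec:
    """One or two log-normal Red:Green modes.

    ``modes`` is a list of ``(fraction, median_ratio, log10_sd)``. GFP is
    drawn log-normally around ``gfp_median``; RFP is ratio x GFP, so the
    per-event ratio carries exactly the mode's log-normal spread. Channel
    read noise (additive, SD ``channel_noise_sd``) is off by default —
    measurement spread is folded into the mode log-SDs.
    """

    n_events: int = 10000
    modes: tuple = ((1.0, 1.0, 0.1),)
    gfp_median: float = 1000.0
    gfp_log10_sd: float = 0.2
    channel_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_events < 1:
            raise InvalidSpecError("n_events must be >= 1")
        fracs = [m[0] for m in self.modes]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise InvalidSpecError(f"mode fractions must sum to 1 (got {sum(fracs)})")
        if any(f < 0 for f in fracs):
            raise InvalidSpecError("mode fractions must be nonnegative")
        if any(m[1] <= 0 for m in self.modes):
            raise InvalidSpecError("mode median ratios must be > 0")


def generate_flow_population(spec: FlowPopSpec) -> pd.DataFrame:
    """Per-event table with columns RFP, GFP, true_mode (shuffled)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = [int(round(f * spec.n_events)) for f, _, _ in spec.modes]
    counts[-1] = spec.n_events - sum(counts[:-1])
    parts = []
    for mode_idx, ((_, med, lsd), n) in enumerate(zip(spec.modes, counts)):
        if n <= 0:
            continue
        ratio = med * 10.0 ** rng.normal(0.0, lsd, size=n)
        gfp = spec.gfp_median * 10.0 ** rng.normal(0.0, spec.gfp_log10_sd, size=n)
        rfp = ratio * gfp
        parts.append(pd.DataFrame({"RFP": rfp, "GFP": gfp, "true_mode": mode_idx}))
    df = pd.concat(parts, ignore_index=True)
    if spec.channel_noise_sd > 0:
        df["RFP"] += rng.normal(0, spec.channel_noise_sd, size=len(df))
        df["GFP"] += rng.normal(0, spec.channel_noise_sd, size=len(df))
    order = rng.permutation(len(df))
    return df.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sorted-screen simulation


@dataclass
class ScreenSimSpec:
    """FACS-sorted pooled screen conditions.

    Each cell carries one sgRNA; a knockout of a hit gene shifts the
    cell's log2 Red:Green ratio by the gene's effect. The realized top and
    bottom ``sorted_fraction`` of cells (by ratio) are collected, and read
    counts per bin are multinomial over the bin's sgRNA composition at
    ``mean_reads_per_sgrna`` coverage — the published screens averaged
    200-400 reads per sgRNA, and sorted the top and bottom thirds.
    """

    n_genes: int = 1000
    sgrnas_per_gene: int = 4
    hits: dict = dc_field(default_factory=dict)  # gene -> effect on log2 ratio
    sorted_fraction: float = 1.0 / 3.0
    mean_reads_per_sgrna: float = 300.0
    n_replicates: int = 2
    cells_per_sgrna: int = 500
    cell_log2_sd: float = 1.0
    reporter: str = "tfLC3"
    gene_names: tuple | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.sorted_fraction <= 0.5):
            raise InvalidSpecError("sorted_fraction must be in (0, 0.5]")
        if self.n_genes < 1 or self.sgrnas_per_gene < 1:
            raise InvalidSpecError("need at least one gene and one sgRNA per gene")
        if self.mean_reads_per_sgrna < 0:
            raise InvalidSpecError("mean reads per sgRNA must be nonnegative")
        if not (1 <= self.n_replicates):
            raise InvalidSpecError("n_replicates must be >= 1")

    def genes(self) -> list[str]:
        if self.gene_names is not None:
            if len(self.gene_names) != self.n_genes:
                raise InvalidSpecError("gene_names length must equal n_genes")
            return list(self.gene_names)
        width = len(str(self.n_genes))
        return [f"GENE{i:0{width}d}" for i in range(1, self.n_genes + 1)]


def simulate_sorted_screen(spec: ScreenSimSpec) -> ScreenCounts:
    """Simulate input/high/low read counts per replicate.

    Returns a :class:`ScreenCounts` whose ``extras`` carry the per-replicate
    realized bin sizes (``bin_sizes``) and the per-sgRNA true effects.
    """
    spec.validate()
    genes = spec.genes()
    unknown = [g for g in spec.hits if g not in set(genes)]
    if unknown:
        raise UnknownGeneError(f"hit table names genes absent from the library: {unknown[:5]}")
    rng = np.random.default_rng(spec.seed)
    n_sgrna = spec.n_genes * spec.sgrnas_per_gene
    sgrna_ids = [f"{g}_sg{j}" for g in genes for j in range(1, spec.sgrnas_per_gene + 1)]
    gene_of_sgrna = np.repeat(np.arange(spec.n_genes), spec.sgrnas_per_gene)
    effects = np.array([spec.hits.get(g, 0.0) for g in genes])[gene_of_sgrna]

    n_cells = n_sgrna * spec.cells_per_sgrna
    n_bin = int(np.floor(spec.sorted_fraction * n_cells))
    total_reads = int(round(spec.mean_reads_per_sgrna * n_sgrna))

    cols = {}
    meta_rows = []
    bin_sizes = {}
    cell_sgrna = np.repeat(np.arange(n_sgrna), spec.cells_per_sgrna)
    input_freq = np.bincount(cell_sgrna, minlength=n_sgrna).astype(float)
    for rep in range(1, spec.n_replicates + 1):
        ratios = effects[cell_sgrna] + rng.normal(0.0, spec.cell_log2_sd, size=n_cells)
        order = np.argsort(ratios, kind="stable")
        low_cells = cell_sgrna[order[:n_bin]]
        high_cells = cell_sgrna[order[n_cells - n_bin:]]
        bin_sizes[rep] = {"high": n_bin, "low": n_bin, "unsorted": n_cells - 2 * n_bin}
        for bin_name, members in (("input", None), ("high", high_cells), ("low", low_cells)):
            freq = input_freq if members is None else np.bincount(members, minlength=n_sgrna).astype(float)
            p = freq / freq.sum()
            reads = rng.multinomial(total_reads, p)
            col = f"{spec.reporter}_rep{rep}_{bin_name}"
            cols[col] = reads
            meta_rows.append(dict(sample=col, reporter=spec.reporter, replicate=rep, bin=bin_name))

    counts = pd.DataFrame(cols, index=pd.Index(sgrna_ids, name="sgRNA"))
    guide_map = pd.Series(np.array(genes)[gene_of_sgrna], index=counts.index, name="gene")
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return ScreenCounts(
        counts=counts, guide_map=guide_map, samples=samples,
        extras={"bin_sizes": bin_sizes, "true_effects": dict(spec.hits),
                "n_cells": n_cells},
    )


def default_screen_sim(n_genes: int = 200, hit_effect: float = 2.0, seed: int = 0) -> ScreenSimSpec:
    """A modest screen whose library carries the ATG9A reference gene as a hit.

    Used by the end-to-end runner so reference-gene normalization is
    exercised out of the box.
    """
    width = len(str(n_genes))
    genes = ["ATG9A"] + [f"GENE{i:0{width}d}" for i in range(1, n_genes)]
    return ScreenSimSpec(
        n_genes=n_genes, gene_names=tuple(genes), hits={"ATG9A": hit_effect},
        cells_per_sgrna=200, seed=seed,
    )


# ---------------------------------------------------------------------------
# Synthetic FASTQ (for the anchored sgRNA extractor)

_BASES = np.array(list("ACGT"))


def make_library(n_guides: int, genes_per_guide_group: int = 4, seed: int = 0) -> pd.DataFrame:
    """Random unique-20-mer library table (sgrna, gene, sequence)."""
    rng = np.random.default_rng(seed)
    seqs = set()
    while len(seqs) < n_guides:
        seqs.add("".join(rng.choice(_BASES, size=20)))
    seqs = sorted(seqs)
    rows = []
    for i, s in enumerate(seqs):
        gene = f"GENE{i // genes_per_guide_group + 1:04d}"
        rows.append(dict(sgrna=f"{gene}_sg{i % genes_per_guide_group + 1}", gene=gene, sequence=s))
    return pd.DataFrame(rows)


def write_synthetic_fastq(path, library: pd.DataFrame, n_reads: int, seed: int = 0,
                          anchorless_fraction: float = 0.0) -> pd.Series:
    """Write a FASTQ of vector-anchored reads; returns the true counts drawn.

    Each read is random stuffer + CACCG + a library guide + stuffer, so the
    extractor's recovered counts must equal the multinomial draw exactly.
    """
    rng = np.random.default_rng(seed)
    n_anchorless = int(round(anchorless_fraction * n_reads))
    n_real = n_reads - n_anchorless
    draw = rng.multinomial(n_real, np.full(len(library), 1.0 / len(library)))
    truth = pd.Series(draw, index=library["sgrna"].to_numpy(), name="count")
    no_c = np.array(list("AGT"))  # C-free stuffer cannot spawn a spurious anchor
    reads = []
    for seq, k in zip(library["sequence"], draw):
        for _ in range(k):
            pre = "".join(rng.choice(no_c, size=rng.integers(0, 6)))
            post = "".join(rng.choice(_BASES, size=8))
            reads.append(pre + "CACCG" + seq + post)
    for _ in range(n_anchorless):
        reads.append("".join(rng.choice(no_c, size=33)))
    order = rng.permutation(len(reads))
    with open(path, "w") as fh:
        for i in order:
            fh.write(f"@read{i}\n{reads[i]}\n+\n{'I' * len(reads[i])}\n")
    return truth


__all__ = [
    "SceneSpec", "GroundTruth", "FlowPopSpec", "ScreenSimSpec",
    "generate_empty_field", "generate_scene", "write_truth_csv",
    "generate_flow_population", "simulate_sorted_screen", "default_screen_sim",
    "make_library", "write_synthetic_fastq",
]
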