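"""Stage orchestration with config, logging, and seeded reproducibility.

A :class:`RunConfig` holds every tunable of every stage, with defaults
equal to the documented design values; a run serializes its fully
resolved config alongside its outputs, together with a per-stage object
count log, so any figure-style statistic can be re-derived from the output
directory without re-running segmentation. A single root seed fans out to
per-stage seeds deterministically, so stage subsets re-run reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import flux as flux_mod
from . import masking, puncta, screen, segmentation, synth
from .errors import AutofluxError, InvalidParameterError, PipelineStageError
from .stacks import ImageStack, write_labels, write_mask, write_stack


@dataclass
class RunConfig:
    """All pipeline parameters in one place (flat key=value serializable)."""

    seed: int = 0
    # masking; the speck gate defaults to the bundled synthetic scale
    # (a synthetic cell is ~15k voxels); real 2048^2-class acquisitions
    # use masking.DEFAULT_MIN_SPECK_VOXELS (100,000).
    alpha: float = masking.DEFAULT_ALPHA
    smoothing_sigma: tuple = masking.DEFAULT_SMOOTHING_SIGMA
    min_speck_voxels: int = 2000
    focus_mode: str = "rule"  # rule | svm
    focus_f_min: float = 1e-3
    # segmentation
    relative_threshold: float = segmentation.DEFAULT_RELATIVE_THRESHOLD
    min_nucleus_volume: int = segmentation.DEFAULT_MIN_NUCLEUS_VOLUME
    min_peak_distance: int = 6
    erosion_radius_xy: int = segmentation.DEFAULT_EROSION_RADIUS_XY
    erosion_radius_z: int = segmentation.DEFAULT_EROSION_RADIUS_Z
    # puncta; absolute Canny thresholds determined empirically for the
    # bundled synthetic conditions (quantile mode is available for data
    # where no calibration exists: canny_use_quantiles=True, low/high as
    # gradient-magnitude quantiles, e.g. 0.90/0.99)
    canny_sigma: float = 1.0
    canny_low: float = 100.0
    canny_high: float = 180.0
    canny_use_quantiles: bool = False
    puncta_min_volume: int = 4
    puncta_max_volume: int = 10_000
    min_overlap_vox: int = 1
    restrict_puncta_to_cells: bool = True
    # flux
    min_events: int = flux_mod.DEFAULT_MIN_EVENTS
    # screen
    reference_gene: str = screen.DEFAULT_REFERENCE_GENE
    pseudocount: float = 0.5
    # simulation specs (used by simulate-* and run-all)
    scene: synth.SceneSpec = field(default_factory=synth.SceneSpec)
    flow: synth.FlowPopSpec = field(
        default_factory=lambda: synth.FlowPopSpec(modes=((0.5, 1.0, 0.1), (0.5, 10.0, 0.1)))
    )
    screen_sim: synth.ScreenSimSpec = field(default_factory=synth.default_screen_sim)

    # -- flat (key=value) serialization ------------------------------------
    def to_flat(self) -> dict[str, str]:
        out: dict[str, str] = {}

        def emit(prefix: str, obj) -> None:
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                key = f"{prefix}{f.name}"
                if dataclasses.is_dataclass(v):
                    emit(key + ".", v)
                elif isinstance(v, (tuple, list)):
                    if any(isinstance(x, (tuple, list)) for x in v):
                        out[key] = json.dumps([list(x) for x in v])
                    else:
                        out[key] = ",".join(str(x) for x in v)
                elif isinstance(v, dict):
                    out[key] = json.dumps(v, sort_keys=True)
                else:
                    out[key] = str(v)

        emit("", self)
        return out

    @classmethod
    def from_flat(cls, flat: dict[str, str]) -> "RunConfig":
        cfg = cls()

        def coerce(current, raw: str):
            if isinstance(current, bool):
                return raw.lower() in ("1", "true", "yes")
            if isinstance(current, int):
                return int(raw)
            if isinstance(current, float):
                return float(raw)
            if isinstance(current, (tuple, list)):
                if raw.strip() == "":
                    return type(current)()
                if raw.lstrip().startswith("["):
                    return tuple(
                        tuple(x) if isinstance(x, list) else x for x in json.loads(raw)
                    )

                def item(p: str):
                    for cast in (int, float):
                        try:
                            return cast(p)
                        except ValueError:
                            pass
                    return p

                return tuple(item(p.strip()) for p in raw.split(","))
            if isinstance(current, dict):
                return json.loads(raw) if raw.strip() else {}
            return raw

        for key, raw in flat.items():
            obj = cfg
            *path, leaf = key.split(".")
            for p in path:
                if not hasattr(obj, p):
                    raise InvalidParameterError(f"unknown config section {p!r} in {key!r}")
                obj = getattr(obj, p)
            if not hasattr(obj, leaf):
                raise InvalidParameterError(f"unknown config key {key!r}")
            current = getattr(obj, leaf)
            if raw == "None":
                setattr(obj, leaf, None)
            elif current is None:
                setattr(obj, leaf, _guess(raw))
            else:
                setattr(obj, leaf, coerce(current, raw))
        return cfg

    def save(self, path) -> None:
        flat = self.to_flat()
        with open(path, "w") as fh:
            for k in sorted(flat):
                fh.write(f"{k}={flat[k]}\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        flat = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                flat[k.strip()] = v.strip()
        return cls.from_flat(flat)

    def canny_params(self) -> puncta.CannyParams:
        return puncta.CannyParams(
            sigma=self.canny_sigma, low_threshold=self.canny_low,
            high_threshold=self.canny_high, use_quantiles=self.canny_use_quantiles,
            min_volume=self.puncta_min_volume, max_volume=self.puncta_max_volume,
        )

    def stage_seeds(self, n: int = 4) -> list[int]:
        """Deterministic per-stage seeds fanned out from the root seed."""
        state = np.random.SeedSequence(self.seed).generate_state(n)
        return [int(s % (2**31 - 1)) for s in state]


def _guess(raw: str):
    """Best-effort parse for config fields whose default is None."""
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    if "," in raw:
        return tuple(_guess(p.strip()) for p in raw.split(","))
    return raw


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except AutofluxError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise PipelineStageError(name, str(exc)) from exc
        return wrapped
    return deco


def run_image_pipeline(
    config: RunConfig,
    stacks: dict[str, ImageStack],
    empty_field: ImageStack,
    outdir=None,
    field_id: str = "field0",
    focus_classifier: masking.FocusClassifier | None = None,
):
    """Full image analysis: background fit -> mask -> specks -> focus ->
    nuclei -> cells -> erode -> border removal -> puncta -> coloc -> CSV.

    Returns a dict with every intermediate (model, mask, label volumes,
    assignments, PunctaTable, per-stage counts). With ``outdir`` set, all
    stage outputs, the resolved config, and the count log are persisted;
    identical config + inputs reproduce identical files.
    """
    if empty_field is None:
        raise PipelineStageError("calibration", "missing required input: empty-field green stack")
    for ch in ("green", "red", "blue"):
        if ch not in stacks:
            raise PipelineStageError("input", f"missing required channel stack: {ch}")
    counts: dict[str, float] = {}

    model = _stage("fit_background")(masking.fit_background_gaussian)(
        empty_field, smoothing_sigma=config.smoothing_sigma, alpha=config.alpha
    )
    smoothed_green = masking.smooth_stack(stacks["green"], config.smoothing_sigma)
    mask = _stage("cell_mask")(masking.compute_cell_mask)(smoothed_green, model)
    counts["masked_voxels_raw"] = mask.volume()
    mask = _stage("speck_removal")(masking.remove_small_specks)(mask, config.min_speck_voxels)
    counts["masked_voxels_despeck"] = mask.volume()
    clf = focus_classifier or masking.FocusClassifier.rule_based(config.focus_f_min)
    mask, focus_decisions = _stage("focus_filter")(masking.filter_out_of_focus_planes)(
        mask, smoothed_green, clf
    )
    counts["masked_voxels"] = mask.volume()
    counts["in_focus_planes"] = int(focus_decisions["in_focus"].sum())

    nuclei = _stage("nuclei")(segmentation.segment_nuclei)(
        stacks["blue"], relative_threshold=config.relative_threshold,
        min_volume=config.min_nucleus_volume, min_peak_distance=config.min_peak_distance,
    )
    counts["nuclei"] = nuclei.n_objects
    cells, n_unassigned = _stage("cells")(segmentation.segment_cells)(mask, nuclei)
    counts["cells"] = cells.n_objects
    counts["unassigned_mask_voxels"] = n_unassigned
    cells = _stage("erode")(segmentation.erode_cell_edges)(
        cells, radius_xy=config.erosion_radius_xy, radius_z=config.erosion_radius_z
    )
    cells = _stage("border")(segmentation.remove_border_cells)(cells)
    counts["cells_surviving"] = cells.n_objects

    params = config.canny_params()
    cell_restrict = cells if config.restrict_puncta_to_cells else None
    green_p = _stage("puncta_green")(puncta.segment_puncta)(stacks["green"], cell_restrict, params)
    red_p = _stage("puncta_red")(puncta.segment_puncta)(stacks["red"], cell_restrict, params)
    counts["puncta_green"] = green_p.n_objects
    counts["puncta_red"] = red_p.n_objects
    g_assign = puncta.assign_puncta_to_cells(green_p, cells)
    r_assign = puncta.assign_puncta_to_cells(red_p, cells)
    table = _stage("colocalization")(puncta.count_colocalization)(
        green_p, red_p, g_assign, r_assign, cells,
        min_overlap_vox=config.min_overlap_vox, field_id=field_id,
    )

    result = dict(
        model=model, mask=mask, focus_decisions=focus_decisions,
        nuclei=nuclei, cells=cells, puncta_green=green_p, puncta_red=red_p,
        green_assignment=g_assign, red_assignment=r_assign,
        table=table, counts=counts,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.save(outdir / "config.resolved.txt")
        write_mask(outdir / "cell_mask.tif", mask)
        write_labels(outdir / "nuclei.tif", nuclei)
        write_labels(outdir / "cells.tif", cells)
        write_labels(outdir / "puncta_green.tif", green_p)
        write_labels(outdir / "puncta_red.tif", red_p)
        focus_decisions.to_csv(outdir / "focus_decisions.csv", index=False, float_format="%.6g")
        puncta.write_puncta_csv(table, outdir / "puncta.csv")
        with open(outdir / "stage_counts.log", "w") as fh:
            for k, v in counts.items():
                fh.write(f"{k}={v}\n")
    return result


def run_flux(config: RunConfig, events: pd.DataFrame, reference_sample: str | None = None,
             outdir=None):
    """Summarize Red:Green ratios per sample, optionally normalized to a
    reference sample's median; also gates each sample for bimodality.

    ``events`` must have columns sample_id, RFP, GFP.
    """
    if "sample_id" not in events.columns:
        events = events.assign(sample_id="sample0")
    summaries: dict[str, flux_mod.FluxSummary] = {}
    gates: dict[str, flux_mod.BifurcationGate] = {}
    ratios_by_sample: dict[str, np.ndarray] = {}
    for sample, grp in events.groupby("sample_id"):
        pop = flux_mod.FlowPopulation(grp[["RFP", "GFP"]])
        ratios, _ = flux_mod.compute_ratios(pop)
        ratios_by_sample[sample] = ratios
        summaries[sample] = flux_mod.summarize(ratios, min_events=config.min_events)
        gates[sample] = flux_mod.bifurcate(ratios, min_events=config.min_events)
    if reference_sample is not None:
        ref = summaries[reference_sample]
        summaries = {
            k: flux_mod.normalize(s, ref, label=reference_sample) for k, s in summaries.items()
        }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        flux_mod.write_summary_csv(outdir / "flux_summary.csv", summaries)
        rows = [dict(sample=k, threshold=g.threshold, low_fraction=g.low_fraction,
                     high_fraction=g.high_fraction, low_median=g.low_median,
                     high_median=g.high_median, separation=g.separation,
                     degenerate=g.degenerate) for k, g in gates.items()]
        pd.DataFrame(rows).to_csv(outdir / "bifurcation.csv", index=False, float_format="%.6g")
    return dict(summaries=summaries, gates=gates, ratios=ratios_by_sample)


def run_screen(config: RunConfig, sc: screen.ScreenCounts, outdir=None):
    """Score a binned screen: per-replicate enrichment -> replicate mean ->
    reference-gene normalization."""
    per_rep = screen.score_screen(sc, pseudocount=config.pseudocount)
    averaged = screen.average_replicates(per_rep)
    normalized = screen.normalize_by_reference_gene(averaged, reference=config.reference_gene)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        screen.write_gene_score_csv(outdir / "gene_scores_raw.csv", averaged)
        screen.write_gene_score_csv(outdir / "gene_scores_normalized.csv", normalized)
    return dict(per_replicate=per_rep, averaged=averaged, normalized=normalized)


def run_all(config: RunConfig, outdir):
    """simulate scene + flow + screen, then analyze all three.

    The root seed fans out deterministically to the scene, empty-field,
    flow, and screen simulations.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s_scene, s_empty, s_flow, s_screen = config.stage_seeds(4)

    scene_spec = dataclasses.replace(config.scene, seed=s_scene)
    stacks, truth = synth.generate_scene(scene_spec)
    empty = synth.generate_empty_field(dataclasses.replace(scene_spec, seed=s_empty))
    img_dir = outdir / "imaging"
    img_dir.mkdir(exist_ok=True)
    for ch, st in stacks.items():
        write_stack(img_dir / f"{ch}.tif", st)
    write_stack(img_dir / "empty.tif", empty)
    synth.write_truth_csv(truth, img_dir / "truth_puncta.csv", img_dir / "truth_cells.csv")
    image_result = run_image_pipeline(config, stacks, empty, outdir=img_dir)

    flow_spec = dataclasses.replace(config.flow, seed=s_flow)
    events = synth.generate_flow_population(flow_spec)
    events = events.assign(sample_id="sim")
    flow_dir = outdir / "flux"
    events.to_csv(outdir / "flow_events.csv", index=False, float_format="%.6g")
    flux_result = run_flux(config, events, outdir=flow_dir)

    screen_spec = dataclasses.replace(config.screen_sim, seed=s_screen)
    sc = synth.simulate_sorted_screen(screen_spec)
    screen_dir = outdir / "screen"
    screen_dir.mkdir(exist_ok=True)
    screen.write_counts_tsv(screen_dir / "counts.tsv", sc)
    screen_result = run_screen(config, sc, outdir=screen_dir)

    config.save(outdir / "config.resolved.txt")
    return dict(image=image_result, flux=flux_result, screen=screen_result, truth=truth)


__all__ = ["RunConfig", "run_image_pipeline", "run_flux", "run_screen", "run_all"]
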