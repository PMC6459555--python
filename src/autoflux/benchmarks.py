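"""Ground-truth recovery studies on synthetic scenes.

These helpers freeze the two imaging study conditions used to validate the
pipeline and provide the matching evaluation harnesses:

* the segmentation-recovery condition: the default 30-cell field, on which
  nucleus/cell counts must match truth exactly and per-cell puncta counts
  are scored by mean absolute error;
* the colocalization conditions: sparse fields of large cells in a
  high-colocalization ("KO-like", planted fraction 0.79) and a
  low-colocalization ("WT-like", 0.08) regime — the contrast the
  object-based counting exists to resolve.

Segmented cells are matched to true cells through the segmented nucleus
centroid (which must fall inside the true cell body).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from . import synth
from .pipeline import RunConfig, run_image_pipeline

KO_LIKE_COLOC = 0.79
WT_LIKE_COLOC = 0.08


def segmentation_benchmark_spec(seed: int) -> synth.SceneSpec:
    """The default 30-cell scene condition."""
    return synth.SceneSpec(seed=seed)


def coloc_benchmark_spec(coloc_fraction: float, seed: int) -> synth.SceneSpec:
    """Sparse large-cell condition for colocalization recovery."""
    return synth.SceneSpec(
        field_shape=(20, 384, 384), n_cells=10, cell_radius_vox=32.0,
        nucleus_radius_vox=10.0, z_aspect=0.25,
        puncta_per_cell_green=2.5, puncta_per_cell_red=2.5,
        coloc_fraction=coloc_fraction, seed=seed,
    )


def _match_cells_to_truth(result, truth) -> dict[int, int]:
    """Map segmented cell label -> true cell id via the nucleus centroid."""
    nuclei = result["nuclei"]
    ids = nuclei.label_ids()
    centroids = ndi.center_of_mass(np.ones(nuclei.shape), nuclei.labels, ids)
    mapping = {}
    for lab, (cz, cy, cx) in zip(ids, centroids):
        true_id = int(truth.cells.labels[int(round(cz)), int(round(cy)), int(round(cx))])
        if true_id:
            mapping[int(lab)] = true_id
    return mapping


def scene_recovery(config: RunConfig, spec: synth.SceneSpec, empty_seed: int) -> dict:
    """Run the full pipeline on one scene; score counts against truth.

    Returns exact-count flags plus per-cell absolute puncta-count errors
    for both channels.
    """
    stacks, truth = synth.generate_scene(spec)
    empty = synth.generate_empty_field(
        dataclasses.replace(spec, seed=empty_seed, n_cells=0)
    )
    result = run_image_pipeline(config, stacks, empty)
    mapping = _match_cells_to_truth(result, truth)
    per_cell = result["table"].per_cell.set_index("cell_label")
    out = {
        "n_true": truth.n_cells(),
        "n_nuclei": result["nuclei"].n_objects,
        "n_cells": result["cells"].n_objects,
        "counts_exact": (
            result["nuclei"].n_objects == truth.n_cells()
            and result["cells"].n_objects == truth.n_cells()
        ),
        "abs_errors": [],
        "true_counts": [],
    }
    for ch, col in (("green", "n_green"), ("red", "n_red")):
        true_counts = truth.puncta_counts(ch)
        est = dict.fromkeys(true_counts.index, 0)
        for seg_label, row in per_cell.iterrows():
            true_id = mapping.get(int(seg_label))
            if true_id:
                est[true_id] = int(row[col])
        for cid in true_counts.index:
            out["abs_errors"].append(abs(est[cid] - int(true_counts[cid])))
            out["true_counts"].append(int(true_counts[cid]))
    return out


def coloc_recovery(config: RunConfig, spec: synth.SceneSpec, empty_seed: int) -> dict:
    """Run the pipeline on one scene; compare the recovered green->red
    overlap fraction with the realized planted fraction."""
    stacks, truth = synth.generate_scene(spec)
    empty = synth.generate_empty_field(
        dataclasses.replace(spec, seed=empty_seed, n_cells=0)
    )
    result = run_image_pipeline(config, stacks, empty)
    s = result["table"].field_summary.iloc[0]
    green = truth.puncta[truth.puncta["channel"] == "green"]
    return {
        "overlapping": int(s.total_green_overlapping),
        "total": int(s.total_green),
        "estimate": s.total_green_overlapping / s.total_green if s.total_green else np.nan,
        "truth_pairs": int((green["partner_id"] >= 0).sum()),
        "truth_total": int(len(green)),
        "truth_fraction": truth.realized_coloc_fraction(),
    }


__all__ = [
    "KO_LIKE_COLOC", "WT_LIKE_COLOC",
    "segmentation_benchmark_spec", "coloc_benchmark_spec",
    "scene_recovery", "coloc_recovery",
]
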