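"""Planted-truth evaluation utilities.

Scores a pipeline run on a synthetic ROI against its ground truth: vessel
detection+subtype F1 (greedy centroid matching), cell class recovery, TLS
count error, and relative density errors.  Used by the validation suite and
the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pipeline import PipelineParams, analyze_roi
from .simulate import generate_roi, random_roi_spec


@dataclass
class RoiScore:
    vessel_f1: float
    cell_recovery: float
    tls_count_error: int
    density_rel_errors: list[float]   # per-region total vessel+cell densities


def match_vessels(truth_vessels, detected, max_dist_um: float = 20.0) -> tuple[int, int, int]:
    """Greedy one-to-one matching by centroid distance and subtype equality.

    Returns (true positives, false positives, false negatives).
    """
    used: set[int] = set()
    tp = 0
    for _, row in truth_vessels.iterrows():
        c = (row.center_row_um, row.center_col_um)
        best, best_d = None, max_dist_um
        for j, v in enumerate(detected):
            if j in used or v.subtype.value != row.subtype:
                continue
            d = float(np.hypot(v.centroid_um[0] - c[0], v.centroid_um[1] - c[1]))
            if d < best_d:
                best, best_d = j, d
        if best is not None:
            used.add(best)
            tp += 1
    fp = len(detected) - tp
    fn = len(truth_vessels) - tp
    return tp, fp, fn


def cell_class_recovery(truth_cells, detected, max_dist_um: float = 5.0) -> float:
    """Fraction of planted cells whose nearest detected cell (within
    ``max_dist_um``) carries the planted class."""
    if len(truth_cells) == 0:
        return 1.0
    if not detected:
        return 0.0
    pts = [c.centroid_um for c in detected]
    classes = [c.cell_class for c in detected]
    tree = cKDTree(pts)
    ok = 0
    for _, row in truth_cells.iterrows():
        d, i = tree.query((row.center_row_um, row.center_col_um))
        if d <= max_dist_um and classes[i] == row.cell_class:
            ok += 1
    return ok / len(truth_cells)


def score_planted_roi(seed: int, params: PipelineParams | None = None,
                      **spec_kwargs) -> RoiScore:
    """Generate a random ROI, run the pipeline, score against ground truth."""
    spec = random_roi_spec(seed=seed, **spec_kwargs)
    stack, truth = generate_roi(spec)
    result = analyze_roi(stack, params)

    tp, fp, fn = match_vessels(truth.vessels, result.vessels)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    recovery = cell_class_recovery(truth.cells, result.cells)
    tls_err = abs(len(result.tls) - len(truth.tls))

    density_errors = []
    px2mm2 = (spec.pixel_size / 1000.0) ** 2
    true_areas = {
        "IT": truth.intratumoral.sum() * px2mm2,
        "PT": (truth.tissue & ~truth.intratumoral).sum() * px2mm2,
    }
    det_areas = {
        "IT": result.masks.area_mm2("intratumoral"),
        "PT": result.masks.area_mm2("peritumoral"),
    }
    for region in ("IT", "PT"):
        if true_areas[region] <= 0:
            continue
        true_v = (truth.vessels.region == region).sum() / true_areas[region]
        det_v = sum(1 for v in result.vessels if v.region == region) / det_areas[region]
        true_c = (truth.cells.region == region).sum() / true_areas[region]
        det_c = sum(1 for c in result.cells if c.region == region) / det_areas[region]
        if true_v > 0:
            density_errors.append(abs(det_v - true_v) / true_v)
        if true_c > 0:
            density_errors.append(abs(det_c - true_c) / true_c)
    return RoiScore(
        vessel_f1=f1,
        cell_recovery=recovery,
        tls_count_error=tls_err,
        density_rel_errors=density_errors,
    )
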