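"""End-to-end ROI analysis and run orchestration.

``analyze_roi`` runs region segmentation, vessel and cell analysis, TLS
detection and the spatial summary on one registered stack; ``run_pipeline``
drives a whole run from a structured config (synthetic spec or channel
files), writing every table and a run log with the effective parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import CellParams, cells_to_frame, gate_cells, segment_cells
from .regions import (
    DEFAULT_ASF_RADII,
    DEFAULT_MIN_NEST_AREA_UM2,
    make_region_masks,
    segment_tissue,
    segment_tumor,
)
from .spatial import (
    TLSParams,
    associate_tls_vessels,
    detect_tls,
    summarize_roi,
    tls_to_frame,
)
from .stack import ChannelStack
from .vessels import VesselParams, segment_vessels, vessels_to_frame

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    min_nest_area_um2: float = DEFAULT_MIN_NEST_AREA_UM2
    asf_radii: tuple[int, ...] = DEFAULT_ASF_RADII
    vessel: VesselParams = field(default_factory=VesselParams)
    cell: CellParams = field(default_factory=CellParams)
    tls: TLSParams = field(default_factory=TLSParams)

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineParams":
        params = cls()
        for key, value in (cfg or {}).items():
            if key == "vessel":
                params.vessel = VesselParams(**value)
            elif key == "cell":
                params.cell = CellParams(**value)
            elif key == "tls":
                params.tls = TLSParams(**value)
            elif hasattr(params, key):
                setattr(params, key, value)
            else:
                raise ValueError(f"unknown pipeline parameter {key!r}")
        return params


@dataclass
class RoiResult:
    stack: ChannelStack
    masks: object
    vessel_labels: np.ndarray
    vessels: list
    cells: list
    tls: list
    summary: object


def analyze_roi(stack: ChannelStack, params: PipelineParams | None = None) -> RoiResult:
    """Run the full per-ROI analysis on a registered channel stack."""
    params = params or PipelineParams()
    stack.require("hematoxylin", "S100")
    ps = stack.pixel_size

    tissue = segment_tissue(stack["hematoxylin"], ps)
    it = segment_tumor(
        stack["S100"], ps, tissue=tissue,
        min_nest_area_um2=params.min_nest_area_um2, asf_radii=params.asf_radii,
    )
    masks = make_region_masks(tissue, it, ps)

    labels, vessels = segment_vessels(stack, masks, params.vessel)
    cells = segment_cells(stack, masks, params.cell)
    cells = gate_cells(cells)
    tls = detect_tls(cells, params.tls, masks)
    tls = associate_tls_vessels(tls, vessels, cells, params.tls.assoc_radius_um)
    summary = summarize_roi(stack.roi_id, vessels, cells, masks, tls)
    return RoiResult(
        stack=stack, masks=masks, vessel_labels=labels,
        vessels=vessels, cells=cells, tls=tls, summary=summary,
    )


def write_roi_outputs(result: RoiResult, outdir: str | Path) -> dict[str, Path]:
    """Write the standard per-ROI artifacts (CSV tables + mask TIFFs)."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rid = result.stack.roi_id
    paths = {}

    def _csv(name: str, frame: pd.DataFrame) -> None:
        p = outdir / f"{rid}_{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p

    _csv("vessels", vessels_to_frame(result.vessels))
    _csv("cells", cells_to_frame(result.cells))
    _csv("tls", tls_to_frame(result.tls))
    _csv("summary", pd.DataFrame([result.summary.to_row()]))
    _csv("cell_density", result.summary.cell_density)
    _csv("vessel_density", result.summary.vessel_density)
    _csv("vessel_proportions", result.summary.vessel_proportions)
    for name, mask in (("tissue", result.masks.tissue),
                       ("intratumoral", result.masks.intratumoral),
                       ("peritumoral", result.masks.peritumoral)):
        p = outdir / f"{rid}_mask_{name}.tif"
        tifffile.imwrite(p, (mask.astype(np.uint8) * 255))
        paths[f"mask_{name}"] = p
    p = outdir / f"{rid}_vessel_labels.tif"
    tifffile.imwrite(p, result.vessel_labels.astype(np.int32))
    paths["vessel_labels"] = p
    return paths


def run_pipeline(config: dict, outdir: str | Path) -> pd.DataFrame:
    """Execute a full run from a config dict; returns the per-ROI summary table.

    Config keys:
      ``synthetic``: kwargs of :func:`melvasc.simulate.random_roi_spec`, plus
        optional ``n_rois`` (seeds ``seed .. seed + n_rois - 1``); or
      ``rois``: list of ``{directory, roi_id, pixel_size}`` channel-TIFF inputs;
      ``params``: :class:`PipelineParams` overrides.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = PipelineParams.from_dict(config.get("params", {}))

    stacks: list[ChannelStack] = []
    stage = "inputs"
    try:
        if "synthetic" in config:
            from .simulate import generate_roi, random_roi_spec

            syn = dict(config["synthetic"])
            n_rois = int(syn.pop("n_rois", 1))
            seed = int(syn.pop("seed", 0))
            for i in range(n_rois):
                spec = random_roi_spec(seed=seed + i, **syn)
                stack, truth = generate_roi(spec)
                truth.save(outdir / "truth", prefix=stack.roi_id)
                stacks.append(stack)
        elif "rois" in config:
            for item in config["rois"]:
                stacks.append(ChannelStack.load(
                    item["directory"], item["roi_id"], float(item["pixel_size"])
                ))
        else:
            raise ValueError("config needs a 'synthetic' or 'rois' section")

        rows = []
        for stack in stacks:
            stage = f"analyze:{stack.roi_id}"
            result = analyze_roi(stack, params)
            write_roi_outputs(result, outdir / "roi")
            rows.append(result.summary.to_row())
    except Exception:
        log.error("pipeline failed at stage %s; outputs so far under %s",
                  stage, outdir)
        raise

    summaries = pd.DataFrame(rows)
    summaries.to_csv(outdir / "roi_summaries.csv", index=False)
    run_log = {
        "stage": "complete",
        "n_rois": len(stacks),
        "params": _params_dict(params),
        "config": {k: v for k, v in config.items() if k != "params"},
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return summaries


def _params_dict(params: PipelineParams) -> dict:
    d = asdict(params)
    return d
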