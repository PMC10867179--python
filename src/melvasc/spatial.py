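"""Spatial read-outs: region-stratified densities and proportions, CD8
infiltration classification, TLS detection, and TLS-vessel association.

A tertiary lymphoid structure (TLS) is called by co-aggregation of CD8+ T
cells and CD20+ B cells: single-linkage clustering of the pooled lymphocyte
positions at a linkage radius of tens of micrometers, keeping clusters that
contain minimum numbers of both lineages.  HEV-like (AQP1+MECA79+) and PDPN+
vessels whose centroids fall within an association radius of the cluster's
convex hull are recorded with each TLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point

from .cells import CELL_CLASSES, CellRecord
from .regions import RegionMasks
from .vessels import (
    BLOOD_SUBTYPES,
    LYMPHATIC_SUBTYPES,
    VesselObject,
    VesselSubtype,
)

log = logging.getLogger(__name__)


@dataclass
class TLSParams:
    link_radius_um: float = 50.0
    min_cd8: int = 10
    min_cd20: int = 10
    assoc_radius_um: float = 100.0


@dataclass
class TLSRecord:
    id: int
    cd8_ids: list[int]
    cd20_ids: list[int]
    centroid_um: tuple[float, float]
    radius_um: float                      # max member distance from centroid
    region: str | None
    hev_vessel_ids: list[int] = field(default_factory=list)
    pdpn_vessel_ids: list[int] = field(default_factory=list)

    @property
    def n_cd8(self) -> int:
        return len(self.cd8_ids)

    @property
    def n_cd20(self) -> int:
        return len(self.cd20_ids)


def classify_infiltration(
    cd8_it_density: float,
    cd8_pt_density: float,
    cutoff: float = 1.0,
) -> str:
    """Classify an ROI by its intratumoral:peritumoral CD8 density ratio.

    INFILTRATED when IT:PT >= cutoff (including IT > 0 with PT = 0);
    EXCLUDED otherwise; UNDEFINED when both densities are zero or either
    region is missing.
    """
    it, pt = cd8_it_density, cd8_pt_density
    if it is None or pt is None or np.isnan(it) or np.isnan(pt):
        return "UNDEFINED"
    if it < 0 or pt < 0:
        raise ValueError("densities must be nonnegative")
    if it == 0 and pt == 0:
        return "UNDEFINED"
    if pt == 0:
        return "INFILTRATED"
    return "INFILTRATED" if it / pt >= cutoff else "EXCLUDED"


def detect_tls(
    cells: list[CellRecord],
    params: TLSParams | None = None,
    masks: RegionMasks | None = None,
) -> list[TLSRecord]:
    """Single-linkage co-aggregation detection over CD8_T and B_CELL cells.

    Cells within ``link_radius_um`` of each other (transitively) form a
    cluster; clusters with at least ``min_cd8`` T cells AND ``min_cd20`` B
    cells are emitted as TLS.  The TLS region is taken at its centroid.
    """
    params = params or TLSParams()
    lymphocytes = [c for c in cells if c.cell_class in ("CD8_T", "B_CELL")]
    if not lymphocytes:
        return []
    pts = np.array([c.centroid_um for c in lymphocytes])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(params.link_radius_um, output_type="ndarray")
    n = len(lymphocytes)
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)

    records: list[TLSRecord] = []
    for lab in np.unique(labels):
        members = [lymphocytes[i] for i in np.flatnonzero(labels == lab)]
        cd8 = [c.id for c in members if c.cell_class == "CD8_T"]
        cd20 = [c.id for c in members if c.cell_class == "B_CELL"]
        if len(cd8) < params.min_cd8 or len(cd20) < params.min_cd20:
            continue
        coords = np.array([c.centroid_um for c in members])
        centroid = coords.mean(axis=0)
        radius = float(np.max(np.linalg.norm(coords - centroid, axis=1)))
        region = None
        if masks is not None:
            ps = masks.pixel_size
            r = int(round(centroid[0] / ps))
            c = int(round(centroid[1] / ps))
            r = min(max(r, 0), masks.tissue.shape[0] - 1)
            c = min(max(c, 0), masks.tissue.shape[1] - 1)
            if masks.intratumoral[r, c]:
                region = "IT"
            elif masks.tissue[r, c]:
                region = "PT"
        records.append(TLSRecord(
            id=len(records) + 1,
            cd8_ids=cd8,
            cd20_ids=cd20,
            centroid_um=(float(centroid[0]), float(centroid[1])),
            radius_um=radius,
            region=region,
        ))
    return records


def associate_tls_vessels(
    tls: list[TLSRecord],
    vessels: list[VesselObject],
    cells: list[CellRecord],
    assoc_radius_um: float = 100.0,
) -> list[TLSRecord]:
    """Attach HEV-like and PDPN+ vessels to each TLS (in place).

    A vessel is associated when its centroid lies within ``assoc_radius_um``
    of the convex hull of the TLS member cells.
    """
    cell_by_id = {c.id: c for c in cells}
    for rec in tls:
        member_pts = [cell_by_id[i].centroid_um for i in rec.cd8_ids + rec.cd20_ids
                      if i in cell_by_id]
        if not member_pts:
            continue
        hull = MultiPoint([tuple(p) for p in member_pts]).convex_hull
        rec.hev_vessel_ids = []
        rec.pdpn_vessel_ids = []
        for v in vessels:
            d = hull.distance(Point(v.centroid_um))
            if d <= assoc_radius_um:
                if v.hev_like:
                    rec.hev_vessel_ids.append(v.id)
                if v.positivity.get("PDPN", False):
                    rec.pdpn_vessel_ids.append(v.id)
    return tls


@dataclass
class RoiSummary:
    """All per-ROI quantitative read-outs, flattened by :meth:`to_row`."""

    roi_id: str
    cell_density: pd.DataFrame                  # per class x region
    vessel_density: pd.DataFrame                # per subtype x region (+ total area)
    vessel_proportions: pd.DataFrame            # within blood / lymphatic family
    cd8_it_pt_ratio: float
    infiltration: str
    cd8_cd68_ratio_it: float
    tls: list[TLSRecord]
    n_hev_vessels: int

    def to_row(self) -> dict:
        row = {"roi_id": self.roi_id,
               "cd8_it_pt_ratio": self.cd8_it_pt_ratio,
               "infiltration": self.infiltration,
               "cd8_cd68_ratio_it": self.cd8_cd68_ratio_it,
               "n_tls": len(self.tls),
               "n_hev_vessels": self.n_hev_vessels}
        for _, r in self.cell_density.iterrows():
            row[f"density_{r.cell_class}_{r.region}"] = r.density_per_mm2
        for _, r in self.vessel_density.iterrows():
            row[f"vessel_density_{r.subtype}_{r.region}"] = r.density_per_mm2
        for _, r in self.vessel_proportions.iterrows():
            row[f"vessel_prop_{r.subtype}_{r.region}"] = r.proportion
        return row


def _vessel_tables(
    vessels: list[VesselObject], masks: RegionMasks
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vessel densities (per region + whole tissue) and family proportions."""
    named = list(BLOOD_SUBTYPES) + list(LYMPHATIC_SUBTYPES)
    areas = {
        "IT": masks.area_mm2("intratumoral"),
        "PT": masks.area_mm2("peritumoral"),
        "tissue": masks.area_mm2("tissue"),
    }
    dens_rows, prop_rows = [], []
    for region in ("IT", "PT", "tissue"):
        if region == "tissue":
            pool = [v for v in vessels if v.region in ("IT", "PT")]
        else:
            pool = [v for v in vessels if v.region == region]
        fam_counts = {
            "blood": sum(1 for v in pool if v.subtype in BLOOD_SUBTYPES),
            "lymphatic": sum(1 for v in pool if v.subtype in LYMPHATIC_SUBTYPES),
        }
        for st in named:
            n = sum(1 for v in pool if v.subtype == st)
            area = areas[region]
            dens_rows.append({
                "region": region, "subtype": st.value, "count": n,
                "density_per_mm2": n / area if area > 0 else np.nan,
            })
            fam = "blood" if st in BLOOD_SUBTYPES else "lymphatic"
            prop_rows.append({
                "region": region, "subtype": st.value, "family": fam,
                "proportion": n / fam_counts[fam] if fam_counts[fam] > 0 else np.nan,
            })
        for fam, n in fam_counts.items():
            area = areas[region]
            dens_rows.append({
                "region": region, "subtype": f"total_{fam}", "count": n,
                "density_per_mm2": n / area if area > 0 else np.nan,
            })
    return pd.DataFrame(dens_rows), pd.DataFrame(prop_rows)


def summarize_roi(
    roi_id: str,
    vessels: list[VesselObject],
    cells: list[CellRecord],
    masks: RegionMasks,
    tls: list[TLSRecord],
) -> RoiSummary:
    """Assemble the full per-ROI summary from the upstream tables."""
    from .cells import cell_densities

    cdens = cell_densities(cells, masks)
    vdens, vprop = _vessel_tables(vessels, masks)

    def density(cls: str, region: str) -> float:
        sel = cdens[(cdens.cell_class == cls) & (cdens.region == region)]
        return float(sel.density_per_mm2.iloc[0]) if len(sel) else np.nan

    cd8_it = density("CD8_T", "IT")
    cd8_pt = density("CD8_T", "PT")
    if cd8_pt and not np.isnan(cd8_pt) and cd8_pt > 0:
        ratio = cd8_it / cd8_pt
    elif cd8_it and not np.isnan(cd8_it) and cd8_it > 0:
        ratio = np.inf
    else:
        ratio = np.nan
    infiltration = classify_infiltration(cd8_it, cd8_pt)

    mac_it = density("MACROPHAGE", "IT")
    if mac_it and not np.isnan(mac_it) and mac_it > 0 and not np.isnan(cd8_it):
        cd8_cd68 = cd8_it / mac_it
    else:
        cd8_cd68 = np.nan

    return RoiSummary(
        roi_id=roi_id,
        cell_density=cdens,
        vessel_density=vdens,
        vessel_proportions=vprop,
        cd8_it_pt_ratio=float(ratio),
        infiltration=infiltration,
        cd8_cd68_ratio_it=float(cd8_cd68),
        tls=tls,
        n_hev_vessels=sum(1 for v in vessels if v.hev_like),
    )


def tls_to_frame(tls: list[TLSRecord]) -> pd.DataFrame:
    rows = [{
        "id": t.id, "n_cd8": t.n_cd8, "n_cd20": t.n_cd20,
        "centroid_row_um": t.centroid_um[0], "centroid_col_um": t.centroid_um[1],
        "radius_um": t.radius_um, "region": t.region,
        "n_hev_vessels": len(t.hev_vessel_ids),
        "n_pdpn_vessels": len(t.pdpn_vessel_ids),
        "hev_vessel_ids": ";".join(map(str, t.hev_vessel_ids)),
        "pdpn_vessel_ids": ";".join(map(str, t.pdpn_vessel_ids)),
    } for t in tls]
    return pd.DataFrame(rows)
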