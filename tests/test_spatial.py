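"""Infiltration classification, TLS detection/association, ROI summaries."""

import numpy as np
import pytest

from melvasc.cells import CellRecord
from melvasc.spatial import (
    TLSParams,
    associate_tls_vessels,
    classify_infiltration,
    detect_tls,
    summarize_roi,
)


def lymphocyte(i, y, x, cls="CD8_T"):
    rec = CellRecord(id=i, centroid_px=(y, x), centroid_um=(y, x),
                     nucleus_area_um2=40.0, mean_intensity={})
    rec.cell_class = cls
    rec.region = "PT"
    return rec


@pytest.mark.parametrize("it,pt,expected", [
    (10.0, 5.0, "INFILTRATED"),
    (0.0, 8.0, "EXCLUDED"),
    (0.0, 0.0, "UNDEFINED"),
    (5.0, 0.0, "INFILTRATED"),
    (np.nan, 3.0, "UNDEFINED"),
    (1.0, 1.0, "INFILTRATED"),     # ratio exactly at the default cutoff
])
def test_infiltration_rules(it, pt, expected):
    assert classify_infiltration(it, pt) == expected


def test_infiltration_scale_invariance(rng):
    for _ in range(20):
        it, pt = rng.uniform(0.1, 100, 2)
        s = rng.uniform(0.01, 100)
        assert classify_infiltration(it, pt) == classify_infiltration(s * it, s * pt)


def brute_force_clusters(points, radius):
    """Connected components of the pairwise-distance graph by direct search."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(points[i][0] - points[j][0],
                        points[i][1] - points[j][1]) <= radius:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def test_single_linkage_matches_brute_force(rng):
    cells = [lymphocyte(i, *rng.uniform(0, 500, 2),
                        cls=rng.choice(["CD8_T", "B_CELL"]))
             for i in range(150)]
    params = TLSParams(link_radius_um=40.0, min_cd8=1, min_cd20=0)
    records = detect_tls(cells, params)
    detected = {frozenset(r.cd8_ids + r.cd20_ids) for r in records}
    pts = [c.centroid_um for c in cells]
    expected = set()
    for group in brute_force_clusters(pts, 40.0):
        ids = frozenset(cells[i].id for i in group)
        cd8 = sum(cells[i].cell_class == "CD8_T" for i in group)
        if cd8 >= 1:
            expected.add(ids)
    assert detected == expected


def test_planted_aggregate_detected_once(rng):
    cells = []
    i = 0
    for _ in range(20):
        r, a = 100 * np.sqrt(rng.uniform()), rng.uniform(0, 2 * np.pi)
        cells.append(lymphocyte(i, 500 + r * np.sin(a), 500 + r * np.cos(a))); i += 1
    for _ in range(30):
        r, a = 100 * np.sqrt(rng.uniform()), rng.uniform(0, 2 * np.pi)
        cells.append(lymphocyte(i, 500 + r * np.sin(a), 500 + r * np.cos(a),
                                "B_CELL")); i += 1
    tls = detect_tls(cells)
    assert len(tls) == 1
    assert tls[0].n_cd8 == 20 and tls[0].n_cd20 == 30
    assert tls[0].radius_um <= 110


def test_sparse_scatter_yields_no_tls(rng):
    # 200 lymphocytes with hard-core spacing above the linkage radius
    pts = []
    while len(pts) < 200:
        p = rng.uniform(0, 2000, 2)
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) > 55 for q in pts):
            pts.append(p)
    cells = [lymphocyte(i, *p, cls="CD8_T" if i % 2 else "B_CELL")
             for i, p in enumerate(pts)]
    assert detect_tls(cells) == []


def test_tls_requires_co_aggregation(rng):
    cells = [lymphocyte(i, 500 + rng.uniform(-50, 50), 500 + rng.uniform(-50, 50))
             for i in range(30)]   # CD8 only
    assert detect_tls(cells) == []


def test_tls_membership_monotone_in_link_radius(rng):
    cells = []
    for i in range(40):
        cells.append(lymphocyte(i, *rng.uniform(0, 300, 2),
                                cls="CD8_T" if i % 2 else "B_CELL"))
    small = detect_tls(cells, TLSParams(link_radius_um=30, min_cd8=2, min_cd20=2))
    large = detect_tls(cells, TLSParams(link_radius_um=60, min_cd8=2, min_cd20=2))
    for rec in small:
        members = set(rec.cd8_ids + rec.cd20_ids)
        # every small-radius cluster is contained in one large-radius cluster
        assert any(members <= set(big.cd8_ids + big.cd20_ids) for big in large) \
            or all(len(members) > len(set(b.cd8_ids + b.cd20_ids)) for b in large)


class _FakeVessel:
    def __init__(self, vid, y, x, hev=False, pdpn=False):
        self.id = vid
        self.centroid_um = (y, x)
        self.hev_like = hev
        self.positivity = {"PDPN": pdpn}


def test_vessel_association_by_hull_distance(rng):
    cells = []
    for i in range(12):
        cells.append(lymphocyte(i, 100 + 10 * (i % 4), 100 + 10 * (i // 4)))
    for i in range(12, 24):
        cells.append(lymphocyte(i, 100 + 10 * (i % 4), 100 + 10 * ((i - 12) // 4),
                                "B_CELL"))
    tls = detect_tls(cells, TLSParams(link_radius_um=30, min_cd8=10, min_cd20=10))
    assert len(tls) == 1
    vessels = [
        _FakeVessel(1, 140, 120, hev=True),    # ~20 um from the hull
        _FakeVessel(2, 600, 600, hev=True),    # 500 um away
        _FakeVessel(3, 150, 110, pdpn=True),
    ]
    associate_tls_vessels(tls, vessels, cells, assoc_radius_um=100.0)
    assert tls[0].hev_vessel_ids == [1]
    assert tls[0].pdpn_vessel_ids == [3]


def test_summary_proportions_and_ratios(small_roi_result):
    s = small_roi_result.summary
    assert s.infiltration in ("INFILTRATED", "EXCLUDED", "UNDEFINED")
    assert np.isnan(s.cd8_it_pt_ratio) or s.cd8_it_pt_ratio >= 0
    # zero-vessel families are missing, not 0/0
    props = s.vessel_proportions
    for _, row in props.iterrows():
        assert np.isnan(row.proportion) or 0 <= row.proportion <= 1


def test_summary_densities_match_truth(small_roi, small_roi_result):
    _, _, truth = small_roi
    res = small_roi_result
    true_tissue_mm2 = truth.tissue.sum() * 1e-6
    true_total_density = len(truth.vessels) / true_tissue_mm2
    vd = res.summary.vessel_density
    det = vd[(vd.region == "tissue") & (vd.subtype.isin(
        ["total_blood", "total_lymphatic"]))]["count"].sum()
    det_area = res.masks.area_mm2("tissue")
    assert det / det_area == pytest.approx(true_total_density, rel=0.05)
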