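"""Nucleus segmentation, leukocyte gating, and density read-outs."""

import numpy as np
import pytest

from melvasc.cells import (
    CellParams,
    CellRecord,
    cell_densities,
    gate_cells,
    segment_cells,
)
from melvasc.regions import make_region_masks
from melvasc.stack import ChannelStack


def _nuclei_stack(centers, n=300, radius=5, rng=None, extra_channels=()):
    rng = rng or np.random.default_rng(2)
    channels = {"hematoxylin": np.abs(rng.normal(0.05, 0.05, (n, n)))}
    for m in extra_channels:
        channels[m] = np.abs(rng.normal(0.05, 0.05, (n, n)))
    yy, xx = np.mgrid[0:n, 0:n]
    for cy, cx in centers:
        channels["hematoxylin"][(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = 0.55
    return ChannelStack(channels=channels, pixel_size=1.0, roi_id="c")


def test_planted_nonoverlapping_nuclei_all_detected(rng):
    centers = []
    while len(centers) < 50:
        p = rng.integers(20, 280, 2)
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) > 16 for q in centers):
            centers.append(tuple(p))
    stack = _nuclei_stack(centers)
    cells = segment_cells(stack)
    assert len(cells) == 50


def test_empty_image_zero_cells():
    stack = ChannelStack(channels={"hematoxylin": np.zeros((50, 50))},
                         pixel_size=1.0, roi_id="e")
    assert segment_cells(stack) == []


def test_touching_nuclei_split_by_watershed():
    # two overlapping discs, centers a bit over one radius apart
    stack = _nuclei_stack([(100, 100), (100, 112)], radius=10,
                          rng=np.random.default_rng(3))
    cells = segment_cells(stack, params=CellParams(peak_min_distance_um=5.0,
                                                   tophat_radius_um=14.0))
    assert len(cells) == 2


def _cell(i, **means):
    base = {"CD45": 0.0, "CD8": 0.0, "CD20": 0.0, "CD68": 0.0, "S100": 0.0}
    base.update(means)
    return CellRecord(id=i, centroid_px=(0, 0), centroid_um=(0, 0),
                      nucleus_area_um2=50.0, mean_intensity=base)


def test_gate_examples_with_explicit_thresholds():
    thr = {"CD45": 0.2, "CD8": 0.2, "CD20": 0.2, "CD68": 0.2}
    cells = [
        _cell(1, CD45=0.5, CD8=0.5),              # CD8 T cell
        _cell(2, CD45=0.05, CD68=0.5),            # macrophage despite weak CD45
        _cell(3),                                 # all zero
        _cell(4, CD45=0.5, CD20=0.5),             # B cell
        _cell(5, CD45=0.5),                       # other leukocyte
        _cell(6, CD8=0.5),                        # CD8 without CD45: not a T cell
    ]
    gate_cells(cells, thr)
    assert [c.cell_class for c in cells] == [
        "CD8_T", "MACROPHAGE", "NON_LEUKOCYTE", "B_CELL", "OTHER_CD45",
        "NON_LEUKOCYTE",
    ]


def test_multi_lineage_positive_resolved_by_intensity():
    thr = {"CD45": 0.2, "CD8": 0.2, "CD20": 0.2, "CD68": 0.2}
    cells = [_cell(i, CD45=0.5, CD8=0.25, CD68=0.02) for i in range(1, 20)]
    cells.append(_cell(99, CD45=0.5, CD8=0.25, CD68=0.9))
    gate_cells(cells, thr)
    assert cells[-1].cell_class == "MACROPHAGE"
    assert cells[0].cell_class == "CD8_T"


def test_derived_thresholds_silent_on_unstained_marker(rng):
    # CD20 has no positive population: nobody should gate as B cell
    cells = []
    for i in range(200):
        cd45 = 0.5 if i < 100 else 0.03
        cells.append(_cell(i, CD45=cd45 + rng.normal(0, 0.01),
                           CD20=abs(rng.normal(0.03, 0.01))))
    gate_cells(cells)
    assert sum(c.cell_class == "B_CELL" for c in cells) == 0
    assert sum(c.cell_class == "OTHER_CD45" for c in cells) == 100


def test_class_partition_conserves_counts(small_roi_result):
    cells = small_roi_result.cells
    classes = [c.cell_class for c in cells]
    assert "UNGATED" not in classes
    assert len(cells) == sum(
        classes.count(k)
        for k in ("CD8_T", "B_CELL", "MACROPHAGE", "OTHER_CD45", "NON_LEUKOCYTE")
    )


def test_densities_and_missing_region():
    tissue = np.ones((100, 100), dtype=bool)
    it = np.zeros((100, 100), dtype=bool)
    it[:, :50] = True
    masks = make_region_masks(tissue, it, pixel_size=20.0)   # IT area = 2 mm^2
    cells = []
    for i in range(10):
        c = _cell(i, CD45=1, CD8=1)
        c.cell_class = "CD8_T"
        c.region = "IT"
        cells.append(c)
    dens = cell_densities(cells, masks)
    it_cd8 = dens[(dens.region == "IT") & (dens.cell_class == "CD8_T")]
    assert it_cd8.density_per_mm2.iloc[0] == pytest.approx(5.0)
    assert dens["count"].sum() == 10

    empty = make_region_masks(np.zeros((10, 10), bool), np.zeros((10, 10), bool), 1.0)
    dens0 = cell_densities(cells, empty)
    assert dens0.density_per_mm2.isna().all()


def test_density_scale_invariance(small_roi):
    """Same physical layout at doubled pixel size gives the same densities."""
    from melvasc.pipeline import analyze_roi
    from melvasc.simulate import generate_roi, random_roi_spec

    spec_hi = random_roi_spec(seed=21, shape=(600, 600), pixel_size=1.0,
                              n_vessels=8, n_cells=100, n_tls=0)
    spec_lo = random_roi_spec(seed=21, shape=(300, 300), pixel_size=2.0,
                              n_vessels=8, n_cells=100, n_tls=0)
    # identical seeds give identical physical layouts
    assert spec_hi.cells[0].center_um == spec_lo.cells[0].center_um

    res_hi = analyze_roi(generate_roi(spec_hi)[0])
    res_lo = analyze_roi(generate_roi(spec_lo)[0])
    d_hi = res_hi.summary.cell_density
    d_lo = res_lo.summary.cell_density
    for region in ("IT", "PT"):
        n_hi = d_hi[d_hi.region == region]["count"].sum()
        n_lo = d_lo[d_lo.region == region]["count"].sum()
        assert abs(n_hi - n_lo) <= 0.05 * max(n_hi, 1)
        a_hi = d_hi[d_hi.region == region].area_mm2.iloc[0]
        a_lo = d_lo[d_lo.region == region].area_mm2.iloc[0]
        assert a_lo == pytest.approx(a_hi, rel=0.05)


def test_planted_class_proportions_recovered(small_roi, small_roi_result):
    _, _, truth = small_roi
    cells = small_roi_result.cells
    n = len(truth.cells)
    for cls in ("CD8_T", "B_CELL", "MACROPHAGE"):
        true_n = (truth.cells.cell_class == cls).sum()
        det_n = sum(c.cell_class == cls for c in cells)
        # binomial-scale tolerance
        assert abs(det_n - true_n) <= max(3, 2 * np.sqrt(true_n))
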