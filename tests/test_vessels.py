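"""Vessel gating truth table, morphology, preprocessing, and segmentation."""

import itertools

import numpy as np
import pytest

from melvasc.regions import make_region_masks
from melvasc.stack import ChannelStack
from melvasc.vessels import (
    VesselParams,
    VesselSubtype,
    assign_region,
    classify_vessel,
    compute_morphology,
    preprocess_channel,
    segment_vessels,
)


def hand_gate(aqp1, cd34, asma, pdpn, lyve1, panck, meca79):
    """Independently hand-enumerated gate (blood branch first, then lymphatic,
    everything else anomalous)."""
    if aqp1:
        if cd34 and asma:
            return VesselSubtype.IMMATURE_NEOVASC, meca79
        if cd34 and not asma:
            return VesselSubtype.ACTIVATED_CAP_PCV, meca79
        if not cd34 and asma:
            return VesselSubtype.ARTERIOLE, meca79
        return VesselSubtype.REJECTED_SINGLE_CELL, meca79
    if pdpn:
        return (VesselSubtype.LYMPHATIC_CAP if lyve1
                else VesselSubtype.INFLAMED_LYMPHATIC_CAP), False
    return VesselSubtype.UNCLASSIFIED_ANOMALY, False


def test_gate_truth_table_all_combinations():
    markers = ("AQP1", "CD34", "aSMA", "PDPN", "LYVE1", "panCK")
    for combo in itertools.product([False, True], repeat=6):
        for meca in (False, True):
            profile = dict(zip(markers, combo))
            profile["MECA79"] = meca
            assert classify_vessel(profile) == hand_gate(*combo, meca)


@pytest.mark.parametrize("profile,expected", [
    ({"AQP1": True, "CD34": True}, VesselSubtype.ACTIVATED_CAP_PCV),
    ({"PDPN": True}, VesselSubtype.INFLAMED_LYMPHATIC_CAP),
    ({"AQP1": True}, VesselSubtype.REJECTED_SINGLE_CELL),
    ({}, VesselSubtype.UNCLASSIFIED_ANOMALY),
    ({"LYVE1": True}, VesselSubtype.UNCLASSIFIED_ANOMALY),
])
def test_gate_named_examples(profile, expected):
    assert classify_vessel(profile)[0] == expected


def test_gate_partitions_and_counts(small_roi_result):
    vessels = small_roi_result.vessels
    by_subtype = {}
    for v in vessels:
        by_subtype[v.subtype] = by_subtype.get(v.subtype, 0) + 1
    assert sum(by_subtype.values()) == len(vessels)


def _disk_mask(n, r, cy=None, cx=None):
    cy = cy if cy is not None else n // 2
    cx = cx if cx is not None else n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def test_morphology_solid_disc():
    m = compute_morphology(_disk_mask(64, 20), pixel_size=1.0)
    assert m.area_um2 == pytest.approx(np.pi * 400, rel=0.02)
    assert m.eccentricity < 0.1
    assert m.lumen_area_um2 < 0.02 * m.area_um2
    assert 0.9 < m.form_factor <= 1.1
    assert m.solidity > 0.95


def test_morphology_annulus_lumen():
    ring = _disk_mask(64, 20) & ~_disk_mask(64, 10)
    m = compute_morphology(ring, pixel_size=1.0)
    assert m.lumen_area_um2 == pytest.approx(np.pi * 100, rel=0.05)
    assert m.filled_area_um2 == pytest.approx(np.pi * 400, rel=0.02)


def test_morphology_line_eccentricity():
    line = np.zeros((110, 110), dtype=bool)
    line[50, 5:105] = True
    assert compute_morphology(line, 1.0).eccentricity > 0.99


def test_morphology_scales_with_pixel_size():
    m1 = compute_morphology(_disk_mask(64, 20), 1.0)
    m2 = compute_morphology(_disk_mask(64, 20), 2.0)
    assert m2.area_um2 == pytest.approx(4 * m1.area_um2)
    assert m2.perimeter_um == pytest.approx(2 * m1.perimeter_um)
    assert m2.form_factor == pytest.approx(m1.form_factor)


def test_morphology_empty_raises():
    with pytest.raises(ValueError):
        compute_morphology(np.zeros((5, 5), dtype=bool), 1.0)


def test_preprocess_flat_field_zeroed():
    out = preprocess_channel(np.full((64, 64), 0.3))
    assert np.allclose(out, 0.0)


def test_preprocess_removes_gradient_keeps_vessel():
    n = 200
    yy, xx = np.mgrid[0:n, 0:n]
    gradient = 0.3 * xx / n
    ring = (_disk_mask(n, 20) & ~_disk_mask(n, 14)).astype(float)
    channel = gradient + 0.5 * ring
    out = preprocess_channel(channel, median_radius_px=0, tophat_radius_px=15)
    ring_mask = ring > 0
    vessel_contrast = out[ring_mask].mean() - np.median(out[~ring_mask])
    assert abs(vessel_contrast - 0.5) < 0.05          # contrast preserved
    far = out[(xx > 150) & ~ring_mask]
    assert np.median(far) < 0.02                      # gradient flattened


def test_assign_region_rules():
    tissue = np.ones((20, 20), dtype=bool)
    it = np.zeros((20, 20), dtype=bool)
    it[:, :10] = True
    masks = make_region_masks(tissue, it, 1.0)

    inside = np.zeros((20, 20), dtype=bool)
    inside[5:8, 2:5] = True
    assert assign_region(inside, masks) == "IT"

    obj = np.zeros((20, 20), dtype=bool)
    obj[5, 6:16] = True                  # 40% in IT
    assert assign_region(obj, masks) == "PT"

    tie = np.zeros((20, 20), dtype=bool)
    tie[5, 5:15] = True                  # exactly 50% -> PT
    assert assign_region(tie, masks) == "PT"

    outside = np.zeros((20, 20), dtype=bool)
    outside[0, 0] = True
    empty_tissue = make_region_masks(np.zeros((20, 20), bool),
                                     np.zeros((20, 20), bool), 1.0)
    assert assign_region(outside, empty_tissue) is None


def _vessel_stack(extra=None, n=320):
    """Tiny ROI with two planted annuli (one blood, one lymphatic)."""
    rng = np.random.default_rng(11)
    channels = {m: np.abs(rng.normal(0.05, 0.05, (n, n)))
                for m in ("AQP1", "CD34", "aSMA", "PDPN", "LYVE1", "MECA79",
                          "panCK", "hematoxylin", "S100")}
    ring1 = _disk_mask(n, 25, 80, 80) & ~_disk_mask(n, 18, 80, 80)
    ring2 = _disk_mask(n, 22, 220, 220) & ~_disk_mask(n, 16, 220, 220)
    for m in ("AQP1", "CD34"):
        channels[m][ring1] = 0.55
    for m in ("PDPN",):
        channels[m][ring2] = 0.55
    if extra:
        extra(channels)
    stack = ChannelStack(channels=channels, pixel_size=1.0, roi_id="v")
    masks = make_region_masks(np.ones((n, n), bool), np.zeros((n, n), bool), 1.0)
    return stack, masks


def test_segment_vessels_planted_annuli_recovered():
    stack, masks = _vessel_stack()
    labels, objs = segment_vessels(stack, masks)
    assert len(objs) == 2
    subtypes = {o.subtype for o in objs}
    assert subtypes == {VesselSubtype.ACTIVATED_CAP_PCV,
                        VesselSubtype.INFLAMED_LYMPHATIC_CAP}
    for o in objs:
        true_area = np.pi * (25**2 - 18**2) if \
            o.subtype is VesselSubtype.ACTIVATED_CAP_PCV else np.pi * (22**2 - 16**2)
        assert o.morphology.area_um2 == pytest.approx(true_area, rel=0.10)


def test_panck_ribbon_excluded_pdpn_vessel_retained():
    def add_ribbon(channels):
        channels["PDPN"][280:300, 20:300] = 0.55
        channels["panCK"][280:300, 20:300] = 0.55

    stack, masks = _vessel_stack(add_ribbon)
    _, objs = segment_vessels(stack, masks)
    # ribbon removed; the PDPN+panCK- annulus survives
    pdpn_objs = [o for o in objs if o.positivity.get("PDPN")]
    assert len(pdpn_objs) == 1
    assert pdpn_objs[0].morphology.eccentricity < 0.8


def test_small_speck_removed_by_area_filter():
    def add_speck(channels):
        channels["AQP1"][10:14, 10:15] = 0.55     # 20 um^2

    stack, masks = _vessel_stack(add_speck)
    _, objs = segment_vessels(stack, masks, VesselParams(min_area_um2=100))
    assert len(objs) == 2


def test_size_filter_monotonicity():
    stack, masks = _vessel_stack()
    wide = segment_vessels(stack, masks, VesselParams(min_area_um2=50,
                                                      max_area_um2=1e6))[1]
    narrow = segment_vessels(stack, masks, VesselParams(min_area_um2=800,
                                                        max_area_um2=1000))[1]
    assert len(narrow) <= len(wide)


def test_missing_channel_error_names_it():
    stack, masks = _vessel_stack()
    del stack.channels["CD34"]
    with pytest.raises(KeyError, match="CD34"):
        segment_vessels(stack, masks)


def test_family_proportions_sum_to_one(small_roi_result):
    props = small_roi_result.summary.vessel_proportions
    for (region, family), grp in props.groupby(["region", "family"]):
        total = grp.proportion.sum()
        if not np.isnan(total):
            assert total == pytest.approx(1.0, abs=1e-9)
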