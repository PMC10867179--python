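"""Vessel segmentation, hierarchical subtype gating, and morphology.

Candidate vascular objects are segmented from the union of the AQP1, CD34 and
PDPN channels after denoising and local background flattening (white
top-hat), binarized per channel with Otsu's rule, size-filtered, and purged
of PDPN+ basal epithelium via panCK coverage.  Surviving objects carry a
per-marker positive-pixel-coverage and mean-intensity profile and are gated
into five lymphovascular subtypes:

    blood (AQP1+):      CD34+ aSMA+  immature neovasculature
                        CD34+ aSMA-  activated capillary / postcapillary venule
                        CD34- aSMA+  arteriole
                        CD34- aSMA-  rejected (single AQP1+ tumor cell)
    lymphatic (PDPN+):  LYVE1+       lymphatic capillary
                        LYVE1-       inflamed lymphatic capillary

MECA79 positivity on an AQP1+ vessel flags it as HEV-like; it is a
cross-cutting flag, not a sixth exclusive class, because HEV-like vessels are
tabulated across the AQP1+ subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import disk, white_tophat

from .panel import (
    VESSEL_PROFILE_MARKERS,
    VESSEL_SEGMENTATION_MARKERS,
)
from .regions import RegionMasks
from .stack import ChannelStack
from .thresholds import otsu_threshold_image, robust_floor

log = logging.getLogger(__name__)


class VesselSubtype(str, Enum):
    """Exhaustive, mutually exclusive lymphovascular subtype gate outcomes."""

    IMMATURE_NEOVASC = "immature_neovasculature"          # AQP1+ CD34+ aSMA+
    ACTIVATED_CAP_PCV = "activated_capillary_pcv"         # AQP1+ CD34+ aSMA-
    ARTERIOLE = "arteriole"                               # AQP1+ CD34- aSMA+
    LYMPHATIC_CAP = "lymphatic_capillary"                 # PDPN+ LYVE1+
    INFLAMED_LYMPHATIC_CAP = "inflamed_lymphatic_capillary"  # PDPN+ LYVE1-
    REJECTED_SINGLE_CELL = "rejected_single_cell"         # AQP1+ CD34- aSMA-
    UNCLASSIFIED_ANOMALY = "unclassified_anomaly"


#: The three blood subtypes (AQP1+ family) and two lymphatic subtypes
#: (PDPN+ family) over which proportions are reported.
BLOOD_SUBTYPES = (
    VesselSubtype.IMMATURE_NEOVASC,
    VesselSubtype.ACTIVATED_CAP_PCV,
    VesselSubtype.ARTERIOLE,
)
LYMPHATIC_SUBTYPES = (
    VesselSubtype.LYMPHATIC_CAP,
    VesselSubtype.INFLAMED_LYMPHATIC_CAP,
)


@dataclass(frozen=True)
class MorphologyFeatures:
    """Shape descriptors of one vessel object (physical units)."""

    area_um2: float
    filled_area_um2: float
    lumen_area_um2: float          # filled - wall: open lumen area
    perimeter_um: float
    eccentricity: float            # [0, 1)
    solidity: float                # (0, 1]
    form_factor: float             # 4*pi*area / perimeter^2


@dataclass
class VesselObject:
    """A labeled multicellular vascular structure."""

    id: int
    centroid_px: tuple[float, float]
    region: str | None                       # "IT" | "PT" | None (outside tissue)
    coverage: dict[str, float]               # positive-pixel fraction per marker
    mean_intensity: dict[str, float]
    positivity: dict[str, bool]
    subtype: VesselSubtype
    hev_like: bool
    morphology: MorphologyFeatures

    @property
    def centroid_um(self) -> tuple[float, float]:
        return self._centroid_um

    def set_centroid_um(self, pixel_size: float) -> None:
        self._centroid_um = (
            self.centroid_px[0] * pixel_size,
            self.centroid_px[1] * pixel_size,
        )


@dataclass
class VesselParams:
    """Tunable parameters of vessel segmentation and gating.

    Positivity of a marker on an object requires coverage (fraction of object
    pixels above the channel threshold) of at least ``coverage_min`` AND an
    object mean of at least ``intensity_factor`` times the channel threshold.
    """

    min_area_um2: float = 100.0        # excludes single cells / debris
    max_area_um2: float = 1.0e6        # excludes scan artifacts
    coverage_min: float = 0.10
    intensity_factor: float = 0.5
    panck_exclusion_coverage: float = 0.30
    median_radius_px: int = 1
    tophat_radius_px: int = 15
    nbins: int = 256


def classify_vessel(positivity: Mapping[str, bool]) -> tuple[VesselSubtype, bool]:
    """Hierarchical subtype gate on a per-marker positivity profile.

    Gate order: AQP1 first (blood branch, split on CD34/aSMA; the HEV-like
    flag is MECA79 positivity), else PDPN (lymphatic branch, split on LYVE1),
    else anomaly.  Isolated LYVE1+ panCK- structures fall through to the
    anomaly class as well (none are expected on real tissue).  An object
    positive for both AQP1 and PDPN follows the blood branch and is logged.
    """
    aqp1 = bool(positivity.get("AQP1", False))
    pdpn = bool(positivity.get("PDPN", False))
    if aqp1 and pdpn:
        log.info("object positive for both AQP1 and PDPN; taking blood branch")
    if aqp1:
        cd34 = bool(positivity.get("CD34", False))
        asma = bool(positivity.get("aSMA", False))
        hev = bool(positivity.get("MECA79", False))
        if cd34 and asma:
            return VesselSubtype.IMMATURE_NEOVASC, hev
        if cd34:
            return VesselSubtype.ACTIVATED_CAP_PCV, hev
        if asma:
            return VesselSubtype.ARTERIOLE, hev
        return VesselSubtype.REJECTED_SINGLE_CELL, hev
    if pdpn:
        if bool(positivity.get("LYVE1", False)):
            return VesselSubtype.LYMPHATIC_CAP, False
        return VesselSubtype.INFLAMED_LYMPHATIC_CAP, False
    return VesselSubtype.UNCLASSIFIED_ANOMALY, False


def preprocess_channel(
    channel: np.ndarray,
    median_radius_px: int = 1,
    tophat_radius_px: int = 15,
) -> np.ndarray:
    """Denoise (median) and locally flatten (white top-hat) a channel.

    The top-hat structuring element must be wider than a vessel wall so that
    walls survive while smooth illumination/background gradients are removed;
    its radius is a free parameter of the workflow.  Output is nonnegative.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if np.any(channel < 0):
        raise ValueError("channel must be nonnegative")
    out = channel
    if median_radius_px > 0:
        out = ndi.median_filter(out, footprint=disk(median_radius_px))
    if tophat_radius_px > 0:
        se = disk(tophat_radius_px, decomposition="sequence")
        out = white_tophat(out, se)
    return np.clip(out, 0.0, None)


def compute_morphology(mask: np.ndarray, pixel_size: float) -> MorphologyFeatures:
    """Morphology of a single connected object given as a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty pixel set")
    props = regionprops(mask.astype(np.uint8))[0]
    area_px = float(props.area)
    filled_px = float(props.area_filled)
    perim_px = float(props.perimeter)
    ps2 = pixel_size**2
    return MorphologyFeatures(
        area_um2=area_px * ps2,
        filled_area_um2=filled_px * ps2,
        lumen_area_um2=(filled_px - area_px) * ps2,
        perimeter_um=perim_px * pixel_size,
        eccentricity=float(props.eccentricity),
        solidity=float(props.solidity),
        form_factor=(4.0 * np.pi * area_px / perim_px**2) if perim_px > 0 else np.nan,
    )


def assign_region(object_mask: np.ndarray, masks: RegionMasks) -> str | None:
    """IT if strictly more than half the object's pixels lie in the IT mask,
    else PT; ``None`` (excluded, logged by the caller) when the object lies
    entirely outside tissue."""
    object_mask = np.asarray(object_mask, dtype=bool)
    n = int(object_mask.sum())
    if n == 0:
        raise ValueError("empty object")
    if not masks.tissue[object_mask].any():
        return None
    frac_it = float(masks.intratumoral[object_mask].sum()) / n
    return "IT" if frac_it > 0.5 else "PT"


def channel_threshold(channel: np.ndarray, nbins: int = 256) -> float:
    """Data-driven positivity threshold for one channel.

    Otsu's rule, floored by a robust background ceiling (median + 3 scaled
    MADs) so that channels whose marker is absent from the ROI do not get a
    threshold inside the noise band.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.max() == channel.min():
        return float(channel.max())
    return max(otsu_threshold_image(channel, nbins), robust_floor(channel))


def segment_vessels(
    stack: ChannelStack,
    masks: RegionMasks,
    params: VesselParams | None = None,
) -> tuple[np.ndarray, list[VesselObject]]:
    """Segment and gate vascular objects in a registered ROI.

    Returns the label image (surviving objects only, 8-connectivity) and the
    gated :class:`VesselObject` list.  Objects entirely outside tissue are
    excluded and logged, as are PDPN+ objects removed by the panCK epithelium
    rule.
    """
    params = params or VesselParams()
    stack.require(*VESSEL_SEGMENTATION_MARKERS)
    ps = stack.pixel_size

    present = [m for m in VESSEL_PROFILE_MARKERS if m in stack]
    pre = {
        m: preprocess_channel(stack[m], params.median_radius_px, params.tophat_radius_px)
        for m in present
    }
    thr = {m: channel_threshold(pre[m], params.nbins) for m in present}

    fg = np.zeros(stack.shape, dtype=bool)
    for m in VESSEL_SEGMENTATION_MARKERS:
        fg |= pre[m] > thr[m]
    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels, []

    objects: list[VesselObject] = []
    slices = ndi.find_objects(labels)
    next_id = 0
    out_labels = np.zeros_like(labels)
    for lab, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        local = labels[slc] == lab
        area_um2 = float(local.sum()) * ps**2
        if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
            continue

        coverage = {}
        mean_int = {}
        for m in present:
            vals = pre[m][slc][local]
            coverage[m] = float(np.mean(vals > thr[m]))
            mean_int[m] = float(vals.mean())
        positivity = {
            m: (coverage[m] >= params.coverage_min
                and mean_int[m] >= params.intensity_factor * thr[m])
            for m in present
        }

        # panCK rule: PDPN+ basal epithelial ribbons are not vessels
        if positivity.get("PDPN", False) and \
                coverage.get("panCK", 0.0) > params.panck_exclusion_coverage:
            log.info("dropping PDPN+ object with panCK coverage %.2f (epithelium)",
                     coverage.get("panCK", 0.0))
            continue

        full_mask = np.zeros(stack.shape, dtype=bool)
        full_mask[slc] = local
        region = assign_region(full_mask, masks)
        if region is None:
            log.info("dropping object entirely outside tissue")
            continue

        subtype, hev = classify_vessel(positivity)
        morph = compute_morphology(local, ps)
        cy, cx = ndi.center_of_mass(local)
        next_id += 1
        obj = VesselObject(
            id=next_id,
            centroid_px=(float(cy + slc[0].start), float(cx + slc[1].start)),
            region=region,
            coverage=coverage,
            mean_intensity=mean_int,
            positivity=positivity,
            subtype=subtype,
            hev_like=hev,
            morphology=morph,
        )
        obj.set_centroid_um(ps)
        objects.append(obj)
        out_labels[slc][local] = next_id
    return out_labels, objects


def vessels_to_frame(objects: list[VesselObject]):
    """Flat per-object table (one row per vessel) for CSV export."""
    import pandas as pd

    rows = []
    for v in objects:
        row = {
            "id": v.id,
            "subtype": v.subtype.value,
            "hev_like": v.hev_like,
            "region": v.region,
            "centroid_row_px": v.centroid_px[0],
            "centroid_col_px": v.centroid_px[1],
            "area_um2": v.morphology.area_um2,
            "filled_area_um2": v.morphology.filled_area_um2,
            "lumen_area_um2": v.morphology.lumen_area_um2,
            "perimeter_um": v.morphology.perimeter_um,
            "eccentricity": v.morphology.eccentricity,
            "solidity": v.morphology.solidity,
            "form_factor": v.morphology.form_factor,
        }
        for m, c in v.coverage.items():
            row[f"coverage_{m}"] = c
        for m, x in v.mean_intensity.items():
            row[f"mean_{m}"] = x
        for m, p in v.positivity.items():
            row[f"positive_{m}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
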