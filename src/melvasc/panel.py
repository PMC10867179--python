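"""Marker panel used by the sequential chromogenic IHC workflow.

Each marker is imaged in its own staining round (AEC chromogen) on top of a
hematoxylin nuclear counterstain, so a registered ROI carries one grayscale
channel per marker plus the hematoxylin channel.
"""

from __future__ import annotations

#: Full 13-channel panel: nuclear counterstain, tumor/epithelial markers,
#: five lymphovascular markers plus the HEV addressin, and four leukocyte
#: markers.
MARKER_PANEL: tuple[str, ...] = (
    "hematoxylin",
    "S100",       # melanoma / melanocyte marker (tumor-nest mask)
    "panCK",      # pan-cytokeratin; excludes PDPN+ basal epithelium
    "AQP1",       # pan blood-endothelial
    "CD34",       # activated capillary / postcapillary venule
    "aSMA",       # contractile pericyte investment
    "MECA79",     # peripheral-node addressin; HEV-like flag
    "PDPN",       # pan lymphatic-endothelial
    "LYVE1",      # lymphatic hyaluronan receptor; lost on inflamed lymphatics
    "CD45",       # pan-leukocyte
    "CD8",        # cytotoxic T cell
    "CD20",       # B cell
    "CD68",       # macrophage
)

#: Markers measured per vessel object (coverage + mean intensity profile).
VESSEL_PROFILE_MARKERS: tuple[str, ...] = (
    "AQP1", "CD34", "aSMA", "PDPN", "LYVE1", "MECA79", "panCK",
)

#: Channels whose union seeds vessel candidate segmentation.
VESSEL_SEGMENTATION_MARKERS: tuple[str, ...] = ("AQP1", "CD34", "PDPN")

#: Markers measured per cell (mean intensity over the dilated nucleus).
CELL_PROFILE_MARKERS: tuple[str, ...] = ("CD45", "CD8", "CD20", "CD68", "S100")


def validate_marker(name: str) -> str:
    if name not in MARKER_PANEL:
        raise ValueError(f"unknown marker {name!r}; panel is {MARKER_PANEL}")
    return name
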