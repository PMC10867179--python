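"""Ground-truth-annotated synthetic ROIs.

The patient cohort images are not public, so every pipeline stage is
validated on synthetic ROIs that emulate the statistical and spatial
structure the pipeline assumes: S100+ tumor nests on a hematoxylin tissue
wash, vessels drawn as filled annuli (wall positive for the subtype's
membrane markers, lumen at background), disk-shaped leukocyte nuclei carrying
class-specific marker sets, TLS-like lymphocyte aggregates with an optional
HEV-like vessel at their margin, Gaussian noise, and Beer-Lambert chromogen
mixing for RGB rounds.  All randomness derives from the spec seed, so two
runs of the same spec are pixel-identical.

The generator does not attempt photorealism (no tissue texture, melanin, or
scanner artifacts); its value is that the planted geometry gives analytic
ground truth for segmentation, gating, morphology, and density read-outs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chromogen import StainModel, render_rgb
from .panel import MARKER_PANEL
from .stack import ChannelStack
from .vessels import VesselSubtype, classify_vessel

#: Marker sets defining each plantable vessel subtype (the gate truth table).
SUBTYPE_MARKERS: dict[VesselSubtype, frozenset[str]] = {
    VesselSubtype.IMMATURE_NEOVASC: frozenset({"AQP1", "CD34", "aSMA"}),
    VesselSubtype.ACTIVATED_CAP_PCV: frozenset({"AQP1", "CD34"}),
    VesselSubtype.ARTERIOLE: frozenset({"AQP1", "aSMA"}),
    VesselSubtype.LYMPHATIC_CAP: frozenset({"PDPN", "LYVE1"}),
    VesselSubtype.INFLAMED_LYMPHATIC_CAP: frozenset({"PDPN"}),
}

#: Marker sets per planted cell class.  Macrophages additionally receive a
#: weak (sub-threshold) CD45 signal in generate_roi, mimicking the faint
#: myeloid CD45 staining seen in tissue.
CELL_CLASS_MARKERS: dict[str, frozenset[str]] = {
    "CD8_T": frozenset({"CD45", "CD8"}),
    "B_CELL": frozenset({"CD45", "CD20"}),
    "MACROPHAGE": frozenset({"CD68"}),
    "OTHER_CD45": frozenset({"CD45"}),
    "NON_LEUKOCYTE": frozenset({"S100"}),
}

WEAK_CD45_FRACTION = 0.3  # macrophage CD45 level relative to full contrast


@dataclass(frozen=True)
class VesselSpecEntry:
    center_um: tuple[float, float]
    outer_radius_um: float
    wall_thickness_um: float
    markers: frozenset[str]
    region_intent: str = "PT"          # "IT" | "PT"

    def __post_init__(self):
        if self.outer_radius_um <= 0 or self.wall_thickness_um <= 0:
            raise ValueError("vessel radii must be positive")
        if self.wall_thickness_um >= self.outer_radius_um:
            raise ValueError("wall thickness must be smaller than outer radius")
        bad = self.markers - set(MARKER_PANEL)
        if bad:
            raise ValueError(f"unknown vessel markers: {sorted(bad)}")


@dataclass(frozen=True)
class CellSpecEntry:
    center_um: tuple[float, float]
    radius_um: float
    cell_class: str
    markers: frozenset[str]

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("cell radius must be positive")
        bad = self.markers - set(MARKER_PANEL)
        if bad:
            raise ValueError(f"unknown cell markers: {sorted(bad)}")


@dataclass(frozen=True)
class EllipseSpec:
    """Elliptical tissue blob: center and semi-axes in micrometers."""

    center_um: tuple[float, float]
    semi_axes_um: tuple[float, float]

    def contains(self, p: tuple[float, float], pad_um: float = 0.0) -> bool:
        a = self.semi_axes_um[0] - pad_um
        b = self.semi_axes_um[1] - pad_um
        if a <= 0 or b <= 0:
            return False
        dy = p[0] - self.center_um[0]
        dx = p[1] - self.center_um[1]
        return (dy / a) ** 2 + (dx / b) ** 2 <= 1.0


@dataclass(frozen=True)
class TlsSpecEntry:
    center_um: tuple[float, float]
    radius_um: float
    n_cd8: int
    n_cd20: int
    hev_vessel: bool
    cell_indices: tuple[int, ...]      # indices into SyntheticSpec.cells
    vessel_indices: tuple[int, ...]    # indices into SyntheticSpec.vessels

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("TLS radius must be positive")


@dataclass
class SyntheticSpec:
    """Full description of one synthetic ROI; the seed fixes all randomness."""

    shape: tuple[int, int] = (1000, 1000)
    pixel_size: float = 1.0                       # um/px
    tissue: EllipseSpec | None = None             # no tissue drawn when None
    tumor_nests: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    vessels: list[VesselSpecEntry] = field(default_factory=list)
    cells: list[CellSpecEntry] = field(default_factory=list)
    tls: list[TlsSpecEntry] = field(default_factory=list)
    background_level: float = 0.05
    contrast: float = 0.5                         # SNR = contrast / noise_sd
    wash_range: tuple[float, float] = (0.30, 0.70)  # hematoxylin wash, x contrast
    wash_texture_sigma_um: float = 40.0           # scale of counterstain texture
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sd < 0 or self.background_level < 0 or self.contrast <= 0:
            raise ValueError("intensity parameters must be nonnegative")
        for _, r in self.tumor_nests:
            if r <= 0:
                raise ValueError("nest radius must be positive")

    def to_config(self) -> dict:
        cfg = asdict(self)
        for v in cfg["vessels"]:
            v["markers"] = sorted(v["markers"])
        for c in cfg["cells"]:
            c["markers"] = sorted(c["markers"])
        return cfg

    def save(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_config(), sort_keys=False))


@dataclass
class GroundTruth:
    """Planted-object tables consistent with the drawn pixels."""

    vessels: pd.DataFrame      # id, subtype, hev, region, area_um2, merged, ...
    cells: pd.DataFrame        # id, cell_class, region, ...
    tls: pd.DataFrame          # id, member/vessel ids, ...
    tissue: np.ndarray
    intratumoral: np.ndarray

    def save(self, directory: str | Path, prefix: str = "truth") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.vessels.to_csv(directory / f"{prefix}_vessels.csv", index=False)
        self.cells.to_csv(directory / f"{prefix}_cells.csv", index=False)
        self.tls.to_csv(directory / f"{prefix}_tls.csv", index=False)
        meta = {
            "n_vessels": len(self.vessels),
            "n_cells": len(self.cells),
            "n_tls": len(self.tls),
        }
        (directory / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


def _disk(shape: tuple[int, int], center_px: tuple[float, float], radius_px: float) -> tuple:
    """Boolean disk as (slices, local mask), clipped to the image."""
    cy, cx = center_px
    r = radius_px
    r0 = max(0, int(np.floor(cy - r)) - 1)
    r1 = min(shape[0], int(np.ceil(cy + r)) + 2)
    c0 = max(0, int(np.floor(cx - r)) - 1)
    c1 = min(shape[1], int(np.ceil(cx + r)) + 2)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return (slice(r0, r1), slice(c0, c1)), mask


def _paint(canvas: np.ndarray, slc, mask: np.ndarray, level: float) -> None:
    region = canvas[slc]
    region[mask] = np.maximum(region[mask], level)


def generate_roi(spec: SyntheticSpec) -> tuple[ChannelStack, GroundTruth]:
    """Render a synthetic ROI and its ground truth.

    Every marker channel starts at ``background_level``; object pixels are
    set to ``background + contrast`` for positive markers (maximum rule where
    objects overlap); Gaussian noise of ``noise_sd`` is added last and the
    result clipped at zero.  Vessels whose disks overlap another vessel's are
    flagged ``merged`` in the truth table rather than dropped.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ps = spec.pixel_size
    shape = spec.shape
    hi = spec.background_level + spec.contrast

    channels = {m: np.full(shape, spec.background_level, dtype=np.float64)
                for m in MARKER_PANEL}

    # tissue blob: hematoxylin wash with smooth spatial texture, so that the
    # channel histogram has a dominant glass-background peak and a broad
    # tissue tail, as on a scanned slide
    tissue = np.zeros(shape, dtype=bool)
    if spec.tissue is not None:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        cy, cx = spec.tissue.center_um[0] / ps, spec.tissue.center_um[1] / ps
        a, b = spec.tissue.semi_axes_um[0] / ps, spec.tissue.semi_axes_um[1] / ps
        tissue = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        from scipy.ndimage import gaussian_filter

        texture = gaussian_filter(
            rng.standard_normal(shape), sigma=spec.wash_texture_sigma_um / ps
        )
        t0, t1 = texture.min(), texture.max()
        texture = (texture - t0) / (t1 - t0) if t1 > t0 else np.zeros(shape)
        lo, hi_w = spec.wash_range
        wash_field = spec.background_level + spec.contrast * (
            lo + (hi_w - lo) * texture
        )
        channels["hematoxylin"][tissue] = wash_field[tissue]

    # tumor nests -> S100 and the true intratumoral mask
    intratumoral = np.zeros(shape, dtype=bool)
    for center_um, radius_um in spec.tumor_nests:
        slc, mask = _disk(shape, (center_um[0] / ps, center_um[1] / ps), radius_um / ps)
        _paint(channels["S100"], slc, mask, hi)
        intratumoral[slc] |= mask
    intratumoral &= tissue

    # vessels: annular walls
    vessel_rows = []
    wall_masks = []
    for i, v in enumerate(spec.vessels):
        c_px = (v.center_um[0] / ps, v.center_um[1] / ps)
        slc_o, outer = _disk(shape, c_px, v.outer_radius_um / ps)
        slc_i, inner = _disk(shape, c_px, (v.outer_radius_um - v.wall_thickness_um) / ps)
        wall = np.zeros(shape, dtype=bool)
        wall[slc_o] = outer
        inner_full = np.zeros(shape, dtype=bool)
        inner_full[slc_i] = inner
        wall &= ~inner_full
        for m in v.markers:
            channels[m][wall] = np.maximum(channels[m][wall], hi)
        wall_masks.append(wall)

        positivity = {m: (m in v.markers) for m in MARKER_PANEL}
        subtype, hev = classify_vessel(positivity)
        n_wall = int(wall.sum())
        frac_it = float(intratumoral[wall].sum()) / n_wall if n_wall else 0.0
        vessel_rows.append({
            "id": i + 1,
            "subtype": subtype.value,
            "hev": hev,
            "region": "IT" if frac_it > 0.5 else "PT",
            "area_um2": n_wall * ps**2,
            "outer_radius_um": v.outer_radius_um,
            "wall_thickness_um": v.wall_thickness_um,
            "center_row_um": v.center_um[0],
            "center_col_um": v.center_um[1],
            "markers": ";".join(sorted(v.markers)),
            "merged": False,
        })
    # flag vessels whose disks overlap (they may merge into one component)
    for i in range(len(spec.vessels)):
        for j in range(i + 1, len(spec.vessels)):
            vi, vj = spec.vessels[i], spec.vessels[j]
            d = np.hypot(vi.center_um[0] - vj.center_um[0],
                         vi.center_um[1] - vj.center_um[1])
            if d < vi.outer_radius_um + vj.outer_radius_um:
                vessel_rows[i]["merged"] = True
                vessel_rows[j]["merged"] = True

    # cells: nuclear disk in hematoxylin plus class marker disks
    cell_rows = []
    for i, c in enumerate(spec.cells):
        c_px = (c.center_um[0] / ps, c.center_um[1] / ps)
        slc, mask = _disk(shape, c_px, c.radius_um / ps)
        _paint(channels["hematoxylin"], slc, mask, hi)
        for m in c.markers:
            _paint(channels[m], slc, mask, hi)
        if c.cell_class == "MACROPHAGE":
            _paint(channels["CD45"], slc, mask,
                   spec.background_level + WEAK_CD45_FRACTION * spec.contrast)
        r = int(round(c.center_um[0] / ps))
        col = int(round(c.center_um[1] / ps))
        r = min(max(r, 0), shape[0] - 1)
        col = min(max(col, 0), shape[1] - 1)
        cell_rows.append({
            "id": i + 1,
            "cell_class": c.cell_class,
            "region": "IT" if intratumoral[r, col] else "PT",
            "radius_um": c.radius_um,
            "center_row_um": c.center_um[0],
            "center_col_um": c.center_um[1],
        })

    tls_rows = []
    for i, t in enumerate(spec.tls):
        tls_rows.append({
            "id": i + 1,
            "n_cd8": t.n_cd8,
            "n_cd20": t.n_cd20,
            "center_row_um": t.center_um[0],
            "center_col_um": t.center_um[1],
            "radius_um": t.radius_um,
            "hev_vessel": t.hev_vessel,
            "member_cell_ids": ";".join(str(j + 1) for j in t.cell_indices),
            "vessel_ids": ";".join(str(j + 1) for j in t.vessel_indices),
            "region": "IT" if intratumoral[
                min(max(int(round(t.center_um[0] / ps)), 0), shape[0] - 1),
                min(max(int(round(t.center_um[1] / ps)), 0), shape[1] - 1),
            ] else "PT",
        })

    if spec.noise_sd > 0:
        for m in MARKER_PANEL:
            channels[m] = channels[m] + rng.normal(0.0, spec.noise_sd, shape)
    for m in MARKER_PANEL:
        channels[m] = np.clip(channels[m], 0.0, None).astype(np.float32)

    stack = ChannelStack(
        channels=channels, pixel_size=ps, roi_id=f"synthetic-{spec.seed}",
    )
    truth = GroundTruth(
        vessels=pd.DataFrame(vessel_rows),
        cells=pd.DataFrame(cell_rows),
        tls=pd.DataFrame(tls_rows),
        tissue=tissue,
        intratumoral=intratumoral,
    )
    return stack, truth


def render_rgb_round(
    stack: ChannelStack,
    marker: str,
    stains: StainModel | None = None,
    density_scale: float = 1.0,
) -> np.ndarray:
    """Beer-Lambert RGB rendering of one chromogenic round.

    The hematoxylin channel provides the counterstain density and ``marker``
    the AEC density; ``density_scale`` converts channel intensity units to
    optical density.
    """
    stack.require("hematoxylin", marker)
    return render_rgb(
        np.asarray(stack["hematoxylin"], dtype=np.float64) * density_scale,
        np.asarray(stack[marker], dtype=np.float64) * density_scale,
        stains,
    )


# ---------------------------------------------------------------------------
# random layout generation

#: Default subtype mix (blood-dominated, mostly CD34+; lymphatics mostly
#: LYVE1-negative, as in melanoma tissue).
DEFAULT_SUBTYPE_WEIGHTS: dict[VesselSubtype, float] = {
    VesselSubtype.IMMATURE_NEOVASC: 0.20,
    VesselSubtype.ACTIVATED_CAP_PCV: 0.35,
    VesselSubtype.ARTERIOLE: 0.10,
    VesselSubtype.LYMPHATIC_CAP: 0.10,
    VesselSubtype.INFLAMED_LYMPHATIC_CAP: 0.25,
}

#: Default scattered-cell class mix (leukocytes mostly peritumoral;
#: non-leukocytes are S100+ melanocytic cells, mostly intratumoral).
DEFAULT_CELL_CLASS_WEIGHTS: dict[str, float] = {
    "CD8_T": 0.16,
    "B_CELL": 0.08,
    "MACROPHAGE": 0.16,
    "OTHER_CD45": 0.22,
    "NON_LEUKOCYTE": 0.38,
}


def random_roi_spec(
    seed: int,
    shape: tuple[int, int] = (1000, 1000),
    pixel_size: float = 1.0,
    n_vessels: int = 20,
    n_cells: int = 300,
    n_tls: int = 1,
    subtype_weights: dict[VesselSubtype, float] | None = None,
    cell_class_weights: dict[str, float] | None = None,
    meca79_rate: float = 0.10,
    it_vessel_fraction: float = 0.30,
    it_leukocyte_fraction: float = 0.30,
    vessel_outer_radius_um: tuple[float, float] = (15.0, 40.0),
    wall_thickness_um: tuple[float, float] = (5.0, 8.0),
    cell_radius_um: float = 3.0,
    cell_spacing_um: float = 8.0,
    lymphocyte_spacing_um: float = 55.0,
    tls_radius_um: float = 80.0,
    tls_n_cd8: int = 15,
    tls_n_cd20: int = 20,
    noise_sd: float = 0.05,
) -> SyntheticSpec:
    """Random ROI layout with separable planted objects.

    Placement uses rejection sampling with hard-core spacing so that planted
    objects cannot accidentally merge: vessels keep clear of each other,
    scattered CD8/CD20 lymphocytes keep ``lymphocyte_spacing_um`` (larger
    than the TLS linkage radius) from each other and from planted aggregates,
    so the planted TLS list is exactly the set of lymphocyte co-aggregations
    present in the layout.
    """
    rng = np.random.default_rng(seed)
    H_um = shape[0] * pixel_size
    W_um = shape[1] * pixel_size
    subtype_weights = subtype_weights or DEFAULT_SUBTYPE_WEIGHTS
    cell_class_weights = cell_class_weights or DEFAULT_CELL_CLASS_WEIGHTS

    tissue = EllipseSpec(
        center_um=(H_um / 2.0, W_um / 2.0),
        semi_axes_um=(0.42 * H_um, 0.45 * W_um),
    )
    # objects shrink with the ROI (floored at biologically sensible scales)
    scale = max(0.4, min(H_um, W_um) / 1000.0)
    tls_radius_um = max(50.0, tls_radius_um * scale)
    vessel_outer_radius_um = (max(8.0, vessel_outer_radius_um[0] * scale),
                              max(14.0, vessel_outer_radius_um[1] * scale))
    wall_thickness_um = (max(2.5, wall_thickness_um[0] * scale),
                         max(4.0, wall_thickness_um[1] * scale))
    spec = SyntheticSpec(shape=shape, pixel_size=pixel_size, seed=seed,
                         noise_sd=noise_sd, tissue=tissue)

    def sample_in_tissue(pad: float, max_tries: int = 5000) -> tuple[float, float]:
        for _ in range(max_tries):
            p = (rng.uniform(0, H_um), rng.uniform(0, W_um))
            if tissue.contains(p, pad_um=pad):
                return p
        raise RuntimeError("could not sample a point inside tissue")

    # two tumor nests, one per lateral half of the tissue blob
    nest_r = rng.uniform(100.0, 150.0, size=2) * min(H_um, W_um) / 1000.0
    nests = []
    for i, r in enumerate(nest_r):
        for _try in range(5000):
            p = sample_in_tissue(pad=r + 20.0)
            side_ok = p[1] < W_um / 2 - 40 if i == 0 else p[1] > W_um / 2 + 40
            apart = all(
                np.hypot(p[0] - c[0], p[1] - c[1]) > r + rj + 40.0
                for c, rj in nests
            )
            if side_ok and apart:
                break
        else:
            raise RuntimeError("could not place tumor nest")
        nests.append(((float(p[0]), float(p[1])), float(r)))
    spec.tumor_nests = nests

    def in_nest(p, pad=0.0):
        return any(np.hypot(p[0] - c[0], p[1] - c[1]) < r + pad for c, r in nests)

    def nest_index(p):
        for k, (c, r) in enumerate(nests):
            if np.hypot(p[0] - c[0], p[1] - c[1]) < r:
                return k
        return None

    vessels: list[VesselSpecEntry] = []
    cells: list[CellSpecEntry] = []
    tls_entries: list[TlsSpecEntry] = []

    def vessel_clear(p, outer, pad=10.0):
        return all(
            np.hypot(p[0] - v.center_um[0], p[1] - v.center_um[1])
            > outer + v.outer_radius_um + pad
            for v in vessels
        )

    # TLS first (they carry their own HEV vessel and member cells)
    tls_centers = []
    for _ in range(n_tls):
        for _try in range(5000):
            p = sample_in_tissue(pad=tls_radius_um + 40.0)
            if in_nest(p, pad=tls_radius_um):
                continue
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) > 2 * tls_radius_um + 100
                   for q in tls_centers):
                break
        else:
            raise RuntimeError("could not place TLS; relax layout parameters")
        tls_centers.append(p)

        member_idx = []
        placed = []
        classes = ["CD8_T"] * tls_n_cd8 + ["B_CELL"] * tls_n_cd20
        for cls in classes:
            for _try in range(5000):
                rad = tls_radius_um * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                q = (p[0] + rad * np.sin(ang), p[1] + rad * np.cos(ang))
                if all(np.hypot(q[0] - s[0], q[1] - s[1]) >= 2.5 * cell_radius_um
                       for s in placed):
                    break
            else:
                raise RuntimeError("could not place TLS member cell")
            placed.append(q)
            member_idx.append(len(cells))
            cells.append(CellSpecEntry(
                center_um=q, radius_um=cell_radius_um, cell_class=cls,
                markers=CELL_CLASS_MARKERS[cls],
            ))

        vessel_idx = []
        if True:  # each aggregate carries an HEV-like vessel at its margin
            ang = rng.uniform(0, 2 * np.pi)
            vq = (float(p[0] + (tls_radius_um + 20.0) * np.sin(ang)),
                  float(p[1] + (tls_radius_um + 20.0) * np.cos(ang)))
            vessel_idx.append(len(vessels))
            vessels.append(VesselSpecEntry(
                center_um=vq, outer_radius_um=15.0, wall_thickness_um=5.0,
                markers=frozenset({"AQP1", "CD34", "MECA79"}),
                region_intent="PT",
            ))
        tls_entries.append(TlsSpecEntry(
            center_um=p, radius_um=tls_radius_um, n_cd8=tls_n_cd8,
            n_cd20=tls_n_cd20, hev_vessel=True,
            cell_indices=tuple(member_idx), vessel_indices=tuple(vessel_idx),
        ))
    spec.tls = tls_entries

    # scattered vessels
    subtype_list = list(subtype_weights)
    probs = np.array([subtype_weights[s] for s in subtype_list], dtype=float)
    probs /= probs.sum()
    n_remaining = n_vessels - len(vessels)
    for _ in range(n_remaining):
        st = subtype_list[int(rng.choice(len(subtype_list), p=probs))]
        markers = set(SUBTYPE_MARKERS[st])
        if "AQP1" in markers and rng.uniform() < meca79_rate:
            markers.add("MECA79")
        outer = float(rng.uniform(*vessel_outer_radius_um))
        wall = float(rng.uniform(*wall_thickness_um))
        intent = "IT" if rng.uniform() < it_vessel_fraction else "PT"
        for _try in range(5000):
            if intent == "IT":
                k = int(rng.integers(len(nests)))
                c0, r0 = nests[k]
                if r0 <= outer + 10:
                    continue
                rad = (r0 - outer - 10) * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                p = (c0[0] + rad * np.sin(ang), c0[1] + rad * np.cos(ang))
            else:
                p = sample_in_tissue(pad=outer + 10.0)
                if in_nest(p, pad=outer + 10):
                    continue
                if any(np.hypot(p[0] - q[0], p[1] - q[1]) < tls_radius_um + outer + 15
                       for q in tls_centers):
                    continue
            if vessel_clear(p, outer):
                break
        else:
            raise RuntimeError("could not place vessel; relax layout parameters")
        vessels.append(VesselSpecEntry(
            center_um=(float(p[0]), float(p[1])), outer_radius_um=outer,
            wall_thickness_um=wall, markers=frozenset(markers),
            region_intent=intent,
        ))
    spec.vessels = vessels

    # scattered cells
    class_list = list(cell_class_weights)
    cprobs = np.array([cell_class_weights[c] for c in class_list], dtype=float)
    cprobs /= cprobs.sum()
    scattered = []
    lymph_pts = [c.center_um for c in cells]    # TLS members are lymphocytes

    def cell_ok(p, cls):
        if any(np.hypot(p[0] - v.center_um[0], p[1] - v.center_um[1])
               < v.outer_radius_um + cell_radius_um + 3 for v in vessels):
            return False
        if any(np.hypot(p[0] - q[0], p[1] - q[1]) < cell_spacing_um
               for q in scattered):
            return False
        if cls in ("CD8_T", "B_CELL"):
            if any(np.hypot(p[0] - q[0], p[1] - q[1]) < lymphocyte_spacing_um
                   for q in lymph_pts):
                return False
            if any(np.hypot(p[0] - q[0], p[1] - q[1])
                   < tls_radius_um + lymphocyte_spacing_um for q in tls_centers):
                return False
        return True

    def try_place(cls: str, want_it: bool, tries: int = 4000):
        for _try in range(tries):
            if want_it:
                k = int(rng.integers(len(nests)))
                c0, r0 = nests[k]
                rad = (r0 - cell_radius_um - 2) * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                p = (c0[0] + rad * np.sin(ang), c0[1] + rad * np.cos(ang))
            else:
                p = sample_in_tissue(pad=cell_radius_um + 5.0)
                if in_nest(p, pad=cell_radius_um + 2):
                    continue
            if cell_ok(p, cls):
                return p
        return None

    n_scatter = n_cells - len(cells)
    for _ in range(n_scatter):
        cls = class_list[int(rng.choice(len(class_list), p=cprobs))]
        if cls == "NON_LEUKOCYTE":
            want_it = rng.uniform() < 0.8
        else:
            want_it = rng.uniform() < it_leukocyte_fraction
        # fall back to the other compartment when the intended one is packed;
        # an unplaceable lymphocyte (hard-core spacing exhausted) becomes a
        # non-clustering leukocyte so planted aggregates stay unambiguous
        p = try_place(cls, want_it) or try_place(cls, not want_it)
        if p is None and cls in ("CD8_T", "B_CELL"):
            cls = "OTHER_CD45"
            p = try_place(cls, want_it) or try_place(cls, not want_it)
        if p is None:
            raise RuntimeError("could not place cell; relax layout parameters")
        scattered.append(p)
        if cls in ("CD8_T", "B_CELL"):
            lymph_pts.append(p)
        cells.append(CellSpecEntry(
            center_um=(float(p[0]), float(p[1])), radius_um=cell_radius_um,
            cell_class=cls, markers=CELL_CLASS_MARKERS[cls],
        ))
    spec.cells = cells
    return spec
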