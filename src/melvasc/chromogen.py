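"""Hematoxylin / AEC chromogen separation.

Sequential chromogenic IHC produces RGB rounds in which a red AEC signal for
one marker is superimposed on a blue hematoxylin counterstain.  Under the
Beer-Lambert model each stain attenuates transmitted light along a fixed RGB
optical-density direction, so a pixel's OD vector is a nonnegative mixture of
the stain vectors and the per-stain density maps can be recovered by
projecting onto that basis (Ruifrok-Johnston color deconvolution).

Optical density here is the natural-log transform ``OD = -ln(I / I0)`` with
``I0`` the white reference; the convention cancels in the forward/inverse
round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: Published unit optical-density color vectors (Ruifrok-Johnston convention)
#: for hematoxylin and for the AEC chromogen.
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
AEC_OD = (0.2743, 0.6796, 0.6803)

#: OD assigned to saturated-black pixels, where -ln(I/I0) diverges.
MAX_DENSITY = 16.0


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class StainModel:
    """Two-stain (hematoxylin + AEC) optical-density basis.

    ``vectors`` rows are unit RGB OD directions; ``background_rgb`` is the
    white (unstained) transmittance reference.
    """

    names: tuple[str, str] = ("hematoxylin", "aec")
    hematoxylin: tuple[float, float, float] = HEMATOXYLIN_OD
    aec: tuple[float, float, float] = AEC_OD
    background_rgb: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if any(b <= 0 for b in self.background_rgb):
            raise ValueError("white reference must be positive in every channel")
        object.__setattr__(self, "hematoxylin", tuple(_unit(self.hematoxylin)))
        object.__setattr__(self, "aec", tuple(_unit(self.aec)))

    @property
    def vectors(self) -> np.ndarray:
        return np.stack([np.asarray(self.hematoxylin), np.asarray(self.aec)])


def render_rgb(hema: np.ndarray, aec: np.ndarray, stains: StainModel | None = None) -> np.ndarray:
    """Forward Beer-Lambert rendering of two density maps to an RGB image.

    Zero density renders as the white reference; densities must be
    nonnegative.  Returns float RGB with shape ``hema.shape + (3,)``.
    """
    stains = stains or StainModel()
    hema = np.asarray(hema, dtype=np.float64)
    aec = np.asarray(aec, dtype=np.float64)
    if hema.shape != aec.shape:
        raise ValueError("density maps must share a shape")
    if np.any(hema < 0) or np.any(aec < 0):
        raise ValueError("stain densities must be nonnegative")
    od = hema[..., None] * stains.vectors[0] + aec[..., None] * stains.vectors[1]
    return np.asarray(stains.background_rgb) * np.exp(-od)


def deconvolve_h_aec(
    rgb: np.ndarray,
    stains: StainModel | None = None,
    return_saturated: bool = False,
):
    """Separate an RGB round into hematoxylin and AEC density maps.

    Per-pixel OD is projected onto the two-stain basis by least squares;
    negative projections (residual off-basis color) are clipped to zero.
    Saturated-black pixels, whose OD is undefined, are assigned
    ``MAX_DENSITY`` on both stains and flagged.
    """
    stains = stains or StainModel()
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError("expected an (..., 3) RGB array")
    bg = np.asarray(stains.background_rgb)
    saturated = np.any(rgb <= 0, axis=-1)
    ratio = np.clip(rgb / bg, np.exp(-MAX_DENSITY), None)
    od = -np.log(ratio)

    # least-squares projection of OD rows onto the stain basis
    pinv = np.linalg.pinv(stains.vectors)  # (3, 2)
    dens = od @ pinv
    dens = np.clip(dens, 0.0, None)
    hema = dens[..., 0]
    aec = dens[..., 1]
    n_sat = int(np.count_nonzero(saturated))
    if n_sat:
        log.warning("%d saturated-black pixels assigned maximum density", n_sat)
        hema = np.where(saturated, MAX_DENSITY, hema)
        aec = np.where(saturated, MAX_DENSITY, aec)
    if return_saturated:
        return hema, aec, saturated
    return hema, aec


def background_threshold_from_blank(channel: np.ndarray, blank_mask: np.ndarray, k: float = 2.0) -> float:
    """Background threshold as mean + k*SD over a user-designated blank region."""
    vals = np.asarray(channel, dtype=np.float64)[np.asarray(blank_mask, bool)]
    if vals.size == 0:
        raise ValueError("blank region is empty")
    return float(vals.mean() + k * vals.std())


def clean_background(
    channel: np.ndarray,
    threshold: float,
    median_radius: int = 0,
) -> np.ndarray:
    """Background elimination on a density map.

    Optionally median-filters with a disk footprint of ``median_radius``
    (despeckling single-pixel chromogen debris), then zeroes everything at or
    below ``threshold``.  The output is nonnegative and never exceeds the
    input maximum.  With ``median_radius=0`` the operation is a pure
    threshold-to-zero and is exactly idempotent.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if np.any(channel < 0):
        raise ValueError("density channel must be nonnegative")
    out = channel
    if median_radius > 0:
        from scipy import ndimage as ndi
        from skimage.morphology import disk

        out = ndi.median_filter(out, footprint=disk(median_radius))
    out = np.where(out > threshold, out, 0.0)
    return out
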