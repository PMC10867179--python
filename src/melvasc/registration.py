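"""Translation registration of staining rounds and square-ROI extraction.

Sequential chromogenic IHC reimages the same section after every staining
round, so serial rounds differ by a rigid in-plane translation (stage
repositioning); rotation and deformation are out of scope.  Offsets are
estimated by phase correlation and scored by the normalized cross-correlation
(Pearson r) of the overlapping region, which doubles as the registration
quality metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .stack import ChannelStack

log = logging.getLogger(__name__)

#: Rounds scoring below this normalized correlation are considered
#: ill-registered and their ROIs excluded from downstream tables.
DEFAULT_QC_THRESHOLD = 0.5


@dataclass(frozen=True)
class RoiBox:
    """Square ROI in pixel coordinates: half-open box, row-major, 0-based."""

    row: int
    col: int
    side: int

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("ROI side must be positive")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI corner must be nonnegative")

    @classmethod
    def from_area(cls, row: int, col: int, area_mm2: float, pixel_size: float) -> "RoiBox":
        """Box of a given physical area (default workflow preset: 6.25 mm^2)."""
        side = int(round(np.sqrt(area_mm2) * 1000.0 / pixel_size))
        return cls(row=row, col=col, side=side)

    def slices(self, offset: tuple[int, int] = (0, 0)) -> tuple[slice, slice]:
        dy, dx = offset
        return (
            slice(self.row + dy, self.row + dy + self.side),
            slice(self.col + dx, self.col + dx + self.side),
        )


def _overlap_ncc(fixed: np.ndarray, moving: np.ndarray, dy: int, dx: int) -> float:
    """Pearson correlation of the overlap under the convention
    ``moving[r, c] = fixed[r - dy, c - dx]`` (moving is fixed translated by
    ``(+dy, +dx)``)."""
    h, w = fixed.shape
    f_r0, f_r1 = max(0, -dy), min(h, h - dy)
    f_c0, f_c1 = max(0, -dx), min(w, w - dx)
    if f_r1 - f_r0 < 8 or f_c1 - f_c0 < 8:
        return -1.0
    a = fixed[f_r0:f_r1, f_c0:f_c1]
    b = moving[f_r0 + dy:f_r1 + dy, f_c0 + dx:f_c1 + dx]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -1.0
    return float((a * b).sum() / denom)


def estimate_offset(fixed: np.ndarray, moving: np.ndarray) -> tuple[int, int, float]:
    """Estimate the integer translation aligning ``moving`` to ``fixed``.

    Returns ``(dy, dx, quality)`` with the convention that ``moving`` is
    ``fixed`` translated by ``(+dy, +dx)``: content at ``fixed[r, c]``
    appears at ``moving[r + dy, c + dx]`` (``moving = np.roll(fixed,
    (dy, dx))`` for a cyclic shift).  Candidate translations come from the
    peaks of the FFT cross-correlation of the mean-subtracted images; among
    their wraparound interpretations the one maximizing the overlap's
    normalized cross-correlation (Pearson r) is kept, and that correlation
    (clipped to [0, 1]) is the quality score.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("images must share a shape")
    if fixed.std() == 0 or moving.std() == 0:
        raise ValueError("degenerate input: constant image")

    f = np.fft.fft2(fixed - fixed.mean())
    g = np.fft.fft2(moving - moving.mean())
    corr = np.real(np.fft.ifft2(np.conj(f) * g))

    h, w = fixed.shape
    # evaluate the wrap interpretations of the few strongest correlation peaks
    flat = corr.ravel()
    top = np.argsort(flat)[-3:][::-1]
    best = (0, 0, -1.0)
    for idx in top:
        py, px = np.unravel_index(int(idx), corr.shape)
        for dy in {int(py), int(py) - h}:
            for dx in {int(px), int(px) - w}:
                q = _overlap_ncc(fixed, moving, dy, dx)
                if q > best[2]:
                    best = (dy, dx, q)
    dy, dx, q = best
    return int(dy), int(dx), float(np.clip(q, 0.0, 1.0))


def apply_offset_and_crop(
    stack: ChannelStack,
    offsets: dict[str, tuple[int, int]],
    box: RoiBox,
) -> ChannelStack:
    """Crop every channel to the same physical ROI, compensating per-round shifts.

    ``offsets[marker] = (dy, dx)`` follows the :func:`estimate_offset`
    convention, so the aligned crop of that channel is the box displaced by
    ``(dy, dx)``.  Channels without an entry are assumed already aligned.
    Raises ``ValueError`` if the displaced box leaves any channel's bounds.
    """
    h, w = stack.shape
    channels = {}
    for marker, img in stack.channels.items():
        dy, dx = offsets.get(marker, (0, 0))
        r0, c0 = box.row + dy, box.col + dx
        if r0 < 0 or c0 < 0 or r0 + box.side > h or c0 + box.side > w:
            raise ValueError(
                f"ROI box {box} with offset {(dy, dx)} exceeds bounds of channel {marker!r}"
            )
        channels[marker] = img[r0:r0 + box.side, c0:c0 + box.side].copy()
    return ChannelStack(
        channels=channels,
        pixel_size=stack.pixel_size,
        roi_id=f"{stack.roi_id}",
        offsets={m: tuple(offsets.get(m, (0, 0))) for m in stack.channels},
    )


@dataclass
class RegistrationQC:
    passed: bool
    quality: dict[str, float]
    threshold: float
    reference: str


def qc_registration(
    stack: ChannelStack,
    reference: str = "hematoxylin",
    threshold: float = DEFAULT_QC_THRESHOLD,
) -> RegistrationQC:
    """Score each round against the reference channel; fail if any round's
    normalized correlation falls below ``threshold``."""
    stack.require(reference)
    if len(stack.channels) < 2:
        raise ValueError("QC needs at least 2 rounds")
    ref = stack[reference]
    quality = {}
    for marker, img in stack.channels.items():
        if marker == reference:
            continue
        try:
            _, _, q = estimate_offset(ref, img)
        except ValueError:
            q = 0.0
        quality[marker] = q
    passed = all(q >= threshold for q in quality.values())
    if not passed:
        bad = {m: round(q, 3) for m, q in quality.items() if q < threshold}
        log.warning("ROI %s fails registration QC: %s", stack.roi_id, bad)
    return RegistrationQC(passed=passed, quality=quality, threshold=threshold, reference=reference)
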