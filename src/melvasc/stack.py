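"""Co-registered per-marker channel stacks for one ROI."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .panel import MARKER_PANEL


@dataclass
class ChannelStack:
    """One registered ROI: a grayscale image per marker on a common grid.

    ``pixel_size`` is in micrometers per pixel.  ``offsets`` records the
    translation applied to each round's image when the stack was aligned
    (provenance only; images are already on the common grid).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    roi_id: str = "roi"
    offsets: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um/px)")
        shapes = {m: a.shape for m, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        unknown = set(self.channels) - set(MARKER_PANEL)
        if unknown:
            raise ValueError(f"channels outside the marker panel: {sorted(unknown)}")

    def __getitem__(self, marker: str) -> np.ndarray:
        try:
            return self.channels[marker]
        except KeyError:
            raise KeyError(f"channel {marker!r} missing from stack {self.roi_id!r}") from None

    def __contains__(self, marker: str) -> bool:
        return marker in self.channels

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def require(self, *markers: str) -> None:
        missing = [m for m in markers if m not in self.channels]
        if missing:
            raise KeyError(
                f"stack {self.roi_id!r} is missing required channel(s): {missing}"
            )

    def save(self, directory: str | Path) -> None:
        """Write one 32-bit grayscale TIFF per channel into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for marker, img in self.channels.items():
            tifffile.imwrite(
                directory / f"{self.roi_id}_{marker}.tif",
                np.asarray(img, dtype=np.float32),
                resolution=(1e4 / self.pixel_size, 1e4 / self.pixel_size),
            )

    @classmethod
    def load(cls, directory: str | Path, roi_id: str, pixel_size: float) -> "ChannelStack":
        directory = Path(directory)
        channels = {}
        for path in sorted(directory.glob(f"{roi_id}_*.tif")):
            marker = path.stem[len(roi_id) + 1:]
            if marker in MARKER_PANEL:
                channels[marker] = tifffile.imread(path)
        if not channels:
            raise FileNotFoundError(f"no channels for ROI {roi_id!r} under {directory}")
        return cls(channels=channels, pixel_size=pixel_size, roi_id=roi_id)
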