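"""Raster container for rhizoslide imagery.

Images from the platform are plain 24-bit RGB frames; the only metadata the
pipeline cares about is the physical scale (mm per pixel, ~0.13 for the DSLR
root camera), which is needed to convert traced pixel coordinates to cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

from .errors import MetadataError, ShapeMismatchError

#: Root-camera resolution of the imaging station, mm per pixel.
DEFAULT_SCALE_MM_PER_PX = 0.13


@dataclass
class RGBImage:
    """An 8-bit RGB image with a physical scale.

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` array, dtype uint8.
    scale_mm_per_px
        Physical size of one pixel in mm.
    """

    pixels: np.ndarray
    scale_mm_per_px: float = DEFAULT_SCALE_MM_PER_PX

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ShapeMismatchError(
                f"expected (H, W, 3) RGB array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ShapeMismatchError("image must have positive height and width")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def same_geometry(self, other: "RGBImage") -> None:
        """Raise unless *other* is pixel-aligned and on the same scale."""
        if self.pixels.shape != other.pixels.shape:
            raise ShapeMismatchError(
                f"image dimensions differ: {self.pixels.shape[:2]} "
                f"vs {other.pixels.shape[:2]}"
            )
        if not np.isclose(self.scale_mm_per_px, other.scale_mm_per_px):
            raise MetadataError(
                f"mm-per-pixel scales differ: {self.scale_mm_per_px} "
                f"vs {other.scale_mm_per_px}"
            )

    def save(self, path) -> None:
        iio.imwrite(path, self.pixels)


def load_rgb(path, scale_mm_per_px: float = DEFAULT_SCALE_MM_PER_PX) -> RGBImage:
    """Read a PNG/TIFF file as an :class:`RGBImage`.

    Grayscale input is broadcast to three channels; an alpha channel is
    dropped.
    """
    px = np.asarray(iio.imread(path))
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.shape[-1] == 4:
        px = px[..., :3]
    return RGBImage(px.astype(np.uint8), scale_mm_per_px)
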