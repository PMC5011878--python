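"""Fusion of the two differently illuminated root exposures.

Each rhizoslide side is photographed twice, once lit by the left LED bars
and once by the right ones.  Either exposure carries one-sided glare from
the plexiglass; keeping only the per-pixel, per-channel minimum of the two
("minimum tonal image") suppresses the glare while preserving the dark root
signal, because glare only ever brightens a pixel.

The two exposures are taken without moving slide or camera, so pixel
alignment is a precondition here, not something the function solves.
"""

from __future__ import annotations

import numpy as np

from .raster import RGBImage


def fuse_min_tonal(left_lit: RGBImage, right_lit: RGBImage) -> RGBImage:
    """Per-pixel, per-channel minimum of two pixel-aligned exposures.

    Raises
    ------
    ShapeMismatchError
        If the images differ in dimensions.
    MetadataError
        If the mm-per-pixel scales differ.
    """
    left_lit.same_geometry(right_lit)
    fused = np.minimum(left_lit.pixels, right_lit.pixels)
    return RGBImage(fused, left_lit.scale_mm_per_px)


def root_contrast(img: RGBImage, root_mask: np.ndarray, halo_px: int = 6) -> float:
    """Local root-to-paper contrast (grayscale intensity units).

    For every image column containing root pixels, the mean intensity of
    the paper background in a *halo_px*-wide halo around the roots of that
    column is compared with the mean root intensity of the same column;
    the column contrasts are averaged weighted by root-pixel count.
    Comparing within columns matters because the LED illumination (and
    hence any glare) varies across the slide, i.e. along x: what
    determines whether a tracing operator can see a root is the paper
    right next to it, not the far side of the image.  Higher is better.
    """
    from scipy import ndimage

    gray = img.pixels.mean(axis=2)
    mask = np.asarray(root_mask, dtype=bool)
    if mask.shape != gray.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any() or mask.all():
        raise ValueError("mask must contain both root and background pixels")
    halo = ndimage.binary_dilation(mask, iterations=halo_px) & ~mask

    contrasts, weights = [], []
    for col in np.flatnonzero(mask.any(axis=0)):
        root_col = mask[:, col]
        halo_col = halo[:, col]
        if not halo_col.any():
            continue
        contrasts.append(gray[halo_col, col].mean() - gray[root_col, col].mean())
        weights.append(root_col.sum())
    if not contrasts:
        raise ValueError("no column contains both root and halo pixels")
    return float(np.average(contrasts, weights=weights))
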