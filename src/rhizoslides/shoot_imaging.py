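"""Two-step shoot segmentation and the multi-view canopy pixel proxy.

The maize shoot is photographed against a blue background from up to four
viewpoints (front/back side views and two top views).  Segmentation works on
the excess-green feature map ``f = 2G - R - B``:

1. a *coarse* mask ``s_c`` thresholds ``f`` at a fixed, high value (55),
   which reliably hits plant material but clips leaf borders;
2. a *fine* mask ``s_f`` thresholds ``f`` with Otsu's method, which traces
   borders well but admits spurious off-plant regions;
3. the two are combined by keeping the coarse regions and enlarging them to
   every fine-mask connected component they touch.

The mean foreground pixel count over the available views is the canopy-size
proxy used throughout the growth analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateHistogramError, ShapeMismatchError
from .raster import RGBImage

#: Fixed high threshold of the coarse segmentation step.
COARSE_THRESHOLD = 55

#: 8-connectivity structuring element used for components and adjacency.
_STRUCT8 = np.ones((3, 3), dtype=bool)


def excess_green(img: RGBImage, background: Optional[RGBImage] = None) -> np.ndarray:
    """Excess-green feature map ``f = 2G - R - B`` in signed arithmetic.

    If a plant-free *background* reference of the imaging station is given it
    is subtracted channel-wise before the feature map is computed; otherwise
    the step is skipped.

    Returns an ``int16`` array with values in [-510, 510] (wider if a
    background is subtracted).
    """
    px = img.pixels.astype(np.int32)
    if background is not None:
        img.same_geometry(background)
        px = px - background.pixels.astype(np.int32)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    return (2 * g - r - b).astype(np.int16)


def coarse_segment(f: np.ndarray, threshold: int = COARSE_THRESHOLD) -> np.ndarray:
    """Binary mask marking feature-map values ``>= threshold``."""
    return np.asarray(f) >= threshold


def otsu_threshold(f: np.ndarray) -> int:
    """Otsu's threshold over the full signed feature-map histogram.

    Considers every distinct value ``v`` present as a candidate threshold
    (foreground = ``f >= v``) and returns the one maximising the
    between-class variance ``w0 * w1 * (mu0 - mu1)^2``.  Ties are broken
    toward the lower threshold.  The map is *not* rescaled to 0-255 first.
    """
    values = np.asarray(f).ravel()
    vals, counts = np.unique(values, return_counts=True)
    if vals.size < 2:
        raise DegenerateHistogramError(
            "constant feature map: no threshold separates two classes"
        )
    total = counts.sum()
    cum_n = np.cumsum(counts)
    cum_s = np.cumsum(counts * vals.astype(np.float64))
    # candidate i splits classes {v < vals[i]} / {v >= vals[i]}, i >= 1
    w0 = cum_n[:-1].astype(np.float64)
    w1 = total - w0
    mu0 = cum_s[:-1] / w0
    mu1 = (cum_s[-1] - cum_s[:-1]) / w1
    bcv = w0 * w1 * (mu0 - mu1) ** 2
    best = int(np.argmax(bcv))  # first max -> lowest threshold on ties
    return int(vals[best + 1])


def otsu_segment(f: np.ndarray) -> np.ndarray:
    """Fine segmentation: mask of values ``>=`` the Otsu threshold."""
    return np.asarray(f) >= otsu_threshold(f)


def merge_segmentations(s_c: np.ndarray, s_f: np.ndarray) -> np.ndarray:
    """Keep the coarse regions, enlarged to connected fine regions.

    Output = ``s_c`` united with every 8-connected component of ``s_f`` that
    overlaps or touches (8-adjacency) a pixel of ``s_c``.  Components of
    ``s_f`` with no connection to the coarse mask are dropped, so the result
    is always a sub-mask of ``s_f | s_c``.
    """
    s_c = np.asarray(s_c, dtype=bool)
    s_f = np.asarray(s_f, dtype=bool)
    if s_c.shape != s_f.shape:
        raise ShapeMismatchError(
            f"mask dimensions differ: {s_c.shape} vs {s_f.shape}"
        )
    if not s_c.any():
        return np.zeros_like(s_c)
    labels, n = ndimage.label(s_f, structure=_STRUCT8)
    seeds = ndimage.binary_dilation(s_c, structure=_STRUCT8)
    touched = np.unique(labels[seeds & s_f])
    touched = touched[touched > 0]
    return np.isin(labels, touched) | s_c


def segment_shoot(
    img: RGBImage,
    background: Optional[RGBImage] = None,
    coarse_threshold: int = COARSE_THRESHOLD,
) -> np.ndarray:
    """Full two-step shoot segmentation of one view.

    If Otsu's method is undefined (constant feature map) the fine mask is
    taken to be empty and the coarse mask alone is returned.
    """
    f = excess_green(img, background=background)
    s_c = coarse_segment(f, coarse_threshold)
    try:
        s_f = otsu_segment(f)
    except DegenerateHistogramError:
        s_f = np.zeros_like(s_c)
    return merge_segmentations(s_c, s_f)


@dataclass
class ShootViewSet:
    """Up to four shoot views of one plant at one timepoint.

    For a well-posed canopy proxy at least one side and one top view should
    be present; the proxy itself only requires one view of any kind.
    """

    side_front: Optional[RGBImage] = None
    side_back: Optional[RGBImage] = None
    top_front: Optional[RGBImage] = None
    top_back: Optional[RGBImage] = None

    def available(self) -> dict:
        views = {
            "side_front": self.side_front,
            "side_back": self.side_back,
            "top_front": self.top_front,
            "top_back": self.top_back,
        }
        return {k: v for k, v in views.items() if v is not None}


def canopy_pixel_proxy(
    views: ShootViewSet,
    background: Optional[RGBImage] = None,
    coarse_threshold: int = COARSE_THRESHOLD,
) -> float:
    """Mean segmented foreground pixel count over the available views."""
    present = views.available()
    if not present:
        raise ValueError("canopy proxy needs at least one shoot view")
    counts = [
        int(segment_shoot(v, background=background, coarse_threshold=coarse_threshold).sum())
        for v in present.values()
    ]
    return float(np.mean(counts))
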