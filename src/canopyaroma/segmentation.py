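"""RGB-to-binary segmentation of canopy photographs.

Upward-looking photos use the sky as background: the blue channel separates
bright sky/cloud pixels (high blue) from foliage (low blue).  Aerial
per-tree sub-images use the inter-row soil as background: the CIELab ``a*``
channel separates green vegetation (negative ``a*``) from soil and litter
(``a*`` near or above zero).  The automatic threshold is Otsu's criterion
on the relevant channel; a fixed level can be supplied for reproducibility.
"""

from __future__ import annotations

import warnings
from typing import Literal, Sequence

import numpy as np
from skimage.color import rgb2lab
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin

from .gap import BinaryCanopyMask

__all__ = [
    "binarize_upward",
    "binarize_aerial",
    "UpwardSegmenter",
    "AerialSegmenter",
]

ThresholdMode = Literal["otsu", "fixed"]


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.size == 0:
        raise ValueError("expected a non-empty 3-channel RGB image")
    return arr


def _global_threshold(
    channel: np.ndarray,
    mode: ThresholdMode,
    fixed_value: float | None,
    range_midpoint: float,
) -> float:
    if mode == "fixed":
        if fixed_value is None:
            raise ValueError("fixed threshold mode requires fixed_value")
        return float(fixed_value)
    lo, hi = float(channel.min()), float(channel.max())
    if lo == hi:
        # Otsu needs two classes; the midpoint of the channel's physical
        # range keeps the polarity right for uniform sky or foliage tiles.
        warnings.warn(
            "constant channel: Otsu undefined, falling back to midpoint threshold",
            stacklevel=3,
        )
        return range_midpoint
    return float(threshold_otsu(channel))


def binarize_upward(
    img: np.ndarray,
    threshold_mode: ThresholdMode = "otsu",
    fixed_value: float | None = None,
    source_id: str = "",
) -> BinaryCanopyMask:
    """Segment an upward-looking photo on the blue channel.

    Pixels with blue above the threshold are sky (gap); the rest are
    foliage.  Returns a mask with ``orientation='upward'``.
    """
    arr = _validate_rgb(img)
    blue = arr[..., 2].astype(float)
    thr = _global_threshold(blue, threshold_mode, fixed_value, range_midpoint=127.5)
    foliage = blue <= thr
    return BinaryCanopyMask(foliage, orientation="upward", source_id=source_id)


def binarize_aerial(
    img: np.ndarray,
    threshold_mode: ThresholdMode = "otsu",
    fixed_value: float | None = None,
    source_id: str = "",
) -> BinaryCanopyMask:
    """Segment an aerial tile on the CIELab a* channel.

    Green vegetation has negative a*; pixels with a* at or below the
    threshold are foliage, the rest (soil, litter, shadow-free inter-row)
    background.  The resulting mask is analyzed exactly like an
    upward-looking one, with the inter-row as the gap background.
    """
    arr = _validate_rgb(img)
    a_star = rgb2lab(arr[..., :3].astype(np.uint8))[..., 1]
    thr = _global_threshold(a_star, threshold_mode, fixed_value, range_midpoint=0.0)
    foliage = a_star <= thr
    return BinaryCanopyMask(foliage, orientation="aerial", source_id=source_id)


class _ChannelSegmenter(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping RGB images to binary canopy masks."""

    def __init__(self, threshold_mode: ThresholdMode = "otsu", fixed_value: float | None = None):
        self.threshold_mode = threshold_mode
        self.fixed_value = fixed_value

    _binarize = staticmethod(binarize_upward)

    def fit(self, X: Sequence[np.ndarray], y=None):
        return self

    def transform(self, X: Sequence[np.ndarray]) -> list[BinaryCanopyMask]:
        return [
            type(self)._binarize(img, self.threshold_mode, self.fixed_value, f"img{i}")
            for i, img in enumerate(X)
        ]


class UpwardSegmenter(_ChannelSegmenter):
    """Blue-channel sky segmentation for upward canopy photographs."""

    _binarize = staticmethod(binarize_upward)


class AerialSegmenter(_ChannelSegmenter):
    """CIELab a*-channel vegetation segmentation for aerial tiles."""

    _binarize = staticmethod(binarize_aerial)
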