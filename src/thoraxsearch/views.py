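"""Symmetry views: whole image, left half, and horizontally flipped right half.

A frontal radiograph is split at the vertical midline and the right half is
mirrored, a coarse registration that maps both hemithoraces into a common
orientation so one feature extractor sees comparable anatomy from either side.
All three views are resampled bilinearly to the fixed network input size
(224 x 224).

"Left" is the image-coordinate left (columns ``0 .. floor(W/2)-1``), not
anatomical laterality: with image-level labels the choice is a pure
convention, and the flip makes the pipeline invariant to it. Odd widths split
as (floor, ceil). Halves are split from the original image and then resized
independently, not cropped from the resized whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .store import LABEL_NEGATIVE, LABEL_OTHER, LABEL_POSITIVE

#: network input side in pixels
INPUT_SIDE = 224


@dataclass
class ImageRecord:
    """A grayscale image with an image-level label in [0, 1] intensity."""

    id: str
    pixels: np.ndarray
    label: int = LABEL_OTHER
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-d grayscale matrix")
        h, w = self.pixels.shape
        if h < 2 or w < 2:
            raise ValueError("image must be at least 2 x 2")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities must lie in [0, 1], got [{lo}, {hi}]")
        if self.label not in (LABEL_POSITIVE, LABEL_NEGATIVE, LABEL_OTHER):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class ViewSet:
    """The three aligned views of one radiograph, each INPUT_SIDE squared."""

    whole: np.ndarray
    left: np.ndarray
    right_flipped: np.ndarray

    def __post_init__(self) -> None:
        shape = self.whole.shape
        if len(shape) != 2 or shape[0] != shape[1]:
            raise ValueError("views must be square 2-d matrices")
        for name in ("whole", "left", "right_flipped"):
            v = getattr(self, name)
            if v.shape != shape:
                raise ValueError(f"view {name} must match shape {shape}")


def resize_to_input(image: np.ndarray, side: int = INPUT_SIDE) -> np.ndarray:
    """Bilinear resample to ``side x side``, clipped back into [0, 1].

    No anti-alias prefilter; an input already at the target size is returned
    unchanged (up to copy).
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2 or image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("resize_to_input needs a 2-d image of at least 2 x 2")
    if image.shape == (side, side):
        return image.copy()
    out = _sk_resize(image, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def split_halves(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split at the vertical midline: left gets ``floor(W/2)`` columns, right
    the remaining ``ceil(W/2)``; concatenating left|right restores the input."""
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[1] < 2:
        raise ValueError("split_halves needs a 2-d image with width >= 2")
    mid = image.shape[1] // 2
    return image[:, :mid], image[:, mid:]


def hflip(image: np.ndarray) -> np.ndarray:
    """Reverse column order (an involution)."""
    return np.asarray(image)[:, ::-1]


def make_views(image: ImageRecord | np.ndarray, side: int = INPUT_SIDE) -> ViewSet:
    """Build the three aligned views of a radiograph."""
    pixels = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    whole = resize_to_input(pixels, side)
    left_half, right_half = split_halves(pixels)
    return ViewSet(
        whole=whole,
        left=resize_to_input(left_half, side),
        right_flipped=resize_to_input(hflip(right_half), side),
    )
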