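"""Cuticle-redness quantification from RGB photographs.

The pipeline mirrors the morphometric protocol for scoring beetle cuticle
pigmentation: from a ventral photograph, a user-supplied rectangle bounds
the metasternum; the maximal inscribed square is extracted; pixels whose
brightness falls in the top or bottom 10% (by pixel-count rank) are masked
to suppress specular highlights and shadows; and the remaining pixels are
summarized by the redness index

    sum over unmasked pixels of [R - mean(R, G, B)] / n

where n is the number of unmasked pixels. A grayscale image scores exactly
0; a pure-red image scores 255 - 255/3 = 170. Because the index subtracts
the per-pixel channel mean, it is invariant to adding a constant to all
three channels (exposure shifts that do not clip).

Brightness is defined here as the arithmetic mean of R, G and B — the same
quantity the index itself is expressed against. Alternative definitions
(max channel, BT.601 luma) are selectable but not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from PIL import Image

__all__ = [
    "RGBImage",
    "SquareROI",
    "BrightnessMask",
    "RednessResult",
    "BRIGHTNESS_FUNCTIONS",
    "read_image",
    "write_image",
    "extract_square",
    "pixel_brightness",
    "mask_extremes",
    "redness_index",
    "score_image",
    "write_mask_image",
]


@dataclass(frozen=True)
class RGBImage:
    """8-bit RGB raster; ``pixels`` has shape (height, width, 3), dtype uint8."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB array, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if arr.dtype != np.uint8:
            if np.any(arr < 0) or np.any(arr > 255):
                raise ValueError("channel values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "pixels", arr)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class SquareROI:
    """Square region, 0-based, half-open: columns [x0, x0+side), rows [y0, y0+side)."""

    x0: int
    y0: int
    side: int

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0 or self.side < 1:
            raise ValueError("ROI must have nonnegative origin and side >= 1")

    def pixels_from(self, image: RGBImage) -> np.ndarray:
        """Flattened (side*side, 3) pixel array of this ROI, row-major."""
        if self.x0 + self.side > image.width or self.y0 + self.side > image.height:
            raise ValueError("ROI extends beyond image bounds")
        block = image.pixels[
            self.y0 : self.y0 + self.side, self.x0 : self.x0 + self.side
        ]
        return block.reshape(-1, 3)


@dataclass(frozen=True)
class BrightnessMask:
    """Per-pixel exclusion mask (True = excluded) with the fractions that built it."""

    excluded: np.ndarray
    low_frac: float = 0.10
    high_frac: float = 0.10

    def __post_init__(self) -> None:
        object.__setattr__(self, "excluded", np.asarray(self.excluded, dtype=bool))


@dataclass(frozen=True)
class RednessResult:
    """Redness index with pixel bookkeeping; n_pixels_used is the protocol's n."""

    n_pixels_total: int
    n_pixels_used: int
    index: float

    def __post_init__(self) -> None:
        if not (0 < self.n_pixels_used <= self.n_pixels_total):
            raise ValueError("invalid pixel counts")


def _brightness_mean(pixels: np.ndarray) -> np.ndarray:
    return np.asarray(pixels, dtype=np.float64).mean(axis=-1)


def _brightness_max(pixels: np.ndarray) -> np.ndarray:
    return np.asarray(pixels, dtype=np.float64).max(axis=-1)


def _brightness_luma(pixels: np.ndarray) -> np.ndarray:
    w = np.array([0.299, 0.587, 0.114])
    return np.asarray(pixels, dtype=np.float64) @ w

BRIGHTNESS_FUNCTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "mean": _brightness_mean,
    "max": _brightness_max,
    "luma": _brightness_luma,
}


def read_image(path: str | Path) -> RGBImage:
    """Read an 8-bit RGB PNG or TIFF. Images with an alpha channel are rejected."""
    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA", "PA"):
            raise ValueError(
                f"{path}: image has an alpha channel; flatten it before analysis"
            )
        if im.mode != "RGB":
            raise ValueError(f"{path}: expected 8-bit RGB, got mode {im.mode!r}")
        return RGBImage(np.asarray(im, dtype=np.uint8))


def write_image(image: RGBImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)


def extract_square(
    image: RGBImage, rect: tuple[int, int, int, int]
) -> SquareROI:
    """Maximal square inscribed in ``rect`` = (x, y, width, height).

    The square is centered along the rectangle's longer axis; an odd
    leftover is split with the floor toward the top/left.
    """
    x, y, w, h = rect
    if w < 1 or h < 1:
        raise ValueError("rectangle must have positive width and height")
    if x < 0 or y < 0 or x + w > image.width or y + h > image.height:
        raise ValueError("rectangle extends beyond image bounds")
    side = min(w, h)
    return SquareROI(x0=x + (w - side) // 2, y0=y + (h - side) // 2, side=side)


def pixel_brightness(pixel, method: str = "mean") -> float:
    """Brightness of a single (R, G, B) triple; default is mean(R, G, B)."""
    arr = np.asarray(pixel, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("channel values must lie in [0, 255]")
    return float(BRIGHTNESS_FUNCTIONS[method](arr))


def mask_extremes(
    roi_pixels: np.ndarray,
    low_frac: float = 0.10,
    high_frac: float = 0.10,
    brightness: str = "mean",
) -> BrightnessMask:
    """Mask the brightest ``high_frac`` and dimmest ``low_frac`` of pixels.

    Quantiles use the nearest-rank method over all ROI pixels; a pixel is
    masked iff its brightness is strictly below the low quantile or
    strictly above the high quantile. Strict comparisons guarantee that a
    uniform image masks nothing and that at least
    ``(1 - low_frac - high_frac) * N`` pixels are always retained.
    """
    pixels = np.asarray(roi_pixels)
    if pixels.size == 0:
        raise ValueError("ROI contains no pixels")
    if low_frac < 0 or high_frac < 0 or low_frac + high_frac >= 1:
        raise ValueError("fractions must be nonnegative and sum to < 1")
    b = BRIGHTNESS_FUNCTIONS[brightness](pixels)
    n = b.size
    order = np.sort(b)
    # Nearest-rank quantile: value at 1-based rank ceil(q * n), floored at 1.
    low_rank = max(1, int(np.ceil(low_frac * n)))
    high_rank = max(1, int(np.ceil((1.0 - high_frac) * n)))
    low_q = order[low_rank - 1]
    high_q = order[high_rank - 1]
    excluded = (b < low_q) | (b > high_q)
    return BrightnessMask(excluded=excluded, low_frac=low_frac, high_frac=high_frac)


def redness_index(roi_pixels: np.ndarray, mask: BrightnessMask) -> RednessResult:
    """Mean of R - (R+G+B)/3 over unmasked pixels."""
    pixels = np.asarray(roi_pixels, dtype=np.float64)
    keep = ~mask.excluded
    n_used = int(keep.sum())
    if n_used == 0:
        raise ValueError("all pixels masked; redness index undefined")
    kept = pixels[keep]
    index = float(np.mean(kept[:, 0] - kept.mean(axis=1)))
    return RednessResult(
        n_pixels_total=pixels.shape[0], n_pixels_used=n_used, index=index
    )


def score_image(
    image: RGBImage,
    rect: tuple[int, int, int, int],
    low_frac: float = 0.10,
    high_frac: float = 0.10,
    brightness: str = "mean",
) -> RednessResult:
    """Full pipeline: square extraction, extreme-brightness masking, redness index."""
    roi = extract_square(image, rect)
    pixels = roi.pixels_from(image)
    mask = mask_extremes(pixels, low_frac, high_frac, brightness=brightness)
    return redness_index(pixels, mask)


def write_mask_image(
    image: RGBImage,
    rect: tuple[int, int, int, int],
    path: str | Path,
    low_frac: float = 0.10,
    high_frac: float = 0.10,
    brightness: str = "mean",
) -> None:
    """Write the ROI as a PNG with masked pixels painted blue (visual QC)."""
    roi = extract_square(image, rect)
    pixels = roi.pixels_from(image)
    mask = mask_extremes(pixels, low_frac, high_frac, brightness=brightness)
    out = pixels.copy()
    out[mask.excluded] = (0, 0, 255)
    write_image(RGBImage(out.reshape(roi.side, roi.side, 3)), path)
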