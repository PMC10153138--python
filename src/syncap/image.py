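"""Calibrated 2D image container and TIFF round-trip helpers.

The whole pipeline operates on maximum-intensity projections stored as
single-channel rasters with a physical pixel size in micrometres. Images
are written as ImageJ-dialect TIFF (32-bit float for intensities, 16-bit
unsigned for label maps) with the pixel size encoded in the resolution
tags, so FIJI opens them with correct spatial calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Image2D", "read_image", "write_image", "read_labels", "write_labels"]


@dataclass
class Image2D:
    """A calibrated grayscale raster.

    Parameters
    ----------
    pixels
        2D array of nonnegative, finite intensities (any float dtype).
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    channel_name
        Free-text channel label (e.g. ``"mCherry::Moe"``).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D raster, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def field_area_um2(self) -> float:
        """Total imaged area in μm²."""
        return float(self.pixels.size) * self.pixel_size_um**2

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """Copy of this image with the raster replaced, calibration kept."""
        return Image2D(pixels, self.pixel_size_um, self.channel_name)


def _resolution(pixel_size_um: float) -> tuple[tuple[int, int], tuple[int, int]]:
    # pixels per micrometre, as an exact rational for byte-stable output
    r = Fraction(1.0 / pixel_size_um).limit_denominator(10**6)
    return ((r.numerator, r.denominator), (r.numerator, r.denominator))


def write_image(path: str | Path, img: Image2D) -> None:
    """Write as 32-bit float ImageJ TIFF with μm calibration."""
    tifffile.imwrite(
        path,
        img.pixels.astype(np.float32),
        imagej=True,
        resolution=_resolution(img.pixel_size_um),
        metadata={"unit": "um"},
    )


def write_labels(path: str | Path, labels: np.ndarray, pixel_size_um: float) -> None:
    """Write an integer label map as 16-bit unsigned ImageJ TIFF."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label values out of uint16 range")
    tifffile.imwrite(
        path,
        labels.astype(np.uint16),
        imagej=True,
        resolution=_resolution(pixel_size_um),
        metadata={"unit": "um"},
    )


def _pixel_size_from_tags(tf: tifffile.TiffFile) -> float | None:
    page = tf.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    return den / num


def read_image(
    path: str | Path, pixel_size_um: float | None = None, channel_name: str = ""
) -> Image2D:
    """Read a single-channel TIFF; an explicit ``pixel_size_um`` overrides tags."""
    with tifffile.TiffFile(path) as tf:
        pixels = tf.asarray()
        size = pixel_size_um if pixel_size_um is not None else _pixel_size_from_tags(tf)
    if size is None:
        raise ValueError(
            f"{path}: no resolution tags; pass pixel_size_um explicitly"
        )
    return Image2D(np.asarray(pixels, dtype=np.float64), size, channel_name)


def read_labels(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a label-map TIFF; returns (labels, pixel size or None)."""
    with tifffile.TiffFile(path) as tf:
        labels = tf.asarray().astype(np.int64)
        size = _pixel_size_from_tags(tf)
    return labels, size
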