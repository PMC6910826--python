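"""Calibrated image containers and TIFF input/output.

All physical quantities in this package are micrometres (µm) or µm²; all
pixel coordinates are 0-based with half-open bounding boxes. A
:class:`CalibratedImage` couples a 2-D intensity raster to its µm-per-pixel
scale so that downstream morphometry can report physical sizes.

TIFF files written here carry the pixel size twice: exactly, in a JSON
ImageDescription tag, and approximately, in the standard X/YResolution
rational tags (pixels per centimetre) for interoperability with viewers.
On read the JSON value wins; a file with neither and no override is an
error — the pixel size is never silently defaulted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "CalibratedImage",
    "BinaryMask",
    "CalibrationError",
    "read_calibrated_tiff",
    "write_calibrated_tiff",
]


class CalibrationError(ValueError):
    """Raised when a TIFF carries no usable pixel-size calibration."""


@dataclass
class CalibratedImage:
    """A single-channel 2-D fluorescence raster with physical calibration.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities. NaN marks masked-out pixels
        (e.g. outside a rotational-average selection circle).
    pixel_size_um
        Edge length of one pixel in µm. Must be positive.
    channel
        Free-text channel label, e.g. ``"zdisc"`` or ``"actin"``.
    bit_depth
        Nominal acquisition depth; histogramming always uses 256 bins
        regardless, this is informational.
    meta
        Open provenance dictionary (e.g. rotation-average parameters).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = ""
    bit_depth: int = 16
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D raster")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        finite = self.pixels[np.isfinite(self.pixels)]
        if finite.size and finite.min() < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field in µm."""
        h, w = self.pixels.shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)


@dataclass
class BinaryMask:
    """Bright-object mask produced by thresholding a CalibratedImage.

    ``pixels`` is True exactly where the source intensity is strictly
    greater than ``threshold_value`` (dark-background convention).
    """

    pixels: np.ndarray
    threshold_value: float
    polarity: str = "bright"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


_DESC_KEY = "zdiscquant"


def write_calibrated_tiff(path: str | Path, images: CalibratedImage | list[CalibratedImage]) -> None:
    """Write one or more calibrated images as a (multi-page) float32 TIFF."""
    if isinstance(images, CalibratedImage):
        images = [images]
    if not images:
        raise ValueError("nothing to write")
    px = images[0].pixel_size_um
    for im in images:
        if im.pixel_size_um != px:
            raise ValueError("all pages must share one pixel size")
    data = np.stack([im.pixels.astype(np.float32) for im in images])
    if data.shape[0] == 1:
        data = data[0]
    desc = json.dumps(
        {_DESC_KEY: {"pixel_size_um": px, "channels": [im.channel for im in images]}}
    )
    # resolution tags in pixels per centimetre (1 cm = 1e4 µm)
    res = 1e4 / px
    tifffile.imwrite(
        path,
        data,
        description=desc,
        resolution=(res, res),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )


def _pixel_size_from_tags(page: "tifffile.TiffPage") -> float | None:
    try:
        unit = page.tags["ResolutionUnit"].value
        xres = page.tags["XResolution"].value
    except KeyError:
        return None
    num, den = xres
    if num == 0:
        return None
    ppu = num / den  # pixels per unit
    # TIFF resolution units: 2 = inch, 3 = centimetre
    unit = int(unit)
    if unit == 3:
        return 1e4 / ppu
    if unit == 2:
        return 25400.0 / ppu
    return None


def read_calibrated_tiff(
    path: str | Path, pixel_size_override: float | None = None
) -> list[CalibratedImage]:
    """Read a TIFF as a list of CalibratedImage, one per page.

    The pixel size is resolved in this order: explicit override, exact JSON
    description written by :func:`write_calibrated_tiff`, standard
    resolution tags. If none apply a :class:`CalibrationError` is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
        first = tf.pages[0]
        desc = first.description or ""
        channels: list[str] = []
        px: float | None = None
        try:
            payload = json.loads(desc).get(_DESC_KEY, {})
            px = float(payload["pixel_size_um"])
            channels = list(payload.get("channels", []))
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            px = _pixel_size_from_tags(first)
    if pixel_size_override is not None:
        px = float(pixel_size_override)
    if px is None:
        raise CalibrationError(
            f"{path} has no pixel-size metadata; pass pixel_size_override (µm/px)"
        )
    out = []
    for i, raster in enumerate(pages):
        label = channels[i] if i < len(channels) else ""
        out.append(CalibratedImage(np.asarray(raster), px, channel=label))
    return out
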