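"""Grayscale image and ground-truth I/O, breast masking, coordinate conventions.

All code in this package works in a single coordinate frame: 0-based
(row, col) indices with row 0 at the top of the image.  Mini-MIAS ground
truth places its origin at the bottom-left, so the y coordinate is
converted to ``row = height - 1 - y`` at parse time and never touched
again downstream.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import InputError

logger = logging.getLogger(__name__)

#: Pixel spacing of the digitised films the default geometry is tuned to.
DEFAULT_PIXEL_SPACING_MM = 0.07


@dataclass
class GrayImage:
    """A 2-D grayscale intensity grid with an optional physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities.  The dtype of a
        file read is preserved (8- or 16-bit integer); computed images
        may be float.
    pixel_spacing_mm
        Physical side length of one pixel in millimetres.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("image must be a non-empty 2-D grid")
        arr = self.pixels
        if not np.all(np.isfinite(arr.astype(float))):
            raise InputError("image intensities must be finite")
        if np.any(arr.astype(float) < 0):
            raise InputError("image intensities must be non-negative")
        if self.pixel_spacing_mm is not None and self.pixel_spacing_mm <= 0:
            raise InputError("pixel_spacing_mm must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BreastMask:
    """Binary in-breast mask paired with a :class:`GrayImage`."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise InputError("mask must be 2-D")

    @property
    def n_inside(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class MiasTruthRecord:
    """One abnormality from the mini-MIAS ground-truth file.

    The cluster is described as a circle: everything segmented inside it
    is treated as pathological truth.
    """

    image_id: str
    center_col: float
    center_row: float
    radius_px: float
    abnormality_class: str = "CALC"

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise InputError("truth radius must be positive")


def read_image(path: str | os.PathLike, format: str | None = None) -> GrayImage:
    """Read a grayscale PGM/PNG/TIFF raster into a :class:`GrayImage`.

    Bit depth is preserved; row 0 is the top of the image.  A colour
    image raises :class:`InputError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises many concrete types
        raise InputError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise InputError(f"{path} is a colour image; expected grayscale")
    # 16-bit PGM comes back as a signed wide type; store at the true depth
    if np.issubdtype(arr.dtype, np.signedinteger) and arr.min() >= 0:
        arr = arr.astype(np.uint8 if arr.max() <= 255 else np.uint16)
    return GrayImage(arr)


def write_image(image: GrayImage, path: str | os.PathLike) -> None:
    """Write an image to PGM/PNG/TIFF, chosen by file extension.

    Float images are rounded and stored as 16-bit; integer dtypes are
    kept, so a read/write/read cycle is bit-exact.
    """
    arr = image.pixels
    if not np.issubdtype(arr.dtype, np.integer):
        arr = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    iio.imwrite(os.fspath(path), arr)


def parse_mias_truth(path: str | os.PathLike, image_height: int = 1024) -> list[MiasTruthRecord]:
    """Parse a mini-MIAS style ground-truth listing.

    Each line reads ``id background class [severity x y radius]``; lines
    whose class is ``NORM`` or which lack the circle are skipped with a
    warning.  The MIAS y (origin bottom-left) is converted to a top-left
    row index.
    """
    records: list[MiasTruthRecord] = []
    with open(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            image_id = tokens[0]
            abclass = tokens[2] if len(tokens) > 2 else "NORM"
            if abclass.upper() == "NORM":
                continue
            if len(tokens) < 7:
                logger.warning("line %d (%s): no x/y/radius, skipped", lineno, image_id)
                continue
            try:
                x, y, radius = (float(t) for t in tokens[4:7])
            except ValueError as exc:
                raise InputError(f"line {lineno}: malformed numeric field: {line!r}") from exc
            row = image_height - 1 - y
            records.append(
                MiasTruthRecord(
                    image_id=image_id,
                    center_col=x,
                    center_row=row,
                    radius_px=radius,
                    abnormality_class=abclass.upper(),
                )
            )
    return records


def objects_in_circle(objects, truth: MiasTruthRecord):
    """Objects whose centroid lies inside (<= radius) the truth circle.

    This is the circle-as-truth convention: the in-circle segmented
    objects constitute the pathological set for that cluster.
    """
    inside = []
    for obj in objects:
        d = np.hypot(obj.centroid_row - truth.center_row, obj.centroid_col - truth.center_col)
        if d <= truth.radius_px:
            inside.append(obj)
    return inside


def breast_mask(image: GrayImage) -> BreastMask:
    """Estimate the breast region of a real mammogram.

    Otsu threshold, keep the largest connected component, fill holes.
    The original study never describes its breast delimitation; this is
    a standard stand-in isolated behind one function.
    """
    arr = image.pixels.astype(float)
    thr = threshold_otsu(arr)
    fg = arr > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        return BreastMask(np.ones_like(fg, dtype=bool))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(labels == largest)
    return BreastMask(mask)
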