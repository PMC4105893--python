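"""The three-region "form filter" and candidate segmentation.

A plain Laplacian-of-Gaussian responds best to blobs whose radius
matches its scale, so a single LoG cannot serve the whole 0.1-1.0 mm
range of microcalcification sizes.  The form filter fixes this with
three concentric regions:

1. a positive core of radius ``R1`` shaped like the positive lobe of a
   LoG, matched to the smallest detectable microcalcification;
2. a null annulus from ``R1`` to ``R2`` (the largest detectable size),
   whose pixels contribute nothing to the convolution;
3. a narrow negative rim beyond ``R2``: the negative LoG tail translated
   outward by ``dR = R2 - R1`` and rescaled by ``alpha`` so the kernel
   weights sum to zero.

A bright disk of any radius in [R1, R2] then covers the full positive
core and only zero-weight annulus pixels, so the peak response is nearly
constant across the whole pathological size interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, InputError
from .features import MicroObject
from .image_io import BreastMask, GrayImage

__all__ = [
    "FilterConfig",
    "FormKernel",
    "SegmentationConfig",
    "log_value",
    "build_kernel",
    "convolve",
    "segment_response",
    "segment_image",
]


def log_value(x: float, y: float, sigma: float) -> float:
    """Negated Laplacian of Gaussian at pixel offset (x, y).

    -lap(H_sigma)(x, y) = -(1/(pi s^2)) * ((x^2+y^2-2s^2)/(2s^4)) * exp(-(x^2+y^2)/(2s^2))

    Positive at the origin (1/(pi*sigma^4) there), crosses zero on the
    circle r^2 = 2 sigma^2 and is negative beyond it, decaying to zero.
    Accepts scalars or arrays.
    """
    if sigma <= 0:
        raise ConfigError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x * x + y * y
    s2 = sigma * sigma
    val = -(1.0 / (math.pi * s2)) * ((r2 - 2.0 * s2) / (2.0 * s2 * s2)) * np.exp(-r2 / (2.0 * s2))
    return val if val.ndim else float(val)


@dataclass(frozen=True)
class FilterConfig:
    """Geometry of the three-region filter.

    ``r1``/``r2`` bound the target radius interval in pixels.  ``sigma``
    defaults to ``r1 / sqrt(2)`` so the positive LoG lobe (zero crossing
    at sqrt(2)*sigma) exactly spans the core.  ``kernel_halfwidth``
    defaults to the smallest integer >= r2 + 3*sigma, enough for the
    translated negative tail to decay inside the kernel.
    """

    r1: float
    r2: float
    sigma: float | None = None
    kernel_halfwidth: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.r1 <= self.r2):
            raise ConfigError("need 0 < r1 <= r2")
        if self.sigma is None:
            object.__setattr__(self, "sigma", self.r1 / math.sqrt(2.0))
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if self.kernel_halfwidth is None:
            object.__setattr__(self, "kernel_halfwidth", math.ceil(self.r2 + 3.0 * self.sigma))
        if self.kernel_halfwidth < self.r2 + 3.0 * self.sigma:
            raise ConfigError("kernel_halfwidth must be >= r2 + 3*sigma")

    @property
    def delta_r(self) -> float:
        return self.r2 - self.r1

    @classmethod
    def from_spacing(cls, pixel_spacing_mm: float = 0.07,
                     min_radius_mm: float = 0.15, max_radius_mm: float = 0.5) -> "FilterConfig":
        """Default geometry from the microcalcification size range.

        Microcalcifications span 0.1-1.0 mm in diameter with a ~0.3 mm
        mean, which at 0.07 mm spacing gives r1 = 2 px, r2 = 7 px.
        """
        r1 = max(1, round(min_radius_mm / pixel_spacing_mm))
        r2 = max(r1, round(max_radius_mm / pixel_spacing_mm))
        return cls(r1=r1, r2=r2)


@dataclass
class FormKernel:
    """Discrete three-region kernel with the null-sum invariant."""

    weights: np.ndarray
    alpha: float
    config: FilterConfig

    @property
    def positive_sum(self) -> float:
        return float(self.weights[self.weights > 0].sum())

    def save_txt(self, path) -> None:
        np.savetxt(path, self.weights)

    @staticmethod
    def load_txt(path, config: FilterConfig, alpha: float = float("nan")) -> "FormKernel":
        return FormKernel(np.loadtxt(path), alpha, config)


def build_kernel(config: FilterConfig) -> FormKernel:
    """Build the discrete three-region kernel.

    Region 1 (r < r1) carries the LoG values at each offset; region 2
    (r1 <= r <= r2) is exactly zero; region 3 (r > r2) carries the LoG
    evaluated at the translated radius ``r - dR``, scaled by ``alpha``
    so the negative weights sum to the negated positive sum.  Both sums
    are pixel sums on the discrete grid, so the null-sum condition is
    exact up to float rounding.
    """
    hw = int(config.kernel_halfwidth)
    idx = np.arange(-hw, hw + 1, dtype=float)
    dx, dy = np.meshgrid(idx, idx)
    r = np.hypot(dx, dy)

    weights = np.zeros_like(r)
    core = r < config.r1
    weights[core] = log_value(dx[core], dy[core], config.sigma)
    if not np.any(weights > 0):
        raise ConfigError("positive core is empty on the discrete grid; "
                          "increase r1, sigma or the kernel size")

    tail = r > config.r2
    tail_vals = np.zeros_like(r)
    # radial translation: the tail value depends only on r - dR
    tail_vals[tail] = log_value(r[tail] - config.delta_r, 0.0, config.sigma)
    tail_vals[tail_vals > 0] = 0.0  # guard: keep region 3 non-positive
    neg_sum = tail_vals.sum()
    if neg_sum >= 0:
        raise ConfigError("negative tail is empty on the discrete grid; "
                          "increase the kernel halfwidth")

    pos_sum = weights[core].sum()
    alpha = pos_sum / (-neg_sum)
    weights = weights + alpha * tail_vals
    return FormKernel(weights=weights, alpha=float(alpha), config=config)


def convolve(image: GrayImage | np.ndarray, kernel: FormKernel) -> np.ndarray:
    """Correlate the image with the kernel (reflect padding at borders).

    The kernel is rotationally symmetric, so correlation and convolution
    coincide.  The null sum makes the response vanish on constant
    regions; bright compact blobs produce positive peaks.
    """
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if kernel.weights.shape[0] > arr.shape[0] or kernel.weights.shape[1] > arr.shape[1]:
        raise InputError("kernel larger than image")
    return ndimage.correlate(arr.astype(float), kernel.weights, mode="reflect")


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholding and component-filtering rules for the filter response.

    ``quantile`` mode thresholds at the given in-mask response quantile
    (intensity-scale invariant, the default); ``absolute`` uses the raw
    value; ``zscore`` uses mean + value * std of the in-mask response.
    """

    threshold_mode: str = "quantile"
    threshold_value: float = 0.997
    connectivity: int = 8
    min_area_px: int = 1
    max_area_px: int = 400

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("absolute", "quantile", "zscore"):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if self.min_area_px < 1 or self.max_area_px < self.min_area_px:
            raise ConfigError("need 1 <= min_area_px <= max_area_px")

    def resolve_threshold(self, response: np.ndarray, mask: np.ndarray) -> float:
        vals = response[mask]
        if self.threshold_mode == "absolute":
            return float(self.threshold_value)
        if self.threshold_mode == "quantile":
            return float(np.quantile(vals, self.threshold_value))
        return float(vals.mean() + self.threshold_value * vals.std())


def segment_response(
    response: np.ndarray,
    mask: BreastMask | np.ndarray,
    seg: SegmentationConfig,
    image: GrayImage | np.ndarray | None = None,
) -> list[MicroObject]:
    """Group supra-threshold in-mask response pixels into candidate objects.

    Connected components (4- or 8-connectivity) outside the configured
    area band are discarded.  Each surviving component becomes a
    :class:`MicroObject` carrying its pixel set and, when ``image`` is
    given, the original intensities at those pixels (otherwise the
    response values, useful for response-space tests).
    """
    bits = mask.bits if isinstance(mask, BreastMask) else np.asarray(mask, dtype=bool)
    if bits.shape != response.shape:
        raise InputError("mask and response dimensions differ")
    if not bits.any():
        return []
    thr = seg.resolve_threshold(response, bits)
    fg = (response > thr) & bits
    structure = np.ones((3, 3), dtype=bool) if seg.connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    labels, n = ndimage.label(fg, structure=structure)
    if n == 0:
        return []
    source = response if image is None else (image.pixels if isinstance(image, GrayImage) else np.asarray(image))
    objects: list[MicroObject] = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == lab
        area = int(comp.sum())
        if not (seg.min_area_px <= area <= seg.max_area_px):
            continue
        rows, cols = np.nonzero(comp)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        pixels = np.column_stack([rows, cols])
        intens = source[rows, cols].astype(float)
        objects.append(MicroObject(pixels=pixels, intensities=intens))
    return objects


def segment_image(
    image: GrayImage,
    mask: BreastMask | np.ndarray | None = None,
    filter_config: FilterConfig | None = None,
    seg: SegmentationConfig | None = None,
) -> list[MicroObject]:
    """Convenience: build kernel, convolve, threshold, return objects."""
    from .image_io import breast_mask

    if filter_config is None:
        filter_config = FilterConfig.from_spacing(image.pixel_spacing_mm)
    if seg is None:
        seg = SegmentationConfig()
    if mask is None:
        mask = breast_mask(image)
    kernel = build_kernel(filter_config)
    response = convolve(image, kernel)
    return segment_response(response, mask, seg, image=image)
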