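"""Per-object feature extraction and (0,1) normalization.

Each segmented candidate is summarised by nine numbers: its centroid
position (x = column, y = row), three shape descriptors (area,
perimeter, eccentricity) and four intensity statistics (mean, standard
deviation, skewness, kurtosis).  Position alone is what standard
fuzzy c-means clusters on; the seven structural components are what the
feature-augmented variant adds.

Features carry different units, so before clustering each one is mapped
to (0, 1) by ``(x - min) / (max - min)`` with ``min = mean - 4*sigma``
and ``max = mean + 4*sigma`` computed over the population of objects in
the image being clustered, then clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = [
    "FEATURE_NAMES",
    "MicroObject",
    "FeatureVector",
    "NormalizationParams",
    "extract_features",
    "fit_normalization",
    "apply_normalization",
    "feature_matrix",
    "normalize_features",
]

#: Column order of every feature matrix in the package.
FEATURE_NAMES = (
    "x", "y", "area", "perimeter", "eccentricity",
    "mean_int", "std_int", "skew_int", "kurt_int",
)


@dataclass(eq=False)
class MicroObject:
    """A segmented candidate microcalcification.

    ``pixels`` is an (n, 2) array of (row, col) positions, ``intensities``
    the original image values at those pixels, aligned 1:1.
    """

    pixels: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        self.intensities = np.atleast_1d(np.asarray(self.intensities, dtype=float))
        if self.pixels.size == 0:
            raise InputError("object must own at least one pixel")
        if self.pixels.shape[0] != self.intensities.shape[0]:
            raise InputError("pixels and intensities must align 1:1")

    @property
    def area(self) -> int:
        return self.pixels.shape[0]

    @property
    def centroid_row(self) -> float:
        return float(self.pixels[:, 0].mean())

    @property
    def centroid_col(self) -> float:
        return float(self.pixels[:, 1].mean())


@dataclass(frozen=True)
class FeatureVector:
    """The 9-component description of one object (see FEATURE_NAMES)."""

    x: float
    y: float
    area: float
    perimeter: float
    eccentricity: float
    mean_int: float
    std_int: float
    skew_int: float
    kurt_int: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def _crack_perimeter(pixels: np.ndarray) -> float:
    """Boundary length as the count of exposed 4-neighbour pixel edges."""
    cells = {(int(r), int(c)) for r, c in pixels}
    exposed = 0
    for r, c in cells:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (r + dr, c + dc) not in cells:
                exposed += 1
    return float(exposed)


def _eccentricity(pixels: np.ndarray) -> float:
    """Ellipse eccentricity from second central moments of the pixel set.

    Each pixel is treated as a unit square (adds 1/12 to both diagonal
    moments), which keeps the value strictly below 1 even for one-pixel-
    wide bars and returns exactly 0 for symmetric shapes.
    """
    pos = pixels.astype(float)
    mu = pos.mean(axis=0)
    d = pos - mu
    m_rr = float((d[:, 0] ** 2).mean()) + 1.0 / 12.0
    m_cc = float((d[:, 1] ** 2).mean()) + 1.0 / 12.0
    m_rc = float((d[:, 0] * d[:, 1]).mean())
    # eigenvalues of the 2x2 covariance
    tr = m_rr + m_cc
    det = m_rr * m_cc - m_rc * m_rc
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + np.sqrt(disc)
    lam2 = tr / 2.0 - np.sqrt(disc)
    if lam1 <= 0:
        return 0.0
    return float(np.sqrt(max(1.0 - lam2 / lam1, 0.0)))


def extract_features(obj: MicroObject) -> FeatureVector:
    """Compute the 9-component feature vector of a segmented object.

    Intensity skewness and kurtosis use the population-moment
    definitions m3/m2^1.5 and m4/m2^2 (kurtosis is not excess); objects
    with zero intensity variance get std = skew = kurt = 0 so degenerate
    candidates stay neutral.
    """
    vals = obj.intensities
    mean_int = float(vals.mean())
    m2 = float(((vals - mean_int) ** 2).mean())
    if m2 > 0:
        std_int = float(np.sqrt(m2))
        skew_int = float(stats.skew(vals, bias=True))
        kurt_int = float(stats.kurtosis(vals, fisher=False, bias=True))
    else:
        std_int = skew_int = kurt_int = 0.0
    return FeatureVector(
        x=obj.centroid_col,
        y=obj.centroid_row,
        area=float(obj.area),
        perimeter=_crack_perimeter(obj.pixels),
        eccentricity=_eccentricity(obj.pixels),
        mean_int=mean_int,
        std_int=std_int,
        skew_int=skew_int,
        kurt_int=kurt_int,
    )


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature mean and sigma defining the (mean +/- 4 sigma) range."""

    mean: np.ndarray
    sigma: np.ndarray

    @property
    def min(self) -> np.ndarray:
        return self.mean - 4.0 * self.sigma

    @property
    def max(self) -> np.ndarray:
        return self.mean + 4.0 * self.sigma


def fit_normalization(vectors: list[FeatureVector] | np.ndarray) -> NormalizationParams:
    """Sample mean and (n-1) standard deviation of each feature.

    The population is the set of objects of the image being clustered;
    no global training statistics are involved.
    """
    X = np.asarray([v.as_array() for v in vectors] if not isinstance(vectors, np.ndarray) else vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("need at least 2 feature vectors to fit normalization")
    return NormalizationParams(mean=X.mean(axis=0), sigma=X.std(axis=0, ddof=1))


def apply_normalization(v: FeatureVector | np.ndarray, p: NormalizationParams) -> np.ndarray:
    """Map one vector through (x - min)/(max - min), clipped to [0, 1].

    A feature whose sigma is 0 is constant over the population and maps
    to 0.5 for every object.
    """
    x = v.as_array() if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)
    span = p.max - p.min
    out = np.full_like(x, 0.5)
    ok = span > 0
    out[ok] = (x[ok] - p.min[ok]) / span[ok]
    return np.clip(out, 0.0, 1.0)


def feature_matrix(objects) -> np.ndarray:
    """Stack extract_features over objects into an (N, 9) array."""
    return np.asarray([extract_features(o).as_array() for o in objects], dtype=float)


def normalize_features(X: np.ndarray, params: NormalizationParams | None = None):
    """Normalize an (N, 9) feature matrix; returns (X_norm, params)."""
    X = np.asarray(X, dtype=float)
    if params is None:
        if X.shape[0] < 2:
            raise InputError("need at least 2 objects to normalize")
        params = NormalizationParams(mean=X.mean(axis=0), sigma=X.std(axis=0, ddof=1))
    Xn = np.vstack([apply_normalization(row, params) for row in X])
    return Xn, params
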