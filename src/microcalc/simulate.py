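"""Ground-truthed synthetic mammogram generation by cluster injection.

Real pathological clusters cannot ship with the package, so the module
has two halves:

* template generation — a textured breast-like background (low-frequency
  parenchyma field plus white noise under a half-ellipse breast mask)
  and a "mother cluster" of M >= 4 disk-like microcalcifications whose
  footprints, per-pixel intensity elevations and relative geometry stand
  in for a cluster extracted from a reported image;
* the injection procedure — micros drawn without replacement from the
  mother cluster are stamped one at a time, each placed so that its
  displacement (angle and distance) from the previously placed micro is
  preserved, until n of them are in, with n uniform on [P, M] and P the
  nearest integer to 0.8*M.  Elevations are rescaled so the injected
  cluster keeps its mean elevation relative to the local parenchyma.

Because the injected positions are known exactly, images made this way
carry full ground truth for scoring the clustering stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, PlacementError
from .image_io import BreastMask, GrayImage

__all__ = [
    "MicroTemplate",
    "MotherCluster",
    "InjectionRecord",
    "generate_background",
    "generate_mother_cluster",
    "sample_n_micros",
    "inject_cluster",
    "scatter_noise_micros",
]


@dataclass(frozen=True)
class MicroTemplate:
    """One microcalcification of a mother cluster.

    ``offsets`` are (row, col) pixel offsets of the footprint around the
    micro's own centre; ``elevations`` the intensity added over the
    background at each footprint pixel; ``center`` the micro's position
    in the cluster frame.
    """

    offsets: np.ndarray
    elevations: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.offsets).size == 0:
            raise ConfigError("micro footprint must be non-empty")


@dataclass
class MotherCluster:
    """A template cluster whose geometry and intensities get re-injected."""

    micros: list[MicroTemplate]
    cluster_mean_elevation: float

    def __post_init__(self) -> None:
        if len(self.micros) < 4:
            raise ConfigError("a mother cluster needs M >= 4 micros")

    @property
    def M(self) -> int:
        return len(self.micros)

    @property
    def centers(self) -> np.ndarray:
        return np.vstack([m.center for m in self.micros])


@dataclass
class InjectionRecord:
    """Ground truth of one injected cluster."""

    image_id: str
    n_injected: int
    positions: np.ndarray  # (n, 2) centroid (row, col) of each injected micro
    source_indices: np.ndarray  # mother micro indices, in placement order
    labels: dict = field(default_factory=dict)


def generate_background(
    height: int,
    width: int,
    texture_scale_px: float = 40.0,
    base_level: float = 120.0,
    noise_sd: float = 2.0,
    seed=None,
    texture_amplitude: float = 8.0,
    max_value: float = 255.0,
) -> tuple[GrayImage, BreastMask]:
    """Textured parenchyma-like background under a half-ellipse breast mask.

    Band-limited Gaussian noise blurred at ``texture_scale_px`` and
    rescaled to ``texture_amplitude`` models the slow parenchyma
    modulation; independent white noise of sd ``noise_sd`` models film
    grain.  The mask is a half ellipse anchored to the left edge,
    covering well over a quarter of the frame.
    """
    if height < 1 or width < 1:
        raise ConfigError("image dimensions must be positive")
    rng = np.random.default_rng(seed)
    field_ = np.zeros((height, width), dtype=float)
    if texture_amplitude > 0:
        raw = rng.standard_normal((height, width))
        smooth = ndimage.gaussian_filter(raw, sigma=texture_scale_px, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            field_ = smooth * (texture_amplitude / sd)
    noise = rng.normal(0.0, noise_sd, size=(height, width)) if noise_sd > 0 else 0.0
    pixels = np.clip(base_level + field_ + noise, 0.0, max_value)

    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    a = 0.48 * height  # vertical semi-axis
    b = 0.85 * width   # horizontal semi-axis, anchored at col 0
    mask = ((rows - height / 2.0) / a) ** 2 + (cols / b) ** 2 <= 1.0
    return GrayImage(pixels), BreastMask(mask)


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = np.hypot(dy, dx) <= radius
    return np.column_stack([dy[keep], dx[keep]])


def generate_mother_cluster(
    M: int,
    micro_radius_range_px: tuple[float, float] = (1.0, 3.0),
    spread_px: float = 30.0,
    elevation_range: tuple[float, float] = (20.0, 60.0),
    seed=None,
    min_separation_px: float = 10.0,
) -> MotherCluster:
    """Synthesize a template cluster of M disk-like micros.

    Radii are uniform on ``micro_radius_range_px``, centres are scattered
    with Gaussian spread ``spread_px`` around the cluster origin (kept at
    least ``min_separation_px`` apart, as distinct bright spots), and
    per-pixel elevations are uniform on ``elevation_range``.
    """
    if M < 4:
        raise ConfigError("M >= 4 is required for a mother cluster")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    for _ in range(M):
        for _attempt in range(500):
            c = rng.normal(0.0, spread_px, size=2)
            if all(np.hypot(*(c - q)) >= min_separation_px for q in centers):
                centers.append(c)
                break
        else:
            raise ConfigError("could not separate micro centres; "
                              "increase spread_px or lower min_separation_px")
    micros: list[MicroTemplate] = []
    all_elev: list[np.ndarray] = []
    for center in centers:
        radius = rng.uniform(*micro_radius_range_px)
        offsets = _disk_offsets(radius)
        elevations = rng.uniform(*elevation_range, size=offsets.shape[0])
        micros.append(MicroTemplate(offsets=offsets, elevations=elevations, center=center))
        all_elev.append(elevations)
    mean_elev = float(np.concatenate(all_elev).mean())
    return MotherCluster(micros=micros, cluster_mean_elevation=mean_elev)


def sample_n_micros(M: int, seed=None) -> int:
    """Number of micros to inject: uniform on [P, M], P = round(0.8*M).

    The nearest-integer rule is half-up, so M = 4 gives P = 3 and the
    injected count never drops more than ~20% below the template size.
    """
    if M < 4:
        raise ConfigError("M >= 4 is required")
    rng = np.random.default_rng(seed)
    P = int(np.floor(0.8 * M + 0.5))
    return int(rng.integers(P, M + 1))


def inject_cluster(
    image: GrayImage,
    mask: BreastMask,
    mother: MotherCluster,
    seed=None,
    image_id: str = "synthetic",
    max_retries: int = 200,
    max_value: float | None = None,
) -> tuple[GrayImage, InjectionRecord]:
    """Stamp a mother cluster onto an image, preserving its geometry.

    One micro is drawn at random and placed at a random in-breast
    anchor; each subsequent micro (drawn without replacement) is placed
    so its displacement from the previously placed one equals the
    corresponding displacement inside the mother cluster.  The chain of
    preserved displacements makes the injected subset a rigid translate
    of the template subset.  Elevations are scaled by a single factor so
    the injected mean elevation matches ``cluster_mean_elevation`` times
    the local-to-global parenchyma brightness ratio.  Anchors whose
    footprints leave the mask are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    n = sample_n_micros(mother.M, seed=rng)
    order = rng.permutation(mother.M)[:n]
    chosen = [mother.micros[i] for i in order]
    centers = np.vstack([m.center for m in chosen])
    rel = centers - centers[0]  # displacement of each micro from the first

    bits = mask.bits
    in_rows, in_cols = np.nonzero(bits)
    if in_rows.size == 0:
        raise PlacementError("mask has no interior pixels")
    H, W = bits.shape

    placement = None
    for _ in range(max_retries):
        k = rng.integers(0, in_rows.size)
        anchor = np.array([in_rows[k], in_cols[k]], dtype=float)
        positions = anchor + rel
        ok = True
        for m, pos in zip(chosen, positions):
            pix = np.rint(pos + m.offsets).astype(int)
            if (pix[:, 0] < 0).any() or (pix[:, 0] >= H).any() or \
               (pix[:, 1] < 0).any() or (pix[:, 1] >= W).any() or \
               not bits[pix[:, 0], pix[:, 1]].all():
                ok = False
                break
        if ok:
            placement = positions
            break
    if placement is None:
        raise PlacementError("could not place the cluster inside the mask")

    arr = image.pixels.astype(float).copy()
    # intensity matching: one multiplicative rescale per injected cluster
    foot_rows = []
    foot_cols = []
    for m, pos in zip(chosen, placement):
        pix = np.rint(pos + m.offsets).astype(int)
        foot_rows.append(pix[:, 0])
        foot_cols.append(pix[:, 1])
    fr = np.concatenate(foot_rows)
    fc = np.concatenate(foot_cols)
    local_mean = float(arr[fr, fc].mean())
    global_mean = float(arr[bits].mean())
    ratio = local_mean / global_mean if global_mean > 0 else 1.0
    subset_mean = float(np.concatenate([m.elevations for m in chosen]).mean())
    scale = (mother.cluster_mean_elevation / subset_mean) * ratio if subset_mean > 0 else 1.0

    for m, pos in zip(chosen, placement):
        pix = np.rint(pos + m.offsets).astype(int)
        np.add.at(arr, (pix[:, 0], pix[:, 1]), scale * m.elevations)
    if max_value is not None:
        arr = np.clip(arr, 0.0, max_value)

    record = InjectionRecord(
        image_id=image_id,
        n_injected=int(n),
        positions=np.asarray(placement, dtype=float),
        source_indices=np.asarray(order, dtype=int),
    )
    return GrayImage(arr, image.pixel_spacing_mm), record


def scatter_noise_micros(
    image: GrayImage,
    mask: BreastMask,
    n_noise: int,
    micro_radius_range_px: tuple[float, float] = (1.0, 2.5),
    elevation_range: tuple[float, float] = (10.0, 25.0),
    seed=None,
    min_separation_px: float = 12.0,
    avoid: np.ndarray | None = None,
    max_value: float | None = None,
) -> tuple[GrayImage, np.ndarray]:
    """Sprinkle isolated bright spots (false-positive candidates).

    Emulates the healthy segmented objects that survive filtering on a
    real mammogram: small disks with their own intensity statistics,
    placed inside the mask at mutual separation ``min_separation_px``
    and away from ``avoid`` positions.  Returns the new image and the
    (n, 2) centroids actually placed.
    """
    rng = np.random.default_rng(seed)
    arr = image.pixels.astype(float).copy()
    bits = mask.bits
    in_rows, in_cols = np.nonzero(bits)
    placed: list[np.ndarray] = []
    existing = [] if avoid is None else [np.asarray(p, dtype=float) for p in np.atleast_2d(avoid)]
    attempts = 0
    H, W = bits.shape
    while len(placed) < n_noise and attempts < 200 * max(n_noise, 1):
        attempts += 1
        k = rng.integers(0, in_rows.size)
        pos = np.array([in_rows[k], in_cols[k]], dtype=float)
        near = [q for q in placed + existing
                if np.hypot(*(q - pos)) < min_separation_px]
        if near:
            continue
        radius = rng.uniform(*micro_radius_range_px)
        offsets = _disk_offsets(radius)
        pix = np.rint(pos + offsets).astype(int)
        if (pix[:, 0] < 0).any() or (pix[:, 0] >= H).any() or \
           (pix[:, 1] < 0).any() or (pix[:, 1] >= W).any() or \
           not bits[pix[:, 0], pix[:, 1]].all():
            continue
        elev = rng.uniform(*elevation_range, size=pix.shape[0])
        np.add.at(arr, (pix[:, 0], pix[:, 1]), elev)
        placed.append(pos)
    if max_value is not None:
        arr = np.clip(arr, 0.0, max_value)
    pts = np.vstack(placed) if placed else np.empty((0, 2))
    return GrayImage(arr, image.pixel_spacing_mm), pts
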