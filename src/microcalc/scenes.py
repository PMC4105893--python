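"""Object-level synthetic scenes for clustering studies.

The injection simulator (:mod:`microcalc.simulate`) produces full
images; this module skips the imaging stage and builds populations of
:class:`~microcalc.features.MicroObject` directly, which is how the
clustering and evaluation stages are studied in isolation.  Two scene
families cover the interesting regimes:

* :func:`cluster_scene` — one to a few compact, well-separated clusters
  of micros and nothing else; the ground truth for cluster-count
  recovery.  Micros of one cluster share an intensity character (base
  level, spread, distribution shape), as micros of a real pathological
  cluster do.
* :func:`overlap_scene` — one true cluster whose region is interleaved
  with noise objects of different intensity statistics, plus scattered
  far noise.  Position alone cannot separate the interleaved noise from
  the cluster; the structural features can.  This is the regime where
  feature-augmented clustering should beat position-only clustering.

Scenes default to the geometry of a 0.07 mm/px digitisation: cluster
spreads of a few tens of pixels (well under the 250 px pathological
maximum) and separations of a few hundred pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import MicroObject, feature_matrix, normalize_features

__all__ = ["Scene", "disk_object", "cluster_scene", "overlap_scene"]


@dataclass
class Scene:
    """A synthetic object population with ground truth.

    ``truth_clusters`` holds one (n, 2) array of true micro centroids
    per true cluster; ``labels`` gives each object's true cluster index
    (-1 for noise objects).
    """

    objects: list[MicroObject]
    X: np.ndarray
    X_norm: np.ndarray
    positions_px: np.ndarray
    truth_clusters: list[np.ndarray]
    labels: np.ndarray

    @property
    def n_objects(self) -> int:
        return len(self.objects)


def disk_object(center, radius: float, intensities_rng, rng) -> MicroObject:
    """A disk-footprint object at ``center`` with sampled intensities.

    ``intensities_rng`` is a callable ``(rng, n) -> n values``.
    """
    r0, c0 = int(round(center[0])), int(round(center[1]))
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = np.hypot(dy, dx) <= radius
    pixels = np.column_stack([dy[keep] + r0, dx[keep] + c0])
    vals = np.clip(intensities_rng(rng, pixels.shape[0]), 0.0, None)
    return MicroObject(pixels=pixels, intensities=vals)


def _spread_centers(rng, n, low, high, min_sep):
    centers = rng.uniform(low, high, size=(n, 2))
    for _ in range(1000):
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(centers[i] - centers[j])) < min_sep:
                    centers[j] = rng.uniform(low, high, size=2)
                    ok = False
        if ok:
            return centers
    return centers


def _finish(objects, labels, truth_clusters) -> Scene:
    X = feature_matrix(objects)
    X_norm, _ = normalize_features(X)
    positions_px = X[:, [1, 0]]  # (row, col) from (y, x)
    return Scene(
        objects=objects,
        X=X,
        X_norm=X_norm,
        positions_px=positions_px,
        truth_clusters=truth_clusters,
        labels=np.asarray(labels, dtype=int),
    )


def cluster_scene(
    n_clusters: int,
    micros_per_cluster: int = 5,
    seed=None,
    cluster_spread_px: float = 4.0,
    separation_px: float = 300.0,
    image_size_px: int = 1000,
    micro_radius_px: float = 2.0,
    base_intensity_range: tuple[float, float] = (140.0, 220.0),
    intensity_sd_range: tuple[float, float] = (2.0, 8.0),
) -> Scene:
    """Compact well-separated clusters of micros, no noise objects.

    Each cluster draws a base intensity and an intensity spread once and
    shares them across its micros.  Five micros per cluster is the
    regime in which the residual-count rule can resolve the cluster
    number exactly: any split of five micros leaves a fragment below the
    three-micro pathological minimum.
    """
    rng = np.random.default_rng(seed)
    margin = max(150, int(0.15 * image_size_px))
    centers = _spread_centers(rng, n_clusters, margin, image_size_px - margin, separation_px)
    objects: list[MicroObject] = []
    labels: list[int] = []
    truth: list[np.ndarray] = []
    for ci in range(n_clusters):
        base = rng.uniform(*base_intensity_range)
        sd = rng.uniform(*intensity_sd_range)
        pts = []
        for _ in range(micros_per_cluster):
            p = centers[ci] + rng.normal(0.0, cluster_spread_px, 2)
            obj = disk_object(p, micro_radius_px, lambda g, n: g.normal(base, sd, n), rng)
            objects.append(obj)
            labels.append(ci)
            pts.append([obj.centroid_row, obj.centroid_col])
        truth.append(np.asarray(pts))
    return _finish(objects, labels, truth)


def overlap_scene(
    seed=None,
    n_true: int = 8,
    n_overlap: int = 5,
    n_far: int = 12,
    image_size_px: int = 1000,
    region_spread_px: float = 25.0,
    true_base: float = 190.0,
    true_sd: float = 3.0,
    noise_base: float = 150.0,
    noise_sd: float = 12.0,
) -> Scene:
    """One true cluster interleaved with intensity-distinct noise.

    ``n_true`` bright, homogeneous micros and ``n_overlap`` dimmer,
    more variable noise objects share the same spatial region;
    ``n_far`` further noise objects are scattered over the rest of the
    frame.  Truth is the single cluster of true micros.
    """
    rng = np.random.default_rng(seed)
    center = rng.uniform(0.3 * image_size_px, 0.7 * image_size_px, 2)
    objects: list[MicroObject] = []
    labels: list[int] = []
    pts = []
    for _ in range(n_true):
        p = center + rng.normal(0.0, region_spread_px, 2)
        obj = disk_object(p, 2.0, lambda g, n: g.normal(true_base, true_sd, n), rng)
        objects.append(obj)
        labels.append(0)
        pts.append([obj.centroid_row, obj.centroid_col])
    for _ in range(n_overlap):
        p = center + rng.normal(0.0, region_spread_px, 2)
        objects.append(disk_object(p, 2.0, lambda g, n: g.normal(noise_base, noise_sd, n), rng))
        labels.append(-1)
    placed = 0
    while placed < n_far:
        p = rng.uniform(50, image_size_px - 50, 2)
        if np.hypot(*(p - center)) < 6.0 * region_spread_px:
            continue
        objects.append(disk_object(p, 1.5, lambda g, n: g.normal(noise_base, noise_sd, n), rng))
        labels.append(-1)
        placed += 1
    return _finish(objects, labels, [np.asarray(pts)])
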