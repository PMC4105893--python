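"""Automatic estimation of the number of microcalcification clusters.

The cluster count K is an input to fuzzy c-means, but on a real image it
is unknown.  The estimator exploits two clinical constraints: a disease
cluster has at least 3 microcalcifications, so K cannot exceed N/3 for N
segmented objects, and a cluster's spatial extent is bounded (about
250 px at 0.07 mm pixel spacing).

One round runs the clustering ``n_loop`` times at the current K_ini and
counts, per run, the residual clusters

    W = K_ini - N_down + N_up

where N_down clusters have fewer than 3 members (deleted) and N_up
exceed the extent bound.  After a 3-sigma rejection of outlying W
values, the round either stops (the mean W agrees with K_ini to within
3 sigma) or restarts from K_ini = ceil(mean(W) + 3 sigma).  A final run
at K_ini = round(mean(W)) produces the partition that is returned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist

from .errors import InputError
from .fcm import FcmConfig, FuzzyPartition, defuzzify, fcm_fit

logger = logging.getLogger(__name__)

__all__ = [
    "KEstimateConfig",
    "KEstimate",
    "initial_k",
    "cluster_extent",
    "residual_count",
    "estimate_k",
]

#: Maximal cluster extent in pixels at the reference 0.07 mm spacing.
MAX_EXTENT_PX_AT_007 = 250.0


@dataclass(frozen=True)
class KEstimateConfig:
    """Settings of the iterative cluster-count search.

    ``max_extent_px`` defaults to 250 px for 0.07 mm pixels and should
    be rescaled by ``250 * 0.07 / spacing`` for other digitisations.
    """

    n_loop: int = 50
    min_micros: int = 3
    max_extent_px: float = MAX_EXTENT_PX_AT_007
    reject_sigma: float = 3.0
    seed: int | None = None
    max_rounds: int = 20

    def __post_init__(self) -> None:
        if self.n_loop < 2 or self.min_micros < 1 or self.max_extent_px <= 0:
            raise InputError("invalid KEstimateConfig")

    @classmethod
    def for_spacing(cls, pixel_spacing_mm: float, **kw) -> "KEstimateConfig":
        return cls(max_extent_px=MAX_EXTENT_PX_AT_007 * 0.07 / pixel_spacing_mm, **kw)


@dataclass
class KEstimate:
    """Outcome of the search: per-repetition W values and the final count."""

    w_values: list[int]
    w_bar: float
    sigma_w: float
    k_ini_trace: list[int]
    final_k: int
    final_partition: FuzzyPartition | None
    final_labels: np.ndarray | None
    kept_clusters: list[int]
    oversized_clusters: list[int]
    converged: bool
    rounds: list[dict] = field(default_factory=list)


def initial_k(N: int) -> int:
    """Upper bound on the cluster count: floor(N / 3).

    A pathological cluster needs at least 3 microcalcifications, so an
    image with N segmented objects holds at most N/3 clusters.  Fewer
    than 3 objects means no clustering is possible (returns 0).
    """
    if N < 3:
        logger.warning("only %d segmented objects; no clustering possible", N)
        return 0
    return N // 3


def cluster_extent(positions: np.ndarray) -> float:
    """Spatial size of a cluster: max pairwise centroid distance (px).

    Positions are raw (row, col) pixel coordinates, not normalized
    feature values.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[0] < 2:
        return 0.0
    return float(pdist(pos).max())


def residual_count(
    labels: np.ndarray,
    positions_px: np.ndarray,
    k_ini: int,
    cfg: KEstimateConfig,
) -> tuple[int, list[int], list[int]]:
    """Apply the residual-cluster rule W = K_ini - N_down + N_up.

    N_down counts clusters (out of the ``k_ini`` requested) with fewer
    than ``min_micros`` members — these are pruned; N_up counts clusters
    whose extent exceeds ``max_extent_px`` — these are kept but flagged,
    because the raised K_ini of the next round is what resolves them.

    Returns ``(W, kept_cluster_ids, oversized_cluster_ids)``.
    """
    labels = np.asarray(labels)
    kept: list[int] = []
    oversized: list[int] = []
    n_down = 0
    n_up = 0
    for j in range(k_ini):
        members = np.nonzero(labels == j)[0]
        if members.size < cfg.min_micros:
            n_down += 1
            continue
        kept.append(j)
        if cluster_extent(positions_px[members]) > cfg.max_extent_px:
            n_up += 1
            oversized.append(j)
    return k_ini - n_down + n_up, kept, oversized


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def export_w_values(estimate: KEstimate, path) -> None:
    """Write the per-repetition W values of every round to CSV.

    One row per repetition with its round index and starting K_ini —
    the raw material of the W(L_p) histograms used to check that the
    estimate does not depend on the starting point.
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["round", "k_ini", "repetition", "w"])
        for ri, rnd in enumerate(estimate.rounds):
            for li, w in enumerate(rnd["w_values"]):
                writer.writerow([ri, rnd["k_ini"], li, w])


def estimate_k(
    X: np.ndarray,
    positions_px: np.ndarray,
    cfg: KEstimateConfig,
    fcm_cfg: FcmConfig,
    k_start: int | None = None,
) -> KEstimate:
    """Iterate clustering rounds until the residual count stabilises.

    ``X`` is the (N, F) normalized feature matrix of all segmented
    objects, ``positions_px`` their raw pixel centroids (for the extent
    rule).  ``k_start`` overrides the N/3 starting point, e.g. to check
    start-point independence.  Reproducible given ``cfg.seed``.
    """
    X = np.asarray(X, dtype=float)
    positions_px = np.asarray(positions_px, dtype=float)
    N = X.shape[0]
    k_ini = initial_k(N) if k_start is None else int(k_start)
    if k_ini < 1:
        return KEstimate([], float("nan"), float("nan"), [k_ini], 0,
                         None, None, [], [], converged=False)

    ss = np.random.SeedSequence(cfg.seed)
    trace = [k_ini]
    rounds: list[dict] = []
    w_values: list[int] = []
    w_bar = float("nan")
    sigma_w = float("nan")
    converged = False

    for _ in range(cfg.max_rounds):
        seeds = ss.spawn(cfg.n_loop)
        w_values = []
        for child in seeds:
            run_cfg = replace(fcm_cfg, K=k_ini, seed=child)
            part = fcm_fit(X, run_cfg)
            labels = defuzzify(part.U)
            w, _, _ = residual_count(labels, positions_px, k_ini, cfg)
            w_values.append(w)
        w_arr = np.asarray(w_values, dtype=float)
        w_bar = float(w_arr.mean())
        sigma_w = float(w_arr.std())
        # one-pass 3-sigma rejection, then recompute
        if sigma_w > 0:
            keep = np.abs(w_arr - w_bar) <= cfg.reject_sigma * sigma_w
            w_arr = w_arr[keep]
            w_bar = float(w_arr.mean())
            sigma_w = float(w_arr.std())
        rounds.append({"k_ini": k_ini, "w_values": list(w_values),
                       "w_bar": w_bar, "sigma_w": sigma_w})
        if sigma_w == 0:
            stop = w_bar == k_ini
        else:
            stop = abs(w_bar - k_ini) < cfg.reject_sigma * sigma_w
        if stop:
            converged = True
            break
        k_next = math.ceil(w_bar + cfg.reject_sigma * sigma_w)
        # Eq-5 restart must make progress; cap it strictly below the
        # current K_ini (the estimate only ever shrinks toward W-bar).
        k_next = min(k_next, k_ini - 1)
        k_ini = max(k_next, 1)
        trace.append(k_ini)

    k_final = max(_round_half_up(w_bar), 1)
    final_cfg = replace(fcm_cfg, K=k_final, seed=ss.spawn(1)[0])
    part = fcm_fit(X, final_cfg)
    labels = defuzzify(part.U)
    _, kept, oversized = residual_count(labels, positions_px, k_final, cfg)
    return KEstimate(
        w_values=w_values,
        w_bar=w_bar,
        sigma_w=sigma_w,
        k_ini_trace=trace,
        final_k=len(kept),
        final_partition=part,
        final_labels=labels,
        kept_clusters=kept,
        oversized_clusters=oversized,
        converged=converged,
        rounds=rounds,
    )
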