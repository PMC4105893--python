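"""Scoring reconstructed clusters against ground truth.

The central score is the merit figure

    F_M = (N_ini - N_miss) / (N_ini + N_noise)

for a true cluster of N_ini micros of which N_miss are absent from the
reconstructed cluster and N_noise extra objects were swept in: 1 only
for a perfect reconstruction, 0 when every true micro is lost.

Object-level confusion counts follow the usual reading: TP are true
micros correctly associated with the reconstructed cluster, FP healthy
objects erroneously associated with it, FN true micros lost, TN healthy
objects kept out.  From these come sensitivity, accuracy, false
positives per image (FP over all segmented objects) and precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError
from .fcm import FcmConfig, defuzzify, fcm_fit
from .image_io import MiasTruthRecord

__all__ = [
    "ConfusionCounts",
    "MatchResult",
    "merit_figure",
    "match_cluster",
    "summary_metrics",
    "paired_merit",
]

#: Default centroid-matching tolerance on 0.07 mm-scale synthetic images.
DEFAULT_MATCH_RADIUS_PX = 2.0


@dataclass(frozen=True)
class ConfusionCounts:
    """Object-level confusion counts for one image."""

    tp: int
    fp: int
    fn: int
    tn: int
    total_segmented: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching predicted clusters to one true cluster."""

    matched_cluster: int  # index into the predicted cluster list, -1 if none
    n_ini: int
    n_miss: int
    n_noise: int
    counts: ConfusionCounts

    @property
    def merit(self) -> float:
        return merit_figure(self.n_ini, self.n_miss, self.n_noise)


def merit_figure(n_ini: int, n_miss: int, n_noise: int) -> float:
    """F_M = (N_ini - N_miss) / (N_ini + N_noise), in [0, 1]."""
    if n_ini <= 0:
        raise InputError("merit figure undefined for an empty true cluster")
    if not (0 <= n_miss <= n_ini) or n_noise < 0:
        raise InputError("need 0 <= n_miss <= n_ini and n_noise >= 0")
    return (n_ini - n_miss) / (n_ini + n_noise)


def _truth_flags(
    object_positions: np.ndarray,
    truth,
    match_radius_px: float,
) -> tuple[np.ndarray, int]:
    """Map each object to the true micro it represents (or -1).

    With exact injected positions, matching is greedy one-to-one by
    distance within ``match_radius_px``.  With a MIAS circle, every
    in-circle object is its own truth (circle-as-truth convention).
    Returns (assignment per object, number of true micros).
    """
    pos = np.atleast_2d(np.asarray(object_positions, dtype=float))
    N = pos.shape[0]
    assign = np.full(N, -1, dtype=int)
    if isinstance(truth, MiasTruthRecord):
        d = np.hypot(pos[:, 0] - truth.center_row, pos[:, 1] - truth.center_col)
        inside = np.nonzero(d <= truth.radius_px)[0]
        for k, i in enumerate(inside):
            assign[i] = k
        return assign, int(inside.size)
    tpos = np.atleast_2d(np.asarray(truth, dtype=float))
    n_true = tpos.shape[0]
    if N == 0 or n_true == 0:
        return assign, n_true
    d = cdist(pos, tpos)
    pairs = [(d[i, j], i, j) for i in range(N) for j in range(n_true)
             if d[i, j] <= match_radius_px]
    used_obj: set[int] = set()
    used_truth: set[int] = set()
    for dist, i, j in sorted(pairs):
        if i in used_obj or j in used_truth:
            continue
        assign[i] = j
        used_obj.add(i)
        used_truth.add(j)
    return assign, n_true


def match_cluster(
    pred_clusters: list[np.ndarray] | list[list[int]],
    object_positions: np.ndarray,
    truth,
    match_radius_px: float = DEFAULT_MATCH_RADIUS_PX,
) -> MatchResult:
    """Score predicted clusters against one true cluster.

    ``pred_clusters`` holds member-index lists (after pruning);
    ``object_positions`` the raw (row, col) centroid of every segmented
    object; ``truth`` either an (n, 2) array of injected positions or a
    :class:`MiasTruthRecord` circle.

    The predicted cluster containing the most true micros is taken as
    the reconstruction (ties broken by fewer noise members).  TP are its
    true members, FN the true micros not in it, FP its healthy members,
    TN every remaining healthy object.
    """
    pos = np.atleast_2d(np.asarray(object_positions, dtype=float))
    N = pos.shape[0]
    assign, n_true = _truth_flags(pos, truth, match_radius_px)
    if n_true == 0:
        raise InputError("true cluster is empty; nothing to score")

    best = -1
    best_tp = -1
    best_noise = -1
    members_of: list[np.ndarray] = [np.asarray(c, dtype=int) for c in pred_clusters]
    for ci, members in enumerate(members_of):
        truth_ids = {int(assign[i]) for i in members if assign[i] >= 0}
        tp = len(truth_ids)
        noise = int(members.size) - sum(1 for i in members if assign[i] >= 0)
        if tp > best_tp or (tp == best_tp and 0 <= tp and (best_noise < 0 or noise < best_noise)):
            best, best_tp, best_noise = ci, tp, noise

    if best < 0 or best_tp <= 0 and not members_of:
        counts = ConfusionCounts(tp=0, fp=0, fn=n_true, tn=int((assign < 0).sum()),
                                 total_segmented=N)
        return MatchResult(matched_cluster=-1, n_ini=n_true, n_miss=n_true,
                           n_noise=0, counts=counts)

    members = members_of[best]
    in_cluster = np.zeros(N, dtype=bool)
    in_cluster[members] = True
    is_true = assign >= 0
    tp = int(len({int(assign[i]) for i in members if assign[i] >= 0}))
    fp = int((in_cluster & ~is_true).sum())
    fn = n_true - tp
    tn = int((~in_cluster & ~is_true).sum())
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, total_segmented=N)
    return MatchResult(matched_cluster=best, n_ini=n_true, n_miss=fn,
                       n_noise=fp, counts=counts)


def summary_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, accuracy, FP per image and precision from the counts.

    A metric with a zero denominator is reported as None (undefined).
    """
    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "accuracy": ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn),
        "fp_per_image": ratio(c.fp, c.total_segmented),
        "precision": ratio(c.tp, c.tp + c.fp),
    }


def paired_merit(
    X_norm: np.ndarray,
    positions_px: np.ndarray,
    truth,
    k: int,
    fcm_cfg: FcmConfig,
    min_micros: int = 3,
    match_radius_px: float = DEFAULT_MATCH_RADIUS_PX,
) -> dict:
    """Merit figures of position-only FCM vs feature-space FCM-WF.

    Runs both variants at the same K and seed on one scene and scores
    each against the same truth — the per-image paired comparison behind
    the method's headline claim.  Clusters with fewer than ``min_micros``
    members are pruned before scoring.
    """
    out = {}
    for mode in ("spatial_only", "with_features"):
        cfg = replace(fcm_cfg, K=k, feature_mode=mode)
        part = fcm_fit(X_norm, cfg)
        labels = defuzzify(part.U)
        clusters = [np.nonzero(labels == j)[0] for j in range(k)]
        clusters = [c for c in clusters if c.size >= min_micros]
        res = match_cluster(clusters, positions_px, truth, match_radius_px)
        out[mode] = res
    return {
        "merit_spatial_only": out["spatial_only"].merit,
        "merit_with_features": out["with_features"].merit,
        "spatial_only": out["spatial_only"],
        "with_features": out["with_features"],
    }
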