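"""End-to-end orchestration with a reproducible, serializable config.

The pipeline mirrors the detection procedure: segment candidate
microcalcifications with the form filter, extract and normalize the
9-component features, estimate the number of clusters, prune residual
clusters, and — when ground truth is available — score the
reconstruction.  A :class:`RunConfig` captures every stage's settings
plus the global seed; a run writes its resolved config next to its
outputs so any result can be regenerated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .cluster_count import KEstimate, KEstimateConfig, estimate_k, initial_k
from .errors import ConfigError, InputError
from .fcm import FcmConfig
from .features import FEATURE_NAMES, feature_matrix, normalize_features
from .form_filter import FilterConfig, SegmentationConfig, segment_image
from .image_io import BreastMask, GrayImage, MiasTruthRecord, breast_mask, read_image
from .evaluate import DEFAULT_MATCH_RADIUS_PX, match_cluster, paired_merit, summary_metrics
from .simulate import generate_background, generate_mother_cluster, inject_cluster, scatter_noise_micros

logger = logging.getLogger(__name__)

__all__ = ["SimSpec", "RunConfig", "run_pipeline", "objects_to_frame"]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a simulated test image (one injected cluster)."""

    height: int = 512
    width: int = 512
    mother_m: int = 10
    mother_spread_px: float = 40.0
    n_noise: int = 0
    base_level: float = 120.0
    noise_sd: float = 2.0
    texture_scale_px: float = 40.0
    texture_amplitude: float = 8.0


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    filter: FilterConfig = field(default_factory=lambda: FilterConfig.from_spacing())
    seg: SegmentationConfig = field(default_factory=SegmentationConfig)
    fcm: FcmConfig = field(default_factory=lambda: FcmConfig(K=1))
    kest: KEstimateConfig = field(default_factory=KEstimateConfig)
    sim: SimSpec | None = None
    match_radius_px: float = DEFAULT_MATCH_RADIUS_PX
    compare_modes: bool = True
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            if "filter" in d and isinstance(d["filter"], dict):
                d["filter"] = FilterConfig(**d["filter"])
            if "seg" in d and isinstance(d["seg"], dict):
                d["seg"] = SegmentationConfig(**d["seg"])
            if "fcm" in d and isinstance(d["fcm"], dict):
                d["fcm"] = FcmConfig(**d["fcm"])
            if "kest" in d and isinstance(d["kest"], dict):
                d["kest"] = KEstimateConfig(**d["kest"])
            if d.get("sim") is not None and isinstance(d["sim"], dict):
                d["sim"] = SimSpec(**d["sim"])
        except TypeError as exc:
            raise ConfigError(f"bad run config: {exc}") from exc
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def objects_to_frame(objects, image_id: str = "image") -> pd.DataFrame:
    """Tabulate segmented objects: id, centroid and the 9 features."""
    X = feature_matrix(objects)
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df.insert(0, "object_id", np.arange(len(objects)))
    df.insert(0, "image_id", image_id)
    df.insert(2, "row", [o.centroid_row for o in objects])
    df.insert(3, "col", [o.centroid_col for o in objects])
    return df


def _simulate_case(cfg: RunConfig):
    ss = np.random.SeedSequence(cfg.seed)
    s_bg, s_mom, s_inj, s_noise = ss.spawn(4)
    sim = cfg.sim or SimSpec()
    image, mask = generate_background(
        sim.height, sim.width,
        texture_scale_px=sim.texture_scale_px, base_level=sim.base_level,
        noise_sd=sim.noise_sd, seed=s_bg, texture_amplitude=sim.texture_amplitude,
    )
    mother = generate_mother_cluster(sim.mother_m, spread_px=sim.mother_spread_px, seed=s_mom)
    image, record = inject_cluster(image, mask, mother, seed=s_inj, image_id="simulated")
    if sim.n_noise > 0:
        image, _ = scatter_noise_micros(image, mask, sim.n_noise, seed=s_noise,
                                        avoid=record.positions)
    return image, mask, record


def run_pipeline(
    cfg: RunConfig,
    image_path: str | os.PathLike | None = None,
    truth: MiasTruthRecord | np.ndarray | None = None,
) -> dict:
    """Run segmentation -> features -> K estimation -> evaluation.

    With ``image_path`` the pipeline reads a real image (``truth`` may
    be a MIAS circle record); without it, ``cfg.sim`` drives the
    injection simulator and the injected positions serve as truth.
    Returns the report dict; when ``cfg.out_dir`` is set, also writes
    the resolved config, the object table and the report.
    """
    image_id = "simulated"
    if image_path is not None:
        image = read_image(image_path)
        mask = breast_mask(image)
        image_id = os.path.splitext(os.path.basename(os.fspath(image_path)))[0]
    else:
        image, mask, record = _simulate_case(cfg)
        truth = record.positions if truth is None else truth

    objects = segment_image(image, mask, cfg.filter, cfg.seg)
    report: dict = {
        "image_id": image_id,
        "seed": cfg.seed,
        "n_segmented": len(objects),
    }

    if len(objects) < 3:
        report["status"] = "no clustering possible"
        report["final_k"] = 0
        _write_outputs(cfg, report, objects, image_id)
        return report

    X = feature_matrix(objects)
    X_norm, _ = normalize_features(X)
    positions = X[:, [1, 0]]  # (row, col)

    kest_cfg = cfg.kest if cfg.kest.seed is not None else replace(cfg.kest, seed=cfg.seed)
    est = estimate_k(X_norm, positions, kest_cfg, cfg.fcm)
    report.update({
        "status": "ok",
        "k_ini": initial_k(len(objects)),
        "k_ini_trace": est.k_ini_trace,
        "rounds": len(est.rounds),
        "w_bar": est.w_bar,
        "sigma_w": est.sigma_w,
        "final_k": est.final_k,
        "k_loop_converged": est.converged,
    })

    if truth is not None and est.final_labels is not None:
        k_final = est.final_partition.K
        clusters = [np.nonzero(est.final_labels == j)[0] for j in est.kept_clusters]
        res = match_cluster(clusters, positions, truth, cfg.match_radius_px)
        report["merit_figure"] = res.merit
        report["confusion"] = dataclasses.asdict(res.counts)
        report["metrics"] = summary_metrics(res.counts)
        if cfg.compare_modes:
            pm = paired_merit(X_norm, positions, truth, max(k_final, 1),
                              replace(cfg.fcm, seed=cfg.seed),
                              min_micros=cfg.kest.min_micros,
                              match_radius_px=cfg.match_radius_px)
            report["merit_spatial_only"] = pm["merit_spatial_only"]
            report["merit_with_features"] = pm["merit_with_features"]

    _write_outputs(cfg, report, objects, image_id)
    return report


def _write_outputs(cfg: RunConfig, report: dict, objects, image_id: str) -> None:
    if cfg.out_dir is None:
        return
    os.makedirs(cfg.out_dir, exist_ok=True)
    with open(os.path.join(cfg.out_dir, "resolved_config.json"), "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True, default=_json_default)
    if objects:
        objects_to_frame(objects, image_id).to_csv(
            os.path.join(cfg.out_dir, "objects.csv"), index=False)
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.random.SeedSequence):
        return obj.entropy
    raise TypeError(f"not JSON serializable: {type(obj)}")
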