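"""Assembly of per-point predictions into quantified features.

Pipeline per window: select candidate centers (semantic AND center
probability over their thresholds), suppress duplicates greedily in
descending center-probability order using polar-mask containment, assign
every in-mask point to its nearest accepted center (so no point is
quantified twice), and sum raw member intensities as the feature volume.
Feature location is the denormalized coordinate of the selected center
point.  After all windows are processed, only features whose centers fall
in their window's half-open *initial* rectangle are kept, which makes the
merged list exhaustive and duplicate-free over the tiled extent.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as msio
from .autodiff import Tensor
from .network import MSPointNet, PointPrediction
from .polarmask import PolarMask, point_in_mask
from .preprocess import (NormParams, PointCloud, ResolutionModel, Window,
                         denormalize_coords, extract_window, normalize,
                         plan_windows)

log = logging.getLogger(__name__)


@dataclass
class Feature:
    feature_id: int
    mz: float                 # Da, denormalized center
    rt: float                 # minutes, denormalized center
    volume: float             # summed raw member intensity
    window_id: int = 0
    mask: Optional[PolarMask] = None
    norm_params: Optional[NormParams] = None
    n_points: int = 0


@dataclass
class PipelineConfig:
    """End-to-end extraction settings (config-file keys match field names)."""

    analyzer: str = "TOF"
    resolution: float = 30000.0
    resolution_ref_mz: float = 500.0
    rt_fwhm: float = 0.1            # typical RT FWHM, minutes
    window_rt: float = 6.0          # initial window widths
    window_mz: float = 0.8
    expansion_rt: float = 0.3       # expansion margin per side
    expansion_mz: float = 0.05
    intensity_threshold: float = 0.0
    sem_threshold: float = 0.5
    center_threshold: float = 0.5
    n_ensemble: int = 1             # stochastic-forward ensemble size

    def resolution_model(self) -> ResolutionModel:
        return ResolutionModel(self.analyzer, self.resolution,
                               self.resolution_ref_mz)


def ensemble_predict(model: MSPointNet, cloud: PointCloud, seed: int,
                     n_ensemble: int) -> PointPrediction:
    """Average the stochastic forward pass over `n_ensemble` seeds.

    Semantic probabilities and rays are averaged; the center probability
    takes the per-point maximum — the subsampling noise mostly *suppresses*
    weak true centers, so the max is the better-calibrated detector score.
    """
    if n_ensemble <= 1:
        return model.forward(cloud, seed=seed)
    preds = [model.forward(cloud, seed=seed * 131 + t)
             for t in range(n_ensemble)]
    return PointPrediction(
        semantic=Tensor(np.mean([p.semantic_prob for p in preds], axis=0)),
        center=Tensor(np.max([p.center_prob for p in preds], axis=0)),
        rays=Tensor(np.mean([p.ray_lengths for p in preds], axis=0)))


def assemble_features(norm: PointCloud, raw_intensity: np.ndarray,
                      pred: PointPrediction, cfg: "PipelineConfig",
                      window_id: int = 0) -> list[Feature]:
    """Assembly stage only (selection, suppression, assignment,
    quantification) — reusable on cached predictions."""
    cands = select_candidates(norm, pred, cfg.sem_threshold,
                              cfg.center_threshold)
    accepted = deduplicate_centers(norm, cands, pred)
    owner = assign_points(norm, accepted)
    return quantify(norm, raw_intensity, owner, accepted, window_id)


def select_candidates(cloud: PointCloud, pred: PointPrediction,
                      sem_thresh: float = 0.5,
                      center_thresh: float = 0.5) -> np.ndarray:
    """Indices of potential centers, sorted by center probability descending
    (ties broken by higher intensity)."""
    ok = (pred.semantic_prob >= sem_thresh) & (pred.center_prob >= center_thresh)
    idx = np.nonzero(ok)[0]
    order = np.lexsort((-cloud.intensity[idx], -pred.center_prob[idx]))
    return idx[order]


def deduplicate_centers(cloud: PointCloud, candidates: np.ndarray,
                        pred: PointPrediction) -> list[tuple[int, PolarMask]]:
    """Greedy non-maximum suppression by mask containment: a candidate is
    accepted iff it does not lie inside any already-accepted center's mask."""
    accepted: list[tuple[int, PolarMask]] = []
    xy = np.column_stack([cloud.rt, cloud.mz])
    for i in candidates:
        p = xy[i]
        if any(point_in_mask(p, mask) for _, mask in accepted):
            continue
        accepted.append((int(i), PolarMask(center=tuple(p),
                                           rays=pred.ray_lengths[i].copy())))
    return accepted


def assign_points(cloud: PointCloud,
                  accepted: list[tuple[int, PolarMask]]) -> np.ndarray:
    """Owner index (into `accepted`) per point, −1 when in no mask; points
    covered by several masks go to the nearest accepted center."""
    n = len(cloud)
    owner = np.full(n, -1)
    if not accepted:
        return owner
    xy = np.column_stack([cloud.rt, cloud.mz])
    centers = np.array([m.center for _, m in accepted])
    dist = np.linalg.norm(xy[:, None, :] - centers[None, :, :], axis=2)
    inside = np.column_stack([point_in_mask(xy, m) for _, m in accepted])
    dist[~inside] = np.inf
    covered = inside.any(axis=1)
    owner[covered] = dist[covered].argmin(axis=1)
    return owner


def quantify(cloud: PointCloud, raw_intensity: np.ndarray, owner: np.ndarray,
             accepted: list[tuple[int, PolarMask]],
             window_id: int = 0) -> list[Feature]:
    """Features in raw coordinates; volume = Σ raw intensities of the
    member points, location = denormalized selected-center coordinates."""
    params = cloud.norm_params
    feats = []
    for j, (idx, mask) in enumerate(accepted):
        members = owner == j
        if not members.any():
            log.info("window %d: candidate %d has no members, dropped",
                     window_id, idx)
            continue
        rt, mz = denormalize_coords(cloud.rt[idx], cloud.mz[idx], params)
        feats.append(Feature(
            feature_id=-1, mz=float(mz), rt=float(rt),
            volume=float(raw_intensity[members].sum()),
            window_id=window_id, mask=mask, norm_params=params,
            n_points=int(members.sum())))
    return feats


def merge_windows(per_window: list[list[Feature]],
                  windows: list[Window]) -> list[Feature]:
    """Keep each feature iff its center lies in its own window's half-open
    initial rectangle, then re-id globally sorted by (mz, rt)."""
    rects = {w.window_id: w.initial for w in windows}
    kept = [f for feats in per_window for f in feats
            if rects[f.window_id].contains(f.rt, f.mz)]
    kept.sort(key=lambda f: (f.mz, f.rt))
    for i, f in enumerate(kept):
        f.feature_id = i
    return kept


def extract_features(points: np.ndarray, model: MSPointNet,
                     cfg: PipelineConfig, seed: int = 0,
                     windows: Optional[list[Window]] = None) -> list[Feature]:
    """Windowed end-to-end extraction on a raw (n, 3) point set."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return []
    if windows is None:
        extent = (points[:, 0].min(), points[:, 0].max() + 1e-9,
                  points[:, 1].min(), points[:, 1].max() + 1e-9)
        windows = plan_windows(extent, cfg.window_rt, cfg.window_mz,
                               cfg.expansion_rt, cfg.expansion_mz)
    model_res = cfg.resolution_model()
    per_window = []
    for w in windows:
        t0 = time.perf_counter()
        cloud = extract_window(points, w, cfg.intensity_threshold)
        if len(cloud) == 0:
            per_window.append([])
            continue
        raw_intensity = cloud.intensity.copy()
        norm = normalize(cloud, cfg.rt_fwhm, model_res)
        pred = ensemble_predict(model, norm, seed + w.window_id,
                                cfg.n_ensemble)
        feats = assemble_features(norm, raw_intensity, pred, cfg, w.window_id)
        per_window.append(feats)
        log.info("window %d: %d points, %d features (%.2fs)",
                 w.window_id, len(cloud), len(feats),
                 time.perf_counter() - t0)
    return merge_windows(per_window, windows)


def predict_run(input_path, model: MSPointNet, cfg: PipelineConfig,
                output_path=None, seed: int = 0) -> list[Feature]:
    """Full run: read mzML or annotated CSV, extract, optionally write the
    feature table."""
    input_path = Path(input_path)
    if input_path.suffix.lower() == ".csv":
        points = msio.read_annotated_csv(input_path).points
    else:
        points = msio.spectra_to_points(msio.read_mzml(input_path))
    feats = extract_features(points, model, cfg, seed=seed)
    log.info("%s: %d features", input_path.name, len(feats))
    if output_path is not None:
        msio.write_feature_table(feats, output_path)
    return feats
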