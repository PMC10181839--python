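"""Training machinery: targets, augmentation, batching, losses, loop.

Ground-truth targets per point of a normalized annotated cloud:

* ``semantic`` — 1 iff the point belongs to a feature;
* ``centerness`` — a Gaussian field exp(−d²/2σ²) of the RT'–m/z' distance
  to the feature's apex (its maximum-intensity member point), 0 for noise;
* ``gt_rays`` — sector-max polar-mask rays of the feature's member set,
  recomputed about *each* member point as center, so the ray head learns a
  valid contour from any in-feature vantage point.

Losses: focal loss on the two probability branches (the focal weighting is
applied symmetrically to a soft target, reducing to the classic form for
hard 0/1 labels), −log polar IoU on the ray branch for feature members, and
the total is the weighted sum of the three.  Optimization is Adam with
decoupled weight decay; the schedule keeps the best-validation weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .network import MSPointNet, PointPrediction
from .polarmask import rays_about_points
from .preprocess import PointCloud

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr: float = 5e-4
    weight_decay: float = 0.01
    batch_size: int = 8
    epochs: int = 30
    split_ratio: float = 0.7
    loss_weights: tuple = (1.0, 1.0, 1.0)   # semantic, center, mask
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    center_sigma: float = 0.5               # normalized RT'/m/z' units
    mask_loss_center_weighted: bool = False # weight ray loss by centerness
    ray_log_weight: float = 0.0             # auxiliary per-sector log-ray MSE
    pad_batches: bool = True                # equalize batch point counts
    scale_range: tuple = (0.5, 2.0)         # augmentation, log-uniform
    offset_range_rt: float = 1.0            # normalized units
    offset_range_mz: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")


@dataclass
class PointTargets:
    semantic: np.ndarray     # (n,) {0, 1}
    centerness: np.ndarray   # (n,) [0, 1]
    gt_rays: np.ndarray      # (n, n_rays); defined only where valid_mask
    valid_mask: np.ndarray   # (n,) bool — points contributing to the ray loss


def split_dataset(clouds: list, ratio: float, seed: int) -> tuple[list, list]:
    """Deterministic shuffled split; train gets floor(ratio·n) items."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = len(clouds)
    if n < 2:
        raise ValueError("need at least 2 clouds to split")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(ratio * n))
    return ([clouds[i] for i in perm[:n_train]],
            [clouds[i] for i in perm[n_train:]])


def make_targets(cloud: PointCloud, center_sigma: float = 0.5,
                 n_rays: int = 36) -> PointTargets:
    """Targets from a normalized, labeled cloud (see module docstring)."""
    if cloud.labels is None:
        raise ValueError("cloud has no instance labels")
    if not cloud.normalized:
        raise ValueError("targets are built in normalized coordinates")
    n = len(cloud)
    labels = cloud.labels
    semantic = (labels >= 0).astype(float)
    centerness = np.zeros(n)
    gt_rays = np.zeros((n, n_rays))
    xy = np.column_stack([cloud.rt, cloud.mz])
    for inst in np.unique(labels[labels >= 0]):
        members = np.nonzero(labels == inst)[0]
        inten = cloud.intensity[members]
        # apex = max-intensity member; ties to smaller (rt, mz)
        best = np.lexsort((cloud.mz[members], cloud.rt[members], -inten))[0]
        apex = xy[members[best]]
        d2 = ((xy[members] - apex) ** 2).sum(axis=1)
        centerness[members] = np.exp(-d2 / (2.0 * center_sigma ** 2))
        gt_rays[members] = rays_about_points(xy[members], n_rays)
    valid = semantic > 0
    if cloud.pad_mask is not None:
        valid &= ~cloud.pad_mask
    return PointTargets(semantic=semantic, centerness=centerness,
                        gt_rays=gt_rays, valid_mask=valid)


def augment(cloud: PointCloud, seed: int,
            scale_range: tuple = (0.5, 2.0),
            offset_rt: float = 1.0, offset_mz: float = 1.0) -> PointCloud:
    """Per-epoch augmentation in normalized space: every dimension scaled by
    an independent log-uniform factor in `scale_range`, RT'/m/z' shifted by
    uniform offsets.  Labels are untouched; deterministic given the seed."""
    if not cloud.normalized:
        raise ValueError("augmentation operates on normalized clouds")
    rng = np.random.default_rng(seed)
    s = np.exp(rng.uniform(*np.log(scale_range), size=3))
    off_rt = rng.uniform(-offset_rt, offset_rt)
    off_mz = rng.uniform(-offset_mz, offset_mz)
    return PointCloud(rt=cloud.rt * s[0] + off_rt,
                      mz=cloud.mz * s[1] + off_mz,
                      intensity=cloud.intensity * s[2],
                      window=cloud.window, normalized=True,
                      norm_params=cloud.norm_params,
                      labels=cloud.labels, pad_mask=cloud.pad_mask)


def pad_batch(clouds: list[PointCloud], seed: int) -> list[PointCloud]:
    """Equalize point counts within a batch by appending simulated
    low-intensity chemical noise (uniform over each cloud's RT'/m/z' span,
    intensity at the low end of the cloud's own range).  Padding points are
    labeled noise and flagged in ``pad_mask`` so metrics can drop them."""
    if not clouds:
        return clouds
    rng = np.random.default_rng(seed)
    n_max = max(len(c) for c in clouds)
    out = []
    for c in clouds:
        short = n_max - len(c)
        if short == 0:
            pad = np.zeros(len(c), bool) if c.pad_mask is None else c.pad_mask
            out.append(replace(c, pad_mask=pad))
            continue
        lo_i = np.quantile(c.intensity, 0.05) if len(c) else 0.0
        rt = rng.uniform(c.rt.min(), c.rt.max(), short)
        mz = rng.uniform(c.mz.min(), c.mz.max(), short)
        inten = rng.uniform(max(lo_i * 0.5, 0.0), max(lo_i, 1e-3), short)
        out.append(PointCloud(
            rt=np.concatenate([c.rt, rt]),
            mz=np.concatenate([c.mz, mz]),
            intensity=np.concatenate([c.intensity, inten]),
            window=c.window, normalized=c.normalized, norm_params=c.norm_params,
            labels=np.concatenate([c.labels, np.full(short, -1)])
            if c.labels is not None else None,
            pad_mask=np.concatenate(
                [np.zeros(len(c), bool) if c.pad_mask is None else c.pad_mask,
                 np.ones(short, bool)])))
    return out


# -------------------------------------------------------------------- losses
def focal_loss(p: Tensor | np.ndarray, y: np.ndarray,
               alpha: float = 0.25, gamma: float = 2.0) -> Tensor:
    """Mean focal loss.  For hard targets y ∈ {0,1}:

        FL = −α·(1−p)^γ·log p        (y = 1)
             −(1−α)·p^γ·log(1−p)     (y = 0)

    Soft targets y ∈ [0,1] interpolate the two terms linearly, which keeps
    the hard-label case exact and makes the centerness field learnable.
    """
    if not isinstance(p, Tensor):
        p = Tensor(p)
    p = p.clip(1e-7, 1.0 - 1e-7)
    y = np.asarray(y, dtype=float)
    pos = (1.0 - p) ** gamma * p.log() * Tensor(-alpha * y)
    neg = p ** gamma * (1.0 - p).log() * Tensor(-(1.0 - alpha) * (1.0 - y))
    return (pos + neg).mean()


def quality_focal_loss(p: Tensor | np.ndarray, y: np.ndarray,
                       gamma: float = 2.0) -> Tensor:
    """Focal loss generalized to continuous targets y ∈ [0, 1]: binary
    cross-entropy against the soft target, modulated by |y − p|^γ so the
    gradient concentrates on points whose prediction is far from their
    target.  Reduces to the α=0.5-symmetric focal loss (×2) at y ∈ {0, 1}.

    Used for the center branch, whose Gaussian centerness target is
    continuous: the classic α-weighted focal form lets the vast majority of
    near-zero-target points dominate and stalls learning of the sparse
    high-centerness apex points.
    """
    if not isinstance(p, Tensor):
        p = Tensor(p)
    p = p.clip(1e-7, 1.0 - 1e-7)
    y = np.asarray(y, dtype=float)
    mod = np.abs(y - p.data) ** gamma      # modulation, treated as constant
    bce = p.log() * Tensor(-y) + (1.0 - p).log() * Tensor(-(1.0 - y))
    return (bce * Tensor(mod)).mean()


def polar_iou_loss(pred_rays: Tensor, gt_rays: np.ndarray,
                   weights: np.ndarray | None = None) -> Tensor:
    """Mean −log IoU between predicted and target rays at the same points;
    optional per-point weights (normalized to sum 1)."""
    gt = Tensor(np.asarray(gt_rays, dtype=float))
    num = pred_rays.minimum(gt).sum(axis=1)
    den = pred_rays.maximum(gt).sum(axis=1) + 1e-12
    iou = (num / den).clip(1e-7, 1.0)
    if weights is None:
        return -(iou.log().mean())
    w = np.asarray(weights, dtype=float)
    w = w / max(w.sum(), 1e-12)
    return -((iou.log() * Tensor(w)).sum())


def cloud_losses(pred: PointPrediction, targets: PointTargets,
                 cfg: TrainConfig, pad_mask: np.ndarray | None = None):
    """Per-branch losses for one cloud.  Padding noise participates in the
    probability branches (it is a legitimate negative example) but never in
    the ray branch or in any accuracy metric."""
    l_sem = focal_loss(pred.semantic, targets.semantic,
                       cfg.focal_alpha, cfg.focal_gamma)
    l_cen = quality_focal_loss(pred.center, targets.centerness,
                               cfg.focal_gamma)
    valid = np.nonzero(targets.valid_mask)[0]
    if len(valid):
        w = (targets.centerness[valid] ** 2 + 0.02
             if cfg.mask_loss_center_weighted else None)
        pred_valid = pred.rays.gather(valid)
        l_mask = polar_iou_loss(pred_valid, targets.gt_rays[valid], w)
        if cfg.ray_log_weight > 0:
            # per-sector auxiliary: the IoU couples sectors through its sums,
            # so a direct log-ray regression sharpens individual rays
            gt_log = np.log(np.maximum(targets.gt_rays[valid], 1e-3))
            diff = pred_valid.clip(1e-3, 1e9).log() - Tensor(gt_log)
            l_mask = l_mask + Tensor(cfg.ray_log_weight) * (diff ** 2).mean()
    else:
        l_mask = Tensor(0.0)
    return l_sem, l_cen, l_mask


def branch_accuracies(pred: PointPrediction, targets: PointTargets,
                      pad_mask: np.ndarray | None = None) -> dict:
    """Semantic accuracy, binarized center agreement and mean mask IoU,
    excluding batch-padding points."""
    real = (~pad_mask if pad_mask is not None
            else np.ones(len(targets.semantic), bool))
    sem_acc = float(np.mean((pred.semantic_prob[real] >= 0.5)
                            == (targets.semantic[real] >= 0.5)))
    cen_acc = float(np.mean((pred.center_prob[real] >= 0.5)
                            == (targets.centerness[real] >= 0.5)))
    valid = np.nonzero(targets.valid_mask)[0]
    if len(valid):
        a, b = pred.ray_lengths[valid], targets.gt_rays[valid]
        iou = (np.minimum(a, b).sum(axis=1)
               / np.maximum(np.maximum(a, b).sum(axis=1), 1e-12))
        mask_iou = float(iou.mean())
    else:
        mask_iou = float("nan")
    return {"semantic_acc": sem_acc, "center_acc": cen_acc,
            "mask_iou": mask_iou}


# ---------------------------------------------------------------------- loop
def _epoch_losses(model, clouds, cfg, rng, opt=None):
    """One pass; if `opt` is given, update after each batch."""
    sums = np.zeros(3)
    accs = {"semantic_acc": [], "center_acc": [], "mask_iou": []}
    n_clouds = 0
    order = rng.permutation(len(clouds)) if opt is not None else np.arange(len(clouds))
    bs = cfg.batch_size
    for start in range(0, len(order), bs):
        batch_ids = order[start:start + bs]
        batch = [clouds[i] for i in batch_ids]
        if opt is not None:
            batch = [augment(c, int(rng.integers(2 ** 31)),
                             cfg.scale_range, cfg.offset_range_rt,
                             cfg.offset_range_mz) for c in batch]
            if cfg.pad_batches:
                batch = pad_batch(batch, int(rng.integers(2 ** 31)))
            opt.zero_grad()
        for c in batch:
            targets = make_targets(c, cfg.center_sigma, model.config.n_rays)
            pred = model.forward(c, seed=int(rng.integers(2 ** 31)))
            l_sem, l_cen, l_mask = cloud_losses(pred, targets, cfg, c.pad_mask)
            w = cfg.loss_weights
            total = (Tensor(w[0]) * l_sem + Tensor(w[1]) * l_cen
                     + Tensor(w[2]) * l_mask) * Tensor(1.0 / len(batch))
            if not np.isfinite(total.data):
                raise FloatingPointError("training diverged (non-finite loss)")
            if opt is not None:
                total.backward()
            sums += [l_sem.data, l_cen.data, l_mask.data]
            for k, v in branch_accuracies(pred, targets, c.pad_mask).items():
                accs[k].append(v)
            n_clouds += 1
        if opt is not None:
            opt.step()
    out = {"sem_loss": sums[0] / n_clouds, "cen_loss": sums[1] / n_clouds,
           "mask_loss": sums[2] / n_clouds}
    out.update({k: float(np.nanmean(v)) for k, v in accs.items()})
    return out


def train(model: MSPointNet, train_clouds: list[PointCloud],
          val_clouds: list[PointCloud], cfg: TrainConfig) -> tuple[dict, pd.DataFrame]:
    """Optimize the model; returns (best-validation weights, history).

    History has one row per (epoch, split) with the three branch losses and
    accuracies.  Augmentation is re-drawn at the start of every epoch.
    """
    opt = Adam(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    best_val, best_state = np.inf, model.state_copy()
    for epoch in range(cfg.epochs):
        tr = _epoch_losses(model, train_clouds, cfg, rng, opt)
        rows.append({"epoch": epoch, "split": "train", **tr})
        if val_clouds:
            va = _epoch_losses(model, val_clouds, cfg,
                               np.random.default_rng(cfg.seed + 1))
            rows.append({"epoch": epoch, "split": "val", **va})
            w = cfg.loss_weights
            val_total = (w[0] * va["sem_loss"] + w[1] * va["cen_loss"]
                         + w[2] * va["mask_loss"])
            if val_total < best_val:
                best_val, best_state = val_total, model.state_copy()
        else:
            best_state = model.state_copy()
        log.info("epoch %d: train sem %.4f cen %.4f mask %.4f", epoch,
                 tr["sem_loss"], tr["cen_loss"], tr["mask_loss"])
    model.load_state(best_state)
    return best_state, pd.DataFrame(rows)
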