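"""Windowed segmentation, noise filtering and reversible normalization.

A profile LC-MS run is a global set of (rt, m/z, intensity) points.  To keep
network inputs bounded the run is tiled into non-overlapping *initial*
windows which are then grown by an expansion margin on every side, so that a
feature centered inside an initial window is seen whole by the network.  At
merge time only features centered in the initial rectangle are kept, which
makes the tiling exhaustive and duplicate-free.

Before entering the network each windowed cloud is normalized:

* intensity -> log2(intensity), clipped at 1 count;
* rt        -> (rt - rt_center) / rt_fwhm_typical;
* m/z       -> (mz - mz_center) / FWHM_theoretical(mz_center),

where the theoretical m/z FWHM follows from the mass-analyzer resolving
power: constant R for TOF (FWHM = mz / R), R ∝ mz^(-1/2) for Orbitrap
(FWHM = mz^1.5 / (R_ref · sqrt(mz_ref))).  The affine maps are stored with
the cloud, so normalization is exactly invertible.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


class Analyzer(str, enum.Enum):
    TOF = "TOF"
    ORBITRAP = "ORBITRAP"


@dataclass(frozen=True)
class ResolutionModel:
    """Mass analyzer resolving power R specified at a reference m/z."""

    analyzer: Analyzer
    ref_resolution: float
    ref_mz: float

    def __post_init__(self):
        if self.ref_resolution <= 0 or self.ref_mz <= 0:
            raise ValueError("ref_resolution and ref_mz must be positive")
        object.__setattr__(self, "analyzer", Analyzer(self.analyzer))


def theoretical_mz_fwhm(mz: float | np.ndarray, model: ResolutionModel):
    """Theoretical m/z peak FWHM at `mz` for the given analyzer model.

    TOF keeps R constant over m/z; an Orbitrap's R falls off as mz^(-1/2),
    so its FWHM grows as mz^1.5.
    """
    mz = np.asarray(mz, dtype=float)
    if np.any(mz <= 0):
        raise ValueError("mz must be positive")
    if model.analyzer is Analyzer.TOF:
        out = mz / model.ref_resolution
    else:
        out = mz ** 1.5 / (model.ref_resolution * np.sqrt(model.ref_mz))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Rect:
    rt_lo: float
    rt_hi: float
    mz_lo: float
    mz_hi: float

    def contains(self, rt, mz):
        """Half-open membership: [lo, hi) in both dimensions."""
        return ((rt >= self.rt_lo) & (rt < self.rt_hi)
                & (mz >= self.mz_lo) & (mz < self.mz_hi))


@dataclass(frozen=True)
class Window:
    initial: Rect
    expanded: Rect
    window_id: int


@dataclass(frozen=True)
class NormParams:
    rt_center: float
    rt_fwhm: float
    mz_center: float
    mz_fwhm: float


@dataclass
class PointCloud:
    """Points of one (expanded) window, raw or normalized coordinates."""

    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    window: Optional[Window] = None
    normalized: bool = False
    norm_params: Optional[NormParams] = None
    labels: Optional[np.ndarray] = None    # per-point instance id, -1 = noise
    pad_mask: Optional[np.ndarray] = None  # True where point is batch padding

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.rt) == len(self.mz) == len(self.intensity)):
            raise ValueError("rt, mz, intensity must have equal length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.rt):
                raise ValueError("labels length mismatch")

    def __len__(self):
        return len(self.rt)

    def coords3d(self) -> np.ndarray:
        """(n, 3) array of (rt, mz, intensity) in current coordinates."""
        return np.column_stack([self.rt, self.mz, self.intensity])


def plan_windows(extent: tuple, seg_rt: float, seg_mz: float,
                 exp_rt: float, exp_mz: float) -> list[Window]:
    """Tile `extent` = (rt_lo, rt_hi, mz_lo, mz_hi) into half-open initial
    windows of size seg_rt × seg_mz (the last row/column may be short) and
    grow each by the expansion margin on every side.
    """
    rt_lo, rt_hi, mz_lo, mz_hi = map(float, extent)
    if seg_rt <= 0 or seg_mz <= 0:
        raise ValueError("segmentation widths must be positive")
    if exp_rt < 0 or exp_mz < 0:
        raise ValueError("expansion widths must be non-negative")
    if exp_rt == 0 or exp_mz == 0:
        warnings.warn("expansion width is zero; features centered on window "
                      "boundaries may be truncated", stacklevel=2)

    def edges(lo, hi, step):
        n = max(1, int(np.ceil((hi - lo) / step - 1e-12)))
        return [(lo + i * step, min(lo + (i + 1) * step, hi)) for i in range(n)]

    windows, wid = [], 0
    for r0, r1 in edges(rt_lo, rt_hi, seg_rt):
        for m0, m1 in edges(mz_lo, mz_hi, seg_mz):
            init = Rect(r0, r1, m0, m1)
            exp = Rect(r0 - exp_rt, r1 + exp_rt, m0 - exp_mz, m1 + exp_mz)
            windows.append(Window(init, exp, wid))
            wid += 1
    return windows


def extract_window(points: np.ndarray, window: Window,
                   intensity_threshold: float = 0.0,
                   labels: Optional[np.ndarray] = None) -> PointCloud:
    """Points of the expanded rectangle with intensity >= threshold.

    `points` is (n, 3) columns (rt, mz, intensity).  An expanded-rectangle
    membership is half-open like the initial one.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    keep = (window.expanded.contains(points[:, 0], points[:, 1])
            & (points[:, 2] >= intensity_threshold))
    sel = points[keep]
    return PointCloud(rt=sel[:, 0], mz=sel[:, 1], intensity=sel[:, 2],
                      window=window,
                      labels=None if labels is None else np.asarray(labels)[keep])


def normalize(cloud: PointCloud, rt_fwhm_typical: float,
              model: ResolutionModel) -> PointCloud:
    """Center and scale a raw cloud; the affine parameters are stored so the
    transform is exactly invertible.

    The m/z scale uses the theoretical FWHM at the window-center m/z: one
    scale per cloud keeps the map affine, and FWHM varies negligibly over a
    sub-Da window.
    """
    if cloud.normalized:
        raise RuntimeError("cloud is already normalized")
    if rt_fwhm_typical <= 0:
        raise ValueError("rt_fwhm_typical must be positive")
    rect = cloud.window.expanded if cloud.window is not None else Rect(
        cloud.rt.min() if len(cloud) else 0.0, cloud.rt.max() if len(cloud) else 1.0,
        cloud.mz.min() if len(cloud) else 1.0, cloud.mz.max() if len(cloud) else 2.0)
    rt_center = 0.5 * (rect.rt_lo + rect.rt_hi)
    mz_center = 0.5 * (rect.mz_lo + rect.mz_hi)
    mz_fwhm = theoretical_mz_fwhm(mz_center, model)
    params = NormParams(rt_center, rt_fwhm_typical, mz_center, mz_fwhm)
    return PointCloud(
        rt=(cloud.rt - rt_center) / rt_fwhm_typical,
        mz=(cloud.mz - mz_center) / mz_fwhm,
        intensity=np.log2(np.maximum(cloud.intensity, 1.0)),
        window=cloud.window, normalized=True, norm_params=params,
        labels=cloud.labels, pad_mask=cloud.pad_mask)


def denormalize(cloud: PointCloud) -> PointCloud:
    """Exact inverse of :func:`normalize` using the stored parameters."""
    if not cloud.normalized or cloud.norm_params is None:
        raise RuntimeError("cloud is not normalized")
    p = cloud.norm_params
    return PointCloud(
        rt=cloud.rt * p.rt_fwhm + p.rt_center,
        mz=cloud.mz * p.mz_fwhm + p.mz_center,
        intensity=np.exp2(cloud.intensity),
        window=cloud.window, normalized=False, norm_params=None,
        labels=cloud.labels, pad_mask=cloud.pad_mask)


def denormalize_coords(rt_n, mz_n, params: NormParams):
    """Map normalized (rt', mz') back to raw minutes / Da."""
    return rt_n * params.rt_fwhm + params.rt_center, \
        mz_n * params.mz_fwhm + params.mz_center
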