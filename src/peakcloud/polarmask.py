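"""Polar-mask geometry: star-convex feature contours in the RT'–m/z' plane.

A feature boundary is encoded as a center plus `n_rays` equiangular ray
lengths (default 36).  Ray k points at angle θ_k = 2πk/n, measured
counterclockwise from the +RT' axis.  Between rays the boundary radius is
linearly interpolated in angle, which completes the discrete rays to a
star-convex region.  All geometry lives in normalized window coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_N_RAYS = 36


@dataclass
class PolarMask:
    center: tuple          # (rt', mz')
    rays: np.ndarray       # (n_rays,) non-negative lengths

    def __post_init__(self):
        self.rays = np.asarray(self.rays, dtype=float)
        if self.rays.ndim != 1 or len(self.rays) < 3:
            raise ValueError("rays must be a 1-D array of >= 3 lengths")
        if np.any(self.rays < 0):
            raise ValueError("ray lengths must be non-negative")

    @property
    def n_rays(self) -> int:
        return len(self.rays)


def _angles_dists(center, points):
    d = np.asarray(points, dtype=float).reshape(-1, 2) - np.asarray(center, float)
    theta = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2.0 * np.pi)
    return theta, np.hypot(d[:, 0], d[:, 1])


def rays_from_points(center, member_points, n_rays: int = DEFAULT_N_RAYS) -> np.ndarray:
    """Sector-max ray construction.

    Each member point raises the *two* rays adjacent to its angle to at
    least its radial distance; since the boundary radius between rays is
    linearly interpolated, this guarantees every member point lies inside
    the resulting mask.  Sectors with no support are filled by circular
    linear interpolation between the nearest occupied rays, so a compact
    feature never gets a spurious zero-length wedge.
    """
    pts = np.asarray(member_points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("member_points must be non-empty")
    theta, r = _angles_dists(center, pts)
    step = 2.0 * np.pi / n_rays
    lo = np.floor(theta / step).astype(int) % n_rays
    hi = (lo + 1) % n_rays
    rays = np.full(n_rays, -1.0)
    np.maximum.at(rays, lo, r)
    np.maximum.at(rays, hi, r)
    occupied = rays >= 0
    if occupied.all():
        return rays
    if occupied.sum() == 1:
        return np.full(n_rays, rays[occupied][0])
    # circular interpolation across empty sectors
    occ_idx = np.nonzero(occupied)[0]
    xp = np.concatenate([[occ_idx[-1] - n_rays], occ_idx, [occ_idx[0] + n_rays]])
    fp = np.concatenate([[rays[occ_idx[-1]]], rays[occ_idx], [rays[occ_idx[0]]]])
    miss = np.nonzero(~occupied)[0]
    rays[miss] = np.interp(miss, xp, fp)
    return rays


def mask_from_points(center, member_points,
                     n_rays: int = DEFAULT_N_RAYS) -> PolarMask:
    return PolarMask(center=tuple(center),
                     rays=rays_from_points(center, member_points, n_rays))


def radius_at(mask_rays: np.ndarray, theta) -> np.ndarray:
    """Boundary radius at angle(s) `theta`, linearly interpolated between the
    two adjacent rays."""
    rays = np.asarray(mask_rays, dtype=float)
    n = len(rays)
    step = 2.0 * np.pi / n
    t = np.mod(np.asarray(theta, dtype=float), 2.0 * np.pi) / step
    k = np.floor(t).astype(int) % n
    frac = t - np.floor(t)
    return (1.0 - frac) * rays[k] + frac * rays[(k + 1) % n]


def point_in_mask(p, mask: PolarMask, atol: float = 1e-12) -> bool | np.ndarray:
    """Boundary-inclusive membership test; accepts one point or an (m, 2)
    array and returns a scalar or boolean array accordingly."""
    pts = np.asarray(p, dtype=float)
    single = pts.ndim == 1
    theta, dist = _angles_dists(mask.center, pts.reshape(-1, 2))
    inside = dist <= radius_at(mask.rays, theta) + atol
    return bool(inside[0]) if single else inside


def polar_iou(rays_a, rays_b) -> float:
    """IoU of two same-center polar masks: Σ min(a,b) / Σ max(a,b).

    Two all-zero masks are defined to have IoU 1 (vacuous identity), which
    keeps the training loss finite on degenerate targets.
    """
    a = np.asarray(rays_a, dtype=float)
    b = np.asarray(rays_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ray count mismatch")
    denom = np.maximum(a, b).sum()
    if denom == 0.0:
        return 1.0
    return float(np.minimum(a, b).sum() / denom)


def mask_area(mask: PolarMask) -> float:
    """Area of the inscribed n-gon: Σ_k ½ · r_k · r_{k+1} · sin(2π/n)."""
    r = mask.rays
    return float(0.5 * np.sin(2.0 * np.pi / len(r))
                 * np.sum(r * np.roll(r, -1)))


def rays_about_points(points: np.ndarray, n_rays: int = DEFAULT_N_RAYS) -> np.ndarray:
    """Sector-max rays of the point set about *each* point as center.

    Vectorized helper for ground-truth construction: returns (m, n_rays)
    where row i is ``rays_from_points(points[i], points)``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    m = len(pts)
    d = pts[None, :, :] - pts[:, None, :]            # (m, m, 2)
    theta = np.mod(np.arctan2(d[..., 1], d[..., 0]), 2.0 * np.pi)
    r = np.hypot(d[..., 0], d[..., 1])
    step = 2.0 * np.pi / n_rays
    lo = (np.floor(theta / step).astype(int) % n_rays).reshape(-1)
    rays = np.full((m, n_rays), -1.0)
    rows = np.repeat(np.arange(m), m)
    np.maximum.at(rays, (rows, lo), r.reshape(-1))
    np.maximum.at(rays, (rows, (lo + 1) % n_rays), r.reshape(-1))
    # fill empty sectors row by row (cheap: only rows with gaps)
    for i in np.nonzero((rays < 0).any(axis=1))[0]:
        row = rays[i]
        occ = np.nonzero(row >= 0)[0]
        if len(occ) == 1:
            rays[i] = row[occ[0]]
            continue
        xp = np.concatenate([[occ[-1] - n_rays], occ, [occ[0] + n_rays]])
        fp = np.concatenate([[row[occ[-1]]], row[occ], [row[occ[0]]]])
        miss = np.nonzero(row < 0)[0]
        rays[i, miss] = np.interp(miss, xp, fp)
    return rays
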