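"""Multi-task hierarchical point network for MS feature instance segmentation.

The backbone treats a normalized windowed cloud as a 3D point set
(rt', mz', log2 I) and extracts per-point features hierarchically:

1. **Local spatial encoding** — each point's k nearest neighbors (Euclidean
   in normalized 3D space) are expressed as relative coordinates, pushed
   through a shared per-point MLP and max-aggregated.
2. **Encoding levels** — the cloud is repeatedly subsampled by intensity
   probability sampling (inclusion probability proportional to normalized
   intensity); each sampled point aggregates neighbor features from the
   previous level by inverse-distance weighting, concatenated with relative
   coordinates, shared MLP, max over neighbors.  Fewer points, larger
   receptive field, wider features.
3. **Decoding levels** — coarse features are propagated back by
   inverse-distance interpolation over the 3 nearest coarse points,
   concatenated with the skip features of the finer level and transformed by
   a shared MLP.

Three fully connected heads predict per point: the probability of belonging
to a feature (sigmoid), the probability of being a feature center (sigmoid)
and the polar-mask ray lengths (exponential activation, strictly positive).

Sampling randomness is made permutation-equivariant by assigning the random
keys in a canonical (lexicographic) point order, so shuffling the input
points only shuffles the outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from .autodiff import Tensor, concat
from .polarmask import DEFAULT_N_RAYS
from .preprocess import PointCloud

CHECKPOINT_FORMAT = "peakcloud-weights-v1"


@dataclass(frozen=True)
class NetworkConfig:
    n_levels: int = 3
    sample_fracs: tuple = (0.5, 0.25, 0.125)   # of the input point count
    k_neighbors: int = 16
    widths: tuple = (32, 64, 128, 256)         # widths[0] = local encoding
    n_rays: int = DEFAULT_N_RAYS
    head_widths: tuple = (128, 64)
    k_interp: int = 3
    knn_dims: int = 3      # neighbor metric: 3 = (rt', mz', I'), 2 = spatial only

    def __post_init__(self):
        if len(self.sample_fracs) != self.n_levels:
            raise ValueError("need one sample fraction per level")
        if len(self.widths) != self.n_levels + 1:
            raise ValueError("need n_levels+1 widths")
        if any(f2 >= f1 for f1, f2 in zip(self.sample_fracs, self.sample_fracs[1:])):
            raise ValueError("sample fractions must be strictly decreasing")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")


@dataclass
class PointPrediction:
    """Per-point outputs; Tensors retain the autodiff graph for training."""

    semantic: Tensor   # (n,) in (0,1)
    center: Tensor     # (n,) in (0,1)
    rays: Tensor       # (n, n_rays) > 0

    @property
    def semantic_prob(self) -> np.ndarray:
        return self.semantic.data

    @property
    def center_prob(self) -> np.ndarray:
        return self.center.data

    @property
    def ray_lengths(self) -> np.ndarray:
        return self.rays.data


# ----------------------------------------------------------------- sampling
def intensity_probability_sample(weights: np.ndarray, n_sample: int,
                                 seed_or_rng) -> np.ndarray:
    """Sample `n_sample` distinct indices with probability proportional to
    `weights` (weighted sampling without replacement via the
    Efraimidis–Spirakis exponential-key scheme); deterministic per seed."""
    w = np.maximum(np.asarray(weights, dtype=float), 1e-9)
    n = len(w)
    if not 1 <= n_sample <= n:
        raise ValueError("n_sample out of range")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    keys = np.log(rng.random(n)) / w
    return np.argpartition(keys, -n_sample)[-n_sample:]


def _canonical_uniforms(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform draws attached to points by canonical order, not input order."""
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    u = np.empty(len(coords))
    u[order] = rng.random(len(coords))
    return u


def _knn(tree_pts: np.ndarray, query_pts: np.ndarray, k: int):
    """kNN indices and distances; tiny sets are padded by self-duplication."""
    k_eff = min(k, len(tree_pts))
    tree = cKDTree(tree_pts)
    d, idx = tree.query(query_pts, k=k_eff)
    if k_eff == 1:
        d, idx = d[:, None], idx[:, None]
    if k_eff < k:
        pad = k - k_eff
        idx = np.concatenate([idx, np.repeat(idx[:, :1], pad, axis=1)], axis=1)
        d = np.concatenate([d, np.repeat(d[:, :1], pad, axis=1)], axis=1)
    return idx, d


# -------------------------------------------------------------------- model
def _init_mlp(rng, sizes, prefix, params):
    for i, (fan_in, fan_out) in enumerate(zip(sizes, sizes[1:])):
        params[f"{prefix}.W{i}"] = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)),
            requires_grad=True)
        params[f"{prefix}.b{i}"] = Tensor(np.zeros(fan_out), requires_grad=True)


def _mlp(params, prefix, x: Tensor, final_relu: bool = True) -> Tensor:
    i = 0
    while f"{prefix}.W{i}" in params:
        x = x.affine(params[f"{prefix}.W{i}"], params[f"{prefix}.b{i}"])
        i += 1
        if final_relu or f"{prefix}.W{i}" in params:
            x = x.relu()
    return x


class MSPointNet:
    """The detector network: parameters, forward pass, checkpoint I/O."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        p: dict[str, Tensor] = {}
        _init_mlp(rng, (4, cfg.widths[0], cfg.widths[0]), "lse", p)
        for lv in range(cfg.n_levels):
            _init_mlp(rng, (cfg.widths[lv] + 3, cfg.widths[lv + 1],
                            cfg.widths[lv + 1]), f"enc{lv}", p)
        for lv in range(cfg.n_levels):
            _init_mlp(rng, (cfg.widths[lv + 1] + cfg.widths[lv], cfg.widths[lv]),
                      f"dec{lv}", p)
        hw = cfg.head_widths
        # heads see the decoded features plus the point's own normalized
        # intensity (the only absolute coordinate that is physically
        # meaningful across windows)
        # decoded + local-encoding skip + own intensity + local-max margin
        head_in = 2 * cfg.widths[0] + 2
        _init_mlp(rng, (head_in, *hw, 1), "head_sem", p)
        _init_mlp(rng, (head_in, *hw, 1), "head_cen", p)
        _init_mlp(rng, (head_in, *hw, cfg.n_rays), "head_ray", p)
        self.params = p

    # ------------------------------------------------------------- blocks
    def local_spatial_encode(self, coords: np.ndarray, k: int | None = None,
                             return_idx: bool = False):
        """Translation-invariant local descriptor: per neighbor the relative
        3D offset plus its Euclidean norm, shared MLP, max over neighbors."""
        cfg = self.config
        idx, d = _knn(coords[:, :cfg.knn_dims], coords[:, :cfg.knn_dims],
                      k or cfg.k_neighbors)
        rel = coords[idx] - coords[:, None, :]
        x = Tensor(np.concatenate([rel, d[:, :, None]], axis=-1))
        out = _mlp(self.params, "lse", x).max(axis=1)
        return (out, idx) if return_idx else out

    def encode_level(self, lv: int, coords: np.ndarray, feats: Tensor,
                     n_sample: int, rng: np.random.Generator):
        cfg = self.config
        weights = np.maximum(coords[:, 2], 0.0) + 1e-6
        u = _canonical_uniforms(coords, rng)
        keys = np.log(np.maximum(u, 1e-300)) / weights
        samp = np.sort(np.argpartition(keys, -n_sample)[-n_sample:])
        sub = coords[samp]
        idx, d = _knn(coords[:, :cfg.knn_dims], sub[:, :cfg.knn_dims],
                      cfg.k_neighbors)
        w = 1.0 / (d + 1e-6)
        w = w / w.sum(axis=1, keepdims=True)           # (m, k) IDW weights
        neigh = feats.gather(idx) * Tensor(w[:, :, None])
        rel = Tensor(coords[idx] - sub[:, None, :])
        x = concat([neigh, rel], axis=-1)
        out = _mlp(self.params, f"enc{lv}", x).max(axis=1)
        return sub, out

    def decode_level(self, lv: int, coarse_coords, coarse_feats: Tensor,
                     fine_coords, skip_feats: Tensor) -> Tensor:
        cfg = self.config
        idx, d = _knn(coarse_coords[:, :cfg.knn_dims],
                      fine_coords[:, :cfg.knn_dims], cfg.k_interp)
        w = 1.0 / (d + 1e-6)
        w = w / w.sum(axis=1, keepdims=True)
        interp = (coarse_feats.gather(idx) * Tensor(w[:, :, None])).sum(axis=1)
        x = concat([interp, skip_feats], axis=-1)
        return _mlp(self.params, f"dec{lv}", x)

    # ------------------------------------------------------------- forward
    def forward(self, cloud: PointCloud | np.ndarray, seed: int = 0) -> PointPrediction:
        if isinstance(cloud, PointCloud):
            if not cloud.normalized:
                raise ValueError("forward expects a normalized cloud")
            coords = cloud.coords3d()
        else:
            coords = np.asarray(cloud, dtype=float).reshape(-1, 3)
        if len(coords) == 0:
            raise ValueError("empty cloud")
        cfg = self.config
        rng = np.random.default_rng(seed)
        n = len(coords)

        feats, idx0 = self.local_spatial_encode(coords, return_idx=True)
        levels = [(coords, feats)]
        for lv in range(cfg.n_levels):
            n_s = max(1, min(int(np.ceil(cfg.sample_fracs[lv] * n)),
                             len(levels[-1][0])))
            levels.append(self.encode_level(lv, *levels[-1], n_s, rng))
        dec_coords, dec_feats = levels[-1]
        for lv in range(cfg.n_levels - 1, -1, -1):
            fine_coords, skip = levels[lv]
            dec_feats = self.decode_level(lv, dec_coords, dec_feats,
                                          fine_coords, skip)
            dec_coords = fine_coords

        # local-max margin: own log-intensity minus the neighborhood max
        # (>= 0 exactly at local intensity maxima — the natural apex cue)
        lm = coords[:, 2] - coords[idx0, 2].max(axis=1)
        head_in = concat([dec_feats, feats,
                          Tensor(np.column_stack([coords[:, 2], lm]))], axis=-1)
        sem = _mlp(self.params, "head_sem", head_in, final_relu=False)
        cen = _mlp(self.params, "head_cen", head_in, final_relu=False)
        ray = _mlp(self.params, "head_ray", head_in, final_relu=False)
        return PointPrediction(
            semantic=sem.reshape(n).sigmoid(),
            center=cen.reshape(n).sigmoid(),
            rays=ray.clip(-30.0, 30.0).exp())

    __call__ = forward

    # --------------------------------------------------------- checkpoints
    def save(self, path) -> None:
        meta = json.dumps({"format": CHECKPOINT_FORMAT,
                           "config": asdict(self.config)})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{k: v.data for k, v in self.params.items()})

    @classmethod
    def load(cls, path) -> "MSPointNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognized checkpoint format in {path}")
            cfg_d = meta["config"]
            for key in ("sample_fracs", "widths", "head_widths"):
                cfg_d[key] = tuple(cfg_d[key])
            model = cls(NetworkConfig(**cfg_d))
            for k in model.params:
                model.params[k].data = data[k].astype(float)
        return model

    def state_copy(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()


def local_spatial_encode(cloud: PointCloud, k: int,
                         model: MSPointNet | None = None) -> np.ndarray:
    """Functional wrapper around :meth:`MSPointNet.local_spatial_encode`."""
    model = model or MSPointNet()
    coords = cloud.coords3d() if isinstance(cloud, PointCloud) else np.asarray(cloud)
    return model.local_spatial_encode(coords, k).data


def forward(cloud, config: NetworkConfig, model: MSPointNet,
            seed: int = 0) -> PointPrediction:
    """Functional forward pass (the model carries the weights)."""
    if config != model.config:
        raise ValueError("config does not match the model weights")
    return model.forward(cloud, seed=seed)
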