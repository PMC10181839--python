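"""scikit-learn style estimator wrapping the full detector.

``PeakCloudDetector`` is the package's front door: ``fit`` takes annotated
point clouds (normalizes them, splits 7:3, trains the multi-task point
network), ``predict`` takes a raw point set / mzML / annotated CSV and
returns the detected feature table as a DataFrame.  Being a
``BaseEstimator`` it composes with sklearn model selection
(``get_params`` / ``set_params``, ``clone``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import io as msio
from .extractor import PipelineConfig, extract_features, predict_run
from .network import MSPointNet, NetworkConfig
from .preprocess import PointCloud, Rect, Window, normalize
from .trainer import TrainConfig, split_dataset, train


def annotated_to_training_cloud(cloud: msio.AnnotatedCloud,
                                cfg: PipelineConfig) -> PointCloud:
    """Wrap one annotated cloud as a single normalized window."""
    pts = cloud.points
    rect = Rect(pts[:, 0].min(), pts[:, 0].max() + 1e-9,
                pts[:, 1].min(), pts[:, 1].max() + 1e-9)
    pc = PointCloud(rt=pts[:, 0], mz=pts[:, 1], intensity=pts[:, 2],
                    window=Window(rect, rect, 0), labels=cloud.labels)
    return normalize(pc, cfg.rt_fwhm, cfg.resolution_model())


class PeakCloudDetector(BaseEstimator):
    """Untargeted LC-HRMS feature detector and quantifier.

    Parameters mirror the pipeline and training configuration; fitted state
    lives in ``model_`` (trained network) and ``history_`` (per-epoch
    branch losses/accuracies).

    Examples
    --------
    >>> det = PeakCloudDetector(epochs=5, random_state=0)
    >>> det.fit(annotated_clouds)            # doctest: +SKIP
    >>> table = det.predict("run.mzML")      # doctest: +SKIP
    """

    def __init__(self, analyzer="TOF", resolution=30000.0,
                 resolution_ref_mz=500.0, rt_fwhm=0.1,
                 window_rt=6.0, window_mz=0.8,
                 expansion_rt=0.3, expansion_mz=0.05,
                 intensity_threshold=0.0,
                 sem_threshold=0.5, center_threshold=0.5,
                 network_config=None, lr=5e-4, weight_decay=0.01,
                 batch_size=8, epochs=30, split_ratio=0.7,
                 center_sigma=0.5, random_state=0):
        self.analyzer = analyzer
        self.resolution = resolution
        self.resolution_ref_mz = resolution_ref_mz
        self.rt_fwhm = rt_fwhm
        self.window_rt = window_rt
        self.window_mz = window_mz
        self.expansion_rt = expansion_rt
        self.expansion_mz = expansion_mz
        self.intensity_threshold = intensity_threshold
        self.sem_threshold = sem_threshold
        self.center_threshold = center_threshold
        self.network_config = network_config
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.split_ratio = split_ratio
        self.center_sigma = center_sigma
        self.random_state = random_state

    # ------------------------------------------------------------ config
    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            analyzer=self.analyzer, resolution=self.resolution,
            resolution_ref_mz=self.resolution_ref_mz, rt_fwhm=self.rt_fwhm,
            window_rt=self.window_rt, window_mz=self.window_mz,
            expansion_rt=self.expansion_rt, expansion_mz=self.expansion_mz,
            intensity_threshold=self.intensity_threshold,
            sem_threshold=self.sem_threshold,
            center_threshold=self.center_threshold)

    def train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, weight_decay=self.weight_decay,
                           batch_size=self.batch_size, epochs=self.epochs,
                           split_ratio=self.split_ratio,
                           center_sigma=self.center_sigma,
                           seed=self.random_state)

    # --------------------------------------------------------------- fit
    def fit(self, clouds, y=None):
        """Train on a list of :class:`~peakcloud.io.AnnotatedCloud`."""
        cfg = self.pipeline_config()
        tcfg = self.train_config()
        net_cfg = self.network_config or NetworkConfig()
        normed = [annotated_to_training_cloud(c, cfg) for c in clouds]
        train_set, val_set = split_dataset(normed, tcfg.split_ratio, tcfg.seed)
        self.model_ = MSPointNet(net_cfg, seed=self.random_state)
        _, self.history_ = train(self.model_, train_set, val_set, tcfg)
        self.n_train_clouds_ = len(train_set)
        self.n_val_clouds_ = len(val_set)
        return self

    # ----------------------------------------------------------- predict
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("detector is not fitted; call fit() or "
                               "load_weights() first")

    def predict(self, X) -> pd.DataFrame:
        """Detect features in a raw (n, 3) point array, an AnnotatedCloud,
        or a path to mzML / annotated CSV; returns the feature table."""
        self._check_fitted()
        cfg = self.pipeline_config()
        if isinstance(X, (str, Path)):
            feats = predict_run(X, self.model_, cfg, seed=self.random_state)
        else:
            pts = X.points if isinstance(X, msio.AnnotatedCloud) else np.asarray(X)
            feats = extract_features(pts, self.model_, cfg,
                                     seed=self.random_state)
        return pd.DataFrame(
            [{"feature_id": f.feature_id, "mz": f.mz, "rt": f.rt,
              "volume": f.volume, "window_id": f.window_id,
              "n_points": f.n_points} for f in feats],
            columns=["feature_id", "mz", "rt", "volume", "window_id",
                     "n_points"])

    # ------------------------------------------------------- persistence
    def save_weights(self, path) -> None:
        self._check_fitted()
        self.model_.save(path)

    def load_weights(self, path) -> "PeakCloudDetector":
        self.model_ = MSPointNet.load(path)
        return self
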