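"""scikit-learn style estimators wrapping the pipeline stages.

``SpectrogramFeaturizer`` turns fixed-length audio segments into
normalized spectrogram images; ``CamResNet18Classifier`` trains the
channel-attention residual network with the study hyperparameters.
Both follow the sklearn estimator contract (get_params/set_params,
fitted attributes with trailing underscores) and compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .audio import Segment
from .features import featurize_segments
from .nn.resnet import NetworkConfig
from .training import TrainConfig, predict, train_model


class SpectrogramFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer: audio segments -> (n, H, W) feature images.

    Accepts a list of :class:`~coughscope.audio.Segment` or a 2D array
    of equal-length sample rows (interpreted at ``sample_rate``).
    """

    def __init__(self, image_size: int = 224, n_fft: int = 512,
                 frame_len_s: float = 0.025, hop_s: float = 0.010,
                 sample_rate: int = 16_000):
        self.image_size = image_size
        self.n_fft = n_fft
        self.frame_len_s = frame_len_s
        self.hop_s = hop_s
        self.sample_rate = sample_rate

    def fit(self, X, y=None):
        self.n_features_in_ = None
        return self

    def transform(self, X) -> np.ndarray:
        if len(X) and not isinstance(X[0], Segment):
            X = [Segment(np.asarray(row, dtype=np.float64), self.sample_rate) for row in X]
        return featurize_segments(list(X), size=self.image_size, n_fft=self.n_fft,
                                  frame_len_s=self.frame_len_s, hop_s=self.hop_s)


class CamResNet18Classifier(ClassifierMixin, BaseEstimator):
    """Channel-attention 18-layer residual network classifier.

    Parameters default to the study protocol (Adam, lr 0.001, batch 8,
    50 epochs, step decay 0.1 every 7 epochs, He init); ``attention``
    toggles the channel-attention blocks for ablation.

    ``fit`` accepts optional validation data; when given, the weights
    with the best validation accuracy are kept (ties -> earliest epoch)
    and the per-epoch history is stored in ``history_``. Without
    validation data a tail fraction of the training set is split off.
    """

    def __init__(self, attention: bool = True, attention_position: str = "post_sum",
                 input_size: int = 224, epochs: int = 50, lr: float = 0.001,
                 batch_size: int = 8, step_size: int = 7, gamma: float = 0.1,
                 cam_hidden_sizes: tuple[int, ...] = (256, 128),
                 validation_fraction: float = 0.2, seed: int = 0):
        self.attention = attention
        self.attention_position = attention_position
        self.input_size = input_size
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.step_size = step_size
        self.gamma = gamma
        self.cam_hidden_sizes = cam_hidden_sizes
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _net_config(self, n_classes: int) -> NetworkConfig:
        return NetworkConfig(
            num_classes=n_classes, input_size=self.input_size,
            attention_enabled=self.attention,
            attention_position=self.attention_position,
            cam_hidden_sizes=tuple(self.cam_hidden_sizes),
        )

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if X_val is None:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(X))
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X_val, y_val_idx = X[val_idx], y_idx[val_idx]
            X, y_idx = X[tr_idx], y_idx[tr_idx]
        else:
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        cfg = TrainConfig(lr=self.lr, epochs=self.epochs, batch_size=self.batch_size,
                          step_size=self.step_size, gamma=self.gamma, seed=self.seed)
        self.model_, self.history_ = train_model(
            X, y_idx, X_val, y_val_idx, cfg,
            net_cfg=self._net_config(len(self.classes_)))
        self.n_features_in_ = X.shape[-1] * X.shape[-2]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        _, proba = predict(self.model_, np.asarray(X, dtype=np.float32))
        return proba

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        pred, _ = predict(self.model_, np.asarray(X, dtype=np.float32))
        return self.classes_[pred]
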