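"""Scikit-learn-style estimator wrapping the gated-fusion classifier.

:class:`GatedFusionImageClassifier` exposes the three-branch model with
GSAF fusion through the familiar ``fit`` / ``predict`` /
``predict_proba`` surface, so it composes with sklearn model selection
and pipelines operating on image arrays of shape ``(n, size, size, 3)``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .branches import BranchConfig, ImageBatch
from .data.pipeline import AugmentationSpec
from .fusion import HMCTAFModel
from .nn import Tensor
from .training import TrainConfig, train_single
from .utils import substream

__all__ = ["GatedFusionImageClassifier"]


class GatedFusionImageClassifier(BaseEstimator, ClassifierMixin):
    """Three-branch CNN/transformer classifier with gated fusion.

    Parameters mirror :class:`BranchConfig` (architecture) and
    :class:`TrainConfig` (optimization); both may be passed explicitly
    or left at their defaults (the tiny desk-scale architecture preset).

    Attributes set by :meth:`fit` (trailing underscore): ``classes_``,
    ``model_``, ``history_``, ``n_features_in_``.
    """

    def __init__(self, model_config: BranchConfig | None = None,
                 strategy: str = "gsaf", epochs: int = 10,
                 learning_rate: float = 0.001, momentum: float = 0.9,
                 weight_decay: float = 0.0005, batch_size: int = 32,
                 lambda_sparsity: float = 0.10, tau: float = 1.0,
                 warmup_epochs: int = 5, optimizer: str = "sgd",
                 loss: str = "cross_entropy", focal_gamma: float = 2.0,
                 class_aware_sampling: bool = False,
                 augmentation: AugmentationSpec | None = None,
                 seed: int = 0):
        self.model_config = model_config
        self.strategy = strategy
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.lambda_sparsity = lambda_sparsity
        self.tau = tau
        self.warmup_epochs = warmup_epochs
        self.optimizer = optimizer
        self.loss = loss
        self.focal_gamma = focal_gamma
        self.class_aware_sampling = class_aware_sampling
        self.augmentation = augmentation
        self.seed = seed

    # ------------------------------------------------------------------
    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, learning_rate=self.learning_rate,
            momentum=self.momentum, weight_decay=self.weight_decay,
            batch_size=self.batch_size, lambda_sparsity=self.lambda_sparsity,
            tau=self.tau, warmup_epochs=self.warmup_epochs,
            optimizer=self.optimizer, loss=self.loss,
            focal_gamma=self.focal_gamma,
            class_aware_sampling=self.class_aware_sampling, seed=self.seed,
        )

    def _validate_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(
                f"X must have shape (n, size, size, 3); got {X.shape}"
            )
        cfg = self.model_config or BranchConfig.tiny()
        if X.shape[1] != cfg.input_size or X.shape[2] != cfg.input_size:
            raise ValueError(
                f"images are {X.shape[1]}x{X.shape[2]} but the configured "
                f"input size is {cfg.input_size}"
            )
        return X

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "GatedFusionImageClassifier":
        X = self._validate_images(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        cfg = self.model_config or BranchConfig.tiny()
        train_cfg = self._train_config()
        self.model_ = HMCTAFModel(
            cfg, len(self.classes_), strategy=self.strategy,
            seed=int(substream(self.seed, "model/init").integers(2**31)),
            tau=self.tau,
        )
        batch = ImageBatch(X, y_idx)
        self.history_ = train_single(self.model_, batch, train_cfg,
                                     augmentation=self.augmentation)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def _forward(self, X: np.ndarray, batch_size: int = 64):
        check_is_fitted(self, "model_")
        X = self._validate_images(X)
        self.model_.eval()
        logits, gates = [], []
        for i in range(0, len(X), batch_size):
            t = Tensor(np.ascontiguousarray(X[i:i + batch_size]
                                            .transpose(0, 3, 1, 2)))
            lg, gw = self.model_(t)
            logits.append(lg.data)
            if gw is not None:
                gates.append(gw.gate_array)
        return (np.concatenate(logits),
                np.concatenate(gates) if gates else None)

    def predict_proba(self, X) -> np.ndarray:
        logits, _ = self._forward(X)
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        logits, _ = self._forward(X)
        return self.classes_[logits.argmax(axis=-1)]

    def gate_weights(self, X) -> np.ndarray | None:
        """Per-image gate triples (detail, global, transformer), or None
        for strategies without a gate."""
        _, gates = self._forward(X)
        return gates
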