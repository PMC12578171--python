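"""scikit-learn estimator interfaces over the capsule networks.

:class:`CCFMCapsNetClassifier` is the headline surface: a ``fit`` /
``predict`` classifier wrapping either the two-lane CLAHE+CDH capsule
network or the original single-lane baseline.  It accepts image batches of
shape ``(n, H, W, C)`` with intensities in [0, 1] (or flat ``(n, H*W*C)``
matrices together with ``input_shape``, for pipeline compatibility) and
plays with ``clone``, ``get_params`` / ``set_params`` and sklearn model
selection.

Two stateless transformers expose the parameter-free feature layers for use
inside sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .capsules import MarginLossConfig
from .cdh import CdhConfig, cdh_feature_map
from .networks import (ArchitectureConfig, TrainConfig, build_baseline,
                       build_ccfm, count_parameters, predict_and_reconstruct,
                       train)
from .preprocessing import ClaheConfig, apply_clahe

__all__ = ["CCFMCapsNetClassifier", "ClaheTransformer",
           "CdhFeatureMapTransformer"]


class CCFMCapsNetClassifier(ClassifierMixin, BaseEstimator):
    """Capsule-network image classifier with dynamic routing.

    Parameters
    ----------
    architecture : {"ccfm", "baseline"}
        "ccfm" builds the two-lane CLAHE/CDH network; "baseline" the
        original single-lane capsule network.
    epochs, batch_size, learning_rate, decay_rate
        Adam optimization schedule (learning rate decays by ``decay_rate``
        each epoch).
    routing_iters
        Dynamic-routing iterations between primary and class capsules.
    m_plus, m_minus, lambda_down, recon_coeff
        Margin-loss margins/down-weight and the reconstruction-loss weight.
    dropout_rate
        Post-concatenation dropout fraction (two-lane network only).
    ablate
        Iterable of component names to remove, e.g. ``("CDH", "Dropout")``.
    input_shape
        Required only when X is passed flattened as (n, H*W*C).
    random_state
        Seeds weight initialization, shuffling and dropout.

    Attributes
    ----------
    classes_ : array of class labels seen in fit.
    model_ : the underlying network.
    history_ : per-epoch training records.
    n_parameters_ : total parameter count of the built network.
    """

    def __init__(self, architecture: str = "ccfm", epochs: int = 20,
                 batch_size: int = 100, learning_rate: float = 0.001,
                 decay_rate: float = 0.9, routing_iters: int = 3,
                 m_plus: float = 0.9, m_minus: float = 0.1,
                 lambda_down: float = 0.5, recon_coeff: float = 0.392,
                 dropout_rate: float = 0.5, ablate: tuple = (),
                 input_shape: tuple | None = None, random_state: int = 0,
                 verbose: bool = False):
        self.architecture = architecture
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.decay_rate = decay_rate
        self.routing_iters = routing_iters
        self.m_plus = m_plus
        self.m_minus = m_minus
        self.lambda_down = lambda_down
        self.recon_coeff = recon_coeff
        self.dropout_rate = dropout_rate
        self.ablate = ablate
        self.input_shape = input_shape
        self.random_state = random_state
        self.verbose = verbose

    def _as_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            if self.input_shape is None:
                raise ValueError(
                    "flat input requires input_shape=(H, W, C)")
            X = X.reshape(len(X), *self.input_shape)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4 or X.shape[3] not in (1, 3):
            raise ValueError(f"expected (n, H, W, C) images, got {X.shape}")
        if X.min() < -1e-9 or X.max() > 1 + 1e-9:
            raise ValueError("image intensities must lie in [0, 1]")
        return np.clip(X, 0.0, 1.0)

    def fit(self, X, y, validation=None):
        X = self._as_images(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        cfg = ArchitectureConfig(
            input_shape=X.shape[1:], num_classes=len(self.classes_),
            dropout_rate=self.dropout_rate, routing_iters=self.routing_iters,
            ablation_flags=frozenset(self.ablate), seed=self.random_state)
        if self.architecture == "ccfm":
            self.model_ = build_ccfm(cfg)
        elif self.architecture == "baseline":
            self.model_ = build_baseline(cfg)
        else:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        loss_cfg = MarginLossConfig(
            m_plus=self.m_plus, m_minus=self.m_minus,
            lambda_down=self.lambda_down, recon_coeff=self.recon_coeff)
        tcfg = TrainConfig(learning_rate=self.learning_rate,
                           decay_rate=self.decay_rate,
                           batch_size=self.batch_size, epochs=self.epochs,
                           seed=self.random_state)
        if validation is not None:
            Xv, yv = validation
            validation = (self._as_images(Xv),
                          np.searchsorted(self.classes_, np.asarray(yv)))
        self.history_ = train(self.model_, X, y_idx, tcfg,
                              validation=validation, loss_cfg=loss_cfg,
                              verbose=self.verbose)
        self.n_parameters_ = count_parameters(self.model_).total
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def decision_function(self, X):
        """Capsule lengths per class, each in [0, 1)."""
        check_is_fitted(self, "model_")
        scores, _ = predict_and_reconstruct(self.model_, self._as_images(X),
                                            batch_size=self.batch_size)
        return scores

    def predict_proba(self, X):
        scores = self.decision_function(X)
        return scores / scores.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def reconstruct(self, X):
        """Decoder reconstructions from the winning class capsule."""
        check_is_fitted(self, "model_")
        _, recon = predict_and_reconstruct(self.model_, self._as_images(X),
                                           batch_size=self.batch_size)
        return recon


class ClaheTransformer(TransformerMixin, BaseEstimator):
    """Stateless tile-wise contrast-limited equalization of image batches."""

    def __init__(self, clip_limit: float = 2.0, tile_grid: tuple = (8, 8),
                 colour_mode: str = "luminance"):
        self.clip_limit = clip_limit
        self.tile_grid = tile_grid
        self.colour_mode = colour_mode

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        cfg = ClaheConfig(clip_limit=self.clip_limit,
                          tile_grid=tuple(self.tile_grid),
                          colour_mode=self.colour_mode)
        return np.stack([apply_clahe(img, cfg) for img in np.asarray(X)])


class CdhFeatureMapTransformer(TransformerMixin, BaseEstimator):
    """Stateless per-image colour-difference response maps (n, H, W, 3)."""

    def __init__(self, W: int = 72, V: int = 18, D: int = 1,
                 lab_bins: tuple = (8, 3, 3)):
        self.W = W
        self.V = V
        self.D = D
        self.lab_bins = lab_bins

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        cfg = CdhConfig(W=self.W, V=self.V, D=self.D,
                        lab_bins=tuple(self.lab_bins))
        return np.stack([cdh_feature_map(img, cfg) for img in np.asarray(X)])
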