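"""scikit-learn-style estimator wrapping the segmentation network.

``ManetSegmenter`` is a per-pixel binary classifier with the usual
``fit`` / ``predict`` / ``predict_proba`` surface, so it composes with
sklearn model-selection utilities.  ``X`` is a stack of 2-D grayscale
slices ``(n, h, w)`` — raw Hounsfield units by default (the CT intensity
pipeline is applied internally) — and ``y`` the matching binary masks.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .engine import (SliceDataset, TrainConfig, train, tumor_channel,
                     _batch_inputs)
from .network import ArchitectureConfig, build_model, count_parameters
from .preprocess import AugmentSpec, preprocess_slice, split_dataset


class ManetSegmenter(BaseEstimator):
    """Multi-attention residual U-Net tumor segmenter.

    Parameters
    ----------
    variant : architecture variant (ablation row), default the full model.
    base_width : first encoder width; the remaining widths scale as
        [w, 2w, 4w], bridge 8w.  ``base_width=68`` is the full-size model;
        the default 17 is its quarter-width CPU-friendly reduction.
    epochs, batch, lr : optimization protocol (Dice loss, Adam, step decay).
    test_fraction : held-out fraction used for best-checkpoint selection
        during fit (the protocol has no separate validation split).
    preprocess : apply HU windowing + histogram equalization to X.
    classes : 3 for the {background, liver, tumor} head, 1 for a single
        tumor-probability channel.
    seed : seeds weights, batch order, augmentation and the split.
    """

    def __init__(self, variant="manet", base_width=17, epochs=15, batch=4,
                 lr=1e-4, lr_decay_every=30, lr_decay_gamma=0.1,
                 test_fraction=0.2, preprocess=True, classes=3,
                 augment: Optional[AugmentSpec] = None, seed=0):
        self.variant = variant
        self.base_width = base_width
        self.epochs = epochs
        self.batch = batch
        self.lr = lr
        self.lr_decay_every = lr_decay_every
        self.lr_decay_gamma = lr_decay_gamma
        self.test_fraction = test_fraction
        self.preprocess = preprocess
        self.classes = classes
        self.augment = augment
        self.seed = seed

    # ------------------------------------------------------------------
    def _prepare(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_slices, h, w), got shape {X.shape}")
        if self.preprocess:
            X = np.stack([preprocess_slice(s) for s in X])
        return X

    def fit(self, X, y, log=None):
        X = self._prepare(X)
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError(f"y shape {y.shape} must match X shape {X.shape}")
        cfg = TrainConfig(lr=self.lr, lr_decay_gamma=self.lr_decay_gamma,
                          lr_decay_every=self.lr_decay_every, epochs=self.epochs,
                          batch=self.batch, seed=self.seed, variant=self.variant,
                          classes=self.classes,
                          augment=self.augment or AugmentSpec())
        arch = ArchitectureConfig.reduced(self.base_width, variant=self.variant,
                                          out_channels=self.classes)
        idx_train, idx_test = split_dataset(list(range(len(X))),
                                            ratio=1.0 - self.test_fraction, seed=self.seed)
        tr = SliceDataset(X[idx_train], y[idx_train].astype(np.uint8))
        te = SliceDataset(X[idx_test], y[idx_test].astype(np.uint8))
        net = build_model(arch, seed=self.seed)
        ckpt = train(net, tr, te, cfg, log=log)
        net.load_state_dict(ckpt.weights)
        self.model_ = net
        self.checkpoint_ = ckpt
        self.history_ = ckpt.history
        self.n_parameters_ = count_parameters(net)
        self.best_epoch_ = ckpt.epoch
        self.test_dice_ = ckpt.test_dice
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel tumor probability, shape (n, h, w)."""
        self._check_fitted()
        X = self._prepare(X)
        ch = tumor_channel(self.classes)
        out = []
        for i in range(0, len(X), 8):
            out.append(self.model_.predict(_batch_inputs(X[i:i + 8]))[:, ch])
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        """Binary tumor masks at threshold 0.5, shape (n, h, w)."""
        return (self.predict_proba(X) >= 0.5).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-slice Dice of predictions against masks ``y``."""
        pred = self.predict(X).astype(bool)
        y = np.asarray(y).astype(bool)
        dices = []
        for p, t in zip(pred, y):
            denom = p.sum() + t.sum()
            dices.append(1.0 if denom == 0 else 2.0 * np.count_nonzero(p & t) / denom)
        return float(np.mean(dices))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this ManetSegmenter instance is not fitted yet")
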