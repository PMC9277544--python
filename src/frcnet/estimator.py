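"""scikit-learn style estimator wrapping the segmentation network.

``FRCNetSegmenter`` follows the sklearn estimator contract — keyword-only
constructor that stores parameters verbatim, ``fit``/``predict``/
``predict_proba``/``score``, ``get_params``/``set_params`` — so it composes
with sklearn pipelines and model selection. Inputs are image batches rather
than flat feature matrices: X is (N, H, W, 3) or (N, 3, H, W) with values in
[0, 1], y is (N, H, W) or (N, 1, H, W) binary masks.

Training optimizes the compound BCE+Dice loss with Adam (initial learning
rate 1e-3, batch size 4 by default), optionally applying flip/rotation/
photometric augmentation per sample. A seeded fraction of the training
images is held out for validation, and the weights with the best validation
mean Dice are restored after the final epoch.
"""

from __future__ import annotations

import time

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .losses import LossWeights, total_loss
from .metrics import dice_coef
from .network import FRCNet, ModelConfig, count_parameters
from .nn.optim import Adam
from .synthetic import SamplePair, augment

__all__ = ["FRCNetSegmenter"]


class FRCNetSegmenter(BaseEstimator):
    """Binary polyp segmentation with the lightweight context-guided network.

    Parameters
    ----------
    variant : {"baseline", "ecc", "pcf", "mpa", "full"}
        Which context modules are active (ablation switch).
    encoder_widths : tuple of 5 ints
        Channel widths of the five encoder levels.
    lr : float
        Adam initial learning rate.
    batch_size, epochs : int
        Optimization schedule.
    lambda_bce, lambda_dice : float
        Weights of the BCE and Dice terms of the loss.
    augment : bool
        Apply random flip/rotation/brightness/contrast augmentation per sample.
    val_fraction : float
        Seeded fraction of the training images held out for validation-based
        model selection (0 disables the split and selection).
    threshold : float
        Binarization threshold used by :meth:`predict`.
    seed : int
        Seeds weight initialization, the validation split, batch shuffling,
        and augmentation.
    """

    def __init__(self, variant: str = "full",
                 encoder_widths: tuple = (16, 32, 64, 128, 160),
                 lr: float = 1e-3, batch_size: int = 4, epochs: int = 30,
                 lambda_bce: float = 0.6, lambda_dice: float = 0.4,
                 augment: bool = True, val_fraction: float = 0.1,
                 threshold: float = 0.5, seed: int = 0, verbose: int = 0):
        self.variant = variant
        self.encoder_widths = encoder_widths
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.lambda_bce = lambda_bce
        self.lambda_dice = lambda_dice
        self.augment = augment
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.seed = seed
        self.verbose = verbose

    # -- data validation -------------------------------------------------
    @staticmethod
    def _coerce_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError(f"X must be a 4-D image batch, got shape {X.shape}")
        if X.shape[-1] == 3 and X.shape[1] != 3:
            X = np.moveaxis(X, -1, 1)
        if X.shape[1] != 3:
            raise ValueError(f"X must have 3 channels, got shape {X.shape}")
        return np.ascontiguousarray(X)

    @staticmethod
    def _coerce_y(y, X: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        if y.ndim == 3:
            y = y[:, None, :, :]
        if y.ndim != 4 or y.shape[1] != 1:
            raise ValueError(f"y must be (N, H, W) or (N, 1, H, W), got {y.shape}")
        if y.shape[0] != X.shape[0] or y.shape[2:] != X.shape[2:]:
            raise ValueError(f"X shape {X.shape} and y shape {y.shape} disagree")
        vals = np.unique(y)
        if not np.isin(vals, (0, 1)).all():
            if np.isin(vals, (0, 255)).all():
                y = (y > 0)
            else:
                raise ValueError("masks must be binary (0/1 or 0/255)")
        return np.ascontiguousarray(y.astype(np.float32))

    # -- training --------------------------------------------------------
    def fit(self, X, y) -> "FRCNetSegmenter":
        X = self._coerce_X(X)
        y = self._coerce_y(y, X)
        n = X.shape[0]
        rng = np.random.default_rng(self.seed)

        order = rng.permutation(n)
        n_val = int(round(self.val_fraction * n)) if self.val_fraction > 0 else 0
        n_val = min(n_val, n - 1)
        val_idx, train_idx = order[:n_val], order[n_val:]
        self.val_indices_ = val_idx.copy()
        self.train_indices_ = train_idx.copy()

        config = ModelConfig(encoder_widths=tuple(self.encoder_widths),
                             variant=self.variant, seed=self.seed)
        model = FRCNet(config)
        optimizer = Adam(model.parameters(), lr=self.lr)
        weights = LossWeights(self.lambda_bce, self.lambda_dice)

        self.config_ = config
        self.n_params_ = count_parameters(model)
        history = {"train_loss": [], "val_mdice": [], "epoch_seconds": []}
        best_state, best_mdice, best_epoch = None, -1.0, -1

        for epoch in range(self.epochs):
            t0 = time.time()
            model.train()
            epoch_order = rng.permutation(train_idx)
            losses = []
            for start in range(0, len(epoch_order), self.batch_size):
                batch = epoch_order[start:start + self.batch_size]
                xb, yb = X[batch], y[batch]
                if self.augment:
                    xs, ys = [], []
                    for img, msk in zip(xb, yb):
                        pair = augment(SamplePair(image=img, mask=msk), rng)
                        xs.append(pair.image)
                        ys.append(pair.mask.astype(np.float32))
                    xb, yb = np.stack(xs), np.stack(ys)
                model.zero_grad()
                loss = total_loss(nn.Tensor(yb), model(nn.Tensor(xb)), weights)
                value = float(loss.data)
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, "
                        f"batch starting at index {start}")
                loss.backward()
                optimizer.step()
                losses.append(value)
            history["train_loss"].append(float(np.mean(losses)))

            if n_val:
                val_dice = self._mean_dice(model, X[val_idx], y[val_idx])
                history["val_mdice"].append(val_dice)
                if val_dice > best_mdice:
                    best_mdice, best_epoch = val_dice, epoch
                    best_state = model.state_dict()
            history["epoch_seconds"].append(time.time() - t0)
            if self.verbose:
                msg = f"epoch {epoch + 1}/{self.epochs} loss={history['train_loss'][-1]:.4f}"
                if n_val:
                    msg += f" val_mdice={history['val_mdice'][-1]:.4f}"
                print(msg, flush=True)

        if best_state is not None:
            model.load_state_dict(best_state)
        model.eval()
        self.model_ = model
        self.history_ = history
        self.best_epoch_ = best_epoch if n_val else self.epochs - 1
        self.val_mdice_ = best_mdice if n_val else float("nan")
        return self

    def _mean_dice(self, model: FRCNet, X: np.ndarray, y: np.ndarray) -> float:
        probs = self._forward_batched(model, X)
        return float(np.mean([dice_coef(p[0] >= self.threshold, g[0] > 0.5)
                              for p, g in zip(probs, y)]))

    def _forward_batched(self, model: FRCNet, X: np.ndarray) -> np.ndarray:
        model.eval()
        outs = []
        for start in range(0, X.shape[0], max(1, self.batch_size)):
            outs.append(model.predict_proba(X[start:start + self.batch_size]))
        return np.concatenate(outs, axis=0)

    # -- inference -------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Probability maps (N, 1, H, W) in [0, 1]."""
        self._check_fitted()
        return self._forward_batched(self.model_, self._coerce_X(X))

    def predict(self, X) -> np.ndarray:
        """Binary masks (N, H, W) thresholded at ``self.threshold``."""
        return (self.predict_proba(X)[:, 0] >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean Dice of the thresholded predictions against ``y``."""
        self._check_fitted()
        X = self._coerce_X(X)
        y = self._coerce_y(y, X)
        return self._mean_dice(self.model_, X, y)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this FRCNetSegmenter instance is not fitted yet")
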