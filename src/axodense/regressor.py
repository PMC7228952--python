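"""The axon-count density regressor as a scikit-learn-style estimator.

``AxonDensityRegressor.fit`` takes grayscale images and per-image
density targets (built from point annotations with
:func:`axodense.training.build_training_samples`), trains the half-width
U-Net with Adam on the masked, m-scaled MSE, and exposes
``predict_density`` (per-pixel count density), ``predict`` (counts) and
``count_mosaic`` (tile-based whole-nerve counting).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .model import UNetSpec, build, load_model, save_model
from .tiling import TilingScheme, count_full_nerve, predict_density
from .training import TrainingConfig, TrainingSample, train

__all__ = ["AxonDensityRegressor"]


class AxonDensityRegressor(BaseEstimator):
    """U-Net count-density regressor with a scikit-learn interface.

    Parameters mirror the published training recipe: 25 epochs of Adam
    at learning rate 1e-4 with single-image batches, density targets
    scaled by m=1000, reflection padding of 16 px with mirrored pixels
    excluded from the loss, dihedral + multiplicative-noise
    augmentation, and 10-bin uniform-count resampling. ``base_filters``
    (default 32) halves the original U-Net width.
    """

    def __init__(
        self,
        base_filters: int = 32,
        depth: int = 4,
        m: float = 1000.0,
        epochs: int = 25,
        batch_size: int = 1,
        learning_rate: float = 1e-4,
        pad_px: int = 16,
        resample_bins: int = 10,
        resample: bool = True,
        augment: bool = True,
        seed: int = 0,
    ):
        self.base_filters = base_filters
        self.depth = depth
        self.m = m
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.pad_px = pad_px
        self.resample_bins = resample_bins
        self.resample = resample
        self.augment = augment
        self.seed = seed

    # ------------------------------------------------------------------
    def _spec(self) -> UNetSpec:
        return UNetSpec(depth=self.depth, base_filters=self.base_filters, seed=self.seed)

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            m=self.m,
            pad_px=self.pad_px,
            resample_bins=self.resample_bins,
            resample=self.resample,
            augment=self.augment,
            seed=self.seed,
        )

    @staticmethod
    def _as_samples(X, y) -> list[TrainingSample]:
        samples = []
        for i, (img, tgt) in enumerate(zip(X, y)):
            img = np.asarray(img, dtype=np.float64)
            tgt = np.asarray(tgt, dtype=np.float64)
            if img.shape != tgt.shape:
                raise ValueError("images and density targets must share shapes")
            if img.shape[0] % 16 or img.shape[1] % 16:
                raise ValueError("training images must have sides divisible by 16")
            samples.append(
                TrainingSample(
                    image=img, target=tgt, count=float(tgt.sum()),
                    sample_id=f"sample_{i:05d}",
                )
            )
        return samples

    def fit(self, X, y, X_val=None, y_val=None, early_stop=None):
        """Train on images ``X`` and density targets ``y``.

        ``X``: sequence of (H, W) grayscale arrays with sides divisible
        by 16; ``y``: matching density maps whose integrals are the
        (mean manual) counts. Optional validation pairs are evaluated
        per epoch without augmentation.
        """
        samples = self._as_samples(X, y)
        val = self._as_samples(X_val, y_val) if X_val is not None else []
        self.model_ = build(self._spec())
        self.history_ = train(
            self.model_, samples, self._config(), val_samples=val, early_stop=early_stop
        )
        self.n_parameters_ = self.model_.n_parameters
        return self

    # ------------------------------------------------------------------
    def predict_density(self, X) -> np.ndarray:
        """Per-image predicted density maps, shape (n, H, W)."""
        check_is_fitted(self, "model_")
        return np.stack(
            [
                predict_density(
                    self.model_, np.asarray(img, dtype=np.float64), self.m, self.pad_px
                ).values
                for img in X
            ]
        )

    def predict(self, X) -> np.ndarray:
        """Predicted axon counts, one per image."""
        return self.predict_density(X).sum(axis=(1, 2))

    def score(self, X, y) -> float:
        """R^2 of predicted counts against reference counts ``y``."""
        y = np.asarray(y, dtype=float).ravel()
        pred = self.predict(X)
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    def count_mosaic(self, mosaic: np.ndarray, scheme: TilingScheme | None = None):
        """Tile-based count of an arbitrarily large mosaic.

        Returns ``(total_count, DensityMap)``.
        """
        check_is_fitted(self, "model_")
        return count_full_nerve(
            self.model_, np.asarray(mosaic, dtype=np.float64), scheme,
            m=self.m, pad_px=self.pad_px,
        )

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "model_")
        save_model(path, self.model_, self._spec(), self.m)

    @classmethod
    def load(cls, path: str | Path) -> "AxonDensityRegressor":
        model, spec, m = load_model(path)
        est = cls(base_filters=spec.base_filters, depth=spec.depth, m=m, seed=spec.seed)
        est.model_ = model
        est.history_ = pd.DataFrame()
        est.n_parameters_ = model.n_parameters
        return est
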