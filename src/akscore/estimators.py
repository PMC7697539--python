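"""scikit-learn style estimators wrapping the scoring pipeline.

``VoxelGridTransformer`` turns typed complexes into density-grid features;
``AKScoreRegressor`` fits one grouped-convolution residual network;
``AKScoreEnsemble`` averages several independently seeded regressors.  All
three follow the sklearn estimator contract (get_params/set_params, fitted
attributes with trailing underscores), so they compose with pipelines and
model selection.  Inputs X are stacks of (16, 30, 30, 30) grids (or lists
of complexes for the transformer); targets y are affinities in kcal/mol.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .ensemble import EnsembleModel
from .nn import NetworkConfig
from .training import TrainConfig, train_single
from .voxel import GridSpec, voxelize

__all__ = ["VoxelGridTransformer", "AKScoreRegressor", "AKScoreEnsemble"]


class VoxelGridTransformer(TransformerMixin, BaseEstimator):
    """Featurize complexes into (n, 16, 30, 30, 30) density tensors."""

    def __init__(self, edge_length=30.0, boxes_per_axis=30, spacing=1.0,
                 clamp=False, cutoff_margin=5.0):
        self.edge_length = edge_length
        self.boxes_per_axis = boxes_per_axis
        self.spacing = spacing
        self.clamp = clamp
        self.cutoff_margin = cutoff_margin

    def _spec(self) -> GridSpec:
        return GridSpec(edge_length=self.edge_length,
                        boxes_per_axis=self.boxes_per_axis,
                        spacing=self.spacing)

    def fit(self, X=None, y=None):
        self.spec_ = self._spec()
        return self

    def transform(self, X) -> np.ndarray:
        spec = getattr(self, "spec_", self._spec())
        grids = [voxelize(c, spec, clamp=self.clamp,
                          cutoff_margin=self.cutoff_margin).values for c in X]
        return np.stack(grids)


class AKScoreRegressor(RegressorMixin, BaseEstimator):
    """Single grouped-convolution 3D residual network regressor.

    Parameters mirror the training protocol: MAE loss in kcal/mol, Adam
    (beta1 0.99), optional 24-rotation augmentation.  ``network_config``
    defaults to the standard 1.29M-parameter architecture.
    """

    def __init__(self, network_config: NetworkConfig | None = None,
                 learning_rate=7e-4, epochs=200, batch_size=16, seed=0,
                 shuffle=True, augment_rotations=True,
                 validation_fraction=0.0, target_mae=None):
        self.network_config = network_config
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.shuffle = shuffle
        self.augment_rotations = augment_rotations
        self.validation_fraction = validation_fraction
        self.target_mae = target_mae

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, seed=self.seed, shuffle=self.shuffle,
            augment_rotations=self.augment_rotations,
            validation_fraction=self.validation_fraction,
            target_mae=self.target_mae,
            network=self.network_config or NetworkConfig())

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=float)
        result = train_single((X, y), self._train_config())
        self.network_ = result.network
        self.history_ = result.history
        self.val_history_ = result.val_history
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def partial_fit(self, X, y):
        """Continue training the fitted network for another round."""
        check_is_fitted(self, "network_")
        result = train_single((np.asarray(X, np.float32), np.asarray(y, float)),
                              self._train_config(), network=self.network_)
        self.history_ += result.history
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        return self.network_.predict(np.asarray(X, dtype=np.float32))


class AKScoreEnsemble(RegressorMixin, BaseEstimator):
    """Average of independently seeded scoring networks (default 20).

    Members share the architecture, data and hyper-parameters and differ
    only in seed; the prediction is their unweighted mean.
    """

    def __init__(self, n_members=20, network_config: NetworkConfig | None = None,
                 learning_rate=7e-4, epochs=200, batch_size=16, seed=0,
                 shuffle=True, augment_rotations=True, target_mae=None):
        self.n_members = n_members
        self.network_config = network_config
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.shuffle = shuffle
        self.augment_rotations = augment_rotations
        self.target_mae = target_mae

    def fit(self, X, y):
        if self.n_members < 1:
            raise ValueError("n_members must be at least 1")
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=float)
        members, histories = [], []
        for i in range(self.n_members):
            reg = AKScoreRegressor(
                network_config=self.network_config,
                learning_rate=self.learning_rate, epochs=self.epochs,
                batch_size=self.batch_size, seed=self.seed + i,
                shuffle=self.shuffle,
                augment_rotations=self.augment_rotations,
                target_mae=self.target_mae).fit(X, y)
            members.append(reg.network_)
            histories.append(reg.history_)
        self.model_ = EnsembleModel(members)
        self.histories_ = histories
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    @property
    def members_(self):
        check_is_fitted(self, "model_")
        return self.model_.members

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=np.float32))
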