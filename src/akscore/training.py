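"""Training protocol for a single scoring network.

The loss is the mean absolute error between predicted and experimental
binding affinities in kcal/mol.  Optimization uses Adam with beta1 = 0.99
and beta2 = 0.999; candidate learning rates are 1e-4, 5e-4, 7e-4 and 1e-3
(default 7e-4).  The dataset is randomly re-permuted every epoch, and with
rotation augmentation enabled every complex contributes its 24 lattice
rotations as separate training examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import Adam, NetworkConfig, ScoringNetwork, build_network
from .units import kcal_to_pk, pk_to_kcal  # re-exported: labels live in pK
from .voxel import cube_rotations, rotate_grid

__all__ = ["TrainConfig", "train_single", "pk_to_kcal", "kcal_to_pk"]

LEARNING_RATES = (1e-4, 5e-4, 7e-4, 1e-3)


@dataclass
class TrainConfig:
    """Hyper-parameters of a single-network training run."""

    learning_rate: float = 7e-4
    beta1: float = 0.99
    beta2: float = 0.999
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0
    shuffle: bool = True
    augment_rotations: bool = True
    #: re-estimate the norm running statistics on the training data after
    #: the last epoch (the 0.99 momentum converges too slowly otherwise)
    calibrate_norms: bool = True
    validation_fraction: float = 0.0
    #: optional early exit once the epoch training MAE drops below this
    target_mae: float | None = None
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass
class TrainResult:
    network: ScoringNetwork
    history: list[float]            # per-epoch training MAE (kcal/mol)
    val_history: list[float] = field(default_factory=list)


def _as_arrays(dataset):
    if isinstance(dataset, tuple):
        grids, labels = dataset
    else:
        grids = np.stack([g.values if hasattr(g, "values") else g
                          for g, _ in dataset])
        labels = np.array([lab for _, lab in dataset], dtype=float)
    grids = np.asarray(grids, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.float32)
    if grids.ndim == 4:
        grids = grids[None]
    if len(grids) != len(labels):
        raise ValueError("grid and label counts differ")
    if len(grids) == 0:
        raise ValueError("empty training set")
    return grids, labels


def train_single(dataset, config: TrainConfig | None = None,
                 network: ScoringNetwork | None = None,
                 optimizer: Adam | None = None) -> TrainResult:
    """Train one scoring network on (voxel grid, affinity kcal/mol) pairs.

    ``dataset`` is either a (grids, labels) array pair or an iterable of
    (VoxelGrid, label) tuples; labels are kcal/mol.  Pass ``network`` (and
    optionally the matching ``optimizer``) to continue a previous run.
    Returns the trained network plus the per-epoch training MAE history.
    """
    config = config or TrainConfig()
    grids, labels = _as_arrays(dataset)
    if not np.all(np.isfinite(labels)):
        raise ValueError("non-finite affinity labels in the training set")

    rng = np.random.default_rng(config.seed)
    if network is None:
        network = build_network(config.network, seed=config.seed)
        # start the regression intercept at the label mean so early updates
        # go into structure rather than bias travel
        network.fc2.params["bias"][0] = float(labels.mean())
    if optimizer is None:
        optimizer = Adam(network.layers(), lr=config.learning_rate,
                         beta1=config.beta1, beta2=config.beta2)

    n_val = int(round(config.validation_fraction * len(grids)))
    if n_val:
        order = rng.permutation(len(grids))
        val_idx, train_idx = order[:n_val], order[n_val:]
        val_grids, val_labels = grids[val_idx], labels[val_idx]
        grids, labels = grids[train_idx], labels[train_idx]
    rotations = cube_rotations() if config.augment_rotations else [np.eye(3, dtype=int)]

    history, val_history = [], []
    for epoch in range(config.epochs):
        pairs = [(i, r) for i in range(len(grids)) for r in range(len(rotations))]
        if config.shuffle:
            rng.shuffle(pairs)
        errs = []
        for start in range(0, len(pairs), config.batch_size):
            chunk = pairs[start:start + config.batch_size]
            xb = np.stack([
                rotate_grid(grids[i], rotations[r]) if r else grids[i]
                for i, r in chunk])
            yb = labels[[i for i, _ in chunk]]
            pred = network.forward(xb, training=True)
            resid = pred - yb
            batch_mae = float(np.mean(np.abs(resid)))
            if not np.isfinite(batch_mae):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}; last finite epoch "
                    f"MAE: {history[-1] if history else 'n/a'} "
                    f"(lr={config.learning_rate})")
            errs.append((batch_mae, len(chunk)))
            dy = np.sign(resid).astype(np.float32) / len(chunk)
            network.backward(dy)
            optimizer.step()
        epoch_mae = float(np.average([e for e, _ in errs],
                                     weights=[n for _, n in errs]))
        history.append(epoch_mae)
        if n_val:
            val_pred = network.predict(val_grids)
            val_history.append(float(np.mean(np.abs(val_pred - val_labels))))
        if config.target_mae is not None and epoch_mae < config.target_mae:
            break
    if config.calibrate_norms:
        network.calibrate_norms(grids)
    return TrainResult(network=network, history=history, val_history=val_history)
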