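"""Ensembles of independently trained scoring networks.

The ensemble prediction is the unweighted mean of the member predictions.
Members share one architecture and one training set and differ only in the
random seed (initialization, shuffling and augmentation order); averaging
them reduces the seed-to-seed variance of an individual network.  By
convention the standard ensemble has 20 members; a 30-member variant is used
for head-to-head comparisons against other scoring functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .metrics import mae, pearson_r, rmse, spearman_rho
from .nn import ScoringNetwork
from .training import TrainConfig, train_single

__all__ = ["EnsembleModel", "predict_ensemble", "train_ensemble",
           "ensemble_size_curve"]

DEFAULT_ENSEMBLE_SIZE = 20


@dataclass
class EnsembleModel:
    """An average-of-members predictor."""

    members: list[ScoringNetwork]

    def __post_init__(self):
        if not self.members:
            raise ValueError("an ensemble needs at least one member")

    @property
    def size(self) -> int:
        return len(self.members)

    def predict(self, grids, batch_size: int = 8) -> np.ndarray:
        preds = [m.predict(grids, batch_size=batch_size) for m in self.members]
        return np.mean(preds, axis=0)

    def save_manifest(self, manifest_path, member_dir=None) -> None:
        """Write member checkpoints plus a JSON manifest listing them."""
        manifest_path = Path(manifest_path)
        member_dir = Path(member_dir) if member_dir else manifest_path.parent
        member_dir.mkdir(parents=True, exist_ok=True)
        names = []
        for i, m in enumerate(self.members):
            name = f"member_{i:03d}.npz"
            m.save(member_dir / name)
            names.append(name)
        manifest_path.write_text(json.dumps(
            {"members": names, "dir": str(member_dir)}, indent=2))

    @classmethod
    def load_manifest(cls, manifest_path) -> "EnsembleModel":
        manifest_path = Path(manifest_path)
        info = json.loads(manifest_path.read_text())
        base = Path(info.get("dir", manifest_path.parent))
        return cls([ScoringNetwork.load(base / n) for n in info["members"]])


def predict_ensemble(model: EnsembleModel, grids, batch_size: int = 8) -> np.ndarray:
    """Mean of the member predictions, in kcal/mol."""
    return model.predict(grids, batch_size=batch_size)


def train_ensemble(dataset, config: TrainConfig | None = None,
                   n_members: int = DEFAULT_ENSEMBLE_SIZE,
                   base_seed: int = 0) -> EnsembleModel:
    """Train ``n_members`` networks that differ only in their seed."""
    config = config or TrainConfig()
    members = []
    for i in range(n_members):
        cfg_i = TrainConfig(**{**config.__dict__, "seed": base_seed + i})
        members.append(train_single(dataset, cfg_i).network)
    return EnsembleModel(members)


def ensemble_size_curve(members: list[ScoringNetwork], grids, labels,
                        sizes=None, batch_size: int = 8) -> list[dict]:
    """Prediction quality of the first-N-member ensemble versus N.

    For each requested size the mean of the first N member predictions is
    scored against the labels (kcal/mol).  Member order is fixed; shuffle
    the list beforehand (with a seeded RNG) to probe ordering variance.
    """
    labels = np.asarray(labels, dtype=float)
    if sizes is None:
        sizes = range(1, len(members) + 1)
    sizes = sorted(set(int(s) for s in sizes))
    if sizes and sizes[-1] > len(members):
        raise ValueError("requested size exceeds the number of members")
    preds = np.stack([m.predict(grids, batch_size=batch_size) for m in members])
    rows = []
    for n in sizes:
        p = preds[:n].mean(axis=0)
        rows.append({
            "n": n,
            "pearson_r": pearson_r(p, labels),
            "spearman_rho": spearman_rho(p, labels),
            "mae": mae(p, labels),
            "rmse": rmse(p, labels),
        })
    return rows
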