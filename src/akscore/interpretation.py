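"""Model interpretation: channel ablation and Grad-CAM hot-spot mapping.

Channel ablation measures a channel's importance as the increase in mean
absolute error (delta MAE, kcal/mol) when that input channel is destroyed,
either by zeroing it or by shuffling its voxel blocks across the evaluation
set (which preserves the channel's value distribution while decoupling it
from the complexes).  Large delta MAE = important channel.

Grad-CAM localizes the spatial regions driving a prediction.  The regression
head is first converted to a 20-class classifier over binned affinities;
the class-score gradient with respect to the last convolutional feature maps
is spatially averaged into channel weights, and the rectified weighted sum of
the feature maps gives a non-negative importance map, upsampled to the input
grid and optionally aggregated per atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Dense, ScoringNetwork
from .voxel import CHANNEL_LABELS, GridSpec

__all__ = [
    "AblationResult",
    "ablate_channel",
    "ablation_profile",
    "ClassifierNetwork",
    "to_classifier",
    "ImportanceMap",
    "grad_cam",
]


# ---------------------------------------------------------------------------
# ablation

@dataclass
class AblationResult:
    channel_label: str
    channel: int
    mode: str                   # "zero" | "shuffle"
    baseline_mae: float
    ablated_mae: float

    @property
    def delta_mae(self) -> float:
        return self.ablated_mae - self.baseline_mae


def _predict(model, grids):
    return np.asarray(model.predict(grids))


def ablate_channel(model, grids, labels_kcal, channel: int,
                   mode: str = "zero", seed: int = 0,
                   baseline_pred=None) -> AblationResult:
    """Delta MAE from destroying one input channel on an evaluation set.

    ``model`` is anything with ``predict(grids) -> kcal/mol`` (a single
    network or an ensemble).  ``zero`` mode is deterministic; ``shuffle``
    permutes the channel's voxel blocks across complexes with the given
    seed (other channels untouched).
    """
    grids = np.asarray(grids, dtype=np.float32)
    labels = np.asarray(labels_kcal, dtype=float)
    if not 0 <= channel < grids.shape[1]:
        raise ValueError(f"channel index {channel} out of range "
                         f"[0, {grids.shape[1]})")
    if mode not in ("zero", "shuffle"):
        raise ValueError(f"unknown ablation mode {mode!r}")
    if baseline_pred is None:
        baseline_pred = _predict(model, grids)
    baseline_mae = float(np.mean(np.abs(baseline_pred - labels)))
    ablated = grids.copy()
    if mode == "zero":
        ablated[:, channel] = 0.0
    else:
        perm = np.random.default_rng(seed).permutation(len(grids))
        ablated[:, channel] = grids[perm, channel]
    ablated_mae = float(np.mean(np.abs(_predict(model, ablated) - labels)))
    label = (CHANNEL_LABELS[channel] if grids.shape[1] == len(CHANNEL_LABELS)
             else str(channel))
    return AblationResult(channel_label=label, channel=channel, mode=mode,
                          baseline_mae=baseline_mae, ablated_mae=ablated_mae)


def ablation_profile(model, grids, labels_kcal, mode: str = "zero",
                     seeds=(0,), channels=None):
    """Delta MAE for every channel; shuffle mode averages over ``seeds``.

    Returns a list of dicts (channel, label, delta_mae, sd over seeds).
    """
    grids = np.asarray(grids, dtype=np.float32)
    baseline_pred = _predict(model, grids)
    channels = range(grids.shape[1]) if channels is None else channels
    rows = []
    for c in channels:
        deltas = []
        for s in (seeds if mode == "shuffle" else (0,)):
            res = ablate_channel(model, grids, labels_kcal, c, mode=mode,
                                 seed=s, baseline_pred=baseline_pred)
            deltas.append(res.delta_mae)
        rows.append({
            "channel": int(c),
            "label": res.channel_label,
            "mode": mode,
            "baseline_mae": res.baseline_mae,
            "delta_mae": float(np.mean(deltas)),
            "delta_mae_sd": float(np.std(deltas)) if len(deltas) > 1 else 0.0,
        })
    return rows


# ---------------------------------------------------------------------------
# classification head + Grad-CAM

@dataclass
class ClassifierNetwork:
    """A scoring network whose regression neuron was replaced by a
    20-node classification head over binned affinities."""

    backbone: ScoringNetwork
    head: Dense
    bin_edges: np.ndarray       # len n_classes + 1, kcal/mol

    @property
    def n_classes(self) -> int:
        return self.head.params["bias"].shape[0]

    def class_of(self, labels_kcal) -> np.ndarray:
        """Map affinities to class indices via the bin edges."""
        idx = np.digitize(np.asarray(labels_kcal), self.bin_edges[1:-1])
        return idx.astype(int)

    def features(self, grids, training: bool = False) -> np.ndarray:
        """64-dim penultimate features (backbone head, frozen)."""
        net = self.backbone
        x = np.asarray(grids, dtype=np.float32)
        if x.ndim == 4:
            x = x[None]
        h = net.stem.forward(x, training)
        for b in net.blocks:
            h = b.forward(h, training)
        net._feature_cache = h
        h = net.gap.forward(h, training)
        h = net.fc1.forward(h, training)
        return net.head_relu.forward(net.head_norm.forward(h, training), training)

    def logits(self, grids) -> np.ndarray:
        return self.head.forward(self.features(grids))

    def predict_class(self, grids) -> np.ndarray:
        return np.argmax(self.logits(grids), axis=1)


def to_classifier(network: ScoringNetwork, labels_kcal, n_classes: int = 20,
                  bin_edges=None, binning: str = "quantile",
                  head_epochs: int = 200, lr: float = 1e-2,
                  seed: int = 0) -> ClassifierNetwork:
    """Convert a trained regression network into an affinity classifier.

    The backbone (everything up to the penultimate 64-dim features) is kept
    frozen; a fresh fully connected layer with ``n_classes`` nodes is
    trained by softmax cross-entropy on the binned training labels.  Bins
    default to equal-count (quantile) partitions of the label range;
    ``binning="width"`` uses equal-width bins, or pass explicit
    ``bin_edges``.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    labels = np.asarray(labels_kcal, dtype=float)
    if bin_edges is None:
        if binning == "quantile":
            qs = np.linspace(0, 1, n_classes + 1)
            bin_edges = np.quantile(labels, qs)
        elif binning == "width":
            bin_edges = np.linspace(labels.min(), labels.max(), n_classes + 1)
        else:
            raise ValueError(f"unknown binning {binning!r}")
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(bin_edges) != n_classes + 1:
        raise ValueError("bin_edges must have n_classes + 1 entries")
    head = Dense("cls_head", network.config.head_hidden, n_classes,
                 rng=np.random.default_rng(seed))
    clf = ClassifierNetwork(backbone=network, head=head, bin_edges=bin_edges)
    return clf


def fit_classifier_head(clf: ClassifierNetwork, grids, labels_kcal,
                        head_epochs: int = 200, lr: float = 1e-2,
                        seed: int = 0) -> list[float]:
    """Train the classification head (backbone frozen) by cross-entropy.

    Returns the per-epoch loss history.  Features are extracted once, so
    this is cheap even for many epochs.
    """
    feats = clf.features(grids)          # (n, 64), frozen backbone
    classes = clf.class_of(labels_kcal)
    opt = Adam([clf.head], lr=lr, beta1=0.9, beta2=0.999)
    rng = np.random.default_rng(seed)
    history = []
    n = len(feats)
    for _ in range(head_epochs):
        order = rng.permutation(n)
        logits = clf.head.forward(feats[order], training=True)
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(p[np.arange(n), classes[order]] + 1e-12))
        grad = p
        grad[np.arange(n), classes[order]] -= 1.0
        clf.head.backward((grad / n).astype(np.float32))
        opt.step()
        history.append(float(loss))
    return history


@dataclass
class ImportanceMap:
    """Grad-CAM output: non-negative voxel weights plus per-atom scores."""

    voxel_weights: np.ndarray                  # (30, 30, 30), >= 0
    feature_weights: np.ndarray                # channel weights alpha_c
    target_class: int
    atom_scores: dict = field(default_factory=dict)   # atom index -> score


def grad_cam(clf: ClassifierNetwork, grid, target_class: int | None = None,
             complex_=None, spec: GridSpec | None = None) -> ImportanceMap:
    """Gradient-weighted class activation map for one voxel grid.

    The class score's gradient with respect to the last residual block's
    feature maps is averaged over space into per-channel weights alpha_c;
    the map is relu(sum_c alpha_c A_c), trilinearly upsampled to the input
    grid.  ``target_class`` defaults to the model's own predicted class.
    If a complex is given, each atom receives the sum of map values at
    voxel centers within (r_vdw + 1) angstroms of the atom.
    """
    from scipy import ndimage

    values = grid.values if hasattr(grid, "values") else np.asarray(grid)
    values = values.astype(np.float32)
    feats = clf.features(values[None])           # also fills _feature_cache
    fmap = clf.backbone._feature_cache[0]        # (C, s, s, s)
    logits = clf.head.forward(feats)
    if target_class is None:
        target_class = int(np.argmax(logits[0]))
    if not 0 <= target_class < clf.n_classes:
        raise ValueError(f"target class {target_class} out of range")

    # gradient of the class score back through the (linear+norm) head to
    # the global average pool input
    w_head = clf.head.params["weight"][:, target_class]          # (64,)
    # through ReLU and the feature norm (eval mode: affine with fixed scale)
    net = clf.backbone
    relu_mask = (feats[0] > 0).astype(np.float32)
    gamma = net.head_norm.params["gamma"]
    inv = 1.0 / np.sqrt(net.head_norm.moving_var + net.head_norm.eps)
    d_fc1_out = w_head * relu_mask * gamma * inv                  # (64,)
    d_gap = net.fc1.params["weight"] @ d_fc1_out                  # (C,)
    # GAP distributes the gradient uniformly over voxels, so the spatially
    # averaged feature-map gradient is d_gap / V; the constant 1/V does not
    # change the map up to scale and is kept for fidelity
    v = fmap[0].size / fmap.shape[0] if fmap.ndim == 4 else 1
    alpha = d_gap / np.prod(fmap.shape[1:])
    cam = np.maximum((alpha[:, None, None, None] * fmap).sum(axis=0), 0.0)

    n_out = (spec or GridSpec()).boxes_per_axis
    zoom = n_out / cam.shape[0]
    cam_up = ndimage.zoom(cam, zoom, order=1, mode="nearest")
    cam_up = np.maximum(cam_up, 0.0)

    atom_scores = {}
    if complex_ is not None:
        spec = spec or GridSpec()
        offsets = spec.axis_offsets()
        com = complex_.ligand_center_of_mass()
        for i, atom in enumerate(complex_.atoms):
            rel = atom.position - com
            cut = atom.vdw_radius + 1.0
            d2 = ((offsets[:, None, None] - rel[0]) ** 2
                  + (offsets[None, :, None] - rel[1]) ** 2
                  + (offsets[None, None, :] - rel[2]) ** 2)
            atom_scores[i] = float(cam_up[d2 <= cut * cut].sum())
    return ImportanceMap(voxel_weights=cam_up, feature_weights=alpha,
                         target_class=target_class, atom_scores=atom_scores)
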