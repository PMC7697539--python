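"""Voxelization of typed complexes into 16-channel atomic-density grids.

A cubic grid of 30 x 30 x 30 voxels at 1 angstrom spacing is centered on the
ligand center of mass.  Each atom deposits the density

    n(r) = 1 - exp(-(r_vdw / r)^12)

at every voxel center within a cutoff, summed per channel over the atoms that
carry the channel's class flag.  The 16 channels are the 8 atom classes,
separately for protein and ligand atoms.  The proper rotation group of the
cube (24 elements) acts exactly on the voxel lattice, which is what makes the
rotation augmentation an exact symmetry of the featurization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atoms import ATOM_CLASSES, MolecularComplex

__all__ = [
    "GridSpec",
    "VoxelGrid",
    "CHANNEL_LABELS",
    "density",
    "voxelize",
    "cube_rotations",
    "rotate_grid",
    "rotations24",
    "save_grid_archive",
    "load_grid_archive",
]

#: channel order: the 8 atom classes for protein atoms, then for ligand atoms
CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{role}_{cls}" for role in ("protein", "ligand") for cls in ATOM_CLASSES
)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the density grid (defaults: 30 A edge, 1 A spacing)."""

    edge_length: float = 30.0
    boxes_per_axis: int = 30
    spacing: float = 1.0

    def __post_init__(self):
        if not np.isclose(self.edge_length, self.boxes_per_axis * self.spacing):
            raise ValueError("edge_length must equal boxes_per_axis * spacing")

    def axis_offsets(self) -> np.ndarray:
        """Voxel-center offsets from the grid center along one axis.

        For the default grid these are -14.5, -13.5, ..., +14.5 angstroms.
        """
        n = self.boxes_per_axis
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing


@dataclass
class VoxelGrid:
    """A (16, n, n, n) channel-first density tensor plus its geometry."""

    values: np.ndarray
    spec: GridSpec = field(default_factory=GridSpec)
    channel_labels: tuple[str, ...] = CHANNEL_LABELS
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        n = self.spec.boxes_per_axis
        expect = (len(self.channel_labels), n, n, n)
        if self.values.shape != expect:
            raise ValueError(f"grid values must have shape {expect}, "
                             f"got {self.values.shape}")

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.channel_labels.index(label)]

    def channel_sums(self) -> np.ndarray:
        """Total density per channel (length 16)."""
        return self.values.sum(axis=(1, 2, 3))


def density(r, r_vdw):
    """Atomic density n(r) = 1 - exp(-(r_vdw/r)^12), with n(0) = 1.

    Strictly decreasing in r; n(r_vdw) = 1 - 1/e; essentially zero beyond
    about twice the van der Waals radius.
    """
    r = np.asarray(r, dtype=float)
    r_vdw = np.asarray(r_vdw, dtype=float)
    if np.any(r_vdw <= 0):
        raise ValueError("r_vdw must be positive")
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        out = -np.expm1(-((r_vdw / r) ** 12))
    return np.where(r == 0, 1.0, out) if out.ndim else (1.0 if r == 0 else float(out))


def voxelize(complex_: MolecularComplex, spec: GridSpec | None = None,
             clamp: bool = False, cutoff_margin: float = 5.0) -> VoxelGrid:
    """Embed a typed complex into the 16-channel density grid.

    The grid is centered on the ligand center of mass, so the featurization
    is invariant to rigid translations of the whole complex.  Atoms farther
    than ``r_vdw + cutoff_margin`` from a voxel center are skipped (their
    contribution is below 1e-3 at the default margin).  ``clamp`` caps each
    voxel at 1 after summation; by default contributions are summed without
    saturation.
    """
    spec = spec or GridSpec()
    if not complex_.ligand_atoms:
        raise ValueError(f"complex {complex_.id}: cannot voxelize an empty ligand")
    com = complex_.ligand_center_of_mass()
    offsets = spec.axis_offsets()
    n = spec.boxes_per_axis
    # accumulate in float64; the stored grid is float32
    values = np.zeros((len(CHANNEL_LABELS), n, n, n))
    role_base = {"protein": 0, "ligand": len(ATOM_CLASSES)}
    class_index = {c: i for i, c in enumerate(ATOM_CLASSES)}

    for atom in complex_.atoms:
        rel = atom.position - com
        cut = atom.vdw_radius + cutoff_margin
        # bounding sub-box of voxels within the cutoff
        lo = np.searchsorted(offsets, rel - cut, side="left")
        hi = np.searchsorted(offsets, rel + cut, side="right")
        if np.any(lo >= hi):
            continue
        dx = offsets[lo[0]:hi[0]] - rel[0]
        dy = offsets[lo[1]:hi[1]] - rel[1]
        dz = offsets[lo[2]:hi[2]] - rel[2]
        r2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2)
        mask = r2 <= cut * cut
        if not mask.any():
            continue
        r = np.sqrt(r2[mask])
        contrib = np.zeros_like(r2)
        with np.errstate(divide="ignore", over="ignore"):
            d = -np.expm1(-((atom.vdw_radius / r) ** 12))
        contrib[mask] = np.where(r == 0, 1.0, d)
        base = role_base[atom.role]
        for cls in atom.flags:
            values[base + class_index[cls],
                   lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += contrib
    if clamp:
        np.minimum(values, 1.0, out=values)
    return VoxelGrid(values=values.astype(np.float32), spec=spec, center=com)


def cube_rotations() -> list[np.ndarray]:
    """The 24 proper rotations of the cube as signed permutation matrices."""
    mats = []
    for perm in ([0, 1, 2], [0, 2, 1], [1, 0, 2], [1, 2, 0], [2, 0, 1], [2, 1, 0]):
        for signs in np.ndindex(2, 2, 2):
            m = np.zeros((3, 3), dtype=int)
            for row, (axis, s) in enumerate(zip(perm, signs)):
                m[row, axis] = 1 - 2 * s
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    assert len(mats) == 24
    return mats


def rotate_grid(values: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Apply a proper cube rotation to the spatial axes of a grid.

    ``rotation`` is a signed permutation matrix R; the output grid g' obeys
    g'(R v) = g(v) for every voxel-center offset v, matching a rotation of
    the underlying atoms about the grid center.
    """
    rotation = np.asarray(rotation)
    inv = rotation.T  # orthogonal
    # output axis a draws from input axis perm[a], flipped if the sign is -1
    perm = [int(np.argmax(np.abs(inv[:, a]))) for a in range(3)]
    signs = [int(inv[perm[a], a]) for a in range(3)]
    if sorted(perm) != [0, 1, 2]:
        raise ValueError("rotation must be a signed permutation matrix")
    ndim = values.ndim
    lead = ndim - 3  # leading (channel/batch) axes untouched
    out = np.transpose(values, tuple(range(lead)) + tuple(lead + p for p in perm))
    flip_axes = [lead + a for a in range(3) if signs[a] < 0]
    if flip_axes:
        out = np.flip(out, axis=flip_axes)
    return np.ascontiguousarray(out)


def rotations24(grid):
    """All 24 rotated copies of a grid (the identity first).

    Accepts a :class:`VoxelGrid` or a raw array whose last three axes are
    spatial; returns objects of the same kind.
    """
    mats = cube_rotations()
    if isinstance(grid, VoxelGrid):
        return [VoxelGrid(values=rotate_grid(grid.values, m), spec=grid.spec,
                          channel_labels=grid.channel_labels, center=grid.center)
                for m in mats]
    return [rotate_grid(np.asarray(grid), m) for m in mats]


# ---------------------------------------------------------------------------
# grid archive (HDF5)

def save_grid_archive(path, grids, ids=None, labels_kcal=None,
                      spec: GridSpec | None = None) -> None:
    """Write a stack of grids with optional ids and labels to HDF5."""
    import h5py

    grids = np.asarray(grids, dtype=np.float32)
    if grids.ndim == 4:
        grids = grids[None]
    spec = spec or GridSpec()
    with h5py.File(path, "w") as f:
        f.create_dataset("grids", data=grids, chunks=(1,) + grids.shape[1:],
                         compression="gzip", compression_opts=1)
        if ids is not None:
            f.create_dataset("ids", data=np.asarray(ids, dtype="S64"))
        if labels_kcal is not None:
            f.create_dataset("labels_kcal", data=np.asarray(labels_kcal, dtype=float))
        f.attrs["channel_labels"] = [s.encode() for s in CHANNEL_LABELS]
        f.attrs["edge_length"] = spec.edge_length
        f.attrs["boxes_per_axis"] = spec.boxes_per_axis
        f.attrs["spacing"] = spec.spacing


def load_grid_archive(path):
    """Read a grid archive; returns (grids, ids, labels_kcal, spec)."""
    import h5py

    with h5py.File(path, "r") as f:
        grids = f["grids"][...]
        ids = ([s.decode() for s in f["ids"][...]] if "ids" in f else None)
        labels = f["labels_kcal"][...] if "labels_kcal" in f else None
        spec = GridSpec(edge_length=float(f.attrs["edge_length"]),
                        boxes_per_axis=int(f.attrs["boxes_per_axis"]),
                        spacing=float(f.attrs["spacing"]))
    return grids, ids, labels, spec
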