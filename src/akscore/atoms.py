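"""Typed atoms, molecular complexes, and the atom-class vocabulary.

Atoms are classified into eight classes (hydrophobic, aromatic, hydrogen-bond
donor/acceptor, ionizable positive/negative, metallic, excluded volume) and
carry an AutoDock4-style van der Waals radius.  Protein and ligand atoms are
kept separate, which doubles the eight classes into the 16 density channels
of the voxel featurization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ATOM_CLASSES",
    "METALS",
    "VDW_RADII",
    "ATOMIC_MASSES",
    "UnsupportedElementError",
    "TypedAtom",
    "ComplexMetadata",
    "MolecularComplex",
    "vdw_radius",
    "atomic_mass",
]

#: the eight atom classes, in channel order
ATOM_CLASSES = (
    "hydrophobic",
    "aromatic",
    "hbd",
    "hba",
    "positive",
    "negative",
    "metallic",
    "excluded_volume",
)

#: elements classified as metallic
METALS = frozenset({"Mg", "Zn", "Mn", "Ca", "Fe"})

# Van der Waals radii in angstroms (AutoDock4 parameter set, Rii/2).
# Overridable per call through the ``radii`` argument of vdw_radius users.
VDW_RADII: dict[str, float] = {
    "H": 1.00,
    "C": 2.00,
    "N": 1.75,
    "O": 1.60,
    "P": 2.10,
    "S": 2.00,
    "F": 1.545,
    "Cl": 2.045,
    "Br": 2.165,
    "I": 2.36,
    "Mg": 0.65,
    "Zn": 0.74,
    "Mn": 0.65,
    "Ca": 0.99,
    "Fe": 0.65,
}

# Standard atomic weights (g/mol), used for the ligand center of mass.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "F": 18.998, "Cl": 35.45, "Br": 79.904, "I": 126.904,
    "Mg": 24.305, "Zn": 65.38, "Mn": 54.938, "Ca": 40.078, "Fe": 55.845,
}


class UnsupportedElementError(ValueError):
    """Raised for elements outside the supported radius table."""


def vdw_radius(element: str, radii: dict[str, float] | None = None) -> float:
    table = radii if radii is not None else VDW_RADII
    try:
        return table[element]
    except KeyError:
        raise UnsupportedElementError(
            f"element {element!r} is not in the van der Waals radius table; "
            f"supported: {sorted(table)}") from None


def atomic_mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise UnsupportedElementError(
            f"element {element!r} has no tabulated atomic mass") from None


@dataclass
class TypedAtom:
    """An atom with coordinates, channel flags and bookkeeping metadata.

    ``flags`` is the subset of :data:`ATOM_CLASSES` the atom contributes
    density to; ``excluded_volume`` is always a member.
    """

    element: str
    position: np.ndarray
    role: str  # "protein" | "ligand"
    flags: frozenset[str] = frozenset({"excluded_volume"})
    vdw_radius: float = 0.0
    charge_sign: str = "neutral"  # "positive" | "negative" | "neutral"
    is_aromatic: bool = False
    is_polar_hydrogen_bonded: bool = False
    residue_name: Optional[str] = None
    atom_name: Optional[str] = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.role not in ("protein", "ligand"):
            raise ValueError(f"role must be protein or ligand, got {self.role!r}")
        if self.vdw_radius == 0.0:
            self.vdw_radius = vdw_radius(self.element)
        unknown = set(self.flags) - set(ATOM_CLASSES)
        if unknown:
            raise ValueError(f"unknown atom classes: {sorted(unknown)}")

    def validate(self) -> None:
        """Check the atom-class invariants."""
        if "excluded_volume" not in self.flags:
            raise ValueError(f"{self}: excluded_volume must be set on every atom")
        if "aromatic" in self.flags and "hydrophobic" not in self.flags:
            raise ValueError(f"{self}: aromatic atoms are hydrophobic carbons")
        if ("metallic" in self.flags) != (self.element in METALS):
            raise ValueError(f"{self}: metallic flag must mirror the element")
        if "metallic" in self.flags and self.flags & {"hbd", "hba"}:
            raise ValueError(f"{self}: metals are neither donors nor acceptors")
        if self.vdw_radius <= 0:
            raise ValueError(f"{self}: vdw radius must be positive")


@dataclass
class ComplexMetadata:
    """Per-complex annotations consumed by the refined-set filter."""

    resolution: Optional[float] = None          # angstroms
    affinity_type: Optional[str] = None         # Ki | Kd | IC50 | other
    covalent: Optional[bool] = None
    stoichiometry: Optional[tuple[int, int]] = None
    ligand_elements: Optional[frozenset[str]] = None


@dataclass
class MolecularComplex:
    """A protein-ligand complex with optional experimental affinity.

    At most one of ``affinity_pk`` / ``affinity_kcal`` is authoritative;
    conversion between them goes through :mod:`akscore.units`.
    """

    id: str
    protein_atoms: list[TypedAtom] = field(default_factory=list)
    ligand_atoms: list[TypedAtom] = field(default_factory=list)
    affinity_pk: Optional[float] = None
    affinity_kcal: Optional[float] = None
    metadata: ComplexMetadata = field(default_factory=ComplexMetadata)
    ligand_mol: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for a in self.protein_atoms:
            if a.role != "protein":
                raise ValueError(f"protein atom with role {a.role!r}")
        for a in self.ligand_atoms:
            if a.role != "ligand":
                raise ValueError(f"ligand atom with role {a.role!r}")

    @property
    def atoms(self) -> list[TypedAtom]:
        return self.protein_atoms + self.ligand_atoms

    def ligand_center_of_mass(self) -> np.ndarray:
        if not self.ligand_atoms:
            raise ValueError(f"complex {self.id}: empty ligand has no center of mass")
        masses = np.array([atomic_mass(a.element) for a in self.ligand_atoms])
        coords = np.array([a.position for a in self.ligand_atoms])
        return (masses[:, None] * coords).sum(axis=0) / masses.sum()

    def with_ligand_positions(self, positions: np.ndarray, suffix: str = "") -> "MolecularComplex":
        """Copy of the complex with replaced ligand coordinates."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.ligand_atoms), 3):
            raise ValueError("positions must match the ligand atom count")
        new_lig = [replace(a, position=p) for a, p in zip(self.ligand_atoms, positions)]
        return MolecularComplex(
            id=self.id + suffix, protein_atoms=self.protein_atoms,
            ligand_atoms=new_lig, affinity_pk=self.affinity_pk,
            affinity_kcal=self.affinity_kcal, metadata=self.metadata,
            ligand_mol=self.ligand_mol)
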