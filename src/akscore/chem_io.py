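"""Reading protein-ligand complexes and assigning atom classes.

Proteins are read from PDB files (Biopython); ligands from SDF or MOL2 with
explicit bonds (RDKit), which preserves bond orders for aromaticity
perception and Gasteiger-charge calculation.  Atom classes follow an
AutoDock4-flavored typing scheme:

==================  =====================================================
hydrophobic         aliphatic or aromatic carbon
aromatic            aromatic carbon
hbd                 hydrogen bonded to N/O/S, and the heavy atom bearing it
hba                 N, O or S with a lone electron pair
positive/negative   atoms of recognized ionizable groups, signed by their
                    Gasteiger partial charge
metallic            Mg, Zn, Mn, Ca or Fe
excluded_volume     every atom
==================  =====================================================

PDB protein records carry no bond orders, so protein-side aromaticity and
ionizable groups are assigned from residue templates (His/Phe/Trp/Tyr ring
atoms; Lys/Arg/His side-chain nitrogens; Asp/Glu carboxylates and chain
termini).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .atoms import (ATOM_CLASSES, METALS, ComplexMetadata, MolecularComplex,
                    TypedAtom, UnsupportedElementError, vdw_radius)

__all__ = [
    "ParseError",
    "read_complex",
    "read_protein_pdb",
    "read_ligand",
    "assign_atom_types",
    "RefinedSetFilter",
    "FilterResult",
    "filter_refined",
]


class ParseError(ValueError):
    """A structure file could not be parsed."""


# ---------------------------------------------------------------------------
# reading

def read_protein_pdb(path) -> list[TypedAtom]:
    """Read protein atoms (plus any HETATM ions) from a PDB file."""
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms = []
    for atom in structure.get_atoms():
        element = atom.element.capitalize() if atom.element else ""
        if element in ("", "X"):
            continue
        residue = atom.get_parent()
        atoms.append(TypedAtom(
            element=element,
            position=np.asarray(atom.coord, dtype=float),
            role="protein",
            vdw_radius=_radius_or_raise(element, path),
            residue_name=residue.get_resname().strip(),
            atom_name=atom.get_name().strip(),
        ))
    if not atoms:
        raise ParseError(f"no atoms found in PDB file {path}")
    return atoms


def read_ligand(path):
    """Read a ligand from SDF or MOL2; returns an RDKit Mol with hydrogens
    retained and explicit bonds."""
    from rdkit import Chem

    path = Path(path)
    suffix = path.suffix.lower()
    if not path.exists():
        raise ParseError(f"ligand file {path} does not exist")
    if suffix in (".sdf", ".mol", ".sd"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mol = next(iter(supplier), None)
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
    else:
        raise ParseError(f"unsupported ligand format {suffix!r} "
                         f"(expected .sdf or .mol2): {path}")
    if mol is None:
        raise ParseError(f"cannot parse ligand file {path}")
    if mol.GetNumAtoms() == 0:
        raise ParseError(f"ligand file {path} contains zero atoms")
    try:
        Chem.SanitizeMol(
            mol, Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES)
    except Exception as exc:  # rdkit raises bare Exception subclasses
        raise ParseError(f"ligand file {path} failed sanitization: {exc}") from exc
    if mol.GetNumConformers() == 0:
        raise ParseError(f"ligand file {path} has no 3D coordinates")
    return mol


def _radius_or_raise(element, path):
    try:
        return vdw_radius(element)
    except UnsupportedElementError as exc:
        raise UnsupportedElementError(f"{path}: {exc}") from None


def read_complex(protein_path, ligand_path) -> MolecularComplex:
    """Read a protein (PDB) and ligand (SDF/MOL2) into an untyped complex.

    Coordinates are in angstroms; hydrogens are retained if present.  Call
    :func:`assign_atom_types` afterwards to populate the channel flags.
    """
    protein_atoms = read_protein_pdb(protein_path)
    mol = read_ligand(ligand_path)
    conf = mol.GetConformer()
    ligand_atoms = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        element = atom.GetSymbol()
        ligand_atoms.append(TypedAtom(
            element=element,
            position=np.array([pos.x, pos.y, pos.z]),
            role="ligand",
            vdw_radius=_radius_or_raise(element, ligand_path),
        ))
    return MolecularComplex(
        id=Path(protein_path).stem,
        protein_atoms=protein_atoms,
        ligand_atoms=ligand_atoms,
        ligand_mol=mol,
        metadata=ComplexMetadata(
            ligand_elements=frozenset(a.element for a in ligand_atoms)),
    )


# ---------------------------------------------------------------------------
# atom typing

# ring atoms of the standard aromatic residues
_AROMATIC_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}

# heavy atoms that carry a polar hydrogen (hydrogen-bond donors)
_PROTEIN_DONOR_ATOMS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("TRP", "NE1"),
}

# ionizable side-chain atoms, with their charge sign
_PROTEIN_POSITIVE = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"),
                     ("ARG", "NH2"), ("ARG", "CZ")}
_PROTEIN_NEGATIVE = {("ASP", "OD1"), ("ASP", "OD2"),
                     ("GLU", "OE1"), ("GLU", "OE2")}

# protein nitrogens with an available lone pair (imidazole-type)
_PROTEIN_N_ACCEPTORS = {("HIS", "ND1"), ("HIS", "NE2")}

# SMARTS patterns for ionizable ligand groups
_LIGAND_IONIZABLE = [
    ("positive", "[NX3;!$([NX3]C=O);!$([NX3]S(=O)=O);!$(N=*);!$([N+0]a)]"),  # amines
    ("positive", "[NX4+;!$([N+]C=O)]"),                                      # ammonium

    ("positive", "[NX3][CX3](=[NX2,NX3+])[NX3]"),                            # guanidinium/amidinium
    ("positive", "[nX3H1,$([NX3H+])]1cncc1"),                                # imidazolium
    ("negative", "[CX3](=O)[OX2H1,OX1-]"),                                   # carboxyl(ate)
    ("negative", "[PX4](=O)([OX2H1,OX1-])"),                                 # phosphate
    ("negative", "[SX4](=O)(=O)[OX2H1,OX1-]"),                               # sulfate/sulfonate
    ("negative", "[OX1-]"),                                                  # alkoxide/oxide anion
]


def _type_ligand_atoms(mol, atoms: list[TypedAtom]) -> list[TypedAtom]:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    AllChem.ComputeGasteigerCharges(mol)
    # per-atom charge including the implicit-hydrogen contribution, so that
    # e.g. an ammonium nitrogen (negative itself, positive with its protons)
    # is signed by the chemistry of the whole ionizable center
    def _q(a):
        c = float(a.GetProp("_GasteigerCharge"))
        if a.HasProp("_GasteigerHCharge"):
            c += float(a.GetProp("_GasteigerHCharge"))
        return 0.0 if math.isnan(c) or math.isinf(c) else c

    charges = []
    for a in mol.GetAtoms():
        c = _q(a)
        for nb in a.GetNeighbors():   # fold explicit hydrogens in as well
            if nb.GetSymbol() == "H":
                c += _q(nb)
        charges.append(c)

    ionizable: dict[int, str] = {}
    for sign, smarts in _LIGAND_IONIZABLE:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:  # pragma: no cover - patterns are static
            continue
        for match in mol.GetSubstructMatches(patt):
            for idx in match:
                atom = mol.GetAtomWithIdx(idx)
                # flag the ionizable heteroatoms of the group, not its carbons
                if atom.GetSymbol() in ("N",) and sign == "positive":
                    ionizable.setdefault(idx, sign)
                if atom.GetSymbol() in ("O",) and sign == "negative":
                    ionizable.setdefault(idx, sign)

    typed = []
    for atom, rec in zip(mol.GetAtoms(), atoms):
        idx = atom.GetIdx()
        el = atom.GetSymbol()
        flags = {"excluded_volume"}
        aromatic = bool(atom.GetIsAromatic())
        polar_h = False
        if el == "C":
            flags.add("hydrophobic")
            if aromatic:
                flags.add("aromatic")
        if el in METALS:
            flags.add("metallic")
        elif el in ("N", "O", "S"):
            # lone pair present unless the atom is tetravalent (quaternary N)
            if atom.GetTotalValence() < 4 and atom.GetFormalCharge() <= 0:
                flags.add("hba")
            if atom.GetTotalNumHs(includeNeighbors=True) > 0:
                flags.add("hbd")
                polar_h = True
        if el == "H":
            heavy = [n for n in atom.GetNeighbors()]
            if heavy and heavy[0].GetSymbol() in ("N", "O", "S"):
                flags.add("hbd")
                polar_h = True
        sign = "neutral"
        if idx in ionizable:
            sign = ionizable[idx]
            # Gasteiger sign has the final word for ionizable atoms
            if sign == "positive" and charges[idx] >= 0:
                flags.add("positive")
            elif sign == "negative" and charges[idx] <= 0:
                flags.add("negative")
            else:
                sign = "neutral"
        if "metallic" in flags:
            flags -= {"hba", "hbd"}
        typed.append(replace(
            rec, flags=frozenset(flags), charge_sign=sign,
            is_aromatic=aromatic, is_polar_hydrogen_bonded=polar_h))
    return typed


def _type_protein_atom(atom: TypedAtom, donor_heavies: list[TypedAtom]) -> TypedAtom:
    el = atom.element
    res = (atom.residue_name or "").upper()
    name = (atom.atom_name or "").upper()
    key = (res, name)
    flags = {"excluded_volume"}
    aromatic = False
    polar_h = False
    sign = "neutral"
    if el in METALS:
        flags.add("metallic")
    elif el == "C":
        flags.add("hydrophobic")
        if name in _AROMATIC_RING_ATOMS.get(res, ()):
            flags.add("aromatic")
            aromatic = True
    elif el in ("O", "S"):
        flags.add("hba")
    elif el == "N":
        if key in _PROTEIN_N_ACCEPTORS:
            flags.add("hba")
    if key in _PROTEIN_DONOR_ATOMS or (el == "N" and name == "N" and res != "PRO"):
        flags.add("hbd")
        polar_h = True
    if key in _PROTEIN_POSITIVE:
        flags.add("positive")
        sign = "positive"
    if key in _PROTEIN_NEGATIVE or name == "OXT":
        flags.add("negative")
        sign = "negative"
    if el == "H":
        # polar hydrogen: bonded (within covalent range) to N/O/S
        for heavy in donor_heavies:
            if np.linalg.norm(atom.position - heavy.position) < 1.25:
                flags.add("hbd")
                polar_h = True
                break
    if "metallic" in flags:
        flags -= {"hba", "hbd"}
    return replace(atom, flags=frozenset(flags), charge_sign=sign,
                   is_aromatic=aromatic, is_polar_hydrogen_bonded=polar_h)


def assign_atom_types(complex_: MolecularComplex) -> MolecularComplex:
    """Populate the 8 class flags on every atom of the complex.

    Idempotent: re-typing a typed complex yields the same flags.  Ligand
    typing uses the RDKit molecule (bond orders, aromaticity, Gasteiger
    charges) when available and falls back to element rules otherwise.
    """
    donor_heavies = [a for a in complex_.protein_atoms
                     if a.element in ("N", "O", "S")]
    protein = [_type_protein_atom(a, donor_heavies)
               for a in complex_.protein_atoms]
    if complex_.ligand_mol is not None:
        ligand = _type_ligand_atoms(complex_.ligand_mol, complex_.ligand_atoms)
    else:
        # typed atom clouds (e.g. synthetic fixtures): trust existing flags
        # beyond the mandatory ones, but enforce element-determined classes
        ligand = []
        for a in complex_.ligand_atoms:
            flags = set(a.flags) | {"excluded_volume"}
            if a.element in METALS:
                flags |= {"metallic"}
                flags -= {"hba", "hbd"}
            if "aromatic" in flags:
                flags.add("hydrophobic")
            ligand.append(replace(a, flags=frozenset(flags)))
    out = MolecularComplex(
        id=complex_.id, protein_atoms=protein, ligand_atoms=ligand,
        affinity_pk=complex_.affinity_pk, affinity_kcal=complex_.affinity_kcal,
        metadata=complex_.metadata, ligand_mol=complex_.ligand_mol)
    for a in out.atoms:
        a.validate()
    return out


# ---------------------------------------------------------------------------
# refined-set filter

@dataclass(frozen=True)
class RefinedSetFilter:
    """The five quality conditions of the refined-set selection.

    A complex passes iff: resolution <= 2.5 A; the affinity is a Ki or Kd;
    binding is noncovalent; protein:ligand stoichiometry is 1:1; and the
    ligand contains only common organic elements (hydrogen is additionally
    tolerated alongside the printed nine).
    """

    max_resolution: float = 2.5
    allowed_affinity_types: frozenset[str] = frozenset({"Ki", "Kd"})
    allowed_elements: frozenset[str] = frozenset(
        {"C", "N", "O", "P", "S", "F", "Cl", "Br", "I", "H"})
    require_noncovalent: bool = True
    require_one_to_one: bool = True


@dataclass
class FilterResult:
    accepted: list[str]
    rejections: dict[str, str]


def _check_record(meta: ComplexMetadata, flt: RefinedSetFilter, cid: str) -> str | None:
    """Returns the first failed condition's name, or None when accepted."""
    fields = {"resolution": meta.resolution,
              "affinity_type": meta.affinity_type,
              "covalent": meta.covalent,
              "stoichiometry": meta.stoichiometry,
              "ligand_elements": meta.ligand_elements}
    missing = [k for k, v in fields.items() if v is None]
    if missing:
        raise ValueError(f"complex {cid}: missing metadata fields {missing}")
    if meta.resolution > flt.max_resolution:
        return f"resolution {meta.resolution} A > {flt.max_resolution} A"
    if meta.affinity_type not in flt.allowed_affinity_types:
        return (f"affinity type {meta.affinity_type} not in "
                f"{sorted(flt.allowed_affinity_types)}")
    if flt.require_noncovalent and meta.covalent:
        return "covalently bound ligand"
    if flt.require_one_to_one and tuple(meta.stoichiometry) != (1, 1):
        return f"stoichiometry {meta.stoichiometry} is not 1:1"
    bad = set(meta.ligand_elements) - set(flt.allowed_elements)
    if bad:
        return f"ligand elements {sorted(bad)} outside {sorted(flt.allowed_elements)}"
    return None


def filter_refined(records, flt: RefinedSetFilter | None = None) -> FilterResult:
    """Partition complexes into accepted ids and per-id rejection reasons.

    ``records`` is an iterable of :class:`MolecularComplex` or of
    ``(id, ComplexMetadata)`` pairs.  The rejection reason names the first
    failed condition, in the fixed order resolution, affinity type,
    covalency, stoichiometry, elements.  Missing metadata raises.
    """
    flt = flt or RefinedSetFilter()
    accepted, rejections = [], {}
    for rec in records:
        if isinstance(rec, MolecularComplex):
            cid, meta = rec.id, rec.metadata
        else:
            cid, meta = rec
        reason = _check_record(meta, flt, cid)
        if reason is None:
            accepted.append(cid)
        else:
            rejections[cid] = reason
    return FilterResult(accepted=accepted, rejections=rejections)
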