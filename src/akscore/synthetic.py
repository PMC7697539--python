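"""Seeded synthetic protein-ligand complexes with a planted affinity law.

The generator emulates the geometry the scoring pipeline consumes: a ligand
(a typed atom cloud, including optional benzene-like aromatic rings) inside
a spherical pocket, surrounded by a shell of protein atoms.  Atom classes
are drawn from a configurable composition and realized with elements and
residue templates chosen so that the structure files written by
:func:`write_fixture_files` re-type consistently when read back through
``chem_io``.

The affinity of a generated complex is planted by a known mechanism: a
linear functional of the 16 per-channel density sums of its own voxel grid,
plus Gaussian noise (default sd 0.5 kcal/mol, comparable to the intrinsic
error of empirical affinity measurements).  This makes the generator its own
oracle — a model that recovers the channel weights has learned exactly the
planted signal, and ablating a channel with nonzero weight must hurt.

Fixture molecules are not chemically valid compounds; they are typed
coordinate clouds satisfying the atom-class invariants, which is all the
featurization consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atoms import METALS, MolecularComplex, TypedAtom
from .metrics import DockingCase, RankingGroup
from .units import kcal_to_pk
from .voxel import CHANNEL_LABELS, GridSpec, VoxelGrid, voxelize

__all__ = [
    "SyntheticComplexSpec",
    "GeneratedComplex",
    "default_affinity_weights",
    "generate_complex",
    "generate_dataset",
    "generate_ranking_groups",
    "generate_decoys",
    "decoy_docking_inputs",
    "write_fixture_files",
]

# class -> (element, flags) for ligand atoms
_LIGAND_PALETTE = {
    "hydrophobic": ("C", {"hydrophobic"}),
    "aromatic": ("C", {"hydrophobic", "aromatic"}),
    "hbd": ("O", {"hba", "hbd"}),           # hydroxyl-like oxygen
    "hba": ("N", {"hba"}),                  # bare acceptor nitrogen
    "positive": ("N", {"positive", "hbd"}),  # ammonium-like
    "negative": ("O", {"negative", "hba"}),  # alkoxide-like
    "metallic": ("Zn", {"metallic"}),
    "excluded_volume": ("F", set()),
}

# class -> (element, residue, atom name, is_hetatm) for protein atoms
_PROTEIN_PALETTE = {
    "hydrophobic": ("C", "ALA", "CB", False),
    "aromatic": ("C", "PHE", "CZ", False),
    "hbd": ("N", "GLN", "NE2", False),
    "hba": ("O", "ALA", "O", False),
    "positive": ("N", "LYS", "NZ", False),
    "negative": ("O", "ASP", "OD1", False),
    "metallic": ("Zn", "ZN", "ZN", True),
    "excluded_volume": ("Cl", "CL", "CL", True),
}

_DEFAULT_LIGAND_COMPOSITION = {
    "hydrophobic": 0.40, "aromatic": 0.18, "hbd": 0.12, "hba": 0.15,
    "positive": 0.05, "negative": 0.05, "metallic": 0.0,
    "excluded_volume": 0.05,
}
_DEFAULT_PROTEIN_COMPOSITION = {
    "hydrophobic": 0.42, "aromatic": 0.13, "hbd": 0.12, "hba": 0.18,
    "positive": 0.06, "negative": 0.06, "metallic": 0.01,
    "excluded_volume": 0.02,
}

_RING_RADIUS = 1.39  # angstrom, aromatic C-C ring geometry


def default_affinity_weights() -> np.ndarray:
    """Planted channel weights (kcal/mol per unit summed density).

    Dominated by the ligand and pocket excluded volumes — tighter packing
    gives more negative (stronger) planted affinity — with smaller
    hydrophobic and acceptor terms.
    """
    w = {label: 0.0 for label in CHANNEL_LABELS}
    w["ligand_excluded_volume"] = -0.012
    w["protein_excluded_volume"] = -0.0012
    w["ligand_hydrophobic"] = -0.003
    w["protein_hydrophobic"] = -0.001
    w["ligand_hba"] = -0.002
    w["protein_hba"] = -0.001
    return np.array([w[label] for label in CHANNEL_LABELS])


@dataclass
class SyntheticComplexSpec:
    """Parameters of the synthetic-complex generator."""

    seed: int = 0
    n_protein_atoms: int = 80
    n_ligand_atoms: int = 12
    #: when set, each complex draws its ligand atom count uniformly from
    #: this inclusive range (ligand series span a range of sizes, and the
    #: packed volume is the dominant planted-affinity term)
    ligand_size_range: tuple[int, int] | None = (8, 18)
    #: when set, every complex shares one pocket (generated from this seed),
    #: emulating a ligand series binding a single receptor
    shared_protein_seed: int | None = None
    pocket_radius: float = 3.5           # angstrom, ligand-bearing sphere
    shell_width: tuple[float, float] = (1.2, 6.5)  # protein shell, beyond pocket
    ligand_composition: dict = field(
        default_factory=lambda: dict(_DEFAULT_LIGAND_COMPOSITION))
    protein_composition: dict = field(
        default_factory=lambda: dict(_DEFAULT_PROTEIN_COMPOSITION))
    affinity_weights: np.ndarray = field(default_factory=default_affinity_weights)
    noise_sd: float = 0.5                # kcal/mol
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self):
        self.affinity_weights = np.asarray(self.affinity_weights, dtype=float)
        if self.affinity_weights.shape != (len(CHANNEL_LABELS),):
            raise ValueError("affinity_weights must have one entry per channel")
        for comp in (self.ligand_composition, self.protein_composition):
            total = sum(comp.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"composition probabilities sum to {total}, not 1")
        if self.n_ligand_atoms < 1 or self.n_protein_atoms < 0:
            raise ValueError("need at least one ligand atom")
        # crude packing feasibility: ~0.35 A^3 headroom per atom
        max_atoms = (max(self.ligand_size_range) if self.ligand_size_range
                     else self.n_ligand_atoms)
        volume = 4.0 / 3.0 * np.pi * self.pocket_radius ** 3
        if self.pocket_radius <= 0 or volume < 0.35 * max_atoms:
            raise ValueError(
                f"pocket radius {self.pocket_radius} A cannot hold "
                f"{max_atoms} ligand atoms")


@dataclass
class GeneratedComplex:
    """A generated complex plus its grid and planted affinity bookkeeping."""

    complex: MolecularComplex
    grid: VoxelGrid
    affinity_kcal: float        # noisy planted label (= complex.affinity_kcal)
    clean_affinity_kcal: float  # the exact linear functional, before noise


def _sample_point_in_sphere(rng, radius):
    while True:
        p = rng.uniform(-radius, radius, 3)
        if np.dot(p, p) <= radius * radius:
            return p


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _ligand_atoms(rng, spec: SyntheticComplexSpec) -> list[TypedAtom]:
    classes = list(spec.ligand_composition)
    probs = np.array([spec.ligand_composition[c] for c in classes])
    if spec.ligand_size_range:
        lo, hi = spec.ligand_size_range
        n_atoms = int(rng.integers(lo, hi + 1))
    else:
        n_atoms = spec.n_ligand_atoms
    drawn = list(rng.choice(classes, size=n_atoms, p=probs))
    n_rings, leftover = divmod(drawn.count("aromatic"), 6)
    # aromatic atoms come in benzene-like rings of six; stragglers fall back
    # to plain hydrophobic carbon
    drawn = [c for c in drawn if c != "aromatic"] + ["hydrophobic"] * leftover
    atoms: list[TypedAtom] = []
    for _ in range(n_rings):
        center = _sample_point_in_sphere(rng, max(spec.pocket_radius - 1.0, 0.5))
        rot = _random_rotation(rng)
        for i in range(6):
            angle = np.pi / 3.0 * i
            local = np.array([np.cos(angle), np.sin(angle), 0.0]) * _RING_RADIUS
            atoms.append(_make_ligand_atom("aromatic", center + rot @ local))
    for cls in drawn:
        atoms.append(_make_ligand_atom(
            cls, _sample_point_in_sphere(rng, spec.pocket_radius)))
    return atoms


def _make_ligand_atom(cls, position) -> TypedAtom:
    element, flags = _LIGAND_PALETTE[cls]
    return TypedAtom(element=element, position=position, role="ligand",
                     flags=frozenset(flags | {"excluded_volume"}),
                     charge_sign=("positive" if "positive" in flags else
                                  "negative" if "negative" in flags else "neutral"),
                     is_aromatic="aromatic" in flags,
                     is_polar_hydrogen_bonded="hbd" in flags)


def _protein_atoms(rng, spec: SyntheticComplexSpec) -> list[TypedAtom]:
    classes = list(spec.protein_composition)
    probs = np.array([spec.protein_composition[c] for c in classes])
    atoms = []
    lo = spec.pocket_radius + spec.shell_width[0]
    hi = spec.pocket_radius + spec.shell_width[1]
    for cls in rng.choice(classes, size=spec.n_protein_atoms, p=probs):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = direction * rng.uniform(lo, hi)
        element, res, name, _ = _PROTEIN_PALETTE[cls]
        flags = {
            "hydrophobic": {"hydrophobic"},
            "aromatic": {"hydrophobic", "aromatic"},
            "hbd": {"hbd"},
            "hba": {"hba"},
            "positive": {"positive", "hbd"},
            "negative": {"negative", "hba"},
            "metallic": {"metallic"},
            "excluded_volume": set(),
        }[cls]
        atoms.append(TypedAtom(
            element=element, position=pos, role="protein",
            flags=frozenset(flags | {"excluded_volume"}),
            charge_sign=("positive" if "positive" in flags else
                         "negative" if "negative" in flags else "neutral"),
            is_aromatic="aromatic" in flags,
            is_polar_hydrogen_bonded="hbd" in flags,
            residue_name=res, atom_name=name))
    return atoms


def generate_complex(spec: SyntheticComplexSpec,
                     complex_id: str = "synth") -> GeneratedComplex:
    """Generate one seeded complex; same spec => identical output.

    The planted affinity is computed from the complex's own voxel grid:
    affinity = w . channel_sums + N(0, noise_sd), in kcal/mol.
    """
    rng = np.random.default_rng(spec.seed)
    ligand = _ligand_atoms(rng, spec)
    protein_rng = (np.random.default_rng(spec.shared_protein_seed)
                   if spec.shared_protein_seed is not None else rng)
    protein = _protein_atoms(protein_rng, spec)
    cplx = MolecularComplex(id=complex_id, protein_atoms=protein,
                            ligand_atoms=ligand)
    grid = voxelize(cplx, spec.grid)
    clean = float(spec.affinity_weights @ grid.channel_sums())
    noise = float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
    affinity = clean + noise
    cplx.affinity_kcal = affinity
    cplx.affinity_pk = float(kcal_to_pk(affinity))
    return GeneratedComplex(complex=cplx, grid=grid, affinity_kcal=affinity,
                            clean_affinity_kcal=clean)


def _child_specs(spec: SyntheticComplexSpec, n: int, salt: int = 0):
    seeds = np.random.SeedSequence((spec.seed, salt)).generate_state(n)
    for i, s in enumerate(seeds):
        yield SyntheticComplexSpec(**{
            **spec.__dict__, "seed": int(s % (2 ** 31 - 1))})


def generate_dataset(spec: SyntheticComplexSpec, n: int, prefix: str = "synth"):
    """n independently seeded complexes derived from one master spec.

    Returns (generated list, grid array (n, 16, g, g, g), labels kcal/mol).
    """
    gen = [generate_complex(s, complex_id=f"{prefix}{i:03d}")
           for i, s in enumerate(_child_specs(spec, n))]
    grids = np.stack([g.grid.values for g in gen])
    labels = np.array([g.affinity_kcal for g in gen])
    return gen, grids, labels


def generate_ranking_groups(n_groups: int, spec: SyntheticComplexSpec,
                            affinity_span: float = 2.0,
                            members_per_group: int = 5,
                            max_attempts: int = 8):
    """Clusters of five complexes whose planted affinities span >= the
    requested range (pK units; 2 pK emulates a 100-fold affinity spread).

    Member ligand sizes ramp from small to large so the planted packing term
    produces a natural spread.  Returns a list of lists of
    :class:`GeneratedComplex`, one inner list per cluster.
    """
    if affinity_span <= 0:
        raise ValueError("affinity_span must be positive")
    sizes = np.linspace(6, max(18, spec.n_ligand_atoms), members_per_group)
    groups = []
    for g, master in enumerate(_child_specs(spec, n_groups, salt=1)):
        for attempt in range(max_attempts):
            members = []
            child = iter(_child_specs(master, members_per_group, salt=attempt + 2))
            for m, sub in enumerate(child):
                sub.n_ligand_atoms = int(sizes[m])
                sub.ligand_size_range = None   # sizes ramp deterministically
                members.append(generate_complex(sub, complex_id=f"G{g:03d}M{m}"))
            pks = [m.complex.affinity_pk for m in members]
            if max(pks) - min(pks) >= affinity_span:
                groups.append(members)
                break
        else:
            raise RuntimeError(
                f"could not achieve affinity span {affinity_span} pK in group {g}")
    return groups


def ranking_groups_from_predictions(groups, predictions) -> list[RankingGroup]:
    """Assemble metric-ready clusters from generated groups + predictions
    (pK scale, aligned with the flattened group order)."""
    out = []
    i = 0
    for g, members in enumerate(groups):
        triples = []
        for m in members:
            triples.append((m.complex.id, float(m.complex.affinity_pk),
                            float(predictions[i])))
            i += 1
        out.append(RankingGroup(group_id=f"G{g:03d}", members=triples))
    return out


def _axis_angle_rotation(rng, max_angle):
    if max_angle <= 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def generate_decoys(generated: GeneratedComplex, n_decoys: int = 100,
                    rmsd_range: tuple[float, float] = (0.5, 8.0),
                    max_rotation: float = np.pi,
                    seed: int = 0):
    """Rigid-body perturbed ligand poses (the native pose is kept aside).

    Each decoy applies a rotation of up to ``max_rotation`` radians about
    the ligand center of mass plus a translation of magnitude drawn from
    ``rmsd_range``; returns a list of (MolecularComplex, displacement
    magnitude).  Zero rotation and a (0, 0) range reproduce the native pose.
    """
    if n_decoys < 1:
        raise ValueError("need at least one decoy")
    rng = np.random.default_rng(seed)
    cplx = generated.complex
    com = cplx.ligand_center_of_mass()
    coords = np.array([a.position for a in cplx.ligand_atoms])
    decoys = []
    for d in range(n_decoys):
        rot = _axis_angle_rotation(rng, max_rotation)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = direction * rng.uniform(*rmsd_range)
        new = (coords - com) @ rot.T + com + shift
        decoys.append((cplx.with_ligand_positions(new, suffix=f"_decoy{d:03d}"),
                       float(np.linalg.norm(shift))))
    return decoys


def decoy_docking_inputs(generated: GeneratedComplex, score_fn,
                         n_decoys: int = 100,
                         rmsd_range: tuple[float, float] = (0.5, 8.0),
                         seed: int = 0) -> DockingCase:
    """Score native + decoys with ``score_fn(grid values) -> float`` and
    package them as a docking-power case."""
    native_score = float(score_fn(generated.grid.values))
    scores = []
    for decoy, _ in generate_decoys(generated, n_decoys, rmsd_range, seed=seed):
        scores.append(float(score_fn(voxelize(decoy, generated.grid.spec).values)))
    return DockingCase(case_id=generated.complex.id,
                       native_score=native_score, decoy_scores=scores)


# ---------------------------------------------------------------------------
# writing fixtures to standard formats

def _ligand_to_rdkit(atoms: list[TypedAtom]):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    conf_positions = []
    ring_members = [i for i, a in enumerate(atoms) if a.is_aromatic]
    idx_map = {}
    for i, a in enumerate(atoms):
        atom = Chem.Atom(a.element)
        if "positive" in a.flags and a.element == "N":
            atom.SetFormalCharge(1)
        elif "negative" in a.flags and a.element == "O":
            atom.SetFormalCharge(-1)
            atom.SetNoImplicit(True)
        elif a.element in ("N",) and "hba" in a.flags and "hbd" not in a.flags:
            atom.SetNoImplicit(True)
        elif a.element in METALS or a.element in ("F", "Cl", "Br", "I"):
            atom.SetNoImplicit(True)
        idx_map[i] = mol.AddAtom(atom)
        conf_positions.append(a.position)
    # aromatic rings were generated as consecutive runs of six atoms
    for start in range(0, len(ring_members), 6):
        ring = ring_members[start:start + 6]
        if len(ring) < 6:
            continue
        for j in range(6):
            a, b = idx_map[ring[j]], idx_map[ring[(j + 1) % 6]]
            order = Chem.BondType.AROMATIC
            mol.AddBond(a, b, order)
            mol.GetAtomWithIdx(a).SetIsAromatic(True)
            mol.GetAtomWithIdx(b).SetIsAromatic(True)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, p in enumerate(conf_positions):
        conf.SetAtomPosition(i, Point3D(*map(float, p)))
    mol.AddConformer(conf)
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return m


def _pdb_line(serial: int, atom: TypedAtom, resseq: int) -> str:
    _, res, name, het = _PROTEIN_PALETTE.get(
        _atom_class(atom), ("C", "ALA", "CB", False))
    res = atom.residue_name or res
    name = atom.atom_name or name
    record = "HETATM" if het or atom.element in METALS or res in ("ZN", "CL") else "ATOM"
    x, y, z = atom.position
    el = atom.element.upper()
    return (f"{record:<6s}{serial:>5d} {name:<4s}{res:>4s} A{resseq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}")


def _atom_class(atom: TypedAtom) -> str:
    for cls in ("metallic", "aromatic", "positive", "negative", "hbd", "hba",
                "hydrophobic"):
        if cls in atom.flags:
            return cls
    return "excluded_volume"


def write_fixture_files(generated: list[GeneratedComplex], outdir) -> Path:
    """Write each complex as {id}_protein.pdb + {id}_ligand.sdf and a
    labels.csv (id, affinity in pK and kcal/mol); returns the directory."""
    from rdkit import Chem

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["id,affinity_pk,affinity_kcal"]
    for gen in generated:
        cplx = gen.complex
        lines = [f"REMARK synthetic fixture complex {cplx.id}"]
        for i, atom in enumerate(cplx.protein_atoms, start=1):
            lines.append(_pdb_line(i, atom, i))
        lines.append("END")
        (outdir / f"{cplx.id}_protein.pdb").write_text("\n".join(lines) + "\n")
        mol = _ligand_to_rdkit(cplx.ligand_atoms)
        mol.SetProp("_Name", cplx.id)
        with Chem.SDWriter(str(outdir / f"{cplx.id}_ligand.sdf")) as writer:
            writer.write(mol)
        rows.append(f"{cplx.id},{cplx.affinity_pk:.6f},{cplx.affinity_kcal:.6f}")
    (outdir / "labels.csv").write_text("\n".join(rows) + "\n")
    return outdir
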