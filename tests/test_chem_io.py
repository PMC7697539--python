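"""Structure parsing, atom typing and the refined-set filter."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from akscore.atoms import ComplexMetadata, MolecularComplex, TypedAtom
from akscore.chem_io import (ParseError, RefinedSetFilter, assign_atom_types,
                             filter_refined, read_complex)

PEPTIDE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.922  1.00  0.00           C
ATOM      4  O   ALA A   1      13.339   7.183  -3.882  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.521   6.215  -4.115  1.00  0.00           C
ATOM      6  N   PHE A   2      12.854   8.061  -5.901  1.00  0.00           N
ATOM      7  CA  PHE A   2      13.832   9.139  -5.791  1.00  0.00           C
ATOM      8  CG  PHE A   2      13.618  10.816  -7.650  1.00  0.00           C
ATOM      9  CD1 PHE A   2      14.422  10.733  -8.776  1.00  0.00           C
ATOM     10  CZ  PHE A   2      13.200  12.963  -9.361  1.00  0.00           C
ATOM     11  N   LYS A   3      14.412   9.251  -3.378  1.00  0.00           N
ATOM     12  NZ  LYS A   3      18.880   9.049  -0.297  1.00  0.00           N
ATOM     13  OD1 ASP A   4      19.000  10.000  -5.000  1.00  0.00           O
HETATM   14 ZN    ZN A   5      15.000  10.000  -6.000  1.00  0.00          ZN
END
"""


def write_benzene_sdf(path):
    mol = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1"))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    with Chem.SDWriter(str(path)) as w:
        w.write(mol)


def write_sdf_from_smiles(path, smiles):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    with Chem.SDWriter(str(path)) as w:
        w.write(mol)
    return mol


@pytest.fixture()
def peptide_pdb(tmp_path):
    p = tmp_path / "prot.pdb"
    p.write_text(PEPTIDE_PDB)
    return p


def test_read_complex_benzene_has_six_aromatic_carbons(peptide_pdb, tmp_path):
    sdf = tmp_path / "benzene.sdf"
    write_benzene_sdf(sdf)
    cplx = assign_atom_types(read_complex(peptide_pdb, sdf))
    arom = [a for a in cplx.ligand_atoms if "aromatic" in a.flags]
    assert len(arom) == 6
    assert all(a.element == "C" and "hydrophobic" in a.flags for a in arom)
    assert len(cplx.protein_atoms) == 14


def test_empty_ligand_file_raises(peptide_pdb, tmp_path):
    sdf = tmp_path / "empty.sdf"
    sdf.write_text("\n     RDKit          3D\n\n  0  0  0  0  0  0  0  0  0  0999 V2000\nM  END\n$$$$\n")
    with pytest.raises(ParseError):
        read_complex(peptide_pdb, sdf)


def test_unreadable_files_raise_parse_errors(tmp_path):
    bad_pdb = tmp_path / "bad.pdb"
    bad_pdb.write_text("this is not a pdb\n")
    sdf = tmp_path / "benzene.sdf"
    write_benzene_sdf(sdf)
    with pytest.raises(ParseError):
        read_complex(bad_pdb, sdf)
    missing = tmp_path / "nope.sdf"
    with pytest.raises(ParseError):
        read_complex(bad_pdb, missing)


def test_unsupported_ligand_format_raises(peptide_pdb, tmp_path):
    weird = tmp_path / "ligand.xyz"
    weird.write_text("1\nc\nC 0 0 0\n")
    with pytest.raises(ParseError):
        read_complex(peptide_pdb, weird)


# ---------------------------------------------------------------------------
# typing rules

def typed_ligand(tmp_path, peptide_pdb, smiles):
    sdf = tmp_path / "lig.sdf"
    write_sdf_from_smiles(sdf, smiles)
    return assign_atom_types(read_complex(peptide_pdb, sdf))


def test_carbonyl_oxygen_is_acceptor_only(peptide_pdb, tmp_path):
    cplx = typed_ligand(tmp_path, peptide_pdb, "CC(C)=O")  # acetone
    carbonyl_o = [a for a in cplx.ligand_atoms if a.element == "O"]
    assert len(carbonyl_o) == 1
    assert carbonyl_o[0].flags == frozenset({"hba", "excluded_volume"})


def test_aliphatic_carbon_is_hydrophobic_not_aromatic(peptide_pdb, tmp_path):
    cplx = typed_ligand(tmp_path, peptide_pdb, "CC(C)=O")
    carbons = [a for a in cplx.ligand_atoms if a.element == "C"]
    for c in carbons:
        assert "hydrophobic" in c.flags and "aromatic" not in c.flags


def test_carboxylate_oxygens_are_negative(peptide_pdb, tmp_path):
    cplx = typed_ligand(tmp_path, peptide_pdb, "CC(=O)[O-]")  # acetate
    negs = [a for a in cplx.ligand_atoms if "negative" in a.flags]
    assert {a.element for a in negs} == {"O"}
    assert len(negs) >= 1


def test_amine_nitrogen_is_positive_and_donor(peptide_pdb, tmp_path):
    cplx = typed_ligand(tmp_path, peptide_pdb, "CC[NH3+]")   # ethylammonium
    n = [a for a in cplx.ligand_atoms if a.element == "N"][0]
    assert "positive" in n.flags
    assert "hbd" in n.flags


def test_polar_hydrogens_carry_the_donor_flag(peptide_pdb, tmp_path):
    cplx = typed_ligand(tmp_path, peptide_pdb, "CO")         # methanol, with Hs
    hs = [a for a in cplx.ligand_atoms if a.element == "H"]
    polar = [a for a in hs if "hbd" in a.flags]
    assert len(polar) == 1                                   # only the O-H
    o = [a for a in cplx.ligand_atoms if a.element == "O"][0]
    assert "hbd" in o.flags and "hba" in o.flags


def test_protein_typing_from_residue_templates(peptide_pdb, tmp_path):
    sdf = tmp_path / "benzene.sdf"
    write_benzene_sdf(sdf)
    cplx = assign_atom_types(read_complex(peptide_pdb, sdf))
    by_key = {(a.residue_name, a.atom_name): a for a in cplx.protein_atoms}
    assert "aromatic" in by_key[("PHE", "CZ")].flags
    assert "aromatic" not in by_key[("ALA", "CB")].flags
    assert "hydrophobic" in by_key[("ALA", "CB")].flags
    assert "positive" in by_key[("LYS", "NZ")].flags
    assert "negative" in by_key[("ASP", "OD1")].flags
    assert "hba" in by_key[("ASP", "OD1")].flags
    assert "hbd" in by_key[("ALA", "N")].flags               # backbone amide
    zn = by_key[("ZN", "ZN")]
    assert zn.flags == frozenset({"metallic", "excluded_volume"})


def test_every_atom_has_excluded_volume_and_valid_flags(peptide_pdb, tmp_path):
    sdf = tmp_path / "lig.sdf"
    write_sdf_from_smiles(sdf, "c1ccccc1C(=O)[O-]")
    cplx = assign_atom_types(read_complex(peptide_pdb, sdf))
    for a in cplx.atoms:
        a.validate()
        assert "excluded_volume" in a.flags


def test_assign_atom_types_is_idempotent(peptide_pdb, tmp_path):
    sdf = tmp_path / "lig.sdf"
    write_sdf_from_smiles(sdf, "c1ccccc1O")
    once = assign_atom_types(read_complex(peptide_pdb, sdf))
    twice = assign_atom_types(once)
    for a, b in zip(once.atoms, twice.atoms):
        assert a.flags == b.flags
        assert a.charge_sign == b.charge_sign


# ---------------------------------------------------------------------------
# refined-set filter

def meta(resolution=2.0, affinity_type="Kd", covalent=False,
         stoichiometry=(1, 1), elements=("C", "N", "O")):
    return ComplexMetadata(resolution=resolution, affinity_type=affinity_type,
                           covalent=covalent, stoichiometry=stoichiometry,
                           ligand_elements=frozenset(elements))


def test_boundary_resolution_is_accepted():
    res = filter_refined([("ok", meta(resolution=2.5))])
    assert res.accepted == ["ok"]


def test_resolution_just_over_the_limit_is_rejected():
    res = filter_refined([("bad", meta(resolution=2.6))])
    assert "resolution" in res.rejections["bad"]


def test_ic50_affinity_is_rejected():
    res = filter_refined([("bad", meta(affinity_type="IC50"))])
    assert "affinity type" in res.rejections["bad"]


def test_covalent_and_stoichiometry_and_elements():
    res = filter_refined([
        ("cov", meta(covalent=True)),
        ("sto", meta(stoichiometry=(2, 1))),
        ("ele", meta(elements=("C", "Si"))),
    ])
    assert res.accepted == []
    assert "covalent" in res.rejections["cov"]
    assert "stoichiometry" in res.rejections["sto"]
    assert "Si" in res.rejections["ele"]


def test_missing_metadata_raises_not_silently_passes():
    with pytest.raises(ValueError):
        filter_refined([("x", ComplexMetadata(resolution=2.0))])


def test_toy_table_partition_matches_predicate_oracle():
    flt = RefinedSetFilter()
    # ten records, three violating one condition each
    records = [
        ("r0", meta()),
        ("r1", meta(resolution=3.0)),
        ("r2", meta(affinity_type="IC50")),
        ("r3", meta(affinity_type="Ki")),
        ("r4", meta()),
        ("r5", meta(stoichiometry=(1, 1))),
        ("r6", meta()),
        ("r7", meta()),
        ("r8", meta(elements=("C", "B"))),
        ("r9", meta()),
    ]
    res = filter_refined(records, flt)

    def oracle(m):
        return (m.resolution <= 2.5 and m.affinity_type in ("Ki", "Kd")
                and not m.covalent and tuple(m.stoichiometry) == (1, 1)
                and set(m.ligand_elements) <= set(flt.allowed_elements))

    expected = [cid for cid, m in records if oracle(m)]
    assert res.accepted == expected
    assert len(res.accepted) == 7
    # accepted + rejected partition the input
    assert sorted(res.accepted + list(res.rejections)) == sorted(
        cid for cid, _ in records)


def test_filter_accepts_molecular_complexes_too():
    cplx = MolecularComplex("c1", metadata=meta())
    res = filter_refined([cplx])
    assert res.accepted == ["c1"]
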