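"""Density function, voxelization oracle, and cube-rotation properties."""

import numpy as np
import pytest

from akscore.atoms import MolecularComplex, TypedAtom, atomic_mass
from akscore.voxel import (CHANNEL_LABELS, GridSpec, VoxelGrid, cube_rotations,
                           density, load_grid_archive, rotate_grid,
                           rotations24, save_grid_archive, voxelize)


def make_atom(pos, element="C", role="ligand", flags=("excluded_volume",)):
    return TypedAtom(element=element, position=np.asarray(pos, float),
                     role=role, flags=frozenset(flags))


# ---------------------------------------------------------------------------
# density function

def test_density_limit_at_zero_distance():
    assert density(0.0, 1.7) == 1.0


def test_density_at_vdw_radius():
    assert density(2.0, 2.0) == pytest.approx(1 - np.exp(-1), rel=1e-12)


def test_density_at_twice_vdw_radius():
    assert density(4.0, 2.0) == pytest.approx(1 - np.exp(-2.0 ** -12), rel=1e-6)
    assert density(4.0, 2.0) == pytest.approx(2.4411e-4, rel=1e-3)


def test_density_strictly_decreasing_and_bounded():
    r = np.linspace(0.01, 12, 500)
    d = density(r, 1.9)
    assert np.all(np.diff(d) <= 0)
    # strictly decreasing between the float saturation plateaus at 1 and 0
    interior = (d[:-1] < 1.0) & (d[:-1] > 1e-12)
    assert np.all(np.diff(d)[interior] < 0)
    assert np.all((d >= 0) & (d <= 1))


def test_density_far_field_negligible():
    # an atom at >= 5 A + r_vdw contributes below 1e-3
    assert density(5.0 + 1.9, 1.9) < 1e-3


def test_density_rejects_nonpositive_radius():
    with pytest.raises(ValueError):
        density(1.0, 0.0)
    with pytest.raises(ValueError):
        density(1.0, -2.0)


# ---------------------------------------------------------------------------
# voxelization

def naive_voxelize(cplx, spec=None):
    """Independent O(voxels x atoms) double loop over every voxel center."""
    spec = spec or GridSpec()
    com = cplx.ligand_center_of_mass()
    offs = spec.axis_offsets()
    n = spec.boxes_per_axis
    out = np.zeros((16, n, n, n))
    base = {"protein": 0, "ligand": 8}
    classes = ("hydrophobic", "aromatic", "hbd", "hba", "positive",
               "negative", "metallic", "excluded_volume")
    for atom in cplx.atoms:
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    center = com + np.array([offs[i], offs[j], offs[k]])
                    r = np.linalg.norm(center - atom.position)
                    d = density(r, atom.vdw_radius)
                    for cls in atom.flags:
                        out[base[atom.role] + classes.index(cls), i, j, k] += d
    return out


def test_empty_protein_leaves_protein_channels_zero():
    cplx = MolecularComplex("t", [], [make_atom([0.2, -0.3, 0.5])])
    grid = voxelize(cplx)
    assert np.all(grid.values[:8] == 0)
    assert grid.values[15].sum() > 0  # ligand excluded volume populated


def test_atom_exactly_at_voxel_center_saturates_that_voxel():
    # two carbons far apart; equal masses put the center of mass halfway,
    # so both atoms land exactly on voxel centers of the half-integer lattice
    cplx = MolecularComplex("t", [], [
        make_atom([0.0, 0.0, 0.0]), make_atom([7.0, 7.0, 7.0])])
    grid = voxelize(cplx)
    lig_ev = grid.channel("ligand_excluded_volume")
    # atom 1 sits at offset (-3.5, -3.5, -3.5) = index 11; atom 2 at index 18
    assert lig_ev[11, 11, 11] == pytest.approx(1.0, abs=1e-6)
    assert lig_ev[18, 18, 18] == pytest.approx(1.0, abs=1e-6)


def test_empty_ligand_is_an_error():
    cplx = MolecularComplex("t", [make_atom([0, 0, 0], role="protein")], [])
    with pytest.raises(ValueError):
        voxelize(cplx)


def test_matches_naive_double_loop_on_three_atoms():
    cplx = MolecularComplex("t", [
        make_atom([2.0, -1.0, 3.0], "N", "protein", ("hba", "excluded_volume")),
    ], [
        make_atom([0.5, 0.25, -0.75], "C", "ligand",
                  ("hydrophobic", "excluded_volume")),
        make_atom([-1.0, 1.5, 0.0], "O", "ligand", ("hba", "excluded_volume")),
    ])
    fast = voxelize(cplx, cutoff_margin=1e6).values  # no cutoff: exact
    slow = naive_voxelize(cplx)
    assert np.abs(fast - slow).max() < 1e-6


def test_cutoff_error_is_bounded():
    rng = np.random.default_rng(0)
    lig = [make_atom(rng.uniform(-3, 3, 3)) for _ in range(5)]
    cplx = MolecularComplex("t", [], lig)
    exact = voxelize(cplx, cutoff_margin=1e6).values
    cut = voxelize(cplx, cutoff_margin=5.0).values
    assert np.abs(exact - cut).max() < 1e-3


def test_translation_invariance():
    rng = np.random.default_rng(3)
    prot = [make_atom(rng.uniform(-8, 8, 3), "C", "protein",
                      ("hydrophobic", "excluded_volume")) for _ in range(10)]
    lig = [make_atom(rng.uniform(-3, 3, 3)) for _ in range(5)]
    cplx = MolecularComplex("t", prot, lig)
    shift = np.array([13.7, -5.1, 2.9])
    shifted = MolecularComplex(
        "t2",
        [make_atom(a.position + shift, a.element, "protein", tuple(a.flags))
         for a in prot],
        [make_atom(a.position + shift, a.element, "ligand", tuple(a.flags))
         for a in lig])
    assert np.allclose(voxelize(cplx).values, voxelize(shifted).values,
                       atol=1e-5)


def test_clamp_caps_summed_density():
    lig = [make_atom([0, 0, 0]), make_atom([0.3, 0, 0]), make_atom([0, 0.3, 0])]
    cplx = MolecularComplex("t", [], lig)
    raw = voxelize(cplx).values
    clamped = voxelize(cplx, clamp=True).values
    assert raw.max() > 1.0
    assert clamped.max() <= 1.0


# ---------------------------------------------------------------------------
# rotations

def test_rotation_set_is_the_proper_cube_group():
    mats = cube_rotations()
    assert len(mats) == 24
    keys = {m.tobytes() for m in mats}
    assert len(keys) == 24                       # pairwise distinct
    assert np.eye(3, dtype=int).tobytes() in keys  # contains identity
    for m in mats:
        assert round(np.linalg.det(m)) == 1      # proper rotations only
        assert (m @ m.T == np.eye(3, dtype=int)).all()
        for m2 in mats:                          # closed under composition
            assert (m @ m2).tobytes() in keys


def test_identity_rotation_preserves_grid(rng):
    g = rng.random((16, 30, 30, 30), dtype=np.float32)
    assert (rotate_grid(g, np.eye(3, dtype=int)) == g).all()


def test_rotations24_of_asymmetric_grid_are_distinct(rng):
    g = rng.random((16, 30, 30, 30), dtype=np.float32)
    outs = rotations24(g)
    assert len(outs) == 24
    assert len({o.tobytes() for o in outs}) == 24


def test_rotation_composition_matches_sequential_application(rng):
    g = rng.random((4, 6, 6, 6), dtype=np.float32)
    mats = cube_rotations()
    for a in mats[::5]:
        for b in mats[::7]:
            seq = rotate_grid(rotate_grid(g, b), a)
            once = rotate_grid(g, a @ b)
            assert (seq == once).all()


def test_rotation_equivariance_with_atom_rotation():
    """Rotating the atoms about the ligand COM == rotating the grid."""
    rng = np.random.default_rng(9)
    lig = [make_atom(rng.uniform(-3, 3, 3)) for _ in range(4)]
    prot = [make_atom(rng.uniform(-8, 8, 3), "O", "protein",
                      ("hba", "excluded_volume")) for _ in range(6)]
    cplx = MolecularComplex("t", prot, lig)
    base = voxelize(cplx)
    com = cplx.ligand_center_of_mass()
    for rot in cube_rotations()[::4]:
        rotated = MolecularComplex(
            "tr",
            [make_atom(rot @ (a.position - com) + com, a.element, "protein",
                       tuple(a.flags)) for a in prot],
            [make_atom(rot @ (a.position - com) + com, a.element, "ligand",
                       tuple(a.flags)) for a in lig])
        direct = voxelize(rotated).values
        via_grid = rotate_grid(base.values, rot)
        assert np.abs(direct - via_grid).max() < 1e-6


def test_rotations24_on_voxelgrid_returns_voxelgrids(rng):
    g = VoxelGrid(values=rng.random((16, 30, 30, 30), dtype=np.float32))
    outs = rotations24(g)
    assert all(isinstance(o, VoxelGrid) for o in outs)
    assert (outs[0].values == g.values).all()


# ---------------------------------------------------------------------------
# archive round trip

def test_grid_archive_round_trip(tmp_path, rng):
    grids = rng.random((3, 16, 30, 30, 30), dtype=np.float32)
    labels = np.array([-7.5, -9.1, -11.0])
    path = tmp_path / "grids.h5"
    save_grid_archive(path, grids, ids=["a", "b", "c"], labels_kcal=labels)
    g2, ids, lab2, spec = load_grid_archive(path)
    assert (g2 == grids).all()
    assert ids == ["a", "b", "c"]
    assert np.allclose(lab2, labels)
    assert spec == GridSpec()
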