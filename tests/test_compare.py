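"""Kabsch superposition, dihedrals, chi angles and per-residue deltas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import latticetrap as lt
from latticetrap.compare import chi_angles, wrap_angle
from latticetrap.errors import DegenerateGeometryError
from latticetrap.structure import UnitCell
from latticetrap.synthetic import (
    DEFAULT_CHI,
    FixtureSpec,
    build_peptide,
    make_form_pair,
    make_toy_crystal,
)

from conftest import make_structure


def _random_rigid(rng):
    rot = Rotation.random(rng=rng).as_matrix()
    tran = rng.uniform(-20, 20, size=3)
    return rot, tran


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------

def test_kabsch_identical_sets_zero_rmsd():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(10, 3))
    res = lt.kabsch_superpose(a, a)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.rotation, np.eye(3))


def test_kabsch_recovers_rigid_motion():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(12, 3)) * 5.0
    rot, tran = _random_rigid(rng)
    b = (a - tran) @ rot  # a = rot @ b + tran
    res = lt.kabsch_superpose(a, b)
    assert res.rmsd < 1e-9
    assert np.allclose(res.transform(b), a, atol=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


def test_kabsch_matches_independent_oracle():
    """Noisy 10-point pair: RMSD equals scipy's quaternion-based estimator
    to 1e-6 A and is a lower bound over random rotations."""
    rng = np.random.default_rng(2)
    a = rng.normal(size=(10, 3)) * 4.0
    rot, tran = _random_rigid(rng)
    b = (a @ rot.T + tran) + rng.normal(size=(10, 3)) * 0.3
    mine = lt.kabsch_superpose(a, b)

    ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    assert mine.rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-6)

    for _ in range(500):
        r = Rotation.random(rng=rng).as_matrix()
        trial = np.sqrt(((ac - bc @ r.T) ** 2).sum() / len(a))
        assert mine.rmsd <= trial + 1e-9


def test_kabsch_never_reflects():
    """A mirrored point set must still yield a proper rotation."""
    rng = np.random.default_rng(3)
    a = rng.normal(size=(8, 3))
    b = a.copy()
    b[:, 0] = -b[:, 0]
    res = lt.kabsch_superpose(a, b)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)
    assert res.rmsd > 0.1


def test_kabsch_input_validation():
    a = np.zeros((4, 3))
    with pytest.raises(ValueError, match="matched"):
        lt.kabsch_superpose(a, np.zeros((5, 3)))
    with pytest.raises(ValueError, match="3 points"):
        lt.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegenerateGeometryError):
        lt.kabsch_superpose(line, line)


def test_rmsd_symmetric_between_forms():
    rng = np.random.default_rng(4)
    a = rng.normal(size=(20, 3)) * 3.0
    b = a + rng.normal(size=(20, 3)) * 0.5
    assert lt.kabsch_superpose(a, b).rmsd == pytest.approx(
        lt.kabsch_superpose(b, a).rmsd, abs=1e-9)


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def test_dihedral_cis_is_zero():
    assert lt.dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]) == \
        pytest.approx(0.0, abs=1e-12)


def test_dihedral_trans_is_180():
    assert lt.dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]) == \
        pytest.approx(180.0)


def test_dihedral_sign_convention():
    """Looking down the p2->p3 axis, a counterclockwise far bond is
    negative: the standard right-handed convention."""
    plus = lt.dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 1])
    minus = lt.dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, -1])
    assert plus == pytest.approx(45.0)
    assert minus == pytest.approx(-45.0)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_dihedral_invariant_under_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(4, 3)) * 3.0
    try:
        base = lt.dihedral(*pts)
    except DegenerateGeometryError:
        return
    rot, tran = _random_rigid(rng)
    moved = pts @ rot.T + tran
    assert lt.dihedral(*moved) == pytest.approx(base, abs=1e-9)


def test_dihedral_degenerate_inputs_rejected():
    with pytest.raises(DegenerateGeometryError, match="coincident"):
        lt.dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
    with pytest.raises(DegenerateGeometryError, match="collinear"):
        lt.dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])


def test_chi_angles_match_build_targets():
    built = build_peptide(["ALA", "SER", "ARG", "HIS"])
    specs = [("A", seq, name, atom, atom[0], xyz)
             for name, seq, atoms in built for atom, xyz in atoms]
    st_ = make_structure(specs)
    assert chi_angles(st_.find_residue("A", 1)) == {}
    for seq, res_name in ((2, "SER"), (3, "ARG"), (4, "HIS")):
        got = chi_angles(st_.find_residue("A", seq))
        for idx, target in DEFAULT_CHI[res_name].items():
            assert wrap_angle(got[idx] - target) == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# per-residue deltas
# ---------------------------------------------------------------------------

def test_structure_vs_itself_all_zero():
    st_, _ = make_toy_crystal(FixtureSpec(seed=9))
    delta = lt.per_residue_delta(st_, st_)
    assert delta.superposition.rmsd == pytest.approx(0.0, abs=1e-12)
    for rd in delta.per_residue.values():
        assert rd.mainchain_rmsd == pytest.approx(0.0, abs=1e-12)
        if rd.sidechain_rmsd is not None:
            assert rd.sidechain_rmsd == pytest.approx(0.0, abs=1e-12)
        for _, d in rd.chi_deltas:
            assert d == pytest.approx(0.0, abs=1e-9)


def test_single_rotated_sidechain_localized_and_quantified():
    """Rotating one Ser chi1 by 70 degrees changes only that residue; the
    side-chain RMSD matches the chord-length prediction 2 r sin(d/2)."""
    spec = FixtureSpec(seed=9, engineered_moves=[(2, 1, 70.0)])
    fa, fb, _ = make_form_pair(spec)
    delta = lt.per_residue_delta(fa, fb)
    for key, rd in delta.per_residue.items():
        assert rd.mainchain_rmsd == pytest.approx(0.0, abs=1e-9)
        if key[1] != 2:
            if rd.sidechain_rmsd is not None:
                assert rd.sidechain_rmsd == pytest.approx(0.0, abs=1e-9)

    moved = delta.per_residue[("A", 2, "")]
    assert dict(moved.chi_deltas)[1] == pytest.approx(-70.0, abs=1e-6)

    # chord prediction from the unmoved form's geometry
    res = fa.find_residue("A", 2)
    ca, cb, og = (res.get_atom(n).xyz for n in ("CA", "CB", "OG"))
    axis = (cb - ca) / np.linalg.norm(cb - ca)
    arm = og - cb
    r_perp = np.linalg.norm(arm - np.dot(arm, axis) * axis)
    chord = 2.0 * r_perp * np.sin(np.radians(70.0 / 2.0))
    # SER side chain = {CB, OG}; CB sits on the axis and does not move
    assert moved.sidechain_rmsd == pytest.approx(chord / np.sqrt(2.0), abs=1e-3)
    assert moved.atom_displacements["OG"] == pytest.approx(chord, abs=1e-3)


def test_atom_displacement_by_construction():
    st_, _ = make_toy_crystal(FixtureSpec(seed=9))
    import copy
    moved = copy.deepcopy(st_)
    atom = moved.find_residue("A", 2).get_atom("OG")
    atom.xyz = atom.xyz + np.array([1.0, 0.0, 0.0])
    d = lt.atom_displacement(st_, moved, "A", 2, "OG")
    assert d == pytest.approx(1.0, abs=1e-9)
    assert lt.atom_displacement(st_, st_, "A", 2, "OG") == pytest.approx(0.0)


def test_atom_displacement_missing_atom_names_form():
    st_, _ = make_toy_crystal(FixtureSpec(seed=9))
    import copy
    stripped = copy.deepcopy(st_)
    res = stripped.find_residue("A", 2)
    res.atoms = [a for a in res.atoms if a.name != "OG"]
    with pytest.raises(KeyError, match="form_b"):
        lt.atom_displacement(st_, stripped, "A", 2, "OG")


def test_mismatched_atom_content_flagged_not_dropped():
    st_, _ = make_toy_crystal(FixtureSpec(seed=9))
    import copy
    partial = copy.deepcopy(st_)
    res = partial.find_residue("A", 3)
    res.atoms = [a for a in res.atoms if a.name not in ("NH1", "NH2")]
    delta = lt.per_residue_delta(st_, partial)
    rd = delta.per_residue[("A", 3, "")]
    assert any("atom-mismatch" in f for f in rd.flags)
    assert rd.mainchain_rmsd is not None


def test_global_rmsd_parts_and_chain_filter():
    spec = FixtureSpec(seed=9, engineered_moves=[(3, 2, 90.0)])
    fa, fb, _ = make_form_pair(spec)
    delta = lt.per_residue_delta(fa, fb)
    assert delta.global_rmsd("main_chain") == pytest.approx(0.0, abs=1e-9)
    assert delta.global_rmsd("side_chain") > 0.5
    assert delta.global_rmsd("all") < delta.global_rmsd("side_chain")
    with pytest.raises(ValueError):
        delta.global_rmsd("main_chain", chain="Z")


def test_disjoint_numbering_is_an_error():
    spec = FixtureSpec(seed=9)
    fa, _ = make_toy_crystal(spec)
    fb, _ = make_toy_crystal(FixtureSpec(seed=9, start_seq=100))
    with pytest.raises(ValueError, match="mapping"):
        lt.per_residue_delta(fa, fb)
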