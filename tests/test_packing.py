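"""Crystal contacts, nearest-mate distances and solvent-accessible surface."""

import numpy as np
import pytest

import latticetrap as lt
from latticetrap.packing import (
    BurialReport,
    contact_counts,
    element_radius,
    fibonacci_sphere,
    shrake_rupley,
)
from latticetrap.structure import UnitCell
from latticetrap.synthetic import brute_force_contacts, dense_sasa

from conftest import make_structure, single_atom_structure


def _contact_ids(contacts):
    return sorted((c.ref_atom_id(), c.mate_atom_id(), c.symop,
                   c.lattice_translation,
                   round(c.distance, 9)) for c in contacts)


def _oracle_ids(oracle, structure):
    out = []
    for c in oracle:
        out.append(((("A", c["ref_seq"], "", c["ref_atom"], "")),
                    (("A", c["mate_seq"], "", c["mate_atom"], "")),
                    c["symop"], tuple(c["translation"]),
                    round(c["distance"], 9)))
    return sorted(out)


def test_isolated_atom_no_contacts():
    assert lt.find_crystal_contacts(single_atom_structure()) == []


def test_single_atom_tight_cubic_cell_has_six_contacts():
    """One atom in a 3 A cubic P1 cell at 3.5 A cutoff touches the six
    face-adjacent images (+/-a, +/-b, +/-c), each counted once."""
    st = single_atom_structure(cell=UnitCell(3.0, 3.0, 3.0))
    contacts = lt.find_crystal_contacts(st, cutoff=3.5)
    assert len(contacts) == 6
    translations = sorted(c.lattice_translation for c in contacts)
    assert translations == sorted([(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)])
    assert all(c.distance == pytest.approx(3.0) for c in contacts)


@pytest.mark.parametrize("toy", ["p21_toy", "p3121_toy"])
def test_contacts_match_brute_force(toy, request):
    structure, _ = request.getfixturevalue(toy)
    contacts = lt.find_crystal_contacts(structure, cutoff=3.5)
    oracle = brute_force_contacts(structure, cutoff=3.5)
    assert _contact_ids(contacts) == _oracle_ids(oracle, structure)


def test_contact_set_closed_under_frame_swap(p21_toy):
    """Viewing each contact from the mate's frame gives a contact already in
    the set: the unordered pair relation is symmetric."""
    structure, _ = p21_toy
    from latticetrap.packing import _image_key, _inverse_image
    ops = structure.space_group.operators
    contacts = lt.find_crystal_contacts(structure, cutoff=3.5)
    ids = {(c.ref_atom_id(), c.mate_atom_id(), _image_key(ops, c.symop,
                                                          c.lattice_translation))
           for c in contacts}
    for ref_id, mate_id, (p, n) in ids:
        q, n_inv = _inverse_image(ops, p, n)
        assert (mate_id, ref_id, (q, n_inv)) in ids


def test_contact_count_monotone_in_cutoff(p21_toy):
    structure, _ = p21_toy
    counts = [len(lt.find_crystal_contacts(structure, cutoff=c))
              for c in (2.5, 3.0, 3.5, 4.0)]
    assert counts == sorted(counts)


def test_contacts_sorted_by_residue_then_distance(p21_toy):
    structure, _ = p21_toy
    res_order = {r.key: i for i, r in enumerate(structure.residues)}
    contacts = lt.find_crystal_contacts(structure, cutoff=4.0)
    keys = [(res_order[c.ref_residue_key], c.distance) for c in contacts]
    assert keys == sorted(keys)


def test_contact_counts_conventions(p21_toy):
    structure, _ = p21_toy
    contacts = lt.find_crystal_contacts(structure, cutoff=3.5)
    counts = contact_counts(contacts, structure)
    assert counts["atom_image_pairs"] == len(contacts)
    assert counts["unique_molecule_pairs"] <= counts["atom_image_pairs"]
    assert counts["ref_atoms"] <= counts["atom_image_pairs"]
    assert counts["ref_residues"] <= counts["ref_atoms"]


def test_cutoff_validation(p21_toy):
    structure, _ = p21_toy
    with pytest.raises(ValueError):
        lt.find_crystal_contacts(structure, cutoff=0.0)


# ---------------------------------------------------------------------------
# nearest-mate distance
# ---------------------------------------------------------------------------

def test_nearest_mate_none_in_huge_cell():
    st = single_atom_structure()
    assert lt.nearest_mate_distance(st, "A", 1) is None


def test_nearest_mate_engineered_distance():
    """A single atom in a P1 cell with a = 2.8 A: nearest image at 2.8 A."""
    st = single_atom_structure(cell=UnitCell(2.8, 50.0, 50.0))
    d = lt.nearest_mate_distance(st, "A", 1)
    assert d == pytest.approx(2.8, abs=1e-9)


def test_nearest_mate_matches_brute_force(p21_toy):
    structure, _ = p21_toy
    oracle = brute_force_contacts(structure, cutoff=8.0)
    for res in structure.residues:
        want = min((c["distance"] for c in oracle
                    if c["ref_seq"] == res.seq_number), default=None)
        got = lt.nearest_mate_distance(structure, "A", res.seq_number)
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want, abs=1e-9)


def test_nearest_mate_missing_residue_named():
    st = single_atom_structure()
    with pytest.raises(KeyError, match="A/99"):
        lt.nearest_mate_distance(st, "A", 99)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_fibonacci_sphere_unit_and_deterministic():
    pts = fibonacci_sphere(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.allclose(pts, fibonacci_sphere(960))
    # near-uniform: centroid close to the origin
    assert np.linalg.norm(pts.mean(axis=0)) < 1e-3


def test_sasa_lone_atom_is_analytic_sphere():
    """r = 1.7, probe = 1.4: area = 4 pi (3.1)^2 within 0.5% quadrature."""
    area = shrake_rupley(np.zeros((1, 3)), np.array([1.7]), probe=1.4,
                         n_points=960)
    analytic = 4.0 * np.pi * 3.1 ** 2
    assert abs(area[0] - analytic) / analytic < 0.005


def test_sasa_distant_pair_not_occluded():
    coords = np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
    areas = shrake_rupley(coords, np.array([1.7, 1.7]), probe=1.4)
    full = 4.0 * np.pi * 3.1 ** 2
    assert np.allclose(areas, full, rtol=1e-9)


def test_sasa_cluster_matches_dense_grid_oracle():
    rng = np.random.default_rng(11)
    coords = rng.uniform(0.0, 4.0, size=(5, 3))
    radii = np.full(5, 1.7)
    fast = shrake_rupley(coords, radii, n_points=960)
    dense = dense_sasa(coords, radii, n_points=200_000, seed=99)
    total_err = abs(fast.sum() - dense.sum()) / dense.sum()
    assert total_err < 0.02
    scale = 4.0 * np.pi * 3.1 ** 2
    assert np.all(np.abs(fast - dense) / scale < 0.02)


def test_sasa_minimum_points_enforced():
    with pytest.raises(ValueError, match="92"):
        shrake_rupley(np.zeros((1, 3)), np.array([1.7]), n_points=50)


def test_unknown_element_radius_is_reported():
    with pytest.raises(KeyError, match="XX"):
        element_radius("XX")


# ---------------------------------------------------------------------------
# lattice burial
# ---------------------------------------------------------------------------

def test_buried_zero_for_isolated_molecule():
    report = lt.buried_lattice_area(single_atom_structure())
    assert report.buried_total == 0.0
    assert "no symmetry mates" in report.notice


def test_buried_equals_spherical_cap_for_touching_pair():
    """One occluding sphere at distance d buries the cap 2 pi R h with
    h = R - d/2 (equal radii)."""
    r, probe, d = 1.7, 1.4, 2.0
    big_r = r + probe
    area = shrake_rupley(np.zeros((1, 3)), np.array([r]), probe=probe,
                         n_points=4000,
                         occluder_coords=np.array([[d, 0.0, 0.0]]),
                         occluder_radii=np.array([r]))
    buried = 4.0 * np.pi * big_r ** 2 - area[0]
    cap = 2.0 * np.pi * big_r * (big_r - d / 2.0)
    assert abs(buried - cap) / cap < 0.02


def test_buried_monotone_in_occluders():
    rng = np.random.default_rng(4)
    coords = rng.uniform(0, 5, size=(4, 3))
    radii = np.full(4, 1.7)
    occ = np.array([[6.0, 0.0, 0.0], [0.0, 6.0, 0.0]])
    occ_r = np.array([1.7, 1.7])
    a_none = shrake_rupley(coords, radii)
    a_one = shrake_rupley(coords, radii, occluder_coords=occ[:1],
                          occluder_radii=occ_r[:1])
    a_two = shrake_rupley(coords, radii, occluder_coords=occ,
                          occluder_radii=occ_r)
    assert np.all(a_one <= a_none + 1e-12)
    assert np.all(a_two <= a_one + 1e-12)


@pytest.mark.parametrize("toy", ["p21_toy", "p3121_toy"])
def test_buried_lattice_area_matches_dense_oracle(toy, request):
    structure, manifest = request.getfixturevalue(toy)
    report = lt.buried_lattice_area(structure)
    assert isinstance(report, BurialReport)
    assert np.all(report.sasa_in_lattice <= report.sasa_isolated + 1e-9)
    oracle = manifest["buried_area_oracle"]
    if oracle > 0:
        assert abs(report.buried_total - oracle) / oracle < 0.02
    per_res = report.per_residue_buried
    assert sum(per_res.values()) == pytest.approx(report.buried_total)
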