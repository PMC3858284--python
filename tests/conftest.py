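import numpy as np
import pytest

from latticetrap.structure import (
    AtomRecord,
    CrystalStructure,
    ResidueRecord,
    SpaceGroupInfo,
    UnitCell,
)


def make_structure(atom_specs, cell=None, space_group="P 1"):
    """Build a structure from (chain, seq, resname, atomname, element, xyz,
    [altloc, occupancy, b_iso, u]) tuples."""
    cell = cell or UnitCell(100.0, 100.0, 100.0)
    residues = {}
    serial = 0
    for spec in atom_specs:
        chain, seq, resname, atomname, element, xyz = spec[:6]
        extra = spec[6] if len(spec) > 6 else {}
        key = (chain, seq)
        if key not in residues:
            residues[key] = ResidueRecord(chain_id=chain, seq_number=seq,
                                          res_name=resname)
        serial += 1
        residues[key].atoms.append(AtomRecord(
            serial=serial, name=atomname, element=element,
            xyz=np.asarray(xyz, dtype=float),
            altloc=extra.get("altloc", ""),
            occupancy=extra.get("occupancy", 1.0),
            b_iso=extra.get("b_iso", 10.0),
            u=extra.get("u"),
        ))
    return CrystalStructure(cell=cell,
                            space_group=SpaceGroupInfo.from_symbol(space_group),
                            residues=list(residues.values()))


def single_atom_structure(cell=None, space_group="P 1", frac=(0.5, 0.5, 0.5),
                          element="C", name="CA", resname="ALA"):
    cell = cell or UnitCell(100.0, 100.0, 100.0)
    from latticetrap.symmetry import frac_to_cart
    xyz = frac_to_cart(cell, np.asarray(frac, dtype=float))
    return make_structure([("A", 1, resname, name, element, xyz)],
                          cell=cell, space_group=space_group)


@pytest.fixture
def p21_toy():
    """A P2(1) toy crystal tight enough to have symmetry contacts."""
    from latticetrap.synthetic import FixtureSpec, make_toy_crystal
    spec = FixtureSpec(space_group="P 1 21 1",
                       cell=UnitCell(16.0, 17.0, 18.0, 90, 100, 90), seed=3)
    structure, manifest = make_toy_crystal(spec)
    return structure, manifest


@pytest.fixture
def p3121_toy():
    from latticetrap.synthetic import FixtureSpec, make_toy_crystal
    spec = FixtureSpec(space_group="P 31 2 1",
                       cell=UnitCell(26.0, 26.0, 30.0, 90, 90, 120),
                       frac_center=(0.3, 0.62, 0.15), seed=3)
    structure, manifest = make_toy_crystal(spec)
    return structure, manifest
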