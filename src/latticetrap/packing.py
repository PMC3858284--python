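"""Crystal-packing analysis: contacts, nearest-mate distances, buried SASA.

Contact convention
------------------
A *crystal contact* is a pair (reference atom, symmetry-mate image atom)
closer than the cutoff (default 3.5 A).  Contacts are counted per reference
molecule: the images at +a and -a of the same neighbour molecule both count,
which is the convention under which a single atom in a tight cubic P1 cell
has six contacts.  Because the literature rarely defines the counting unit,
:func:`contact_counts` also reports the alternative units (unique unordered
molecule-pair contacts, distinct reference atoms, distinct reference
residues, residue pairs) so printed numbers can be matched under whichever
convention produced them.

Surface areas use an in-package Shrake-Rupley implementation: deterministic
Fibonacci-lattice sphere points (no randomness), probe radius 1.4 A by
default, and a documented van der Waals radius set (Bondi).  Parity with any
particular external accessibility program is therefore approximate (a few
percent), not exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomSite, CrystalStructure, coordinates, select_atoms
from .symmetry import LatticeNeighborhood, SymOp, generate_lattice_neighbors

#: Bondi van der Waals radii (A) by element symbol.
VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39, "FE": 1.63,
    "MN": 1.60, "CU": 1.40,
}


def element_radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise KeyError(
            f"no van der Waals radius for element {element!r}; known elements: "
            + ", ".join(sorted(VDW_RADII))
        ) from None


@dataclass(frozen=True)
class ContactPair:
    """One reference-atom / mate-image-atom contact."""

    ref_chain: str
    ref_seq: int
    ref_icode: str
    ref_resname: str
    ref_atom: str
    ref_altloc: str
    mate_chain: str
    mate_seq: int
    mate_icode: str
    mate_resname: str
    mate_atom: str
    mate_altloc: str
    symop: str
    lattice_translation: tuple[int, int, int]
    distance: float

    @property
    def ref_residue_key(self) -> tuple[str, int, str]:
        return (self.ref_chain, self.ref_seq, self.ref_icode)

    @property
    def mate_residue_key(self) -> tuple[str, int, str]:
        return (self.mate_chain, self.mate_seq, self.mate_icode)

    def ref_atom_id(self) -> tuple:
        return (self.ref_chain, self.ref_seq, self.ref_icode,
                self.ref_atom, self.ref_altloc)

    def mate_atom_id(self) -> tuple:
        return (self.mate_chain, self.mate_seq, self.mate_icode,
                self.mate_atom, self.mate_altloc)


def find_crystal_contacts(
    structure: CrystalStructure,
    cutoff: float = 3.5,
    include_het: bool = False,
    include_hydrogens: bool = False,
    altloc: str = "highest",
    neighborhood: LatticeNeighborhood | None = None,
) -> list[ContactPair]:
    """All atom contacts to symmetry mates below ``cutoff``, sorted by
    (reference residue order, distance)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if neighborhood is None:
        neighborhood = generate_lattice_neighbors(
            structure, cutoff, include_het=include_het,
            include_hydrogens=include_hydrogens, altloc=altloc)
    sites = neighborhood.sites
    ref = neighborhood.ref_coords
    tree = cKDTree(ref)
    res_order = {res.key: idx for idx, res in enumerate(structure.residues)}

    contacts: list[ContactPair] = []
    for mate in neighborhood.mates:
        pairs = tree.query_ball_point(mate.coords, cutoff)
        for j, ref_indices in enumerate(pairs):
            for i in ref_indices:
                d = float(np.linalg.norm(ref[i] - mate.coords[j]))
                ri, ai = sites[i]
                rj, aj = sites[j]
                contacts.append(ContactPair(
                    ref_chain=ri.chain_id, ref_seq=ri.seq_number,
                    ref_icode=ri.insertion_code, ref_resname=ri.res_name,
                    ref_atom=ai.name, ref_altloc=ai.altloc,
                    mate_chain=rj.chain_id, mate_seq=rj.seq_number,
                    mate_icode=rj.insertion_code, mate_resname=rj.res_name,
                    mate_atom=aj.name, mate_altloc=aj.altloc,
                    symop=mate.op.triplet(),
                    lattice_translation=mate.lattice_translation,
                    distance=d,
                ))
    contacts.sort(key=lambda c: (res_order[c.ref_residue_key], c.distance,
                                 c.ref_atom, c.symop, c.lattice_translation,
                                 c.mate_atom))
    return contacts


def _image_key(ops: Sequence[SymOp], symop_triplet: str,
               translation: tuple[int, int, int]) -> tuple[int, tuple[int, int, int]]:
    for idx, op in enumerate(ops):
        if op.triplet() == symop_triplet:
            return idx, translation
    raise ValueError(f"operator {symop_triplet!r} not in space group")


def _inverse_image(ops: Sequence[SymOp], op_index: int,
                   translation: tuple[int, int, int]
                   ) -> tuple[int, tuple[int, int, int]]:
    """Image (q, n') such that applying it to a mate frame recovers the
    reference: the inverse of (ops[op_index], translation)."""
    op = ops[op_index]
    rinv = np.linalg.inv(op.rotation)
    v = op.translation + np.array(translation, dtype=float)
    v_inv = -rinv @ v
    for q, cand in enumerate(ops):
        if np.allclose(cand.rotation, rinv, atol=1e-9):
            n = v_inv - cand.translation
            n_int = np.rint(n).astype(int)
            if np.allclose(n, n_int, atol=1e-6):
                return q, tuple(int(x) for x in n_int)
    raise ValueError("operator set not closed under inversion")


def contact_counts(contacts: Sequence[ContactPair],
                   structure: CrystalStructure) -> dict[str, int]:
    """Contact totals under several counting conventions.

    ``atom_image_pairs`` is the headline per-reference-molecule count;
    ``unique_molecule_pairs`` collapses each contact with its mirror image
    seen from the mate's frame; the residue/atom level counts support
    matching published numbers whose unit was not stated.
    """
    ops = structure.space_group.operators
    unique: set = set()
    for c in contacts:
        p, n = _image_key(ops, c.symop, c.lattice_translation)
        q, n_inv = _inverse_image(ops, p, n)
        a = (p, n, c.ref_atom_id())
        b = (q, n_inv, c.mate_atom_id())
        unique.add(min(a, b))
    return {
        "atom_image_pairs": len(contacts),
        "unique_molecule_pairs": len(unique),
        "ref_atoms": len({c.ref_atom_id() for c in contacts}),
        "ref_residues": len({c.ref_residue_key for c in contacts}),
        "residue_pairs": len({(c.ref_residue_key, c.symop,
                               c.lattice_translation, c.mate_residue_key)
                              for c in contacts}),
    }


def nearest_mate_distance(
    structure: CrystalStructure,
    chain_id: str,
    seq_number: int,
    insertion_code: str = "",
    search_radius: float = 8.0,
    include_het: bool = False,
    altloc: str = "highest",
    neighborhood: LatticeNeighborhood | None = None,
) -> float | None:
    """Minimum distance from any atom of a residue to any symmetry-mate atom,
    or None when nothing lies within ``search_radius``."""
    residue = structure.find_residue(chain_id, seq_number, insertion_code)
    if neighborhood is None:
        neighborhood = generate_lattice_neighbors(
            structure, search_radius, include_het=include_het, altloc=altloc)
    mate_coords = neighborhood.all_mate_coords()
    if mate_coords.shape[0] == 0:
        return None
    res_coords = np.array([a.xyz for a in residue.atoms if not a.is_hydrogen])
    if res_coords.size == 0:
        return None
    tree = cKDTree(mate_coords)
    d, _ = tree.query(res_coords, k=1)
    dmin = float(np.min(d))
    return dmin if dmin <= search_radius else None


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
    occluder_coords: np.ndarray | None = None,
    occluder_radii: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible area (A^2) by sphere-point sampling.

    ``occluder_*`` atoms block surface but are not themselves reported --
    used for lattice burial, where the occluders are symmetry-mate atoms.
    Deterministic for a fixed ``n_points``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.shape[0] != radii.shape[0]:
        raise ValueError("coords and radii length mismatch")
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    if occluder_coords is None:
        occluder_coords = np.empty((0, 3))
        occluder_radii = np.empty((0,))
    occluder_coords = np.asarray(occluder_coords, dtype=float).reshape(-1, 3)
    occluder_radii = np.asarray(occluder_radii, dtype=float)

    all_coords = np.vstack([coords, occluder_coords])
    all_radii = np.concatenate([radii, occluder_radii])
    n = coords.shape[0]
    pts = fibonacci_sphere(n_points)
    tree = cKDTree(all_coords)
    rmax = float(all_radii.max(initial=0.0))
    areas = np.empty(n)
    for i in range(n):
        ri = radii[i] + probe
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + rmax + probe)
                     if j != i]
        sphere = coords[i] + ri * pts
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((sphere[:, None, :] - all_coords[nb][None, :, :]) ** 2).sum(axis=2)
            cut2 = (all_radii[nb] + probe) ** 2
            accessible = ~np.any(d2 < cut2[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ri * ri * frac
    return areas


def sasa(
    sites: Sequence[AtomSite],
    probe: float = 1.4,
    n_points: int = 960,
    occluder_sites: Sequence[AtomSite] | None = None,
    occluder_coords: np.ndarray | None = None,
    occluder_radii: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA for a list of atom sites; radii assigned by element."""
    coords = coordinates(sites)
    radii = np.array([element_radius(s.atom.element) for s in sites])
    if occluder_sites is not None:
        occluder_coords = coordinates(occluder_sites)
        occluder_radii = np.array([element_radius(s.atom.element)
                                   for s in occluder_sites])
    return shrake_rupley(coords, radii, probe=probe, n_points=n_points,
                         occluder_coords=occluder_coords,
                         occluder_radii=occluder_radii)


# ---------------------------------------------------------------------------
# lattice burial
# ---------------------------------------------------------------------------

@dataclass
class BurialReport:
    """Surface area lost to the crystal lattice."""

    sites: list[AtomSite]
    sasa_isolated: np.ndarray     # per-atom, molecule alone (A^2)
    sasa_in_lattice: np.ndarray   # per-atom, with symmetry mates present
    notice: str = ""

    @property
    def buried_per_atom(self) -> np.ndarray:
        return self.sasa_isolated - self.sasa_in_lattice

    @property
    def buried_total(self) -> float:
        return float(self.buried_per_atom.sum())

    @property
    def per_residue_buried(self) -> dict[tuple[str, int, str], float]:
        out: dict[tuple[str, int, str], float] = {}
        for site, b in zip(self.sites, self.buried_per_atom):
            key = site.residue.key
            out[key] = out.get(key, 0.0) + float(b)
        return out


def buried_lattice_area(
    structure: CrystalStructure,
    probe: float = 1.4,
    n_points: int = 960,
    include_het: bool = False,
    altloc: str = "highest",
) -> BurialReport:
    """SASA buried by symmetry-related molecules.

    buried = SASA(reference alone) - SASA(reference among all mate atoms
    within occlusion range).  An atom can only be occluded by atoms within
    ``2 * (r_max + probe)``, so the lattice neighborhood is generated at
    that radius.
    """
    sites = select_atoms(structure, polymer_only=not include_het, altloc=altloc)
    radii = np.array([element_radius(s.atom.element) for s in sites])
    reach = 2.0 * (float(radii.max()) + probe)
    neighborhood = generate_lattice_neighbors(
        structure, reach, include_het=include_het, altloc=altloc)

    ref = coordinates(sites)
    iso = shrake_rupley(ref, radii, probe=probe, n_points=n_points)
    mate_coords = neighborhood.all_mate_coords()
    notice = ""
    if mate_coords.shape[0] == 0:
        lat = iso.copy()
        notice = "no symmetry mates within occlusion range; buried area is 0"
    else:
        # keep only mate atoms that can actually occlude anything
        tree = cKDTree(ref)
        d, _ = tree.query(mate_coords, k=1)
        keep = d <= reach
        mate_radii = np.tile(radii, len(neighborhood.mates))[keep]
        lat = shrake_rupley(ref, radii, probe=probe, n_points=n_points,
                            occluder_coords=mate_coords[keep],
                            occluder_radii=mate_radii)
    return BurialReport(sites=sites, sasa_isolated=iso, sasa_in_lattice=lat,
                        notice=notice)
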