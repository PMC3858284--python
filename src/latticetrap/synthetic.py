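"""Toy crystal structures with known ground truth.

The generator builds an ideal-geometry peptide (Ala/Ser/Arg/His/Gly), places
it in a chosen unit cell and space group with a seeded rigid motion, assigns
per-atom anisotropic U tensors with prescribed anisotropy A and isotropic
B_eq, and optionally engineers alternate conformers and chi-angle changes
between a pair of forms.  Every quantity the analysis modules later measure
is recorded (or recomputable) independently:

* crystal contacts by an all-pairs brute-force scan over operators and
  lattice translations (:func:`brute_force_contacts`),
* buried surface by a dense random-direction sampling oracle
  (:func:`dense_sasa`), independent of the production Fibonacci quadrature,
* anisotropy exactly as assigned, chi angles exactly as built.

All randomness flows from the single integer seed of the spec; the same
seed writes byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .adp import b_eq as adp_b_eq
from .structure import (
    AtomRecord,
    CrystalStructure,
    ResidueRecord,
    SpaceGroupInfo,
    UnitCell,
    coordinates,
    select_atoms,
    write_structure,
)
from .symmetry import cart_to_frac, frac_to_cart

_EIGHT_PI_SQ = 8.0 * math.pi ** 2

# ideal internal coordinates: (bond to parent, angle, torsion reference)
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0

#: atoms rotated by each chi angle (distal to the chi bond), per residue type
CHI_DISTAL: dict[str, dict[int, list[str]]] = {
    "SER": {1: ["OG"]},
    "ARG": {1: ["CG", "CD", "NE", "CZ", "NH1", "NH2"],
            2: ["CD", "NE", "CZ", "NH1", "NH2"],
            3: ["NE", "CZ", "NH1", "NH2"],
            4: ["CZ", "NH1", "NH2"]},
    "HIS": {1: ["CG", "ND1", "CD2", "CE1", "NE2"],
            2: ["ND1", "CD2", "CE1", "NE2"]},
}

#: default chi targets used when the spec does not override them
DEFAULT_CHI: dict[str, dict[int, float]] = {
    "SER": {1: -65.0},
    "ARG": {1: -60.0, 2: 180.0, 3: 65.0, 4: 85.0},
    "HIS": {1: -60.0, 2: -75.0},
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees); the NeRF construction."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang, tor = math.radians(angle), math.radians(torsion)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        bond * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _element_of(atom_name: str) -> str:
    for sym in ("CL",):  # two-letter elements that could be confused
        if atom_name.upper().startswith(sym):
            return sym
    return atom_name[0].upper()


def _build_sidechain(res_name: str, n: np.ndarray, ca: np.ndarray,
                     c: np.ndarray, chi: dict[int, float]) -> list[tuple[str, np.ndarray]]:
    """Side-chain atoms (name, xyz) for one residue with given chi targets."""
    if res_name == "GLY":
        return []
    cb = place_atom(c, n, ca, 1.530, 110.5, -122.6)
    atoms = [("CB", cb)]
    if res_name == "ALA":
        return atoms
    if res_name == "SER":
        og = place_atom(n, ca, cb, 1.417, 110.8, chi[1])
        atoms.append(("OG", og))
    elif res_name == "ARG":
        cg = place_atom(n, ca, cb, 1.520, 114.1, chi[1])
        cd = place_atom(ca, cb, cg, 1.520, 111.3, chi[2])
        ne = place_atom(cb, cg, cd, 1.460, 112.0, chi[3])
        cz = place_atom(cg, cd, ne, 1.330, 124.2, chi[4])
        nh1 = place_atom(cd, ne, cz, 1.330, 120.0, 0.0)
        nh2 = place_atom(cd, ne, cz, 1.330, 120.0, 180.0)
        atoms += [("CG", cg), ("CD", cd), ("NE", ne), ("CZ", cz),
                  ("NH1", nh1), ("NH2", nh2)]
    elif res_name == "HIS":
        cg = place_atom(n, ca, cb, 1.490, 113.8, chi[1])
        nd1 = place_atom(ca, cb, cg, 1.380, 122.7, chi[2])
        cd2 = place_atom(ca, cb, cg, 1.350, 131.1, chi[2] + 180.0)
        ce1 = place_atom(cb, cg, nd1, 1.320, 109.3, 180.0)
        ne2 = place_atom(cg, nd1, ce1, 1.320, 111.7, 0.0)
        atoms += [("CG", cg), ("ND1", nd1), ("CD2", cd2), ("CE1", ce1),
                  ("NE2", ne2)]
    else:
        raise ValueError(f"unsupported residue type {res_name!r}; the toy "
                         "builder knows GLY, ALA, SER, ARG, HIS")
    return atoms


def build_peptide(sequence: list[str],
                  chi_targets: dict[int, dict[int, float]] | None = None,
                  start_seq: int = 1) -> list[tuple[str, int, list[tuple[str, np.ndarray]]]]:
    """Ideal alpha-helical peptide.

    Returns one entry per residue: (res_name, seq_number, [(atom, xyz), ...]).
    ``chi_targets`` maps seq_number -> {chi index -> degrees}; defaults per
    residue type are used otherwise.
    """
    chi_targets = chi_targets or {}
    out = []
    prev_n = prev_ca = prev_c = None
    for i, res_name in enumerate(sequence):
        seq = start_seq + i
        if i == 0:
            n = np.zeros(3)
            ca = np.array([1.458, 0.0, 0.0])
            ang = math.radians(111.2)
            c = ca + 1.525 * np.array([-math.cos(ang), math.sin(ang), 0.0])
            # orient the first C-N bond like every later one
            c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, 1.525, 111.2, _PHI)
        else:
            n = place_atom(prev_n, prev_ca, prev_c, 1.329, 116.2, _PSI)
            ca = place_atom(prev_ca, prev_c, n, 1.458, 121.7, _OMEGA)
            c = place_atom(prev_c, n, ca, 1.525, 111.2, _PHI)
        o = place_atom(n, ca, c, 1.231, 120.8, _PSI + 180.0)
        chi = dict(DEFAULT_CHI.get(res_name, {}))
        chi.update(chi_targets.get(seq, {}))
        atoms = [("N", n), ("CA", ca), ("C", c), ("O", o)]
        atoms += _build_sidechain(res_name, n, ca, c, chi)
        out.append((res_name, seq, atoms))
        prev_n, prev_ca, prev_c = n, ca, c
    return out


# ---------------------------------------------------------------------------
# fixture specification
# ---------------------------------------------------------------------------

@dataclass
class AltlocSpec:
    """Engineered dual side-chain conformer (chi1 split) for one residue."""

    seq_number: int
    delta_chi1: float = 130.0
    occupancies: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.occupancies), 1.0, abs_tol=1e-6):
            raise ValueError("conformer occupancies must sum to 1")


@dataclass
class FixtureSpec:
    """Recipe for a toy crystal with known ground truth.

    ``adp_a`` / ``adp_b_eq`` set the target anisotropy (lambda_min/lambda_max)
    and isotropic-equivalent B (A^2) of every atom; per-atom overrides go in
    ``adp_profile`` keyed by (seq_number, atom_name).  ``engineered_moves``
    lists (seq_number, chi index, delta degrees) applied to the second form
    of :func:`make_form_pair`.
    """

    space_group: str = "P 1"
    cell: UnitCell = field(default_factory=lambda: UnitCell(30.0, 30.0, 30.0))
    sequence: list[str] = field(default_factory=lambda: ["ALA", "SER", "ARG", "HIS"])
    seed: int = 0
    start_seq: int = 1
    chain_id: str = "A"
    frac_center: tuple[float, float, float] = (0.5, 0.5, 0.5)
    adp_a: float = 0.5
    adp_b_eq: float = 20.0
    adp_profile: dict[tuple[int, str], tuple[float, float]] = field(default_factory=dict)
    chi_targets: dict[int, dict[int, float]] = field(default_factory=dict)
    altloc_spec: AltlocSpec | None = None
    engineered_moves: list[tuple[int, int, float]] = field(default_factory=list)
    # optional different lattice/placement for the second form of a pair
    space_group_b: str | None = None
    cell_b: UnitCell | None = None
    frac_center_b: tuple[float, float, float] | None = None


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _adp_tensor(target_a: float, target_b_eq: float,
                rng: np.random.Generator) -> np.ndarray:
    """Random-orientation U with exact anisotropy and B_eq."""
    if not 0.0 < target_a <= 1.0:
        raise ValueError("target anisotropy must be in (0, 1]")
    trace = 3.0 * target_b_eq / _EIGHT_PI_SQ
    lam_max = trace / (1.5 * (1.0 + target_a))
    lam = np.array([lam_max, 0.5 * (1.0 + target_a) * lam_max, target_a * lam_max])
    r = _random_rotation(rng)
    return r @ np.diag(lam) @ r.T


def make_toy_crystal(spec: FixtureSpec) -> tuple[CrystalStructure, dict]:
    """Build one toy crystal form plus its ground-truth manifest.

    Raises when the placed chain clashes with its own symmetry images
    (closest image atom under 1.2 A), i.e. the chain does not fit the cell.
    """
    rng = np.random.default_rng(spec.seed)
    residues = _build_residues(spec, spec.chi_targets, rng)
    structure = _assemble(spec, spec.space_group, spec.cell, residues, rng)
    _check_fit(structure)
    manifest = _manifest(structure, spec)
    return structure, manifest


def make_form_pair(spec: FixtureSpec) -> tuple[CrystalStructure, CrystalStructure, dict]:
    """Two crystal forms of the same chain differing by the engineered chi
    moves (and, when requested, by lattice).

    The second form is rebuilt with the moved chi targets, so each engineered
    change is exact by construction.
    """
    chi_b: dict[int, dict[int, float]] = {k: dict(v) for k, v in spec.chi_targets.items()}
    moved: list[dict] = []
    for seq, chi_idx, delta in spec.engineered_moves:
        res_name = _residue_type(spec, seq)
        if chi_idx not in CHI_DISTAL.get(res_name, {}):
            raise ValueError(
                f"chi{chi_idx} undefined for {res_name}{seq}; movable chis: "
                f"{sorted(CHI_DISTAL.get(res_name, {}))}")
        base = dict(DEFAULT_CHI.get(res_name, {}))
        base.update(spec.chi_targets.get(seq, {}))
        chi_b.setdefault(seq, dict(base))
        chi_b[seq][chi_idx] = base[chi_idx] + delta
        moved.append({"seq_number": seq, "chi": chi_idx, "delta_deg": delta,
                      "res_name": res_name})

    # identical seed: identical placement rotation and ADP orientations
    rng_a = np.random.default_rng(spec.seed)
    form_a = _assemble(spec, spec.space_group, spec.cell,
                       _build_residues(spec, spec.chi_targets, rng_a),
                       np.random.default_rng(spec.seed + 1))
    rng_b = np.random.default_rng(spec.seed)
    form_b = _assemble(spec, spec.space_group_b or spec.space_group,
                       spec.cell_b or spec.cell,
                       _build_residues(spec, chi_b, rng_b),
                       np.random.default_rng(spec.seed + 1),
                       frac_center=spec.frac_center_b)
    _check_fit(form_a)
    _check_fit(form_b)
    manifest = _manifest(form_a, spec)
    manifest["engineered_moves"] = moved
    return form_a, form_b, manifest


def make_fitting_toy_crystal(spec: FixtureSpec, max_tries: int = 32
                             ) -> tuple[CrystalStructure, dict]:
    """Like :func:`make_toy_crystal`, but when the seeded orientation clashes
    with a symmetry image, deterministically re-draws (seed + 1000, + 2000,
    ...) until the chain fits the cell."""
    last: ValueError | None = None
    for k in range(max_tries):
        try:
            return make_toy_crystal(replace(spec, seed=spec.seed + 1000 * k))
        except ValueError as exc:
            if "does not fit" not in str(exc):
                raise
            last = exc
    raise ValueError(f"no clash-free placement in {max_tries} tries: {last}")


def make_fitting_form_pair(spec: FixtureSpec, max_tries: int = 32
                           ) -> tuple[CrystalStructure, CrystalStructure, dict]:
    """Rejection-sampled variant of :func:`make_form_pair` (both forms must
    fit their cells)."""
    last: ValueError | None = None
    for k in range(max_tries):
        try:
            return make_form_pair(replace(spec, seed=spec.seed + 1000 * k))
        except ValueError as exc:
            if "does not fit" not in str(exc):
                raise
            last = exc
    raise ValueError(f"no clash-free placement in {max_tries} tries: {last}")


def _residue_type(spec: FixtureSpec, seq_number: int) -> str:
    idx = seq_number - spec.start_seq
    if not 0 <= idx < len(spec.sequence):
        raise ValueError(f"residue {seq_number} outside the fixture sequence")
    return spec.sequence[idx]


def _build_residues(spec: FixtureSpec, chi_targets: dict[int, dict[int, float]],
                    rng: np.random.Generator) -> list[ResidueRecord]:
    """Residue records with ADPs assigned; conformer duplication applied."""
    built = build_peptide(spec.sequence, chi_targets, spec.start_seq)
    alt = spec.altloc_spec
    alt_atoms: dict[str, np.ndarray] = {}
    if alt is not None:
        res_name = _residue_type(spec, alt.seq_number)
        if 1 not in CHI_DISTAL.get(res_name, {}):
            raise ValueError(f"residue type {res_name} cannot carry a chi1 "
                             "dual conformer")
        base = dict(DEFAULT_CHI[res_name])
        base.update(chi_targets.get(alt.seq_number, {}))
        base[1] = base[1] + alt.delta_chi1
        idx = alt.seq_number - spec.start_seq
        rebuilt = build_peptide(spec.sequence,
                                {**chi_targets, alt.seq_number: base},
                                spec.start_seq)
        alt_atoms = {name: xyz for name, xyz in rebuilt[idx][2]
                     if name in CHI_DISTAL[res_name][1]}

    residues: list[ResidueRecord] = []
    serial = 1
    for res_name, seq, atoms in built:
        rec = ResidueRecord(chain_id=spec.chain_id, seq_number=seq,
                            res_name=res_name)
        for name, xyz in atoms:
            a_target, b_target = spec.adp_profile.get(
                (seq, name), (spec.adp_a, spec.adp_b_eq))
            split = (alt is not None and seq == alt.seq_number
                     and name in alt_atoms)
            for conformer, (altloc, occ) in enumerate(
                    zip(("A", "B"), alt.occupancies) if split else [("", 1.0)]):
                u = _adp_tensor(a_target, b_target, rng)
                pos = alt_atoms[name] if (split and altloc == "B") else xyz
                rec.atoms.append(AtomRecord(
                    serial=serial, name=name, element=_element_of(name),
                    xyz=pos, altloc=altloc if split else "",
                    occupancy=occ, b_iso=round(adp_b_eq(u), 2), u=u))
                serial += 1
        residues.append(rec)
    return residues


def _assemble(spec: FixtureSpec, space_group: str, cell: UnitCell,
              residues: list[ResidueRecord],
              rng: np.random.Generator,
              frac_center: tuple[float, float, float] | None = None,
              ) -> CrystalStructure:
    """Seeded rigid placement of the built chain into the cell."""
    rot = _random_rotation(rng)
    coords = np.array([a.xyz for r in residues for a in r.atoms])
    center = coords.mean(axis=0)
    target = frac_to_cart(cell, np.array(frac_center or spec.frac_center))
    moved = (coords - center) @ rot.T + target
    i = 0
    for r in residues:
        for a in r.atoms:
            a.xyz = moved[i]
            i += 1
    return CrystalStructure(
        cell=cell, space_group=SpaceGroupInfo.from_symbol(space_group),
        residues=residues, provenance=f"synthetic seed={spec.seed}")


def _check_fit(structure: CrystalStructure, clash: float = 1.2) -> None:
    pairs = brute_force_contacts(structure, cutoff=clash)
    if pairs:
        dmin = min(p["distance"] for p in pairs)
        raise ValueError(
            f"chain does not fit the cell: symmetry image only {dmin:.2f} A "
            "away; use a larger cell")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_contacts(structure: CrystalStructure, cutoff: float = 3.5,
                         depth: int | None = None, include_het: bool = False,
                         altloc: str = "highest") -> list[dict]:
    """All-pairs distance scan over every operator and lattice translation.

    Deliberately naive (no spatial grid): serves as the oracle the
    production contact search is checked against.
    """
    sites = select_atoms(structure, polymer_only=not include_het,
                         altloc=altloc, allow_empty=True)
    ref = coordinates(sites)
    if ref.shape[0] == 0:
        return []
    frac = cart_to_frac(structure.cell, ref)
    if depth is None:
        # generous: molecule extent + cutoff in cells, plus however far the
        # molecule sits from the origin cell
        extent = float(np.linalg.norm(ref.max(axis=0) - ref.min(axis=0)))
        min_edge = min(structure.cell.a, structure.cell.b, structure.cell.c)
        offset = float(np.abs(frac).max())
        depth = max(2, int(math.ceil((cutoff + extent) / min_edge))
                    + int(math.ceil(offset)) + 1)
    out: list[dict] = []
    rng_shifts = range(-depth, depth + 1)
    for op in structure.space_group.operators:
        base = op.apply(frac)
        for tx in rng_shifts:
            for ty in rng_shifts:
                for tz in rng_shifts:
                    t = (tx, ty, tz)
                    if op.is_identity and t == (0, 0, 0):
                        continue
                    cart = frac_to_cart(structure.cell,
                                        base + np.array(t, dtype=float))
                    d = cdist(cart, ref)
                    for j, i in zip(*np.nonzero(d < cutoff)):
                        out.append({
                            "ref_atom": sites[i].atom.name,
                            "ref_seq": sites[i].residue.seq_number,
                            "mate_atom": sites[j].atom.name,
                            "mate_seq": sites[j].residue.seq_number,
                            "symop": op.triplet(),
                            "translation": list(t),
                            "distance": float(d[j, i]),
                        })
    return out


def dense_sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
               n_points: int = 20000, seed: int = 1234,
               occluder_coords: np.ndarray | None = None,
               occluder_radii: np.ndarray | None = None) -> np.ndarray:
    """High-density random-direction SASA oracle.

    Independent of the production quadrature: directions are seeded random
    unit vectors rather than a Fibonacci lattice.
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if occluder_coords is None:
        occluder_coords = np.empty((0, 3))
        occluder_radii = np.empty((0,))
    all_coords = np.vstack([coords, np.asarray(occluder_coords, dtype=float).reshape(-1, 3)])
    all_radii = np.concatenate([radii, np.asarray(occluder_radii, dtype=float)])
    areas = np.empty(coords.shape[0])
    for i in range(coords.shape[0]):
        dirs = rng.normal(size=(n_points, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ri = radii[i] + probe
        pts = coords[i] + ri * dirs
        d = cdist(coords[i][None, :], all_coords)[0]
        nb = np.nonzero((d < ri + all_radii + probe)
                        & (np.arange(len(all_radii)) != i))[0]
        if nb.size:
            d2 = ((pts[:, None, :] - all_coords[nb][None, :, :]) ** 2).sum(axis=2)
            acc = ~np.any(d2 < ((all_radii[nb] + probe) ** 2)[None, :], axis=1)
            frac = acc.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ri * ri * frac
    return areas


def _manifest(structure: CrystalStructure, spec: FixtureSpec) -> dict:
    from .packing import element_radius  # local import avoids a cycle

    contacts = brute_force_contacts(structure, cutoff=3.5)
    sites = select_atoms(structure, allow_empty=True)
    radii = np.array([element_radius(s.atom.element) for s in sites])
    reach = 2.0 * (float(radii.max(initial=1.8)) + 1.4)
    occ: list[np.ndarray] = []
    frac = cart_to_frac(structure.cell, coordinates(sites))
    extent = float(np.linalg.norm(coordinates(sites).max(axis=0)
                                  - coordinates(sites).min(axis=0)))
    depth = max(2, int(math.ceil((reach + extent) / min(
        structure.cell.a, structure.cell.b, structure.cell.c))))
    ref = coordinates(sites)
    for op in structure.space_group.operators:
        base = op.apply(frac)
        for tx in range(-depth, depth + 1):
            for ty in range(-depth, depth + 1):
                for tz in range(-depth, depth + 1):
                    if op.is_identity and (tx, ty, tz) == (0, 0, 0):
                        continue
                    cart = frac_to_cart(structure.cell,
                                        base + np.array([tx, ty, tz], float))
                    if cdist(cart, ref).min() < reach:
                        occ.append(cart)
    if occ:
        occ_coords = np.vstack(occ)
        occ_radii = np.tile(radii, len(occ))
        iso = dense_sasa(ref, radii, seed=spec.seed + 17)
        lat = dense_sasa(ref, radii, seed=spec.seed + 17,
                         occluder_coords=occ_coords, occluder_radii=occ_radii)
        buried = float((iso - lat).sum())
    else:
        buried = 0.0

    per_atom_adp = {}
    for r in structure.residues:
        for a in r.atoms:
            key = f"{r.seq_number}:{a.name}:{a.altloc or '-'}"
            target_a, target_b = spec.adp_profile.get(
                (r.seq_number, a.name), (spec.adp_a, spec.adp_b_eq))
            per_atom_adp[key] = {"anisotropy": target_a, "b_eq": target_b}

    return {
        "space_group": structure.space_group.hermann_mauguin,
        "cell": [structure.cell.a, structure.cell.b, structure.cell.c,
                 structure.cell.alpha, structure.cell.beta,
                 structure.cell.gamma],
        "seed": spec.seed,
        "sequence": list(spec.sequence),
        "contact_cutoff": 3.5,
        "contact_count": len(contacts),
        "contacts": contacts,
        "buried_area_oracle": buried,
        "adp": per_atom_adp,
        "altloc": (None if spec.altloc_spec is None else {
            "seq_number": spec.altloc_spec.seq_number,
            "delta_chi1": spec.altloc_spec.delta_chi1,
            "occupancies": list(spec.altloc_spec.occupancies),
        }),
    }


def write_fixture(structure: CrystalStructure, manifest: dict,
                  out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the fixture as <prefix>.pdb plus <prefix>.manifest.json;
    byte-identical for identical input."""
    out_prefix = Path(out_prefix)
    pdb_path = out_prefix.with_suffix(".pdb")
    man_path = out_prefix.with_name(out_prefix.name + ".manifest.json")
    write_structure(structure, pdb_path, format="pdb")
    man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                   default=float) + "\n")
    return pdb_path, man_path
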