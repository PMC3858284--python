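"""Superposition of two crystal forms and per-residue conformational deltas.

The two forms are superposed **once**, by a least-squares (Kabsch) fit on
main-chain atoms of the common residue range, and every per-residue quantity
is then measured in that fixed global frame with no local re-fitting.  This
is the convention under which a residue whose backbone has not moved shows a
near-zero main-chain RMSD even when its side chain swings by a full rotamer.

Side-chain dihedrals (chi angles) follow the standard rotamer-library atom
quadruples (chi1 = N-CA-CB-XG about the CA-CB bond, etc.); deltas are
reported signed in (-180, 180] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError
from .structure import (
    MAIN_CHAIN_ATOMS,
    AtomRecord,
    CrystalStructure,
    ResidueRecord,
)

#: chi-angle atom quadruples per residue type (chi1, chi2, ...).
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
             p4: np.ndarray) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Follows the standard IUPAC sign convention (cis = 0, trans = 180) and is
    invariant under rigid motion of all four points.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b, label in ((p1, p2, "p1/p2"), (p2, p3, "p2/p3"), (p3, p4, "p3/p4")):
        if np.linalg.norm(b - a) < 1e-10:
            raise DegenerateGeometryError(f"coincident consecutive points {label}")
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear points: dihedral undefined")
    angle = np.degrees(np.arctan2(
        np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)), np.dot(n1, n2)))
    return 180.0 if np.isclose(angle, -180.0) else float(angle)


def wrap_angle(delta: float) -> float:
    """Wrap an angle difference into (-180, 180] degrees."""
    wrapped = (delta + 180.0) % 360.0 - 180.0
    return 180.0 if np.isclose(wrapped, -180.0) else float(wrapped)


def chi_angles(residue: ResidueRecord, altloc: str | None = None) -> dict[int, float]:
    """chi angles (1-based index -> degrees) computable for a residue.

    Angles whose atoms are missing are omitted; residue types without chi
    angles (Gly, Ala) give an empty dict.  ``altloc`` selects one conformer;
    blank-altloc atoms (shared backbone) participate in every conformer.
    """
    out: dict[int, float] = {}
    for idx, quad in enumerate(CHI_ATOMS.get(residue.res_name, []), start=1):
        atoms = [residue.get_atom(name, altloc) for name in quad]
        if any(a is None for a in atoms):
            continue
        out[idx] = dihedral(*(a.xyz for a in atoms))
    return out


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Least-squares rigid-body fit of coords_b onto coords_a."""

    rotation: np.ndarray     # proper 3x3, det = +1
    translation: np.ndarray  # x_a ~ R x_b + t
    rmsd: float
    atom_count: int
    atom_set_descriptor: str = ""

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray,
                     descriptor: str = "") -> SuperpositionResult:
    """Optimal (least-squares) superposition of coords_b onto coords_a.

    A reflection is never returned: the rotation is forced proper even when
    an improper transform would fit better (near-planar point sets).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    for name, x in (("a", a0), ("b", b0)):
        if np.linalg.matrix_rank(x, tol=1e-9) < 2:
            raise DegenerateGeometryError(
                f"coordinate set {name} is collinear; rotation is underdetermined")
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    tran = ca - rot @ cb
    rmsd = float(np.sqrt(((a - (b @ rot.T + tran)) ** 2).sum() / a.shape[0]))
    return SuperpositionResult(rotation=rot, translation=tran, rmsd=rmsd,
                               atom_count=a.shape[0],
                               atom_set_descriptor=descriptor)


# ---------------------------------------------------------------------------
# per-residue comparison of two forms
# ---------------------------------------------------------------------------

@dataclass
class ResidueDelta:
    """Conformational difference of one residue between two forms,
    measured in the global superposition frame."""

    key: tuple[str, int, str]
    res_name: str
    mainchain_rmsd: float | None
    sidechain_rmsd: float | None
    chi_deltas: list[tuple[int, float]]          # (chi index, signed degrees)
    atom_displacements: dict[str, float]         # atom name -> A
    flags: list[str] = field(default_factory=list)

    @property
    def max_abs_chi_delta(self) -> float | None:
        if not self.chi_deltas:
            return None
        return max(abs(d) for _, d in self.chi_deltas)


@dataclass
class ConformationDelta:
    """Result of comparing two crystal forms of the same molecule."""

    superposition: SuperpositionResult
    per_residue: dict[tuple[str, int, str], ResidueDelta]
    _pairs: dict[tuple[str, int, str], list[tuple[str, np.ndarray, np.ndarray]]]

    def global_rmsd(self, part: str = "main_chain", chain: str | None = None,
                    residue_range: tuple[int, int] | None = None) -> float:
        """RMSD over all matched atoms of the given part, in the global frame.

        ``part`` is ``main_chain``, ``side_chain`` or ``all``; optional chain
        and residue-range filters allow e.g. a bound-peptide-only RMSD.
        """
        sq, n = 0.0, 0
        for key, pairs in self._pairs.items():
            if chain is not None and key[0] != chain:
                continue
            if residue_range is not None and not (
                    residue_range[0] <= key[1] <= residue_range[1]):
                continue
            for name, xa, xb in pairs:
                in_main = name in MAIN_CHAIN_ATOMS
                if part == "main_chain" and not in_main:
                    continue
                if part == "side_chain" and in_main:
                    continue
                sq += float(((xa - xb) ** 2).sum())
                n += 1
        if n == 0:
            raise ValueError(f"no matched atoms for part={part!r} chain={chain!r}")
        return float(np.sqrt(sq / n))


def _matched_atoms(res_a: ResidueRecord, res_b: ResidueRecord, altloc: str
                   ) -> tuple[list[tuple[str, AtomRecord, AtomRecord]], list[str]]:
    """Pair atoms of corresponding residues by name (one conformer each)."""
    from .structure import _pick_altlocs  # shared altloc policy

    flags: list[str] = []
    picked_a = {a.name: a for a in _pick_altlocs(res_a, altloc) if not a.is_hydrogen}
    picked_b = {a.name: a for a in _pick_altlocs(res_b, altloc) if not a.is_hydrogen}
    pairs = [(n, picked_a[n], picked_b[n]) for n in picked_a if n in picked_b]
    for n in sorted(set(picked_a) ^ set(picked_b)):
        flags.append(f"atom-mismatch:{n}")
    return pairs, flags


def per_residue_delta(
    form_a: CrystalStructure,
    form_b: CrystalStructure,
    align_chain: str | None = None,
    align_range: tuple[int, int] | None = None,
    altloc: str = "highest",
) -> ConformationDelta:
    """Superpose form_b onto form_a and measure per-residue differences.

    Residues correspond by author numbering (chain id, residue number,
    insertion code).  The global fit uses main-chain atoms of the common
    polymer residues, optionally restricted to ``align_chain`` /
    ``align_range``; per-residue RMSDs, chi-angle deltas and named-atom
    displacements are then evaluated in that frame without re-fitting.
    """
    res_b_by_key = {r.key: r for r in form_b.residues}
    common: list[tuple[ResidueRecord, ResidueRecord]] = []
    mismatched: list[tuple[str, int, str]] = []
    for res_a in form_a.residues:
        res_b = res_b_by_key.get(res_a.key)
        if res_b is None:
            continue
        if res_a.res_name != res_b.res_name:
            mismatched.append(res_a.key)
            continue
        common.append((res_a, res_b))
    if not common:
        raise ValueError(
            "forms share no residues under author numbering; supply an "
            "explicit residue mapping (renumber one form) first")

    # global alignment on main-chain atoms of the requested range
    fit_a, fit_b = [], []
    for res_a, res_b in common:
        if not res_a.is_polymer:
            continue
        if align_chain is not None and res_a.chain_id != align_chain:
            continue
        if align_range is not None and not (
                align_range[0] <= res_a.seq_number <= align_range[1]):
            continue
        pairs, _ = _matched_atoms(res_a, res_b, altloc)
        for name, aa, ab in pairs:
            if name in MAIN_CHAIN_ATOMS:
                fit_a.append(aa.xyz)
                fit_b.append(ab.xyz)
    if len(fit_a) < 3:
        raise ValueError("fewer than 3 matched main-chain atoms to align on")
    sup = kabsch_superpose(np.array(fit_a), np.array(fit_b),
                           descriptor="main-chain atoms of common range")

    per_residue: dict[tuple[str, int, str], ResidueDelta] = {}
    all_pairs: dict[tuple[str, int, str], list[tuple[str, np.ndarray, np.ndarray]]] = {}
    for res_a, res_b in common:
        pairs, flags = _matched_atoms(res_a, res_b, altloc)
        coord_pairs = [(name, aa.xyz, sup.transform(ab.xyz)) for name, aa, ab in pairs]
        all_pairs[res_a.key] = coord_pairs

        def _rmsd(names_in_main: bool) -> float | None:
            pts = [(xa, xb) for name, xa, xb in coord_pairs
                   if (name in MAIN_CHAIN_ATOMS) == names_in_main]
            if not pts:
                return None
            sq = sum(float(((xa - xb) ** 2).sum()) for xa, xb in pts)
            return float(np.sqrt(sq / len(pts)))

        chi_a = chi_angles(res_a)
        # chi of form B can be computed in its own frame: dihedrals are
        # invariant under the rigid superposition
        chi_b = chi_angles(res_b)
        chi_deltas = [(idx, wrap_angle(chi_a[idx] - chi_b[idx]))
                      for idx in sorted(set(chi_a) & set(chi_b))]
        per_residue[res_a.key] = ResidueDelta(
            key=res_a.key,
            res_name=res_a.res_name,
            mainchain_rmsd=_rmsd(True),
            sidechain_rmsd=_rmsd(False),
            chi_deltas=chi_deltas,
            atom_displacements={name: float(np.linalg.norm(xa - xb))
                                for name, xa, xb in coord_pairs},
            flags=flags,
        )
    for key in mismatched:
        per_residue[key] = ResidueDelta(
            key=key, res_name="?", mainchain_rmsd=None, sidechain_rmsd=None,
            chi_deltas=[], atom_displacements={}, flags=["resname-mismatch"])
        all_pairs[key] = []

    return ConformationDelta(superposition=sup, per_residue=per_residue,
                             _pairs=all_pairs)


def atom_displacement(
    form_a: CrystalStructure,
    form_b: CrystalStructure,
    chain_id: str,
    seq_number: int,
    atom_name: str,
    insertion_code: str = "",
    superposition: SuperpositionResult | None = None,
    **align_kwargs,
) -> float:
    """Displacement (A) of one named atom between the two forms, measured in
    the global superposition frame."""
    res_a = form_a.find_residue(chain_id, seq_number, insertion_code)
    res_b = form_b.find_residue(chain_id, seq_number, insertion_code)
    atom_a = res_a.get_atom(atom_name)
    atom_b = res_b.get_atom(atom_name)
    if atom_a is None:
        raise KeyError(f"atom {atom_name} missing in form_a {res_a.label}")
    if atom_b is None:
        raise KeyError(f"atom {atom_name} missing in form_b {res_b.label}")
    if superposition is None:
        superposition = per_residue_delta(form_a, form_b, **align_kwargs).superposition
    return float(np.linalg.norm(atom_a.xyz - superposition.transform(atom_b.xyz)))
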