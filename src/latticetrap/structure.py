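"""Crystal-structure I/O and atom selection.

Structures are read with :mod:`gemmi` (PDB and mmCIF) and exposed through a
small validated in-memory model: a :class:`CrystalStructure` holds a unit
cell, a space group, and residues with their atoms, alternate conformers,
isotropic B-factors and (when deposited) anisotropic U tensors.

Conventions
-----------
* ANISOU integers in PDB files are U * 10^4; atoms expose ``u`` in squared
  angstroms directly.
* Main-chain atoms are {N, CA, C, O}; every other non-hydrogen atom of an
  amino acid counts as side chain (OXT included).
* Hydrogens are excluded from selections by default; deposited models from
  anisotropic refinement carry riding hydrogens that the analyses ignore.
* Author residue numbering (chain id + residue number + insertion code) is
  the canonical residue key throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptySelectionError,
    MissingCellError,
    StructureParseError,
    UnknownSpaceGroupError,
)
from .symmetry import SymOp

MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Three-letter codes treated as polymer (protein) residues.
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL MSE".split()
)

#: Average residue masses (Da) of amino-acid residues *in a chain*
#: (monomer mass minus one water); used for Matthews-coefficient input.
RESIDUE_MASSES = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09,
    "CYS": 103.14, "GLN": 128.13, "GLU": 129.12, "GLY": 57.05,
    "HIS": 137.14, "ILE": 113.16, "LEU": 113.16, "LYS": 128.17,
    "MET": 131.19, "MSE": 178.09, "PHE": 147.18, "PRO": 97.12,
    "SER": 87.08, "THR": 101.10, "TRP": 186.21, "TYR": 163.18,
    "VAL": 99.13,
}
WATER_MASS = 18.02


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in angstroms, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell edge {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180) degrees")
        if self._volume_factor() <= 0:
            raise ValueError("cell angles give non-positive volume")

    def _volume_factor(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def volume(self) -> float:
        """Cell volume in cubic angstroms (standard triclinic formula)."""
        return self.a * self.b * self.c * math.sqrt(self._volume_factor())

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 fractional->Cartesian matrix (a along x, b in the xy plane)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(self._volume_factor())
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def frac_matrix(self) -> np.ndarray:
        """3x3 Cartesian->fractional matrix (inverse of :attr:`orth_matrix`)."""
        return np.linalg.inv(self.orth_matrix)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class SpaceGroupInfo:
    """Hermann-Mauguin symbol plus the full operator list of the group."""

    hermann_mauguin: str
    operators: tuple[SymOp, ...]

    def __post_init__(self) -> None:
        if not self.operators:
            raise ValueError("operator list must be nonempty")
        if not any(op.is_identity for op in self.operators):
            raise ValueError("operator list must contain the identity")

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroupInfo":
        sg = gemmi.find_spacegroup_by_name(symbol)
        if sg is None:
            raise UnknownSpaceGroupError(
                f"unknown space-group symbol {symbol!r}; use a Hermann-Mauguin "
                "symbol as printed in CRYST1 columns 56-66 (e.g. 'P 1', "
                "'P 1 21 1', 'P 31 2 1')"
            )
        ops = tuple(SymOp.from_gemmi(op) for op in sg.operations())
        return cls(hermann_mauguin=sg.hm, operators=ops)

    @property
    def order(self) -> int:
        """Number of symmetry operators (asymmetric units per cell)."""
        return len(self.operators)


@dataclass
class AtomRecord:
    """One atom site (one altloc of one atom)."""

    serial: int
    name: str
    element: str
    xyz: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    b_iso: float = 0.0
    u: np.ndarray | None = None  # symmetric 3x3 ADP tensor, A^2

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.b_iso < 0:
            raise ValueError(f"atom {self.name}: negative B-factor")
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)
            if self.u.shape != (3, 3) or not np.allclose(self.u, self.u.T, atol=1e-8):
                raise ValueError(f"atom {self.name}: U tensor must be symmetric 3x3")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class ResidueRecord:
    """One residue identified by author numbering."""

    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.seq_number}{self.insertion_code}"

    @property
    def is_polymer(self) -> bool:
        return self.res_name in AMINO_ACIDS

    def altlocs(self) -> list[str]:
        """Distinct altloc labels in this residue ('' for single-conformer atoms)."""
        seen: list[str] = []
        for a in self.atoms:
            if a.altloc not in seen:
                seen.append(a.altloc)
        return seen

    def get_atom(self, name: str, altloc: str | None = None) -> AtomRecord | None:
        """First atom with the given name; optionally restricted to one altloc
        (blank-altloc atoms match any requested conformer)."""
        for a in self.atoms:
            if a.name == name and (altloc is None or a.altloc == altloc or a.altloc == ""):
                return a
        return None


class AtomSite(NamedTuple):
    """An atom together with its residue context."""

    residue: ResidueRecord
    atom: AtomRecord


@dataclass
class CrystalStructure:
    """One crystal form: unit cell, space group, and ordered residues."""

    cell: UnitCell
    space_group: SpaceGroupInfo
    residues: list[ResidueRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        for res in self.residues:
            for atom in res.atoms:
                if not np.all(np.isfinite(atom.xyz)):
                    raise ValueError(f"non-finite coordinates in {res.label}")

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def find_residue(self, chain_id: str, seq_number: int,
                     insertion_code: str = "") -> ResidueRecord:
        for r in self.residues:
            if r.key == (chain_id, seq_number, insertion_code):
                return r
        raise KeyError(f"residue {chain_id}/{seq_number}{insertion_code} not in structure")

    def iter_atoms(self) -> Iterator[AtomSite]:
        for r in self.residues:
            for a in r.atoms:
                yield AtomSite(r, a)

    def polymer_mass(self) -> float:
        """Approximate polymer mass (Da) from the residue sequence, one water
        added back per chain for the termini."""
        mass = 0.0
        chains: set[str] = set()
        for r in self.residues:
            if r.is_polymer:
                mass += RESIDUE_MASSES.get(r.res_name, 110.0)
                chains.add(r.chain_id)
        return mass + WATER_MASS * len(chains)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _u_from_gemmi(atom: gemmi.Atom) -> np.ndarray | None:
    an = atom.aniso
    if not an.nonzero():
        return None
    return np.array([
        [an.u11, an.u12, an.u13],
        [an.u12, an.u22, an.u23],
        [an.u13, an.u23, an.u33],
    ], dtype=float)


def read_structure(path: str | Path, format: str = "auto") -> CrystalStructure:
    """Read a PDB or mmCIF file into a :class:`CrystalStructure`.

    Raises a hard error when the unit cell is missing, the space-group symbol
    is unknown, the file is malformed, or it contains more than one model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise ValueError(f"unknown format {format!r} (use pdb, mmcif or auto)")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        # gemmi reports the offending line/record in its message
        raise StructureParseError(f"{path}: {exc}") from exc

    cell = st.cell
    if st.spacegroup_hm == "" and abs(cell.volume - 1.0) < 1e-6:
        raise MissingCellError(
            f"{path}: no unit-cell record (CRYST1 / _cell + _symmetry) found"
        )
    if cell.a <= 0 or cell.b <= 0 or cell.c <= 0:
        raise MissingCellError(f"{path}: invalid unit-cell lengths in CRYST1/_cell")
    if len(st) != 1:
        raise StructureParseError(
            f"{path}: {len(st)} models found; only single-model crystal "
            "structures are supported (split multi-model files first)"
        )

    sg = SpaceGroupInfo.from_symbol(st.spacegroup_hm or "P 1")
    ucell = UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)

    residues: list[ResidueRecord] = []
    for chain in st[0]:
        for res in chain:
            rec = ResidueRecord(
                chain_id=chain.name,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                res_name=res.name,
            )
            for atom in res:
                rec.atoms.append(AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element.name.upper(),
                    xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    altloc=atom.altloc.strip("\0 ") if atom.altloc else "",
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    b_iso=atom.b_iso,
                    u=_u_from_gemmi(atom),
                ))
            residues.append(rec)

    return CrystalStructure(cell=ucell, space_group=sg, residues=residues,
                            provenance=str(path))


_PDB_COORD_LIMIT = 9999.999


def to_gemmi_structure(structure: CrystalStructure, name: str = "xtal") -> gemmi.Structure:
    """Convert the in-memory model to a ``gemmi.Structure`` (one model)."""
    st = gemmi.Structure()
    st.name = name
    st.cell = structure.cell.to_gemmi()
    st.spacegroup_hm = structure.space_group.hermann_mauguin
    model = gemmi.Model("1")
    current_chain: gemmi.Chain | None = None
    for res in structure.residues:
        if current_chain is None or current_chain.name != res.chain_id:
            current_chain = gemmi.Chain(res.chain_id)
            model.add_chain(current_chain)
            current_chain = model[-1]
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
        gres.het_flag = "A" if res.is_polymer else "H"
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element.capitalize())
            ga.pos = gemmi.Position(*atom.xyz)
            ga.altloc = atom.altloc or "\0"
            ga.occ = atom.occupancy
            ga.b_iso = atom.b_iso
            ga.serial = atom.serial
            if atom.u is not None:
                # quantize to the ANISOU integer grid (U x 10^4) so that
                # writing is idempotent; +0.0 normalizes -0
                u = np.rint(atom.u * 1e4) / 1e4 + 0.0
                ga.aniso = gemmi.SMat33f(u[0, 0], u[1, 1], u[2, 2],
                                         u[0, 1], u[0, 2], u[1, 2])
            gres.add_atom(ga)
        current_chain.add_residue(gres)
    st.add_model(model)
    return st


def write_structure(structure: CrystalStructure, path: str | Path,
                    format: str = "auto") -> None:
    """Write a structure as PDB or mmCIF.

    Round trip through :func:`read_structure` preserves coordinates to the
    fixed-width PDB precision (0.001 A) and U tensors to 1e-4 A^2 (the ANISOU
    integer scale).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt == "pdb":
        for site in structure.iter_atoms():
            if np.any(np.abs(site.atom.xyz) > _PDB_COORD_LIMIT):
                raise ValueError(
                    f"coordinates of {site.residue.label}/{site.atom.name} exceed "
                    "the PDB fixed-width field range; write mmCIF instead"
                )
    st = to_gemmi_structure(structure)
    if fmt == "pdb":
        path.write_text(st.make_pdb_string())
    elif fmt in ("mmcif", "cif"):
        st.setup_entities()
        doc = st.make_mmcif_document()
        doc.write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r} (use pdb, mmcif or auto)")


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _pick_altlocs(res: ResidueRecord, policy: str) -> list[AtomRecord]:
    if policy == "expand":
        return list(res.atoms)
    picked: dict[str, AtomRecord] = {}
    for atom in res.atoms:
        prev = picked.get(atom.name)
        if prev is None:
            picked[atom.name] = atom
        elif policy == "first":
            pass  # keep first occurrence
        elif policy == "highest":
            # higher occupancy wins; tie broken toward the smaller altloc label
            if (atom.occupancy, _altloc_rank(atom.altloc)) > \
               (prev.occupancy, _altloc_rank(prev.altloc)):
                picked[atom.name] = atom
        else:
            raise ValueError(f"unknown altloc policy {policy!r}")
    return [picked[a.name] for a in res.atoms if picked.get(a.name) is a]


def _altloc_rank(altloc: str) -> float:
    # '' (single conformer) ranks above 'A' above 'B' ...
    return 0.0 if altloc == "" else -ord(altloc[0])


def select_atoms(
    structure: CrystalStructure,
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
    part: str = "all",
    altloc: str = "highest",
    include_hydrogens: bool = False,
    polymer_only: bool = True,
    allow_empty: bool = False,
) -> list[AtomSite]:
    """Deterministic, order-stable atom selection.

    Parameters
    ----------
    part:
        ``all``, ``main_chain`` ({N, CA, C, O}) or ``side_chain`` (every
        other non-hydrogen atom).
    altloc:
        ``expand`` (every conformer), ``first``, or ``highest``
        (highest occupancy, ties toward altloc 'A').
    allow_empty:
        When False (default) an empty selection raises
        :class:`EmptySelectionError` rather than silently yielding zero
        statistics.
    """
    if part not in ("all", "main_chain", "side_chain"):
        raise ValueError(f"unknown part {part!r}")
    sites: list[AtomSite] = []
    for res in structure.residues:
        if chain is not None and res.chain_id != chain:
            continue
        if residue_range is not None and not (
                residue_range[0] <= res.seq_number <= residue_range[1]):
            continue
        if polymer_only and not res.is_polymer:
            continue
        for atom in _pick_altlocs(res, altloc):
            if not include_hydrogens and atom.is_hydrogen:
                continue
            in_main = atom.name in MAIN_CHAIN_ATOMS
            if part == "main_chain" and not in_main:
                continue
            if part == "side_chain" and in_main:
                continue
            sites.append(AtomSite(res, atom))
    if not sites and not allow_empty:
        raise EmptySelectionError(
            f"selection matched no atoms (chain={chain!r}, "
            f"range={residue_range!r}, part={part!r})"
        )
    return sites


def coordinates(sites: Sequence[AtomSite]) -> np.ndarray:
    """(n, 3) coordinate array for a list of atom sites."""
    if len(sites) == 0:
        return np.empty((0, 3))
    return np.array([s.atom.xyz for s in sites])
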