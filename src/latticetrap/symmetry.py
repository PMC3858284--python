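"""Space-group operator algebra and lattice-neighborhood generation.

A crystal is the reference asymmetric unit replicated by the space-group
operators plus integer lattice translations.  This module parses operators
in x,y,z triplet notation, converts between fractional and Cartesian
coordinates, and enumerates the symmetry-mate copies that come close enough
to the reference molecule to matter for packing analysis.

Operator tables come from gemmi's space-group database, looked up by
Hermann-Mauguin symbol; explicit operator strings (e.g. from mmCIF
``_symmetry_equiv``) are accepted for anything unusual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import TYPE_CHECKING, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .structure import AtomSite, CrystalStructure, UnitCell

#: Protein partial-specific-volume constant (Da/A^3 reciprocal scale) in the
#: standard Matthews solvent-fraction formula  f_solv = 1 - 1.230 / Vm.
MATTHEWS_CONSTANT = 1.230

_DEN = 24  # gemmi stores rotations/translations as integers scaled by 24


@dataclass(frozen=True)
class SymOp:
    """A symmetry operator in fractional space: x' = R x + t, t in [0, 1)."""

    rot: tuple[tuple[float, float, float], ...]
    tran: tuple[float, float, float]

    def __post_init__(self) -> None:
        det = round(float(np.linalg.det(self.rotation)))
        if det not in (1, -1):
            raise ValueError(f"operator rotation determinant {det} not +/-1")

    @property
    def rotation(self) -> np.ndarray:
        return np.array(self.rot, dtype=float)

    @property
    def translation(self) -> np.ndarray:
        return np.array(self.tran, dtype=float)

    @classmethod
    def from_matrix(cls, rot: np.ndarray, tran: np.ndarray) -> "SymOp":
        # snap to the 1/24 grid (all crystallographic fractions live on it)
        # so that composed/inverted operators compare exactly
        def _snap(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            grid = np.rint(x * _DEN) / _DEN
            return np.where(np.abs(x - grid) < 1e-9, grid, x)

        tran = _snap(np.mod(np.asarray(tran, dtype=float), 1.0))
        tran[np.isclose(tran, 1.0, atol=1e-9)] = 0.0
        return cls(
            rot=tuple(tuple(float(x) for x in row) for row in _snap(rot)),
            tran=tuple(float(x) for x in tran),
        )

    @classmethod
    def from_gemmi(cls, op: gemmi.Op) -> "SymOp":
        op = op.wrap()
        return cls.from_matrix(np.array(op.rot) / _DEN, np.array(op.tran) / _DEN)

    def to_gemmi(self) -> gemmi.Op:
        op = gemmi.Op()
        op.rot = [[int(round(x * _DEN)) for x in row] for row in self.rot]
        op.tran = [int(round(x * _DEN)) for x in self.tran]
        return op

    def triplet(self) -> str:
        """Canonical textual form, e.g. ``-x,y+1/2,-z``."""
        return self.to_gemmi().triplet()

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3)) and np.allclose(self.translation, 0.0)

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates; accepts a 3-vector or (n, 3)."""
        frac = np.asarray(frac, dtype=float)
        return frac @ self.rotation.T + self.translation

    def compose(self, other: "SymOp") -> "SymOp":
        """self after other: (self.compose(other))(x) = self(other(x)),
        with the translation wrapped back into [0, 1)."""
        rot = self.rotation @ other.rotation
        tran = self.rotation @ other.translation + self.translation
        return SymOp.from_matrix(rot, tran)

    def __mul__(self, other: "SymOp") -> "SymOp":
        return self.compose(other)

    def inverse(self) -> "SymOp":
        rinv = np.linalg.inv(self.rotation)
        return SymOp.from_matrix(rinv, -rinv @ self.translation)

    def __repr__(self) -> str:
        return f"SymOp({self.triplet()!r})"


def parse_symop(text: str) -> SymOp:
    """Parse an ``x,y,z``-algebra triplet such as ``-X,Y+1/2,-Z``."""
    try:
        return SymOp.from_gemmi(gemmi.Op(text.lower()))
    except (RuntimeError, ValueError) as exc:
        parts = text.split(",")
        bad = text if len(parts) == 3 else f"{text} (expected 3 comma-separated components)"
        for part in parts:
            try:
                gemmi.parse_triplet_part(part.lower())
            except (RuntimeError, ValueError):
                bad = part.strip()
                break
        raise ValueError(f"cannot parse symmetry operator: bad token {bad!r}") from exc


# ---------------------------------------------------------------------------
# fractional <-> Cartesian
# ---------------------------------------------------------------------------

def frac_to_cart(cell: "UnitCell", v: np.ndarray) -> np.ndarray:
    """Fractional -> Cartesian (angstrom); accepts a 3-vector or (n, 3)."""
    try:
        m = cell.orth_matrix
    except ValueError as exc:
        raise DegenerateGeometryError(str(exc)) from exc
    return np.asarray(v, dtype=float) @ m.T


def cart_to_frac(cell: "UnitCell", v: np.ndarray) -> np.ndarray:
    """Cartesian (angstrom) -> fractional; accepts a 3-vector or (n, 3)."""
    try:
        m = cell.frac_matrix
    except ValueError as exc:
        raise DegenerateGeometryError(str(exc)) from exc
    return np.asarray(v, dtype=float) @ m.T


def _perpendicular_widths(cell: "UnitCell") -> np.ndarray:
    """Distance between opposite cell faces along each axis (A)."""
    m = cell.orth_matrix
    a, b, c = m[:, 0], m[:, 1], m[:, 2]
    vol = abs(np.dot(a, np.cross(b, c)))
    return np.array([
        vol / np.linalg.norm(np.cross(b, c)),
        vol / np.linalg.norm(np.cross(c, a)),
        vol / np.linalg.norm(np.cross(a, b)),
    ])


# ---------------------------------------------------------------------------
# lattice neighborhood
# ---------------------------------------------------------------------------

@dataclass
class LatticeMate:
    """One symmetry-mate image with >= 1 atom near the reference molecule."""

    op_index: int
    op: SymOp
    lattice_translation: tuple[int, int, int]
    coords: np.ndarray  # (n_atoms, 3) Cartesian, same atom order as reference

    @property
    def image_id(self) -> str:
        t = self.lattice_translation
        return f"{self.op.triplet()} + ({t[0]},{t[1]},{t[2]})"


@dataclass
class LatticeNeighborhood:
    """Symmetry-mate copies near the reference molecule.

    ``sites`` lists the reference atoms (in selection order); every mate's
    ``coords`` row i is the image of reference atom i.  The identity operator
    with zero lattice translation is never included.
    """

    sites: list["AtomSite"]
    ref_coords: np.ndarray
    mates: list[LatticeMate]
    cutoff_used: float

    def all_mate_coords(self) -> np.ndarray:
        if not self.mates:
            return np.empty((0, 3))
        return np.vstack([m.coords for m in self.mates])


def generate_lattice_neighbors(
    structure: "CrystalStructure",
    cutoff: float,
    search_depth: int = 2,
    include_het: bool = False,
    include_hydrogens: bool = False,
    altloc: str = "highest",
) -> LatticeNeighborhood:
    """Enumerate symmetry-mate images with any atom within ``cutoff``.

    All space-group operators combined with integer lattice translations in a
    ``+/- search_depth`` shell are tried; the shell is widened automatically
    when the molecule's extent plus the cutoff spans more cells than the
    requested depth (thin cells, long molecules).  Ordering is deterministic:
    operator index, then translation lexicographic.
    """
    from .structure import coordinates, select_atoms

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ops = structure.space_group.operators
    if not ops:
        raise ValueError("structure has no symmetry operators")

    sites = select_atoms(structure, polymer_only=not include_het,
                         include_hydrogens=include_hydrogens, altloc=altloc)
    ref = coordinates(sites)
    frac = cart_to_frac(structure.cell, ref)

    # candidate lattice translations per operator: the image's fractional
    # bounding box must overlap the reference box within a cutoff margin
    # (|d_frac_k| <= |d_cart| / perpendicular width_k), floored at the
    # requested +/- search_depth shell
    margins = cutoff / _perpendicular_widths(structure.cell)
    fmin, fmax = frac.min(axis=0), frac.max(axis=0)

    tree = cKDTree(ref)
    mates: list[LatticeMate] = []
    for op_index, op in enumerate(ops):
        frac_op = op.apply(frac)
        gmin, gmax = frac_op.min(axis=0), frac_op.max(axis=0)
        lo = np.minimum(np.floor(fmin - gmax - margins).astype(int),
                        -search_depth)
        hi = np.maximum(np.ceil(fmax - gmin + margins).astype(int),
                        search_depth)
        for t in product(*(range(lo[k], hi[k] + 1) for k in range(3))):
            if op.is_identity and t == (0, 0, 0):
                continue
            cart = frac_to_cart(structure.cell, frac_op + np.array(t, dtype=float))
            d, _ = tree.query(cart, k=1, distance_upper_bound=cutoff)
            if np.any(np.isfinite(d)):
                mates.append(LatticeMate(op_index, op, t, cart))
    return LatticeNeighborhood(sites=sites, ref_coords=ref, mates=mates,
                               cutoff_used=cutoff)


# ---------------------------------------------------------------------------
# solvent content
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolventContent:
    matthews_vm: float       # A^3 / Da
    solvent_fraction: float  # 1 - 1.230/Vm, may fall outside [0, 1] for
                             # unphysical inputs (a warning is emitted)

    @property
    def solvent_fraction_clamped(self) -> float:
        return min(max(self.solvent_fraction, 0.0), 1.0)


def solvent_content(structure: "CrystalStructure",
                    molecular_weight: float | None = None,
                    z_asym: int = 1) -> SolventContent:
    """Matthews coefficient and solvent fraction of a crystal form.

    Vm = V_cell / (n_ops * z_asym * MW); the solvent fraction uses the
    standard protein partial-specific-volume constant 1.230.  When
    ``molecular_weight`` is omitted it is estimated from the polymer
    sequence of the structure.
    """
    if z_asym < 1:
        raise ValueError("z_asym must be >= 1")
    if molecular_weight is None:
        molecular_weight = structure.polymer_mass()
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    n_au = structure.space_group.order
    vm = structure.cell.volume / (n_au * z_asym * molecular_weight)
    fraction = 1.0 - MATTHEWS_CONSTANT / vm
    if not 0.0 <= fraction <= 1.0:
        warnings.warn(
            f"solvent fraction {fraction:.3f} outside [0, 1]; check MW "
            f"({molecular_weight:.0f} Da) and Z ({z_asym})", stacklevel=2)
    return SolventContent(matthews_vm=vm, solvent_fraction=fraction)
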