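"""Anisotropic displacement parameter (ADP) analysis.

Each atom of an anisotropically refined crystal structure carries a
symmetric 3x3 tensor U (A^2) describing the directional spread of its
displacement.  Two scalars summarize it:

* the isotropic-equivalent B factor,  B_eq = 8 pi^2 tr(U) / 3,
* the anisotropy  A = lambda_min / lambda_max  of U, with A = 1 for
  perfectly isotropic motion and small A for strongly directional motion.

Selection statistics (mean and standard deviation of A and B over all /
main-chain / side-chain atoms) reproduce the usual per-residue report of
anisotropically refined structures.  The standard deviation is the
population sigma (divide by n) by default; sample sigma is a flag away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptySelectionError, NonPositiveDefiniteError
from .structure import CrystalStructure, select_atoms

_EIGHT_PI_SQ = 8.0 * np.pi ** 2


def _as_symmetric(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.shape != (3, 3):
        raise ValueError("U tensor must be 3x3")
    asym = float(np.abs(u - u.T).max())
    if asym > 1e-8:
        warnings.warn(f"U tensor asymmetry {asym:.2e} exceeds 1e-8; "
                      "symmetrizing", stacklevel=3)
    return 0.5 * (u + u.T)


def anisotropy(u: np.ndarray) -> float:
    """A = lambda_min / lambda_max of the ADP tensor U; in (0, 1]."""
    u = _as_symmetric(u)
    lam = np.linalg.eigvalsh(u)
    if lam[0] <= 0:
        raise NonPositiveDefiniteError(float(lam[0]))
    return float(lam[0] / lam[-1])


def b_eq(u: np.ndarray) -> float:
    """Isotropic-equivalent B factor, 8 pi^2 tr(U)/3, in A^2."""
    u = _as_symmetric(u)
    return float(_EIGHT_PI_SQ * np.trace(u) / 3.0)


@dataclass
class PrincipalAxes:
    """Eigen-decomposition of U, eigenvalues descending."""

    eigenvalues: np.ndarray  # (3,), descending
    axes: np.ndarray         # (3, 3); row i is the unit axis of eigenvalue i
    degenerate: bool         # near-equal eigenvalues: axes unstable

    def __iter__(self):
        return iter(zip(self.eigenvalues, self.axes))


def principal_axes(u: np.ndarray, degeneracy_tol: float = 1e-12) -> PrincipalAxes:
    """Ordered eigenpairs of U (largest displacement first).

    Axis sign convention: first nonzero component positive.  When two
    eigenvalues coincide within ``degeneracy_tol`` the corresponding axes
    are arbitrary within the eigenplane and are flagged as unstable.
    """
    u = _as_symmetric(u)
    lam, vec = np.linalg.eigh(u)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order].T
    for i in range(3):
        for comp in vec[i]:
            if abs(comp) > 1e-12:
                if comp < 0:
                    vec[i] = -vec[i]
                break
    degenerate = bool(np.any(np.abs(np.diff(lam)) < degeneracy_tol))
    return PrincipalAxes(eigenvalues=lam, axes=vec, degenerate=degenerate)


@dataclass
class PartStats:
    """Mean/sigma of anisotropy A and isotropic B over one atom subset."""

    n: int
    n_missing_u: int         # selected atoms without an ADP tensor
    n_non_positive: int      # tensors excluded as non-positive-definite
    mean_a: float | None
    sd_a: float | None
    mean_b: float | None
    sd_b: float | None


@dataclass
class AdpStats:
    """Per-selection ADP statistics split into all/main-chain/side-chain."""

    descriptor: str
    parts: dict[str, PartStats]  # keys: "all", "main_chain", "side_chain"

    def __getitem__(self, part: str) -> PartStats:
        return self.parts[part]


def selection_adp_stats(
    structure: CrystalStructure,
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
    altloc: str = "highest",
    population_sd: bool = True,
    polymer_only: bool = True,
) -> AdpStats:
    """Mean and sigma of anisotropy and isotropic B over a selection.

    Atoms without a U tensor are excluded from the anisotropy statistics and
    counted in ``n_missing_u``; non-positive-definite tensors are excluded
    with a warning rather than failing the run.  Isotropic-B statistics use
    the per-atom ``b_iso`` field of every (heavy) selected atom.
    """
    ddof = 0 if population_sd else 1
    parts: dict[str, PartStats] = {}
    descriptor = f"chain={chain or '*'} range={residue_range or 'all'}"
    for part in ("all", "main_chain", "side_chain"):
        try:
            sites = select_atoms(structure, chain=chain,
                                 residue_range=residue_range, part=part,
                                 altloc=altloc, polymer_only=polymer_only)
        except EmptySelectionError:
            parts[part] = PartStats(0, 0, 0, None, None, None, None)
            continue
        a_vals: list[float] = []
        b_vals: list[float] = []
        missing = 0
        non_pd = 0
        for site in sites:
            b_vals.append(site.atom.b_iso)
            if site.atom.u is None:
                missing += 1
                continue
            try:
                a_vals.append(anisotropy(site.atom.u))
            except NonPositiveDefiniteError as exc:
                non_pd += 1
                warnings.warn(
                    f"{site.residue.label}/{site.atom.name}: non-positive-"
                    f"definite U (lambda_min={exc.lambda_min:.2e}); excluded",
                    stacklevel=2)

        def _stats(vals: list[float]) -> tuple[float | None, float | None]:
            if not vals or len(vals) <= ddof:
                return (None, None) if not vals else (float(np.mean(vals)), None)
            arr = np.asarray(vals)
            return float(arr.mean()), float(arr.std(ddof=ddof))

        mean_a, sd_a = _stats(a_vals)
        mean_b, sd_b = _stats(b_vals)
        parts[part] = PartStats(n=len(sites), n_missing_u=missing,
                                n_non_positive=non_pd, mean_a=mean_a,
                                sd_a=sd_a, mean_b=mean_b, sd_b=sd_b)
    if all(p.n == 0 for p in parts.values()):
        raise EmptySelectionError(f"ADP selection matched no atoms ({descriptor})")
    if parts["all"].n > 0 and parts["all"].n == parts["all"].n_missing_u:
        raise EmptySelectionError(
            f"no atom in the selection carries an ADP tensor ({descriptor})")
    return AdpStats(descriptor=descriptor, parts=parts)
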