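# Methods

This note documents the conventions, defaults and numerical choices behind
`latticetrap`, and what its synthetic fixtures do and do not emulate.

## Model of a crystal

A crystal form is represented as one asymmetric unit (the deposited
coordinates) plus a unit cell `(a, b, c, α, β, γ)` and a space group given
by its Hermann–Mauguin symbol.  The full lattice is the orbit of the
asymmetric unit under all operators `x' = R x + t` (fractional space)
combined with integer lattice translations.  Operators come from gemmi's
space-group database — any symbol gemmi knows is accepted, which covers all
230 groups rather than only the handful a hand-built table would; explicit
triplet strings (`-x,y+1/2,-z`) are parsed for anything unusual.  Operator
rotations and translations are snapped to the 1/24 fractional grid (every
crystallographic translation lives on it) so that composed and inverted
operators compare exactly.

Fractional↔Cartesian conversion uses the standard orthogonalization with
**a** along x and **b** in the xy plane; it is cross-checked against gemmi
to 1e-9 Å in the tests.

Only single-model files are accepted; multi-model ensembles are rejected
rather than silently reduced to model 1.  ANISOU integers are U·10⁴ Å²;
when writing, U is quantized back to that grid so writing is idempotent.
Hydrogens (riding hydrogens from anisotropic refinement) are excluded from
every analysis by default; a flag re-includes them.  Author numbering
(chain, residue number, insertion code) is the residue key throughout;
bound-peptide positions (…, −1, 0) are simply whatever author numbers the
depositor used, and range filters operate on those.

## Lattice neighborhood and contacts

A symmetry-mate image is included when at least one of its atoms lies
within the cutoff of any reference atom.  Candidate lattice translations
are bounded per operator by fractional bounding boxes: the fractional
offset of two points along axis *k* is at most their Cartesian distance
divided by the perpendicular cell width along *k*, so a cutoff margin in
each axis suffices.  This makes the search correct for molecules placed
anywhere, not just inside the origin cell, and results are invariant under
whole-lattice shifts of the reference (tested).  Enumeration order
(operator index, then translation lexicographic) is deterministic.
Distance queries use a k-d tree; tests require identity with an all-pairs
brute-force scan.

A **contact** is a (reference atom, mate image atom) pair below the cutoff,
3.5 Å by default.  Contacts are counted per reference molecule: the images
at +**a** and −**a** both count, which is the convention under which a
single atom in a 3 Å cubic P1 cell has exactly six contacts.  Published
contact totals rarely define their unit, so the report also carries the
collapsed unique-molecule-pair count (each contact identified with its
mirror image seen from the mate's frame), distinct reference atoms,
distinct reference residues, and residue-pair counts.  Waters, ions and
other non-polymer residues are excluded by default (`--include-het`
overrides); for alternate conformers the highest-occupancy conformer is
used (ties toward altloc A), with `expand` and `first` policies available.

`nearest_mate_distance` reports the minimum residue-to-lattice distance
within a search radius (default 8 Å), or none beyond it.

## Surface areas

SASA is computed by Shrake–Rupley sphere-point sampling: each atom's
solvent sphere (van der Waals radius + probe, probe 1.4 Å) is sampled with
a deterministic Fibonacci (golden-angle) lattice, 960 points per atom by
default, and a point is accessible when outside every neighbor's solvent
sphere.  The radius set is Bondi (C 1.70, N 1.55, O 1.52, S 1.80 … Å),
hard-coded and documented in `packing.VDW_RADII`; unknown elements raise.
A lone atom reproduces its analytic sphere to <0.5 % at 960 points.
Parity with any particular accessibility program is approximate — a
different radius set or quadrature shifts totals by a few percent — which
is why cross-program comparisons should use ~5 % tolerances.

**Lattice burial** is SASA(molecule alone) − SASA(molecule surrounded by
mate atoms).  Mate atoms occlude but are not reported.  Occlusion range is
bounded by 2·(r_max + probe), so the neighborhood is generated at exactly
that radius.  The independent oracle for tests is a dense random-direction
sampler (seeded, ≥10⁵ points per atom available) that shares no point set
with the production quadrature; agreement is required within 2 %.

## Solvent content

Matthews coefficient `V_M = V_cell / (n_ops · Z · MW)` with `n_ops` the
space-group order and Z molecules per asymmetric unit; solvent fraction
`1 − 1.230/V_M` with the standard protein partial-specific-volume constant
1.230.  MW defaults to a sequence-based estimate (average residue masses).
Unphysical fractions are returned with a warning, plus a clamped accessor.

## Superposition and per-residue deltas

Two forms are aligned **once** by a Kabsch (SVD) least-squares fit on
main-chain atoms {N, CA, C, O} of the common residue range (configurable);
the rotation is forced proper, so a reflection is never returned even for
near-planar selections.  All per-residue quantities are then measured in
that fixed frame without local re-fitting — the convention that makes a
residue with an unmoved backbone show ~0 main-chain RMSD while its side
chain swings.  Per-residue side-chain RMSD uses all non-hydrogen,
non-main-chain atoms matched by name (OXT counts as side chain under the
strict {N, CA, C, O} main-chain definition); mismatched atom content is
flagged per residue, never silently dropped.

Dihedrals follow the IUPAC sign convention (cis 0°, trans 180°), computed
with the atan2 formulation, range (−180°, 180°]; χ atom quadruples follow
the standard rotamer-library definitions embedded in `compare.CHI_ATOMS`.
χ deltas are signed and wrapped; rankings use absolute values.  Dihedrals
are invariant under the global superposition, so form B's χ angles are
computed in its own frame.

Across-form conformer pairing uses the selected altloc policy; within one
structure, dual conformers are compared directly per altloc
(`chi_angles(residue, altloc)`), which is how an engineered 130° χ1 split
at 0.5/0.5 occupancy is verified.

## ADP analysis

`A = λ_min/λ_max` from an eigendecomposition of the symmetric U tensor;
inputs asymmetric beyond 1e-8 are symmetrized with a warning;
non-positive-definite tensors raise (single-tensor API) or are excluded
with a warning and counted (selection statistics).  `B_eq = 8π² tr(U)/3`.
Principal axes are reported descending with the first nonzero component
positive; near-degenerate eigenvalues flag the axes as unstable.
Selection statistics use the population σ (divide by n) by default —
the common convention in crystallographic reports — with sample σ behind a
flag; atoms lacking tensors are excluded from A statistics and counted in a
coverage field.  Isotropic-B statistics use the per-atom B column.

## Synthetic fixtures

The generator builds an ideal α-helical peptide (φ −57°, ψ −47°, ω 180°,
standard bond lengths/angles, NeRF construction) from Gly/Ala/Ser/Arg/His
— the residue types needed to exercise χ1–χ4, rings and dual conformers —
places it in a chosen cell and space group by a seeded random rotation at
a chosen fractional center, and assigns each atom a U tensor with exact
target anisotropy and B_eq (eigenvalues `λ_max·(1, (1+A)/2, A)` in a
seeded random orientation; default A 0.5, B_eq 20 Å², large enough that
ANISOU rounding perturbs A by <1e-3).  `b_iso` is set to B_eq(U), keeping
files self-consistent.  Engineered χ moves rebuild the second form with
shifted χ targets, so each move is exact by construction; dual conformers
duplicate the atoms distal to the χ1 bond with prescribed occupancies.

Ground truth accompanying each fixture: brute-force contact pairs (naive
all-pairs scan over operators and a generous translation cube), per-atom
anisotropy as assigned, and buried area from the dense random oracle.
Placements that clash with their own symmetry images (closest image atom
< 1.2 Å) are rejected with an error; `make_fitting_*` wrappers redraw
deterministically (seed + 1000·k) until the chain fits, so all randomness
still flows from one seed.

What the fixtures do **not** emulate: real packing energetics (placements
are geometric, not minimized), realistic B-factor gradients along side
chains, correlated ADPs (each atom's tensor orientation is independent),
solvent/ion content, and realistic solvent fractions (a short peptide in a
small cell is mostly empty space, so Matthews numbers of toys are large).
Passing tests therefore demonstrate the correctness of the *measurement
machinery* — symmetry expansion, surface quadrature, superposition,
tensor algebra — not the realism of any particular crystal.

## Pipeline and flag rule

`compare_forms` joins packing, conformational and ADP measurements into
one per-residue table.  The packing-induced-change flag is deliberately
explicit: side-chain RMSD ≥ 0.5 Å (configurable) **and** a changed packing
environment — the residue is within the contact cutoff of the lattice in
exactly one form, or its sets of contact-partner residues differ.  A list
of ligand-interacting residues is domain knowledge the user supplies as
annotation; the report does not hard-code one.  Reports render with fixed
3-decimal formatting, so identical inputs give byte-identical TSV, JSON
(schema-versioned) and markdown.

## Problem sizes and defaults

Toy fixtures use 4–6 residue chains (30–45 heavy atoms) in 16–30 Å cells —
large enough to produce tens of symmetry contacts and exercise all three
supported lattices (P1, P2₁, P3₁21 in the hexagonal setting), small enough
that the brute-force and dense-sampling oracles run in seconds.  The
acceptance study uses a 6-residue chain with a 90° Arg χ2 move, a 130° His
χ2 move, a 130° Ser χ1 dual conformer, and per-form anisotropy targets
0.489/0.337 — the magnitudes characteristic of rotamer trapping between a
tightly and a loosely packed form.  Analyses of real deposited structures
(~700 protein atoms) run in a few seconds per form with the same defaults
(960 sphere points; 8 Å nearest-mate radius; ±2 minimum translation
shells).

## Known limitations

* Residue correspondence is by author numbering only; forms with different
  numbering need renumbering first (a mismatch raises, it is not guessed).
* The toy builder's His ring closes only approximately (ideal internal
  coordinates, no ring-closure refinement); χ1/χ2 are exact, ring-internal
  geometry is near-ideal.
* SASA treats alternate conformers under one policy at a time; it does not
  occupancy-weight partial conformers within one calculation.
* No non-crystallographic symmetry, twinning, or interface classification
  (crystallographic vs biological); contacts are geometric, not energetic.
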