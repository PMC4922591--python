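# Methods

This note documents the models and procedures implemented in
`enmexplore`, the assumptions behind them, the parameters that matter,
and what the synthetic test world does and does not establish.

## Elastic network model

Residues are network nodes placed at the arithmetic mean of their
heavy-atom positions. Hydrogens are excluded both from centroids and
from contact counting: they are absent from most crystal structures, and
excluding them keeps spring weights resolution-independent. The spring
constant between residues i and j is

    k_ij = γ · (number of heavy-atom pairs, one atom from each residue,
                within the contact cutoff)

with cutoff 10 Å and a uniform base force constant γ = 1 in arbitrary
units. Only relative spring strengths and mode shapes matter downstream,
because the deformation step renormalizes amplitude to a fixed RMSD;
γ therefore carries no physical meaning and is not exposed as a knob.

The Hessian uses the standard anisotropic-network super-elements
H_ij = −k_ij d d^T / |d|² (d the centroid difference vector), with
diagonal blocks equal to minus the sum of the off-diagonal blocks in
their row. This matrix is symmetric positive semidefinite with exactly
six null modes (rigid translations and rotations) for a connected
network.

Numerical choices:

* Dense `eigh` diagonalization throughout. The systems this package
  targets (hundreds of residues, 3N in the low thousands) diagonalize in
  seconds; a sparse solver would add code paths without benefit at this
  scale.
* Rigid-body modes are removed by a relative eigenvalue threshold
  (|λ| ≤ 1e-8 · λ_max), not by explicit projection. More than six
  near-zero eigenvalues raises a connectivity error: it means the
  network is disconnected or contains an internal mechanism, and slow
  "modes" of such a network are meaningless.
* Eigenvector sign is fixed by making the first component above 1e-10
  positive. Signs of eigenvectors are arbitrary; a deterministic
  convention makes reruns bit-for-bit reproducible. Because coefficient
  tuples are enumerated symmetrically (c and −c both occur), the
  convention does not bias the search.

## Deformation

The M slowest modes are combined with coefficients a_j ∈ {−1, 0, +1},
each mode weighted by 1/λ_j^{1/2} so that softer modes contribute larger
amplitude, and the combined vector is rescaled to norm DF·√N. This makes
the per-node displacement RMS exactly DF — the *deformation RMSD* — for
every direction. DF defaults to 2 Å, with 3 Å appropriate for extreme
transitions (≈15 Å); the synthetic-fixture tests use 1 Å, scaled to the
fixture's 60 residues and 5 Å transition. The magnitude contract is
defined on the raw displacement (no re-superposition), which makes it
exact; the optimally fitted RMSD between parent and child is reported
separately and can only be smaller.

All atoms of a residue are translated rigidly by their node's
displacement. No side-chain rebuilding or torsion-space correction is
attempted: repairing local distortion is the relaxation step's job.

With M = 3 and the {−1, 0, +1} alphabet, each parent yields
3³ − 1 = 26 children per generation. The per-mode coefficient alphabet
and M are configurable; the all-zero tuple is always excluded.

## Relaxation backends

The production minimization protocol is defined as a backend contract
(`implicit_solvent`): 500 steepest-descent cycles followed by conjugate
gradient to a 0.01 kcal/mol/Å gradient under a pairwise generalized-Born
implicit solvent, 16 Å nonbonded cutoff, 0.1 M monovalent salt treated
by Debye–Hückel screening. The adapter raises a configuration error
naming the missing molecular-mechanics engine when unavailable; this
package deliberately does not reimplement force-field physics.

The shipped `fallback` backend minimizes a fully specified surrogate:

* harmonic pseudo-bonds between sequential Cα atoms of each chain,
  k = 10 energy/Å², rest lengths taken from the *reference* structure
  (the parent conformer for deformed children) so the bonded term is
  zero at the reference geometry and relaxation preserves chain
  connectivity rather than inventing it;
* soft-sphere repulsion E = ε(σ − d)² for heavy-atom pairs closer than
  σ = 3.0 Å, with ε = 1 energy/Å², excluding pairs within the same or
  sequence-adjacent residues of one chain (those are covalently bonded
  neighbours, not clashes).

Minimization uses L-BFGS-B with an analytic gradient and is
deterministic. These constants exist for testability — clash relief and
connectivity — not physical fidelity. Two consequences are documented
rather than hidden: energies are comparable only within one backend (the
engine asserts a single backend per run), and because a clash-free
structure scores exactly zero, the surrogate's energy-based search
degenerates — no child can fall strictly below a clash-free reference,
so energy-based runs terminate after one generation. That reproduces the
real phenomenon seen for proteins whose entire first generation is
uphill in energy, and it is the correct behaviour of the selection rule
under this potential, but it means the energy-based mode's scientific
value is only realized with a physical backend.

`energy_of` evaluates the same potential with the structure itself as
bond reference, i.e. it measures clashes only; a clash-free structure
scores 0 by construction.

## Clustering

Structures are clustered by mutual optimally-fitted Cα RMSD with a fixed
cluster radius equal to DF — the deformation step's resolution — using a
spawn-on-overflow k-means variant: a structure joins the nearest
existing centroid within the radius, otherwise it seeds a new cluster.
Centroids are recomputed after every assignment pass by superposing each
member onto the cluster representative and averaging Cα coordinates; the
averaged structure is used only for distances and never emitted as a
conformer. The representative — the real member closest to the
centroid — is what gets promoted. The first assignment pass processes
structures in a seeded random order; subsequent passes are in input
order; the procedure is deterministic for a fixed seed and input order.
Non-convergence within `max_iterations` (default 100) returns the last
assignment flagged unconverged. Ties in representative selection fall to
the earliest pool index.

Whether cluster centers should be coordinate averages or medoids was an
open choice; coordinate averages were adopted, with the medoid-like
representative always being a real member, so no averaged (potentially
unphysical) structure ever propagates.

## The generation engine

Per generation: every eligible parent is deformed along all 26
directions (modes recomputed on that parent, which is what lets the
search follow curved transition paths); children are relaxed, and
relaxation failures are discarded; surviving children are pooled with
*all* ancestors (every representative emitted so far, not just the
immediate parents) and clustered at radius DF; representatives of
ancestor-free clusters become the next generation. Pooling all ancestors
prevents the search from re-visiting territory already covered in any
earlier generation; a previous-generation-only variant was considered
and rejected because it allows slow oscillation between adjacent basins.

Termination: a mandatory `max_generations` in blind mode (the stopping
point of an unbiased search is inherently user-dependent); additionally,
exhaustion (no ancestor-free cluster) in either mode, the energy rule in
energy-based mode, and an optional total-conformer budget
(`max_conformers`) for large systems.

The radius-of-gyration filter runs *after* the search, never during it:
conformers with whole-structure RG above the apo RG are discarded at
reporting/export time (boundary inclusive — equal compactness is kept).
For multimers the filter can be applied per chain: a conformer survives
if at least one chain (optionally: every chain) is at least as compact
as the same chain of the start structure. Keeping the filter out of the
search loop preserves the unbiased contract; so does evaluation —
RMSD-to-reference is computed only when a reference is supplied and
never feeds back.

The docking chain is the lowest-RG surviving conformer (ties: lowest id)
plus its parents up to the apo root, exported root-first as a
multi-MODEL PDB.

Re-seeded runs on a ligand-bound complex use the identical engine; the
ligand chains are ordinary network nodes that shape the modes and move
with the deformation. The generation-0 reference energy is that of the
minimized complex (receptor-only versus complex reference was an open
choice; the complex is used because generation 0 *is* the minimized
input, and the choice is logged prominently). Receptor-only metrics are
obtained downstream by chain subsetting.

## Structure handling

PDB input is parsed with Biopython. Alternate locations collapse to the
highest-occupancy conformer (ties by altLoc label order); hydrogens are
kept but flagged; waters are dropped, and non-standard HETATM residues
are dropped by default behind a keep flag. Residues carry a 0-based
contiguous internal index; author numbering is preserved for output.
Cα RMSD between two structures pairs residues by author numbering over
the common residue set of shared chains (falling back to order when
numbering schemes are disjoint); no sequence alignment is attempted —
the intended comparisons are between conformers of the same protein.
Superposition is the closed-form Kabsch/SVD solution with the proper
rotation (det +1) branch; the radius of gyration is mass-unweighted over
Cα atoms.

## The synthetic test world

`make_hinge` builds the caricature of a hinge protein the tests run on:
two tower-shaped domains (2×2×⌈n/4⌉ lattice walks, 4.2 Å constant) stand
on a common hinge line, their facing surfaces within contact range only
near that line; the 4 linker residues lie *on* the hinge axis; and the
open state is wedged apart by 45°. Every relative domain motion except
rotation about the hinge line stretches contact springs at first order,
so the hinge bend is the unique soft mode — the slowest-mode overlap
with the open→closed displacement is ≈0.99 across seeds, which is the
load-bearing property making closed-state recovery a fair test for a
3-mode search. (An earlier design with an off-axis zigzag linker strand
was abandoned: chain-of-nodes linkers carry floating mechanisms — nodes
whose springs are coplanar — that contaminate the null space.) The
closed reference rotates the second domain about the hinge line by an
angle solved numerically (Brent) to hit the requested open/closed RMSD;
residues use a reduced 5-atom model (N, CA, C, O, CB as sub-Å offsets
around the Cα) with seeded 0.03 Å jitter; both states are clash-free
(surrogate energy exactly 0); everything is a deterministic function of
the seed. Reference PDBs are not committed — the generators are
bit-reproducible, and tests regenerate fixtures at run time.

What the fixture does *not* emulate: real side-chain packing, secondary
structure, sequence effects, rugged energy landscapes, or any force-field
energetics. A green hinge-recovery test establishes that the
deform–relax–cluster–select loop can track a curved, large-amplitude
hinge closure when the slow modes contain it; it does not establish
force-field-level accuracy, energy-based selection efficacy, or
performance on transitions (like extended→collapsed calmodulin) where
the softest modes correlate poorly with the transition.

## Known limitations

* No molecular-mechanics backend ships with the package; energy-based
  search is only scientifically meaningful with one bound in.
* No sequence alignment: apo/holo comparisons require consistent author
  numbering or identical residue counts.
* Missing loops, protonation and other structure-preparation issues are
  out of scope and must be fixed upstream.
* The cluster count — and hence run time — grows with generations;
  `max_conformers` is the coarse control. The dominant costs are
  relaxation (per child) and clustering (quadratic-ish in pool size, but
  batched SVD keeps constants small).
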