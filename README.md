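# enmexplore

Iterative, unbiased conformer generation for proteins that undergo large
apo→holo transitions (hinge-bending domain closures of 4–15 Å backbone
RMSD). Starting from nothing but an unbound (apo) structure, the pipeline
walks outward through conformational space along the protein's slowest
elastic-network modes, producing close-to-bound and intermediate states —
together with their full parent lineage — for use as receptor ensembles in
flexible docking.

Intended users are structural bioinformaticians and docking practitioners
who need bound-like receptor conformations when no holo structure exists.

## The algorithm

One *generation* applies these steps to every eligible parent conformer
(generation 0 is the energy-minimized apo structure):

1. **Elastic network.** Each residue becomes a node at its heavy-atom
   centroid. Node pairs interact through harmonic springs whose strength
   k_ij equals the number of heavy-atom pairs between the two residues
   within a 10 Å cutoff, so well-packed interfaces are stiffer than
   grazing contacts. The anisotropic-network Hessian of this network is
   diagonalized and, after discarding the six rigid-body null modes, the
   M = 3 slowest eigenpairs (u_j, λ_j) are kept.
2. **Deformation.** All coefficient combinations a_j ∈ {−1, 0, +1}
   (excluding all-zero; 3³ − 1 = 26 for three modes) are formed as

       V = Σ_j a_j u_j / λ_j^{1/2},   v = DF · N^{1/2} · V / |V|

   so softer modes contribute more, and every deformation has per-residue
   displacement RMS exactly equal to the deformation RMSD **DF**
   (default 2 Å; 3 Å for very large transitions). Each residue's
   displacement is applied rigidly to all atoms of that residue.
3. **Relaxation.** Every deformed child is energy-minimized to repair
   distortions and assigned an energy. The production protocol —
   steepest descent then conjugate gradient under a generalized-Born
   implicit solvent — is a pluggable backend contract; the shipped
   `fallback` backend minimizes a documented surrogate potential
   (sequential-Cα pseudo-bonds + soft-sphere repulsion) so the complete
   pipeline runs with zero external dependencies.
4. **Clustering.** Relaxed children are pooled with all ancestor
   structures and clustered by mutual Cα RMSD with cluster radius DF
   (fixed-radius, spawn-on-overflow k-means). The representative of every
   cluster containing no ancestor — the member closest to the cluster
   average — is promoted to parent of the next generation.

The search is **blind** (no information about the bound state) or
**energy-based**: only conformers with energy strictly below the
minimized apo reference may parent the next generation, and the run ends
when none exist. After the run, conformers more expanded than the apo
structure (radius of gyration above the apo RG) are discarded, and the
docking chain — the most compact surviving conformer plus its parents up
to the apo root — is exported as a multi-MODEL PDB ensemble. A bound
complex can be re-seeded into a second-stage run (`reseed_with_ligand`)
in which the ligand's residues are ordinary network nodes.

## Worked example

Generate a synthetic two-domain hinge protein (60 residues, open and
closed states 5 Å apart), run a blind search, and evaluate against the
known closed state:

```bash
enmexplore fixtures --kind hinge --n 28 --rmsd 5.0 --seed 2 --out fx/
enmexplore run --apo fx/open.pdb --df 1.0 --modes 3 --max-gens 5 \
    --backend fallback --seed 2 --out run/
enmexplore chain --run run/ --out chain.pdb
enmexplore eval --run run/ --holo fx/closed.pdb --out eval.tsv
```

The same workflow through the library (seed 1) prints:

```
blind search, seed 1: 207 conformers, 75 after RG filter,
min RMSD to closed reference 1.44 A (g5.c101);
docking chain g0.c00 -> g1.c04 -> g2.c11 -> g3.c27 -> g4.c54 -> g5.c101
```

Reading: the 5-generation blind run produced 207 distinct conformers
(clusters); 75 are at least as compact as the start structure and survive
the RG post-filter; the best conformer lies 1.44 Å (Cα RMSD) from the
closed reference the search never saw; the docking chain traces that
family from the apo root through one representative per generation.
Conformer ids are `g<generation>.c<index>`.

For experimental structures, point `--apo` at any single- or multi-chain
PDB file and supply a holo PDB to `enmexplore eval` to reproduce
min-RMSD/compactness summary tables.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's core computation from scratch: it builds the hinge
fixture for the given seed, executes the full blind search with the
fallback relaxation backend, evaluates every conformer against the closed
reference, applies the RG post-filter, extracts the docking chain, and
prints the run summary before writing the JSON manifest.
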