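"""Energy relaxation of deformed conformers.

The production protocol this module targets is an implicit-solvent
molecular-mechanics minimization (steepest descent followed by conjugate
gradient under a generalized-Born solvent model with Debye-Hueckel salt
screening). That engine is a *backend contract* here: the adapter raises
a configuration error naming the missing dependency unless a molecular
mechanics engine is importable, so the rest of the pipeline never depends
on one being installed.

The shipped ``fallback`` backend minimizes a fully documented surrogate
potential instead:

* harmonic pseudo-bonds between sequential C-alpha atoms within a chain,
  restrained to their distances in the input structure
  (k = 10 energy / A^2);
* soft-sphere repulsion between heavy atoms of non-adjacent residues,
  quadratic below sigma = 3.0 A: E = eps * (sigma - d)^2 for d < sigma.

This is enough to relieve steric clashes and keep the chain connected,
which is all the generation engine needs from relaxation; the constants
exist for testability, not physical fidelity. Energies are comparable
only within a single backend.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial import cKDTree

from .structio import Structure

__all__ = [
    "RelaxConfig",
    "RelaxResult",
    "BackendUnavailableError",
    "SurrogatePotential",
    "minimize",
    "energy_of",
    "PSEUDO_BOND_K",
    "SOFT_SPHERE_SIGMA",
    "SOFT_SPHERE_EPS",
]

PSEUDO_BOND_K = 10.0  # energy / A^2
SOFT_SPHERE_SIGMA = 3.0  # A
SOFT_SPHERE_EPS = 1.0  # energy / A^2


class BackendUnavailableError(RuntimeError):
    """Requested relaxation backend cannot be provided in this install."""


@dataclasses.dataclass(frozen=True)
class RelaxConfig:
    backend: str = "fallback"  # "implicit_solvent" | "fallback" | "none"
    sd_steps: int = 500
    gradient_tolerance: float = 0.01  # kcal/mol/A (backend scale)
    nonbonded_cutoff: float = 16.0  # A
    salt_concentration: float = 0.1  # M
    max_cg_steps: int = 10_000

    def __post_init__(self):
        if self.gradient_tolerance <= 0 or self.nonbonded_cutoff <= 0:
            raise ValueError("tolerance and cutoff must be positive")


@dataclasses.dataclass
class RelaxResult:
    structure: Structure
    energy: float
    converged: bool
    backend_used: str


class SurrogatePotential:
    """Pseudo-bond + soft-sphere surrogate for one structure topology.

    Bond reference distances come from the reference structure handed to
    the constructor (the parent conformer, for deformed children), so the
    bonded term is zero there and minimization only relieves clashes.
    """

    def __init__(self, reference: Structure):
        self.reference = reference
        ca = reference.ca_indices()
        res_of_ca = reference.atom_residue[ca]
        chains = np.array(
            [reference.residue_table[r].chain_id for r in res_of_ca]
        )
        same_chain = chains[:-1] == chains[1:]
        self.bond_i = ca[:-1][same_chain]
        self.bond_j = ca[1:][same_chain]
        d = reference.coords[self.bond_i] - reference.coords[self.bond_j]
        self.bond_ref = np.linalg.norm(d, axis=1)
        self.heavy_idx = np.nonzero(reference.is_heavy)[0]
        self.heavy_res = reference.atom_residue[self.heavy_idx]
        chain_of_res = [k.chain_id for k in reference.residue_table]
        chain_codes = {c: i for i, c in enumerate(dict.fromkeys(chain_of_res))}
        self.res_chain = np.array([chain_codes[c] for c in chain_of_res])

    def _clash_pairs(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xyz = coords[self.heavy_idx]
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(SOFT_SPHERE_SIGMA, output_type="ndarray")
        if pairs.size == 0:
            empty = np.empty(0, dtype=int)
            return empty, empty
        ri = self.heavy_res[pairs[:, 0]]
        rj = self.heavy_res[pairs[:, 1]]
        # atoms of the same or sequence-adjacent residues (within one chain)
        # are bonded neighbours, not clashes
        bonded = (np.abs(ri - rj) <= 1) & (self.res_chain[ri] == self.res_chain[rj])
        keep = ~bonded
        return self.heavy_idx[pairs[keep, 0]], self.heavy_idx[pairs[keep, 1]]

    def energy_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = coords.reshape(-1, 3)
        grad = np.zeros_like(coords)
        energy = 0.0
        # bonded term
        dvec = coords[self.bond_i] - coords[self.bond_j]
        d = np.linalg.norm(dvec, axis=1)
        delta = d - self.bond_ref
        energy += PSEUDO_BOND_K * float((delta ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(d[:, None] > 0, dvec / np.maximum(d, 1e-12)[:, None], 0.0)
        f = 2.0 * PSEUDO_BOND_K * delta[:, None] * unit
        np.add.at(grad, self.bond_i, f)
        np.add.at(grad, self.bond_j, -f)
        # soft-sphere term
        ci, cj = self._clash_pairs(coords)
        if ci.size:
            dvec = coords[ci] - coords[cj]
            d = np.linalg.norm(dvec, axis=1)
            overlap = SOFT_SPHERE_SIGMA - d
            energy += SOFT_SPHERE_EPS * float((overlap ** 2).sum())
            unit = dvec / np.maximum(d, 1e-12)[:, None]
            f = -2.0 * SOFT_SPHERE_EPS * overlap[:, None] * unit
            np.add.at(grad, ci, f)
            np.add.at(grad, cj, -f)
        return energy, grad.ravel()

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_gradient(coords)[0]


def _fallback_minimize(
    structure: Structure, config: RelaxConfig, reference: Structure | None = None
) -> RelaxResult:
    pot = SurrogatePotential(reference if reference is not None else structure)
    x0 = structure.coords.ravel().copy()
    e0, g0 = pot.energy_gradient(x0)
    tol = config.gradient_tolerance
    if np.abs(g0).max() <= tol:
        return RelaxResult(structure.with_coords(x0), float(e0), True, "fallback")
    res = _scipy_minimize(
        pot.energy_gradient,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.max_cg_steps, "gtol": tol, "ftol": 1e-12},
    )
    energy = float(res.fun)
    if not np.isfinite(energy):
        return RelaxResult(structure, float("nan"), False, "fallback")
    _, g = pot.energy_gradient(res.x)
    converged = bool(np.abs(g).max() <= tol)
    return RelaxResult(structure.with_coords(res.x), energy, converged, "fallback")


def _implicit_solvent_minimize(structure: Structure, config: RelaxConfig) -> RelaxResult:
    try:
        import openmm  # noqa: F401
    except ImportError as exc:
        raise BackendUnavailableError(
            "implicit_solvent backend requires the 'openmm' molecular "
            "mechanics engine, which is not installed; use backend='fallback'"
        ) from exc
    raise BackendUnavailableError(
        "implicit_solvent adapter is a contract stub in this build"
    )


def minimize(
    structure: Structure, config: RelaxConfig, reference: Structure | None = None
) -> RelaxResult:
    """Relax a conformer and report its energy under the chosen backend.

    ``reference`` supplies the pseudo-bond rest distances for the surrogate
    backends (the parent conformer, for deformed children); when omitted
    the structure's own distances are used, so the bonded term vanishes at
    the input geometry.
    """
    if config.backend == "fallback":
        return _fallback_minimize(structure, config, reference)
    if config.backend == "none":
        pot = SurrogatePotential(structure)
        return RelaxResult(structure, pot.energy(structure.coords), True, "none")
    if config.backend == "implicit_solvent":
        return _implicit_solvent_minimize(structure, config)
    raise ValueError(f"unknown backend {config.backend!r}")


def energy_of(structure: Structure, config: RelaxConfig) -> float:
    """Single-point energy without moving atoms (backend scale).

    For the surrogate backends the pseudo-bond reference is the structure
    itself, so a clash-free structure scores exactly zero.
    """
    if config.backend in ("fallback", "none"):
        return SurrogatePotential(structure).energy(structure.coords)
    if config.backend == "implicit_solvent":
        return _implicit_solvent_minimize(structure, config).energy
    raise ValueError(f"unknown backend {config.backend!r}")
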