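"""Iterative generation engine.

One *generation* deforms every eligible parent along all combinations of
the slowest network modes at a fixed deformation RMSD, relaxes each child
(discarding relaxation failures), pools the relaxed children with every
ancestor structure, clusters the pool at radius DF, and promotes the
representative of each parent-free cluster to the next generation.
Generation 0 is the relaxed input structure.

Two search modes are supported. *Blind* search imposes no knowledge of
the bound state and stops at ``max_generations`` (or when no new cluster
appears). *Energy-based* search additionally requires a conformer's
energy to lie strictly below the generation-0 reference before it may
parent the next generation, and terminates when no such conformer exists.

Radius-of-gyration filtering is applied after the run, never during it:
conformers more expanded than the start structure are discarded when
assembling the docking chain, but the search itself stays unbiased.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import clustering, deform, enm, relax, structio
from .structio import Structure

__all__ = [
    "Conformer",
    "ExploreConfig",
    "LineageTree",
    "run",
    "energy_filter",
    "rg_filter",
    "docking_chain",
    "reseed_with_ligand",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Conformer:
    id: str
    structure: Structure
    energy: float
    rg: float
    generation: int
    parent_id: str | None
    rg_per_chain: dict[str, float] = dataclasses.field(default_factory=dict)
    coefficients: tuple[float, ...] | None = None
    rmsd_to_reference: float | None = None


@dataclasses.dataclass(frozen=True)
class ExploreConfig:
    mode: str = "blind"  # "blind" | "energy_based"
    DF: float = 2.0  # deformation RMSD, A
    n_modes: int = 3
    max_generations: int = 7
    enm_cutoff: float = 10.0
    relax: relax.RelaxConfig = dataclasses.field(default_factory=relax.RelaxConfig)
    cluster_seed: int = 0
    rg_filter_scope: str = "global"  # "global" | "per_chain"
    ligand_chains: tuple[str, ...] = ()
    max_conformers: int | None = None  # optional size-based termination

    def __post_init__(self):
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.DF <= 0:
            raise ValueError("DF must be positive")
        if self.mode not in ("blind", "energy_based"):
            raise ValueError(f"unknown search mode {self.mode!r}")


class LineageTree:
    """Conformers across generations with child -> parent edges."""

    def __init__(self) -> None:
        self.nodes: dict[str, Conformer] = {}
        self.generations: list[list[str]] = []

    @property
    def root_id(self) -> str:
        return self.generations[0][0]

    @property
    def edges(self) -> dict[str, str]:
        return {
            c.id: c.parent_id for c in self.nodes.values() if c.parent_id is not None
        }

    def add(self, conformer: Conformer) -> None:
        if conformer.id in self.nodes:
            raise ValueError(f"duplicate conformer id {conformer.id}")
        if conformer.generation >= 1 and conformer.parent_id not in self.nodes:
            raise ValueError(f"unknown parent {conformer.parent_id}")
        self.nodes[conformer.id] = conformer
        while len(self.generations) <= conformer.generation:
            self.generations.append([])
        self.generations[conformer.generation].append(conformer.id)

    def conformers(self) -> list[Conformer]:
        return [self.nodes[i] for g in self.generations for i in g]

    def lineage(self, leaf_id: str) -> list[Conformer]:
        """Chain of conformers from the root down to ``leaf_id``."""
        chain = [self.nodes[leaf_id]]
        while chain[-1].parent_id is not None:
            chain.append(self.nodes[chain[-1].parent_id])
        return chain[::-1]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "generations": self.generations,
            "nodes": [
                {
                    "id": c.id,
                    "generation": c.generation,
                    "parent_id": c.parent_id,
                    "energy": c.energy,
                    "rg": c.rg,
                    "rg_per_chain": c.rg_per_chain,
                    "coefficients": c.coefficients,
                }
                for c in self.conformers()
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _rg_maps(structure: Structure) -> tuple[float, dict[str, float]]:
    rg = structio.radius_of_gyration(structure)
    per_chain = {
        ch: structio.radius_of_gyration(structure, [ch]) for ch in structure.chain_ids
    }
    return rg, per_chain


def run(apo: Structure, config: ExploreConfig) -> LineageTree:
    """Execute the full iterative search starting from one structure."""
    tree = LineageTree()
    r0 = relax.minimize(apo, config.relax)
    if not r0.converged or not np.isfinite(r0.energy):
        raise RuntimeError("relaxation of the starting structure failed")
    rg0, rg0_chain = _rg_maps(r0.structure)
    root = Conformer(
        id="g0.c00",
        structure=r0.structure,
        energy=r0.energy,
        rg=rg0,
        generation=0,
        parent_id=None,
        rg_per_chain=rg0_chain,
    )
    tree.add(root)
    reference_energy = root.energy

    parents: list[Conformer] = [root]
    ancestors: list[Conformer] = [root]  # all representatives emitted so far
    spec = deform.DeformationSpec(DF=config.DF, M=config.n_modes)

    for gen in range(1, config.max_generations + 1):
        if (
            config.max_conformers is not None
            and len(tree.nodes) >= config.max_conformers
        ):
            logger.info("stopping: conformer budget (%d) reached", config.max_conformers)
            break
        children: list[tuple[Structure, float, str]] = []
        n_failed = 0
        for parent in parents:
            coarse = structio.coarse_grain(parent.structure)
            network = enm.build_network(coarse, parent.structure, config.enm_cutoff)
            modes = enm.slow_modes(enm.hessian(network), config.n_modes)
            for direction in deform.enumerate_directions(modes, spec):
                child = deform.apply_deformation(parent.structure, coarse, direction)
                result = relax.minimize(child, config.relax, reference=parent.structure)
                if not result.converged or not np.isfinite(result.energy):
                    n_failed += 1
                    continue
                children.append((result.structure, result.energy, parent.id))
        if gen == 1 and not children:
            raise RuntimeError("no conformer of the first generation survived relaxation")
        if not children:
            logger.info("generation %d: no relaxed children; stopping", gen)
            break

        pool_structures = [c[0] for c in children] + [a.structure for a in ancestors]
        pool_ids = [f"child{k}" for k in range(len(children))] + [a.id for a in ancestors]
        ancestor_ids = {a.id for a in ancestors}
        clusters = clustering.kcluster(
            pool_structures,
            clustering.ClusterConfig(radius=config.DF, seed=config.cluster_seed),
            ids=pool_ids,
            parent_ids=ancestor_ids,
        )
        rep_ids = clustering.select_representatives(clusters, ancestor_ids)
        if not rep_ids:
            logger.info("generation %d: no parent-free cluster; stopping", gen)
            break

        new_conformers: list[Conformer] = []
        for k, rep in enumerate(sorted(rep_ids, key=lambda s: int(s[5:]))):
            child_idx = int(rep[5:])
            structure, energy, parent_id = children[child_idx]
            rg, rg_chain = _rg_maps(structure)
            conf = Conformer(
                id=f"g{gen}.c{k:02d}",
                structure=structure,
                energy=energy,
                rg=rg,
                generation=gen,
                parent_id=parent_id,
                rg_per_chain=rg_chain,
            )
            tree.add(conf)
            new_conformers.append(conf)
        ancestors.extend(new_conformers)
        logger.info(
            "generation %d: %d children (%d failed relaxation), %d clusters, %d representatives",
            gen, len(children), n_failed, len(clusters), len(new_conformers),
        )

        if config.mode == "energy_based":
            parents = energy_filter(new_conformers, reference_energy)
            if not parents:
                logger.info(
                    "generation %d: no conformer below the reference energy; stopping",
                    gen,
                )
                break
        else:
            parents = new_conformers
    return tree


def energy_filter(
    candidates: Iterable[Conformer], reference_energy: float
) -> list[Conformer]:
    """Conformers with energy strictly below the reference."""
    return [c for c in candidates if c.energy < reference_energy]


def rg_filter(
    conformers: Iterable[Conformer],
    apo_rg: float | dict[str, float],
    scope: str = "global",
    require_all_chains: bool = False,
) -> list[Conformer]:
    """Discard conformers more expanded than the start structure.

    ``global`` compares whole-structure radii of gyration (boundary
    inclusive: equal RG is kept). ``per_chain`` keeps a conformer when at
    least one chain is at least as compact as the same chain of the start
    structure — set ``require_all_chains`` to demand it of every chain.
    """
    if scope == "global":
        if not isinstance(apo_rg, float | int):
            raise ValueError("global scope expects a scalar start RG")
        return [c for c in conformers if c.rg <= apo_rg]
    if scope == "per_chain":
        if not isinstance(apo_rg, dict):
            raise ValueError("per_chain scope expects a chain -> RG map")
        out = []
        for c in conformers:
            if set(c.rg_per_chain) != set(apo_rg):
                raise ValueError(
                    f"conformer {c.id} chains {sorted(c.rg_per_chain)} do not match "
                    f"start chains {sorted(apo_rg)}"
                )
            ok = [c.rg_per_chain[ch] <= apo_rg[ch] for ch in apo_rg]
            if (all(ok) if require_all_chains else any(ok)):
                out.append(c)
        return out
    raise ValueError(f"unknown scope {scope!r}")


def docking_chain(tree: LineageTree, filtered: Sequence[Conformer]) -> list[Conformer]:
    """Lineage from the root to the most compact filtered conformer.

    The conformer with the lowest radius of gyration (ties broken by
    lowest id) is the docking start point; the returned chain runs
    root -> ... -> that conformer.
    """
    if not filtered:
        raise ValueError("no conformer survived filtering")
    best = min(filtered, key=lambda c: (c.rg, c.id))
    return tree.lineage(best.id)


def reseed_with_ligand(complex_structure: Structure, config: ExploreConfig) -> LineageTree:
    """Second-stage run on a ligand-bound complex.

    The ligand chains named in the config are ordinary network nodes:
    they carry springs, shape the slow modes and move with the
    deformation. The generation-0 reference energy is that of the
    minimized complex (receptor-only metrics are reported downstream).
    With no ligand chains configured this is exactly :func:`run`.
    """
    missing = set(config.ligand_chains) - set(complex_structure.chain_ids)
    if missing:
        raise ValueError(f"ligand chain(s) {sorted(missing)} not found in complex")
    if config.ligand_chains:
        logger.info(
            "re-seeded run: reference energy is the minimized complex "
            "(ligand chains %s included as network nodes)",
            ",".join(config.ligand_chains),
        )
    return run(complex_structure, config)
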