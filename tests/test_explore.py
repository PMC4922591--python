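"""Generation engine: search loop, filters, lineage and re-seeding."""

import numpy as np
import pytest

from enmexplore import explore, fixtures, relax, structio
from enmexplore.explore import Conformer, ExploreConfig
from enmexplore.structio import Structure

from conftest import build_structure


def make_conformer(cid, gen, energy=0.0, rg=10.0, parent=None, structure=None,
                   rg_per_chain=None):
    return Conformer(id=cid, structure=structure, energy=energy, rg=rg,
                     generation=gen, parent_id=parent,
                     rg_per_chain=rg_per_chain or {})


def attach_peptide(receptor, positions, seed=0):
    """Add a short peptide chain B at the given C-alpha positions."""
    pep = fixtures._structure_from_ca(np.asarray(positions, float), seed=seed,
                                      chain_id="B")
    return Structure(
        np.vstack([receptor.coords, pep.coords]),
        receptor.names + pep.names,
        receptor.elements + pep.elements,
        list(receptor.serials) + [int(x) + receptor.n_atoms for x in pep.serials],
        np.concatenate([receptor.atom_residue, pep.atom_residue + receptor.n_residues]),
        receptor.residue_table + pep.residue_table,
    )


class TestRun:
    def test_single_generation_bounds_and_provenance(self, small_hinge):
        config = ExploreConfig(mode="blind", DF=1.0, max_generations=1, cluster_seed=1)
        tree = explore.run(small_hinge.open_structure, config)
        gen1 = tree.generations[1]
        assert 0 <= len(gen1) <= 26  # 3^3 - 1 children bound the cluster count
        for cid in gen1:
            conf = tree.nodes[cid]
            assert conf.parent_id == tree.root_id
            assert conf.generation == 1
            assert conf.rg > 0
        assert tree.nodes[tree.root_id].generation == 0

    def test_counts_bounded_by_parents(self, blind_run):
        _, tree = blind_run
        for g in range(1, len(tree.generations)):
            assert len(tree.generations[g]) <= 26 * len(tree.generations[g - 1])

    def test_ids_unique_and_lineage_reconstructs(self, blind_run):
        _, tree = blind_run
        ids = [c.id for c in tree.conformers()]
        assert len(ids) == len(set(ids)) == len(tree.nodes)
        for cid in tree.generations[-1]:
            chain = tree.lineage(cid)
            assert chain[0].id == tree.root_id
            assert chain[-1].id == cid
            # every consecutive pair is a parent-child edge
            for parent, child in zip(chain, chain[1:]):
                assert child.parent_id == parent.id
            assert [c.generation for c in chain] == list(range(len(chain)))

    def test_rerun_is_bitwise_identical(self, small_hinge):
        config = ExploreConfig(mode="blind", DF=1.0, max_generations=2, cluster_seed=5)
        t1 = explore.run(small_hinge.open_structure, config)
        t2 = explore.run(small_hinge.open_structure, config)
        assert t1.generations == t2.generations
        assert t1.edges == t2.edges
        for cid in t1.nodes:
            np.testing.assert_array_equal(
                t1.nodes[cid].structure.coords, t2.nodes[cid].structure.coords
            )
            assert t1.nodes[cid].energy == t2.nodes[cid].energy

    def test_energy_based_stops_when_nothing_beats_reference(self, small_hinge):
        # the clash-free start scores the surrogate minimum (zero), so no
        # child can fall strictly below it and the search ends after one
        # generation -- the same behaviour as a protein whose first
        # generation is all uphill in energy
        config = ExploreConfig(mode="energy_based", DF=1.0, max_generations=4,
                               cluster_seed=1)
        tree = explore.run(small_hinge.open_structure, config)
        assert len(tree.generations) == 2
        assert all(c.energy >= tree.nodes[tree.root_id].energy
                   for c in tree.conformers())


class TestFilters:
    def test_energy_filter_is_strict_and_matches_brute_force(self):
        rng = np.random.default_rng(12)
        energies = rng.normal(size=100)
        confs = [make_conformer(f"c{i}", 1, energy=e) for i, e in enumerate(energies)]
        ref = 0.0
        kept = explore.energy_filter(confs, ref)
        assert [c.id for c in kept] == [c.id for c in confs if c.energy < ref]
        assert explore.energy_filter([make_conformer("x", 1, energy=0.0)], 0.0) == []

    def test_rg_filter_global_boundary_inclusive(self):
        confs = [make_conformer(f"c{i}", 1, rg=r) for i, r in
                 enumerate([9.8, 10.0, 10.2])]
        kept = explore.rg_filter(confs, 10.0, scope="global")
        assert [c.rg for c in kept] == [9.8, 10.0]
        assert explore.rg_filter(confs, 9.0, scope="global") == []

    def test_rg_filter_per_chain(self):
        apo = {"A": 10.0, "B": 12.0}
        c1 = make_conformer("c1", 1, rg_per_chain={"A": 9.0, "B": 13.0})
        c2 = make_conformer("c2", 1, rg_per_chain={"A": 11.0, "B": 13.0})
        c3 = make_conformer("c3", 1, rg_per_chain={"A": 9.0, "B": 11.0})
        kept = explore.rg_filter([c1, c2, c3], apo, scope="per_chain")
        assert [c.id for c in kept] == ["c1", "c3"]
        kept_all = explore.rg_filter([c1, c2, c3], apo, scope="per_chain",
                                     require_all_chains=True)
        assert [c.id for c in kept_all] == ["c3"]
        with pytest.raises(ValueError):
            explore.rg_filter([make_conformer("x", 1, rg_per_chain={"Z": 1.0})],
                              apo, scope="per_chain")


class TestDockingChain:
    def test_depth_one_chain(self, small_hinge):
        config = ExploreConfig(mode="blind", DF=1.0, max_generations=1, cluster_seed=1)
        tree = explore.run(small_hinge.open_structure, config)
        kept = explore.rg_filter(tree.conformers(), tree.nodes[tree.root_id].rg)
        chain = explore.docking_chain(tree, kept)
        assert chain[0].id == tree.root_id
        assert len(chain) <= 2

    def test_lowest_rg_wins_with_id_tiebreak(self, blind_run):
        _, tree = blind_run
        confs = tree.conformers()
        chain = explore.docking_chain(tree, confs)
        min_rg = min(c.rg for c in confs)
        assert chain[-1].rg == min_rg
        tied = sorted((c for c in confs if c.rg == min_rg), key=lambda c: c.id)
        assert chain[-1].id == tied[0].id

    def test_chain_is_a_path_in_the_tree(self, blind_run):
        _, tree = blind_run
        kept = explore.rg_filter(tree.conformers(), tree.nodes[tree.root_id].rg)
        chain = explore.docking_chain(tree, kept)
        # independent traversal: follow parent pointers from the leaf
        walk = [chain[-1].id]
        while tree.nodes[walk[-1]].parent_id is not None:
            walk.append(tree.nodes[walk[-1]].parent_id)
        assert walk[::-1] == [c.id for c in chain]

    def test_empty_filtered_set_rejected(self, blind_run):
        _, tree = blind_run
        with pytest.raises(ValueError):
            explore.docking_chain(tree, [])


class TestReseed:
    def test_ligand_free_reseed_equals_plain_run(self, small_hinge):
        config = ExploreConfig(mode="blind", DF=1.0, max_generations=1, cluster_seed=2)
        t1 = explore.run(small_hinge.open_structure, config)
        t2 = explore.reseed_with_ligand(small_hinge.open_structure, config)
        assert t1.generations == t2.generations
        for cid in t1.nodes:
            np.testing.assert_array_equal(
                t1.nodes[cid].structure.coords, t2.nodes[cid].structure.coords
            )

    def test_missing_ligand_chain_rejected(self, small_hinge):
        config = ExploreConfig(ligand_chains=("Q",))
        with pytest.raises(ValueError):
            explore.reseed_with_ligand(small_hinge.open_structure, config)

    def test_peptide_residues_become_network_nodes(self, small_hinge):
        from enmexplore import enm

        receptor = small_hinge.open_structure
        complex_s = attach_peptide(
            receptor, [[3.75, -4.0, 3.0], [3.75, 0.0, 3.0], [3.75, 4.0, 3.0]]
        )
        coarse = structio.coarse_grain(complex_s)
        assert coarse.n_nodes == receptor.n_residues + 3
        net = enm.build_network(coarse, complex_s)
        assert net.is_connected()

    def test_bound_peptide_guides_further_closure(self, hinge):
        # a peptide bridging the two domains in the cleft reshapes the slow
        # modes so the same blind search approaches the closed state more
        # closely than the ligand-free run
        from enmexplore.fixtures import DOMAIN_GAP

        x = DOMAIN_GAP / 2.0
        complex_s = attach_peptide(
            hinge.open_structure,
            [[x, -4.0, 3.0], [x, 0.0, 3.0], [x, 4.0, 3.0]], seed=1,
        )
        kwargs = dict(mode="blind", DF=1.0, n_modes=3, max_generations=4,
                      relax=relax.RelaxConfig(), cluster_seed=1)
        free_tree = explore.run(hinge.open_structure, ExploreConfig(**kwargs))
        pep_tree = explore.reseed_with_ligand(
            complex_s, ExploreConfig(ligand_chains=("B",), **kwargs)
        )
        best_free = min(structio.rmsd_ca(c.structure, hinge.closed_structure)
                        for c in free_tree.conformers())
        best_pep = min(
            structio.rmsd_ca(c.structure.subset_chains(["A"]), hinge.closed_structure)
            for c in pep_tree.conformers()
        )
        assert best_pep < best_free
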