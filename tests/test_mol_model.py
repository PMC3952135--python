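"""Ligand parsing, typing, torsion trees and forward kinematics."""

import logging

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from incdock import (
    build_torsion_tree,
    extract_fragment,
    make_chain_ligand,
    parse_mol2,
    parse_pdb_receptor,
    select_root_atom,
    write_mol2,
)
from incdock.mol import (
    BatchKinematics,
    Conformation,
    Mol2ParseError,
    apply_genome,
    measure_dihedral,
    randomize_conformation,
    tree_depth,
)
from incdock.scoring import BindingBox
from incdock.synthetic import make_test_receptor_pdb

from conftest import ALTLOC_PDB, BENZENE_MOL2, BUTANE_MOL2, ETHANE_MOL2


class TestParseMol2:
    def test_ethane_counts_and_charges(self):
        lig = parse_mol2(ETHANE_MOL2)
        assert len(lig.atoms) == 8
        assert len(lig.bonds) == 7
        assert lig.atoms[0].charge == pytest.approx(-0.06)
        assert lig.atoms[2].charge == pytest.approx(0.02)
        assert [a.element for a in lig.atoms[:2]] == ["C", "C"]

    def test_missing_charges_warns_and_zeroes(self, caplog):
        with caplog.at_level(logging.WARNING, logger="incdock.mol"):
            lig = parse_mol2(BENZENE_MOL2)
        assert all(a.charge == 0.0 for a in lig.atoms)
        assert any("charge" in rec.message for rec in caplog.records)

    def test_malformed_record_names_line(self):
        bad = ETHANE_MOL2.replace("2 C2  1.5400  0.0000  0.0000 C.3 1 ETH -0.0600",
                                  "2 C2  badvalue")
        with pytest.raises(Mol2ParseError, match="line 8"):
            parse_mol2(bad)

    def test_disconnected_graph_rejected(self):
        text = ETHANE_MOL2.replace("1 1 2 1\n", "")
        with pytest.raises(Mol2ParseError, match="disconnected"):
            parse_mol2(text)

    @pytest.mark.parametrize("n_torsions", [0, 3, 9])
    def test_round_trip_preserves_structure(self, n_torsions):
        lig = make_chain_ligand(n_torsions)
        back = parse_mol2(write_mol2(lig))
        assert len(back.atoms) == len(lig.atoms)
        assert [a.name for a in back.atoms] == [a.name for a in lig.atoms]
        assert np.allclose(back.coords(), lig.coords(), atol=1e-4)
        assert back.n_rotatable() == lig.n_rotatable()
        assert [a.charge for a in back.atoms] == pytest.approx(
            [a.charge for a in lig.atoms], abs=1e-4
        )


class TestParsePdbReceptor:
    def test_synthetic_peptide_heavy_count(self):
        atoms = parse_pdb_receptor(make_test_receptor_pdb(n_residues=3))
        assert len(atoms) == 12  # 4 backbone heavy atoms per residue
        assert {a.atom_type for a in atoms} == {"N", "C", "OA"}

    def test_altloc_resolved_to_highest_occupancy(self):
        atoms = parse_pdb_receptor(ALTLOC_PDB)
        ca = [a for a in atoms if a.name == "CA"]
        assert len(ca) == 1
        assert ca[0].coords[0] == pytest.approx(1.470)  # occupancy 0.60 wins

    def test_no_atoms_is_an_error(self):
        with pytest.raises(ValueError, match="no ATOM"):
            parse_pdb_receptor("HEADER  EMPTY\nEND\n")

    def test_types_assigned_without_conect(self):
        atoms = parse_pdb_receptor(make_test_receptor_pdb(1))
        by_name = {a.name: a for a in atoms}
        assert by_name["N"].atom_type == "N" and by_name["N"].hbond_role == "donor"
        assert by_name["O"].atom_type == "OA" and by_name["O"].hbond_role == "acceptor"
        assert by_name["CA"].atom_type == "C"


class TestRotatableBonds:
    def test_butane_central_bond_only(self):
        lig = parse_mol2(BUTANE_MOL2)
        rot = [(b.a, b.b) for b in lig.bonds if b.rotatable]
        assert rot == [(1, 2)]

    def test_benzene_has_none(self):
        lig = parse_mol2(BENZENE_MOL2)
        assert lig.n_rotatable() == 0

    def test_bonds_to_hydrogen_never_rotatable(self):
        lig = parse_mol2(ETHANE_MOL2)
        assert lig.n_rotatable() == 0  # C-C is terminal-heavy on both sides

    @pytest.mark.parametrize("n", [1, 5, 14])
    def test_chain_count_matches_construction(self, n):
        assert make_chain_ligand(n).n_rotatable() == n

    @pytest.mark.parametrize("n_heavy", [4, 6, 9])
    def test_rule_agrees_with_rdkit_on_alkanes(self, n_heavy):
        """Independent cross-check of the rotatability rule on plain chains."""
        rdkit = pytest.importorskip("rdkit")
        from rdkit.Chem import Lipinski, MolFromSmiles

        ours = make_chain_ligand(n_heavy - 3, polar_head=False)
        theirs = Lipinski.NumRotatableBonds(MolFromSmiles("C" * n_heavy))
        assert ours.n_rotatable() == theirs


def _brute_force_root(ligand, fragment_size=6):
    """Independent re-derivation of the root-selection rule."""
    g = ligand.graph()
    rigid = g.copy()
    rigid.remove_edges_from((b.a, b.b) for b in ligand.bonds if b.rotatable)
    comp_of = {}
    for comp in nx.connected_components(rigid):
        for a in comp:
            comp_of[a] = frozenset(comp)

    def da(atoms):
        n = 0
        for i in atoms:
            role = ligand.atoms[i].hbond_role
            n += (role in ("donor", "both")) + (role in ("acceptor", "both"))
        return n

    best = None
    for atom in ligand.atoms:
        if atom.element == "H":
            continue
        tree = build_torsion_tree(ligand, atom.index)
        frag = tree.atoms_up_to_rank(min(fragment_size, tree.n_bonds))
        key = (-da(frag), tree_depth(tree), atom.index)
        if best is None or key < best:
            best, winner = key, atom.index
    return winner


class TestRootSelection:
    def test_matches_brute_force_oracle(self):
        for n in (4, 8, 14):
            lig = make_chain_ligand(n)
            assert select_root_atom(lig) == _brute_force_root(lig)

    def test_polar_head_dominates_initial_fragment(self, chain14):
        """The chosen root's initial fragment must contain the donor/acceptor head."""
        root = select_root_atom(chain14)
        tree = build_torsion_tree(chain14, root)
        frag = tree.atoms_up_to_rank(6)
        head = {chain14.atom_by_name(n).index for n in ("O1", "O2", "N1")}
        assert head <= frag

    def test_tie_breaks_to_lower_index(self):
        lig = parse_mol2(ETHANE_MOL2)
        assert select_root_atom(lig) == 0


class TestTorsionTree:
    @pytest.mark.parametrize("n", [0, 1, 5, 14])
    def test_partition_and_rank_completeness(self, n):
        lig = make_chain_ligand(n)
        tree = build_torsion_tree(lig, select_root_atom(lig))
        all_atoms = set()
        total = 0
        for node in tree.nodes:
            assert not (all_atoms & node)
            all_atoms |= node
            total += len(node)
        assert all_atoms == set(range(len(lig.atoms)))
        assert total == len(lig.atoms)
        assert sorted(e.rank for e in tree.edges) == list(range(1, n + 1))

    def test_ranks_nondecreasing_with_depth(self, chain14):
        tree = build_torsion_tree(chain14, select_root_atom(chain14))
        depth = {0: 0}
        ranks_by_depth = []
        for e in tree.edges:
            depth[e.child_node] = depth[e.parent_node] + 1
            ranks_by_depth.append((depth[e.child_node], e.rank))
        assert sorted(ranks_by_depth) == ranks_by_depth

    def test_rigid_ligand_single_node(self):
        lig = parse_mol2(BENZENE_MOL2)
        tree = build_torsion_tree(lig, 0)
        assert len(tree.nodes) == 1
        assert tree.nodes[0] == frozenset(range(6))


class TestExtractFragment:
    def test_initial_fragment_of_14_bond_tree(self, chain14):
        tree = build_torsion_tree(chain14, select_root_atom(chain14))
        frag = extract_fragment(tree, chain14, 6, set(range(1, 7)))
        assert frag.active_ranks == frozenset(range(1, 7))
        assert frag.frozen_ranks == frozenset()
        assert frag.atom_subset == tree.atoms_up_to_rank(6)

    def test_full_ligand_fragment(self, chain9):
        tree = build_torsion_tree(chain9, select_root_atom(chain9))
        frag = extract_fragment(tree, chain9, 9, set(range(1, 10)))
        assert frag.atom_subset == frozenset(range(len(chain9.atoms)))

    def test_extension_freezes_older_ranks(self, chain14):
        tree = build_torsion_tree(chain14, select_root_atom(chain14))
        parent = Conformation(
            translation=np.zeros(3),
            orientation=np.array([1.0, 0, 0, 0]),
            torsions={r: 0.1 * r for r in range(1, 7)},
        )
        frag = extract_fragment(tree, chain14, 9, set(range(4, 10)), parent=parent)
        assert frag.frozen_ranks == frozenset({1, 2, 3})
        assert frag.frozen_torsions == pytest.approx({r: 0.1 * r for r in (1, 2, 3)})

    def test_active_beyond_max_rank_rejected(self, chain14):
        tree = build_torsion_tree(chain14, select_root_atom(chain14))
        with pytest.raises(ValueError):
            extract_fragment(tree, chain14, 6, {5, 6, 7})


class TestKinematics:
    def test_identity_reproduces_reference(self, chain9):
        tree = build_torsion_tree(chain9, select_root_atom(chain9))
        kin = BatchKinematics(chain9, tree)
        out = apply_genome(
            chain9, tree, kin.root_centroid, [1, 0, 0, 0], {r: 0.0 for r in range(1, 10)}
        )
        assert np.allclose(out, chain9.coords(), atol=1e-12)

    def test_pure_translation_shifts_every_atom(self, chain9):
        tree = build_torsion_tree(chain9, select_root_atom(chain9))
        kin = BatchKinematics(chain9, tree)
        out = apply_genome(
            chain9, tree, kin.root_centroid + [3, 0, 0], [1, 0, 0, 0],
            {r: 0.0 for r in range(1, 10)},
        )
        assert np.allclose(out - chain9.coords(), [3.0, 0.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("delta", [np.pi, -np.pi / 2, 0.7])
    def test_torsion_delta_matches_dihedral_oracle(self, delta):
        """Dihedral recomputed from output geometry equals reference + delta."""
        lig = make_chain_ligand(3)
        tree = build_torsion_tree(lig, select_root_atom(lig))
        rank = 2
        i, j, k, l = tree.dihedral_atoms(rank, lig)
        ref_angle = measure_dihedral(lig.coords(), i, j, k, l)
        torsions = {r: 0.0 for r in range(1, 4)}
        torsions[rank] = delta
        kin = BatchKinematics(lig, tree)
        out = apply_genome(lig, tree, kin.root_centroid, [1, 0, 0, 0], torsions)
        got = measure_dihedral(out, i, j, k, l)
        diff = (got - ref_angle - delta + np.pi) % (2 * np.pi) - np.pi
        assert abs(diff) < 1e-9

    def test_missing_torsion_is_contract_violation(self, chain9):
        tree = build_torsion_tree(chain9, select_root_atom(chain9))
        with pytest.raises(ValueError, match="missing torsion"):
            apply_genome(chain9, tree, np.zeros(3), [1, 0, 0, 0], {1: 0.0})

    def test_rigidity_over_random_genomes(self, chain9):
        """Bond lengths and angles are invariant under any genome (1e-6)."""
        tree = build_torsion_tree(chain9, select_root_atom(chain9))
        kin = BatchKinematics(chain9, tree)
        rng = np.random.default_rng(42)
        P = 1000
        q = rng.standard_normal((P, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        coords = kin.coords(
            rng.uniform(-5, 5, (P, 3)), q, rng.uniform(-np.pi, np.pi, (P, 9))
        )
        ref = chain9.coords()
        for b in chain9.bonds:
            d_ref = np.linalg.norm(ref[b.a] - ref[b.b])
            d_new = np.linalg.norm(coords[:, b.a] - coords[:, b.b], axis=1)
            assert np.all(np.abs(d_new - d_ref) < 1e-6)
        g = chain9.graph()
        for j in range(len(chain9.atoms)):
            nbrs = sorted(g.neighbors(j))
            for x in range(len(nbrs)):
                for y in range(x + 1, len(nbrs)):
                    a, c = nbrs[x], nbrs[y]
                    v1 = coords[:, a] - coords[:, j]
                    v2 = coords[:, c] - coords[:, j]
                    cosang = (v1 * v2).sum(1) / (
                        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                    )
                    r1, r2 = ref[a] - ref[j], ref[c] - ref[j]
                    cosref = r1 @ r2 / (np.linalg.norm(r1) * np.linalg.norm(r2))
                    assert np.all(np.abs(np.arccos(np.clip(cosang, -1, 1))
                                         - np.arccos(np.clip(cosref, -1, 1))) < 1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_batch_and_single_genome_agree(self, seed):
        lig = make_chain_ligand(4)
        tree = build_torsion_tree(lig, select_root_atom(lig))
        rng = np.random.default_rng(seed)
        tor = {r: float(rng.uniform(-np.pi, np.pi)) for r in range(1, 5)}
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        t = rng.uniform(-3, 3, 3)
        single = apply_genome(lig, tree, t, q, tor)
        kin = BatchKinematics(lig, tree)
        batch = kin.coords(t[None], q[None], np.array([[tor[r] for r in kin.ranks]]))[0]
        assert np.array_equal(single, batch)


class TestRandomize:
    def test_same_seed_reproduces_genome(self, chain9):
        tree = build_torsion_tree(chain9, select_root_atom(chain9))
        box = BindingBox(center=np.zeros(3), npts=(41, 41, 41), spacing=0.375)
        c1 = randomize_conformation(chain9, tree, box, np.random.default_rng(5))
        c2 = randomize_conformation(chain9, tree, box, np.random.default_rng(5))
        assert np.array_equal(c1.translation, c2.translation)
        assert np.array_equal(c1.orientation, c2.orientation)
        assert c1.torsions == c2.torsions
        assert np.array_equal(c1.coords, c2.coords)

    def test_translations_inside_box_and_torsions_uniform(self, chain9):
        from scipy.stats import kstest

        tree = build_torsion_tree(chain9, select_root_atom(chain9))
        box = BindingBox(center=np.array([1.0, -2.0, 3.0]), npts=(41, 41, 41))
        rng = np.random.default_rng(7)
        lo, hi = box.bounds()
        samples = {r: [] for r in range(1, 10)}
        for _ in range(1500):
            c = randomize_conformation(chain9, tree, box, rng)
            assert np.all(c.translation >= lo) and np.all(c.translation <= hi)
            for r, v in c.torsions.items():
                samples[r].append(v)
        for r, vals in samples.items():
            stat = kstest(np.array(vals), "uniform", args=(-np.pi, 2 * np.pi))
            assert stat.pvalue > 0.01, f"rank {r} torsion distribution not uniform"
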