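"""Increment schedule, selection, extension and the full protocol loop."""

import numpy as np
import pytest

from incdock import (
    ProtocolConfig,
    extend_conformation,
    make_planted_complex,
    plan_schedule,
    run_protocol,
    select_conformations,
)
from incdock.mol import build_torsion_tree, extract_fragment, measure_dihedral
from incdock.protocol import PlanStep
from incdock.scoring import Restraint, ScoredConformation
from incdock.engine import dock

from conftest import fast_engine, fast_protocol


def _independent_schedule(n_bonds, frag=6, ext=3, re=3):
    """Oracle: re-derive the rank windows by plain enumeration."""
    steps = [list(range(1, min(frag, n_bonds) + 1))]
    done = min(frag, n_bonds)
    prev_new = steps[0]
    while done < n_bonds:
        new = list(range(done + 1, min(done + ext, n_bonds) + 1))
        steps.append(prev_new[-re:] + new)
        prev_new = new
        done = new[-1]
    return [tuple(s) for s in steps]


class TestPlanSchedule:
    def test_fourteen_bond_walkthrough(self):
        plan = plan_schedule(14)
        assert [s.active_ranks for s in plan.steps] == [
            tuple(range(1, 7)),
            tuple(range(4, 10)),
            tuple(range(7, 13)),
            tuple(range(10, 15)),
        ]
        assert plan.steps[1].frozen_ranks == (1, 2, 3)
        assert plan.steps[3].new_ranks == (13, 14)
        assert plan.steps[3].reexplored_ranks == (10, 11, 12)

    def test_six_bonds_single_step(self):
        plan = plan_schedule(6)
        assert len(plan.steps) == 1
        assert plan.steps[0].active_ranks == tuple(range(1, 7))

    def test_eight_bonds_clipped_extension(self):
        plan = plan_schedule(8)
        assert [s.active_ranks for s in plan.steps] == [
            tuple(range(1, 7)),
            tuple(range(4, 9)),
        ]

    @pytest.mark.parametrize("n_bonds", list(range(0, 25)))
    def test_every_rank_new_exactly_once(self, n_bonds):
        plan = plan_schedule(n_bonds)
        seen = []
        for s in plan.steps:
            seen.extend(s.new_ranks)
        assert sorted(seen) == list(range(1, n_bonds + 1))
        assert len(seen) == len(set(seen))
        assert [s.active_ranks for s in plan.steps] == _independent_schedule(n_bonds)

    @pytest.mark.parametrize("n_bonds", [5, 9, 14, 17])
    def test_windows_are_consecutive_and_end_at_max_rank(self, n_bonds):
        for s in plan_schedule(n_bonds).steps:
            active = s.active_ranks
            assert active == tuple(range(active[0], active[-1] + 1))
            assert active[-1] == s.max_rank
            assert s.frozen_ranks == tuple(r for r in range(1, s.max_rank + 1)
                                           if r not in active)


def _fake_pose(score, coords):
    from incdock.mol import Conformation

    conf = Conformation(
        translation=np.zeros(3), orientation=np.array([1.0, 0, 0, 0]), torsions={},
        coords=np.asarray(coords, float), atom_indices=tuple(range(len(coords))),
    )
    return ScoredConformation(conformation=conf, s_ad=score, s_total=score)


class TestSelectConformations:
    def test_k_lowest_by_score(self):
        pool = [_fake_pose(s, [[0, 0, 0]]) for s in [3.0, -1.0, 2.0, -5.0, 0.0, 4.0]]
        got = select_conformations(pool, 3)
        assert [sc.s_ad for sc in got] == [-5.0, -1.0, 0.0]

    def test_small_pool_returned_whole(self):
        pool = [_fake_pose(s, [[0, 0, 0]]) for s in [1.0, 2.0]]
        assert len(select_conformations(pool, 5)) == 2

    def test_restraint_separates_equal_engine_scores(self, chain9):
        """Equal s_ad; the pose with its restrained atom at target wins by
        the 2.5 kcal/mol penalty of a 10 A^2 displacement."""
        target = np.array([1.0, 1.0, 1.0])
        at_target = np.tile(target, (len(chain9.atoms), 1))
        away = at_target.copy()
        o1 = chain9.atom_by_name("O1").index
        away[o1] += [np.sqrt(10.0), 0.0, 0.0]
        pool = [_fake_pose(-6.0, away), _fake_pose(-6.0, at_target)]
        restraint = Restraint(atom_name="O1", target=target)
        got = select_conformations(pool, 2, restraint=restraint, ligand=chain9)
        assert got[0].conformation.coords[o1] == pytest.approx(target)
        assert got[1].s_total - got[1].s_ad == pytest.approx(2.5)
        assert got[0].s_total == got[0].s_ad

    def test_empty_pool_is_error(self):
        with pytest.raises(ValueError):
            select_conformations([], 3)


class TestExtendConformation:
    def test_extension_step_freezes_one_to_three(self, planted9):
        pc = planted9
        tree = build_torsion_tree(pc.ligand, pc.root_atom)
        frag6 = extract_fragment(tree, pc.ligand, 6, set(range(1, 7)))
        parent = dock(frag6, pc.field, fast_engine(ga_run=1), seed=0).conformations[0]
        step = PlanStep(new_ranks=(7, 8, 9), reexplored_ranks=(4, 5, 6),
                        frozen_ranks=(1, 2, 3), max_rank=9)
        frag = extend_conformation(parent, tree, pc.ligand, step)
        assert frag.frozen_ranks == frozenset({1, 2, 3})
        assert frag.active_ranks == frozenset(range(4, 10))

    def test_final_step_covers_full_ligand(self, planted9):
        pc = planted9
        tree = build_torsion_tree(pc.ligand, pc.root_atom)
        frag6 = extract_fragment(tree, pc.ligand, 6, set(range(1, 7)))
        parent = dock(frag6, pc.field, fast_engine(ga_run=1), seed=0).conformations[0]
        step = PlanStep(new_ranks=(7, 8, 9), reexplored_ranks=(4, 5, 6),
                        frozen_ranks=(1, 2, 3), max_rank=9)
        frag = extend_conformation(parent, tree, pc.ligand, step)
        assert frag.atom_subset == frozenset(range(len(pc.ligand.atoms)))

    def test_frozen_dihedrals_match_parent_geometry(self, planted9):
        """Measured from Cartesian coordinates, frozen dihedrals equal the
        parent's within 1e-9."""
        pc = planted9
        tree = build_torsion_tree(pc.ligand, pc.root_atom)
        frag6 = extract_fragment(tree, pc.ligand, 6, set(range(1, 7)))
        parent = dock(frag6, pc.field, fast_engine(ga_run=1), seed=1).conformations[0]
        step = PlanStep(new_ranks=(7, 8, 9), reexplored_ranks=(4, 5, 6),
                        frozen_ranks=(1, 2, 3), max_rank=9)
        frag = extend_conformation(parent, tree, pc.ligand, step)
        child = dock(frag, pc.field, fast_engine(ga_run=1), seed=2).conformations[0]
        parent_pos = {a: i for i, a in enumerate(parent.conformation.atom_indices)}
        child_pos = {a: i for i, a in enumerate(child.conformation.atom_indices)}
        for rank in (1, 2, 3):
            quad = tree.dihedral_atoms(rank, pc.ligand)
            d_parent = measure_dihedral(parent.conformation.coords,
                                        *[parent_pos[a] for a in quad])
            d_child = measure_dihedral(child.conformation.coords,
                                       *[child_pos[a] for a in quad])
            diff = (d_child - d_parent + np.pi) % (2 * np.pi) - np.pi
            assert abs(diff) < 1e-9

    def test_parent_missing_torsion_rejected(self, planted9):
        pc = planted9
        tree = build_torsion_tree(pc.ligand, pc.root_atom)
        bad_parent = _fake_pose(0.0, [[0, 0, 0]])
        step = PlanStep(new_ranks=(7, 8, 9), reexplored_ranks=(4, 5, 6),
                        frozen_ranks=(1, 2, 3), max_rank=9)
        with pytest.raises(ValueError, match="lacks torsions"):
            extend_conformation(bad_parent, tree, pc.ligand, step)


@pytest.fixture(scope="module")
def small_run(planted9):
    pc = planted9
    res = run_protocol(
        pc.ligand, pc.field, fast_protocol(), fast_engine(), root_atom=pc.root_atom
    )
    return pc, res


class TestRunProtocol:
    def test_pool_sizes_follow_bookkeeping(self, small_run):
        pc, res = small_run
        # 9 bonds -> steps [1-6], [4-9]; 50 initial poses, 5 parents x 20 runs
        assert len(res.per_step_pools[0]) == 50
        assert len(res.per_step_pools[1]) == 100
        assert len(res.final_pool) == 100
        assert len(res.plan.steps) == 2

    def test_final_poses_cover_all_torsions(self, small_run):
        pc, res = small_run
        for sc in res.final_pool:
            assert set(sc.conformation.torsions) == set(range(1, 10))
            assert len(sc.conformation.atom_indices) == len(pc.ligand.atoms)

    def test_fragment_growth_is_nested(self, small_run):
        pc, res = small_run
        tree = res.tree
        subsets = [tree.atoms_up_to_rank(s.max_rank) for s in res.plan.steps]
        for a, b in zip(subsets, subsets[1:]):
            assert a < b
        assert subsets[-1] == frozenset(range(len(pc.ligand.atoms)))

    def test_frozen_torsions_conserved_along_provenance(self, small_run):
        """A torsion never changes after its last active step."""
        pc, res = small_run
        final_step = res.plan.steps[-1]
        for sc, prov in zip(res.final_pool, res.provenance):
            parent = res.selected_per_step[-1][prov[-1]]
            for rank in final_step.frozen_ranks:
                assert sc.conformation.torsions[rank] == parent.conformation.torsions[rank]

    def test_degenerate_small_ligand_single_dock(self):
        pc = make_planted_complex(n_torsions=3, seed=1)
        res = run_protocol(pc.ligand, pc.field, fast_protocol(), fast_engine(),
                           root_atom=pc.root_atom)
        assert len(res.plan.steps) == 1
        assert len(res.final_pool) == 50  # initial_runs
        assert res.per_step_pools[0] is res.final_pool or \
            [sc.s_ad for sc in res.per_step_pools[0]] == [sc.s_ad for sc in res.final_pool]

    def test_bitwise_determinism(self, planted9):
        pc = planted9
        kwargs = dict(protocol_config=fast_protocol(seed=4), engine_config=fast_engine(),
                      root_atom=pc.root_atom)
        r1 = run_protocol(pc.ligand, pc.field, **kwargs)
        r2 = run_protocol(pc.ligand, pc.field, **kwargs)
        assert [sc.s_ad for sc in r1.final_pool] == [sc.s_ad for sc in r2.final_pool]
        for a, b in zip(r1.final_pool, r2.final_pool):
            assert np.array_equal(a.conformation.coords, b.conformation.coords)

    def test_restraint_picks_restrained_atom_as_root(self, planted9):
        pc = planted9
        restraint = Restraint(atom_name="O1", target=pc.planted.coords[pc.root_atom])
        res = run_protocol(pc.ligand, pc.field, fast_protocol(), fast_engine(),
                           restraint=restraint)
        assert res.root_atom == pc.ligand.atom_by_name("O1").index
        # selection scores carry the restraint penalty
        for sc in res.final_pool:
            assert sc.s_total >= sc.s_ad

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ProtocolConfig(select_k=60, initial_runs=50)
        with pytest.raises(ValueError):
            ProtocolConfig(fragment_size=0)
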