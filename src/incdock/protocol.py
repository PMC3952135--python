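"""Incremental docking protocol: dock a fragment, select, extend, repeat.

A large ligand is never docked in one shot.  The initial fragment (root
group plus the bonds ranked 1..6 by default) is docked with many independent
engine runs; the few lowest-scoring poses are kept, extended by the next few
ranked bonds, and re-docked with the oldest torsions frozen and the most
recent ones re-explored, until every rotatable bond has been sampled.  With
the defaults on a 14-bond ligand the active rank windows are [1-6], [4-9],
[7-12], [10-14]: at each extension 3 new bonds enter and the last 3
previously explored bonds are re-explored while everything older is frozen.
The first docking emits 50 poses, 5 survive selection, and every later step
docks each survivor 20 times, pooling 100 candidates.

When a positional restraint is set, the restrained atom is chosen as the
root atom (so it is present from the first fragment onward) and selection
ranks poses by the restrained score S = w*Da + S_AD instead of the raw
engine score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclasses_field, replace

import numpy as np

from .engine import EngineConfig, dock
from .mol import Fragment, Ligand, TorsionTree, build_torsion_tree, extract_fragment, select_root_atom
from .scoring import Field, Restraint, ScoredConformation, restrained_score

logger = logging.getLogger(__name__)

__all__ = [
    "ProtocolConfig",
    "PlanStep",
    "IncrementPlan",
    "ProtocolResult",
    "plan_schedule",
    "select_conformations",
    "extend_conformation",
    "run_protocol",
]


@dataclass
class ProtocolConfig:
    """Increment-schedule and bookkeeping parameters.

    Defaults follow the walkthrough conditions: 6-bond initial fragment,
    extend by 3, re-explore 3, keep 5, 50 initial runs, 20 runs per kept
    parent, 250000 score evaluations per engine run.
    """

    fragment_size: int = 6
    extension_size: int = 3
    reexplore_size: int = 3
    select_k: int = 5
    initial_runs: int = 50
    runs_per_parent: int = 20
    step_num_evals: int = 250_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_size < 1 or self.extension_size < 1 or self.reexplore_size < 0:
            raise ValueError("fragment_size/extension_size must be >= 1, reexplore_size >= 0")
        if self.select_k < 1 or self.select_k > self.initial_runs:
            raise ValueError("select_k must lie in 1..initial_runs")
        if self.select_k > self.select_k * self.runs_per_parent:
            raise ValueError("runs_per_parent must be >= 1")


@dataclass(frozen=True)
class PlanStep:
    """One docking round: which ranks are new, re-explored, frozen."""

    new_ranks: tuple[int, ...]
    reexplored_ranks: tuple[int, ...]
    frozen_ranks: tuple[int, ...]
    max_rank: int

    @property
    def active_ranks(self) -> tuple[int, ...]:
        return tuple(sorted(self.reexplored_ranks + self.new_ranks))


@dataclass
class IncrementPlan:
    steps: list[PlanStep]


def plan_schedule(n_bonds: int, config: ProtocolConfig | None = None) -> IncrementPlan:
    """Ordered schedule of (new, re-explored, frozen) rank windows.

    Step 1 activates ranks ``1..min(fragment_size, n_bonds)``.  Each later
    step adds the next ``extension_size`` unexplored ranks (clipped at
    ``n_bonds``) and re-explores the trailing ``reexplore_size`` ranks of
    the previous step's new set; all older ranks are frozen.  A rigid
    ligand (``n_bonds == 0``) gets a single step with no torsions.
    """
    config = config or ProtocolConfig()
    if n_bonds < 0:
        raise ValueError("n_bonds must be >= 0")
    first_max = min(config.fragment_size, n_bonds)
    steps = [
        PlanStep(
            new_ranks=tuple(range(1, first_max + 1)),
            reexplored_ranks=(),
            frozen_ranks=(),
            max_rank=first_max,
        )
    ]
    prev_new = steps[0].new_ranks
    explored = first_max
    while explored < n_bonds:
        new = tuple(range(explored + 1, min(explored + config.extension_size, n_bonds) + 1))
        re = prev_new[-config.reexplore_size:] if config.reexplore_size else ()
        max_rank = new[-1]
        frozen = tuple(r for r in range(1, max_rank + 1) if r not in new and r not in re)
        steps.append(
            PlanStep(new_ranks=new, reexplored_ranks=re, frozen_ranks=frozen, max_rank=max_rank)
        )
        prev_new = new
        explored = max_rank
    return IncrementPlan(steps=steps)


def _selection_key(sc: ScoredConformation, idx: int) -> tuple[float, float, int]:
    return (sc.s_total, sc.s_ad, idx)


def _apply_restraint(
    pool: list[ScoredConformation], restraint: Restraint | None, ligand: Ligand | None
) -> list[ScoredConformation]:
    """Return the pool with s_total set to the restrained score (or s_ad)."""
    if restraint is None:
        return [ScoredConformation(sc.conformation, sc.s_ad, sc.s_ad) for sc in pool]
    if ligand is None:
        raise ValueError("a ligand is required to resolve the restraint atom")
    atom_idx = restraint.resolve(ligand)
    out = []
    for sc in pool:
        try:
            pos = sc.conformation.atom_indices.index(atom_idx)
        except ValueError:
            raise ValueError(
                f"restrained atom {restraint.atom_name!r} is not part of the fragment"
            ) from None
        s_tot = restrained_score(sc.s_ad, sc.conformation.coords[pos], restraint)
        out.append(ScoredConformation(sc.conformation, sc.s_ad, s_tot))
    return out


def select_conformations(
    pool: list[ScoredConformation],
    k: int,
    restraint: Restraint | None = None,
    ligand: Ligand | None = None,
) -> list[ScoredConformation]:
    """The ``k`` lowest-scoring poses of a pool.

    Ranking is by ``s_total`` (the restrained score when a restraint is
    set, else the engine score), ties broken by engine score then by
    insertion order.  A pool smaller than ``k`` is returned whole.
    """
    if not pool:
        raise ValueError("cannot select from an empty pool")
    scored = _apply_restraint(pool, restraint, ligand)
    order = sorted(range(len(scored)), key=lambda i: _selection_key(scored[i], i))
    return [scored[i] for i in order[:k]]


def extend_conformation(
    parent: ScoredConformation,
    tree: TorsionTree,
    ligand: Ligand,
    step: PlanStep,
) -> Fragment:
    """Grow a selected pose to the next step's fragment.

    The returned fragment freezes the parent's angles on ``frozen_ranks``,
    re-activates ``reexplored_ranks`` starting from the parent's angles,
    and introduces ``new_ranks`` at the reference geometry.
    """
    required = [r for r in range(1, (min(step.new_ranks) if step.new_ranks else step.max_rank + 1))]
    missing = [r for r in required if r not in parent.conformation.torsions]
    if missing:
        raise ValueError(f"parent conformation lacks torsions for ranks {missing}")
    return extract_fragment(
        tree,
        ligand,
        max_rank=step.max_rank,
        active_ranks=set(step.active_ranks),
        parent=parent.conformation,
    )


@dataclass
class ProtocolResult:
    """Full-ligand pool plus per-step history and parent provenance.

    ``provenance[i]`` lists, for final pose ``i``, the index of the selected
    parent it descended from at each extension step.
    """

    final_pool: list[ScoredConformation]
    per_step_pools: list[list[ScoredConformation]]
    provenance: list[tuple[int, ...]]
    plan: IncrementPlan
    tree: TorsionTree
    root_atom: int
    selected_per_step: list[list[ScoredConformation]] = dataclasses_field(default_factory=list)


def _step_seed(master: int, step_idx: int, parent_idx: int) -> int:
    """Order-independent engine seed for one sub-docking."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(step_idx, parent_idx))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_protocol(
    ligand: Ligand,
    field: Field,
    protocol_config: ProtocolConfig | None = None,
    engine_config: EngineConfig | None = None,
    restraint: Restraint | None = None,
    root_atom: int | None = None,
) -> ProtocolResult:
    """Dock a ligand incrementally against a scoring field.

    The root atom is the restrained atom when a restraint is given,
    otherwise the donor/acceptor-maximizing choice (or ``root_atom`` when
    forced).  Step 1 docks the initial fragment with ``initial_runs`` engine
    runs; every extension step docks each of the ``select_k`` selected
    parents with ``runs_per_parent`` runs from independent seed streams
    (results do not depend on sub-docking execution order), pools the
    candidates, and selects again.  The last step's pool — every torsion
    assigned — is returned in full.
    """
    pc = protocol_config or ProtocolConfig()
    ec = engine_config or EngineConfig()
    if root_atom is None:
        root_atom = restraint.resolve(ligand) if restraint is not None else select_root_atom(ligand, pc.fragment_size)
    tree = build_torsion_tree(ligand, root_atom)
    plan = plan_schedule(tree.n_bonds, pc)

    per_step_pools: list[list[ScoredConformation]] = []
    selected_per_step: list[list[ScoredConformation]] = []
    pool_provenance: list[tuple[int, ...]] = []
    pool: list[ScoredConformation] = []
    selected: list[ScoredConformation] = []
    selected_prov: list[tuple[int, ...]] = []

    for step_idx, step in enumerate(plan.steps):
        if step_idx == 0:
            fragment = extract_fragment(tree, ligand, step.max_rank, set(step.active_ranks))
            cfg = replace(ec, ga_run=pc.initial_runs, ga_num_evals=pc.step_num_evals)
            result = dock(fragment, field, cfg, seed=_step_seed(pc.seed, 0, 0))
            pool = result.conformations
            pool_provenance = [() for _ in pool]
            logger.info(
                "step 1: docked ranks %s, %d poses, best %.3f",
                list(step.active_ranks), len(pool), pool[0].s_ad,
            )
        else:
            pool = []
            pool_provenance = []
            cfg = replace(ec, ga_run=pc.runs_per_parent, ga_num_evals=pc.step_num_evals)
            for p_idx, parent in enumerate(selected):
                fragment = extend_conformation(parent, tree, ligand, step)
                result = dock(fragment, field, cfg, seed=_step_seed(pc.seed, step_idx, p_idx))
                pool.extend(result.conformations)
                pool_provenance.extend(selected_prov[p_idx] + (p_idx,) for _ in result.conformations)
            logger.info(
                "step %d: new %s re-explored %s frozen %s, %d poses, best %.3f",
                step_idx + 1, list(step.new_ranks), list(step.reexplored_ranks),
                list(step.frozen_ranks), len(pool), min(sc.s_ad for sc in pool),
            )
        per_step_pools.append(pool)
        if step_idx < len(plan.steps) - 1:
            scored = _apply_restraint(pool, restraint, ligand)
            order = sorted(range(len(scored)), key=lambda i: _selection_key(scored[i], i))
            keep = order[: pc.select_k]
            selected = [scored[i] for i in keep]
            selected_prov = [pool_provenance[i] for i in keep]
            selected_per_step.append(selected)

    final = _apply_restraint(pool, restraint, ligand)
    return ProtocolResult(
        final_pool=final,
        per_step_pools=per_step_pools,
        provenance=pool_provenance,
        plan=plan,
        tree=tree,
        root_atom=root_atom,
        selected_per_step=selected_per_step,
    )
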