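"""Stochastic search engine: a genetic algorithm over one fragment's genome.

One *run* evolves a population of genomes (rigid-body translation,
orientation quaternion, and the fragment's active torsion deltas) against a
scoring field under a hard budget of score evaluations, and returns the best
conformation it saw.  A docking consists of ``ga_run`` independent runs,
each seeded from its own stream of a splittable RNG so results do not depend
on execution order.

The GA is generational with elitism 1, tournament selection (k=2),
two-point genome crossover, Gaussian mutation (sigma 1 A translation,
0.1 rad rotation and torsion), and an optional greedy local search applied
to the top decile each generation (Lamarckian: improved genomes re-enter
the population).  Frozen torsions are never altered.  Any backend mapping
(fragment, field, config) -> DockingResult can stand in for this engine;
the incremental protocol depends only on that contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mol import BatchKinematics, Conformation, Fragment, random_quaternion
from .scoring import Field, ScoredConformation

__all__ = ["EngineConfig", "DockingResult", "dock", "local_search"]

# mutation scales (see module docstring)
SIGMA_TRANSLATION = 1.0  # A
SIGMA_ROTATION = 0.1  # rad
SIGMA_TORSION = 0.1  # rad
# local-search proposal scales: an order of magnitude finer
LS_SIGMA_TRANSLATION = 0.1
LS_SIGMA_ANGLE = 0.03


@dataclass
class EngineConfig:
    """Sampler settings.

    ``ga_num_evals`` caps score evaluations per run (the headline cost
    control); ``ga_run`` independent runs yield that many output poses.
    """

    ga_num_evals: int = 250_000
    ga_run: int = 50
    population_size: int = 150
    mutation_rate: float = 0.3
    crossover_rate: float = 0.8
    local_search_steps: int = 5
    polish_steps: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ga_num_evals < self.population_size:
            raise ValueError("ga_num_evals must cover at least one population evaluation")
        if self.ga_run < 1:
            raise ValueError("ga_run must be >= 1")
        for p in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class DockingResult:
    """Outcome of one docking: one best pose per run, sorted by score."""

    conformations: list[ScoredConformation]
    evals_used: int


def _quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product of quaternions (w, x, y, z); batched on axis 0."""
    w1, x1, y1, z1 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    w2, x2, y2, z2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    out[..., 0] = w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2
    out[..., 1] = w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2
    out[..., 2] = w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2
    out[..., 3] = w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2
    return out


def _small_rotation(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """n small random-axis rotation quaternions with Gaussian angles."""
    return _rotation_from_draws(rng.standard_normal((n, 4)), sigma)


def _rotation_from_draws(draws: np.ndarray, sigma: float) -> np.ndarray:
    """Quaternions from raw standard-normal draws (axis 3 + angle 1)."""
    axes = draws[..., :3]
    axes = axes / np.sqrt((axes * axes).sum(axis=-1, keepdims=True))
    half = 0.5 * sigma * draws[..., 3]
    out = np.empty(draws.shape)
    out[..., 0] = np.cos(half)
    out[..., 1:] = np.sin(half)[..., None] * axes
    return out


class _Evaluator:
    """Batched genome -> (coords, score) with an evaluation counter."""

    def __init__(self, fragment: Fragment, field: Field):
        self.kin = BatchKinematics(fragment.ligand, fragment.tree, fragment.max_rank)
        self.atoms = [fragment.ligand.atoms[i] for i in self.kin.atom_indices]
        self.field = field
        self.active = sorted(fragment.active_ranks)
        self.n_active = len(self.active)
        frozen = fragment.frozen_torsions
        self.full_torsions = np.zeros(fragment.max_rank)
        for rank, angle in frozen.items():
            self.full_torsions[rank - 1] = angle
        self.active_cols = np.array([r - 1 for r in self.active], dtype=int)
        self.evals = 0

    def genome_length(self) -> int:
        return 7 + self.n_active

    def coords(self, genomes: np.ndarray) -> np.ndarray:
        P = genomes.shape[0]
        torsions = np.broadcast_to(self.full_torsions, (P, len(self.full_torsions))).copy()
        if self.n_active:
            torsions[:, self.active_cols] = genomes[:, 7:]
        q = genomes[:, 3:7]
        q = q / np.linalg.norm(q, axis=1, keepdims=True)
        return self.kin.coords(genomes[:, :3], q, torsions)

    def scores(self, genomes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xyz = self.coords(genomes)
        s = self.field.score_many(xyz, self.atoms)
        self.evals += genomes.shape[0]
        return xyz, s


def _init_population(
    ev: _Evaluator, fragment: Fragment, field: Field, P: int, rng: np.random.Generator
) -> np.ndarray:
    G = ev.genome_length()
    pop = np.empty((P, G))
    parent = fragment.parent_geometry
    if parent is not None:
        base = np.empty(G)
        base[:3] = parent.translation
        base[3:7] = parent.orientation
        base[7:] = [parent.torsions.get(r, 0.0) for r in ev.active]
        pop[:] = base
        # keep one exact copy of the parent; scatter the rest around it
        pop[1:, :3] += rng.normal(0.0, SIGMA_TRANSLATION, size=(P - 1, 3))
        pop[1:, 3:7] = _quat_mul(_small_rotation(rng, P - 1, SIGMA_ROTATION), pop[1:, 3:7])
        if ev.n_active:
            pop[1:, 7:] += rng.normal(0.0, SIGMA_TORSION, size=(P - 1, ev.n_active))
    else:
        lo, hi = field.box.bounds()
        pop[:, :3] = rng.uniform(lo, hi, size=(P, 3))
        for i in range(P):
            pop[i, 3:7] = random_quaternion(rng)
        if ev.n_active:
            pop[:, 7:] = rng.uniform(-np.pi, np.pi, size=(P, ev.n_active))
    return pop


def _generation_schedule(config: EngineConfig) -> tuple[int, int, int]:
    """(n_generations, n_top, polish_steps) fitting the evaluation budget.

    Every generation costs one population evaluation plus, when local search
    is enabled, ``local_search_steps`` evaluations of the top decile; a
    final adaptive polish of the run best costs one evaluation per step.
    The initial population evaluation and the polish are paid off the top;
    whatever budget remains after the last full generation is left unused,
    so the per-run eval count never exceeds ``ga_num_evals``.
    """
    P = config.population_size
    n_top = max(1, P // 10) if config.local_search_steps > 0 else 0
    per_gen = P + config.local_search_steps * n_top
    polish = min(config.polish_steps, max(0, config.ga_num_evals - P))
    n_gens = max(0, (config.ga_num_evals - P - polish) // per_gen)
    return n_gens, n_top, polish


def _ga_runs(
    ev: _Evaluator,
    fragment: Fragment,
    field: Field,
    config: EngineConfig,
    rngs: list[np.random.Generator],
) -> list[tuple[np.ndarray, float]]:
    """Evolve several independent GA runs in lock-step.

    Each run has its own RNG stream and its own population; they share no
    state, so results are identical whichever order (or grouping) the runs
    execute in — the lock-step layout only batches the expensive
    genome-to-score evaluation across runs.
    """
    R = len(rngs)
    P = config.population_size
    G = ev.genome_length()
    n_gens, n_top, polish = _generation_schedule(config)

    pop = np.empty((R, P, G))
    for r, rng in enumerate(rngs):
        pop[r] = _init_population(ev, fragment, field, P, rng)

    def eval_all(block: np.ndarray) -> np.ndarray:
        flat = block.reshape(-1, G)
        _, s = ev.scores(flat)
        return s.reshape(block.shape[0], block.shape[1])

    scores = eval_all(pop)
    best_idx = scores.argmin(axis=1)
    best_genome = pop[np.arange(R), best_idx].copy()
    best_score = scores[np.arange(R), best_idx].copy()

    n_act = ev.n_active
    for _ in range(n_gens):
        # Lamarckian local search on each run's top decile; all of a run's
        # Gaussian draws for this generation come from one rng call
        if n_top:
            order = np.argsort(scores, axis=1, kind="stable")[:, :n_top]
            rows = np.arange(R)[:, None]
            steps = config.local_search_steps
            draws = np.empty((R, steps, n_top, 7 + n_act))
            for r, rng in enumerate(rngs):
                draws[r] = rng.standard_normal((steps, n_top, 7 + n_act))
            for step in range(steps):
                cand = pop[rows, order].copy()
                d = draws[:, step]
                cand[:, :, :3] += LS_SIGMA_TRANSLATION * d[:, :, :3]
                cand[:, :, 3:7] = _quat_mul(
                    _rotation_from_draws(d[:, :, 3:7], LS_SIGMA_ANGLE), cand[:, :, 3:7]
                )
                if n_act:
                    cand[:, :, 7:] += LS_SIGMA_ANGLE * d[:, :, 7:]
                cs = eval_all(cand)
                better = cs < scores[rows, order]
                bi = np.where(better)
                pop[bi[0], order[bi]] = cand[bi]
                scores[bi[0], order[bi]] = cs[bi]

        # per-run GA bookkeeping (draws stay within each run's own stream)
        next_pop = np.empty_like(pop)
        for r, rng in enumerate(rngs):
            s = scores[r]
            sel = rng.integers(0, P, size=(2, P))
            cuts = rng.integers(0, G, size=(P // 2, 2))
            unif = rng.random((P, 5 + n_act))
            norm = rng.standard_normal((P, 7 + n_act))
            winners = np.where(s[sel[0]] <= s[sel[1]], sel[0], sel[1])
            child = pop[r, winners].copy()
            # two-point crossover on consecutive pairs
            for pair in np.flatnonzero(unif[: P // 2, 0] < config.crossover_rate):
                i = 2 * pair
                lo, hi = sorted(cuts[pair])
                if lo != hi and i + 1 < P:
                    tmp = child[i, lo:hi].copy()
                    child[i, lo:hi] = child[i + 1, lo:hi]
                    child[i + 1, lo:hi] = tmp
            # Gaussian mutation
            child[:, :3] += (unif[:, 1:4] < config.mutation_rate) * (
                SIGMA_TRANSLATION * norm[:, :3]
            )
            mq = unif[:, 4] < config.mutation_rate
            dq = _rotation_from_draws(norm[:, 3:7], SIGMA_ROTATION)
            child[:, 3:7] = np.where(mq[:, None], _quat_mul(dq, child[:, 3:7]), child[:, 3:7])
            if n_act:
                child[:, 7:] += (unif[:, 5:] < config.mutation_rate) * (
                    SIGMA_TORSION * norm[:, 7:]
                )
            child[0] = best_genome[r]  # elitism
            next_pop[r] = child

        pop = next_pop
        scores = eval_all(pop)
        idx = scores.argmin(axis=1)
        improved = scores[np.arange(R), idx] < best_score
        best_genome[improved] = pop[np.arange(R), idx][improved]
        best_score[improved] = scores[np.arange(R), idx][improved]

    if polish:
        # coordinate-wise adaptive hill-climb of each run's best genome:
        # one gene perturbed per step (cycling), with a per-gene step scale
        # that grows on success and shrinks on failure — this descends the
        # narrow anisotropic valleys a joint Gaussian move cannot
        draws = np.empty((R, polish))
        for r, rng in enumerate(rngs):
            draws[r] = rng.standard_normal(polish)
        scale = _coordinate_scales(G)
        rho = np.ones((R, G))
        for step in range(polish):
            d = step % G
            cand = best_genome.copy()
            cand[:, d] += rho[:, d] * scale[d] * draws[:, step]
            cs = eval_all(cand[:, None, :])[:, 0]
            better = cs < best_score
            best_genome[better] = cand[better]
            best_score[better] = cs[better]
            rho[:, d] = np.where(better, np.minimum(rho[:, d] * 1.6, 10.0), rho[:, d] * 0.8)

    return [(best_genome[r].copy(), float(best_score[r])) for r in range(R)]


def _coordinate_scales(G: int) -> np.ndarray:
    """Base per-gene proposal scales: 0.2 A translation, 0.05 otherwise."""
    scale = np.full(G, 0.05)
    scale[:3] = 0.2
    return scale


def _genome_to_conformation(ev: _Evaluator, genome: np.ndarray, score: float) -> ScoredConformation:
    q = genome[3:7] / np.linalg.norm(genome[3:7])
    torsions = {r + 1: float(ev.full_torsions[r]) for r in range(len(ev.full_torsions))}
    for slot, rank in enumerate(ev.active):
        torsions[rank] = float(genome[7 + slot])
    coords = ev.coords(genome[None])[0]
    conf = Conformation(
        translation=genome[:3].copy(),
        orientation=q,
        torsions=torsions,
        coords=coords,
        atom_indices=ev.kin.atom_indices,
    )
    conf.score = score
    return ScoredConformation(conformation=conf, s_ad=score, s_total=score)


def dock(
    fragment: Fragment,
    field: Field,
    config: EngineConfig,
    seed: int | None = None,
) -> DockingResult:
    """Dock one fragment: ``ga_run`` independent GA runs, one pose each.

    Each run draws from its own RNG stream derived from the master seed and
    the run index, so results are bitwise reproducible and independent of
    execution order.  Output poses are sorted ascending by score (ties by
    run index).
    """
    if len(fragment.active_ranks) > 6:
        raise ValueError("engine explores at most 6 active torsions per docking")
    master = config.seed if seed is None else seed
    ev = _Evaluator(fragment, field)
    rngs = [
        np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(entropy=master, spawn_key=(run,)))
        )
        for run in range(config.ga_run)
    ]
    ev.evals = 0
    per_run = _ga_runs(ev, fragment, field, config, rngs)
    total_evals = ev.evals
    results = [(score, run, genome) for run, (genome, score) in enumerate(per_run)]
    results.sort(key=lambda t: (t[0], t[1]))
    ev.evals = 0  # conversion rescoring below is bookkeeping, not search
    conformations = [_genome_to_conformation(ev, g, s) for s, _, g in results]
    return DockingResult(conformations=conformations, evals_used=total_evals)


def local_search(
    fragment: Fragment,
    conformation: Conformation,
    field: Field,
    steps: int,
    rng: np.random.Generator,
) -> Conformation:
    """Coordinate-wise stochastic hill-climb on one conformation's genome.

    Each step perturbs a single gene (cycling through translation,
    orientation and active torsions) with a per-gene adaptive scale that
    grows on success and shrinks on failure, keeping only improving moves;
    on a convex field this converges to the minimum.  With ``steps == 0``
    the input is returned unchanged; the returned conformation's score is
    never worse than the input's.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if steps == 0:
        return conformation
    ev = _Evaluator(fragment, field)
    G = ev.genome_length()
    genome = np.empty(G)
    genome[:3] = conformation.translation
    genome[3:7] = conformation.orientation
    genome[7:] = [conformation.torsions[r] for r in ev.active]
    _, s = ev.scores(genome[None])
    score = float(s[0])
    scale = _coordinate_scales(G)
    rho = np.ones(G)
    for step in range(steps):
        d = step % G
        cand = genome.copy()
        cand[d] += rho[d] * scale[d] * rng.standard_normal()
        _, cs = ev.scores(cand[None])
        if float(cs[0]) < score:
            genome, score = cand, float(cs[0])
            rho[d] = min(rho[d] * 1.6, 10.0)
        else:
            rho[d] *= 0.8
    return _genome_to_conformation(ev, genome, score).conformation
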