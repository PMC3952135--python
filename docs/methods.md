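# Methods

## Model

A ligand is an explicit atom/bond graph.  Its flexibility is reduced to a
**torsion tree**: removing all rotatable bonds from the graph leaves rigid
groups (the nodes); each rotatable bond is an edge, ranked 1..n by
breadth-first visit order from the root group.  A **genome** is
(translation, orientation quaternion, torsion angles); forward kinematics
applies the dihedral rotations root-outward and then the rigid-body
transform, so bond lengths, bond angles and non-rotatable dihedrals are
exactly those of the reference geometry.

Two conventions matter for reproducibility:

* **Torsions are deltas** relative to the reference geometry read from the
  input file.  The identity genome reproduces the input coordinates
  bit-for-bit, and a frozen torsion is conserved by copying a single float.
* **The rigid-body transform acts about the centroid of the root group**,
  which no torsion can move.  A parent pose's translation/orientation is
  therefore valid unchanged for every extended fragment that grows from it.

Rotatable bonds are acyclic single bonds between atoms that each have at
least two heavy neighbours; aromatic and amide C–N bonds are excluded.
Atom types come from a fixed table over (element, aromaticity,
polar-hydrogen attachment): `{C, A, N, NA, O, OA, S, SA, H, HD, P,
halogens}`; donors are N/O bearing a polar hydrogen, acceptors are
NA/OA/SA.  The root atom is the heavy atom maximizing donors + acceptors in
the fragment induced by bonds ranked 1..6 (an atom with role "both" counts
twice); ties break to the smaller maximum tree depth, then the lower atom
index.  On a long chain with a polar head this places the root a few bonds
*inside* the chain — the deepest position whose 6-bond fragment still
contains the whole head — which is the documented tie-break operating as
intended.

## Scoring

The engine score of a pose is the sum over atoms of trilinear
interpolations into per-atom-type potential grids plus charge × an
electrostatic grid.  Grid nodes hold the clamped pairwise sum over receptor
atoms of

* a 12-6 van der Waals term with arithmetic-mean radii and geometric-mean
  well depths (Rii: C/A 4.0 Å, N/NA 3.5, O/OA 3.2, S/SA 4.0, H/HD 2.0 Å;
  εii: 0.02–0.55 kcal/mol),
* a 12-10 hydrogen-bond term (R = 1.9 Å, ε = 5.0 kcal/mol) for
  donor–acceptor type pairs,
* Coulomb with the distance-dependent dielectric ε(r) = 4r
  (332.0636 kcal·Å·mol⁻¹·e⁻²).

Values are clamped at 10⁵ kcal/mol; an atom outside the box contributes a
10⁶ kcal/mol penalty instead of a map value.  Grid spacing defaults to
0.375 Å with dimensions counted in grid points.  There is no desolvation or
torsional-entropy term: the field is a deliberately simple, fully
reproducible stand-in, and the engine depends only on the
`Field.score_many` interface, so an adapter around an external docking
engine can replace it.

Interpolation accuracy: against the direct pairwise sum the grid score
agrees to ≲ 0.1 kcal/mol at 0.375 Å spacing *outside the repulsive wall*
(pair distances ≳ 3.7 Å for C–C); inside the wall the 12-6 term varies by
orders of magnitude between neighbouring nodes and both representations are
clamped, so no accuracy statement is meaningful there.  The error decreases
monotonically with spacing (checked at 0.75/0.375/0.1875 Å).

The restrained selection score is `S = w·D_a + S_AD` with `D_a` the squared
distance (Å²) of one named atom from its target and `w = 0.25`
kcal·mol⁻¹·Å⁻² by default, calibrated so that `D_a > 10 Å²` costs more
than 2.5 kcal/mol.  The restraint affects **selection only**, never the
engine's objective.

## Search engine

One docking = `ga_run` independent runs of a generational GA (elitism 1,
tournament selection k = 2, two-point genome crossover, Gaussian mutation
with σ = 1 Å translation and 0.1 rad rotation/torsion), each capped at
`ga_num_evals` score evaluations.  Defaults: population 150, mutation rate
0.3, crossover rate 0.8.  Two refinement stages are built in:

* a short fixed-scale Lamarckian local search of the top decile each
  generation (5 steps by default), and
* a **coordinate-wise adaptive polish** of each run's best genome at the
  end of the run (300 steps by default): one gene perturbed per step with a
  per-gene scale that grows ×1.6 on success and shrinks ×0.8 on failure.
  Joint Gaussian proposals stall in the anisotropic valleys of the pose
  landscape (a torsion error can be partly compensated by a small rigid
  shift); perturbing one coordinate at a time descends the shallow
  direction and reaches ~10⁻³–10⁻⁴ of the funnel minimum where joint moves
  plateau 100× higher.

All evaluations — initial population, per-generation, local search, polish
— are counted against `ga_num_evals`; whatever budget a full generation no
longer fits into is left unused, so the cap is never exceeded.  Each run
draws from its own RNG stream (`SeedSequence(master, spawn_key=(run,))`),
so results are bitwise reproducible and independent of run execution order
or grouping; internally all runs of a docking evolve in lock-step so that
genome→score evaluation is batched across runs.

Population initialization is uniform over the box/quaternion sphere/torsion
range for the first fragment, and parent-seeded at extensions: one exact
copy of the parent genome plus mutation-scale scatter.  Whether extension
steps should re-sample the rigid placement across the whole box is an open
modelling choice; parent seeding with full-box mutation range is this
package's choice, on the grounds that the parent placement is the only
information worth keeping between increments.

## Incremental protocol

Defaults (all configurable): initial fragment 6 bonds, extension 3,
re-exploration 3, select 5, 50 initial runs, 20 runs per parent, 250 000
evaluations per engine run.  For 14 bonds the active windows are
[1–6], [4–9], [7–12], [10–14] (the final window has 3 re-explored + 2 new
bonds: the new set is clipped, the re-explored set kept).  Selection pools
all candidates of a step (no per-parent quota) and keeps the `select_k`
lowest by `s_total`, ties by engine score then insertion order.
Sub-dockings draw independent seed streams keyed by (step, parent), so a
parallel implementation would reproduce serial results exactly.

## Synthetic fixtures and what they do (not) show

The chain-ligand generator emulates the one property that drives the
protocol — many rotatable bonds in series — with ideal geometry (C–C
1.54 Å, 109.47° angles) and an optional polar head (two acceptor oxygens,
one donor N–H) that anchors root selection; backbone carbons carry small
alternating charges so the electrostatic path is exercised.  The planted
complex places a random genome of such a ligand inside a ligand-derived box
(margin 8 Å per side, redrawing until every atom is ≥ 1 Å inside) and
builds per-atom harmonic wells (k = 1 kcal·mol⁻¹·Å⁻²) at the planted atom
positions, optionally with a bounded cosine roughness that leaves the
global minimum in place.  Because the planted pose is *provably* the global
minimum, pose recovery is an unambiguous pass/fail signal.

What passing these tests does **not** show: performance on real energy
landscapes (rugged, with competing minima and inter-fragment frustration),
ring conformers, protonation effects, or receptor flexibility.  The funnel
rewards every fragment for sitting at its planted position, so the greedy
increment-and-select loop is well matched to it by construction; on real
fields the selection pressure can discard the basin of the true pose early,
which is exactly the failure mode the re-exploration window mitigates but
cannot eliminate.

## Problem sizes used in the checks

Recovery checks run the 9-torsion planted complex at 20 000 evaluations per
engine run over 10 seeds; the full-bookkeeping count check and the
acceptance script run the 14-torsion complex at 300–2 000 evaluations per
run, since the pool arithmetic (50 → 5 → 5×20 = 100 → 6 reported) is
structural and independent of the search budget.

The restraint-efficacy comparison needs care: on the plain funnel the
engine score already contains a harmonic term on the head atom that is
steeper than the restraint (k = 1 vs w = 0.25), so restrained and
unrestrained selection pick essentially the same poses and the comparison
degenerates to a tie.  The efficacy check therefore uses the ``flat_head``
funnel variant — wells removed from the head group, so the field carries no
information about the head position, exactly the situation a positional
restraint exists for — at 2 000 evaluations per run, 10 seeds per arm, with
the same root atom in both arms so the only difference is the selection
score.

## Known limitations

* The scoring field omits desolvation, torsional entropy and receptor
  charges unless provided; absolute energies are not comparable to
  production scoring functions.
* RMSD uses identity atom correspondence without graph-automorphism
  correction; symmetric ligands can report inflated RMSD.
* Receptor preparation is minimal (heavy atoms, element-based typing,
  highest-occupancy altLoc); no protonation or charge assignment.
* The engine explores at most 6 active torsions per docking by design;
  ligands are assumed connected with at least two heavy atoms.
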