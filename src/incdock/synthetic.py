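"""Synthetic ligands, receptors and fields with known ground truth.

Real docking benchmarks need deposited structures and a production scoring
function; everything here is generated from a handful of parameters so that
each stage of the pipeline can be exercised against provable expectations:

* :func:`make_chain_ligand` builds an idealized acyclic carbon chain with a
  chosen number of rotatable bonds (1.54 A C-C bonds, 109.47 deg angles)
  and, optionally, a polar head group (two acceptor oxygens and one donor
  N-H) that concentrates the hydrogen-bond donors/acceptors at one end.
* :func:`make_planted_complex` plants a random pose of such a ligand inside
  a binding box and returns a scoring field whose global minimum is, by
  construction, exactly that pose — per-atom harmonic wells centred on the
  planted atom positions.  Recovering the planted pose is then an
  unambiguous success criterion.

Every fixture is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mol import (
    Atom,
    Bond,
    Conformation,
    Ligand,
    apply_genome,
    assign_atom_types,
    build_torsion_tree,
    detect_rotatable_bonds,
    random_quaternion,
    write_mol2,
)
from .scoring import BindingBox, Field, GridField, build_field, resolve_box

__all__ = [
    "make_chain_ligand",
    "make_planted_complex",
    "HarmonicFunnelField",
    "make_point_receptor_field",
    "make_test_receptor_pdb",
]

CC_BOND = 1.54  # A
CO_BOND = 1.43
CN_BOND = 1.47
NH_BOND = 1.01
TET_ANGLE = np.deg2rad(109.47)


def make_chain_ligand(
    n_torsions: int,
    polar_head: bool = True,
    name: str | None = None,
) -> Ligand:
    """An acyclic chain ligand with exactly ``n_torsions`` rotatable bonds.

    The backbone is an all-anti carbon zig-zag; with ``polar_head`` the
    first carbon additionally carries O1, O2 (acceptors) and an N1-H1 donor,
    so root-atom selection is drawn to the head.  Backbone carbons carry
    small alternating charges and the head is polarized, keeping the
    electrostatic term non-trivial.  Deterministic; the rotatable-bond count
    is asserted against the detection rule before returning.
    """
    if n_torsions < 0:
        raise ValueError("n_torsions must be >= 0")
    n_carbons = n_torsions + (2 if polar_head else 3)
    if n_carbons < 2:
        n_carbons = 2

    half = (np.pi - TET_ANGLE) / 2.0
    step = CC_BOND * np.array([np.cos(half), np.sin(half), 0.0])
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    pos = np.zeros(3)
    for i in range(n_carbons):
        charge = 0.05 if i % 2 else -0.05
        atoms.append(Atom(index=i, name=f"C{i + 1}", element="C", coords=pos.copy(), charge=charge))
        if i > 0:
            bonds.append(Bond(a=i - 1, b=i, order=1))
        d = step.copy()
        d[1] = -d[1] if i % 2 else d[1]
        pos = pos + d

    if polar_head:
        c1 = atoms[0].coords
        back = c1 - atoms[1].coords
        back = back / np.linalg.norm(back)

        def _place(direction: np.ndarray, length: float) -> np.ndarray:
            d = direction / np.linalg.norm(direction)
            return c1 + length * d

        o1 = _place(back + np.array([0.0, 0.0, 1.2]), CO_BOND)
        o2 = _place(back + np.array([0.0, 0.0, -1.2]), CO_BOND)
        n1 = _place(back + np.array([0.0, 1.2, 0.0]), CN_BOND)
        h1 = n1 + NH_BOND * back
        base = len(atoms)
        atoms.append(Atom(index=base, name="O1", element="O", coords=o1, charge=-0.40))
        atoms.append(Atom(index=base + 1, name="O2", element="O", coords=o2, charge=-0.40))
        atoms.append(Atom(index=base + 2, name="N1", element="N", coords=n1, charge=-0.30))
        atoms.append(Atom(index=base + 3, name="H1", element="H", coords=h1, charge=0.30))
        atoms[0].charge = 0.35
        bonds.append(Bond(a=0, b=base, order=1))
        bonds.append(Bond(a=0, b=base + 1, order=1))
        bonds.append(Bond(a=0, b=base + 2, order=1))
        bonds.append(Bond(a=base + 2, b=base + 3, order=1))

    ligand = Ligand(atoms=atoms, bonds=bonds, name=name or f"chain{n_torsions}")
    assign_atom_types(ligand)
    detect_rotatable_bonds(ligand)
    found = ligand.n_rotatable()
    if found != n_torsions:
        raise AssertionError(f"fixture bug: built {found} rotatable bonds, wanted {n_torsions}")
    return ligand


def make_chain_ligand_mol2(n_torsions: int, polar_head: bool = True) -> str:
    """mol2 serialization of :func:`make_chain_ligand` (round-trip friendly)."""
    return write_mol2(make_chain_ligand(n_torsions, polar_head))


class HarmonicFunnelField(Field):
    """Analytic field with its global minimum planted at a known pose.

    The score of a pose is ``sum_i k * |x_i - x_i*|^2`` over the atoms
    present (``x_i*`` the planted position of ligand atom ``i``), plus an
    optional bounded roughness term ``noise * (1 - cos(omega * |x_i - x_i*|))``
    that adds local ripples without moving the global minimum.  Both terms
    vanish exactly at the planted pose and are positive elsewhere, so the
    planted pose is provably the unique global minimum.  Translating the
    planted coordinates and the pose together leaves the score unchanged.
    """

    def __init__(
        self,
        box: BindingBox,
        planted_coords: np.ndarray,
        k: float = 1.0,
        noise: float = 0.0,
        noise_omega: float = 4.0,
        weights: np.ndarray | None = None,
    ):
        self.box = box
        self.planted_coords = np.asarray(planted_coords, dtype=float)
        self.k = float(k)
        self.noise = float(noise)
        self.noise_omega = float(noise_omega)
        # per-atom well weights; a zero entry makes the field agnostic about
        # that atom's position (used to study restraints, whose information
        # must then come from the restraint alone)
        self.weights = (
            np.ones(len(self.planted_coords)) if weights is None
            else np.asarray(weights, dtype=float)
        )

    def score_many(self, coords: np.ndarray, atoms) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        idx = [a.index for a in atoms]
        target = self.planted_coords[idx]
        w = self.weights[idx]
        diff = coords - target
        d2 = (diff * diff).sum(axis=-1)  # (P, N)
        if self.noise:
            e = w * (self.k * d2 + self.noise * (1.0 - np.cos(self.noise_omega * np.sqrt(d2))))
            return e.sum(axis=1)
        return self.k * (w * d2).sum(axis=1)


@dataclass
class PlantedComplex:
    """A synthetic docking problem with a known answer."""

    ligand: Ligand
    box: BindingBox
    field: Field
    planted: Conformation
    root_atom: int


def make_planted_complex(
    n_torsions: int = 9,
    seed: int = 0,
    field_kind: str = "analytic_funnel",
    noise: float = 0.0,
    polar_head: bool = True,
    margin: float = 8.0,
    root_atom: int | None = None,
    flat_head: bool = False,
) -> PlantedComplex:
    """Plant a random pose of a chain ligand inside a ligand-derived box.

    The box is centred on the reference ligand with ``margin`` per side; the
    planted genome draws uniform torsions and orientation with the root
    centroid near the box centre, re-drawing (up to 200 tries) until every
    atom lies at least 1 A inside the box.  ``analytic_funnel`` plants
    per-atom harmonic wells at the resulting coordinates; ``point_receptor``
    instead builds a grid field from a single carbon receptor atom (useful
    for interpolation oracles, with no planted-minimum guarantee).

    With ``flat_head`` the funnel's wells on the polar head group (O1, O2,
    N1, H1) are removed: the field then says nothing about where the head
    sits, emulating the situation where an anchor atom's location is known
    only from outside evidence and must be supplied as a restraint.
    """
    ligand = make_chain_ligand(n_torsions, polar_head=polar_head)
    box = resolve_box("ligand", "ligand", ligand=ligand, margin=margin)
    if root_atom is None:
        root_atom = ligand.atom_by_name("O1").index if polar_head else 0
    tree = build_torsion_tree(ligand, root_atom)
    rng = np.random.default_rng(seed)
    lo, hi = box.bounds()
    for _ in range(200):
        torsions = {r: float(rng.uniform(-np.pi, np.pi)) for r in range(1, tree.n_bonds + 1)}
        orientation = random_quaternion(rng)
        translation = box.center + rng.uniform(-1.0, 1.0, size=3)
        coords = apply_genome(ligand, tree, translation, orientation, torsions)
        if np.all((coords >= lo + 1.0) & (coords <= hi - 1.0)):
            break
    else:
        raise ValueError("could not plant a pose inside the box; enlarge the margin")
    planted = Conformation(
        translation=translation,
        orientation=orientation,
        torsions=torsions,
        coords=coords,
        atom_indices=tuple(range(len(ligand.atoms))),
    )
    if field_kind == "analytic_funnel":
        weights = None
        if flat_head:
            if not polar_head:
                raise ValueError("flat_head requires a polar head group")
            weights = np.ones(len(ligand.atoms))
            for atom_name in ("O1", "O2", "N1", "H1"):
                weights[ligand.atom_by_name(atom_name).index] = 0.0
        field: Field = HarmonicFunnelField(box, coords, noise=noise, weights=weights)
    elif field_kind == "point_receptor":
        head = coords[root_atom] + np.array([0.0, 0.0, 4.0])
        receptor = [
            Atom(index=0, name="C1", element="C", coords=head, charge=0.0, atom_type="C")
        ]
        types = {a.atom_type for a in ligand.atoms}
        field = build_field(receptor, box, types)
    else:
        raise ValueError(f"unknown field kind {field_kind!r}")
    return PlantedComplex(ligand=ligand, box=box, field=field, planted=planted, root_atom=root_atom)


def make_point_receptor_field(
    box: BindingBox, position: np.ndarray | None = None, ligand_types: set[str] | None = None
) -> GridField:
    """Grid field from a single neutral carbon receptor atom.

    The direct pairwise score is trivially recomputable, which makes this
    the reference problem for grid-interpolation accuracy checks.
    """
    pos = np.asarray(position, dtype=float) if position is not None else box.center
    receptor = [Atom(index=0, name="C1", element="C", coords=pos, charge=0.0, atom_type="C")]
    return build_field(receptor, box, ligand_types or {"C"})


def make_test_receptor_pdb(n_residues: int = 3) -> str:
    """PDB text of a tiny synthetic poly-glycine strand (backbone only).

    Purely artificial geometry (residues spaced along x); intended for
    parser and typing tests, not for physics.
    """
    lines = []
    serial = 1
    for res in range(1, n_residues + 1):
        x0 = 3.8 * (res - 1)
        for name, element, (dx, dy, dz) in [
            ("N", "N", (0.0, 0.0, 0.0)),
            ("CA", "C", (1.46, 0.0, 0.0)),
            ("C", "C", (2.20, 1.20, 0.0)),
            ("O", "O", (2.00, 2.30, 0.5)),
        ]:
            lines.append(
                f"ATOM  {serial:>5d}  {name:<3s} GLY A{res:>4d}    "
                f"{x0 + dx:8.3f}{dy:8.3f}{dz:8.3f}  1.00  0.00          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
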