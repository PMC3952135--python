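"""Ligand and receptor models: parsing, typing, torsion trees and kinematics.

The ligand is an explicit atom/bond graph.  Flexibility is described by a
*torsion tree*: a rooted tree whose nodes are rigid groups of atoms (connected
through non-rotatable bonds only) and whose edges are the rotatable bonds,
ranked by breadth-first visit order from the root group.  A *fragment* is the
sub-ligand spanned by the root group plus all bonds up to some rank; docking a
fragment samples the rigid-body placement plus the torsions of its *active*
bonds while *frozen* bonds keep the angles inherited from a parent pose.

Conventions
-----------
* Coordinates are Angstrom throughout; torsion angles are radians.
* Torsion angles in a genome are *deltas relative to the ligand's reference
  geometry* (the coordinates read from the input file); a zero delta leaves
  the reference dihedral untouched, so the identity genome reproduces the
  reference coordinates exactly.
* The rigid-body orientation is applied about the centroid of the root-group
  atoms, which no torsion can move; the translation component of a genome is
  therefore the absolute position of that centroid.  This makes genomes
  directly transferable when a fragment is extended.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Bond",
    "Ligand",
    "TorsionTree",
    "TreeEdge",
    "Fragment",
    "Conformation",
    "Mol2ParseError",
    "parse_mol2",
    "write_mol2",
    "parse_pdb_receptor",
    "detect_rotatable_bonds",
    "select_root_atom",
    "build_torsion_tree",
    "extract_fragment",
    "apply_genome",
    "randomize_conformation",
    "measure_dihedral",
    "BatchKinematics",
]

#: Elements treated as halogens in the typing table.
HALOGENS = {"F", "Cl", "Br", "I"}

#: Tokens the typing table can emit.
ATOM_TYPES = {"C", "A", "N", "NA", "O", "OA", "S", "SA", "H", "HD", "P"} | HALOGENS


@dataclass
class Atom:
    """One atom of a ligand or receptor.

    ``atom_type`` is a token from the documented typing table; ``hbond_role``
    is one of ``{"donor", "acceptor", "both", "none"}`` and is kept consistent
    with the type (donors are N/O bearing a polar hydrogen; acceptors are the
    NA/OA/SA types).
    """

    index: int
    name: str
    element: str
    coords: np.ndarray
    charge: float = 0.0
    atom_type: str = ""
    hbond_role: str = "none"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")


@dataclass
class Bond:
    """Covalent bond between atom indices ``a`` and ``b``.

    ``kind`` keeps the raw mol2 bond-type token ("1", "2", "3", "am", "ar");
    ``order`` is its integer reduction (aromatic and amide count as 1).
    """

    a: int
    b: int
    order: int = 1
    kind: str = "1"
    rotatable: bool = False

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("bond endpoints must differ")


@dataclass
class Ligand:
    """Atom/bond graph of a ligand."""

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = "ligand"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise ValueError(f"bond ({bond.a},{bond.b}) references missing atom")
        if sum(1 for a in self.atoms if a.element != "H") < 2:
            raise ValueError("ligand must have at least 2 heavy atoms")
        if n > 1 and not nx.is_connected(self.graph()):
            raise ValueError("ligand bond graph is disconnected")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.a, b.b) for b in self.bonds)
        return g

    def coords(self) -> np.ndarray:
        """Reference coordinates, shape ``(n_atoms, 3)``."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.element != "H"]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a == i:
                out.append(b.b)
            elif b.b == i:
                out.append(b.a)
        return sorted(out)

    def n_rotatable(self) -> int:
        return sum(1 for b in self.bonds if b.rotatable)

    def atom_by_name(self, name: str) -> Atom:
        hits = [a for a in self.atoms if a.name == name]
        if len(hits) != 1:
            raise ValueError(
                f"atom name {name!r} matches {len(hits)} atoms "
                f"(candidates: {sorted({a.name for a in self.atoms})})"
            )
        return hits[0]


class Mol2ParseError(ValueError):
    """Raised when a TRIPOS mol2 document cannot be parsed; names the line."""


def _element_from_mol2(sybyl_type: str, name: str) -> str:
    """Element symbol from a SYBYL atom type ('C.3', 'O.co2', 'Du') or name."""
    base = sybyl_type.split(".")[0]
    if base and base[0].isalpha():
        cand = base[:2].capitalize() if len(base) >= 2 and base[1].islower() else base[0].upper()
        known = {"C", "N", "O", "S", "P", "H", "F", "Cl", "Br", "I", "B", "Si", "Se", "Zn", "Fe", "Mg", "Mn", "Ca", "Na", "K"}
        if cand in known:
            return cand
        if base[0].upper() in {k for k in known if len(k) == 1}:
            return base[0].upper()
    # fall back to the atom name
    stripped = "".join(ch for ch in name if ch.isalpha())
    return (stripped[:1] or "X").upper()


def parse_mol2(text: str, *, name: str | None = None) -> Ligand:
    """Parse a TRIPOS mol2 document into a :class:`Ligand`.

    Atom names, elements and coordinates come from the ATOM records; partial
    charges are taken from the file when the charge column is present,
    otherwise set to zero with a logged warning.  Atom types and H-bond roles
    are assigned from the documented table, and rotatable bonds are flagged.

    Raises
    ------
    Mol2ParseError
        On a malformed record (the message names the offending line) or when
        the bond graph is disconnected.
    """
    section = None
    mol_name = name
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    idmap: dict[int, int] = {}
    mol_lines = 0
    saw_charges = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            mol_lines = 0
            continue
        if section == "MOLECULE":
            mol_lines += 1
            if mol_lines == 1 and mol_name is None:
                mol_name = line
        elif section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise Mol2ParseError(f"line {lineno}: malformed ATOM record: {raw!r}")
            try:
                aid = int(parts[0])
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            except ValueError as exc:
                raise Mol2ParseError(f"line {lineno}: malformed ATOM record: {exc}") from None
            charge = 0.0
            if len(parts) >= 9:
                try:
                    charge = float(parts[8])
                    saw_charges = True
                except ValueError as exc:
                    raise Mol2ParseError(f"line {lineno}: bad charge field: {exc}") from None
            idmap[aid] = len(atoms)
            atoms.append(
                Atom(
                    index=len(atoms),
                    name=parts[1],
                    element=_element_from_mol2(parts[5], parts[1]),
                    coords=xyz,
                    charge=charge,
                )
            )
        elif section == "BOND":
            parts = line.split()
            if len(parts) < 4:
                raise Mol2ParseError(f"line {lineno}: malformed BOND record: {raw!r}")
            try:
                a, b = idmap[int(parts[1])], idmap[int(parts[2])]
            except (ValueError, KeyError):
                raise Mol2ParseError(
                    f"line {lineno}: BOND references unknown atom id: {raw!r}"
                ) from None
            kind = parts[3]
            order = {"1": 1, "2": 2, "3": 3, "am": 1, "ar": 1, "du": 1, "un": 1}.get(kind, 1)
            bonds.append(Bond(a=a, b=b, order=order, kind=kind))

    if not atoms:
        raise Mol2ParseError("no ATOM records found")
    if not saw_charges:
        logger.warning("mol2 input carries no charge column; all charges set to 0")
    try:
        ligand = Ligand(atoms=atoms, bonds=bonds, name=mol_name or "ligand")
    except ValueError as exc:
        raise Mol2ParseError(str(exc)) from None
    assign_atom_types(ligand)
    detect_rotatable_bonds(ligand)
    return ligand


def write_mol2(ligand: Ligand) -> str:
    """Serialize a ligand back to TRIPOS mol2 text (inverse of :func:`parse_mol2`)."""
    buf = io.StringIO()
    buf.write("@<TRIPOS>MOLECULE\n")
    buf.write(f"{ligand.name}\n")
    buf.write(f"{len(ligand.atoms)} {len(ligand.bonds)} 0 0 0\n")
    buf.write("SMALL\nUSER_CHARGES\n")
    buf.write("@<TRIPOS>ATOM\n")
    for a in ligand.atoms:
        x, y, z = a.coords
        buf.write(
            f"{a.index + 1:>7d} {a.name:<8s} {x:>9.4f} {y:>9.4f} {z:>9.4f} "
            f"{a.element:<5s} 1 LIG {a.charge:>9.4f}\n"
        )
    buf.write("@<TRIPOS>BOND\n")
    for i, b in enumerate(ligand.bonds, start=1):
        buf.write(f"{i:>6d} {b.a + 1:>5d} {b.b + 1:>5d} {b.kind:>4s}\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# atom typing


def assign_atom_types(ligand: Ligand) -> Ligand:
    """Assign atom types and hydrogen-bond roles from the documented table.

    The table maps (element, aromaticity, polar-hydrogen attachment) to the
    tokens ``{C, A, N, NA, O, OA, S, SA, H, HD, F, Cl, Br, I, P}``:

    * carbon: ``A`` when aromatic (mol2 ``ar`` bond or ``.ar`` type), else ``C``;
    * nitrogen: ``N`` (donor) when it bears a hydrogen, else ``NA`` (acceptor);
    * oxygen: ``OA`` (acceptor; role ``both`` when it also bears a hydrogen);
    * sulfur: ``SA`` (acceptor); phosphorus: ``P``;
    * hydrogen: ``HD`` when bonded to N/O/S (polar), else ``H``;
    * halogens keep their element symbol, role ``none``.
    """
    g = ligand.graph()
    aromatic_atoms: set[int] = set()
    for b in ligand.bonds:
        if b.kind == "ar":
            aromatic_atoms.update((b.a, b.b))

    def has_h(i: int) -> bool:
        return any(ligand.atoms[j].element == "H" for j in g.neighbors(i))

    for a in ligand.atoms:
        el = a.element
        if el == "C":
            a.atom_type, a.hbond_role = ("A" if a.index in aromatic_atoms else "C"), "none"
        elif el == "N":
            if has_h(a.index):
                a.atom_type, a.hbond_role = "N", "donor"
            else:
                a.atom_type, a.hbond_role = "NA", "acceptor"
        elif el == "O":
            a.atom_type = "OA"
            a.hbond_role = "both" if has_h(a.index) else "acceptor"
        elif el == "S":
            a.atom_type, a.hbond_role = "SA", "acceptor"
        elif el == "P":
            a.atom_type, a.hbond_role = "P", "none"
        elif el == "H":
            polar = any(
                ligand.atoms[j].element in ("N", "O", "S") for j in g.neighbors(a.index)
            )
            a.atom_type, a.hbond_role = ("HD" if polar else "H"), "none"
        elif el in HALOGENS:
            a.atom_type, a.hbond_role = el, "none"
        else:
            a.atom_type, a.hbond_role = "C", "none"  # permissive fallback for exotica
    return ligand


# ---------------------------------------------------------------------------
# receptor parsing


def parse_pdb_receptor(text: str) -> list[Atom]:
    """Extract typed heavy atoms from a PDB document.

    Hydrogens are dropped; alternate locations are resolved to the highest
    occupancy (ties to the earlier altLoc identifier).  Types come from the
    element: C->C, N->N (treated as a donor), O->OA, S->SA, P->P, halogens
    keep their symbol.  Raises ``ValueError`` when no ATOM/HETATM records are
    present.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("receptor", io.StringIO(text))

    out: list[Atom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for pdb_atom in residue:
                    if pdb_atom.is_disordered():
                        alts = sorted(
                            pdb_atom.disordered_get_list(),
                            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                        )
                        pdb_atom = alts[0]
                    element = (pdb_atom.element or pdb_atom.get_name()[:1]).strip().capitalize()
                    if element == "H":
                        continue
                    role = {"O": "acceptor", "S": "acceptor", "N": "donor"}.get(element, "none")
                    atype = {"C": "C", "N": "N", "O": "OA", "S": "SA", "P": "P"}.get(element)
                    if atype is None:
                        atype = element if element in HALOGENS else "C"
                    out.append(
                        Atom(
                            index=len(out),
                            name=pdb_atom.get_name(),
                            element=element,
                            coords=np.asarray(pdb_atom.get_coord(), dtype=float),
                            charge=0.0,
                            atom_type=atype,
                            hbond_role=role,
                        )
                    )
        break  # first model only
    if not out:
        raise ValueError("no ATOM/HETATM records found in PDB input")
    return out


# ---------------------------------------------------------------------------
# rotatable bonds


def detect_rotatable_bonds(ligand: Ligand) -> Ligand:
    """Flag each bond as rotatable or not, in place, and return the ligand.

    A bond is rotatable iff it is a single bond (not aromatic, not amide),
    lies in no ring, and both endpoints have at least two heavy-atom
    neighbours.  The heavy-neighbour condition removes bonds to hydrogens and
    bonds to terminal groups whose rotation moves only hydrogens.  Amide C-N
    bonds are excluded both by the mol2 ``am`` token and structurally (a
    C(=O)-N bond).
    """
    g = ligand.graph()
    ring_edges: set[frozenset[int]] = set()
    for cycle in nx.cycle_basis(g):
        for i in range(len(cycle)):
            ring_edges.add(frozenset((cycle[i], cycle[(i + 1) % len(cycle)])))

    heavy_deg = {
        i: sum(1 for j in g.neighbors(i) if ligand.atoms[j].element != "H")
        for i in range(len(ligand.atoms))
    }

    def is_amide(a: int, b: int) -> bool:
        ea, eb = ligand.atoms[a].element, ligand.atoms[b].element
        if {ea, eb} != {"C", "N"}:
            return False
        c = a if ea == "C" else b
        for bond in ligand.bonds:
            if bond.order == 2 and c in (bond.a, bond.b):
                other = bond.b if bond.a == c else bond.a
                if ligand.atoms[other].element == "O":
                    return True
        return False

    for bond in ligand.bonds:
        bond.rotatable = (
            bond.order == 1
            and bond.kind not in ("ar", "am")
            and frozenset((bond.a, bond.b)) not in ring_edges
            and heavy_deg[bond.a] >= 2
            and heavy_deg[bond.b] >= 2
            and not is_amide(bond.a, bond.b)
        )
    return ligand


# ---------------------------------------------------------------------------
# torsion tree


@dataclass(frozen=True)
class TreeEdge:
    """One rotatable bond inside a torsion tree.

    ``pivot`` is the bond endpoint on the parent (root-facing) side and
    ``moved`` the endpoint on the child side; rotation about the pivot->moved
    axis moves the child node's atoms and everything below them.
    """

    rank: int
    parent_node: int
    child_node: int
    pivot: int
    moved: int


@dataclass
class TorsionTree:
    """Rooted rigid-group decomposition of a ligand.

    ``nodes[0]`` is the root group (the root atom plus everything reachable
    through non-rotatable bonds); each edge is a rotatable bond carrying a
    breadth-first rank from 1 to the number of rotatable bonds.
    """

    root_atom: int
    nodes: list[frozenset[int]]
    edges: list[TreeEdge]
    moved_sets: dict[int, frozenset[int]] = field(default_factory=dict)

    @property
    def n_bonds(self) -> int:
        return len(self.edges)

    def edge_by_rank(self, rank: int) -> TreeEdge:
        return self.edges[rank - 1]

    def atoms_up_to_rank(self, max_rank: int) -> frozenset[int]:
        """Root-group atoms plus the atoms of every bond ranked <= ``max_rank``."""
        out = set(self.nodes[0])
        for edge in self.edges[:max_rank]:
            out |= self.nodes[edge.child_node]
        return frozenset(out)

    def dihedral_atoms(self, rank: int, ligand: Ligand) -> tuple[int, int, int, int]:
        """A canonical (i, j, k, l) quadruple measuring this bond's dihedral.

        j, k are the pivot and moved endpoints; i is the lowest-index
        neighbour of j other than k, and l the lowest-index neighbour of k
        other than j.
        """
        edge = self.edge_by_rank(rank)
        j, k = edge.pivot, edge.moved
        i = min(x for x in ligand.neighbors(j) if x != k)
        l = min(x for x in ligand.neighbors(k) if x != j)
        return i, j, k, l


def build_torsion_tree(ligand: Ligand, root_atom: int) -> TorsionTree:
    """Build the torsion tree rooted at ``root_atom``.

    Rigid groups are the connected components of the bond graph with the
    rotatable bonds removed; the tree is the quotient graph over rotatable
    bonds, ranked by breadth-first visit order with children explored in
    ascending index of their bond's distal atom (determinism tie-break).
    """
    g = ligand.graph()
    rigid = g.copy()
    rot_bonds = [b for b in ligand.bonds if b.rotatable]
    rigid.remove_edges_from((b.a, b.b) for b in rot_bonds)

    comp_of: dict[int, int] = {}
    groups: list[frozenset[int]] = []
    for comp in nx.connected_components(rigid):
        for atom in comp:
            comp_of[atom] = len(groups)
        groups.append(frozenset(comp))

    root_group = comp_of[root_atom]
    # adjacency between rigid groups through rotatable bonds
    group_links: dict[int, list[tuple[int, int, int]]] = {i: [] for i in range(len(groups))}
    for b in rot_bonds:
        group_links[comp_of[b.a]].append((b.b, b.a, comp_of[b.b]))
        group_links[comp_of[b.b]].append((b.a, b.b, comp_of[b.a]))

    order = {root_group: 0}
    nodes: list[frozenset[int]] = [groups[root_group]]
    edges: list[TreeEdge] = []
    queue = [root_group]
    children: dict[int, list[int]] = {}
    while queue:
        grp = queue.pop(0)
        for distal, pivot, other in sorted(group_links[grp]):
            if other in order:
                continue
            order[other] = len(nodes)
            nodes.append(groups[other])
            edges.append(
                TreeEdge(
                    rank=len(edges) + 1,
                    parent_node=order[grp],
                    child_node=order[other],
                    pivot=pivot,
                    moved=distal,
                )
            )
            children.setdefault(order[grp], []).append(order[other])
            queue.append(other)

    # atoms moved by each bond: child node plus all descendant nodes
    moved_sets: dict[int, frozenset[int]] = {}
    for edge in reversed(edges):
        moved = set(nodes[edge.child_node])
        for child in children.get(edge.child_node, []):
            child_edge = next(e for e in edges if e.child_node == child)
            moved |= moved_sets[child_edge.rank]
        moved_sets[edge.rank] = frozenset(moved)

    return TorsionTree(root_atom=root_atom, nodes=nodes, edges=edges, moved_sets=moved_sets)


def tree_depth(tree: TorsionTree) -> int:
    """Maximum number of rotatable bonds on any root-to-leaf path."""
    depth = {0: 0}
    out = 0
    for edge in tree.edges:  # edges are in BFS order, parents precede children
        depth[edge.child_node] = depth[edge.parent_node] + 1
        out = max(out, depth[edge.child_node])
    return out


def _da_count(ligand: Ligand, atoms: frozenset[int]) -> int:
    """Hydrogen-bond donors plus acceptors among ``atoms`` (``both`` counts twice)."""
    n = 0
    for i in atoms:
        role = ligand.atoms[i].hbond_role
        if role == "donor" or role == "both":
            n += 1
        if role == "acceptor" or role == "both":
            n += 1
    return n


def select_root_atom(ligand: Ligand, fragment_size: int = 6) -> int:
    """Pick the root atom maximizing donors+acceptors in the initial fragment.

    Every heavy atom is a candidate root; for each, the torsion tree is built
    and the fragment induced by the root group plus bonds ranked
    ``1..fragment_size`` is scored by its combined count of hydrogen-bond
    donors and acceptors.  Ties break to the smaller maximum tree depth, then
    to the lower atom index.
    """
    best: tuple[int, int, int] | None = None  # (-count, depth, index)
    best_atom = None
    for atom in ligand.atoms:
        if atom.element == "H":
            continue
        tree = build_torsion_tree(ligand, atom.index)
        frag = tree.atoms_up_to_rank(min(fragment_size, tree.n_bonds))
        key = (-_da_count(ligand, frag), tree_depth(tree), atom.index)
        if best is None or key < best:
            best, best_atom = key, atom.index
    assert best_atom is not None
    return best_atom


# ---------------------------------------------------------------------------
# fragments and conformations


@dataclass
class Conformation:
    """A pose genome plus its derived Cartesian coordinates.

    ``torsions`` maps bond rank to a delta angle (radians) relative to the
    reference geometry.  ``coords`` covers ``atom_indices`` in ascending
    ligand-index order.  ``score`` is the engine score in kcal/mol, or None
    before scoring.
    """

    translation: np.ndarray
    orientation: np.ndarray
    torsions: dict[int, float]
    coords: np.ndarray | None = None
    atom_indices: tuple[int, ...] = ()
    score: float | None = None

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValueError("orientation quaternion must have unit norm")


@dataclass
class Fragment:
    """The sub-ligand docked at one increment.

    ``atom_subset`` is the root group plus the atoms of every bond ranked up
    to ``max_rank``; torsions in ``active_ranks`` are sampled, those in
    ``frozen_ranks`` are held at the parent's angles.
    """

    ligand: Ligand
    tree: TorsionTree
    max_rank: int
    atom_subset: frozenset[int]
    active_ranks: frozenset[int]
    frozen_ranks: frozenset[int]
    parent_geometry: Conformation | None = None

    @property
    def frozen_torsions(self) -> dict[int, float]:
        if self.parent_geometry is None:
            return {}
        return {r: self.parent_geometry.torsions[r] for r in sorted(self.frozen_ranks)}


def extract_fragment(
    tree: TorsionTree,
    ligand: Ligand,
    max_rank: int,
    active_ranks: set[int] | frozenset[int],
    parent: Conformation | None = None,
) -> Fragment:
    """Extract the fragment spanned by bonds ranked ``1..max_rank``.

    Frozen ranks are ``1..max_rank`` minus ``active_ranks``; when a parent is
    given its torsion angles are inherited for the frozen ranks (and must be
    present).  Without a parent there must be no frozen ranks.
    """
    active = frozenset(active_ranks)
    if max_rank > tree.n_bonds:
        raise ValueError(f"max_rank {max_rank} exceeds {tree.n_bonds} rotatable bonds")
    if any(r < 1 or r > max_rank for r in active):
        raise ValueError(f"active_ranks {sorted(active)} not within 1..{max_rank}")
    frozen = frozenset(range(1, max_rank + 1)) - active
    if frozen and parent is None:
        raise ValueError("frozen ranks present but no parent geometry supplied")
    if parent is not None:
        missing = [r for r in frozen if r not in parent.torsions]
        if missing:
            raise ValueError(f"parent geometry lacks torsions for frozen ranks {missing}")
    return Fragment(
        ligand=ligand,
        tree=tree,
        max_rank=max_rank,
        atom_subset=tree.atoms_up_to_rank(max_rank),
        active_ranks=active,
        frozen_ranks=frozen,
        parent_geometry=parent,
    )


# ---------------------------------------------------------------------------
# kinematics


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices from unit quaternions (w, x, y, z); batched (..., 4)."""
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - z * w)
    m[..., 0, 2] = 2 * (x * z + y * w)
    m[..., 1, 0] = 2 * (x * y + z * w)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - x * w)
    m[..., 2, 0] = 2 * (x * z - y * w)
    m[..., 2, 1] = 2 * (y * z + x * w)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


class BatchKinematics:
    """Forward kinematics for a fragment, vectorized over a population.

    Precomputes, for each rank up to the fragment's ``max_rank``, the
    positions (within the fragment's atom ordering) of the bond axis and of
    the atoms it moves; :meth:`coords` then maps a whole population of
    genomes to Cartesian coordinates in one pass.  Dihedral rotations are
    applied root-outward (ascending rank) with the Rodrigues formula, then
    the rigid-body transform about the root-group centroid.
    """

    def __init__(self, ligand: Ligand, tree: TorsionTree, max_rank: int | None = None):
        if max_rank is None:
            max_rank = tree.n_bonds
        self.tree = tree
        self.max_rank = max_rank
        self.atom_indices = tuple(sorted(tree.atoms_up_to_rank(max_rank)))
        pos = {atom: i for i, atom in enumerate(self.atom_indices)}
        self.ref = ligand.coords()[list(self.atom_indices)]
        root_pos = [pos[a] for a in sorted(tree.nodes[0])]
        self.root_centroid = self.ref[root_pos].mean(axis=0)
        self.ranks = tuple(range(1, max_rank + 1))
        self._rank_data = []
        for rank in self.ranks:
            edge = tree.edge_by_rank(rank)
            moved = sorted(m for m in tree.moved_sets[rank] if m in pos)
            self._rank_data.append(
                (pos[edge.pivot], pos[edge.moved], np.array([pos[m] for m in moved]))
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)

    def coords(
        self, translation: np.ndarray, orientation: np.ndarray, torsions: np.ndarray
    ) -> np.ndarray:
        """Coordinates for a population of genomes.

        ``translation`` is (P, 3), ``orientation`` (P, 4) unit quaternions,
        ``torsions`` (P, R) delta angles ordered by rank 1..max_rank.
        Returns (P, n_atoms, 3).
        """
        t = np.atleast_2d(np.asarray(translation, dtype=float))
        q = np.atleast_2d(np.asarray(orientation, dtype=float))
        th = np.atleast_2d(np.asarray(torsions, dtype=float))
        P = t.shape[0]
        X = np.broadcast_to(self.ref, (P,) + self.ref.shape).copy()
        for j, (ppos, mpos, moved) in enumerate(self._rank_data):
            theta = th[:, j]
            if not np.any(theta):
                continue
            pivot = X[:, ppos]  # (P, 3)
            axis = X[:, mpos] - pivot
            axis /= np.sqrt((axis * axis).sum(axis=1))[:, None]
            v = X[:, moved] - pivot[:, None, :]  # (P, m, 3)
            c = np.cos(theta)[:, None, None]
            # negative sign: a positive delta increases the signed dihedral
            # measured with the standard i-j-k-l convention
            s = -np.sin(theta)[:, None, None]
            a = axis[:, None, :]
            # manual cross/dot: np.cross is slow on small batches
            av = np.empty_like(v)
            av[..., 0] = a[..., 1] * v[..., 2] - a[..., 2] * v[..., 1]
            av[..., 1] = a[..., 2] * v[..., 0] - a[..., 0] * v[..., 2]
            av[..., 2] = a[..., 0] * v[..., 1] - a[..., 1] * v[..., 0]
            va = (v * a).sum(axis=2, keepdims=True)
            X[:, moved] = v * c + av * s + (va * a) * (1 - c) + pivot[:, None, :]
        R = _quat_to_matrix(q)
        return (X - self.root_centroid) @ R.transpose(0, 2, 1) + t[:, None, :]


def apply_genome(
    ligand: Ligand,
    tree: TorsionTree,
    translation: np.ndarray,
    orientation: np.ndarray,
    torsions: dict[int, float],
    max_rank: int | None = None,
) -> np.ndarray:
    """Cartesian coordinates of one genome (see :class:`BatchKinematics`).

    ``torsions`` must carry a delta for every rank up to ``max_rank``
    (default: all rotatable bonds).  Bond lengths, bond angles and
    non-rotatable dihedrals of the reference geometry are preserved exactly.
    """
    if max_rank is None:
        max_rank = tree.n_bonds
    missing = [r for r in range(1, max_rank + 1) if r not in torsions]
    if missing:
        raise ValueError(f"missing torsion angles for ranks {missing}")
    kin = BatchKinematics(ligand, tree, max_rank)
    th = np.array([[torsions[r] for r in kin.ranks]]) if kin.ranks else np.zeros((1, 0))
    return kin.coords(np.asarray(translation)[None], np.asarray(orientation)[None], th)[0]


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit quaternion (Gaussian 4-vector, normalized)."""
    q = rng.standard_normal(4)
    return q / np.linalg.norm(q)


def randomize_conformation(ligand: Ligand, tree: TorsionTree, box, rng: np.random.Generator) -> Conformation:
    """Uniform random genome: torsions on [-pi, pi), orientation uniform on
    the quaternion sphere, translation uniform inside ``box``.

    Used to discard any memory of the input pose before docking starts.
    """
    torsions = {r: float(rng.uniform(-np.pi, np.pi)) for r in range(1, tree.n_bonds + 1)}
    lo, hi = box.bounds()
    translation = rng.uniform(lo, hi)
    orientation = random_quaternion(rng)
    coords = apply_genome(ligand, tree, translation, orientation, torsions)
    return Conformation(
        translation=translation,
        orientation=orientation,
        torsions=torsions,
        coords=coords,
        atom_indices=tuple(range(len(ligand.atoms))),
    )


def measure_dihedral(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral angle (radians) of atoms i-j-k-l in ``coords``."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
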