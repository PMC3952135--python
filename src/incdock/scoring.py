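"""Energy model: binding box, grid-map scoring field, and positional restraints.

The engine score of a pose is a sum of per-atom contributions read from
per-atom-type potential grids by trilinear interpolation, plus a charge
times an electrostatic grid.  The grids are precomputed from the receptor
with a simplified pairwise model: a 12-6 van der Waals term with type-pair
mixing, a 12-10 hydrogen-bond term for donor/acceptor pairs, and a
Coulomb term with the distance-dependent dielectric eps(r) = 4r.  There is
no desolvation or torsional-entropy term; the model is a deliberately
reproducible stand-in, isolated behind :func:`score_pose` so any external
engine can replace it.

When conformations are selected under a positional restraint the engine
score is augmented with a quadratic penalty

    S = w * D_a + S_AD

where ``D_a`` is the squared distance (A^2) of the restrained atom from its
desired location and the default weight ``w = 0.25`` kcal/(mol*A^2) makes a
large displacement (D_a > 10 A^2) cost more than 2.5 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .mol import Atom, Conformation, Ligand  # noqa: F401 (Conformation used in annotations)

__all__ = [
    "BindingBox",
    "Field",
    "GridField",
    "Restraint",
    "ScoredConformation",
    "resolve_box",
    "build_field",
    "score_pose",
    "restrained_score",
    "DEFAULT_SPACING",
    "ENERGY_CEILING",
    "OUT_OF_BOX_PENALTY",
]

DEFAULT_SPACING = 0.375  # A per grid step
DEFAULT_MARGIN = 8.0  # A added per side in ligand-derived boxes
ENERGY_CEILING = 1.0e5  # kcal/mol clamp on grid values
OUT_OF_BOX_PENALTY = 1.0e6  # kcal/mol per stray atom
COULOMB = 332.0636  # kcal*A/(mol*e^2)

# per-type Lennard-Jones parameters: equilibrium self-distance Rii (A) and
# well depth eps_ii (kcal/mol); pairs mix as R=(Ri+Rj)/2, eps=sqrt(ei*ej)
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "C": (4.00, 0.150),
    "A": (4.00, 0.150),
    "N": (3.50, 0.160),
    "NA": (3.50, 0.160),
    "O": (3.20, 0.200),
    "OA": (3.20, 0.200),
    "S": (4.00, 0.200),
    "SA": (4.00, 0.200),
    "H": (2.00, 0.020),
    "HD": (2.00, 0.020),
    "P": (4.20, 0.200),
    "F": (3.09, 0.080),
    "Cl": (4.09, 0.276),
    "Br": (4.33, 0.389),
    "I": (4.72, 0.550),
}
# 12-10 hydrogen-bond term between a donor/acceptor pair
HBOND_RADIUS = 1.9  # A
HBOND_DEPTH = 5.0  # kcal/mol
ACCEPTOR_TYPES = {"OA", "NA", "SA"}
DONOR_TYPES = {"N", "HD"}


@dataclass
class BindingBox:
    """Rectangular search region: center, grid points per axis, spacing.

    The physical extent per axis is ``(npts - 1) * spacing`` Angstrom, the
    AutoDock-style convention in which dimensions count grid points.
    """

    center: np.ndarray
    npts: tuple[int, int, int]
    spacing: float = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.npts = tuple(int(n) for n in self.npts)
        if any(n < 2 for n in self.npts):
            raise ValueError("npts must be >= 2 on every axis")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    def extent(self) -> np.ndarray:
        return (np.array(self.npts) - 1) * self.spacing

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        half = self.extent() / 2.0
        return self.center - half, self.center + half

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lo, hi = self.bounds()
        return tuple(np.linspace(lo[i], hi[i], self.npts[i]) for i in range(3))

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds()
        pts = np.asarray(points, dtype=float)
        return np.all((pts >= lo) & (pts <= hi), axis=-1)


def resolve_box(
    center_mode: str,
    size_mode: str,
    ligand: Ligand | None = None,
    receptor: list[Atom] | None = None,
    center: np.ndarray | None = None,
    npts: tuple[int, int, int] | None = None,
    margin: float = DEFAULT_MARGIN,
    spacing: float = DEFAULT_SPACING,
) -> BindingBox:
    """Resolve the binding box from one center mode and one size mode.

    ``center_mode`` is one of ``absolute`` (use ``center`` verbatim),
    ``ligand`` or ``receptor`` (unweighted geometric center of that
    molecule's atoms).  ``size_mode`` is ``absolute`` (grid points ``npts``
    verbatim) or ``ligand`` (ligand bounding box extended by ``margin`` per
    side, converted to grid points at ``spacing``).  With a ligand-derived
    size the box is guaranteed to contain the ligand; an absolute box too
    small to contain the ligand's bounding sphere is rejected.
    """
    if center_mode == "absolute":
        if center is None:
            raise ValueError("absolute center mode requires center coordinates")
        c = np.asarray(center, dtype=float)
    elif center_mode == "ligand":
        if ligand is None:
            raise ValueError("ligand center mode requires a ligand")
        c = ligand.coords().mean(axis=0)
    elif center_mode == "receptor":
        if receptor is None:
            raise ValueError("receptor center mode requires a receptor")
        c = np.array([a.coords for a in receptor]).mean(axis=0)
    else:
        raise ValueError(f"unknown center mode {center_mode!r}")

    if size_mode == "absolute":
        if npts is None:
            raise ValueError("absolute size mode requires npts")
        n = tuple(int(v) for v in npts)
    elif size_mode == "ligand":
        if ligand is None:
            raise ValueError("ligand size mode requires a ligand")
        xyz = ligand.coords()
        span = xyz.max(axis=0) - xyz.min(axis=0) + 2.0 * margin
        n = tuple(int(np.ceil(s / spacing)) + 1 for s in span)
    else:
        raise ValueError(f"unknown size mode {size_mode!r}")

    box = BindingBox(center=c, npts=n, spacing=spacing)
    # sanity-check user-specified sizes only: a ligand-derived box contains
    # the ligand by construction (elongated ligands would otherwise always
    # fail the bounding-sphere test on their narrow axes)
    if size_mode == "absolute" and ligand is not None:
        xyz = ligand.coords()
        radius = float(np.linalg.norm(xyz - xyz.mean(axis=0), axis=1).max())
        if float(box.extent().min()) < 2.0 * radius:
            raise ValueError(
                f"box extent {box.extent().round(2)} A too small for the ligand's "
                f"bounding sphere (diameter {2 * radius:.2f} A)"
            )
    return box


@dataclass
class Restraint:
    """Quadratic positional restraint on one named ligand atom."""

    atom_name: str
    target: np.ndarray
    weight: float = 0.25  # kcal/(mol*A^2)

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        if self.weight < 0:
            raise ValueError("restraint weight must be >= 0")

    def resolve(self, ligand: Ligand) -> int:
        """Ligand atom index the restraint applies to (must be unique)."""
        return ligand.atom_by_name(self.atom_name).index


@dataclass
class ScoredConformation:
    """A conformation with its engine score and selection score.

    ``s_total`` equals ``s_ad`` unless a restraint was in force at selection
    time, in which case it is the restrained score of Eq. S = w*Da + S_AD.
    """

    conformation: Conformation
    s_ad: float
    s_total: float


def restrained_score(s_ad: float, atom_coords: np.ndarray, restraint: Restraint) -> float:
    """Selection score: ``restraint.weight * ||atom - target||^2 + s_ad``."""
    d2 = float(np.sum((np.asarray(atom_coords, dtype=float) - restraint.target) ** 2))
    return restraint.weight * d2 + s_ad


class Field:
    """Scoring-field interface: maps pose coordinates to kcal/mol.

    ``atoms`` is the list of ligand :class:`~incdock.mol.Atom` objects in the
    same order as the coordinate rows (they carry type, charge, and the
    original ligand index).
    """

    box: BindingBox

    def score_many(self, coords: np.ndarray, atoms: list[Atom]) -> np.ndarray:
        """Scores for a batch of poses, shape (P, N, 3) -> (P,)."""
        raise NotImplementedError

    def score(self, coords: np.ndarray, atoms: list[Atom]) -> float:
        return float(self.score_many(np.asarray(coords)[None], atoms)[0])


def _pair_energy(r: np.ndarray, ligand_type: str, receptor_atom: Atom) -> np.ndarray:
    """Pairwise vdW/H-bond energy between one ligand type and a receptor atom."""
    ri, ei = VDW_PARAMS[ligand_type]
    rj, ej = VDW_PARAMS[receptor_atom.atom_type]
    req = 0.5 * (ri + rj)
    eps = float(np.sqrt(ei * ej))
    rr = np.maximum(r, 1e-6)
    hb = (ligand_type in ACCEPTOR_TYPES and receptor_atom.hbond_role in ("donor", "both")) or (
        ligand_type in DONOR_TYPES and receptor_atom.hbond_role in ("acceptor", "both")
    )
    if hb:
        x = HBOND_RADIUS / rr
        e = HBOND_DEPTH * (5.0 * x**12 - 6.0 * x**10)
    else:
        x = req / rr
        e = eps * (x**12 - 2.0 * x**6)
    return np.minimum(e, ENERGY_CEILING)


class GridField(Field):
    """Per-atom-type potential grids plus an electrostatic grid.

    Values are clamped at :data:`ENERGY_CEILING`; poses with atoms outside
    the box pay :data:`OUT_OF_BOX_PENALTY` per stray atom instead of a map
    contribution.
    """

    def __init__(
        self,
        box: BindingBox,
        type_maps: dict[str, np.ndarray],
        electrostatic_map: np.ndarray,
        receptor_atoms: list[Atom] | None = None,
        out_of_box_penalty: float = OUT_OF_BOX_PENALTY,
    ):
        self.box = box
        self.type_maps = type_maps
        self.electrostatic_map = electrostatic_map
        self.receptor_atoms = receptor_atoms or []
        self.out_of_box_penalty = out_of_box_penalty
        axes = box.axes()
        self._interp = {
            t: RegularGridInterpolator(axes, m, bounds_error=False, fill_value=None)
            for t, m in type_maps.items()
        }
        self._interp_elec = RegularGridInterpolator(
            axes, electrostatic_map, bounds_error=False, fill_value=None
        )

    def score_many(self, coords: np.ndarray, atoms: list[Atom]) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        P, N, _ = coords.shape
        inside = self.box.contains(coords)  # (P, N)
        flat = coords.reshape(P * N, 3)
        lo, hi = self.box.bounds()
        clipped = np.clip(flat, lo, hi)
        contrib = np.zeros((P, N))
        types = np.array([a.atom_type for a in atoms])
        charges = np.array([a.charge for a in atoms])
        for t in np.unique(types):
            if t not in self._interp:
                raise KeyError(f"no grid map for ligand atom type {t!r}")
            cols = np.flatnonzero(types == t)
            pts = clipped.reshape(P, N, 3)[:, cols].reshape(-1, 3)
            contrib[:, cols] = self._interp[t](pts).reshape(P, len(cols))
        elec = self._interp_elec(clipped).reshape(P, N) * charges[None, :]
        total = np.where(inside, contrib + elec, self.out_of_box_penalty)
        return total.sum(axis=1)

    def direct_score(self, coords: np.ndarray, atoms: list[Atom]) -> float:
        """Pairwise sum over receptor atoms without grid interpolation.

        The independent reference for the grid/interpolation path; requires
        the receptor atoms the field was built from.
        """
        if not self.receptor_atoms:
            raise ValueError("field was not built from explicit receptor atoms")
        coords = np.asarray(coords, dtype=float)
        total = 0.0
        for i, atom in enumerate(atoms):
            if not self.box.contains(coords[i]):
                total += self.out_of_box_penalty
                continue
            e = 0.0
            for rec in self.receptor_atoms:
                r = float(np.linalg.norm(coords[i] - rec.coords))
                e += float(_pair_energy(np.array(r), atom.atom_type, rec))
                if rec.charge != 0.0 and atom.charge != 0.0:
                    rr = max(r, 1e-6)
                    e += min(COULOMB * atom.charge * rec.charge / (4.0 * rr * rr), ENERGY_CEILING)
            total += e
        return total


def build_field(
    receptor_atoms: list[Atom],
    box: BindingBox,
    ligand_types: set[str] | list[str],
) -> GridField:
    """Precompute potential grids for every ligand atom type over the box.

    Each node of a type map holds the clamped pairwise sum over receptor
    atoms; the electrostatic map holds ``sum_j q_j / (4 r_j * r_j)`` in
    kcal/(mol*e) with the distance-dependent dielectric.  An empty receptor
    yields identically zero maps.
    """
    for rec in receptor_atoms:
        if rec.atom_type not in VDW_PARAMS:
            raise ValueError(f"receptor atom {rec.name} (index {rec.index}) has unknown type {rec.atom_type!r}")
    ax, ay, az = box.axes()
    gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
    nodes = np.stack([gx, gy, gz], axis=-1)  # (nx, ny, nz, 3)
    type_maps: dict[str, np.ndarray] = {}
    for t in sorted(set(ligand_types)):
        grid = np.zeros(box.npts)
        for rec in receptor_atoms:
            r = np.linalg.norm(nodes - rec.coords, axis=-1)
            grid += _pair_energy(r, t, rec)
        type_maps[t] = np.minimum(grid, ENERGY_CEILING)
    elec = np.zeros(box.npts)
    for rec in receptor_atoms:
        if rec.charge == 0.0:
            continue
        r = np.maximum(np.linalg.norm(nodes - rec.coords, axis=-1), 1e-6)
        elec += COULOMB * rec.charge / (4.0 * r * r)
    elec = np.clip(elec, -ENERGY_CEILING, ENERGY_CEILING)
    return GridField(box=box, type_maps=type_maps, electrostatic_map=elec, receptor_atoms=receptor_atoms)


def score_pose(coords: np.ndarray, charges: np.ndarray, types: list[str], field: Field) -> float:
    """Score one pose against a field given raw coordinate/charge/type arrays.

    Thin convenience over :meth:`Field.score` for callers that do not hold
    :class:`~incdock.mol.Atom` objects.
    """
    atoms = [
        Atom(index=i, name=f"X{i}", element="C", coords=coords[i], charge=float(charges[i]), atom_type=types[i])
        for i in range(len(types))
    ]
    return field.score(coords, atoms)
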