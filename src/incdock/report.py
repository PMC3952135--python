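"""Pose analysis: RMSD, rankings, clustering, benchmark metrics, reports.

Accuracy is measured as the heavy-atom RMSD between a docked pose and a
reference pose in the same receptor frame (no superposition): both poses
live in the coordinate system of the rigid receptor, so displacement *is*
the docking error.  ``Top-scoring`` denotes the pose ranked first by score
and ``Top-RMSD`` the pose closest to the reference.  Pools are condensed
for reporting into six poses: the three lowest-scoring ones plus the
representatives of the three largest clusters under greedy leader
clustering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mol import Ligand
from .scoring import ScoredConformation

logger = logging.getLogger(__name__)

__all__ = [
    "compute_rmsd",
    "RankedResults",
    "rank_results",
    "ClusterSet",
    "cluster_poses",
    "ReportEntry",
    "report_top6",
    "BenchmarkMetrics",
    "benchmark_metrics",
    "write_poses",
    "CLUSTER_CUTOFF",
    "ACCEPTABLE_RMSD",
]

#: default greedy-clustering cutoff; 2 A is the conventional "very accurate" radius
CLUSTER_CUTOFF = 2.0
#: report annotation threshold for an acceptably accurate pose
ACCEPTABLE_RMSD = 4.0


def compute_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two coordinate sets, in Angstrom.

    Assumes identity atom correspondence (row i of ``a`` is the same atom as
    row i of ``b``) and performs no superposition.  Raises ``ValueError`` on
    a shape mismatch.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ or are not (n, 3): {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _pose_coords(sc: ScoredConformation, heavy_indices: list[int] | None) -> np.ndarray:
    coords = sc.conformation.coords
    if heavy_indices is None:
        return coords
    pos = {atom: i for i, atom in enumerate(sc.conformation.atom_indices)}
    return coords[[pos[h] for h in heavy_indices]]


@dataclass
class RankedResults:
    """Dual orderings of a pool: by selection score and (optionally) by RMSD."""

    by_score: list[ScoredConformation]
    by_rmsd: list[tuple[ScoredConformation, float]] = field(default_factory=list)

    @property
    def top_scoring(self) -> ScoredConformation:
        return self.by_score[0]

    @property
    def top_rmsd(self) -> tuple[ScoredConformation, float]:
        if not self.by_rmsd:
            raise ValueError("no reference was supplied; RMSD ranking unavailable")
        return self.by_rmsd[0]


def rank_results(
    pool: list[ScoredConformation],
    reference: np.ndarray | None = None,
    heavy_indices: list[int] | None = None,
) -> RankedResults:
    """Rank a scored pool ascending by ``s_total`` and, with a reference,
    ascending by heavy-atom RMSD to it.

    ``reference`` must give coordinates for the same atoms as the pool's
    poses (restricted to ``heavy_indices`` when supplied).  Ties break by
    engine score then insertion order.
    """
    if not pool:
        raise ValueError("cannot rank an empty pool")
    order = sorted(range(len(pool)), key=lambda i: (pool[i].s_total, pool[i].s_ad, i))
    by_score = [pool[i] for i in order]
    by_rmsd: list[tuple[ScoredConformation, float]] = []
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if heavy_indices is not None:
            ref_sel = ref[heavy_indices] if len(ref) > len(heavy_indices) else ref
        else:
            ref_sel = ref
        rmsds = [compute_rmsd(_pose_coords(sc, heavy_indices), ref_sel) for sc in pool]
        ridx = sorted(range(len(pool)), key=lambda i: (rmsds[i], pool[i].s_total, i))
        by_rmsd = [(pool[i], rmsds[i]) for i in ridx]
    return RankedResults(by_score=by_score, by_rmsd=by_rmsd)


@dataclass
class Cluster:
    representative: ScoredConformation
    members: list[ScoredConformation]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """Greedy-leader partition of a pool, largest clusters first."""

    clusters: list[Cluster]
    cutoff: float


def cluster_poses(
    pool: list[ScoredConformation],
    cutoff: float = CLUSTER_CUTOFF,
    heavy_indices: list[int] | None = None,
) -> ClusterSet:
    """Greedy leader clustering of poses by pairwise RMSD.

    Poses are visited in ascending ``s_total`` (ties: engine score, then
    insertion order); each joins the first existing cluster whose
    representative lies within ``cutoff`` RMSD, else founds a new cluster.
    Because visit order is by score, every representative is the
    lowest-scoring member of its cluster.  The result is ordered by
    descending size, ties broken by better representative score.
    """
    if not pool:
        raise ValueError("cannot cluster an empty pool")
    order = sorted(range(len(pool)), key=lambda i: (pool[i].s_total, pool[i].s_ad, i))
    clusters: list[Cluster] = []
    rep_coords: list[np.ndarray] = []
    for i in order:
        coords = _pose_coords(pool[i], heavy_indices)
        for c, rc in zip(clusters, rep_coords):
            if compute_rmsd(coords, rc) <= cutoff:
                c.members.append(pool[i])
                break
        else:
            clusters.append(Cluster(representative=pool[i], members=[pool[i]]))
            rep_coords.append(coords)
    clusters.sort(key=lambda c: (-c.size, c.representative.s_total))
    return ClusterSet(clusters=clusters, cutoff=cutoff)


@dataclass
class ReportEntry:
    """One pose of the six-pose report."""

    pose: ScoredConformation
    kind: str  # "low_score" or "cluster_rep"
    rank: int  # 1..3 within its section
    cluster_size: int | None = None
    duplicate: bool = False


def report_top6(
    pool: list[ScoredConformation],
    cutoff: float = CLUSTER_CUTOFF,
    heavy_indices: list[int] | None = None,
) -> list[ReportEntry]:
    """The six-conformation report: 3 lowest-scoring poses + 3 largest
    clusters' representatives.

    A representative that coincides with one of the lowest-scoring poses is
    still emitted, flagged ``duplicate``.  Smaller pools (or fewer clusters)
    yield fewer entries; never more than six, never fewer than
    ``min(len(pool), 3)``.
    """
    ranked = rank_results(pool)
    entries: list[ReportEntry] = []
    low = ranked.by_score[:3]
    for i, sc in enumerate(low, start=1):
        entries.append(ReportEntry(pose=sc, kind="low_score", rank=i))
    clusters = cluster_poses(pool, cutoff=cutoff, heavy_indices=heavy_indices)
    seen = {id(sc) for sc in low}
    for i, cluster in enumerate(clusters.clusters[:3], start=1):
        rep = cluster.representative
        entries.append(
            ReportEntry(
                pose=rep,
                kind="cluster_rep",
                rank=i,
                cluster_size=cluster.size,
                duplicate=id(rep) in seen,
            )
        )
    return entries


@dataclass
class BenchmarkMetrics:
    """Per-complex and aggregate accuracy summaries.

    ``r_cs[c]`` is the mean over repeats of the Top-scoring pose's RMSD for
    complex ``c``; ``r_cr[c]`` the same for the Top-RMSD pose.  ``ra_cs`` /
    ``ra_cr`` average those over complexes.  By definition the Top-RMSD pose
    is at least as close as the Top-scoring one, so r_cr <= r_cs per repeat.
    """

    r_cs: dict[str, float]
    r_cr: dict[str, float]
    ra_cs: float
    ra_cr: float


def benchmark_metrics(per_complex: dict[str, list[RankedResults]]) -> BenchmarkMetrics:
    """Aggregate repeated docking experiments into benchmark metrics.

    ``per_complex`` maps a complex identifier to its per-repeat ranked
    results (each built with a reference).  Complexes whose results carry no
    RMSD ranking are excluded with a warning.
    """
    r_cs: dict[str, float] = {}
    r_cr: dict[str, float] = {}
    for cid, repeats in per_complex.items():
        if not repeats or any(not r.by_rmsd for r in repeats):
            logger.warning("complex %s has repeats without a reference; excluded", cid)
            continue
        ts = []
        tr = []
        for ranked in repeats:
            rmsd_of = {id(sc): r for sc, r in ranked.by_rmsd}
            ts.append(rmsd_of[id(ranked.top_scoring)])
            tr.append(ranked.top_rmsd[1])
        r_cs[cid] = float(np.mean(ts))
        r_cr[cid] = float(np.mean(tr))
    if not r_cs:
        raise ValueError("no complex had usable references")
    return BenchmarkMetrics(
        r_cs=r_cs,
        r_cr=r_cr,
        ra_cs=float(np.mean(list(r_cs.values()))),
        ra_cr=float(np.mean(list(r_cr.values()))),
    )


def _pose_table(
    entries: list[ReportEntry],
    reference: np.ndarray | None = None,
    heavy_indices: list[int] | None = None,
) -> pd.DataFrame:
    rows = []
    for model, e in enumerate(entries, start=1):
        row = {
            "model": model,
            "kind": e.kind,
            "rank": e.rank,
            "score": e.pose.s_total,
            "engine_score": e.pose.s_ad,
            "cluster_size": e.cluster_size,
            "duplicate": e.duplicate,
        }
        if reference is not None:
            ref = np.asarray(reference, dtype=float)
            if heavy_indices is not None and len(ref) > len(heavy_indices):
                ref = ref[heavy_indices]
            rmsd = compute_rmsd(_pose_coords(e.pose, heavy_indices), ref)
            row["rmsd"] = rmsd
            row["acceptable"] = rmsd <= ACCEPTABLE_RMSD
        rows.append(row)
    return pd.DataFrame(rows)


def write_poses(
    entries: list[ReportEntry],
    ligand: Ligand,
    path_prefix: str,
    reference: np.ndarray | None = None,
    heavy_indices: list[int] | None = None,
) -> dict[str, str]:
    """Write a pose report as multi-model PDB plus TSV and JSON tables.

    ``path_prefix`` yields ``<prefix>.pdb``, ``<prefix>.tsv`` and
    ``<prefix>.json``.  Each PDB MODEL carries its score in a REMARK; the
    tables hold scores, cluster sizes and (with a reference) RMSDs.  An
    empty entry list is an error and creates no files.
    """
    if not entries:
        raise ValueError("no poses to write")
    pdb_path = f"{path_prefix}.pdb"
    tsv_path = f"{path_prefix}.tsv"
    json_path = f"{path_prefix}.json"
    try:
        with open(pdb_path, "w") as fh:
            for model, e in enumerate(entries, start=1):
                conf = e.pose.conformation
                fh.write(f"MODEL     {model:>4d}\n")
                fh.write(f"REMARK   1 SCORE {e.pose.s_total:.4f} KIND {e.kind} RANK {e.rank}\n")
                for row, atom_idx in enumerate(conf.atom_indices):
                    atom = ligand.atoms[atom_idx]
                    x, y, z = conf.coords[row]
                    fh.write(
                        f"HETATM{row + 1:>5d} {atom.name:>4.4s} LIG A   1    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {atom.element:>2s}\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")
        table = _pose_table(entries, reference, heavy_indices)
        table.to_csv(tsv_path, sep="\t", index=False)
        with open(json_path, "w") as fh:
            json.dump(json.loads(table.to_json(orient="records")), fh, indent=1)
    except OSError as exc:
        raise OSError(f"failed writing pose report to {path_prefix}.*: {exc}") from exc
    return {"pdb": pdb_path, "tsv": tsv_path, "json": json_path}
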