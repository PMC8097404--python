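"""Conformational clustering of binder poses: Jarvis–Patrick and GROMOS.

Both operate on a pairwise pose-RMSD matrix.  Jarvis–Patrick defines
neighbors by a distance cutoff and links two poses when each lists the
other as a neighbor and they share at least a required number of common
neighbors; clusters are the connected components of the link graph, with
unlinked poses reported as singletons.  GROMOS greedily extracts the pose
with the most within-cutoff neighbors as a cluster centroid, removes it
and its neighbors from the pool, and repeats.  All ties break toward the
lowest pose index, making results deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, StructureError

__all__ = [
    "PoseSet",
    "ClusterResult",
    "pose_rmsd_matrix",
    "jarvis_patrick_cluster",
    "gromos_cluster",
    "representative_pose",
    "cluster_populations",
]


@dataclass
class PoseSet:
    """Coordinates of a fixed atom selection across frames: (n_poses, n_atoms, 3)."""

    coordinates: np.ndarray
    frame_indices: list[int] | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise StructureError("poses must be (n_poses, n_atoms, 3)")
        if self.frame_indices is None:
            self.frame_indices = list(range(self.coordinates.shape[0]))

    @property
    def n_poses(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class ClusterResult:
    labels: np.ndarray  # pose -> cluster id; -1 for JP singletons bin
    representatives: dict[int, int] = field(default_factory=dict)
    populations: dict[int, float] = field(default_factory=dict)
    algorithm: str = ""
    parameters: dict = field(default_factory=dict)

    def members(self, cid: int) -> np.ndarray:
        return np.nonzero(self.labels == cid)[0]

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(c for c in set(self.labels.tolist()) if c >= 0)


def _superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (Kabsch)."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    s = s.copy()
    s[-1] *= sign
    msd = (ac * ac).sum() + (bc * bc).sum() - 2.0 * s.sum()
    return float(np.sqrt(max(msd, 0.0) / a.shape[0]))


def pose_rmsd_matrix(poses: PoseSet, superpose: bool = False) -> np.ndarray:
    """Symmetric pairwise RMSD matrix over poses.

    Without superposition the raw-coordinate RMSD is used (appropriate when
    the protein frame is positionally restrained); with ``superpose`` each
    pair is least-squares rigid-fit first.
    """
    x = poses.coordinates
    n = x.shape[0]
    if n < 2:
        raise ArgumentError("need at least two poses")
    if superpose:
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = _superpose_rmsd(x[i], x[j])
        return dm
    diff = x[:, None, :, :] - x[None, :, :, :]
    dm = np.sqrt(np.einsum("ijak,ijak->ij", diff, diff) / x.shape[1])
    np.fill_diagonal(dm, 0.0)
    return dm


def _check_dm(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise StructureError("distance matrix must be square")
    if not np.allclose(dm, dm.T):
        raise StructureError("distance matrix must be symmetric")
    return dm


def jarvis_patrick_cluster(
    dm: np.ndarray,
    cutoff: float,
    common_neighbors: int = 3,
    n_nearest: int | None = None,
) -> ClusterResult:
    """Jarvis–Patrick clustering on a distance matrix.

    Neighbor lists contain every pose within ``cutoff`` (or, with
    ``n_nearest``, the fixed-size nearest-neighbor variant).  Two poses are
    linked when each is in the other's neighbor list and they share at
    least ``common_neighbors`` neighbors; clusters are connected components
    of the link graph.  Poses with no links form the singleton bin
    (label -1), reported separately in the populations.
    """
    dm = _check_dm(dm)
    if cutoff <= 0:
        raise ArgumentError("cutoff must be > 0")
    if common_neighbors < 0:
        raise ArgumentError("common_neighbors must be >= 0")
    n = dm.shape[0]
    neigh = []
    for i in range(n):
        if n_nearest is None:
            s = {j for j in range(n) if j != i and dm[i, j] <= cutoff}
        else:
            order = [int(j) for j in np.lexsort((np.arange(n), dm[i])) if j != i]
            s = set(order[:n_nearest])
        neigh.append(s)

    # union-find over linked pairs
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    linked = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if j in neigh[i] and i in neigh[j] and len(neigh[i] & neigh[j]) >= common_neighbors:
                linked[i] = linked[j] = True
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    labels = np.full(n, -1, dtype=int)
    roots = {}
    for i in range(n):
        if linked[i]:
            r = find(i)
            labels[i] = roots.setdefault(r, len(roots))
    result = ClusterResult(
        labels=labels,
        algorithm="jarvis-patrick",
        parameters={
            "cutoff": cutoff,
            "common_neighbors": common_neighbors,
            "n_nearest": n_nearest,
        },
    )
    result.populations = cluster_populations(result)
    result.representatives = representative_pose(result, dm)
    return result


def gromos_cluster(dm: np.ndarray, cutoff: float) -> ClusterResult:
    """GROMOS clustering: greedy extraction of maximal-neighbor centroids.

    The pose with the most within-cutoff neighbors among remaining poses
    becomes a centroid (ties to the lowest index); it and its neighbors are
    removed permanently, and the procedure repeats until every pose is
    assigned.  The output is a partition.
    """
    dm = _check_dm(dm)
    if cutoff <= 0:
        raise ArgumentError("cutoff must be > 0")
    n = dm.shape[0]
    remaining = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    reps = {}
    cid = 0
    within = dm <= cutoff
    np.fill_diagonal(within, False)
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centroid = int(np.argmax(counts))  # argmax ties -> lowest index
        members = np.nonzero(remaining & (within[centroid] | (np.arange(n) == centroid)))[0]
        labels[members] = cid
        reps[cid] = centroid
        remaining[members] = False
        cid += 1
    result = ClusterResult(
        labels=labels,
        algorithm="gromos",
        parameters={"cutoff": cutoff, "centroids": reps},
    )
    result.populations = cluster_populations(result)
    result.representatives = representative_pose(result, dm)
    return result


def representative_pose(result: ClusterResult, dm: np.ndarray) -> dict[int, int]:
    """Per cluster, the member with the smallest mean distance to the rest.

    Ties break to the lowest pose index; singleton clusters return their
    sole member.
    """
    dm = _check_dm(dm)
    reps = {}
    for cid in result.cluster_ids:
        members = result.members(cid)
        if members.size == 1:
            reps[cid] = int(members[0])
            continue
        sub = dm[np.ix_(members, members)]
        mean_d = sub.sum(axis=1) / (members.size - 1)
        reps[cid] = int(members[int(np.argmin(mean_d))])
    return reps


def cluster_populations(result: ClusterResult) -> dict[int, float]:
    """Cluster-size fractions (singleton bin under key -1), summing to 1."""
    n = result.labels.size
    pops = {}
    for cid in set(result.labels.tolist()):
        pops[int(cid)] = float(np.sum(result.labels == cid)) / n
    return dict(sorted(pops.items(), key=lambda kv: (-kv[1], kv[0])))
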