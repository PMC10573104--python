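"""Conformational clustering of trajectory ensembles.

Pairwise best-fit RMSD over a user selection feeds average-linkage
agglomerative clustering (the common cpptraj-style recipe), terminated
either at a distance cutoff eps (merge while the average inter-cluster
RMSD is within eps) or at a fixed cluster count k.  Clusters are reported
with occupancy percentages, descending, and a representative frame — the
member minimizing the mean distance to its co-members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .analysis import kabsch_superpose
from .structure import Selection, Structure, Trajectory, select


@dataclass
class ClusterResult:
    """Per-frame labels (1 = most occupied cluster), occupancies (%,
    descending), representative frame indices (0-based) and the cluster
    count.  Occupancies sum to 100."""

    labels: np.ndarray
    occupancy: np.ndarray
    representative: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.representative = np.asarray(self.representative, dtype=int)
        if abs(self.occupancy.sum() - 100.0) > 1e-6:
            raise ValueError("occupancies must sum to 100")
        if len(self.occupancy) != self.n_clusters:
            raise ValueError("occupancy length != n_clusters")
        for rank, rep in enumerate(self.representative, start=1):
            if self.labels[rep] != rank:
                raise ValueError(f"representative of cluster {rank} not in cluster")


def pairwise_rmsd_matrix(traj: Trajectory, sel: Selection | str = "all") -> np.ndarray:
    """Symmetric F x F matrix of best-fit RMSD (Å) between all frame pairs
    over the selection; zero diagonal."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    idx = select(traj.topology, Selection(sel) if isinstance(sel, str) else sel)
    coords = traj.frames[:, idx, :]
    f = traj.n_frames
    mat = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            _, _, rmsd = kabsch_superpose(coords[j], coords[i])
            mat[i, j] = mat[j, i] = rmsd
    return mat


def cluster_frames(dist: np.ndarray, eps: float | None = None,
                   k: int | None = None) -> ClusterResult:
    """Average-linkage clustering of a frame-distance matrix.

    Exactly one of ``eps`` (Å; merge until the average-linkage distance
    between any two clusters exceeds it) or ``k`` (target cluster count)
    must be given.  Clusters are numbered 1..n by descending occupancy,
    ties broken by the lowest member frame index; the representative frame
    minimizes the mean distance to its co-members (lowest index on ties).
    """
    dist = np.asarray(dist, dtype=float)
    f = dist.shape[0]
    if f < 2:
        raise ValueError("need at least 2 frames to cluster")
    if (eps is None) == (k is None):
        raise ValueError("give exactly one of eps or k")
    if not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0):
        raise ValueError("dist must be symmetric with zero diagonal")
    if k is not None and k == f:
        raw = np.arange(1, f + 1)
    else:
        z = linkage(squareform(dist, checks=False), method="average")
        if eps is not None:
            raw = fcluster(z, t=eps, criterion="distance")
        else:
            raw = fcluster(z, t=k, criterion="maxclust")
    ids = np.unique(raw)
    # order clusters by descending occupancy, ties by lowest member index
    def sort_key(cid):
        members = np.nonzero(raw == cid)[0]
        return (-len(members), members.min())
    ordered = sorted(ids, key=sort_key)
    labels = np.empty(f, dtype=int)
    occupancy = np.empty(len(ordered))
    representative = np.empty(len(ordered), dtype=int)
    for rank, cid in enumerate(ordered, start=1):
        members = np.nonzero(raw == cid)[0]
        labels[members] = rank
        occupancy[rank - 1] = 100.0 * len(members) / f
        sub = dist[np.ix_(members, members)]
        representative[rank - 1] = members[int(np.argmin(sub.mean(axis=1)))]
    occupancy *= 100.0 / occupancy.sum()  # exact-sum guard against fp drift
    return ClusterResult(labels, occupancy, representative, len(ordered))


def extract_representatives(traj: Trajectory, result: ClusterResult) -> list[Structure]:
    """One Structure per cluster (descending occupancy), coordinates
    bit-equal to the representative frame."""
    if len(result.labels) != traj.n_frames:
        raise ValueError("cluster result inconsistent with trajectory")
    return [traj.frame_structure(int(rep)) for rep in result.representative]
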