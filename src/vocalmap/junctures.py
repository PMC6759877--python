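"""Junctures, their single-linkage clusters, and articulatory chunks.

A juncture is a point on a motor trajectory created where an executed
combination exited one trajectory or entered another; the endpoints of every
bridging segment become junctures.  Junctures are clustered by single linkage
at threshold eps: two junctures share a cluster iff they are connected by a
chain of pairwise articulatory distances below eps.  These clusters, together
with their linked perceptual points, are the emergent perceptual-motor units:
pivots where production can switch between trajectories.  The paths between
consecutive junctures on a trajectory are articulatory chunks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .spaces import ValidationError
from .trajectories import MotorTrajectory

__all__ = [
    "Juncture",
    "ClusterState",
    "Chunk",
    "find_near_crossings",
    "cluster_batch",
    "chunks_of",
]

DEFAULT_EPS = 0.15


@dataclass(frozen=True)
class Juncture:
    """A pivot point: trajectory id, relative time, configuration there."""

    traj_id: str
    t: float
    config: np.ndarray
    origin: str = ""


@dataclass(frozen=True)
class Chunk:
    """A juncture-delimited sub-path of a motor trajectory."""

    traj_id: str
    start: float
    end: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError("chunk requires start < end")

    @property
    def duration(self) -> float:
        return self.end - self.start


class ClusterState:
    """Incremental single-linkage eps-clustering of junctures (union-find).

    Adding a juncture links it to every existing juncture closer than eps;
    this realizes the three developmental possibilities — join the one nearby
    cluster, merge several clusters through the new point, or start a
    singleton — and is order-independent: any insertion order yields the
    eps-graph's connected components.
    """

    def __init__(self, eps: float = DEFAULT_EPS):
        self.eps = float(eps)
        self.junctures: list[Juncture] = []
        self._configs = np.empty((0, 20))
        self._parent: list[int] = []

    def __len__(self) -> int:
        return len(self.junctures)

    def _find(self, i: int) -> int:
        root = i
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[i] != root:  # path compression
            self._parent[i], i = root, self._parent[i]
        return root

    def add_juncture(self, j: Juncture) -> "ClusterState":
        """Insert one juncture and update the partition in place."""
        cfg = np.asarray(j.config, dtype=float)
        idx = len(self.junctures)
        self.junctures.append(j)
        self._parent.append(idx)
        if idx:
            d = np.sqrt(np.sum((self._configs - cfg) ** 2, axis=1))
            for other in np.nonzero(d < self.eps)[0]:
                self._parent[self._find(int(other))] = self._find(idx)
        self._configs = np.vstack([self._configs, cfg])
        return self

    def register_combination_junctures(self, endpoints: list[Juncture]) -> "ClusterState":
        """Register the bridge endpoints created by one executed combination."""
        for j in endpoints:
            self.add_juncture(j)
        return self

    def clusters(self) -> list[set[int]]:
        """Current partition as sets of juncture indices."""
        groups: dict[int, set[int]] = {}
        for i in range(len(self.junctures)):
            groups.setdefault(self._find(i), set()).add(i)
        return sorted(groups.values(), key=min)

    @property
    def n_clusters(self) -> int:
        return len({self._find(i) for i in range(len(self.junctures))})

    def junctures_on(self, traj_id: str) -> list[Juncture]:
        return [j for j in self.junctures if j.traj_id == traj_id]


def cluster_batch(junctures: list[Juncture], eps: float) -> list[set[int]]:
    """Single-linkage partition of a finite juncture set, cut just below eps.

    Computed as the connected components of the graph with edges where
    d_artic < eps; equals the single-linkage dendrogram stopped before its
    height reaches eps.
    """
    if not junctures:
        return []
    X = np.array([np.asarray(j.config, dtype=float) for j in junctures])
    D = cdist(X, X)
    adj = csr_matrix(D < eps)
    n, labels = connected_components(adj, directed=False)
    groups: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(i)
    return sorted(groups.values(), key=min)


def find_near_crossings(
    m1: MotorTrajectory, m2: MotorTrajectory, eps: float
) -> list[tuple[float, float, float]]:
    """Grid points where the two trajectories nearly cross in motor space.

    Returns (t1, t2, distance) for every pair of sample times where
    d_artic(m1(t1), m2(t2)) < eps and the distance surface has a local minimum
    over its grid neighborhood (the minimum filter avoids reporting a
    continuum of hits along a shared valley).  Sorted by distance.
    """
    D = cdist(m1.values, m2.values)
    P = np.pad(D, 1, constant_values=np.inf)
    neigh = np.min(
        [
            P[1 + di : P.shape[0] - 1 + di, 1 + dj : P.shape[1] - 1 + dj]
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            if (di, dj) != (0, 0)
        ],
        axis=0,
    )
    mask = (D < eps) & (D <= neigh)
    hits = [
        (float(m1.times[i]), float(m2.times[j]), float(D[i, j]))
        for i, j in zip(*np.nonzero(mask))
    ]
    return sorted(hits, key=lambda h: h[2])


def chunks_of(traj: MotorTrajectory, state: ClusterState, time_tol: float = 1e-9) -> list[Chunk]:
    """Partition a trajectory at its junctures' times (plus the domain ends)."""
    cuts = sorted({j.t for j in state.junctures_on(traj.id)})
    edges = [0.0]
    for t in cuts:
        if t - edges[-1] > time_tol and traj.domain_end - t > time_tol:
            edges.append(t)
    edges.append(traj.domain_end)
    return [Chunk(traj.id, a, b) for a, b in zip(edges, edges[1:])]
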