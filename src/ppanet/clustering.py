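"""Markov Cluster (MCL) partitioning of the high-confidence network and the
derived cluster-cluster association network.

MCL simulates random walks on the weighted graph: the column-stochastic
transition matrix is alternately *expanded* (raised to a matrix power, letting
walks spread) and *inflated* (raised elementwise to a power and renormalised,
sharpening strong transitions and starving weak ones).  The process converges
to a doubly idempotent matrix whose attractor rows read out the clusters.
Flow never crosses between disconnected components, so components are never
merged.

The inflation parameter controls granularity: higher inflation fragments the
graph into more, smaller clusters.  Defaults (inflation 2.0, expansion 2,
prune 1e-5) are the standard operating point of the algorithm; clusters
smaller than ``min_size`` (default 5) are moved to the unassigned pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import HighConfidenceNetwork
from .projection import PPAN

__all__ = [
    "Cluster",
    "Clustering",
    "ClusterNetwork",
    "mcl",
    "filter_clusters",
    "cluster_network",
    "DEFAULT_MIN_CLUSTER_SIZE",
]

DEFAULT_MIN_CLUSTER_SIZE = 5


@dataclass(frozen=True)
class Cluster:
    id: int
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Clustering:
    """Disjoint protein clusters plus the unassigned remainder.

    Clusters and ``unassigned`` together cover every clustered protein
    exactly once.  ``parameters`` echoes the MCL settings; ``converged`` is
    False when the iteration hit ``max_iter`` and the best iterate was
    returned.
    """

    clusters: list[Cluster]
    unassigned: frozenset[str]
    parameters: dict = field(default_factory=dict)
    converged: bool = True
    n_iterations: int = 0

    @property
    def all_proteins(self) -> frozenset[str]:
        out: set[str] = set(self.unassigned)
        for c in self.clusters:
            out.update(c.members)
        return frozenset(out)

    def as_partition(self) -> dict[str, int]:
        """Map each clustered protein to its cluster id (unassigned omitted)."""
        return {p: c.id for c in self.clusters for p in c.members}

    def to_frame(self) -> pd.DataFrame:
        rows = [(c.id, p) for c in self.clusters for p in sorted(c.members)]
        rows += [(-1, p) for p in sorted(self.unassigned)]
        return pd.DataFrame(rows, columns=["cluster_id", "protein_id"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _as_ppan(network: PPAN | HighConfidenceNetwork) -> PPAN:
    return network.network if isinstance(network, HighConfidenceNetwork) else network


def mcl(
    network: PPAN | HighConfidenceNetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 200,
    self_loop: str | float = "max",
) -> Clustering:
    """Run Markov clustering on the wscore-weighted network.

    ``self_loop`` sets each node's self-loop weight before normalisation:
    ``"max"`` (default) uses the node's maximum incident edge weight, which
    stabilises attractors; a float applies a constant.  Entries below
    ``prune`` are zeroed after each inflation to keep the matrix sparse in
    effect.  Non-convergence after ``max_iter`` iterations returns the last
    iterate's clustering with ``converged=False`` and a warning.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must exceed 1")
    if expansion < 2:
        raise ValueError("expansion must be at least 2")
    ppan = _as_ppan(network)
    nodes = sorted(ppan.proteins)
    if not nodes:
        raise ValueError("empty network")
    index = {p: i for i, p in enumerate(nodes)}
    n = len(nodes)

    A = np.zeros((n, n))
    for (a, b), e in ppan.edges.items():
        A[index[a], index[b]] = e.wscore
        A[index[b], index[a]] = e.wscore
    if self_loop == "max":
        loops = A.max(axis=0)
        loops[loops == 0.0] = 1.0  # isolated node: unit self-loop
    else:
        loops = np.full(n, float(self_loop))
    np.fill_diagonal(A, loops)

    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # expansion: let flow spread along walks of length `expansion`
        expanded = np.linalg.matrix_power(M, expansion)
        # inflation: sharpen columns, then prune negligible flow
        inflated = expanded ** inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        if np.any(colsum == 0.0):  # pruning emptied a column; restore self flow
            dead = np.nonzero(colsum[0] == 0.0)[0]
            inflated[dead, dead] = 1.0
            colsum = inflated.sum(axis=0, keepdims=True)
        inflated /= colsum
        assert abs(inflated.sum(axis=0) - 1.0).max() < 1e-9, "column stochasticity lost"
        change = np.abs(inflated - M).max()
        M = inflated
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations")

    clusters = _clusters_from_matrix(M, nodes, threshold=max(prune, 1e-8))
    params = {
        "inflation": inflation,
        "expansion": expansion,
        "prune": prune,
        "tol": tol,
        "max_iter": max_iter,
        "self_loop": self_loop,
    }
    return Clustering(
        clusters=clusters,
        unassigned=frozenset(),
        parameters=params,
        converged=converged,
        n_iterations=it,
    )


def _clusters_from_matrix(M: np.ndarray, nodes: list[str], threshold: float) -> list[Cluster]:
    """Read clusters from a converged MCL matrix.

    Attractors are rows with positive diagonal mass; each attractor row's
    support is one cluster.  Attractor systems sharing any node are merged
    (union-find) so the result is a strict partition; any node outside every
    support becomes a singleton cluster.
    """
    n = len(nodes)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    attractors = np.nonzero(np.diag(M) > threshold)[0]
    covered = np.zeros(n, dtype=bool)
    for i in attractors:
        support = np.nonzero(M[i] > threshold)[0]
        covered[support] = True
        for j in support:
            union(i, j)

    groups: dict[int, set[str]] = {}
    for j in range(n):
        if covered[j]:
            groups.setdefault(find(j), set()).add(nodes[j])
        else:
            groups[n + j] = {nodes[j]}  # orphan: singleton cluster
    ordered = sorted(groups.values(), key=lambda s: (-len(s), min(s)))
    return [Cluster(id=i + 1, members=frozenset(s)) for i, s in enumerate(ordered)]


def filter_clusters(
    clustering: Clustering, min_size: int = DEFAULT_MIN_CLUSTER_SIZE
) -> Clustering:
    """Move clusters below ``min_size`` members into the unassigned pool."""
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    kept, dropped = [], set(clustering.unassigned)
    for c in clustering.clusters:
        if c.size >= min_size:
            kept.append(c)
        else:
            dropped.update(c.members)
    kept = [Cluster(id=i + 1, members=c.members) for i, c in enumerate(kept)]
    return Clustering(
        clusters=kept,
        unassigned=frozenset(dropped),
        parameters={**clustering.parameters, "min_size": min_size},
        converged=clustering.converged,
        n_iterations=clustering.n_iterations,
    )


@dataclass
class ClusterNetwork:
    """Cluster-level association network.

    Each cluster pair connected by at least one inter-cluster edge in the
    underlying network gets one edge weighted by the arithmetic mean of those
    edges' wscores.
    """

    cluster_ids: tuple[int, ...]
    edges: dict[tuple[int, int], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, w) for (a, b), w in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "mean_wscore"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def cluster_network(
    clustering: Clustering, network: PPAN | HighConfidenceNetwork
) -> ClusterNetwork:
    """Aggregate the protein network to a cluster-cluster network."""
    ppan = _as_ppan(network)
    membership = clustering.as_partition()
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for (a, b), e in ppan.edges.items():
        ca, cb = membership.get(a), membership.get(b)
        if ca is None or cb is None or ca == cb:
            continue
        key = (min(ca, cb), max(ca, cb))
        sums[key] = sums.get(key, 0.0) + e.wscore
        counts[key] = counts.get(key, 0) + 1
    edges = {k: sums[k] / counts[k] for k in sums}
    return ClusterNetwork(
        cluster_ids=tuple(c.id for c in clustering.clusters), edges=edges
    )
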