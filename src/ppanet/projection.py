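"""Bipartite projection of chemical-protein associations into a scored
protein-protein association network (P-PAN).

Two proteins are connected whenever at least one chemical is associated with
both.  Each edge carries two reliability scores:

* ``wscore`` — the weighted score: the sum over shared chemicals of weights
  inversely proportional to the chemical's target count, w_c = 1/n_c.  A
  promiscuous chemical hitting hundreds of proteins therefore contributes
  almost nothing to any single pair, while a specific chemical shared by only
  two proteins contributes 1/2.
* ``hscore`` — minus log10 of the upper-tail hypergeometric probability of
  the observed shared-chemical overlap, given each protein's chemical count
  and the total number of distinct chemicals N in the table.

The weighted score obeys an exact conservation identity: summed over all
edges it equals sum over chemicals with n_c >= 2 of (n_c - 1)/2, because a
chemical with n_c targets creates C(n_c, 2) pairs each weighted 1/n_c.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import AssociationTable, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "ScoredEdge",
    "PPAN",
    "project",
    "weighted_score",
    "hypergeometric_score",
    "HSCORE_CAP",
]

#: Smallest positive representable double; hscore is capped at -log10 of it
#: when the hypergeometric tail underflows to zero.
_P_FLOOR = 5e-324
HSCORE_CAP = -math.log10(_P_FLOOR)


@dataclass(frozen=True)
class ScoredEdge:
    """One undirected protein-protein association with its reliability scores.

    ``pair`` is stored in canonical (lexicographic) order.  ``shared_chemicals``
    may be ``None`` for edges read back from disk (the shared set is not
    serialised); ``n_shared`` is always available.
    """

    pair: tuple[str, str]
    wscore: float
    hscore: float
    n_shared: int
    shared_chemicals: frozenset[str] | None = None


class PPAN:
    """Scored undirected protein-protein association network.

    ``universe_size`` is the number of distinct chemicals N in the source
    table — the hypergeometric universe for edge scores.
    """

    def __init__(
        self,
        proteins: Iterable[str],
        edges: Iterable[ScoredEdge],
        universe_size: int,
    ):
        self.proteins: frozenset[str] = frozenset(proteins)
        self.edges: dict[tuple[str, str], ScoredEdge] = {}
        for e in edges:
            a, b = e.pair
            if a == b:
                raise ValueError(f"self-loop edge on {a}")
            if e.pair != canonical_pair(a, b):
                raise ValueError(f"edge pair {e.pair} not in canonical order")
            if e.pair in self.edges:
                raise ValueError(f"duplicate edge {e.pair}")
            self.edges[e.pair] = e
        missing = {p for pair in self.edges for p in pair} - self.proteins
        if missing:
            raise ValueError(f"edge endpoints not in protein set: {sorted(missing)[:5]}")
        self.universe_size = int(universe_size)
        self._adjacency: dict[str, dict[str, float]] | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.edges

    def adjacency(self) -> dict[str, dict[str, float]]:
        """Neighbour map ``protein -> {neighbour: wscore}`` (cached)."""
        if self._adjacency is None:
            adj: dict[str, dict[str, float]] = {p: {} for p in self.proteins}
            for (a, b), e in self.edges.items():
                adj[a][b] = e.wscore
                adj[b][a] = e.wscore
            self._adjacency = adj
        return self._adjacency

    def degrees(self) -> dict[str, int]:
        return {p: len(nbrs) for p, nbrs in self.adjacency().items()}

    def subset(self, pairs: Iterable[tuple[str, str]], drop_isolated: bool = True) -> "PPAN":
        """Restrict to the given edge pairs (canonical order assumed)."""
        kept = {p: self.edges[p] for p in pairs}
        if drop_isolated:
            proteins = {x for pair in kept for x in pair}
        else:
            proteins = self.proteins
        return PPAN(proteins, kept.values(), self.universe_size)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, e.n_shared, e.wscore, e.hscore)
            for (a, b), e in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows, columns=["protein_a", "protein_b", "n_shared", "wscore", "hscore"]
        )

    def write_edges(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def read_edges(cls, path: str | Path, universe_size: int = 0) -> "PPAN":
        df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
        edges = [
            ScoredEdge(
                pair=canonical_pair(str(r.protein_a), str(r.protein_b)),
                wscore=float(r.wscore),
                hscore=float(r.hscore),
                n_shared=int(r.n_shared),
            )
            for r in df.itertuples(index=False)
        ]
        proteins = {p for e in edges for p in e.pair}
        return cls(proteins, edges, universe_size)

    @classmethod
    def from_weighted_edges(
        cls, weighted: Iterable[tuple[str, str, float]], universe_size: int = 0
    ) -> "PPAN":
        """Build a network from bare ``(a, b, wscore)`` triples (hscore 0)."""
        edges = [
            ScoredEdge(canonical_pair(a, b), wscore=w, hscore=0.0, n_shared=1)
            for a, b, w in weighted
        ]
        proteins = {p for e in edges for p in e.pair}
        return cls(proteins, edges, universe_size)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.proteins))
        for (a, b), e in self.edges.items():
            g.add_edge(a, b, wscore=e.wscore, hscore=e.hscore, n_shared=e.n_shared)
        return g


def _upper_tail(k: np.ndarray, N: int, K: np.ndarray, n: np.ndarray) -> np.ndarray:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), vectorised."""
    return stats.hypergeom.sf(k - 1, N, K, n)


def project(table: AssociationTable, universe_size: int | None = None) -> PPAN:
    """Project a chemical-protein table into the scored P-PAN.

    Every unordered protein pair sharing at least one chemical becomes one
    edge (A-B and B-A collapse to a single canonical association).  ``N``
    defaults to the number of distinct chemicals with a non-negated
    association in the table.
    """
    if len(table.chemical_index) == 0:
        raise ValueError("association table has no active associations")
    shared: dict[tuple[str, str], set[str]] = {}
    for chem in sorted(table.chemical_index):
        targets = sorted(table.chemical_index[chem])
        if len(targets) < 2:
            continue
        for a, b in itertools.combinations(targets, 2):
            shared.setdefault((a, b), set()).add(chem)
    N = table.n_chemicals if universe_size is None else int(universe_size)
    if not shared:
        warnings.warn("no chemical is shared by two or more proteins; empty P-PAN")
        return PPAN(table.proteins, [], N)

    pairs = sorted(shared)
    k = np.array([len(shared[p]) for p in pairs])
    K = np.array([len(table.protein_index[p[0]]) for p in pairs])
    n = np.array([len(table.protein_index[p[1]]) for p in pairs])
    if np.any(k > np.minimum(K, n)):
        raise AssertionError("shared-chemical count exceeds a margin; corrupt indices")
    pvals = _upper_tail(k, N, K, n)
    capped = pvals <= 0.0
    if capped.any():
        logger.info("hscore underflow on %d edge(s); capped at %.2f", capped.sum(), HSCORE_CAP)
    hscores = np.where(capped, HSCORE_CAP, -np.log10(np.where(capped, 1.0, pvals)))

    inv_nc = {c: 1.0 / len(tgts) for c, tgts in table.chemical_index.items()}
    edges = []
    for pair, h, kk in zip(pairs, hscores, k):
        chems = frozenset(shared[pair])
        w = sum(inv_nc[c] for c in chems)
        edges.append(
            ScoredEdge(pair=pair, wscore=w, hscore=float(h), n_shared=int(kk), shared_chemicals=chems)
        )
    return PPAN(table.proteins, edges, N)


def weighted_score(pair: tuple[str, str], table: AssociationTable) -> float:
    """Weighted association score for one protein pair: sum of 1/n_c over
    shared chemicals (0 when nothing is shared)."""
    a, b = pair
    shared = table.protein_index.get(a, frozenset()) & table.protein_index.get(b, frozenset())
    return sum(1.0 / len(table.chemical_index[c]) for c in shared)


def hypergeometric_score(
    pair: tuple[str, str],
    table: AssociationTable,
    universe_size: int | None = None,
) -> float:
    """Hypergeometric association score for one protein pair.

    With N chemicals in total, K of them hitting the first protein and n the
    second, the probability that k or more chemicals hit both by chance is the
    upper hypergeometric tail; the score is -log10 of it (0 when k = 0).
    Symmetric in the pair by symmetry of the hypergeometric distribution.
    """
    a, b = pair
    Ca = table.protein_index.get(a, frozenset())
    Cb = table.protein_index.get(b, frozenset())
    N = table.n_chemicals if universe_size is None else int(universe_size)
    K, n, k = len(Ca), len(Cb), len(Ca & Cb)
    if N < max(K, n):
        raise ValueError(f"universe size {N} smaller than a margin ({K}, {n})")
    if k > min(K, n):
        raise AssertionError("overlap exceeds a margin; inconsistent table")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    if p <= 0.0:
        logger.info("hscore underflow for pair %s; capped at %.2f", pair, HSCORE_CAP)
        return HSCORE_CAP
    return -math.log10(p)
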