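"""Benchmarking P-PAN edge scores against reference protein-protein
interaction sets.

The association network is validated by sorting its edges by a reliability
score and asking, for increasing top fractions of the ranking, how many
reference interactions are recovered.  A good score concentrates reference
edges near the top of the ranking; the no-signal baseline is the same network
with node labels randomly permuted, which preserves the topology and the
score multiset exactly but destroys the identity of every pair.

The default operating point keeps the top 8% of edges by weighted score,
with 5%, 12.5% and 17% exposed as presets for robustness scans.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ReferenceInteractionSet, canonical_pair
from .projection import PPAN, ScoredEdge

__all__ = [
    "CalibrationCurve",
    "HighConfidenceNetwork",
    "DEFAULT_FRACTIONS",
    "FRACTION_PRESETS",
    "overlap_curve",
    "select_threshold",
    "permute_network",
    "expected_permuted_overlap",
]

DEFAULT_FRACTIONS: tuple[float, ...] = tuple(round(0.01 * i, 2) for i in range(1, 21))

#: Operating points used in the robustness scan; 0.08 is the default.
FRACTION_PRESETS: tuple[float, ...] = (0.05, 0.08, 0.125, 0.17)

_SCORE_KINDS = ("wscore", "hscore", "overlap_count")


def _edge_score(edge: ScoredEdge, kind: str) -> float:
    if kind == "wscore":
        return edge.wscore
    if kind == "hscore":
        return edge.hscore
    if kind == "overlap_count":
        return float(edge.n_shared)
    raise ValueError(f"unknown score kind {kind!r}")


def _ranked_edges(ppan: PPAN, kind: str) -> list[tuple[tuple[str, str], float]]:
    scored = [(pair, _edge_score(e, kind)) for pair, e in ppan.edges.items()]
    # descending score; pair order only stabilises the listing, the tie rule
    # at a fraction boundary includes every edge at the cutoff score
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def _top_count_with_ties(scores: list[float], fraction: float, n_edges: int) -> int:
    m = math.ceil(fraction * n_edges)
    if m >= n_edges:
        return n_edges
    cutoff = scores[m - 1]
    while m < n_edges and scores[m] == cutoff:
        m += 1
    return m


@dataclass
class CalibrationCurve:
    """Reference-interaction recovery as a function of the top-edge fraction.

    ``overlap_pct_raw`` divides by the full reference size;
    ``overlap_pct_restricted`` divides by the reference edges whose endpoints
    both occur in the network (the recoverable part).  ``random_counts`` is
    the mean overlap of node-permuted networks when permutations were
    requested.
    """

    score_kind: str
    fractions: tuple[float, ...]
    top_sizes: tuple[int, ...]
    overlap_counts: tuple[int, ...]
    n_reference: int
    n_reference_restricted: int
    random_counts: tuple[float, ...] | None = None
    n_permutations: int = 0

    @property
    def overlap_pct_raw(self) -> tuple[float, ...]:
        if self.n_reference == 0:
            return tuple(0.0 for _ in self.overlap_counts)
        return tuple(100.0 * c / self.n_reference for c in self.overlap_counts)

    @property
    def overlap_pct_restricted(self) -> tuple[float, ...]:
        if self.n_reference_restricted == 0:
            return tuple(0.0 for _ in self.overlap_counts)
        return tuple(100.0 * c / self.n_reference_restricted for c in self.overlap_counts)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "fraction": self.fractions,
            "top_edges": self.top_sizes,
            "overlap_count": self.overlap_counts,
            "overlap_pct_raw": self.overlap_pct_raw,
            "overlap_pct_restricted": self.overlap_pct_restricted,
        }
        if self.random_counts is not None:
            data["random_overlap_count"] = self.random_counts
        return pd.DataFrame(data)


def overlap_curve(
    ppan: PPAN,
    reference: ReferenceInteractionSet,
    score_kind: str = "wscore",
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    permutations: int = 0,
    seed: int | None = None,
) -> CalibrationCurve:
    """Compute the reference-overlap calibration curve for one score kind.

    For each fraction f the top ceil(f * |E|) edges by descending score are
    taken (extended through ties at the cutoff score) and intersected with the
    reference edge set.  With ``permutations > 0`` the same curve is averaged
    over that many node-permuted copies of the network as a random baseline.
    """
    if score_kind not in _SCORE_KINDS:
        raise ValueError(f"score_kind must be one of {_SCORE_KINDS}")
    if len(reference) == 0:
        raise ValueError("reference interaction set is empty")
    fr = tuple(fractions)
    if not fr or any(not (0.0 < f <= 1.0) for f in fr) or list(fr) != sorted(set(fr)):
        raise ValueError("fractions must be strictly increasing values in (0, 1]")
    if not (reference.proteins & ppan.proteins):
        warnings.warn("reference proteins are disjoint from the network; zero-overlap curve")
    restricted = sum(
        1 for a, b in reference.edges if a in ppan.proteins and b in ppan.proteins
    )

    def counts_for(net: PPAN) -> tuple[tuple[int, ...], tuple[int, ...]]:
        ranked = _ranked_edges(net, score_kind)
        scores = [s for _, s in ranked]
        in_ref = np.fromiter(
            (pair in reference.edges for pair, _ in ranked), dtype=bool, count=len(ranked)
        )
        cum = np.concatenate(([0], np.cumsum(in_ref)))
        sizes, overlaps = [], []
        for f in fr:
            m = _top_count_with_ties(scores, f, len(ranked)) if ranked else 0
            sizes.append(m)
            overlaps.append(int(cum[m]))
        return tuple(sizes), tuple(overlaps)

    top_sizes, overlap_counts = counts_for(ppan)

    random_counts = None
    if permutations > 0:
        seeds = np.random.SeedSequence(seed).spawn(permutations)
        acc = np.zeros(len(fr))
        for ss in seeds:
            perm = permute_network(ppan, rng=np.random.default_rng(ss))
            _, rc = counts_for(perm)
            acc += np.asarray(rc, dtype=float)
        random_counts = tuple(acc / permutations)

    return CalibrationCurve(
        score_kind=score_kind,
        fractions=fr,
        top_sizes=top_sizes,
        overlap_counts=overlap_counts,
        n_reference=len(reference),
        n_reference_restricted=restricted,
        random_counts=random_counts,
        n_permutations=permutations,
    )


@dataclass
class HighConfidenceNetwork:
    """Top-fraction sub-network by weighted score.

    ``cutoff`` is the realised score of the weakest retained edge.  Because
    ties at the boundary are always included, the network at a smaller
    fraction is a subset of the network at a larger one.
    """

    network: PPAN
    fraction: float
    cutoff: float

    @property
    def proteins(self) -> frozenset[str]:
        return self.network.proteins

    @property
    def n_edges(self) -> int:
        return self.network.n_edges


def select_threshold(ppan: PPAN, fraction: float = 0.08) -> HighConfidenceNetwork:
    """Keep the top ``fraction`` of edges by weighted score.

    Edges tied with the boundary score are all retained; proteins left
    without any retained edge are dropped from the node set.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if ppan.n_edges == 0:
        raise ValueError("cannot threshold an empty network")
    ranked = _ranked_edges(ppan, "wscore")
    scores = [s for _, s in ranked]
    m = _top_count_with_ties(scores, fraction, len(ranked))
    kept = [pair for pair, _ in ranked[:m]]
    cutoff = scores[m - 1]
    sub = ppan.subset(kept, drop_isolated=True)
    return HighConfidenceNetwork(network=sub, fraction=fraction, cutoff=cutoff)


def permute_network(
    ppan: PPAN,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PPAN:
    """Uniformly relabel the network's nodes (node-permutation null).

    The returned network has exactly the same degree multiset and edge score
    multiset; only the identities attached to each position change, so any
    agreement with a reference interaction set is down to chance.
    """
    if len(ppan.proteins) < 2:
        raise ValueError("need at least two proteins to permute")
    if rng is None:
        rng = np.random.default_rng(seed)
    nodes = sorted(ppan.proteins)
    perm = rng.permutation(len(nodes))
    mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
    edges = [
        ScoredEdge(
            pair=canonical_pair(mapping[a], mapping[b]),
            wscore=e.wscore,
            hscore=e.hscore,
            n_shared=e.n_shared,
            shared_chemicals=e.shared_chemicals,
        )
        for (a, b), e in sorted(ppan.edges.items())
    ]
    return PPAN(ppan.proteins, edges, ppan.universe_size)


def expected_permuted_overlap(
    ppan: PPAN, reference: ReferenceInteractionSet
) -> tuple[float, int, float]:
    """Analytic expectation of the permuted network's reference overlap.

    Under uniform relabeling each specific unordered pair of network proteins
    is an edge with probability |E| / C(P, 2); only reference edges with both
    endpoints in the network can ever be recovered.  Returns
    ``(expected_count, n_recoverable_reference_edges, per_pair_probability)``.
    """
    P = len(ppan.proteins)
    total_pairs = P * (P - 1) // 2
    p_edge = ppan.n_edges / total_pairs if total_pairs else 0.0
    n_restricted = sum(
        1 for a, b in reference.edges if a in ppan.proteins and b in ppan.proteins
    )
    return n_restricted * p_edge, n_restricted, p_edge
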