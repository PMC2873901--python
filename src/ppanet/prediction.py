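"""Neighbor-protein procedure: guilt-by-association target prediction.

Starting from a chemical's known protein targets (the input set), the
procedure (1) places the input proteins and their mutual associations in a
sub-network, (2) adds each first-order neighbour whose *inclusion ratio* —
the fraction of its network edges that touch the input set — meets a
threshold (default 0.1), then completes all associations among the retained
proteins, and (3) scores every sub-network protein against random complexes:
R input sets of the same size drawn from the network's proteins.

For protein v the statistic is t(v), the summed wscore of v's edges into the
input set.  The per-protein confidence score (cpscore) is the z-score of
t_obs(v) against its null distribution, with a companion empirical p-value
(1 + #{null >= obs}) / (R + 1); the sub-network confidence score (cscore) is
the analogous z-score of the summed statistic over the non-input sub-network
proteins.  Proteins are ranked by cpscore; candidates that are not known
targets are the predicted novel targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import HighConfidenceNetwork
from .projection import PPAN

__all__ = [
    "Subnetwork",
    "QueryResult",
    "EvaluationMetrics",
    "inclusion_ratio",
    "pull_down",
    "score_complex",
    "predict_targets",
    "evaluate",
    "DEFAULT_INCLUSION_THRESHOLD",
    "DEFAULT_RANDOMIZATIONS",
]

DEFAULT_INCLUSION_THRESHOLD = 0.1
DEFAULT_RANDOMIZATIONS = 10_000


class MissingInputError(ValueError):
    """None of the query proteins occur in the network."""


def _as_ppan(network: PPAN | HighConfidenceNetwork) -> PPAN:
    return network.network if isinstance(network, HighConfidenceNetwork) else network


def inclusion_ratio(
    candidate: str,
    input_set: frozenset[str] | set[str],
    network: PPAN | HighConfidenceNetwork,
) -> float:
    """Fraction of a candidate's edges that connect to the input set.

    Always in [0, 1]; raises for an isolated candidate, for which the ratio
    is undefined (such nodes are excluded from pull-downs).
    """
    adj = _as_ppan(network).adjacency()
    nbrs = adj.get(candidate)
    if not nbrs:
        raise ValueError(f"{candidate!r} has no edges; inclusion ratio undefined")
    to_input = sum(1 for nb in nbrs if nb in input_set)
    return to_input / len(nbrs)


@dataclass(frozen=True)
class Subnetwork:
    """Pulled-down sub-network around a chemical's known targets."""

    nodes: frozenset[str]
    inputs: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @property
    def neighbors(self) -> frozenset[str]:
        return self.nodes - self.inputs


def pull_down(
    chemical_targets: frozenset[str] | set[str],
    network: PPAN | HighConfidenceNetwork,
    threshold: float = DEFAULT_INCLUSION_THRESHOLD,
    strict: bool = False,
) -> Subnetwork:
    """Extract the neighbourhood sub-network around the input proteins.

    First-order neighbours of the inputs are retained when their inclusion
    ratio meets the threshold (``>=`` by default; ``strict=True`` demands a
    strictly greater ratio).  Finally all network edges among the retained
    proteins are added, completing the complex.
    """
    ppan = _as_ppan(network)
    inputs = frozenset(chemical_targets) & ppan.proteins
    if not inputs:
        missing = sorted(frozenset(chemical_targets))
        raise MissingInputError(
            f"no query protein present in the network (queried: {missing[:10]})"
        )
    adj = ppan.adjacency()
    neighbors = sorted(
        {nb for p in inputs for nb in adj[p] if nb not in inputs}
    )
    kept = set(inputs)
    for cand in neighbors:
        ratio = inclusion_ratio(cand, inputs, ppan)
        if (ratio > threshold) if strict else (ratio >= threshold):
            kept.add(cand)
    edges = frozenset(
        pair for pair in ppan.edges if pair[0] in kept and pair[1] in kept
    )
    return Subnetwork(nodes=frozenset(kept), inputs=inputs, edges=edges)


@dataclass
class QueryResult:
    """Scored pull-down for one chemical query.

    ``table`` holds one row per sub-network protein: inclusion ratio,
    cpscore, empirical p and rank (by descending cpscore; proteins whose null
    statistic is degenerate — sd 0 — get NaN cpscore and rank last).
    """

    chemical_id: str
    input_proteins: frozenset[str]
    subnetwork: Subnetwork
    table: pd.DataFrame
    cscore: float
    cscore_empirical_p: float
    n_randomizations: int
    seed: int | None

    def novel_candidates(self) -> pd.DataFrame:
        """Non-input sub-network proteins, best cpscore first."""
        return self.table[~self.table["is_input"]].reset_index(drop=True)


def score_complex(
    subnetwork: Subnetwork | None,
    input_set: frozenset[str] | set[str],
    network: PPAN | HighConfidenceNetwork,
    R: int = DEFAULT_RANDOMIZATIONS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    degree_matched: bool = False,
    chemical_id: str = "",
) -> QueryResult:
    """Score a pulled-down complex against R random input sets.

    The null draws R protein sets of the input's cardinality uniformly from
    the network's proteins (``degree_matched=True`` instead samples
    proportionally to weighted degree, guarding against hub bias).  The
    empirical p-value carries a +1 pseudocount so its minimum is 1/(R+1).

    ``subnetwork=None`` scans the whole network: every protein is scored as
    if it were a sub-network member, which is the right candidate set for an
    unbiased evaluation (restricting to pulled-down neighbours conditions on
    connectivity to the observed inputs and skews null p-values small).
    """
    if R < 100:
        raise ValueError("need at least 100 randomizations")
    ppan = _as_ppan(network)
    inputs = frozenset(input_set) & ppan.proteins
    if not inputs:
        raise MissingInputError("input set has no protein in the network")
    if subnetwork is None:
        subnetwork = Subnetwork(
            nodes=ppan.proteins, inputs=inputs, edges=frozenset(ppan.edges)
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    nodes = sorted(ppan.proteins)
    index = {p: i for i, p in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for (a, b), e in ppan.edges.items():
        W[index[a], index[b]] = e.wscore
        W[index[b], index[a]] = e.wscore

    sub_nodes = sorted(subnetwork.nodes)
    sub_idx = np.array([index[p] for p in sub_nodes])
    input_idx = np.array(sorted(index[p] for p in inputs))
    m = len(input_idx)

    W_sub = W[sub_idx, :]  # |sub| x n
    t_obs = W_sub[:, input_idx].sum(axis=1)

    if degree_matched:
        wdeg = W.sum(axis=0)
        probs = wdeg / wdeg.sum()
    else:
        probs = None
    # null input-set indicator matrix, n x R
    S = np.zeros((n, R))
    for r in range(R):
        draw = rng.choice(n, size=m, replace=False, p=probs)
        S[draw, r] = 1.0
    T_null = W_sub @ S  # |sub| x R

    # condition each protein's null on sets not containing the protein itself:
    # a candidate is never a member of its own input set, and null sets that
    # include it have one fewer potential neighbour, biasing the null low
    cpscore = np.empty(len(sub_nodes))
    emp_p = np.empty(len(sub_nodes))
    for i, g in enumerate(sub_idx):
        mask = S[g] == 0.0
        null_i = T_null[i, mask] if mask.any() else T_null[i]
        sd = null_i.std(ddof=1) if len(null_i) > 1 else 0.0
        cpscore[i] = (t_obs[i] - null_i.mean()) / sd if sd > 0.0 else np.nan
        emp_p[i] = (1.0 + (null_i >= t_obs[i]).sum()) / (len(null_i) + 1.0)
    if np.isnan(cpscore).any():
        warnings.warn(
            f"{int(np.isnan(cpscore).sum())} protein(s) have a degenerate null "
            "(sd 0); cpscore undefined for them"
        )

    is_input = np.array([p in inputs for p in sub_nodes])
    ratios = np.full(len(sub_nodes), np.nan)
    adj = ppan.adjacency()
    for i, p in enumerate(sub_nodes):
        if adj[p]:
            ratios[i] = sum(1 for nb in adj[p] if nb in inputs) / len(adj[p])

    # sub-network statistic: total input connectivity of the non-input members
    free = ~is_input
    if free.any():
        s_obs = float(t_obs[free].sum())
        s_null = T_null[free].sum(axis=0)
        s_sd = s_null.std(ddof=1)
        cscore = float((s_obs - s_null.mean()) / s_sd) if s_sd > 0 else float("nan")
        cscore_p = float((1.0 + (s_null >= s_obs).sum()) / (R + 1.0))
    else:
        cscore, cscore_p = float("nan"), float("nan")

    table = pd.DataFrame(
        {
            "protein_id": sub_nodes,
            "is_input": is_input,
            "inclusion_ratio": ratios,
            "cpscore": cpscore,
            "empirical_p": emp_p,
        }
    )
    order = table["cpscore"].rank(ascending=False, method="first", na_option="bottom")
    table["rank"] = order.astype(int)
    table = table.sort_values("rank", kind="stable").reset_index(drop=True)
    return QueryResult(
        chemical_id=chemical_id,
        input_proteins=inputs,
        subnetwork=subnetwork,
        table=table,
        cscore=cscore,
        cscore_empirical_p=cscore_p,
        n_randomizations=R,
        seed=seed,
    )


def predict_targets(
    chemical_targets: frozenset[str] | set[str],
    network: PPAN | HighConfidenceNetwork,
    threshold: float = DEFAULT_INCLUSION_THRESHOLD,
    R: int = DEFAULT_RANDOMIZATIONS,
    seed: int | None = None,
    strict: bool = False,
    degree_matched: bool = False,
    chemical_id: str = "",
) -> QueryResult:
    """Pull down and score in one call (the full neighbor-protein procedure)."""
    sub = pull_down(chemical_targets, network, threshold=threshold, strict=strict)
    return score_complex(
        sub,
        sub.inputs,
        network,
        R=R,
        seed=seed,
        degree_matched=degree_matched,
        chemical_id=chemical_id,
    )


@dataclass(frozen=True)
class EvaluationMetrics:
    """Recall and precision of predicted chemical-protein pairs against an
    independent reference catalogue; precision is None when nothing was
    predicted."""

    recall: float
    precision: float | None
    n_predicted: int
    n_reference: int
    n_hits: int


def evaluate(
    predictions: set[tuple[str, str]] | frozenset[tuple[str, str]],
    reference_pairs: set[tuple[str, str]] | frozenset[tuple[str, str]],
) -> EvaluationMetrics:
    """Compare predicted (chemical, protein) pairs with a reference set."""
    if not reference_pairs:
        raise ValueError("reference pair set is empty")
    preds = frozenset(predictions)
    ref = frozenset(reference_pairs)
    hits = preds & ref
    precision = len(hits) / len(preds) if preds else None
    if precision is None:
        warnings.warn("no predictions; precision undefined")
    return EvaluationMetrics(
        recall=len(hits) / len(ref),
        precision=precision,
        n_predicted=len(preds),
        n_reference=len(ref),
        n_hits=len(hits),
    )
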