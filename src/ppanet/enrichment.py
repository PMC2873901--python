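"""Hypergeometric over-representation analysis of clusters.

Given a cluster of n annotatable proteins drawn from a background of N, a
term annotating K background proteins and k cluster members is tested with
the upper hypergeometric tail P(X >= k).  Raw p-values are Bonferroni
corrected within each cluster's family (the m terms with at least one
annotated cluster member) and called significant at a corrected alpha of
0.05 by default.

The same machinery mines clusters for associated chemicals — each chemical's
target set acts as a term — and, for disease-enriched clusters, reports how
many disease-annotated cluster members each chemical touches.  The network
gives no direction: whether a chemical causes or protects against the
disease cannot be read off the association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationTable, AssociationTable, UsageError

__all__ = [
    "EnrichmentResult",
    "ChemicalDiseaseMining",
    "CutoffCalibration",
    "enrich",
    "mine_chemical_disease",
    "calibrate_disease_cutoff",
    "results_frame",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one term in one cluster.

    k of the n (annotatable) cluster members carry the term, against K of the
    N background proteins; ``p_bonferroni`` is min(1, m * p_raw) with m the
    number of terms tested in this cluster's family.
    """

    cluster_id: int
    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_bonferroni: float
    significant: bool


def _upper_tail(k: int, N: int, K: int, n: int) -> float:
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    cluster_members: frozenset[str] | set[str],
    annotations: AnnotationTable,
    background: frozenset[str] | set[str],
    alpha: float = DEFAULT_ALPHA,
    cluster_id: int = 0,
    annotatable_background: bool = True,
) -> list[EnrichmentResult]:
    """Test every term with >= 1 annotated cluster member for enrichment.

    With ``annotatable_background`` (default) the universe N is restricted to
    background proteins carrying at least one annotation of this kind, and n
    to the annotatable cluster members — proteins that could never be counted
    for any term are not allowed to dilute the test.  Annotation quality
    filters (evidence codes, disease score cutoffs) are expected to have been
    applied upstream.  Results are sorted by corrected p-value.
    """
    if not cluster_members <= set(background):
        raise ValueError("cluster members must be a subset of the background")
    if annotatable_background:
        universe = frozenset(background) & annotations.proteins
    else:
        universe = frozenset(background)
    members = frozenset(cluster_members) & universe
    if not members:
        warnings.warn(f"cluster {cluster_id}: no annotatable members")
        return []
    N, n = len(universe), len(members)

    terms = sorted(
        {t for p in members for t in annotations.terms_by_protein.get(p, ())}
    )
    m = len(terms)
    results = []
    for term in terms:
        annotated = annotations.proteins_by_term[term] & universe
        K = len(annotated)
        k = len(annotated & members)
        p_raw = _upper_tail(k, N, K, n)
        p_bonf = min(1.0, m * p_raw)
        results.append(
            EnrichmentResult(
                cluster_id=cluster_id,
                term_id=term,
                term_name=annotations.term_names.get(term, ""),
                k=k,
                n=n,
                K=K,
                N=N,
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                significant=p_bonf <= alpha,
            )
        )
    results.sort(key=lambda r: (r.p_bonferroni, r.p_raw, r.term_id))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.cluster_id,
                r.term_id,
                r.term_name,
                r.k,
                r.n,
                r.K,
                r.N,
                r.p_raw,
                r.p_bonferroni,
                int(r.significant),
            )
            for r in results
        ],
        columns=[
            "cluster_id",
            "term_id",
            "term_name",
            "k",
            "n",
            "K",
            "N",
            "p_raw",
            "p_bonferroni",
            "significant",
        ],
    )


@dataclass
class ChemicalDiseaseMining:
    """Chemical enrichment in a cluster plus chemical-disease overlap counts.

    ``chemical_results`` ranks chemicals by their target-set enrichment in
    the cluster (background: the high-confidence network proteins).
    ``overlaps`` counts, per (chemical, disease) pair present in the cluster,
    the disease-annotated cluster members the chemical targets.
    """

    cluster_id: int
    chemical_results: list[EnrichmentResult]
    overlaps: pd.DataFrame


def mine_chemical_disease(
    cluster_members: frozenset[str] | set[str],
    associations: AssociationTable,
    disease_annotations: AnnotationTable,
    background: frozenset[str] | set[str],
    alpha: float = DEFAULT_ALPHA,
    cluster_id: int = 0,
) -> ChemicalDiseaseMining:
    """Rank chemicals by enrichment of their target sets in a cluster.

    Chemicals with no target in the cluster are excluded from the report (an
    empty overlap gives p = 1 and carries no information).  For each reported
    chemical and each disease annotating at least one cluster member, the
    overlap table lists |targets(chemical) ∩ disease-annotated members| — the
    count behind a claim like "of the cluster's disease proteins, this many
    respond to the chemical".
    """
    members = frozenset(cluster_members) & frozenset(background)
    universe = frozenset(background)
    N, n = len(universe), len(members)
    chems = sorted(
        {c for p in members for c in associations.protein_index.get(p, ())}
    )
    m = len(chems)
    results = []
    for chem in chems:
        targets = associations.chemical_index[chem] & universe
        K = len(targets)
        k = len(targets & members)
        if k == 0:
            continue
        p_raw = _upper_tail(k, N, K, n)
        p_bonf = min(1.0, m * p_raw)
        results.append(
            EnrichmentResult(
                cluster_id=cluster_id,
                term_id=chem,
                term_name=chem,
                k=k,
                n=n,
                K=K,
                N=N,
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                significant=p_bonf <= alpha,
            )
        )
    results.sort(key=lambda r: (r.p_bonferroni, r.p_raw, r.term_id))

    rows = []
    diseases = sorted(
        {
            t
            for p in members
            for t in disease_annotations.terms_by_protein.get(p, ())
        }
    )
    for r in results:
        targets = associations.chemical_index[r.term_id]
        for d in diseases:
            annotated_members = disease_annotations.proteins_by_term[d] & members
            rows.append(
                (
                    cluster_id,
                    r.term_id,
                    d,
                    disease_annotations.term_names.get(d, ""),
                    len(annotated_members),
                    len(annotated_members & targets),
                )
            )
    overlaps = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "chemical_id",
            "disease_id",
            "disease_name",
            "n_disease_members",
            "n_targeted_disease_members",
        ],
    )
    return ChemicalDiseaseMining(
        cluster_id=cluster_id, chemical_results=results, overlaps=overlaps
    )


@dataclass
class CutoffCalibration:
    """Two-source agreement of protein-disease annotations along a score grid.

    ``overlaps[i]`` counts the (protein, disease) pairs present in both
    sources whose score in the scored source is >= ``grid[i]``; it is
    non-increasing along the grid.  ``suggested_cutoff`` is the smallest grid
    value at which the marginal overlap loss first exceeds the elbow
    criterion (a fraction of the total shared pairs lost in one grid step).
    """

    grid: tuple[float, ...]
    overlaps: tuple[int, ...]
    suggested_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.grid, "overlap": self.overlaps})


def calibrate_disease_cutoff(
    source_a: AnnotationTable,
    source_b: AnnotationTable,
    score_grid: tuple[float, ...] | list[float],
    elbow: float = 0.05,
) -> CutoffCalibration:
    """Choose a confidence-score cutoff for a scored disease source by
    benchmarking it against a second, unscored source.

    Shared (protein, disease) pairs act as trusted annotations; sweeping the
    cutoff upward, agreement stays flat while only unscored noise is removed
    and starts dropping once genuine shared annotations are cut.  The
    suggested cutoff sits at the first grid step whose loss exceeds
    ``elbow`` * total shared pairs.
    """
    if source_a.kind != "disease":
        raise UsageError("source_a must be a disease annotation table")
    scored = {
        (e.protein_id, e.term_id): e.score
        for e in source_a.entries
        if e.score is not None
    }
    shared = set(scored) & source_b.pairs()
    if not shared:
        raise ValueError("no shared protein-disease pairs between the sources")
    grid = tuple(sorted(score_grid))
    if not grid:
        raise ValueError("empty score grid")
    overlaps = tuple(
        sum(1 for pair in shared if scored[pair] >= cut) for cut in grid
    )
    total = len(shared)
    suggested = grid[-1]
    for i in range(len(grid) - 1):
        if overlaps[i] - overlaps[i + 1] > elbow * total:
            suggested = grid[i]
            break
    return CutoffCalibration(grid=grid, overlaps=overlaps, suggested_cutoff=suggested)
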