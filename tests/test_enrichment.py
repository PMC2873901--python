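"""Cluster over-representation statistics and the disease-cutoff calibration."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import hypergeom_tail_exact
from ppanet.enrichment import (
    calibrate_disease_cutoff,
    enrich,
    mine_chemical_disease,
)
from ppanet.io import (
    AnnotationEntry,
    AnnotationTable,
    AssociationRecord,
    AssociationTable,
    UsageError,
)
from ppanet.synthetic import generate_two_source_disease


def annotation_table(assignments: dict[str, list[str]], kind="go") -> AnnotationTable:
    return AnnotationTable(
        [AnnotationEntry(p, t) for t, prots in assignments.items() for p in prots],
        kind=kind,
    )


BACKGROUND = frozenset(f"p{i:02d}" for i in range(20))


class TestEnrich:
    def test_hand_computed_p(self):
        """N=20, K=5, n=4, k=4 -> p = C(5,4)*C(15,0)/C(20,4) = 5/4845."""
        cluster = {"p00", "p01", "p02", "p03"}
        ann = annotation_table({"T": ["p00", "p01", "p02", "p03", "p04"]})
        # make every background protein annotatable so N stays 20
        ann = AnnotationTable(
            list(ann.entries) + [AnnotationEntry(p, "other") for p in sorted(BACKGROUND)],
            kind="go",
        )
        results = {r.term_id: r for r in enrich(cluster, ann, BACKGROUND)}
        assert results["T"].p_raw == pytest.approx(5 / 4845, abs=1e-12)
        assert results["T"].k == 4 and results["T"].K == 5 and results["T"].N == 20

    def test_term_annotating_everything_is_null(self):
        cluster = {"p00", "p01"}
        ann = annotation_table({"T": sorted(BACKGROUND)})
        (res,) = enrich(cluster, ann, BACKGROUND)
        assert res.p_raw == pytest.approx(1.0)
        assert not res.significant

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(4)
        background = frozenset(f"q{i}" for i in range(10))
        ann = AnnotationTable(
            [
                AnnotationEntry(p, f"T{j}")
                for j in range(4)
                for p in sorted(background)
                if rng.random() < 0.4
            ],
            kind="go",
        )
        cluster = set(sorted(background)[:5]) & ann.proteins
        for r in enrich(cluster, ann, background):
            exact = float(hypergeom_tail_exact(r.k, r.N, r.K, r.n))
            assert r.p_raw == pytest.approx(exact, abs=1e-12)

    def test_bonferroni_bounds_and_family_size(self):
        rng = np.random.default_rng(9)
        ann = AnnotationTable(
            [
                AnnotationEntry(p, f"T{j}")
                for j in range(6)
                for p in sorted(BACKGROUND)
                if rng.random() < 0.3
            ],
            kind="go",
        )
        cluster = set(sorted(BACKGROUND)[:6])
        results = enrich(cluster, ann, BACKGROUND)
        m = len(results)
        for r in results:
            assert r.p_bonferroni >= r.p_raw
            assert r.p_bonferroni <= 1.0
            assert r.p_bonferroni == pytest.approx(min(1.0, m * r.p_raw))

    def test_no_annotatable_members_warns_empty(self):
        ann = annotation_table({"T": ["p10", "p11"]})
        with pytest.warns(UserWarning, match="no annotatable"):
            assert enrich({"p00", "p01"}, ann, BACKGROUND) == []

    def test_background_restriction_toggle(self):
        """Unannotated background proteins only dilute the test when the
        full-background mode is requested."""
        ann = annotation_table({"T": ["p00", "p01", "p02"], "U": ["p03"]})
        cluster = {"p00", "p01"}
        restricted = {r.term_id: r for r in enrich(cluster, ann, BACKGROUND)}
        full = {
            r.term_id: r
            for r in enrich(cluster, ann, BACKGROUND, annotatable_background=False)
        }
        assert restricted["T"].N == 4  # only p00..p03 carry annotations
        assert full["T"].N == 20
        assert full["T"].p_raw < restricted["T"].p_raw

    def test_cluster_outside_background_rejected(self):
        ann = annotation_table({"T": ["p00"]})
        with pytest.raises(ValueError):
            enrich({"zz"}, ann, BACKGROUND)

    def test_type1_error_controlled_under_random_annotations(self):
        rng = np.random.default_rng(12)
        prots = sorted(BACKGROUND)
        cluster = set(prots[:6])
        false_clusters = 0
        trials = 50
        for _ in range(trials):
            ann = AnnotationTable(
                [
                    AnnotationEntry(p, f"T{j}")
                    for j in range(10)
                    for p in prots
                    if rng.random() < 0.2
                ],
                kind="go",
            )
            results = enrich(cluster, ann, BACKGROUND, alpha=0.05)
            false_clusters += any(r.significant for r in results)
        assert false_clusters / trials <= 0.05


class TestMineChemicalDisease:
    @pytest.fixture
    def setting(self):
        cluster = frozenset({"p00", "p01", "p02", "p03"})
        records = [AssociationRecord("focused", p) for p in sorted(cluster)]
        records += [AssociationRecord("broad", p) for p in sorted(BACKGROUND)[:8]]
        records += [AssociationRecord("outside", "p15")]
        table = AssociationTable(records)
        disease = annotation_table(
            {"D1": ["p00", "p01", "p10"]}, kind="disease"
        )
        return cluster, table, disease

    def test_focused_chemical_beats_broad_one(self, setting):
        cluster, table, disease = setting
        mining = mine_chemical_disease(cluster, table, disease, BACKGROUND)
        by_id = {r.term_id: r for r in mining.chemical_results}
        assert mining.chemical_results[0].term_id == "focused"
        assert by_id["focused"].p_raw < by_id["broad"].p_raw

    def test_zero_target_chemical_excluded(self, setting):
        cluster, table, disease = setting
        mining = mine_chemical_disease(cluster, table, disease, BACKGROUND)
        assert "outside" not in {r.term_id for r in mining.chemical_results}

    def test_disease_overlap_counts(self, setting):
        cluster, table, disease = setting
        mining = mine_chemical_disease(cluster, table, disease, BACKGROUND)
        row = mining.overlaps.query("chemical_id == 'focused' and disease_id == 'D1'")
        # two cluster members are D1-annotated and both are focused targets
        assert int(row["n_disease_members"].iloc[0]) == 2
        assert int(row["n_targeted_disease_members"].iloc[0]) == 2


class TestCutoffCalibration:
    def test_extreme_cutoffs(self):
        a, b = generate_two_source_disease(n_true=50, n_noise=50, seed=1)
        cal = calibrate_disease_cutoff(a, b, score_grid=[-10.0, 1000.0])
        assert cal.overlaps[0] == 50  # below every score: all shared pairs
        assert cal.overlaps[-1] == 0  # above every score: none

    def test_overlap_non_increasing(self):
        a, b = generate_two_source_disease(seed=2)
        cal = calibrate_disease_cutoff(a, b, score_grid=list(np.arange(0, 101, 5.0)))
        assert list(cal.overlaps) == sorted(cal.overlaps, reverse=True)

    def test_suggested_cutoff_near_planted_changepoint(self):
        a, b = generate_two_source_disease(changepoint=60.0, seed=3)
        grid = list(np.arange(0.0, 100.1, 5.0))
        cal = calibrate_disease_cutoff(a, b, score_grid=grid)
        assert abs(cal.suggested_cutoff - 60.0) <= 5.0

    def test_no_shared_pairs_is_error(self):
        a = AnnotationTable([AnnotationEntry("p1", "D1", score=70.0)], kind="disease")
        b = AnnotationTable([AnnotationEntry("p2", "D2")], kind="disease")
        with pytest.raises(ValueError, match="no shared"):
            calibrate_disease_cutoff(a, b, score_grid=[50.0])

    def test_unscored_source_rejected(self):
        a = AnnotationTable([AnnotationEntry("p1", "T1", evidence="IDA")], kind="go")
        b = AnnotationTable([AnnotationEntry("p1", "D1")], kind="disease")
        with pytest.raises(UsageError):
            calibrate_disease_cutoff(a, b, score_grid=[50.0])
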