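"""Neighbor-protein pull-down, randomisation scoring and evaluation."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from ppanet.prediction import (
    MissingInputError,
    Subnetwork,
    evaluate,
    inclusion_ratio,
    predict_targets,
    pull_down,
    score_complex,
)
from ppanet.projection import PPAN


def star_ppan() -> PPAN:
    """hub 'x' with 10 spokes; spoke s0 also linked to inputs i1..i3."""
    triples = [("x", f"s{i}", 1.0) for i in range(10)]
    triples += [(f"i{j}", "s0", 1.0) for j in range(1, 4)]
    triples += [("i1", "i2", 1.0)]
    return PPAN.from_weighted_edges(triples)


class TestInclusionRatio:
    def test_all_edges_to_input(self):
        ppan = PPAN.from_weighted_edges(
            [("v", f"i{j}", 1.0) for j in range(4)] + [("i0", "i1", 1.0)]
        )
        inputs = {f"i{j}" for j in range(4)}
        assert inclusion_ratio("v", inputs, ppan) == 1.0

    def test_no_edges_to_input_is_zero(self):
        ppan = star_ppan()
        assert inclusion_ratio("s3", {"i1", "i2", "i3"}, ppan) == 0.0

    def test_boundary_one_of_ten_retained_at_default(self):
        ppan = PPAN.from_weighted_edges(
            [("v", f"n{j}", 1.0) for j in range(9)] + [("v", "i0", 1.0), ("i0", "i1", 1.0)]
        )
        assert inclusion_ratio("v", {"i0", "i1"}, ppan) == pytest.approx(0.1)
        sub = pull_down({"i0", "i1"}, ppan, threshold=0.1)
        assert "v" in sub.nodes  # inclusive comparison keeps the boundary case
        strict = pull_down({"i0", "i1"}, ppan, threshold=0.1, strict=True)
        assert "v" not in strict.nodes

    def test_isolated_candidate_undefined(self):
        ppan = PPAN(["a", "b", "lonely"], PPAN.from_weighted_edges([("a", "b", 1.0)]).edges.values(), 0)
        with pytest.raises(ValueError, match="no edges"):
            inclusion_ratio("lonely", {"a"}, ppan)


class TestPullDown:
    def test_whole_component_recovered(self):
        comp = [f"c{i}" for i in range(5)]
        triples = [(a, b, 1.0) for a, b in itertools.combinations(comp, 2)]
        triples += [("z1", "z2", 1.0)]
        ppan = PPAN.from_weighted_edges(triples)
        sub = pull_down(set(comp), ppan)
        assert sub.nodes == set(comp)
        assert len(sub.edges) == 10

    def test_threshold_above_one_keeps_inputs_only(self):
        ppan = star_ppan()
        sub = pull_down({"i1", "i2", "i3"}, ppan, threshold=1.01)
        assert sub.nodes == {"i1", "i2", "i3"}
        assert ("i1", "i2") in sub.edges

    def test_missing_inputs_error_names_them(self):
        ppan = star_ppan()
        with pytest.raises(MissingInputError, match="zz"):
            pull_down({"zz"}, ppan)

    def test_raising_threshold_never_grows_subnetwork(self):
        ppan = star_ppan()
        inputs = {"i1", "i2", "i3"}
        sizes = [
            len(pull_down(inputs, ppan, threshold=t).nodes)
            for t in (0.0, 0.1, 0.3, 0.6, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_completion_adds_edges_among_retained(self):
        # v1 and v2 both qualify; their mutual edge must appear even though
        # neither brought it in during the neighbour scan
        triples = [("i0", "v1", 1.0), ("i0", "v2", 1.0), ("v1", "v2", 1.0), ("i0", "i1", 1.0)]
        ppan = PPAN.from_weighted_edges(triples)
        sub = pull_down({"i0", "i1"}, ppan, threshold=0.1)
        assert ("v1", "v2") in sub.edges


class TestScoreComplex:
    def _dense_ppan(self, rng, n=30):
        nodes = [f"n{i:02d}" for i in range(n)]
        triples = [
            (a, b, float(rng.uniform(0.05, 1.0)))
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.7
        ]
        return PPAN.from_weighted_edges(triples)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(0)
        ppan = self._dense_ppan(rng)
        inputs = set(sorted(ppan.proteins)[:5])
        a = predict_targets(inputs, ppan, R=200, seed=42)
        b = predict_targets(inputs, ppan, R=200, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.cscore == b.cscore

    def test_input_only_node_tops_equal_degree_peers(self):
        # v's only edges go to inputs; u has the same degree but random peers
        triples = [("v", f"i{j}", 0.5) for j in range(3)]
        triples += [("u", f"o{j}", 0.5) for j in range(3)]
        triples += [("i0", "i1", 0.5), ("o0", "o1", 0.5)]
        ppan = PPAN.from_weighted_edges(triples)
        inputs = {"i0", "i1", "i2"}
        res = score_complex(None, inputs, ppan, R=300, seed=1)
        scores = dict(zip(res.table.protein_id, res.table.cpscore))
        assert scores["v"] > scores["u"]

    def test_ranking_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(5)
        ppan = self._dense_ppan(rng)
        scaled = PPAN.from_weighted_edges(
            [(a, b, 7.5 * e.wscore) for (a, b), e in ppan.edges.items()]
        )
        inputs = set(sorted(ppan.proteins)[:5])
        a = score_complex(None, inputs, ppan, R=200, seed=3)
        b = score_complex(None, inputs, scaled, R=200, seed=3)
        assert list(a.table.protein_id) == list(b.table.protein_id)
        np.testing.assert_allclose(
            a.table.cpscore.to_numpy(), b.table.cpscore.to_numpy(), rtol=1e-9
        )

    def test_empirical_p_honest_minimum(self):
        rng = np.random.default_rng(6)
        ppan = self._dense_ppan(rng)
        inputs = set(sorted(ppan.proteins)[:5])
        res = score_complex(None, inputs, ppan, R=200, seed=7)
        assert (res.table.empirical_p >= 1.0 / 201.0).all()
        assert (res.table.empirical_p <= 1.0).all()

    def test_degenerate_null_reported_as_nan(self):
        # complete graph with equal weights and a single input: every null
        # set yields the same statistic, so sd is 0
        nodes = ["a", "b", "c", "d"]
        triples = [(x, y, 1.0) for x, y in itertools.combinations(nodes, 2)]
        ppan = PPAN.from_weighted_edges(triples)
        with pytest.warns(UserWarning, match="degenerate"):
            res = score_complex(None, {"a"}, ppan, R=100, seed=0)
        assert res.table.cpscore.isna().any()

    def test_too_few_randomizations_rejected(self):
        ppan = star_ppan()
        with pytest.raises(ValueError):
            score_complex(None, {"i1"}, ppan, R=10, seed=0)


class TestEvaluate:
    def test_perfect_prediction(self):
        pairs = {("c", "p1"), ("c", "p2")}
        m = evaluate(pairs, pairs)
        assert m.recall == 1.0 and m.precision == 1.0

    def test_disjoint_sets(self):
        m = evaluate({("c", "p1")}, {("c", "p2")})
        assert m.recall == 0.0 and m.precision == 0.0

    def test_hand_counted_overlap(self):
        preds = {("c", f"p{i}") for i in range(6)}
        ref = {("c", f"p{i}") for i in range(4, 10)}
        m = evaluate(preds, ref)
        assert m.n_hits == 2
        assert m.recall == pytest.approx(2 / 6)
        assert m.precision == pytest.approx(2 / 6)

    def test_empty_predictions_precision_undefined(self):
        with pytest.warns(UserWarning, match="precision"):
            m = evaluate(set(), {("c", "p1")})
        assert m.precision is None
        assert m.recall == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            evaluate({("c", "p")}, set())
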