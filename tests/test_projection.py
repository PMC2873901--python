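"""Projection of the bipartite table into the scored protein network."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import (
    brute_force_projection,
    hypergeom_tail_enumerated,
    hypergeom_tail_exact,
    random_association_table,
)
from ppanet.io import AssociationRecord, AssociationTable
from ppanet.projection import (
    PPAN,
    hypergeometric_score,
    project,
    weighted_score,
)


def table_from_targets(targets: dict[str, list[str]]) -> AssociationTable:
    return AssociationTable(
        AssociationRecord(c, p) for c, prots in targets.items() for p in prots
    )


class TestProjectStructure:
    def test_single_shared_chemical(self):
        ppan = project(table_from_targets({"c1": ["A", "B"], "c2": ["C"]}))
        assert set(ppan.edges) == {("A", "B")}
        assert ppan.edges[("A", "B")].shared_chemicals == {"c1"}

    def test_triple_target_gives_three_edges(self):
        ppan = project(table_from_targets({"c": ["A", "B", "C"]}))
        assert set(ppan.edges) == {("A", "B"), ("A", "C"), ("B", "C")}
        assert all(e.shared_chemicals == {"c"} for e in ppan.edges.values())

    def test_no_sharing_warns_empty(self):
        with pytest.warns(UserWarning, match="no chemical is shared"):
            ppan = project(table_from_targets({"c1": ["A"], "c2": ["B"]}))
        assert ppan.n_edges == 0
        assert ppan.proteins == {"A", "B"}

    def test_pairs_canonical_and_deduplicated(self):
        ppan = project(table_from_targets({"c1": ["B", "A"], "c2": ["A", "B"]}))
        assert list(ppan.edges) == [("A", "B")]
        assert ppan.edges[("A", "B")].n_shared == 2

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        table = random_association_table(rng, n_proteins=30, n_chemicals=20)
        ppan = project(table)
        oracle = brute_force_projection(table)
        assert set(ppan.edges) == set(oracle)
        for pair, (shared, w) in oracle.items():
            edge = ppan.edges[pair]
            assert edge.shared_chemicals == shared
            assert edge.wscore == pytest.approx(w, abs=1e-12)

    def test_edge_list_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        ppan = project(random_association_table(rng))
        path = tmp_path / "edges.tsv"
        ppan.write_edges(path)
        back = PPAN.read_edges(path)
        assert set(back.edges) == set(ppan.edges)
        for pair, e in ppan.edges.items():
            assert back.edges[pair].wscore == pytest.approx(e.wscore, rel=1e-10)


class TestWeightedScore:
    def test_hand_summation(self, tiny_table):
        # shared = {c1 (n=2), c2 (n=4)} -> 1/2 + 1/4
        assert weighted_score(("A", "B"), tiny_table) == pytest.approx(0.75)

    def test_empty_sum_is_zero(self, tiny_table):
        assert weighted_score(("C", "D"), tiny_table) == pytest.approx(0.25)
        table = table_from_targets({"c1": ["A", "B"], "c2": ["C", "D"]})
        assert weighted_score(("A", "C"), table) == 0.0

    def test_closed_form_when_all_chemicals_pairwise(self):
        # every chemical has exactly two targets -> wscore = k/2
        table = table_from_targets({f"c{i}": ["A", "B"] for i in range(6)})
        assert weighted_score(("A", "B"), table) == pytest.approx(3.0)

    def test_symmetry(self, tiny_table):
        assert weighted_score(("A", "B"), tiny_table) == weighted_score(("B", "A"), tiny_table)


class TestHypergeometricScore:
    def test_hand_example(self):
        # N=10 chemicals, K=4 hit A, n=5 hit B, k=3 shared:
        # P(X>=3) = (C(4,3)C(6,2) + C(4,4)C(6,1)) / C(10,5) = 66/252
        targets: dict[str, list[str]] = {}
        shared = ["c0", "c1", "c2"]
        only_a = ["c3"]
        only_b = ["c4", "c5"]
        rest = ["c6", "c7", "c8", "c9"]
        for c in shared:
            targets[c] = ["A", "B"]
        for c in only_a:
            targets[c] = ["A", "X"]
        for c in only_b:
            targets[c] = ["B", "X"]
        for c in rest:
            targets[c] = ["X"]
        table = table_from_targets(targets)
        assert table.n_chemicals == 10
        expected = -math.log10(66 / 252)
        got = hypergeometric_score(("A", "B"), table)
        assert got == pytest.approx(expected, abs=1e-12)
        assert hypergeometric_score(("B", "A"), table) == pytest.approx(got, abs=1e-12)

    def test_zero_overlap_full_tail(self):
        table = table_from_targets({"c1": ["A", "X"], "c2": ["B", "X"]})
        assert hypergeometric_score(("A", "B"), table) == 0.0

    @pytest.mark.parametrize("N", [5, 8, 12])
    def test_matches_exact_enumeration(self, N):
        from scipy import stats

        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(max(0, K + n - N), min(K, n) + 1):
                    exact = float(hypergeom_tail_exact(k, N, K, n))
                    got = float(stats.hypergeom.sf(k - 1, N, K, n))
                    assert got == pytest.approx(exact, abs=1e-12)

    def test_closed_form_equals_literal_enumeration(self):
        # validates the rational-arithmetic oracle itself against a literal
        # walk over every possible draw
        for (k, N, K, n) in [(3, 10, 4, 5), (2, 8, 3, 4), (0, 6, 2, 3), (4, 9, 4, 4)]:
            assert hypergeom_tail_exact(k, N, K, n) == hypergeom_tail_enumerated(k, N, K, n)

    def test_universe_smaller_than_margin_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_score(("A", "B"), tiny_table, universe_size=1)


class TestInvariants:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_conservation_identity(self, seed):
        """Sum of edge wscores equals sum over chemicals of (n_c - 1)/2."""
        rng = np.random.default_rng(seed)
        table = random_association_table(
            rng,
            n_proteins=int(rng.integers(5, 25)),
            n_chemicals=int(rng.integers(2, 15)),
            density=float(rng.uniform(0.1, 0.5)),
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ppan = project(table)
        total = sum(e.wscore for e in ppan.edges.values())
        expected = sum(
            (len(t) - 1) / 2 for t in table.chemical_index.values() if len(t) >= 2
        )
        assert total == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_shared_chemicals(self):
        """One more shared chemical strictly raises wscore and never lowers
        hscore (margins fixed by padding with a dummy protein)."""
        base = {
            "c0": ["A", "B"],
            "c1": ["A", "X"],
            "c2": ["B", "X"],
            "c3": ["X"],
            "c4": ["X"],
        }
        more = dict(base)
        more["c1"] = ["A", "B"]  # now shared; margins K, n, N unchanged
        t1, t2 = table_from_targets(base), table_from_targets(more)
        assert weighted_score(("A", "B"), t2) > weighted_score(("A", "B"), t1)
        assert hypergeometric_score(("A", "B"), t2) >= hypergeometric_score(("A", "B"), t1)

    def test_edge_count_matches_cooccurrence_oracle(self):
        rng = np.random.default_rng(5)
        table = random_association_table(rng, n_proteins=15, n_chemicals=10)
        ppan = project(table)
        cooccur = set()
        for targets in table.chemical_index.values():
            ts = sorted(targets)
            for i, a in enumerate(ts):
                for b in ts[i + 1 :]:
                    cooccur.add((a, b))
        assert set(ppan.edges) == cooccur
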