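"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import pytest
from hypothesis import settings

from ppanet.io import AssociationRecord, AssociationTable
from ppanet.projection import project
from ppanet.synthetic import WorldSpec, generate_world

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


# ---------------------------------------------------------------- oracles


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact upper-tail P(X >= k) as a rational number (binomial sums)."""
    total = math.comb(N, n)
    hi = min(K, n)
    acc = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(max(k, 0), hi + 1))
    return Fraction(acc, total)


def hypergeom_tail_enumerated(k: int, N: int, K: int, n: int) -> Fraction:
    """Literal enumeration over all C(N, n) draws from a population with K
    marked elements; independent of any closed form.  Small N only."""
    population = [1] * K + [0] * (N - K)
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return Fraction(hits, total)


def brute_force_projection(table: AssociationTable):
    """O(P^2) double loop over all protein pairs: edge set, shared-chemical
    sets and weighted scores computed without any of the library's indexing
    shortcuts."""
    proteins = sorted(table.protein_index)
    edges = {}
    for i, a in enumerate(proteins):
        for b in proteins[i + 1 :]:
            shared = table.protein_index[a] & table.protein_index[b]
            if shared:
                w = sum(1.0 / len(table.chemical_index[c]) for c in shared)
                edges[(a, b)] = (frozenset(shared), w)
    return edges


def random_association_table(rng, n_proteins=20, n_chemicals=12, density=0.25):
    proteins = [f"p{i:02d}" for i in range(n_proteins)]
    records = []
    for j in range(n_chemicals):
        for p in proteins:
            if rng.random() < density:
                records.append(AssociationRecord(f"c{j:02d}", p))
    if not records:
        records.append(AssociationRecord("c00", proteins[0]))
        records.append(AssociationRecord("c00", proteins[1]))
    return AssociationTable(records)


# ---------------------------------------------------------------- fixtures


def small_world_spec(n_modules=3, module_size=8, **overrides) -> WorldSpec:
    """A reduced planted world whose background targets fit the protein count."""
    defaults = dict(
        n_modules=n_modules,
        module_size=module_size,
        chemicals_per_module=4,
        n_background_chemicals=4,
        background_targets=max(2, n_modules * module_size // 2),
    )
    defaults.update(overrides)
    return WorldSpec(**defaults)


@pytest.fixture
def tiny_table() -> AssociationTable:
    """Hand-built table: c1 -> {A, B} (n=2), c2 -> {A, B, C, D} (n=4).

    The pair (A, B) shares both chemicals, so its weighted score is
    1/2 + 1/4 = 0.75.
    """
    recs = [
        AssociationRecord("c1", "A"),
        AssociationRecord("c1", "B"),
        AssociationRecord("c2", "A"),
        AssociationRecord("c2", "B"),
        AssociationRecord("c2", "C"),
        AssociationRecord("c2", "D"),
    ]
    return AssociationTable(recs)


@pytest.fixture(scope="session")
def default_world():
    return generate_world(WorldSpec(), seed=1)


@pytest.fixture(scope="session")
def default_ppan(default_world):
    return project(default_world.associations)
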