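"""Synthetic chemical-protein worlds with planted structure.

The generator emulates the statistical shape of a curated toxicogenomics
resource: proteins organised in functional modules, module-specific
chemicals that hit a random subset of their module's proteins (creating
dense within-module shared-chemical structure), promiscuous background
chemicals whose large target sets create many weak cross-module pairs (the
case the 1/n_c weighting is built to down-weight), module-aligned disease
and GO-like annotations with controlled noise, and a reference interaction
set derived from the planted modules at a chosen true-positive rate plus
uniform false positives.

Everything is drawn from named distributions (Binomial, Poisson, uniform)
under a single seeded generator, so the worlds double as null simulators and
every run is reproducible bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AnnotationEntry,
    AnnotationTable,
    AssociationRecord,
    AssociationTable,
    ReferenceInteractionSet,
    write_annotations,
    write_associations,
    write_reference_interactions,
)

__all__ = [
    "WorldSpec",
    "GroundTruth",
    "World",
    "generate_world",
    "holdout_targets",
    "generate_two_source_disease",
]

_RELATIONS = (
    "increases expression",
    "decreases expression",
    "binds",
    "affects expression",
)


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a planted chemical-protein world.

    ``n_modules`` modules of ``module_size`` proteins each;
    ``chemicals_per_module`` chemicals per module, each hitting its module's
    proteins independently with probability ``hit_prob`` plus
    Poisson(``cross_module_rate`` * module_size) out-of-module proteins;
    ``n_background_chemicals`` promiscuous chemicals each hitting
    ``background_targets`` proteins uniformly.  Disease and GO annotations
    follow module identity at ``annotation_coverage``, with
    ``disease_flip_prob`` of disease labels flipped to a random other module
    and extra sub-cutoff-score / non-experimental-evidence noise entries that
    the quality filters are expected to remove.  The reference interaction
    set contains each within-module pair with probability ``ppi_tp_rate``
    and each other pair with probability ``ppi_fp_rate``.
    """

    n_modules: int = 6
    module_size: int = 20
    chemicals_per_module: int = 8
    hit_prob: float = 0.5
    n_background_chemicals: int = 10
    background_targets: int = 60
    cross_module_rate: float = 0.02
    disease_flip_prob: float = 0.05
    annotation_coverage: float = 0.9
    annotation_noise_rate: float = 0.2
    ppi_tp_rate: float = 0.3
    ppi_fp_rate: float = 0.005
    negated_fraction: float = 0.05
    seed: int | None = None

    def validate(self) -> None:
        probs = {
            "hit_prob": self.hit_prob,
            "cross_module_rate": self.cross_module_rate,
            "disease_flip_prob": self.disease_flip_prob,
            "annotation_coverage": self.annotation_coverage,
            "ppi_tp_rate": self.ppi_tp_rate,
            "ppi_fp_rate": self.ppi_fp_rate,
            "negated_fraction": self.negated_fraction,
        }
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_modules * self.module_size < 2:
            raise ValueError("world needs at least two proteins")
        if self.chemicals_per_module > 0 and self.hit_prob == 0.0 and self.cross_module_rate == 0.0:
            raise ValueError("module chemicals demanded but hit_prob and cross_module_rate are both 0")
        if self.background_targets > self.n_modules * self.module_size:
            raise ValueError("background_targets exceeds the number of proteins")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure behind a generated world."""

    protein_module: dict[str, int]
    chemical_module: dict[str, int]  # module chemicals only
    disease_of_module: dict[int, str]
    go_term_of_module: dict[int, str]

    def module_members(self, module: int) -> frozenset[str]:
        return frozenset(p for p, m in self.protein_module.items() if m == module)

    def module_labels(self, proteins: list[str]) -> list[int]:
        return [self.protein_module[p] for p in proteins]


@dataclass
class World:
    """A generated world: the emitted tables plus their ground truth."""

    spec: WorldSpec
    associations: AssociationTable
    go_annotations: AnnotationTable
    disease_annotations: AnnotationTable
    chemical_annotations: AnnotationTable
    reference: ReferenceInteractionSet
    truth: GroundTruth
    seed: int | None = None

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "associations": out / "associations.tsv",
            "reference": out / "reference_ppi.tsv",
            "go": out / "go_annotations.tsv",
            "disease": out / "disease_annotations.tsv",
            "chemical": out / "chemical_annotations.tsv",
            "truth": out / "ground_truth.tsv",
        }
        write_associations(self.associations, paths["associations"])
        write_reference_interactions(self.reference, paths["reference"])
        write_annotations(self.go_annotations, paths["go"])
        write_annotations(self.disease_annotations, paths["disease"])
        write_annotations(self.chemical_annotations, paths["chemical"])
        rows = [("protein", p, m) for p, m in sorted(self.truth.protein_module.items())]
        rows += [("chemical", c, m) for c, m in sorted(self.truth.chemical_module.items())]
        rows += [("disease", d, m) for m, d in sorted(self.truth.disease_of_module.items())]
        pd.DataFrame(rows, columns=["kind", "id", "module"]).to_csv(
            paths["truth"], sep="\t", index=False
        )
        return paths


def generate_world(spec: WorldSpec, seed: int | None = None) -> World:
    """Generate one world; ``seed`` overrides ``spec.seed`` when given."""
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    M, m = spec.n_modules, spec.module_size
    n_proteins = M * m
    proteins = [f"P{i:03d}" for i in range(n_proteins)]
    protein_module = {proteins[i]: i // m for i in range(n_proteins)}
    module_proteins = {j: proteins[j * m : (j + 1) * m] for j in range(M)}

    records: list[AssociationRecord] = []
    chemical_module: dict[str, int] = {}
    for j in range(M):
        for t in range(spec.chemicals_per_module):
            chem = f"CM{j}_{t:02d}"
            chemical_module[chem] = j
            hits = [p for p in module_proteins[j] if rng.random() < spec.hit_prob]
            n_out = rng.poisson(spec.cross_module_rate * m)
            others = [p for p in proteins if protein_module[p] != j]
            if n_out > 0:
                out_hits = rng.choice(len(others), size=min(n_out, len(others)), replace=False)
                hits += [others[i] for i in sorted(out_hits)]
            for p in hits:
                rel = _RELATIONS[int(rng.integers(len(_RELATIONS)))]
                records.append(AssociationRecord(chem, p, rel, False))
    for t in range(spec.n_background_chemicals):
        chem = f"BG{t:02d}"
        hits = rng.choice(n_proteins, size=spec.background_targets, replace=False)
        for i in sorted(hits):
            rel = _RELATIONS[int(rng.integers(len(_RELATIONS)))]
            records.append(AssociationRecord(chem, proteins[i], rel, False))

    # spurious negated rows on non-target pairs; the negation filter and the
    # index construction must both keep them out of every downstream count
    true_pairs = {(r.chemical_id, r.protein_id) for r in records}
    n_neg = int(round(spec.negated_fraction * len(records)))
    all_chems = sorted({r.chemical_id for r in records})
    attempts = 0
    added = 0
    while added < n_neg and attempts < 20 * max(n_neg, 1) and all_chems:
        chem = all_chems[int(rng.integers(len(all_chems)))]
        prot = proteins[int(rng.integers(n_proteins))]
        attempts += 1
        if (chem, prot) in true_pairs:
            continue
        records.append(AssociationRecord(chem, prot, "does not affect expression", True))
        true_pairs.add((chem, prot))
        added += 1

    associations = AssociationTable(records)

    disease_of_module = {j: f"DIS{j}" for j in range(M)}
    go_term_of_module = {j: f"GO{j:04d}" for j in range(M)}
    allowed_codes = ("IDA", "IMP", "IPI", "IGI", "TAS")

    disease_entries: list[AnnotationEntry] = []
    go_entries: list[AnnotationEntry] = []
    for p in proteins:
        j = protein_module[p]
        if rng.random() < spec.annotation_coverage:
            dj = j
            if rng.random() < spec.disease_flip_prob and M > 1:
                dj = int(rng.choice([x for x in range(M) if x != j]))
            disease_entries.append(
                AnnotationEntry(
                    p,
                    disease_of_module[dj],
                    f"disease of module {dj}",
                    score=float(np.round(rng.uniform(60.0, 100.0), 2)),
                )
            )
        if rng.random() < spec.annotation_coverage:
            code = allowed_codes[int(rng.integers(len(allowed_codes)))]
            go_entries.append(
                AnnotationEntry(p, go_term_of_module[j], f"function of module {j}", evidence=code)
            )
    # noise the quality filters must remove: sub-cutoff disease scores and
    # electronically inferred GO codes on random modules
    n_noise = int(round(spec.annotation_noise_rate * n_proteins))
    for _ in range(n_noise):
        p = proteins[int(rng.integers(n_proteins))]
        dj = int(rng.integers(M))
        disease_entries.append(
            AnnotationEntry(
                p,
                disease_of_module[dj],
                f"disease of module {dj}",
                score=float(np.round(rng.uniform(0.0, 59.9), 2)),
            )
        )
        p2 = proteins[int(rng.integers(n_proteins))]
        gj = int(rng.integers(M))
        go_entries.append(
            AnnotationEntry(p2, go_term_of_module[gj], f"function of module {gj}", evidence="IEA")
        )
    disease_annotations = AnnotationTable(disease_entries, kind="disease")
    go_annotations = AnnotationTable(go_entries, kind="go")

    chemical_annotations = AnnotationTable(
        [
            AnnotationEntry(r.protein_id, r.chemical_id, r.chemical_id)
            for r in associations.records
            if not r.negated
        ],
        kind="chemical",
    )

    ppi_pairs = []
    for a, b in itertools.combinations(proteins, 2):
        same = protein_module[a] == protein_module[b]
        rate = spec.ppi_tp_rate if same else spec.ppi_fp_rate
        if rng.random() < rate:
            ppi_pairs.append((a, b))
    reference = ReferenceInteractionSet.from_pairs(ppi_pairs)

    truth = GroundTruth(
        protein_module=protein_module,
        chemical_module=chemical_module,
        disease_of_module=disease_of_module,
        go_term_of_module=go_term_of_module,
    )
    return World(
        spec=spec,
        associations=associations,
        go_annotations=go_annotations,
        disease_annotations=disease_annotations,
        chemical_annotations=chemical_annotations,
        reference=reference,
        truth=truth,
        seed=seed,
    )


def holdout_targets(
    world_or_table: World | AssociationTable,
    chemical: str,
    fraction: float,
    seed: int | None = None,
) -> tuple[AssociationTable, frozenset[tuple[str, str]]]:
    """Remove a fraction of one chemical's targets for prediction evaluation.

    Returns the reduced table and the removed (chemical, protein) pairs.  The
    chemical must have at least 3 targets and at least one must remain as
    query input.
    """
    table = (
        world_or_table.associations
        if isinstance(world_or_table, World)
        else world_or_table
    )
    targets = sorted(table.chemical_index.get(chemical, ()))
    if len(targets) < 3:
        raise ValueError(f"{chemical!r} has fewer than 3 targets; cannot hold out")
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    n_hold = int(round(fraction * len(targets)))
    if len(targets) - n_hold < 1:
        raise ValueError("holdout would leave no input target")
    if n_hold == 0:
        return table, frozenset()
    rng = np.random.default_rng(seed)
    held_idx = rng.choice(len(targets), size=n_hold, replace=False)
    held = frozenset((chemical, targets[i]) for i in sorted(held_idx))
    kept = [
        r
        for r in table.records
        if (r.chemical_id, r.protein_id) not in held
    ]
    return AssociationTable(kept), held


def generate_two_source_disease(
    n_true: int = 200,
    n_noise: int = 200,
    changepoint: float = 60.0,
    score_max: float = 100.0,
    seed: int | None = None,
) -> tuple[AnnotationTable, AnnotationTable]:
    """Two protein-disease sources with a planted score-accuracy changepoint.

    Source A is scored; its entries with score >= ``changepoint`` are genuine
    (present in the unscored source B), entries below are noise absent from
    B.  Sweeping a cutoff over A's scores, the shared-pair overlap therefore
    stays flat until the cutoff crosses the changepoint — the elbow a cutoff
    calibration should find.
    """
    rng = np.random.default_rng(seed)
    entries_a, entries_b = [], []
    for i in range(n_true):
        p, d = f"TP{i:04d}", f"D{i % 10}"
        score = float(np.round(rng.uniform(changepoint, score_max), 2))
        entries_a.append(AnnotationEntry(p, d, d, score=score))
        entries_b.append(AnnotationEntry(p, d, d))
    for i in range(n_noise):
        p, d = f"FP{i:04d}", f"D{i % 10}"
        score = float(np.round(rng.uniform(0.0, np.nextafter(changepoint, 0.0)), 2))
        entries_a.append(AnnotationEntry(p, d, d, score=score))
    return (
        AnnotationTable(entries_a, kind="disease"),
        AnnotationTable(entries_b, kind="disease"),
    )
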