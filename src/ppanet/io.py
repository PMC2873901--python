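"""Parsing, validation and normalisation of chemical-protein association data.

This module holds the three tabular inputs the pipeline consumes:

* curated chemical->protein association tables (CTD-style exports),
* reference protein-protein interaction edge lists used for calibration,
* flat annotation tables (GO terms, disease annotations with a numeric
  confidence score, or chemical target sets).

All containers are immutable after construction and deduplicate on load, so
downstream code can treat them as set-valued indices.  Negated associations
("chemical x does not affect protein z") are retained in the record list for
provenance but are *never* entered into the chemical/protein indices, which is
what every downstream computation reads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "AssociationTable",
    "ReferenceInteractionSet",
    "AnnotationEntry",
    "AnnotationTable",
    "FormatError",
    "EmptyInputError",
    "UsageError",
    "DEFAULT_EVIDENCE_CODES",
    "DEFAULT_MIN_DISEASE_SCORE",
    "read_associations",
    "write_associations",
    "filter_negations",
    "read_reference_interactions",
    "write_reference_interactions",
    "read_annotations",
    "write_annotations",
    "filter_annotations",
    "read_id_mapping",
]


class FormatError(ValueError):
    """An input file does not match the expected column layout."""


class EmptyInputError(ValueError):
    """An input file contains no usable rows."""


class UsageError(ValueError):
    """A filter or option was applied to data of the wrong kind."""


#: GO evidence codes accepted by default: experimentally supported or with a
#: traceable reference (direct assay, mutant phenotype, genetic or physical
#: interaction, traceable author statement).
DEFAULT_EVIDENCE_CODES = frozenset({"IMP", "IGI", "IPI", "IDA", "TAS"})

#: Default minimum disease-annotation confidence score (inclusive).
DEFAULT_MIN_DISEASE_SCORE = 60.0

#: Phrases that mark a free-text interaction description as negated; used only
#: when the input lacks an explicit ``negated`` column.
NEGATION_PHRASES = ("does not", "do not", "no effect of", "not result in")

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


@dataclass(frozen=True)
class AssociationRecord:
    """One curated chemical-protein association.

    ``relation`` is the free-text interaction phrase (e.g. "increases
    expression", "binds"); all non-negated relation kinds are treated
    identically downstream.
    """

    chemical_id: str
    protein_id: str
    relation: str = ""
    negated: bool = False


class AssociationTable:
    """Deduplicated chemical-protein associations with bidirectional indices.

    ``chemical_index`` maps each chemical to its protein target set P(c) and
    ``protein_index`` maps each protein to its chemical set C(p).  The two
    indices are exact transposes of each other and cover only non-negated
    records.  Duplicate (chemical, protein) pairs collapse to a single record;
    if any duplicate carries a negation flag the collapsed record is negated
    (the conservative choice for curated data with contradictory rows).
    """

    def __init__(self, records: Iterable[AssociationRecord]):
        dedup: dict[tuple[str, str], AssociationRecord] = {}
        for rec in records:
            if not rec.chemical_id or not rec.protein_id:
                raise ValueError("association record with empty chemical or protein id")
            key = (rec.chemical_id, rec.protein_id)
            prev = dedup.get(key)
            if prev is None:
                dedup[key] = rec
            elif rec.negated and not prev.negated:
                dedup[key] = replace(prev, negated=True)
        self.records: tuple[AssociationRecord, ...] = tuple(
            dedup[k] for k in sorted(dedup)
        )
        chem: dict[str, set[str]] = {}
        prot: dict[str, set[str]] = {}
        for rec in self.records:
            if rec.negated:
                continue
            chem.setdefault(rec.chemical_id, set()).add(rec.protein_id)
            prot.setdefault(rec.protein_id, set()).add(rec.chemical_id)
        self.chemical_index: dict[str, frozenset[str]] = {
            c: frozenset(v) for c, v in chem.items()
        }
        self.protein_index: dict[str, frozenset[str]] = {
            p: frozenset(v) for p, v in prot.items()
        }

    @property
    def chemicals(self) -> frozenset[str]:
        """Chemicals with at least one non-negated association."""
        return frozenset(self.chemical_index)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.protein_index)

    @property
    def n_chemicals(self) -> int:
        return len(self.chemical_index)

    def pairs(self) -> frozenset[tuple[str, str]]:
        """Active (chemical, protein) pairs, negated records excluded."""
        return frozenset(
            (r.chemical_id, r.protein_id) for r in self.records if not r.negated
        )

    def n_targets(self, chemical_id: str) -> int:
        """Number of distinct protein targets of a chemical (n_c)."""
        return len(self.chemical_index.get(chemical_id, ()))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AssociationTable):
            return NotImplemented
        return self.records == other.records

    def __hash__(self) -> int:
        return hash(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chemical_id": [r.chemical_id for r in self.records],
                "chemical_name": [r.chemical_id for r in self.records],
                "protein_id": [r.protein_id for r in self.records],
                "relation": [r.relation for r in self.records],
                "negated": [int(r.negated) for r in self.records],
            }
        )


def _parse_negated(value: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise FormatError(f"unparseable negation flag: {value!r}")


def _infer_negated(relation: str) -> bool:
    low = relation.lower()
    return any(phrase in low for phrase in NEGATION_PHRASES)


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Read an optional two-column ``source_id -> canonical_id`` mapping."""
    df = _read_tsv(path, required=("source_id", "canonical_id"))
    return dict(zip(df["source_id"], df["canonical_id"]))


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_associations(
    path: str | Path,
    id_mapping: Mapping[str, str] | None = None,
) -> AssociationTable:
    """Read a chemical-protein association TSV.

    Required columns: ``chemical_id``, ``protein_id``.  Optional columns:
    ``relation`` (free-text phrase) and ``negated`` (boolean flag).  When the
    ``negated`` column is absent, negation is inferred from a fixed phrase
    list applied to ``relation``.  Rows with empty ids are skipped with a
    logged count; an ``id_mapping`` (see :func:`read_id_mapping`) is applied
    to both id columns before deduplication.
    """
    df = _read_tsv(path, required=("chemical_id", "protein_id"))
    if df.empty:
        raise EmptyInputError(f"{path}: no association rows")
    has_neg = "negated" in df.columns
    has_rel = "relation" in df.columns
    records = []
    skipped = 0
    for row in df.itertuples(index=False):
        chem = getattr(row, "chemical_id").strip()
        prot = getattr(row, "protein_id").strip()
        if not chem or not prot:
            skipped += 1
            continue
        if id_mapping:
            chem = id_mapping.get(chem, chem)
            prot = id_mapping.get(prot, prot)
        relation = getattr(row, "relation").strip() if has_rel else ""
        if has_neg:
            negated = _parse_negated(getattr(row, "negated"))
        else:
            negated = _infer_negated(relation)
        records.append(AssociationRecord(chem, prot, relation, negated))
    if skipped:
        logger.warning("%s: skipped %d rows with empty ids", path, skipped)
    if not records:
        raise EmptyInputError(f"{path}: no parseable association rows")
    table = AssociationTable(records)
    logger.info(
        "%s: %d rows -> %d unique associations (%d chemicals, %d proteins)",
        path,
        len(df),
        len(table),
        table.n_chemicals,
        len(table.proteins),
    )
    return table


def write_associations(table: AssociationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def filter_negations(table: AssociationTable) -> AssociationTable:
    """Drop negated associations; idempotent."""
    kept = [r for r in table.records if not r.negated]
    if not kept:
        warnings.warn("all associations are negated; returning an empty table")
    return AssociationTable(kept)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) order for an unordered protein pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ReferenceInteractionSet:
    """Unordered, self-loop-free set of reference protein-protein interactions."""

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ReferenceInteractionSet":
        edges = set()
        dropped = 0
        for a, b in pairs:
            if a == b:
                dropped += 1
                continue
            edges.add(canonical_pair(a, b))
        if dropped:
            warnings.warn(f"dropped {dropped} self-interaction row(s)")
        return cls(frozenset(edges))

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for e in self.edges for p in e)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.edges


def read_reference_interactions(path: str | Path) -> ReferenceInteractionSet:
    """Read a two-column ``protein_a, protein_b`` reference interaction TSV."""
    df = _read_tsv(path, required=("protein_a", "protein_b"))
    if df.empty:
        raise EmptyInputError(f"{path}: no interaction rows")
    return ReferenceInteractionSet.from_pairs(
        zip(df["protein_a"].str.strip(), df["protein_b"].str.strip())
    )


def write_reference_interactions(ref: ReferenceInteractionSet, path: str | Path) -> None:
    rows = sorted(ref.edges)
    pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class AnnotationEntry:
    protein_id: str
    term_id: str
    term_name: str = ""
    evidence: str | None = None
    score: float | None = None


ANNOTATION_KINDS = ("go", "disease", "chemical")


class AnnotationTable:
    """Flat protein->term annotations of one kind (go, disease or chemical).

    Disease entries carry a numeric confidence score (GeneCards-AKS2 style);
    GO entries carry an evidence code; chemical entries map proteins to the
    chemicals whose target sets they belong to.  Unique on
    (protein_id, term_id); duplicates keep the first occurrence.
    """

    def __init__(self, entries: Iterable[AnnotationEntry], kind: str):
        if kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {kind!r}")
        self.kind = kind
        dedup: dict[tuple[str, str], AnnotationEntry] = {}
        for e in entries:
            if not e.protein_id or not e.term_id:
                raise ValueError("annotation entry with empty protein or term id")
            dedup.setdefault((e.protein_id, e.term_id), e)
        self.entries: tuple[AnnotationEntry, ...] = tuple(
            dedup[k] for k in sorted(dedup)
        )
        by_term: dict[str, set[str]] = {}
        by_protein: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for e in self.entries:
            by_term.setdefault(e.term_id, set()).add(e.protein_id)
            by_protein.setdefault(e.protein_id, set()).add(e.term_id)
            if e.term_name and e.term_id not in names:
                names[e.term_id] = e.term_name
        self.proteins_by_term: dict[str, frozenset[str]] = {
            t: frozenset(v) for t, v in by_term.items()
        }
        self.terms_by_protein: dict[str, frozenset[str]] = {
            p: frozenset(v) for p, v in by_protein.items()
        }
        self.term_names: dict[str, str] = names

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.terms_by_protein)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.proteins_by_term)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self.kind == other.kind and self.entries == other.entries

    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((e.protein_id, e.term_id) for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        def ev_or_score(e: AnnotationEntry) -> str:
            if e.score is not None:
                return format(e.score, "g")
            return e.evidence or ""

        return pd.DataFrame(
            {
                "protein_id": [e.protein_id for e in self.entries],
                "term_id": [e.term_id for e in self.entries],
                "term_name": [e.term_name for e in self.entries],
                "evidence_or_score": [ev_or_score(e) for e in self.entries],
            }
        )


def read_annotations(path: str | Path, kind: str) -> AnnotationTable:
    """Read an annotation TSV (``protein_id, term_id, term_name,
    evidence_or_score``); the last column is parsed as a numeric score when
    possible, otherwise as an evidence code."""
    df = _read_tsv(path, required=("protein_id", "term_id"))
    if df.empty:
        raise EmptyInputError(f"{path}: no annotation rows")
    has_name = "term_name" in df.columns
    has_ev = "evidence_or_score" in df.columns
    entries = []
    for row in df.itertuples(index=False):
        raw = getattr(row, "evidence_or_score").strip() if has_ev else ""
        evidence: str | None = None
        score: float | None = None
        if raw:
            try:
                score = float(raw)
            except ValueError:
                evidence = raw
        entries.append(
            AnnotationEntry(
                protein_id=getattr(row, "protein_id").strip(),
                term_id=getattr(row, "term_id").strip(),
                term_name=getattr(row, "term_name").strip() if has_name else "",
                evidence=evidence,
                score=score,
            )
        )
    return AnnotationTable(entries, kind=kind)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def filter_annotations(
    table: AnnotationTable,
    allowed_evidence: frozenset[str] | set[str] | None = None,
    min_score: float | None = None,
) -> AnnotationTable:
    """Apply the kind-appropriate quality filter.

    GO tables are filtered on evidence code (default: the experimentally
    supported / traceable codes in :data:`DEFAULT_EVIDENCE_CODES`); disease
    tables on a minimum confidence score (default 60, inclusive: a "minimum
    score of 60" means 60 itself passes).  Passing a score filter to a GO
    table (or vice versa) raises :class:`UsageError`.
    """
    if table.kind == "go":
        if min_score is not None:
            raise UsageError("min_score filter does not apply to GO annotations")
        allowed = frozenset(allowed_evidence) if allowed_evidence is not None else DEFAULT_EVIDENCE_CODES
        kept = [e for e in table.entries if e.evidence in allowed]
    elif table.kind == "disease":
        if allowed_evidence is not None:
            raise UsageError("evidence filter does not apply to disease annotations")
        cutoff = DEFAULT_MIN_DISEASE_SCORE if min_score is None else min_score
        kept = [e for e in table.entries if e.score is not None and e.score >= cutoff]
    else:
        if allowed_evidence is not None or min_score is not None:
            raise UsageError("no quality filter applies to chemical annotations")
        kept = list(table.entries)
    return AnnotationTable(kept, kind=table.kind)
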