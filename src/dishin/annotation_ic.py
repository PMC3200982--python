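"""Annotation corpora, descendant-propagated frequencies, information content.

The information content of a concept measures how specific it is in a given
annotation corpus: ``IC(c) = -log(freq(c) / maxFreq)``, where ``freq(c)``
counts the distinct entities annotated to ``c`` or to any of its
descendants, and ``maxFreq`` is the largest such count (the frequency of
the root when one exists).  Frequency counts distinct entities, not
annotation rows, so an entity annotated to two descendants of ``c`` still
contributes 1 to ``freq(c)``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .dag_core import OntologyDAG
from .errors import EmptyCorpusError, GafParseError

logger = logging.getLogger(__name__)

_GAF_COLUMNS = 17  # GAF 2.0/2.1/2.2


@dataclass
class AnnotationCorpus:
    """Entity → annotated concept ids, with optional evidence provenance."""

    annotations: dict[str, set[str]]
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for entity in self.annotations:
            if not entity:
                raise ValueError("empty entity id in annotation corpus")

    @property
    def entities(self) -> set[str]:
        return set(self.annotations)

    def concepts(self) -> set[str]:
        out: set[str] = set()
        for cs in self.annotations.values():
            out |= cs
        return out

    def restricted_to(self, dag: OntologyDAG) -> "AnnotationCorpus":
        """Drop annotations to concepts absent from *dag* (logged)."""
        kept: dict[str, set[str]] = {}
        dropped: set[str] = set()
        for entity, cs in self.annotations.items():
            known = {c for c in cs if c in dag}
            dropped |= cs - known
            if known:
                kept[entity] = known
        if dropped:
            logger.warning(
                "dropped annotations to %d concept id(s) absent from the "
                "ontology: %s",
                len(dropped),
                ", ".join(sorted(dropped)[:5]) + ("..." if len(dropped) > 5 else ""),
            )
        provenance = {
            (e, c): ev
            for (e, c), ev in self.provenance.items()
            if e in kept and c in kept[e]
        }
        return AnnotationCorpus(kept, provenance)


@dataclass(frozen=True)
class FrequencyTable:
    """Descendant-propagated entity counts per concept.

    ``freq`` omits zero-count concepts; :meth:`get` reads them as 0.
    """

    freq: Mapping[str, int]
    max_freq: int

    def get(self, concept_id: str) -> int:
        return self.freq.get(concept_id, 0)


@dataclass(frozen=True)
class ICTable:
    """Per-concept information content, in log units of ``log_base``.

    Concepts with zero corpus frequency carry no IC and are simply absent
    (no smoothing); downstream code treats an absent ancestor as outside the
    common-ancestor set and an absent query concept as an error.
    """

    ic: Mapping[str, float]
    log_base: float = math.e

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.ic

    def __getitem__(self, concept_id: str) -> float:
        return self.ic[concept_id]

    def get(self, concept_id: str, default: float | None = None) -> float | None:
        return self.ic.get(concept_id, default)

    def __len__(self) -> int:
        return len(self.ic)


def parse_gaf(
    source: IO[str] | Iterable[str],
    evidence_filter: set[str] | None = None,
) -> AnnotationCorpus:
    """Read a GAF 2.x annotation file.

    The entity is the DB object id (column 2), the concept the ontology term
    id (column 5).  Rows whose qualifier (column 4) contains ``NOT`` are
    excluded; *evidence_filter*, when given, keeps only the listed evidence
    codes (column 7) — by default every code, manual and electronic, is kept.
    """
    annotations: dict[str, set[str]] = {}
    provenance: dict[tuple[str, str], set[str]] = {}
    reader = csv.reader(source, delimiter="\t", quoting=csv.QUOTE_NONE)
    for lineno, row in enumerate(reader, start=1):
        if not row or (row[0].startswith("!")):
            continue
        if len(row) != _GAF_COLUMNS:
            raise GafParseError(
                f"line {lineno}: expected {_GAF_COLUMNS} tab-separated columns, "
                f"got {len(row)}"
            )
        entity, qualifier, concept, evidence = row[1], row[3], row[4], row[6]
        if "NOT" in qualifier.split("|"):
            continue
        if evidence_filter is not None and evidence not in evidence_filter:
            continue
        annotations.setdefault(entity, set()).add(concept)
        provenance.setdefault((entity, concept), set()).add(evidence)
    return AnnotationCorpus(annotations, provenance)


def propagate_frequencies(dag: OntologyDAG, corpus: AnnotationCorpus) -> FrequencyTable:
    """Count, per concept, the distinct entities annotated at or below it.

    Each entity contributes once to every ancestor of every concept it is
    annotated to (the "annotated with it or with any of its descendants"
    rule), so frequencies are monotone non-decreasing toward the roots.
    """
    usable = corpus.restricted_to(dag)
    if not usable.annotations:
        raise EmptyCorpusError(
            "annotation corpus is empty (or no concept resolves in the "
            "ontology); information content is undefined"
        )
    freq: dict[str, int] = {}
    for concepts in usable.annotations.values():
        reached: set[str] = set()
        for c in concepts:
            reached |= dag.ancestors(c)
        for a in reached:
            freq[a] = freq.get(a, 0) + 1
    return FrequencyTable(freq=freq, max_freq=max(freq.values()))


def information_content(ftab: FrequencyTable, log_base: float = math.e) -> ICTable:
    """``IC(c) = -log(freq(c) / maxFreq)`` for every concept with freq > 0."""
    if ftab.max_freq <= 0:
        raise ValueError("maxFreq must be positive")
    if log_base <= 0 or log_base == 1:
        raise ValueError("log base must be positive and != 1")
    scale = math.log(log_base)
    ic = {
        c: (-math.log(k / ftab.max_freq) / scale) + 0.0  # +0.0 avoids -0.0 roots
        for c, k in ftab.freq.items()
        if k > 0
    }
    return ICTable(ic=ic, log_base=log_base)


def write_gaf(corpus: AnnotationCorpus, stream: IO[str], db: str = "dishin") -> None:
    """Serialise a corpus as a minimal GAF 2.2 file (stable ordering)."""
    stream.write("!gaf-version: 2.2\n")
    for entity in sorted(corpus.annotations):
        for concept in sorted(corpus.annotations[entity]):
            evidence = sorted(corpus.provenance.get((entity, concept), {"IEA"}))[0]
            row = [""] * _GAF_COLUMNS
            row[0] = db
            row[1] = entity
            row[2] = entity
            row[3] = "enables"
            row[4] = concept
            row[5] = f"{db}:REF"
            row[6] = evidence
            row[8] = "F"
            row[11] = "protein"
            row[12] = "taxon:0"
            row[13] = "20110831"
            row[14] = db
            stream.write("\t".join(row) + "\n")
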