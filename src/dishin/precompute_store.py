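"""Persistent precomputed store and the SQL query plan for DiShIn.

The expensive parts of the pipeline — the transitive closure with path
counts and the corpus-derived information content — are computed once per
ontology/corpus release and persisted in an embedded SQLite database with
the two-table layout::

    IC    (concept TEXT PRIMARY KEY, value REAL)
    Paths (concept TEXT, ancestor TEXT, value INTEGER,
           PRIMARY KEY (concept, ancestor))

With indexes on ``Paths``, DiShIn for a pair is a single O(n) SQL query
(n = number of common ancestors): join the two concepts' path rows on the
shared ancestor, group by the absolute path-count difference, take the
maximum IC per group, and average.  The query touches one joined row per
common ancestor.

Auxiliary tables (``Concepts``, ``Edges``, ``Annotations``, ``metadata``)
carry the ontology structure, the annotation map and build provenance so a
store file is self-contained for every CLI operation, including GraSM
(which needs the edge structure) and entity comparison (which needs the
annotations).
"""

from __future__ import annotations

import hashlib
import sqlite3
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

from .annotation_ic import (
    AnnotationCorpus,
    ICTable,
    information_content,
    propagate_frequencies,
)
from .config import SimilarityConfig
from .dag_core import Concept, OntologyDAG, PathTable, transitive_closure_paths
from .errors import StoreError, UnknownConceptError, ZeroFrequencyError

_SCHEMA = """
CREATE TABLE IF NOT EXISTS IC (concept TEXT PRIMARY KEY, value REAL NOT NULL);
CREATE TABLE IF NOT EXISTS Paths (
    concept TEXT NOT NULL, ancestor TEXT NOT NULL, value INTEGER NOT NULL,
    PRIMARY KEY (concept, ancestor)
);
CREATE INDEX IF NOT EXISTS idx_paths_concept ON Paths (concept);
CREATE TABLE IF NOT EXISTS Concepts (
    id TEXT PRIMARY KEY, name TEXT NOT NULL, namespace TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS Edges (
    child TEXT NOT NULL, parent TEXT NOT NULL, relation TEXT NOT NULL,
    PRIMARY KEY (child, parent)
);
CREATE TABLE IF NOT EXISTS Annotations (
    entity TEXT NOT NULL, concept TEXT NOT NULL,
    PRIMARY KEY (entity, concept)
);
CREATE TABLE IF NOT EXISTS metadata (key TEXT PRIMARY KEY, value TEXT NOT NULL);
"""

#: The DiShIn query plan: one joined row per common ancestor, grouped by
#: path difference, max IC per group, averaged.
_DISHIN_QUERY = """
SELECT AVG(DCA.value) FROM (
    SELECT MAX(IC.value) AS value
    FROM IC, (
        SELECT p1.ancestor AS ancestor, ABS(p1.value - p2.value) AS value
        FROM Paths p1, Paths p2
        WHERE p1.concept = ? AND p2.concept = ?
          AND p1.ancestor = p2.ancestor
          AND p1.value > 0 AND p2.value > 0
    ) AS PD
    WHERE IC.concept = PD.ancestor
    GROUP BY PD.value
) AS DCA
"""

_PD_SUBQUERY = """
SELECT p1.ancestor AS ancestor, ABS(p1.value - p2.value) AS value
FROM Paths p1, Paths p2
WHERE p1.concept = ? AND p2.concept = ?
  AND p1.ancestor = p2.ancestor
  AND p1.value > 0 AND p2.value > 0
"""


def _dag_fingerprint(dag: OntologyDAG, corpus: AnnotationCorpus) -> str:
    h = hashlib.sha256()
    for c in sorted(dag.concepts, key=lambda c: c.id):
        h.update(f"C\t{c.id}\t{c.name}\t{c.namespace}\n".encode())
    for e in sorted(dag.edges):
        h.update(("E\t" + "\t".join(e) + "\n").encode())
    for entity in sorted(corpus.annotations):
        for concept in sorted(corpus.annotations[entity]):
            h.update(f"A\t{entity}\t{concept}\n".encode())
    return h.hexdigest()


@dataclass
class SimStore:
    """Handle on an open precomputed-store database."""

    path: str
    connection: sqlite3.Connection

    def close(self) -> None:
        self.connection.close()

    def __enter__(self) -> "SimStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def metadata(self) -> dict[str, str]:
        rows = self.connection.execute("SELECT key, value FROM metadata").fetchall()
        return dict(rows)

    # -- loading back into in-memory structures ---------------------------

    def load_ic(self) -> ICTable:
        rows = self.connection.execute("SELECT concept, value FROM IC").fetchall()
        base = float(self.metadata.get("log_base", "2.718281828459045"))
        return ICTable(ic=dict(rows), log_base=base)

    def load_paths(self) -> PathTable:
        rows = self.connection.execute(
            "SELECT concept, ancestor, value FROM Paths"
        ).fetchall()
        return PathTable({(c, a): int(v) for c, a, v in rows})

    def load_dag(self) -> OntologyDAG:
        concepts = [
            Concept(id=i, name=n, namespace=ns)
            for i, n, ns in self.connection.execute(
                "SELECT id, name, namespace FROM Concepts"
            )
        ]
        edges = list(
            self.connection.execute("SELECT child, parent, relation FROM Edges")
        )
        return OntologyDAG(concepts, edges)

    def load_annotations(self) -> AnnotationCorpus:
        annotations: dict[str, set[str]] = {}
        for entity, concept in self.connection.execute(
            "SELECT entity, concept FROM Annotations"
        ):
            annotations.setdefault(entity, set()).add(concept)
        return AnnotationCorpus(annotations)

    def export_tables(self, ic_stream, paths_stream) -> None:
        """Dump the two core tables as TSV (stable ordering)."""
        ic_stream.write("concept\tic\n")
        for concept, value in self.connection.execute(
            "SELECT concept, value FROM IC ORDER BY concept"
        ):
            ic_stream.write(f"{concept}\t{value!r}\n")
        paths_stream.write("concept\tancestor\tpaths\n")
        for concept, ancestor, value in self.connection.execute(
            "SELECT concept, ancestor, value FROM Paths ORDER BY concept, ancestor"
        ):
            paths_stream.write(f"{concept}\t{ancestor}\t{value}\n")


def open_store(path: str | Path) -> SimStore:
    path = str(path)
    if path != ":memory:" and not Path(path).exists():
        raise StoreError(f"store file {path!r} does not exist")
    return SimStore(path=path, connection=sqlite3.connect(path))


def build_store(
    dag: OntologyDAG,
    corpus: AnnotationCorpus,
    config: SimilarityConfig | None = None,
    destination: str | Path = ":memory:",
) -> SimStore:
    """Precompute path counts and IC and persist them.

    Rebuilding over an existing store with identical inputs is idempotent
    (table contents are rewritten deterministically); rebuilding over a
    store built from *different* inputs or configuration raises rather than
    silently mixing releases.
    """
    config = config or SimilarityConfig()
    destination = str(destination)
    fingerprint = _dag_fingerprint(dag, corpus)
    config_desc = f"relations={','.join(sorted(config.relations))};log_base={config.log_base!r}"
    try:
        conn = sqlite3.connect(destination)
    except sqlite3.Error as exc:
        raise StoreError(f"cannot open store destination {destination!r}: {exc}") from exc
    try:
        existing = dict(
            conn.execute("SELECT key, value FROM metadata").fetchall()
        )
    except sqlite3.Error:
        existing = {}
    if existing:
        if (
            existing.get("source_fingerprint") != fingerprint
            or existing.get("config") != config_desc
        ):
            conn.close()
            raise StoreError(
                f"store {destination!r} was built from different inputs or "
                "configuration; refusing to overwrite"
            )
    paths = transitive_closure_paths(dag)
    ic = information_content(propagate_frequencies(dag, corpus), config.log_base)
    with conn:
        conn.executescript(_SCHEMA)
        for table in ("IC", "Paths", "Concepts", "Edges", "Annotations", "metadata"):
            conn.execute(f"DELETE FROM {table}")
        conn.executemany(
            "INSERT INTO IC VALUES (?, ?)",
            sorted(ic.ic.items()),
        )
        conn.executemany(
            "INSERT INTO Paths VALUES (?, ?, ?)",
            sorted(paths.items()),
        )
        conn.executemany(
            "INSERT INTO Concepts VALUES (?, ?, ?)",
            sorted((c.id, c.name, c.namespace) for c in dag.concepts),
        )
        conn.executemany(
            "INSERT INTO Edges VALUES (?, ?, ?)",
            sorted(dag.edges),
        )
        conn.executemany(
            "INSERT INTO Annotations VALUES (?, ?)",
            sorted(
                (e, c)
                for e, cs in corpus.restricted_to(dag).annotations.items()
                for c in cs
            ),
        )
        conn.executemany(
            "INSERT INTO metadata VALUES (?, ?)",
            [
                ("source_fingerprint", fingerprint),
                ("config", config_desc),
                ("log_base", repr(config.log_base)),
                ("built_at", datetime.now(timezone.utc).isoformat()),
            ],
        )
    return SimStore(path=destination, connection=conn)


def _check_known(store: SimStore, *concepts: str) -> None:
    for c in concepts:
        row = store.connection.execute(
            "SELECT 1 FROM Paths WHERE concept = ? LIMIT 1", (c,)
        ).fetchone()
        if row is None:
            raise UnknownConceptError(f"concept {c!r} not present in store")
        ic_row = store.connection.execute(
            "SELECT 1 FROM IC WHERE concept = ?", (c,)
        ).fetchone()
        if ic_row is None:
            raise ZeroFrequencyError(
                f"concept {c!r} has no information content in store"
            )


def query_share_dishin(store: SimStore, c1: str, c2: str) -> float:
    """DiShIn shared information straight from the store, via the SQL plan."""
    _check_known(store, c1, c2)
    (value,) = store.connection.execute(_DISHIN_QUERY, (c1, c2)).fetchone()
    return 0.0 if value is None else float(value)


def query_dca_dishin(store: SimStore, c1: str, c2: str) -> tuple[str, ...]:
    """The DiShIn ancestor set from the store, with the package tie-break.

    One representative per path-difference group, highest IC first and
    lexicographically smallest id among IC ties — bit-consistent with the
    in-memory engine.
    """
    _check_known(store, c1, c2)
    query = f"""
    SELECT ancestor FROM (
        SELECT PD.ancestor AS ancestor, IC.value AS icv,
               ROW_NUMBER() OVER (
                   PARTITION BY PD.value
                   ORDER BY IC.value DESC, PD.ancestor ASC
               ) AS rank
        FROM IC, ({_PD_SUBQUERY}) AS PD
        WHERE IC.concept = PD.ancestor
    ) WHERE rank = 1 ORDER BY icv DESC, ancestor ASC
    """
    rows = store.connection.execute(query, (c1, c2)).fetchall()
    return tuple(r[0] for r in rows)


def count_common_ancestor_rows(store: SimStore, c1: str, c2: str) -> int:
    """Rows produced by the inner join — one per common ancestor.

    Exposes the linear-cost accounting of the query plan: the outer
    grouping and average only ever see this many rows.
    """
    (n,) = store.connection.execute(
        f"SELECT COUNT(*) FROM ({_PD_SUBQUERY})", (c1, c2)
    ).fetchone()
    return int(n)
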