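"""Materialized annotation tables.

For each free-text column enabled for semantic queries, a side table named
``_<Table>_<Column>`` stores, per source row: one row for every direct
concept match (Level 0) and one row for every distinct isA ancestor of
those concepts at its minimal semantic distance (Level ≥ 1).  Rows are
linked to the source table through its single-column primary key; source
tables are never modified.  Indexes on ConceptID and on the key column keep
the IN-subclause rewrite cheap.

Reference storage is a single-file SQLite database, addressed through the
DB-API connection, so any engine with a compatible DB-API adapter and ANSI
SQL subset can be substituted.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from typing import Iterable

from .annotator import Annotator, AnnotatorConfig
from .terminology import Ontology

__all__ = [
    "AnnotationTableSpec",
    "AnnotationRow",
    "annotation_table_name",
    "build_annotation_table",
    "refresh_annotations",
    "annotation_rows_for_text",
    "StoreError",
    "MissingColumnError",
    "PrimaryKeyError",
]


class StoreError(ValueError):
    """Base class for annotation-store failures."""


class MissingColumnError(StoreError):
    pass


class PrimaryKeyError(StoreError):
    """Source table lacks the single-column primary key the design requires."""


def annotation_table_name(source_table: str, source_column: str) -> str:
    return f"_{source_table}_{source_column}"


@dataclass(frozen=True)
class AnnotationTableSpec:
    """Identifies one (table, column) pair to annotate.

    ``key_column`` may be omitted; it is then discovered from the table's
    declared primary key and must be a single column either way.
    """

    source_table: str
    source_column: str
    key_column: str | None = None

    @property
    def table_name(self) -> str:
        return annotation_table_name(self.source_table, self.source_column)


@dataclass(frozen=True)
class AnnotationRow:
    record_key: object
    concept_id: str
    concept_label: str
    level: int

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("level must be >= 0")


def _table_columns(conn: sqlite3.Connection, table: str) -> list[tuple[str, int]]:
    rows = conn.execute(f'PRAGMA table_info("{table}")').fetchall()
    if not rows:
        raise MissingColumnError(f"table {table!r} does not exist")
    return [(r[1], r[5]) for r in rows]  # (name, pk position)


def _primary_key(conn: sqlite3.Connection, table: str) -> str:
    pk = [name for name, pos in _table_columns(conn, table) if pos > 0]
    if len(pk) == 0:
        raise PrimaryKeyError(
            f"table {table!r} has no declared primary key; annotation tables "
            "link rows through a single-column primary key"
        )
    if len(pk) > 1:
        raise PrimaryKeyError(
            f"table {table!r} has a composite primary key {pk}; only "
            "single-column keys are supported"
        )
    return pk[0]


def _validate(conn: sqlite3.Connection, spec: AnnotationTableSpec) -> str:
    columns = [name for name, _ in _table_columns(conn, spec.source_table)]
    if spec.source_column not in columns:
        raise MissingColumnError(
            f"column {spec.source_column!r} not found in table "
            f"{spec.source_table!r} (has: {', '.join(columns)})"
        )
    key = _primary_key(conn, spec.source_table)
    if spec.key_column is not None and spec.key_column != key:
        raise PrimaryKeyError(
            f"declared key column {spec.key_column!r} is not the primary key "
            f"({key!r}) of {spec.source_table!r}"
        )
    return key


def annotation_rows_for_text(
    record_key: object, text: str | None, annotator: Annotator
) -> list[AnnotationRow]:
    """Annotation rows for one source row: direct matches plus isA ancestors.

    Each (key, concept) pair appears once, at its minimal level across all
    direct matches of the record (direct annotation, level 0, wins).
    """
    if not text:
        return []
    levels: dict[str, int] = {}
    for match in annotator.annotate(text):
        levels[match.concept_id] = 0
    for concept_id in list(levels):
        for ancestor, level in annotator.ontology.ancestors(concept_id):
            if level < levels.get(ancestor, level + 1):
                levels[ancestor] = level
    ontology = annotator.ontology
    return [
        AnnotationRow(record_key, cid, ontology.label(cid), lvl)
        for cid, lvl in sorted(levels.items(), key=lambda t: (t[1], t[0]))
    ]


def build_annotation_table(
    conn: sqlite3.Connection,
    spec: AnnotationTableSpec,
    ontology: Ontology,
    config: AnnotatorConfig | None = None,
) -> int:
    """Create and fill ``_<Table>_<Column>``; returns rows written.

    An existing annotation table is dropped first (drop-and-rebuild is the
    refresh strategy; annotations are derived data).
    """
    key = _validate(conn, spec)
    annotator = Annotator(ontology, config)
    name = spec.table_name
    conn.execute(f'DROP TABLE IF EXISTS "{name}"')
    conn.execute(
        f'CREATE TABLE "{name}" ('
        f'"{key}" NOT NULL, '
        f'"ConceptID" TEXT NOT NULL, '
        f'"ConceptLabel" TEXT NOT NULL, '
        f'"Level" INTEGER NOT NULL)'
    )
    count = 0
    cursor = conn.execute(
        f'SELECT "{key}", "{spec.source_column}" FROM "{spec.source_table}"'
    )
    insert = (
        f'INSERT INTO "{name}" ("{key}", "ConceptID", "ConceptLabel", "Level") '
        "VALUES (?, ?, ?, ?)"
    )
    for record_key, text in cursor.fetchall():
        rows = annotation_rows_for_text(record_key, text, annotator)
        conn.executemany(
            insert,
            [(r.record_key, r.concept_id, r.concept_label, r.level) for r in rows],
        )
        count += len(rows)
    conn.execute(f'CREATE INDEX "idx{name}_concept" ON "{name}" ("ConceptID")')
    conn.execute(f'CREATE INDEX "idx{name}_key" ON "{name}" ("{key}")')
    conn.commit()
    return count


def refresh_annotations(
    conn: sqlite3.Connection,
    spec: AnnotationTableSpec,
    ontology: Ontology,
    config: AnnotatorConfig | None = None,
) -> int:
    """Drop-and-rebuild; the result is identical to a fresh build."""
    return build_annotation_table(conn, spec, ontology, config)


def annotation_key_column(conn: sqlite3.Connection, table_name: str) -> str:
    """First column of an annotation table = the source table's key column."""
    return _table_columns(conn, table_name)[0][0]
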