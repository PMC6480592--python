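"""O-SQL: semantic expressions embedded in SQL, rewritten to standard SQL.

An O-SQL expression has the shape::

    [prefix][relation][{modifier}][:depth][[query]](table.column, ...)

e.g. ``[chd](diagnosis_column)``, ``+partOf[Prandin](tableMed.Drug)`` or
``hasContext{indication}:5[diabetes](Drug)``.  The free-text ``query`` is
mapped to ontology concepts by the annotator; the relation expands that
concept set (part-of closure, depth-limited context-attribute inheritance);
and the expression is replaced in place by an ``IN`` clause over the
record keys found in the pre-built annotation table of each target column.
Because annotation tables materialize all isA ancestors, a plain membership
lookup on a concept realizes subsumption: records annotated with any
descendant match too.  All bytes outside expression spans are preserved, so
NOT/AND/OR and parentheses behave exactly as in standard SQL.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass, field
from typing import Sequence

from .annotation_store import annotation_key_column, annotation_table_name
from .annotator import AnnotatorConfig, annotate
from .terminology import Ontology

__all__ = [
    "OSQLExpression",
    "ExpressionReport",
    "RewriteResult",
    "extract_expressions",
    "parse_expression",
    "resolve_concept_set",
    "build_subclause",
    "rewrite",
    "execute",
    "OsqlError",
    "OsqlSyntaxError",
    "UnresolvableQueryError",
    "MissingAnnotationTableError",
    "AmbiguousTargetError",
    "OsqlExecutionError",
]

# Relation keywords; "context" and "hasContext" are synonyms.
RELATIONS = {"isa": "isA", "partof": "partOf", "context": "context", "hascontext": "hasContext"}
CONTEXT_RELATIONS = frozenset({"context", "hasContext"})

# Keys enumerated literally in the IN list up to this count; beyond it a
# temporary key table is joined instead.
DEFAULT_IN_LIST_CAP = 10_000


class OsqlError(ValueError):
    """Base class for O-SQL processing errors."""


class OsqlSyntaxError(OsqlError):
    def __init__(self, message: str, position: int | None = None):
        self.position = position
        where = f" at position {position}" if position is not None else ""
        super().__init__(f"{message}{where}")


class UnresolvableQueryError(OsqlError):
    """The free-text query mapped to no terminology concept."""

    def __init__(self, query_text: str):
        self.query_text = query_text
        super().__init__(
            f"query text {query_text!r} could not be resolved to any concept"
        )


class MissingAnnotationTableError(OsqlError):
    def __init__(self, table_name: str):
        self.table_name = table_name
        super().__init__(
            f"annotation table {table_name!r} does not exist; build it first"
        )


class AmbiguousTargetError(OsqlError):
    pass


class OsqlExecutionError(OsqlError):
    """SQL engine error; carries the rewritten query for debugging."""

    def __init__(self, message: str, standard_sql: str):
        self.standard_sql = standard_sql
        super().__init__(f"{message}\nrewritten query: {standard_sql}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OSQLExpression:
    """Parsed semantic expression."""

    query_text: str
    targets: tuple[tuple[str | None, str], ...]
    relation: str = "isA"
    prefix: bool = False
    modifier: str | None = None
    depth: int | None = None
    raw: str = ""


@dataclass
class ExpressionReport:
    """Concept feedback for one expression (which concepts were actually used)."""

    expression: str
    relation: str
    modifier: str | None
    depth: int | None
    query_concepts: list[tuple[str, str]]
    expanded_size: int
    matched_keys: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "expression": self.expression,
            "relation": self.relation,
            "modifier": self.modifier,
            "depth": self.depth,
            "query_concepts": [
                {"id": cid, "label": label} for cid, label in self.query_concepts
            ],
            "expanded_size": self.expanded_size,
            "matched_keys": dict(self.matched_keys),
            "notes": list(self.notes),
        }


@dataclass
class RewriteResult:
    standard_sql: str
    reports: list[ExpressionReport]


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

_EXPR_RE = re.compile(
    r"""
    (?:(?P<prefix>\+)\s*)?
    (?:(?P<relation>[A-Za-z_]\w*)\s*)?
    (?:\{(?P<modifier>[^{}]*)\}\s*)?
    (?::(?P<depth>\d+)\s*)?
    \[(?P<query>[^\][]*)\]\s*
    \((?P<targets>[^()]*)\)
    """,
    re.VERBOSE,
)


def _literal_mask(sql: str) -> list[bool]:
    """True at positions inside single-quoted SQL string literals."""
    mask = [False] * len(sql)
    i = 0
    while i < len(sql):
        if sql[i] == "'":
            j = i + 1
            while j < len(sql):
                if sql[j] == "'":
                    if j + 1 < len(sql) and sql[j + 1] == "'":  # '' escape
                        j += 2
                        continue
                    break
                j += 1
            for k in range(i, min(j + 1, len(sql))):
                mask[k] = True
            i = j + 1
        else:
            i += 1
    return mask


def extract_expressions(sql: str) -> list[tuple[tuple[int, int], str]]:
    """Locate every O-SQL expression with its exact character span.

    Text inside single-quoted string literals is never matched.  Stray
    square brackets outside any well-formed expression raise
    :class:`OsqlSyntaxError` with their position.
    """
    mask = _literal_mask(sql)
    found: list[tuple[tuple[int, int], str]] = []
    covered = [False] * len(sql)
    pos = 0
    while True:
        m = _EXPR_RE.search(sql, pos)
        if m is None:
            break
        if any(mask[m.start() : m.end()]):
            pos = m.start() + 1
            continue
        start = m.start()
        relation = m.group("relation")
        if relation is not None and relation.lower() not in RELATIONS:
            if m.group("prefix") or m.group("modifier") is not None:
                raise OsqlSyntaxError(
                    f"unknown relation keyword {relation!r}", m.start()
                )
            # a preceding SQL word (e.g. WHERE, NOT) is not part of the
            # expression; the expression starts at its :depth or [query]
            if m.group("depth") is not None:
                start = m.start("depth") - 1  # include the ':'
            else:
                start = m.start("query") - 1
        found.append(((start, m.end()), sql[start : m.end()]))
        for k in range(start, m.end()):
            covered[k] = True
        pos = m.end()
    for i, ch in enumerate(sql):
        if ch in "[]" and not mask[i] and not covered[i]:
            raise OsqlSyntaxError(f"unbalanced bracket {ch!r}", i)
    return found


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_expression(raw: str) -> OSQLExpression:
    """Parse one raw expression (as produced by :func:`extract_expressions`)."""
    m = _EXPR_RE.fullmatch(raw.strip())
    if m is None:
        raise OsqlSyntaxError(f"not a valid O-SQL expression: {raw!r}")
    relation_word = m.group("relation")
    if relation_word is None:
        relation = "isA"  # "The default value for the relation is isA"
    else:
        try:
            relation = RELATIONS[relation_word.lower()]
        except KeyError:
            raise OsqlSyntaxError(f"unknown relation keyword {relation_word!r}") from None
    modifier = m.group("modifier")
    if modifier is not None:
        modifier = " ".join(modifier.split())
        if not modifier:
            raise OsqlSyntaxError("empty context modifier")
    if modifier is not None and relation not in CONTEXT_RELATIONS:
        raise OsqlSyntaxError(
            f"modifier {modifier!r} is only allowed with a context relation"
        )
    if relation in CONTEXT_RELATIONS and modifier is None:
        raise OsqlSyntaxError("context relation requires a {modifier}")
    depth = None
    if m.group("depth") is not None:
        depth = int(m.group("depth"))
        if depth < 1:
            raise OsqlSyntaxError("depth must be a positive integer")
    query_text = m.group("query").strip()
    if not query_text:
        raise OsqlSyntaxError("empty query text")
    targets: list[tuple[str | None, str]] = []
    for part in m.group("targets").split(","):
        part = part.strip()
        if not part:
            continue
        if "." in part:
            table, _, column = part.rpartition(".")
            targets.append((table.strip(), column.strip()))
        else:
            targets.append((None, part))
    if not targets:
        raise OsqlSyntaxError("expression names no target column")
    return OSQLExpression(
        query_text=query_text,
        targets=tuple(targets),
        relation=relation,
        prefix=m.group("prefix") is not None,
        modifier=modifier,
        depth=depth,
        raw=raw,
    )


# ---------------------------------------------------------------------------
# Concept resolution
# ---------------------------------------------------------------------------

def resolve_concept_set(
    expr: OSQLExpression,
    ontology: Ontology,
    config: AnnotatorConfig | None = None,
) -> set[str]:
    """Map the free-text query to concepts and apply the relation.

    * ``isA``: the annotated concepts themselves — membership lookups in
      the annotation tables realize subsumption, since ancestors are
      materialized there.
    * ``partOf``: union of part-of closures; ``+`` adds the query concepts.
    * context relations: context targets of the query concepts' descendants
      within ``depth`` generations (default 1 = no inheritance); ``+`` adds
      the query concepts.

    Raises :class:`UnresolvableQueryError` when the query text maps to no
    concept — a silent empty result would hide terminology gaps.
    """
    query_concepts = {m.concept_id for m in annotate(expr.query_text, ontology, config)}
    if not query_concepts:
        raise UnresolvableQueryError(expr.query_text)
    if expr.relation == "isA":
        return set(query_concepts)
    if expr.relation == "partOf":
        result: set[str] = set()
        for cid in query_concepts:
            result |= ontology.part_of_closure(cid)
    else:  # context relation
        depth = expr.depth if expr.depth is not None else 1
        result = set()
        for cid in query_concepts:
            result |= ontology.context_targets(
                ontology.descendants(cid, depth), expr.modifier or ""
            )
    if expr.prefix:
        result |= query_concepts
    return result


def query_concepts(
    expr: OSQLExpression, ontology: Ontology, config: AnnotatorConfig | None = None
) -> list[tuple[str, str]]:
    """(id, label) pairs the free-text query resolved to, for the report."""
    ids = sorted({m.concept_id for m in annotate(expr.query_text, ontology, config)})
    return [(cid, ontology.label(cid)) for cid in ids]


# ---------------------------------------------------------------------------
# Subclause construction
# ---------------------------------------------------------------------------

def _sql_literal(value: object) -> str:
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, (int, float)):
        return repr(value)
    text = str(value).replace("'", "''")
    return f"'{text}'"


_temp_counter = 0


def build_subclause(
    conn: sqlite3.Connection,
    expr: OSQLExpression,
    concept_set: set[str],
    resolved_targets: Sequence[tuple[str, str, bool]] | None = None,
    max_level: int | None = None,
    in_list_cap: int = DEFAULT_IN_LIST_CAP,
) -> tuple[str, dict[str, int]]:
    """Build the boolean IN clause replacing one expression.

    ``resolved_targets`` is a sequence of (table, column, qualify); when
    omitted every expression target must carry an explicit table name.
    Each target contributes ``<key> IN (k1, ...)`` over the record keys
    whose annotation rows hit ``concept_set`` (optionally restricted to
    ``Level <= max_level``); multiple targets are OR-joined in parentheses.
    An empty key set yields ``<key> IN (NULL)``, which matches no row.
    Beyond ``in_list_cap`` keys, a temporary key table is joined instead of
    enumerating literals.
    """
    global _temp_counter
    if resolved_targets is None:
        resolved_targets = []
        for table, column in expr.targets:
            if table is None:
                raise AmbiguousTargetError(
                    f"target column {column!r} has no table; qualify it or "
                    "pass resolved targets"
                )
            resolved_targets.append((table, column, True))
    parts: list[str] = []
    counts: dict[str, int] = {}
    for table, column, qualify in resolved_targets:
        ann = annotation_table_name(table, column)
        exists = conn.execute(
            "SELECT 1 FROM sqlite_master WHERE type='table' AND name=?", (ann,)
        ).fetchone()
        if exists is None:
            raise MissingAnnotationTableError(ann)
        key_col = annotation_key_column(conn, ann)
        concepts = sorted(concept_set)
        if concepts:
            placeholders = ", ".join("?" for _ in concepts)
            sql = (
                f'SELECT DISTINCT "{key_col}" FROM "{ann}" '
                f'WHERE "ConceptID" IN ({placeholders})'
            )
            params: list[object] = list(concepts)
            if max_level is not None:
                sql += ' AND "Level" <= ?'
                params.append(max_level)
            keys = sorted(row[0] for row in conn.execute(sql, params))
        else:
            keys = []
        counts[f"{table}.{column}"] = len(keys)
        ref = f"{table}.{key_col}" if qualify else key_col
        if not keys:
            parts.append(f"{ref} IN (NULL)")
        elif len(keys) > in_list_cap:
            _temp_counter += 1
            tmp = f"_osql_keys_{_temp_counter}"
            conn.execute(f'CREATE TEMP TABLE "{tmp}" (k)')
            conn.executemany(
                f'INSERT INTO "{tmp}" (k) VALUES (?)', [(k,) for k in keys]
            )
            parts.append(f'{ref} IN (SELECT k FROM "{tmp}")')
        else:
            parts.append(f"{ref} IN ({', '.join(_sql_literal(k) for k in keys)})")
    if len(parts) == 1:
        return parts[0], counts
    return "(" + " OR ".join(parts) + ")", counts


# ---------------------------------------------------------------------------
# Rewrite and execute
# ---------------------------------------------------------------------------

_FROM_RE = re.compile(
    r"\bFROM\s+(?P<tables>.*?)(?:\bWHERE\b|\bGROUP\s+BY\b|\bORDER\s+BY\b"
    r"|\bLIMIT\b|\bHAVING\b|;|$)",
    re.IGNORECASE | re.DOTALL,
)


def _from_tables(sql: str) -> list[str]:
    m = _FROM_RE.search(sql)
    if m is None:
        return []
    chunk = re.split(r"\bJOIN\b", m.group("tables"), flags=re.IGNORECASE)
    names = []
    for piece in chunk:
        for part in piece.split(","):
            tokens = part.replace(" ON ", " on ").split(" on ")[0].split()
            if tokens:
                names.append(tokens[0].strip('"'))
    return names


def _resolve_targets(
    expr: OSQLExpression, sql: str
) -> list[tuple[str, str, bool]]:
    resolved: list[tuple[str, str, bool]] = []
    from_tables: list[str] | None = None
    for table, column in expr.targets:
        if table is not None:
            resolved.append((table, column, True))
            continue
        if from_tables is None:
            from_tables = _from_tables(sql)
        if len(from_tables) != 1:
            raise AmbiguousTargetError(
                f"target column {column!r} names no table and the query's "
                f"FROM clause lists {len(from_tables or [])} tables"
            )
        resolved.append((from_tables[0], column, False))
    return resolved


def rewrite(
    sql: str,
    conn: sqlite3.Connection,
    ontology: Ontology,
    config: AnnotatorConfig | None = None,
    in_list_cap: int = DEFAULT_IN_LIST_CAP,
) -> RewriteResult:
    """Replace every O-SQL expression by its IN subclause.

    Every byte outside expression spans is preserved, so surrounding SQL —
    including NOT, AND, OR and parentheses — functions unchanged.  Each
    expression is converted independently.
    """
    spans = extract_expressions(sql)
    out: list[str] = []
    reports: list[ExpressionReport] = []
    cursor = 0
    for (start, end), raw in spans:
        try:
            expr = parse_expression(raw)
        except OsqlSyntaxError as exc:
            if exc.position is None:
                raise OsqlSyntaxError(str(exc), start) from exc
            raise
        concepts = resolve_concept_set(expr, ontology, config)
        max_level = None
        notes: list[str] = []
        if expr.relation == "isA" and expr.depth is not None:
            # depth with plain isA restricts how many subsumption
            # generations below the query concept may match
            max_level = expr.depth - 1
            notes.append(
                f"depth {expr.depth} on isA: restricted to annotation rows "
                f"with Level <= {max_level}"
            )
        clause, counts = build_subclause(
            conn,
            expr,
            concepts,
            _resolve_targets(expr, sql),
            max_level=max_level,
            in_list_cap=in_list_cap,
        )
        reports.append(
            ExpressionReport(
                expression=raw,
                relation=expr.relation,
                modifier=expr.modifier,
                depth=expr.depth,
                query_concepts=query_concepts(expr, ontology, config),
                expanded_size=len(concepts),
                matched_keys=counts,
                notes=notes,
            )
        )
        out.append(sql[cursor:start])
        out.append(clause)
        cursor = end
    out.append(sql[cursor:])
    return RewriteResult(standard_sql="".join(out), reports=reports)


def execute(
    sql: str,
    conn: sqlite3.Connection,
    ontology: Ontology,
    config: AnnotatorConfig | None = None,
) -> tuple[list[tuple], RewriteResult]:
    """Rewrite, run on the SQL engine, and return (rows, rewrite result)."""
    result = rewrite(sql, conn, ontology, config)
    try:
        rows = conn.execute(result.standard_sql).fetchall()
    except sqlite3.Error as exc:
        raise OsqlExecutionError(str(exc), result.standard_sql) from exc
    return rows, result
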