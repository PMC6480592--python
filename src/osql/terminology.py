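"""In-process terminology service.

Holds a medical ontology — concepts with labels, synonyms and abbreviations,
connected by ``isA`` (taxonomy), ``partOf`` (mereology) and labeled *context*
edges (e.g. ``Ibuprofen —indication→ Pain``) — and answers the traversal
queries the rest of the system needs: taxonomy (ancestors with semantic
distance), depth-limited subsumption (descendants), part-of closure, context
targets, and lexical label resolution.

Two input formats are supported: a reference JSON-lines dialect (one concept
or edge object per line, documented in the package README) and a subset of
OBO 1.4 read through :mod:`obonet` (``is_a`` → ``isA``, ``relationship:
part_of`` → ``partOf``).
"""

from __future__ import annotations

import json
import re
import unicodedata
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import networkx as nx
import obonet

__all__ = [
    "Concept",
    "SemanticEdge",
    "Ontology",
    "load_ontology",
    "load_obo",
    "save_ontology",
    "fold_text",
    "label_key",
    "tokenize_words",
    "OntologyError",
    "OntologyParseError",
    "CycleError",
    "DanglingEdgeError",
    "UnknownConceptError",
]

ISA = "isA"
PARTOF = "partOf"
CONTEXT = "context"
EDGE_KINDS = frozenset({ISA, PARTOF, CONTEXT})


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class OntologyError(ValueError):
    """Base class for ontology validation and lookup errors."""


class OntologyParseError(OntologyError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


class CycleError(OntologyError):
    """The isA subgraph contains a cycle (taxonomies must be DAGs)."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("isA cycle detected: " + " -> ".join(cycle + cycle[:1]))


class DanglingEdgeError(OntologyError):
    def __init__(self, concept_id: str):
        self.concept_id = concept_id
        super().__init__(f"edge references unknown concept {concept_id!r}")


class UnknownConceptError(OntologyError, KeyError):
    def __init__(self, concept_id: str):
        self.concept_id = concept_id
        super().__init__(f"unknown concept {concept_id!r}")


# ---------------------------------------------------------------------------
# Text normalization shared with the annotator
# ---------------------------------------------------------------------------

_UMLAUTS = str.maketrans({"ä": "ae", "ö": "oe", "ü": "ue", "ß": "ss"})

# A word, or an abbreviation-shaped token with interior periods ("schw.brtg").
WORD_RE = re.compile(r"\w+(?:\.\w+)+|\w+", re.UNICODE)


def fold_text(text: str) -> str:
    """Lowercase with German umlaut expansion and diacritic stripping."""
    text = text.lower().translate(_UMLAUTS)
    text = unicodedata.normalize("NFD", text)
    return "".join(c for c in text if not unicodedata.combining(c))


def tokenize_words(text: str) -> list[str]:
    """Folded word tokens; interior periods survive in abbreviation tokens."""
    return [fold_text(m.group()) for m in WORD_RE.finditer(text)]


def label_key(text: str) -> str:
    """Canonical lexical key for a label: folded words joined by one space."""
    return " ".join(tokenize_words(text))


def _collapse_ws(text: str) -> str:
    return " ".join(text.split())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Concept:
    """One terminology entry.

    ``concept_id`` is an opaque non-empty identifier (e.g. ``"D0009F4"``);
    ``preferred_label`` the display name; synonyms and abbreviations are
    alternative surface forms resolved by the lexical index.
    """

    concept_id: str
    preferred_label: str
    synonyms: tuple[str, ...] = ()
    abbreviations: tuple[str, ...] = ()
    language: str = "en"

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise OntologyError("concept_id must be non-empty")
        if not self.preferred_label.strip():
            raise OntologyError(f"concept {self.concept_id}: empty preferred label")
        if any(not s.strip() for s in self.synonyms):
            raise OntologyError(f"concept {self.concept_id}: empty synonym")
        object.__setattr__(self, "synonyms", tuple(self.synonyms))
        object.__setattr__(self, "abbreviations", tuple(self.abbreviations))


@dataclass(frozen=True)
class SemanticEdge:
    """Typed edge: source isA/partOf target, or source —context_label→ target."""

    source_id: str
    target_id: str
    kind: str
    context_label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise OntologyError(f"unknown edge kind {self.kind!r}")
        if self.kind == CONTEXT and not (self.context_label or "").strip():
            raise OntologyError("context edge requires a context_label")
        if self.kind != CONTEXT and self.context_label is not None:
            raise OntologyError(f"{self.kind} edge must not carry a context_label")


class Ontology:
    """Concept set plus typed edges, with traversal and lexical indexes.

    The isA subset must be a DAG (checked at construction); partOf and
    context graphs may contain cycles, closures terminate via visited sets.
    """

    def __init__(self, concepts: Iterable[Concept], edges: Iterable[SemanticEdge]):
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.concept_id in self.concepts:
                raise OntologyError(f"duplicate concept id {c.concept_id!r}")
            self.concepts[c.concept_id] = c
        self.edges: list[SemanticEdge] = list(edges)
        for e in self.edges:
            for endpoint in (e.source_id, e.target_id):
                if endpoint not in self.concepts:
                    raise DanglingEdgeError(endpoint)

        self._isa = nx.DiGraph()
        self._isa.add_nodes_from(self.concepts)
        self._partof = nx.DiGraph()
        self._partof.add_nodes_from(self.concepts)
        # context edges indexed by folded, whitespace-collapsed label
        self._context: dict[str, dict[str, set[str]]] = {}
        for e in self.edges:
            if e.kind == ISA:
                self._isa.add_edge(e.source_id, e.target_id)
            elif e.kind == PARTOF:
                self._partof.add_edge(e.source_id, e.target_id)
            else:
                key = _collapse_ws(fold_text(e.context_label or ""))
                by_src = self._context.setdefault(key, {})
                by_src.setdefault(e.source_id, set()).add(e.target_id)

        try:
            cycle = nx.find_cycle(self._isa)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise CycleError([u for u, _ in cycle])

        self._label_index: dict[str, set[str]] = {}
        for c in self.concepts.values():
            for surface in (c.preferred_label, *c.synonyms, *c.abbreviations):
                key = label_key(surface)
                if key:
                    self._label_index.setdefault(key, set()).add(c.concept_id)

    # -- basic access ------------------------------------------------------

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def get(self, concept_id: str) -> Concept:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise UnknownConceptError(concept_id) from None

    def label(self, concept_id: str) -> str:
        return self.get(concept_id).preferred_label

    def _check(self, concept_id: str) -> None:
        if concept_id not in self.concepts:
            raise UnknownConceptError(concept_id)

    # -- traversals --------------------------------------------------------

    def ancestors(self, concept_id: str) -> list[tuple[str, int]]:
        """All isA ancestors with their semantic distance.

        The distance (level) is the minimal number of isA edges on any path
        from the queried concept; the concept itself is excluded.  Order is
        deterministic: level ascending, then concept id.
        """
        self._check(concept_id)
        lengths = nx.single_source_shortest_path_length(self._isa, concept_id)
        out = [(cid, lvl) for cid, lvl in lengths.items() if lvl > 0]
        out.sort(key=lambda t: (t[1], t[0]))
        return out

    def descendants(self, concept_id: str, max_generations: int | None = None) -> set[str]:
        """Concepts subsumed by ``concept_id`` within a generation budget.

        Generation 1 is the concept itself; ``max_generations=d`` inspects
        d generations, i.e. descendants within d−1 isA edges.  ``None``
        means unbounded.
        """
        self._check(concept_id)
        if max_generations is not None and max_generations < 1:
            raise OntologyError("max_generations must be >= 1")
        budget = None if max_generations is None else max_generations - 1
        seen = {concept_id}
        frontier = deque([(concept_id, 0)])
        while frontier:
            node, dist = frontier.popleft()
            if budget is not None and dist >= budget:
                continue
            for child in self._isa.predecessors(node):
                if child not in seen:
                    seen.add(child)
                    frontier.append((child, dist + 1))
        return seen

    def part_of_closure(self, concept_id: str) -> set[str]:
        """All concepts that are transitively part of ``concept_id``."""
        self._check(concept_id)
        seen: set[str] = set()
        frontier = deque([concept_id])
        while frontier:
            node = frontier.popleft()
            for part in self._partof.predecessors(node):
                if part not in seen:
                    seen.add(part)
                    frontier.append(part)
        seen.discard(concept_id)
        return seen

    def context_targets(self, source_ids: Iterable[str], context_label: str) -> set[str]:
        """Union of targets of context edges labeled ``context_label``.

        Label matching is case-insensitive with whitespace collapsed.
        """
        sources = list(source_ids)
        for cid in sources:
            self._check(cid)
        by_src = self._context.get(_collapse_ws(fold_text(context_label)), {})
        out: set[str] = set()
        for cid in sources:
            out |= by_src.get(cid, set())
        return out

    def resolve_label(self, text: str) -> set[str]:
        """Concept ids whose label, synonym or abbreviation normalizes to ``text``."""
        return set(self._label_index.get(label_key(text), ()))


# ---------------------------------------------------------------------------
# Loading / saving
# ---------------------------------------------------------------------------

Source = Union[str, Path, IO[str]]


def _open_lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def load_ontology(source: Source) -> Ontology:
    """Load the reference JSON-lines dialect.

    Each non-blank line is one JSON object: a concept
    ``{"id", "label", "synonyms", "abbreviations"}`` or an edge
    ``{"source", "kind", "target"}`` with ``"context_label"`` required when
    ``kind == "context"``.  A path ending in ``.obo`` is delegated to
    :func:`load_obo`.
    """
    if isinstance(source, (str, Path)) and str(source).endswith(".obo"):
        return load_obo(source)
    concepts: list[Concept] = []
    edges: list[SemanticEdge] = []
    for lineno, line in enumerate(_open_lines(source), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise OntologyParseError(f"invalid JSON: {exc.msg}", lineno) from exc
        if not isinstance(obj, dict):
            raise OntologyParseError("expected a JSON object", lineno)
        try:
            if "id" in obj:
                concepts.append(
                    Concept(
                        concept_id=str(obj["id"]),
                        preferred_label=str(obj["label"]),
                        synonyms=tuple(obj.get("synonyms", ())),
                        abbreviations=tuple(obj.get("abbreviations", ())),
                        language=str(obj.get("language", "en")),
                    )
                )
            elif "source" in obj:
                edges.append(
                    SemanticEdge(
                        source_id=str(obj["source"]),
                        target_id=str(obj["target"]),
                        kind=str(obj["kind"]),
                        context_label=obj.get("context_label"),
                    )
                )
            else:
                raise OntologyParseError(
                    'object is neither a concept ("id") nor an edge ("source")', lineno
                )
        except KeyError as exc:
            raise OntologyParseError(f"missing field {exc.args[0]!r}", lineno) from exc
        except OntologyError as exc:
            if isinstance(exc, OntologyParseError):
                raise
            raise OntologyParseError(str(exc), lineno) from exc
    return Ontology(concepts, edges)


_OBO_SYN_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def load_obo(source: Source) -> Ontology:
    """Read an OBO 1.4 subset: [Term] id/name/synonym/is_a/relationship part_of."""
    graph = obonet.read_obo(source, ignore_obsolete=True)
    concepts: list[Concept] = []
    edges: list[SemanticEdge] = []
    for node, data in graph.nodes(data=True):
        synonyms = []
        for raw in data.get("synonym", ()):
            m = _OBO_SYN_RE.match(raw)
            if m:
                synonyms.append(m.group(1).replace('\\"', '"'))
        concepts.append(
            Concept(
                concept_id=node,
                preferred_label=data.get("name", node),
                synonyms=tuple(synonyms),
            )
        )
    for u, v, key in graph.edges(keys=True):
        if key == "is_a":
            edges.append(SemanticEdge(u, v, ISA))
        elif key == "part_of":
            edges.append(SemanticEdge(u, v, PARTOF))
    return Ontology(concepts, edges)


def save_ontology(ontology: Ontology, path: str | Path) -> None:
    """Write an :class:`Ontology` back out in the reference JSON-lines dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in sorted(ontology.concepts.values(), key=lambda c: c.concept_id):
            obj: dict = {"id": c.concept_id, "label": c.preferred_label}
            if c.synonyms:
                obj["synonyms"] = list(c.synonyms)
            if c.abbreviations:
                obj["abbreviations"] = list(c.abbreviations)
            if c.language != "en":
                obj["language"] = c.language
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
        for e in ontology.edges:
            obj = {"source": e.source_id, "kind": e.kind, "target": e.target_id}
            if e.context_label is not None:
                obj["context_label"] = e.context_label
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
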