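"""Free-text to concept annotation.

Maps short clinical narratives onto ontology concepts through a lightweight,
fully deterministic pipeline: tokenization with umlaut/diacritic folding,
abbreviation expansion from a discipline dictionary, edit-distance spell
correction against the ontology lexicon, compound-word splitting (German
noun compounds such as "Schwangerenberatung"), and a greedy left-to-right
longest-match phrase mapper with a fixed disambiguation order (longer span,
then higher score, then smaller concept id).  Stop-words may be skipped
inside multi-word matches but never produce concepts themselves.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import edlib

from .terminology import WORD_RE, Ontology, fold_text, tokenize_words

__all__ = [
    "TokenSpan",
    "ConceptMatch",
    "AnnotatorConfig",
    "Annotator",
    "normalize",
    "expand_abbreviations",
    "correct_spelling",
    "split_compound",
    "annotate",
    "load_abbreviations",
    "edit_distance",
    "default_edit_threshold",
]

# Match-kind scores; ``exact`` is the only kind with score 1.
KIND_SCORES = {
    "exact": 1.0,
    "synonym": 0.9,
    "abbreviation": 0.85,
    "compound-split": 0.75,
    "spell-corrected": 0.7,
}
_KIND_RANK = {k: i for i, k in enumerate(KIND_SCORES)}  # lower = stronger

DEFAULT_STOPWORDS = frozenset(
    "a an and for in of on or the to with without "
    "der die das und mit ohne fuer bei seit".split()
)

# Plural/inflection suffixes stripped when proposing lexical variants.
DEFAULT_SUFFIX_RULES = ("s", "es", "en", "e")


def default_edit_threshold(token_length: int) -> int:
    """Length-dependent edit-distance budget: 0 (≤4), 1 (5–8), 2 (≥9)."""
    if token_length <= 4:
        return 0
    if token_length <= 8:
        return 1
    return 2


@dataclass(frozen=True)
class TokenSpan:
    """A normalized token with offsets into the *original* text."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")


@dataclass(frozen=True)
class ConceptMatch:
    """One annotator hit: concept, the token spans it covers, kind, score."""

    concept_id: str
    spans: tuple[TokenSpan, ...]
    match_kind: str
    score: float

    def __post_init__(self) -> None:
        if not self.spans:
            raise ValueError("a match covers at least one span")
        if self.match_kind not in KIND_SCORES:
            raise ValueError(f"unknown match kind {self.match_kind!r}")

    @property
    def start(self) -> int:
        return self.spans[0].start

    @property
    def end(self) -> int:
        return self.spans[-1].end


@dataclass
class AnnotatorConfig:
    """Tunable pipeline settings.

    ``abbreviations`` maps a folded short form to one or more expansions;
    ``max_edit_distance`` maps token length to an edit budget;
    ``min_subword_length`` is the shortest compound part considered.
    """

    abbreviations: dict[str, tuple[str, ...]] = field(default_factory=dict)
    max_edit_distance: Callable[[int], int] = default_edit_threshold
    min_subword_length: int = 4
    max_compound_parts: int = 3
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    suffix_rules: tuple[str, ...] = DEFAULT_SUFFIX_RULES
    language: str = "en"

    def __post_init__(self) -> None:
        folded = {}
        for abbr, exps in self.abbreviations.items():
            if isinstance(exps, str):
                exps = (exps,)
            if not exps:
                raise ValueError(f"abbreviation {abbr!r} has no expansion")
            folded[fold_text(abbr)] = tuple(exps)
        self.abbreviations = folded


def load_abbreviations(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Two-column TSV (abbreviation, expansion); repeated keys accumulate."""
    out: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"abbreviation row needs two columns: {row!r}")
            out.setdefault(fold_text(row[0].strip()), []).append(row[1].strip())
    return {k: tuple(v) for k, v in out.items()}


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Levenshtein distance; −1 when a bound ``k`` is given and exceeded."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def normalize(text: str) -> list[TokenSpan]:
    """Tokenize with case/diacritic folding; offsets reference ``text``.

    Punctuation is split off except for periods interior to
    abbreviation-shaped tokens ("Schw.brtg" stays one token).
    """
    return [
        TokenSpan(fold_text(m.group()), m.start(), m.end())
        for m in WORD_RE.finditer(text)
    ]


def expand_abbreviations(
    tokens: Sequence[TokenSpan] | Sequence[str], config: AnnotatorConfig
) -> list[list[str]]:
    """Per-token alternatives: the token itself plus dictionary expansions."""
    out = []
    for tok in tokens:
        text = tok.text if isinstance(tok, TokenSpan) else fold_text(tok)
        alts = [text]
        for exp in config.abbreviations.get(text, ()):
            folded = " ".join(tokenize_words(exp))
            if folded and folded not in alts:
                alts.append(folded)
        out.append(alts)
    return out


def correct_spelling(
    token: str,
    lexicon: Mapping[str, int] | Iterable[str],
    config: AnnotatorConfig | None = None,
) -> list[tuple[str, int]]:
    """Lexicon words within the edit budget, ranked by
    (distance, descending frequency, lexicographic)."""
    config = config or AnnotatorConfig()
    freq = lexicon if isinstance(lexicon, Mapping) else {w: 1 for w in lexicon}
    k = config.max_edit_distance(len(token))
    hits = []
    for word, count in freq.items():
        d = edit_distance(token, word, k=k)
        if d >= 0:
            hits.append((word, d, count))
    hits.sort(key=lambda t: (t[1], -t[2], t[0]))
    return [(w, d) for w, d, _ in hits]


def split_compound(
    token: str,
    lexicon: Mapping[str, int] | Iterable[str],
    config: AnnotatorConfig | None = None,
) -> list[list[str]]:
    """Segmentations of a concatenated compound into ≥2 lexicon words.

    Parts must reach the configured minimum length; a part may also be an
    edit-distance-tolerant variant of a lexicon word.  Results are ordered
    by fewest parts, then total edit distance.  A token that is itself a
    lexicon word is not split (whole-word match wins).
    """
    config = config or AnnotatorConfig()
    words = set(lexicon)
    if token in words:
        return []
    min_len = config.min_subword_length
    results: list[tuple[int, int, list[str]]] = []

    def best_fuzzy(piece: str) -> tuple[str, int] | None:
        ranked = correct_spelling(piece, words, config)
        return ranked[0] if ranked else None

    def rec(pos: int, parts: list[str], cost: int) -> None:
        if len(parts) >= config.max_compound_parts and pos < len(token):
            return
        if pos == len(token):
            if len(parts) >= 2:
                results.append((len(parts), cost, list(parts)))
            return
        for end in range(pos + min_len, len(token) + 1):
            piece = token[pos:end]
            if piece in words:
                rec(end, parts + [piece], cost)
            else:
                hit = best_fuzzy(piece)
                if hit is not None and hit[1] > 0:
                    rec(end, parts + [hit[0]], cost + hit[1])

    rec(0, [], 0)
    results.sort(key=lambda t: (t[0], t[1], t[2]))
    seen: set[tuple[str, ...]] = set()
    out = []
    for _, _, parts in results:
        key = tuple(parts)
        if key not in seen:
            seen.add(key)
            out.append(parts)
    return out


# ---------------------------------------------------------------------------
# Phrase mapping
# ---------------------------------------------------------------------------

class Annotator:
    """Reusable annotation engine for one (ontology, config) pair.

    Builds the phrase index (label word-tuples → concepts) and the word
    lexicon once; :meth:`annotate` is then cheap per narrative.
    """

    def __init__(self, ontology: Ontology, config: AnnotatorConfig | None = None):
        self.ontology = ontology
        self.config = config or AnnotatorConfig()
        # phrase entries: word tuple -> list of (concept_id, base_kind)
        self.phrases: dict[tuple[str, ...], list[tuple[str, str]]] = {}
        self.lexicon: Counter[str] = Counter()
        for c in ontology.concepts.values():
            surfaces = [(c.preferred_label, "exact")]
            surfaces += [(s, "synonym") for s in c.synonyms]
            surfaces += [(a, "abbreviation") for a in c.abbreviations]
            for surface, kind in surfaces:
                words = tuple(tokenize_words(surface))
                if not words:
                    continue
                self.phrases.setdefault(words, []).append((c.concept_id, kind))
                if kind != "abbreviation":
                    self.lexicon.update(words)
        self._max_phrase_words = max((len(w) for w in self.phrases), default=0)

    # -- token alternatives ----------------------------------------------

    def _alternatives(self, token: str) -> list[tuple[tuple[str, ...], str, int]]:
        """Candidate word sequences one token can stand for.

        Returns (words, provenance kind, edit cost), strongest first.
        """
        alts: list[tuple[tuple[str, ...], str, int]] = [((token,), "exact", 0)]
        for suffix in self.config.suffix_rules:
            stem = token[: -len(suffix)] if token.endswith(suffix) else None
            if stem and len(stem) >= 3 and stem in self.lexicon:
                alts.append(((stem,), "exact", 0))
        for exp in self.config.abbreviations.get(token, ()):
            words = tuple(tokenize_words(exp))
            if words:
                alts.append((words, "abbreviation", 0))
        if token not in self.lexicon:
            for word, dist in correct_spelling(token, self.lexicon, self.config)[:3]:
                if dist > 0:
                    alts.append(((word,), "spell-corrected", dist))
            for parts in split_compound(token, self.lexicon, self.config)[:2]:
                alts.append((tuple(parts), "compound-split", 0))
        return alts

    # -- matching ---------------------------------------------------------

    def _try_phrase(
        self,
        words: tuple[str, ...],
        start: int,
        tokens: Sequence[TokenSpan],
        alternatives: Sequence[Sequence[tuple[tuple[str, ...], str, int]]],
    ) -> tuple[int, list[int], str] | None:
        """Match a label word-tuple starting at token ``start``.

        Returns (next token index, consumed token indexes, worst piece kind)
        or ``None``.  Interior stop-word tokens may be skipped.
        """
        j, k = start, 0
        used: list[int] = []
        worst = "exact"
        while k < len(words):
            if j >= len(tokens):
                return None
            hit = None
            for ws, kind, _cost in alternatives[j]:
                if len(ws) <= len(words) - k and tuple(words[k : k + len(ws)]) == ws:
                    hit = (ws, kind)
                    break
            if hit is not None:
                used.append(j)
                k += len(hit[0])
                if _KIND_RANK[hit[1]] > _KIND_RANK[worst]:
                    worst = hit[1]
                j += 1
            elif used and tokens[j].text in self.config.stopwords:
                j += 1  # skip interior stop-word
            else:
                return None
        return j, used, worst

    def annotate(self, text: str) -> list[ConceptMatch]:
        """Greedy left-to-right longest-match annotation of ``text``."""
        tokens = normalize(text)
        if not tokens or not self.phrases:
            return []
        alternatives = [self._alternatives(t.text) for t in tokens]
        matches: list[ConceptMatch] = []
        i = 0
        while i < len(tokens):
            if tokens[i].text in self.config.stopwords:
                i += 1
                continue
            best: tuple[tuple[int, float, str], int, ConceptMatch] | None = None
            for words, entries in self.phrases.items():
                res = self._try_phrase(words, i, tokens, alternatives)
                if res is None:
                    continue
                nxt, used, piece_kind = res
                for concept_id, base_kind in entries:
                    kind = max(base_kind, piece_kind, key=lambda k: _KIND_RANK[k])
                    score = KIND_SCORES[kind]
                    # disambiguation: longer span, higher score, smaller id
                    rank = (len(used), score, _neg_lex(concept_id))
                    if best is None or rank > best[0]:
                        match = ConceptMatch(
                            concept_id=concept_id,
                            spans=tuple(tokens[u] for u in used),
                            match_kind=kind,
                            score=score,
                        )
                        best = (rank, nxt, match)
            if best is None:
                i += 1
            else:
                matches.append(best[2])
                i = best[1]
        return matches


class _neg_lex(str):
    """Inverts lexicographic order so that *smaller* ids rank higher."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def annotate(
    text: str, ontology: Ontology, config: AnnotatorConfig | None = None
) -> list[ConceptMatch]:
    """Convenience wrapper; caches one :class:`Annotator` per ontology+config."""
    config = config or AnnotatorConfig()
    cache = getattr(ontology, "_annotator_cache", None)
    if cache is None or cache[0] is not config:
        cache = (config, Annotator(ontology, config))
        ontology._annotator_cache = cache  # type: ignore[attr-defined]
    return cache[1].annotate(text)
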