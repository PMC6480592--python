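# Methods

## Problem and approach

Clinical databases routinely keep their most informative content —
diagnoses, course-of-disease narratives, postmortem descriptions — as free
text. `osql` makes such columns queryable *semantically* from plain SQL, in
two steps:

1. **Annotation.** Every enabled free-text column gets a side table,
   `_<Table>_<Column>`, holding one row per recognized ontology concept per
   source row (`Level = 0`), plus one row for every distinct isA ancestor of
   those concepts at its minimal taxonomic distance (`Level ≥ 1`). Rows are
   linked through the source table's single-column primary key. Source
   tables are never modified.
2. **Query rewriting.** An O-SQL expression
   `[prefix][relation][{modifier}][:depth][[query]](table.column, …)`
   embedded in otherwise ordinary SQL is resolved against the ontology and
   replaced, in place, by an `IN` clause enumerating the matching record
   keys from the annotation table. Everything outside expression spans is
   byte-preserved, so `NOT`, `AND`, `OR` and parentheses keep their standard
   SQL semantics.

Because ancestors are materialized, subsumption needs no recursion at query
time: looking up the concept *cephalea* matches any record directly
annotated with a descendant such as *Bing-Horton syndrome*, via the stored
ancestor row. This is the core trade: annotation-time graph closure buys
query-time `IN`-list membership, which relational engines index well.

## Relation semantics

Let Q be the concept set the annotator extracts from the free-text query.

* `isA` (default): the rewritten clause looks up Q itself; descendants
  match through materialized ancestors. A `:d` depth on `isA` is accepted
  and restricts matches to annotation rows with `Level ≤ d − 1`, i.e. to at
  most d subsumption generations (the query concept counts as generation 1);
  the rewrite report flags this interpretation.
* `partOf`: the union of transitive part-of closures of Q (parts of a drug
  product include its agents). The `+` prefix adds Q itself.
* `context{m}` / `hasContext{m}` (synonyms): context edges are generically
  labeled (e.g. `indication`, `side effect`), so one syntax covers
  arbitrary ontology-specific relations. Targets are collected from all isA
  descendants of Q within `:d` generations — context attributes are
  inherited down the taxonomy *opt-in*, with default depth 1 (no
  inheritance). `+` again adds Q.

Depth convention throughout: depth d inspects d generations with the query
concept as generation 1; an indication attached to a direct child is found
from depth 2 upward.

A query text that maps to no concept raises an error rather than returning
an empty result: silent misses (an unknown abbreviation, say) are the
failure mode the per-expression concept-feedback report exists to prevent.
The report lists, per expression, the resolved query concepts with labels,
the expanded concept-set size, and per-target matched-key counts.

## Annotator

The annotator is a deterministic approximation of a full NLP terminology
service, sufficient for short narrative fragments:

* **Normalization** — lowercase, German umlaut expansion (ä→ae, ö→oe,
  ü→ue, ß→ss), canonical (NFD) diacritic stripping; punctuation split off
  except periods interior to abbreviation-shaped tokens (`Schw.brtg`).
  Offsets always reference the original text.
* **Abbreviation expansion** — a two-column TSV dictionary, several
  expansions per short form allowed; ontology-level abbreviations resolve
  through the label index as well.
* **Spell correction** — Levenshtein candidates from the ontology word
  lexicon within a length-dependent budget: 0 edits for tokens ≤ 4
  characters, 1 for 5–8, 2 for ≥ 9 (short clinical tokens are too easy to
  "correct" into the wrong concept). Ranking: distance, then lexicon
  frequency, then lexicographic.
* **Compound splitting** — segmentation of concatenated noun compounds
  into ≥ 2 lexicon words (minimum part length 4, at most 3 parts), exact
  parts preferred, edit-tolerant parts allowed; ordered by fewest parts,
  then total edit distance. A token that is itself a lexicon word is never
  split.
* **Mapping** — greedy left-to-right longest match of label word-tuples
  over per-token alternatives; ties broken by higher score, then smaller
  concept id. Interior stop-words are skippable inside multi-word matches
  but never emit concepts. Plural/inflection suffixes (`-s`, `-es`, `-en`,
  `-e`) are stripped as lexical variants when the stem is a lexicon word.
  Match kinds carry fixed scores (exact 1.0 — and only exact is 1.0 —
  synonym 0.9, abbreviation 0.85, compound-split 0.75, spell-corrected
  0.7); a match's kind is the weakest evidence it used.

Greedy longest-match with a fixed tie-break was chosen over statistical
disambiguation deliberately: it is reproducible, testable, and handles the
worked examples; its residual ambiguity cost is visible in (and bounded by)
the synthetic-corpus sensitivity measurements. Negation detection, document
sectioning and full German morphology are out of scope.

## Storage and rewriting details

* Reference storage is SQLite through the DB-API connection; all emitted
  SQL is plain ANSI (quoted identifiers, literal `IN` lists), so another
  engine's DB-API adapter can be substituted.
* Annotation tables are indexed on `ConceptID` and on the key column, and
  are dropped and rebuilt on refresh — annotations are derived data, and
  rebuild equals fresh build by construction.
* Shared ancestors of several direct matches of one record are stored once
  at the global minimal level; membership queries only need existence.
  Only isA ancestors are materialized (partOf closures are expanded at
  query time instead).
* `IN` lists are literal key enumerations up to 10,000 keys (sorted, for
  deterministic output); beyond that a temporary key table is joined.
* An empty key set emits `<key> IN (NULL)`, which matches no rows and
  keeps `NOT` semantics correct.
* Unqualified target columns resolve against the query's FROM clause only
  when it names exactly one table; otherwise the expression is rejected as
  ambiguous.
* Composite or absent primary keys are refused with an explanation; the
  design requires single-column keys.

## Synthetic data

The generator stands in for transcribed clinical records (which are
proprietary in the motivating setting). It emulates three failure modes
observed in such text — misspellings, discipline abbreviations, and
concatenated compound nouns — under seeded, controllable rates
(`NoiseConfig`; defaults: misspelling 0.1 per label token, abbreviation
substitution 0.2 and compound concatenation 0.1 per label occurrence,
chosen as a plausibly noisy transcription regime).

* Toy ontologies: syllable-built words ≥ 6 characters, pairwise Levenshtein
  distance ≥ 3 (one typo is therefore always unambiguously attributable),
  one- or two-word labels, ~⅓ of concepts with a short abbreviation, isA
  edges forming a DAG by construction over a topological order.
* Corpora: each record embeds 1–3 concept labels in short filler words
  (all ≤ 4 characters, below the spell-correction budget, so fillers can
  never be corrected into concepts). One perturbation is drawn per label
  occurrence (abbreviation, else compound concatenation), then per-token
  misspelling with one random edit operation
  (substitute/transpose/delete/insert). Ground truth records the embedded
  concept ids, the clean text, and named binary flags (flag true iff an
  embedded concept is the flag's root or one of its isA descendants; flag
  roots default to the two concepts with the largest descendant sets).

What passing tests on this corpus show — and do not show: the pipeline
recovers exactly the planted concepts at zero noise and degrades gracefully
under the modeled noise; real clinical text adds phenomena the generator
does not model (negation, context-dependent abbreviations, inflectional
morphology beyond simple suffixes, multi-label overlap), so measured
sensitivities here bound implementation correctness, not clinical
performance.

A note on the noise model: "one edit" includes transposition, which costs 2
in plain Levenshtein; a transposed 5–8-character token exceeds its 1-edit
correction budget and is a realistic, intentional source of residual
sensitivity loss.

## Evaluation statistics

Confusion counts (record-level for flags; micro-averaged over
record × concept pairs for annotation quality) yield sensitivity,
specificity, PPV, prevalence and F-score (2·PPV·sens/(PPV+sens)), each
rate with an exact Clopper–Pearson 95% interval (`scipy.stats.binomtest`).
Exact intervals were fixed over normal approximations for reproducibility
at small counts; a zero-trial denominator reports the vacuous interval
(0, 1).

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by choice: demo fixtures
of ~20 concepts and ≤ 8-row tables for the worked examples; randomized
cross-checks on DAGs of ≤ 100 nodes; corpus checks at 200–500 records over
30–40 concepts, which is where the statistics of interest (noise
sensitivity ≥ 0.95, specificity ≥ 0.99) stabilize. All randomness flows
from explicit integer seeds (`random.Random`, `numpy.random.default_rng`);
traversal and rewrite outputs are sorted, so identical inputs give
byte-identical outputs regardless of hash ordering or edge-list order.

## Known limitations

* No nested O-SQL expressions (an expression inside another's query text).
* Post-coordination is not composed: each matched span resolves to atomic
  concepts only.
* The `+` prefix is the only implemented prefix.
* Context-relation expressions require a `{modifier}`.
* One annotation table per (table, column); cross-database attachment is
  possible by handing in a connection with an attached schema, but not
  managed by the package.
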