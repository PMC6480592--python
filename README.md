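# osql — Ontology-SQL for free-text clinical databases

Relational databases in clinical research keep much of their substance in
free-text columns — diagnoses, course-of-death narratives, epicrises — that
plain SQL cannot search by meaning. `osql` implements **Ontology-SQL
(O-SQL)**: a small semantic extension to SQL in which a free-text,
ontology-aware expression

```
[prefix][relation][{modifier}][:depth][[query]](table.column, …)
```

is embedded directly in a query, resolved against a terminology, and
rewritten to pure standard SQL. It is aimed at clinical informaticians and
researchers who already know SQL and want subsumption-aware queries over
annotated free text without an RDF stack.

The package provides:

* **terminology** — an in-process terminology service: a concept/edge
  ontology (isA taxonomy, partOf mereology, labeled *context* edges such as
  `Ibuprofen —indication→ Pain`) with a JSON-lines reference dialect and an
  OBO 1.4 subset reader; taxonomy, depth-limited subsumption, part-of
  closure, context-target and label-resolution queries.
* **annotator** — deterministic mapping of short clinical narratives to
  concepts: umlaut/diacritic folding, abbreviation expansion, edit-distance
  spell correction, compound-noun splitting, greedy longest-match phrase
  mapping.
* **annotation_store** — per-column annotation tables
  `_<Table>_<Column>(<key>, ConceptID, ConceptLabel, Level)` holding every
  direct match (Level 0) and every isA ancestor at its minimal semantic
  distance, linked by the source table's primary key.
* **osql_engine** — extraction, parsing, concept-set expansion and
  splice-back rewriting of O-SQL expressions into `IN` clauses over the
  annotation tables, plus execution with a per-expression concept report.
* **evalkit** — seeded toy ontologies and noisy synthetic corpora with
  ground truth, and confusion statistics (sensitivity, specificity, PPV,
  prevalence, F-score) with exact 95% confidence intervals.
* **cli** — `osql init-demo | annotate | rewrite | query | eval`.

Subsumption works by *materialization*: because every record's isA
ancestors are stored with their level, querying a general concept is a flat
`IN`-list membership test — `SELECT … WHERE ID IN (…)` — that any RDBMS
serves from an index, with no recursion at query time.

## Worked example

```
$ osql init-demo demo
demo/demo_ontology.jsonl
demo/abbreviations.tsv
demo/demo.db

$ osql query --db demo/demo.db --ontology demo/demo_ontology.jsonl \
      --abbrev demo/abbreviations.tsv --explain \
      'SELECT DiagnosisId, Diagnosis FROM diagnoses WHERE [cephalea](Diagnosis)'
1	cluster headache for two weeks
-- rewritten: SELECT DiagnosisId, Diagnosis FROM diagnoses WHERE DiagnosisId IN (1)
-- {"expression": "[cephalea](Diagnosis)", "relation": "isA", "modifier": null,
--  "depth": null, "query_concepts": [{"id": "D0000C9", "label": "cephalea"}],
--  "expanded_size": 1, "matched_keys": {"diagnoses.Diagnosis": 1}, "notes": []}
```

No record *says* "cephalea". Record 1 reads "cluster headache for two
weeks"; the annotator mapped "cluster headache" to the Bing-Horton-syndrome
concept, and the annotation table stores that concept's ancestors — among
them cephalea at Level 4 (a parent of the 4th degree). The rewrite
therefore finds the record by a plain key lookup, and the `--explain`
report shows which terminology concept the free-text query actually used.

Context attributes are inherited down the taxonomy only when a depth is
given. Indications are attached to Ibuprofen (a direct child of
Analgesic), so a depth-2 query finds the records annotated with Pain or
Fever, while depth 1 finds none:

```
$ osql rewrite --db demo/demo.db --ontology demo/demo_ontology.jsonl \
      'SELECT CID FROM tableMed WHERE hasContext{indication}:2[Analgesic](Drug)'
SELECT CID FROM tableMed WHERE CID IN (6, 7)
```

The same machinery runs from Python:

```python
import sqlite3
from osql import generate_demo_ontology, build_demo_database, execute
from osql.evalkit import demo_annotator_config

ontology, config = generate_demo_ontology(), demo_annotator_config()
conn = sqlite3.connect(":memory:")
build_demo_database(conn, ontology, config)
rows, report = execute(
    "select tableMed.CID from tableMed, tableDiag where "
    "tableMed.CID = tableDiag.CID and "
    "+partOf[Prandin](tableMed.Drug) and "
    "hasContext{side effect} [repaglinide](tableDiag.Diag)",
    conn, ontology, config)
print(rows)   # [(1,), (2,)]
```

Row 2's diagnosis reads "hyperinsulinism": it is returned because
hyperinsulinism *is a* form of hypoglycemia, the recorded side effect of
repaglinide — subsumption again, through the stored ancestor rows.

## Synthetic evaluation

`osql eval --n 500 --seed 42 --json` generates a toy ontology and a noisy
corpus (misspellings, abbreviation substitutions, concatenated compounds)
with ground truth, annotates it, runs flag queries end to end, and reports
sensitivity/specificity/PPV/F with exact binomial confidence intervals.
See `docs/methods.md` for the noise model and its limits.

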