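"""O-SQL engine: extraction, parsing, resolution, rewrite and execution."""

import random
import sqlite3

import pytest

from osql.annotation_store import AnnotationTableSpec, build_annotation_table
from osql.annotator import Annotator
from osql.evalkit import NoiseConfig, generate_corpus, generate_eval_ontology
from osql.osql_engine import (
    AmbiguousTargetError,
    MissingAnnotationTableError,
    OsqlSyntaxError,
    UnresolvableQueryError,
    build_subclause,
    execute,
    extract_expressions,
    parse_expression,
    resolve_concept_set,
    rewrite,
)

PRANDIN_SQL = (
    "select * from tableMed, tableDiag where "
    "tableMed.CID = tableDiag.CID and "
    "+partOf[Prandin](tableMed.Drug) and "
    "hasContext{side effect} [repaglinide](tableDiag.Diag)"
)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

class TestExtract:
    def test_simple_expression_with_exact_span(self):
        sql = "SELECT * FROM t WHERE [chd](diag)"
        [(span, raw)] = extract_expressions(sql)
        assert raw == "[chd](diag)"
        assert sql[span[0] : span[1]] == raw

    def test_string_literals_shield_expressions(self):
        assert extract_expressions("SELECT * FROM t WHERE note = '[chd](diag)'") == []

    def test_prandin_query_contains_two_expressions(self):
        raws = [raw for _, raw in extract_expressions(PRANDIN_SQL)]
        assert raws == [
            "+partOf[Prandin](tableMed.Drug)",
            "hasContext{side effect} [repaglinide](tableDiag.Diag)",
        ]

    def test_unbalanced_bracket_is_a_syntax_error_with_position(self):
        with pytest.raises(OsqlSyntaxError) as exc:
            extract_expressions("SELECT * FROM t WHERE [chd(diag)")
        assert exc.value.position == 22

    def test_plain_sql_has_no_expressions(self):
        assert extract_expressions("SELECT count(*) FROM t WHERE a = 'b'") == []

    def test_unknown_relation_with_modifier_is_rejected(self):
        with pytest.raises(OsqlSyntaxError, match="frobnicate"):
            extract_expressions("SELECT * FROM t WHERE frobnicate{x}[q](c)")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestParse:
    def test_full_context_expression(self):
        e = parse_expression("hasContext{indication}:5[diabetes](Drug)")
        assert (e.relation, e.modifier, e.depth) == ("hasContext", "indication", 5)
        assert e.query_text == "diabetes"
        assert e.targets == ((None, "Drug"),)
        assert not e.prefix

    def test_simplest_expression_defaults_to_isa(self):
        e = parse_expression("[free-text](tablename.columnname)")
        assert e.relation == "isA"
        assert not e.prefix and e.modifier is None and e.depth is None
        assert e.targets == (("tablename", "columnname"),)

    def test_prefix_and_partof(self):
        e = parse_expression("+partOf[Prandin](tableMed.Drug)")
        assert e.prefix and e.relation == "partOf"

    def test_comma_separated_targets_are_split_and_trimmed(self):
        e = parse_expression("[q]( t1.c1 , c2 )")
        assert e.targets == (("t1", "c1"), (None, "c2"))

    @pytest.mark.parametrize(
        "raw,message",
        [
            ("[  ](t.c)", "empty query"),
            (":0[q](t.c)", "positive"),
            ("isA{mod}[q](t.c)", "context relation"),
            ("[q]()", "no target"),
            ("hasContext[q](t.c)", "requires"),
            ("bogus{m}[q](t.c)", "bogus"),
        ],
    )
    def test_malformed_expressions_are_rejected(self, raw, message):
        with pytest.raises(OsqlSyntaxError, match=message):
            parse_expression(raw)


# ---------------------------------------------------------------------------
# concept resolution
# ---------------------------------------------------------------------------

class TestResolve:
    def test_isa_query_resolves_to_annotated_concepts(self, demo_ontology, demo_config):
        e = parse_expression("[chd](diag)")
        assert resolve_concept_set(e, demo_ontology, demo_config) == {"D000100"}

    def test_prefixed_partof_includes_query_concepts(self, demo_ontology, demo_config):
        e = parse_expression("+partOf[Prandin](t.Drug)")
        assert resolve_concept_set(e, demo_ontology, demo_config) == {
            "M000010",
            "M000011",
        }

    def test_context_depth_two_finds_inherited_indications(
        self, demo_ontology, demo_config
    ):
        e = parse_expression("hasContext{indication}:2[Analgesic](Drug)")
        assert resolve_concept_set(e, demo_ontology, demo_config) == {
            "S000001",
            "S000002",
        }

    def test_context_depth_defaults_to_one(self, demo_ontology, demo_config):
        e = parse_expression("hasContext{indication}[Analgesic](Drug)")
        assert resolve_concept_set(e, demo_ontology, demo_config) == set()

    def test_unresolvable_query_text_is_a_hard_error(self, demo_ontology, demo_config):
        with pytest.raises(UnresolvableQueryError, match="qwertyuiop"):
            resolve_concept_set(
                parse_expression("[qwertyuiop](t.c)"), demo_ontology, demo_config
            )


# ---------------------------------------------------------------------------
# subclause construction
# ---------------------------------------------------------------------------

class TestSubclause:
    def test_ancestor_membership_realizes_subsumption(self, demo_conn):
        e = parse_expression("[cephalea](diagnoses.Diagnosis)")
        clause, counts = build_subclause(demo_conn, e, {"D0000C9"})
        assert clause == "diagnoses.DiagnosisId IN (1)"
        assert counts == {"diagnoses.Diagnosis": 1}

    def test_empty_concept_set_matches_no_rows(self, demo_conn):
        e = parse_expression("[cephalea](diagnoses.Diagnosis)")
        clause, _ = build_subclause(demo_conn, e, set())
        assert clause == "diagnoses.DiagnosisId IN (NULL)"
        rows = demo_conn.execute(
            f"SELECT * FROM diagnoses WHERE {clause}"
        ).fetchall()
        assert rows == []

    def test_missing_annotation_table_is_named(self, demo_conn):
        e = parse_expression("[fever](diagnoses.Icd10Code)")
        with pytest.raises(MissingAnnotationTableError, match="_diagnoses_Icd10Code"):
            build_subclause(demo_conn, e, {"S000002"})

    def test_two_targets_or_joined_equal_union_oracle(self, demo_conn):
        e = parse_expression("[hypoglycemia](tableMed.Drug, tableDiag.Diag)")
        clause, _ = build_subclause(demo_conn, e, {"S000010"})
        assert clause.startswith("(") and " OR " in clause
        rows = demo_conn.execute(
            "SELECT tableMed.CID FROM tableMed JOIN tableDiag "
            f"ON tableMed.CID = tableDiag.CID WHERE {clause}"
        ).fetchall()
        # brute-force union over both columns, row by row
        annotator = Annotator(demo_conn_ontology(demo_conn))
        expected = []
        for cid, drug, diag in demo_conn.execute(
            "SELECT tableMed.CID, Drug, Diag FROM tableMed JOIN tableDiag "
            "ON tableMed.CID = tableDiag.CID"
        ):
            if _semantically_matches(annotator, drug, {"S000010"}) or (
                _semantically_matches(annotator, diag, {"S000010"})
            ):
                expected.append((cid,))
        assert sorted(rows) == sorted(expected)

    def test_large_key_sets_switch_to_temp_table_join(self, demo_conn):
        e = parse_expression("[hypoglycemia](tableDiag.Diag)")
        clause, _ = build_subclause(demo_conn, e, {"S000010"}, in_list_cap=1)
        assert "SELECT k FROM" in clause
        rows = demo_conn.execute(
            f"SELECT CID FROM tableDiag WHERE {clause} ORDER BY CID"
        ).fetchall()
        assert rows == [(1,), (2,), (4,)]


def demo_conn_ontology(conn):
    from osql.evalkit import generate_demo_ontology

    return generate_demo_ontology()


def _semantically_matches(annotator, text, concept_set, max_level=None):
    """Per-row brute-force oracle: does the text's annotation (direct
    concepts plus materialized isA ancestors) hit the concept set?"""
    levels = {}
    for m in annotator.annotate(text or ""):
        levels[m.concept_id] = 0
        for anc, lvl in annotator.ontology.ancestors(m.concept_id):
            levels[anc] = min(levels.get(anc, lvl), lvl)
    for cid, lvl in levels.items():
        if cid in concept_set and (max_level is None or lvl <= max_level):
            return True
    return False


# ---------------------------------------------------------------------------
# rewrite
# ---------------------------------------------------------------------------

class TestRewrite:
    def test_conversion_template_structure(self, demo_ontology, demo_config):
        conn = sqlite3.connect(":memory:")
        conn.execute("CREATE TABLE table_name (ID INTEGER PRIMARY KEY, note TEXT)")
        conn.executemany(
            "INSERT INTO table_name VALUES (?, ?)",
            [(1, "fever"), (2, "pain"), (3, "healthy")],
        )
        build_annotation_table(
            conn, AnnotationTableSpec("table_name", "note"), demo_ontology, demo_config
        )
        result = rewrite(
            "SELECT * FROM table_name WHERE [fever](note)",
            conn, demo_ontology, demo_config,
        )
        assert result.standard_sql == "SELECT * FROM table_name WHERE ID IN (1)"

    def test_sql_without_expressions_is_returned_unchanged(
        self, demo_conn, demo_ontology, demo_config
    ):
        sql = "SELECT * FROM diagnoses WHERE PatientId = 101"
        result = rewrite(sql, demo_conn, demo_ontology, demo_config)
        assert result.standard_sql == sql and result.reports == []

    def test_all_bytes_outside_expressions_are_preserved(
        self, demo_conn, demo_ontology, demo_config
    ):
        sql = (
            "SELECT  DiagnosisId ,PatientId FROM diagnoses  WHERE "
            "NOT ( [chd](Diagnosis) )\n\tAND PatientId > 0 -- trailing"
        )
        result = rewrite(sql, demo_conn, demo_ontology, demo_config)
        [(span, raw)] = extract_expressions(sql)
        expected_prefix = sql[: span[0]]
        expected_suffix = sql[span[1] :]
        assert result.standard_sql.startswith(expected_prefix)
        assert result.standard_sql.endswith(expected_suffix)
        assert "[" not in result.standard_sql

    def test_report_lists_concept_feedback_per_expression(
        self, demo_conn, demo_ontology, demo_config
    ):
        result = rewrite(PRANDIN_SQL, demo_conn, demo_ontology, demo_config)
        assert len(result.reports) == 2
        first = result.reports[0]
        assert first.query_concepts == [("M000010", "Prandin")]
        assert first.expanded_size == 2
        assert first.matched_keys == {"tableMed.Drug": 3}

    def test_unqualified_target_with_multi_table_from_is_ambiguous(
        self, demo_conn, demo_ontology, demo_config
    ):
        with pytest.raises(AmbiguousTargetError):
            rewrite(
                "SELECT * FROM tableMed, tableDiag WHERE [fever](Diag)",
                demo_conn, demo_ontology, demo_config,
            )


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

class TestExecute:
    def test_inherited_indication_query_finds_pain_and_fever_rows(
        self, demo_conn, demo_ontology, demo_config
    ):
        rows, result = execute(
            "SELECT CID FROM tableMed WHERE hasContext{indication}:2[Analgesic](Drug)",
            demo_conn, demo_ontology, demo_config,
        )
        assert sorted(rows) == [(6,), (7,)]
        assert result.reports[0].expanded_size == 2

    def test_count_with_never_matching_expression_is_zero(
        self, demo_conn, demo_ontology, demo_config
    ):
        rows, _ = execute(
            "SELECT COUNT(*) FROM tableMed WHERE "
            "hasContext{indication}:1[Analgesic](Drug)",
            demo_conn, demo_ontology, demo_config,
        )
        assert rows == [(0,)]

    def test_published_chd_query_returns_seeded_coronary_rows(
        self, demo_conn, demo_ontology, demo_config
    ):
        rows, _ = execute(
            "SELECT DiagnosisId FROM diagnoses WHERE [chd](Diagnosis)",
            demo_conn, demo_ontology, demo_config,
        )
        assert sorted(rows) == [(2,), (3,)]

    def test_published_prandin_query_includes_hyperinsulinism_record(
        self, demo_conn, demo_ontology, demo_config
    ):
        rows, _ = execute(
            PRANDIN_SQL.replace("select *", "select tableMed.CID"),
            demo_conn, demo_ontology, demo_config,
        )
        assert sorted(rows) == [(1,), (2,)]

    def test_published_diabetes_query_depth_five(
        self, demo_conn, demo_ontology, demo_config
    ):
        rows, _ = execute(
            "SELECT CID FROM tableMed WHERE hasContext{indication}:5[diabetes](Drug)",
            demo_conn, demo_ontology, demo_config,
        )
        assert sorted(rows) == [(2,), (4,), (5,)]

    def test_de_morgan_consistency_on_osql_atoms(
        self, demo_conn, demo_ontology, demo_config
    ):
        a = (
            "SELECT DiagnosisId FROM diagnoses WHERE "
            "NOT ([chd](Diagnosis) OR [two](Diagnosis))"
        )
        b = (
            "SELECT DiagnosisId FROM diagnoses WHERE "
            "NOT [chd](Diagnosis) AND NOT [two](Diagnosis)"
        )
        ra, _ = execute(a, demo_conn, demo_ontology, demo_config)
        rb, _ = execute(b, demo_conn, demo_ontology, demo_config)
        assert sorted(ra) == sorted(rb)

    def test_context_rows_monotone_in_depth(self, demo_conn, demo_ontology, demo_config):
        previous: set = set()
        for d in range(1, 6):
            rows, _ = execute(
                f"SELECT CID FROM tableMed WHERE "
                f"hasContext{{indication}}:{d}[Analgesic](Drug)",
                demo_conn, demo_ontology, demo_config,
            )
            current = set(rows)
            assert previous <= current
            previous = current

    def test_prefix_yields_row_superset(self, demo_conn, demo_ontology, demo_config):
        plain, _ = execute(
            "SELECT CID FROM tableMed WHERE partOf[Prandin](Drug)",
            demo_conn, demo_ontology, demo_config,
        )
        prefixed, _ = execute(
            "SELECT CID FROM tableMed WHERE +partOf[Prandin](Drug)",
            demo_conn, demo_ontology, demo_config,
        )
        assert set(plain) <= set(prefixed)


# ---------------------------------------------------------------------------
# randomized oracle equivalence
# ---------------------------------------------------------------------------

def random_queries(rng, ontology, flags, count):
    labels = [c.preferred_label for c in ontology.concepts.values()]
    queries = []
    for _ in range(count):
        label = rng.choice(labels)
        kind = rng.choice(["isa", "isa_not", "isa_depth", "pair"])
        if kind == "isa":
            where = f"[{label}](Narrative)"
        elif kind == "isa_not":
            where = f"NOT [{label}](Narrative)"
        elif kind == "isa_depth":
            where = f":{rng.randint(1, 3)}[{label}](Narrative)"
        else:
            other = rng.choice(labels)
            op = rng.choice(["AND", "OR"])
            where = f"([{label}](Narrative) {op} NOT [{other}](Narrative))"
        queries.append(f"SELECT RecordId FROM records WHERE {where}")
    return queries


def test_fifty_random_queries_match_per_row_semantic_oracle():
    rng = random.Random(1234)
    ontology, flags = generate_eval_ontology(n_concepts=30, seed=5)
    conn, _ = generate_corpus(ontology, 200, NoiseConfig(0.1, 0.2, 0.1, seed=5))
    build_annotation_table(conn, AnnotationTableSpec("records", "Narrative"), ontology)
    annotator = Annotator(ontology)
    corpus = conn.execute("SELECT RecordId, Narrative FROM records").fetchall()

    def oracle(query_label, negate=False, max_level=None):
        concepts = {m.concept_id for m in annotator.annotate(query_label)}
        keys = {
            key
            for key, text in corpus
            if _semantically_matches(annotator, text, concepts, max_level)
        }
        return {key for key, _ in corpus} - keys if negate else keys

    checked = 0
    for sql in random_queries(rng, ontology, flags, 50):
        try:
            rows, _ = execute(sql, conn, ontology)
        except UnresolvableQueryError:
            continue
        got = {r[0] for r in rows}
        # reconstruct the oracle answer from the WHERE clause we generated
        import re as _re

        atoms = _re.findall(r"(NOT )?(?::(\d+))?\[([^\]]+)\]", sql)
        sets = [
            oracle(label, negate=bool(neg), max_level=int(d) - 1 if d else None)
            for neg, d, label in atoms
        ]
        if " OR " in sql:
            expected = sets[0] | sets[1]
        elif " AND " in sql:
            expected = sets[0] & sets[1]
        else:
            expected = sets[0]
        assert got == expected, sql
        checked += 1
    assert checked >= 40
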