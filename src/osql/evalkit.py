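"""Synthetic data and evaluation statistics.

Three pieces:

* a deterministic demo ontology and database reproducing the worked
  examples used throughout the documentation and tests (the cluster-headache
  taxonomy, the Analgesic/Ibuprofen indication fragment, the
  Prandin/repaglinide/hypoglycemia fragment, the ``chd`` abbreviation, and
  an anti-diabetic indication fragment);
* a seeded generator for toy ontologies and noisy clinical-narrative
  corpora with per-record ground truth (which concepts were embedded, and
  named binary flags), emulating the failure modes of transcribed clinical
  text: misspellings, abbreviation substitution, concatenated compounds;
* confusion-matrix statistics — sensitivity, specificity, PPV, prevalence,
  F-score — with exact (Clopper–Pearson) 95% confidence intervals.
"""

from __future__ import annotations

import sqlite3
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binomtest

from .annotation_store import AnnotationTableSpec, build_annotation_table
from .annotator import Annotator, AnnotatorConfig
from .terminology import CONTEXT, ISA, PARTOF, Concept, Ontology, SemanticEdge

__all__ = [
    "NoiseConfig",
    "GroundTruthRecord",
    "EvalResult",
    "generate_demo_ontology",
    "demo_annotator_config",
    "build_demo_database",
    "generate_eval_ontology",
    "default_flags",
    "generate_corpus",
    "evaluate_flags",
    "evaluate_annotation",
]


# ---------------------------------------------------------------------------
# Demo fixtures
# ---------------------------------------------------------------------------

def generate_demo_ontology() -> Ontology:
    """Deterministic demo terminology covering the worked examples.

    Contains: "Bing-Horton syndrome" (synonym "cluster headache") with a
    four-edge isA chain up to "cephalea"; Ibuprofen isA Analgesic with
    indication edges to Pain and Fever; repaglinide partOf Prandin with a
    side-effect edge to hypoglycemia and hyperinsulinism isA hypoglycemia;
    coronary heart disease carrying the abbreviation "chd" with an isA
    descendant; and a small anti-diabetic fragment for depth-limited
    indication queries.
    """
    concepts = [
        Concept("D0009F4", "Bing-Horton syndrome", synonyms=("cluster headache",)),
        Concept("D0009A1", "trigeminal autonomic cephalalgia"),
        Concept("D0009A2", "primary headache"),
        Concept("D0009A3", "headache disorder"),
        Concept("D0000C9", "cephalea"),
        Concept("Z000002", "two"),
        Concept("GA000F8", "week", synonyms=("weeks",)),
        Concept("M000001", "Analgesic", synonyms=("analgesics",)),
        Concept("M000002", "Ibuprofen"),
        Concept("S000001", "Pain"),
        Concept("S000002", "Fever"),
        Concept("M000010", "Prandin"),
        Concept("M000011", "repaglinide"),
        Concept("S000010", "hypoglycemia"),
        Concept("S000011", "hyperinsulinism"),
        Concept("D000100", "coronary heart disease",
                synonyms=("coronary artery disease",), abbreviations=("chd",)),
        Concept("D000101", "coronary artery stenosis"),
        Concept("D000200", "diabetes mellitus", synonyms=("diabetes",)),
        Concept("D000201", "type 1 diabetes mellitus"),
        Concept("D000202", "type 2 diabetes mellitus"),
        Concept("M000020", "insulin"),
        Concept("M000021", "metformin"),
    ]
    edges = [
        SemanticEdge("D0009F4", "D0009A1", ISA),
        SemanticEdge("D0009A1", "D0009A2", ISA),
        SemanticEdge("D0009A2", "D0009A3", ISA),
        SemanticEdge("D0009A3", "D0000C9", ISA),
        SemanticEdge("M000002", "M000001", ISA),
        SemanticEdge("M000002", "S000001", CONTEXT, "indication"),
        SemanticEdge("M000002", "S000002", CONTEXT, "indication"),
        SemanticEdge("M000011", "M000010", PARTOF),
        SemanticEdge("M000011", "S000010", CONTEXT, "side effect"),
        SemanticEdge("S000011", "S000010", ISA),
        SemanticEdge("D000101", "D000100", ISA),
        SemanticEdge("D000201", "D000200", ISA),
        SemanticEdge("D000202", "D000200", ISA),
        SemanticEdge("D000200", "M000020", CONTEXT, "indication"),
        SemanticEdge("D000202", "M000021", CONTEXT, "indication"),
        SemanticEdge("D000202", "M000011", CONTEXT, "indication"),
    ]
    return Ontology(concepts, edges)


DEMO_ABBREVIATIONS = {
    "chd": ("coronary heart disease",),
    "schw.brtg": ("Schwangerenberatung",),
}


def demo_annotator_config() -> AnnotatorConfig:
    return AnnotatorConfig(abbreviations=dict(DEMO_ABBREVIATIONS))


def build_demo_database(
    conn: sqlite3.Connection,
    ontology: Ontology | None = None,
    config: AnnotatorConfig | None = None,
    build_annotations: bool = True,
) -> None:
    """Create and fill the demo tables (diagnoses, tableMed, tableDiag).

    With ``build_annotations`` (the default) the three annotation tables
    are materialized as well, so O-SQL queries run immediately.
    """
    ontology = ontology or generate_demo_ontology()
    config = config or demo_annotator_config()
    conn.executescript(
        """
        CREATE TABLE diagnoses (
            DiagnosisId INTEGER PRIMARY KEY,
            PatientId INTEGER,
            Icd10Code TEXT,
            Diagnosis TEXT
        );
        CREATE TABLE tableMed (CID INTEGER PRIMARY KEY, Drug TEXT);
        CREATE TABLE tableDiag (CID INTEGER PRIMARY KEY, Diag TEXT);
        """
    )
    conn.executemany(
        "INSERT INTO diagnoses (DiagnosisId, PatientId, Icd10Code, Diagnosis) "
        "VALUES (?, ?, ?, ?)",
        [
            (1, 101, "G44.0", "cluster headache for two weeks"),
            (2, 102, "I25.1", "coronary heart disease"),
            (3, 103, "I25.1", "coronary artery stenosis"),
            (4, 104, "R50.9", "fever and pain"),
            (5, 105, "E11.9", "type 2 diabetes mellitus"),
            (6, 106, None, ""),
        ],
    )
    conn.executemany(
        "INSERT INTO tableMed (CID, Drug) VALUES (?, ?)",
        [
            (1, "Prandin"),
            (2, "repaglinide"),
            (3, "Prandin"),
            (4, "metformin"),
            (5, "insulin"),
            (6, "Pain"),
            (7, "Fever"),
            (8, "Ibuprofen"),
        ],
    )
    conn.executemany(
        "INSERT INTO tableDiag (CID, Diag) VALUES (?, ?)",
        [
            (1, "hypoglycemia"),
            (2, "hyperinsulinism"),
            (3, "fever"),
            (4, "hypoglycemia"),
        ],
    )
    conn.commit()
    if build_annotations:
        for table, column in (
            ("diagnoses", "Diagnosis"),
            ("tableMed", "Drug"),
            ("tableDiag", "Diag"),
        ):
            build_annotation_table(
                conn, AnnotationTableSpec(table, column), ontology, config
            )


# ---------------------------------------------------------------------------
# Random toy ontologies
# ---------------------------------------------------------------------------

_SYLLABLES = (
    "ba den dor fel gra hin kel lor mun nar pel qua ros sta tur "
    "vek wil zan bro cli"
).split()

# Short filler words (≤4 chars: below the spell-correction budget, so they
# can never be "corrected" into a concept word).
_FILLERS = ("case", "of", "with", "and", "mild", "old", "on", "note", "seen", "the")


def _edit_distance(a: str, b: str, k: int) -> int:
    import edlib

    if a == b:
        return 0
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


def _fresh_word(rng: np.random.Generator, taken: list[str]) -> str:
    """A syllable word keeping Levenshtein distance ≥ 3 to all taken words."""
    while True:
        n = int(rng.integers(3, 5))
        word = "".join(rng.choice(_SYLLABLES) for _ in range(n))
        if all(_edit_distance(word, w, k=2) < 0 for w in taken):
            taken.append(word)
            return word


def generate_eval_ontology(
    n_concepts: int = 40, seed: int = 0
) -> tuple[Ontology, dict[str, str]]:
    """Seeded toy ontology with unique labels plus named flag definitions.

    Concepts get one- or two-word synthetic labels built from syllables
    (every word ≥ 6 characters and ≥ 3 edits from every other word, so a
    single typo is always unambiguously correctable); roughly a third carry
    a short abbreviation.  isA edges form a DAG by construction.  Returns
    the ontology and a mapping flag name → root concept id; a flag is true
    for a record iff it embeds the root or any isA descendant.
    """
    rng = np.random.default_rng(seed)
    taken: list[str] = []
    concepts: list[Concept] = []
    edges: list[SemanticEdge] = []
    abbrevs_taken: set[str] = set(_FILLERS)
    for i in range(n_concepts):
        two_words = rng.random() < 0.5
        words = [_fresh_word(rng, taken) for _ in range(2 if two_words else 1)]
        label = " ".join(words)
        abbreviations: tuple[str, ...] = ()
        if rng.random() < 0.35:
            abbr = "".join(w[:2] for w in words)[:4]
            if abbr not in abbrevs_taken and len(abbr) >= 2:
                abbrevs_taken.add(abbr)
                abbreviations = (abbr,)
        concepts.append(Concept(f"T{i:04d}", label, abbreviations=abbreviations))
        if i >= 3:  # first three are roots
            n_parents = int(rng.integers(1, 3))
            parents = rng.choice(i, size=min(n_parents, i), replace=False)
            for p in sorted(set(int(x) for x in parents)):
                edges.append(SemanticEdge(f"T{i:04d}", f"T{p:04d}", ISA))
    ontology = Ontology(concepts, edges)
    return ontology, default_flags(ontology)


def default_flags(ontology: Ontology, n_flags: int = 2) -> dict[str, str]:
    """Flag name → root concept id, for the roots with most descendants."""
    sized = sorted(
        ((len(ontology.descendants(cid)), cid) for cid in ontology.concepts),
        key=lambda t: (-t[0], t[1]),
    )
    return {f"flag_{cid}": cid for _, cid in sized[:n_flags]}


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Perturbation rates for the corpus generator (all in [0, 1]).

    One perturbation is chosen per embedded label occurrence: with
    ``abbreviation_rate`` the label is replaced by its abbreviation (when it
    has one), else with ``compound_rate`` two adjacent label words are
    concatenated (when the label is multi-word); independently, each
    remaining label token is misspelled (one random edit) with
    ``misspelling_rate``.
    """

    misspelling_rate: float = 0.1
    abbreviation_rate: float = 0.2
    compound_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("misspelling_rate", "abbreviation_rate", "compound_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


@dataclass(frozen=True)
class GroundTruthRecord:
    record_key: int
    text: str
    clean_text: str
    true_concept_ids: frozenset[str]
    true_flags: dict[str, bool] = field(default_factory=dict)


def _misspell(word: str, rng: np.random.Generator) -> str:
    """One random edit (substitute / transpose / delete / insert)."""
    letters = string.ascii_lowercase
    for _ in range(20):
        op = rng.choice(["substitute", "transpose", "delete", "insert"])
        i = int(rng.integers(0, len(word)))
        if op == "substitute":
            out = word[:i] + letters[int(rng.integers(0, 26))] + word[i + 1 :]
        elif op == "transpose" and len(word) >= 2:
            i = min(i, len(word) - 2)
            out = word[:i] + word[i + 1] + word[i] + word[i + 2 :]
        elif op == "delete" and len(word) >= 2:
            out = word[:i] + word[i + 1 :]
        else:
            out = word[:i] + letters[int(rng.integers(0, 26))] + word[i:]
        if out != word:
            return out
    return word


def generate_corpus(
    ontology: Ontology,
    n: int,
    noise: NoiseConfig,
    flags: Mapping[str, str] | None = None,
    conn: sqlite3.Connection | None = None,
    table: str = "records",
    column: str = "Narrative",
) -> tuple[sqlite3.Connection, list[GroundTruthRecord]]:
    """Seeded corpus of n noisy narrative records with ground truth.

    Each record embeds 1–3 concept labels in filler text, perturbed per
    ``noise``; ground truth records exactly the embedded concepts and the
    flag values (flag true iff an embedded concept is the flag root or one
    of its isA descendants).  Identical seeds yield identical corpora.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(noise.seed)
    flags = default_flags(ontology) if flags is None else dict(flags)
    flag_sets = {name: ontology.descendants(root) for name, root in flags.items()}
    concept_ids = sorted(ontology.concepts)
    if conn is None:
        conn = sqlite3.connect(":memory:")
    conn.execute(
        f'CREATE TABLE "{table}" ('
        f'"RecordId" INTEGER PRIMARY KEY, "{column}" TEXT, "TokenCount" INTEGER)'
    )
    records: list[GroundTruthRecord] = []
    for key in range(1, n + 1):
        k = int(rng.integers(1, 4))
        chosen = [concept_ids[int(i)] for i in rng.choice(len(concept_ids), size=k, replace=False)]
        clean_parts: list[str] = [str(rng.choice(_FILLERS))]
        noisy_parts: list[str] = list(clean_parts)
        for cid in chosen:
            concept = ontology.get(cid)
            words = concept.preferred_label.split()
            clean_parts.extend(words)
            r = rng.random()
            if r < noise.abbreviation_rate and concept.abbreviations:
                noisy_parts.append(concept.abbreviations[0])
            elif (
                r < noise.abbreviation_rate + noise.compound_rate and len(words) >= 2
            ):
                noisy_parts.append(words[0] + words[1])
                noisy_parts.extend(words[2:])
            else:
                for w in words:
                    if rng.random() < noise.misspelling_rate:
                        noisy_parts.append(_misspell(w, rng))
                    else:
                        noisy_parts.append(w)
            filler = str(rng.choice(_FILLERS))
            clean_parts.append(filler)
            noisy_parts.append(filler)
        clean_text = " ".join(clean_parts)
        text = " ".join(noisy_parts)
        true_flags = {
            name: any(cid in members for cid in chosen)
            for name, members in flag_sets.items()
        }
        records.append(
            GroundTruthRecord(key, text, clean_text, frozenset(chosen), true_flags)
        )
        conn.execute(
            f'INSERT INTO "{table}" ("RecordId", "{column}", "TokenCount") '
            "VALUES (?, ?, ?)",
            (key, text, len(text.split())),
        )
    conn.commit()
    return conn, records


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------

def _exact_ci(successes: int, trials: int) -> tuple[float, float]:
    if trials == 0:
        return (0.0, 1.0)
    ci = binomtest(successes, trials).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    return (float(ci.low), float(ci.high))


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts with derived rates and exact 95% CIs."""

    true_pos: int
    false_pos: int
    true_neg: int
    false_neg: int
    sensitivity: float
    specificity: float
    ppv: float
    prevalence: float
    f_score: float
    ci: dict[str, tuple[float, float]]

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "EvalResult":
        if min(tp, fp, tn, fn) < 0:
            raise ValueError("counts must be non-negative")
        total = tp + fp + tn + fn
        if total == 0:
            raise ValueError("empty evaluation: all counts are zero")
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        ppv = tp / (tp + fp) if tp + fp else float("nan")
        prev = (tp + fn) / total
        f = 2 * ppv * sens / (ppv + sens) if ppv + sens > 0 else 0.0
        ci = {
            "sensitivity": _exact_ci(tp, tp + fn),
            "specificity": _exact_ci(tn, tn + fp),
            "ppv": _exact_ci(tp, tp + fp),
            "prevalence": _exact_ci(tp + fn, total),
        }
        return cls(tp, fp, tn, fn, sens, spec, ppv, prev, f, ci)

    def to_dict(self) -> dict:
        return {
            "counts": {
                "tp": self.true_pos,
                "fp": self.false_pos,
                "tn": self.true_neg,
                "fn": self.false_neg,
            },
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "prevalence": self.prevalence,
            "f_score": self.f_score,
            "ci95": {k: list(v) for k, v in self.ci.items()},
        }


def evaluate_flags(
    predicted_keys: Iterable[int],
    truth: Sequence[GroundTruthRecord],
    flag_name: str,
) -> EvalResult:
    """Record-level confusion of a predicted key set against a truth flag."""
    if not truth:
        raise ValueError("empty truth list")
    if flag_name not in truth[0].true_flags:
        raise KeyError(f"flag {flag_name!r} not defined in ground truth")
    predicted = set(predicted_keys)
    tp = fp = tn = fn = 0
    for rec in truth:
        actual = rec.true_flags[flag_name]
        guessed = rec.record_key in predicted
        if actual and guessed:
            tp += 1
        elif actual:
            fn += 1
        elif guessed:
            fp += 1
        else:
            tn += 1
    return EvalResult.from_counts(tp, fp, tn, fn)


def evaluate_annotation(
    predicted: Mapping[int, Iterable[str]],
    truth: Sequence[GroundTruthRecord],
    concept_universe: Iterable[str],
) -> EvalResult:
    """Micro-averaged confusion over (record, concept) pairs.

    ``predicted`` maps record key → directly annotated concept ids; the
    universe is typically the ontology's full concept set.
    """
    if not truth:
        raise ValueError("empty truth list")
    universe = set(concept_universe)
    tp = fp = tn = fn = 0
    for rec in truth:
        pred = set(predicted.get(rec.record_key, ())) & universe
        true = set(rec.true_concept_ids) & universe
        tp += len(pred & true)
        fp += len(pred - true)
        fn += len(true - pred)
        tn += len(universe) - len(pred | true)
    return EvalResult.from_counts(tp, fp, tn, fn)


def annotate_corpus(
    conn: sqlite3.Connection,
    ontology: Ontology,
    config: AnnotatorConfig | None = None,
    table: str = "records",
    column: str = "Narrative",
    key: str = "RecordId",
) -> dict[int, set[str]]:
    """Direct (level-0) concept predictions per record key."""
    annotator = Annotator(ontology, config)
    out: dict[int, set[str]] = {}
    for record_key, text in conn.execute(
        f'SELECT "{key}", "{column}" FROM "{table}"'
    ):
        out[record_key] = {m.concept_id for m in annotator.annotate(text or "")}
    return out
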