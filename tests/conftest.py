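import sqlite3

import pytest

from osql.evalkit import (
    build_demo_database,
    demo_annotator_config,
    generate_demo_ontology,
)


@pytest.fixture(scope="session")
def demo_ontology():
    return generate_demo_ontology()


@pytest.fixture(scope="session")
def demo_config():
    return demo_annotator_config()


@pytest.fixture()
def demo_conn(demo_ontology, demo_config):
    """In-memory demo database with annotation tables built."""
    conn = sqlite3.connect(":memory:")
    build_demo_database(conn, demo_ontology, demo_config)
    yield conn
    conn.close()
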