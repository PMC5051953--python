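from __future__ import annotations

import random
from pathlib import Path

import pytest

import pubmedkit as pk

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def corpus200():
    """A 200-record synthetic corpus: (xml bytes, ground-truth citations)."""
    return pk.generate_corpus(200, seed=42)


@pytest.fixture(scope="session")
def store200(corpus200):
    xml, _ = corpus200
    store = pk.Store()
    store.load(pk.parse_citations(xml))
    yield store
    store.close()


@pytest.fixture(scope="session")
def index200(store200):
    return pk.build_index(store200, "full")


@pytest.fixture()
def rng():
    return random.Random(20160)


@pytest.fixture(scope="session")
def bioc_fixture_path() -> Path:
    return DATA_DIR / "bioc_synthetic_100475.xml"
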