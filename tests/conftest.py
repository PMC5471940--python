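from pathlib import Path

import numpy as np
import pytest

from actopics.corpus import Corpus, Document

REPO_ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = REPO_ROOT / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


def make_docs():
    """Two tiny documents: 5 tokens total, shared author, two journals."""
    return [
        Document(
            id="d1",
            authors=["Alice A", "Bob B"],
            journal="J One",
            year=1997,
            title="t1",
            abstract="a1",
            tokens=["apple", "berry", "apple"],
        ),
        Document(
            id="d2",
            authors=["Alice A"],
            journal="J Two",
            year=2003,
            title="t2",
            abstract="a2",
            tokens=["citrus", "berry"],
        ),
    ]


@pytest.fixture
def tiny_corpus() -> Corpus:
    return Corpus(make_docs())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
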