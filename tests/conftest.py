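import numpy as np
import pytest

from kgfuse.kg_data import KnowledgeGraph, Triple
from kgfuse.scores import ScoreTable


@pytest.fixture
def typed_kg() -> KnowledgeGraph:
    """Small hand-built KG with all four relation layers plus an off-schema node."""
    triples = {
        Triple("d1", "treats", "z1"),
        Triple("d1", "treats", "z2"),
        Triple("d2", "treats", "z2"),
        Triple("d2", "treats", "z3"),
        Triple("d3", "treats", "z1"),
        Triple("d1", "targets", "p1"),
        Triple("d2", "targets", "p2"),
        Triple("p1", "activates", "p2"),
        Triple("p2", "associated_with", "z1"),
        Triple("d3", "causes", "se1"),
    }
    types = {
        "d1": "drug", "d2": "drug", "d3": "drug",
        "p1": "protein", "p2": "protein",
        "z1": "disease", "z2": "disease", "z3": "disease",
        "se1": "side_effect",
    }
    return KnowledgeGraph(triples, types)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_table(model_id: str, scores: dict[tuple[str, str], float]) -> ScoreTable:
    pairs = list(scores)
    return ScoreTable.from_pairs(model_id, pairs, [scores[p] for p in pairs])


@pytest.fixture
def table_factory():
    return make_table
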