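import io

import numpy as np
import pytest

from comic.kg_core import Entity, KnowledgeGraph, Triple, load_kg


def make_kg(edge_rows):
    """Build a KnowledgeGraph from (head, head_type, relation, tail, tail_type)."""
    entities = {}
    triples = []
    for h, ht, r, t, tt in edge_rows:
        entities.setdefault(h, Entity(h, ht))
        entities.setdefault(t, Entity(t, tt))
        triples.append(Triple(h, r, t))
    return KnowledgeGraph(entities.values(), triples)


@pytest.fixture
def tiny_kg():
    """A 5-entity graph with one indication and a 3-hop mechanism chain."""
    return make_kg([
        ("d1", "drug", "indication", "z1", "disease"),
        ("d1", "drug", "targets", "p1", "protein"),
        ("p1", "protein", "participates", "w1", "pathway"),
        ("w1", "pathway", "associated", "z1", "disease"),
        ("d2", "drug", "drug_drug", "d1", "drug"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def kg_from_text(text):
    return load_kg(io.StringIO(text))
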