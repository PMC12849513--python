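"""Knowledge-graph data model, typed edge-list I/O, splits, and diagnostics.

The on-disk dialect is a 5-column TSV: head id, head type, relation,
tail id, tail type, with one optional ``#``-prefixed header line. Triples
are directed; duplicate rows collapse to one triple. Walk-time traversal
treats adjacency as undirected (see :mod:`comic.sampling`).
"""

from __future__ import annotations

import json
import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np

#: Relations whose edges are the prediction targets.
THERAPEUTIC_RELATIONS = frozenset({"indication", "contraindication"})

HEADER = "# head_id\thead_type\trelation\ttail_id\ttail_type"


class KGError(Exception):
    """Base error for knowledge-graph handling."""


class ParseError(KGError):
    pass


class TypeConflictError(KGError):
    pass


@dataclass(frozen=True)
class Entity:
    id: str
    type: str
    name: str | None = None


@dataclass(frozen=True, order=True)
class Triple:
    head: str
    relation: str
    tail: str

    def key(self) -> tuple[str, str, str]:
        return (self.head, self.relation, self.tail)


class KnowledgeGraph:
    """Typed entities + directed triples with adjacency and degree indexes.

    Entity and relation vocabularies are frozen at construction; looking up
    an unknown entity raises ``KeyError`` rather than cold-starting it.
    """

    def __init__(self, entities: Iterable[Entity], triples: Iterable[Triple],
                 allow_self_loops: bool = False):
        self.entities: dict[str, Entity] = {}
        for e in entities:
            if e.id in self.entities and self.entities[e.id].type != e.type:
                raise TypeConflictError(
                    f"entity {e.id!r} declared with types "
                    f"{self.entities[e.id].type!r} and {e.type!r}")
            self.entities.setdefault(e.id, e)

        seen: set[tuple[str, str, str]] = set()
        self.triples: list[Triple] = []
        for t in triples:
            if t.head not in self.entities or t.tail not in self.entities:
                raise KGError(f"triple {t} references unknown entity")
            if t.head == t.tail and not allow_self_loops:
                raise KGError(f"self-loop forbidden: {t}")
            if t.key() in seen:
                continue
            seen.add(t.key())
            self.triples.append(t)
        self._triple_set = seen

        self.relations: list[str] = sorted({t.relation for t in self.triples})
        self._relation_set = set(self.relations)

        self.out_edges: dict[str, list[Triple]] = defaultdict(list)
        self.in_edges: dict[str, list[Triple]] = defaultdict(list)
        for t in self.triples:
            self.out_edges[t.head].append(t)
            self.in_edges[t.tail].append(t)

        self.degrees: dict[str, int] = {eid: 0 for eid in self.entities}
        for t in self.triples:
            self.degrees[t.head] += 1
            self.degrees[t.tail] += 1

        self._by_type: dict[str, list[str]] = defaultdict(list)
        for eid, e in self.entities.items():
            self._by_type[e.type].append(eid)
        for ids in self._by_type.values():
            ids.sort()

    # -- queries -----------------------------------------------------------
    @property
    def type_vocabulary(self) -> set[str]:
        return set(self._by_type)

    def entities_of_type(self, etype: str) -> list[str]:
        return list(self._by_type.get(etype, []))

    def entity_type(self, eid: str) -> str:
        return self.entities[eid].type

    def has_triple(self, t: Triple) -> bool:
        return t.key() in self._triple_set

    def incident(self, eid: str) -> list[Triple]:
        """All triples touching the entity (out then in), with multiplicity."""
        if eid not in self.entities:
            raise KeyError(eid)
        return list(self.out_edges.get(eid, ())) + list(self.in_edges.get(eid, ()))

    def neighbors(self, eid: str) -> list[tuple[str, Triple, bool]]:
        """Undirected neighborhood: (other endpoint, triple, traversed_forward)."""
        out = [(t.tail, t, True) for t in self.out_edges.get(eid, ())]
        out += [(t.head, t, False) for t in self.in_edges.get(eid, ())]
        return out

    def subgraph_with_triples(self, triples: Iterable[Triple]) -> "KnowledgeGraph":
        """Same entity set, restricted triple set."""
        return KnowledgeGraph(self.entities.values(), triples)

    def __len__(self) -> int:
        return len(self.triples)


# -- I/O -------------------------------------------------------------------

def load_kg(source: str | os.PathLike | IO[str]) -> KnowledgeGraph:
    """Load a knowledge graph from the 5-column TSV dialect.

    Raises :class:`ParseError` (naming the line) on malformed rows, and
    :class:`TypeConflictError` when an entity id appears with two types.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    entities: dict[str, Entity] = {}
    triples: list[Triple] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise ParseError(f"line {lineno}: expected 5 tab-separated columns, "
                             f"got {len(cols)}")
        head_id, head_type, relation, tail_id, tail_type = (c.strip() for c in cols)
        if not all((head_id, head_type, relation, tail_id, tail_type)):
            raise ParseError(f"line {lineno}: empty field")
        for eid, etype in ((head_id, head_type), (tail_id, tail_type)):
            prev = entities.get(eid)
            if prev is not None and prev.type != etype:
                raise TypeConflictError(
                    f"line {lineno}: entity {eid!r} typed {etype!r} but "
                    f"previously {prev.type!r}")
            entities.setdefault(eid, Entity(eid, etype))
        triples.append(Triple(head_id, relation, tail_id))
    return KnowledgeGraph(entities.values(), triples)


def write_kg(kg: KnowledgeGraph, dest: str | os.PathLike | IO[str]) -> None:
    lines = [HEADER]
    for t in kg.triples:
        h, l = kg.entities[t.head], kg.entities[t.tail]
        lines.append(f"{h.id}\t{h.type}\t{t.relation}\t{l.id}\t{l.type}")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)


# -- degree / profile ------------------------------------------------------

def degree_index(kg: KnowledgeGraph) -> dict[str, int]:
    """Degree per entity: incident triples counted over both directions and
    all relation types, with multiplicity."""
    return dict(kg.degrees)


@dataclass
class ConnectionProfile:
    entity: str
    counts: dict[str, int]
    total: int
    drug_drug_fraction: float
    fractions: dict[str, float] = field(default_factory=dict)


def connection_profile(kg: KnowledgeGraph, entity: str,
                       similarity_relation: str = "drug_drug") -> ConnectionProfile:
    """Partition an entity's incident triples by relation.

    For an isolated entity the profile is empty and the similarity fraction
    is reported as 0 with total 0.
    """
    if entity not in kg.entities:
        raise KeyError(f"unknown entity {entity!r}")
    counts = Counter(t.relation for t in kg.incident(entity))
    total = sum(counts.values())
    fractions = {r: c / total for r, c in counts.items()} if total else {}
    dd = fractions.get(similarity_relation, 0.0)
    return ConnectionProfile(entity, dict(counts), total, dd, fractions)


# -- splits ----------------------------------------------------------------

@dataclass
class SplitSpec:
    train: list[Triple]
    validation: list[Triple]
    test: list[Triple]
    held_out_neighbor_edges: list[Triple]
    seed: int
    mode: str  # "disease_area" | "random"

    def partitions(self) -> dict[str, list[Triple]]:
        return {"train": self.train, "validation": self.validation,
                "test": self.test,
                "held_out_neighbor_edges": self.held_out_neighbor_edges}

    def to_dir(self, kg: KnowledgeGraph, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name, part in self.partitions().items():
            write_kg(kg.subgraph_with_triples(part),
                     os.path.join(out_dir, f"{name}.tsv"))
        manifest = {"seed": self.seed, "mode": self.mode,
                    "counts": {k: len(v) for k, v in self.partitions().items()}}
        with open(os.path.join(out_dir, "split_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def from_dir(cls, in_dir: str | os.PathLike) -> "SplitSpec":
        with open(os.path.join(in_dir, "split_manifest.json")) as fh:
            manifest = json.load(fh)
        parts = {}
        for name in ("train", "validation", "test", "held_out_neighbor_edges"):
            parts[name] = load_kg(os.path.join(in_dir, f"{name}.tsv")).triples
        return cls(parts["train"], parts["validation"], parts["test"],
                   parts["held_out_neighbor_edges"],
                   seed=manifest["seed"], mode=manifest["mode"])


def _per_relation_sample(triples: Sequence[Triple], fraction: float,
                         seed: int) -> tuple[list[Triple], list[Triple]]:
    """Sample floor(fraction * n_r) triples independently per relation type.

    Each relation partition is shuffled with a relation-index-offset seed and
    the prefix taken; a relation too small to contribute one edge contributes
    zero. Returns (sampled, rest). Fractional counts floor.
    """
    by_rel: dict[str, list[Triple]] = defaultdict(list)
    for t in triples:
        by_rel[t.relation].append(t)
    sampled: list[Triple] = []
    rest: list[Triple] = []
    for ridx, rel in enumerate(sorted(by_rel)):
        part = sorted(by_rel[rel])
        rng = np.random.default_rng(np.random.SeedSequence([seed, ridx]))
        order = rng.permutation(len(part))
        k = int(np.floor(fraction * len(part)))
        chosen = {int(i) for i in order[:k]}
        for i, t in enumerate(part):
            (sampled if i in chosen else rest).append(t)
    return sampled, rest


def disease_area_split(kg: KnowledgeGraph, area_diseases: set[str],
                       val_fraction: float = 0.125,
                       neighbor_removal_fraction: float = 0.05,
                       seed: int = 0) -> SplitSpec:
    """Hold out an entire disease area.

    test: every indication/contraindication triple touching an area disease.
    held_out_neighbor_edges: a globally sampled fraction of the remaining
    non-therapeutic triples incident to area diseases, removed from train.
    validation: ``val_fraction`` of what remains, sampled independently per
    relation type (floor). train: the rest.
    """
    if not area_diseases:
        raise ValueError("area_diseases must be nonempty")
    unknown = area_diseases - set(kg.entities)
    if unknown:
        raise KeyError(f"unknown area diseases: {sorted(unknown)[:5]}")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")

    test, remaining = [], []
    for t in kg.triples:
        therapeutic = t.relation in THERAPEUTIC_RELATIONS
        touches = t.head in area_diseases or t.tail in area_diseases
        (test if therapeutic and touches else remaining).append(t)

    neighbor_pool = [t for t in remaining
                     if t.head in area_diseases or t.tail in area_diseases]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    n_remove = int(np.floor(neighbor_removal_fraction * len(neighbor_pool)))
    order = rng.permutation(len(neighbor_pool))
    held = {neighbor_pool[int(i)].key() for i in order[:n_remove]}
    held_out = [t for t in remaining if t.key() in held]
    remaining = [t for t in remaining if t.key() not in held]

    validation, train = _per_relation_sample(remaining, val_fraction, seed)
    return SplitSpec(train, validation, test, held_out, seed=seed,
                     mode="disease_area")


def random_split(kg: KnowledgeGraph, seed: int = 0,
                 test_fraction: float = 0.05,
                 val_fraction: float = 0.125) -> SplitSpec:
    """Random split: ``test_fraction`` of therapeutic edges form the test
    set; ``val_fraction`` of all remaining edges (per relation type, floor)
    form validation; the rest train."""
    if not kg.triples:
        raise ValueError("graph is empty")
    therapeutic = [t for t in kg.triples if t.relation in THERAPEUTIC_RELATIONS]
    other = [t for t in kg.triples if t.relation not in THERAPEUTIC_RELATIONS]
    test, rest_therapeutic = _per_relation_sample(therapeutic, test_fraction,
                                                  seed ^ 0x5F5E1)
    remaining = rest_therapeutic + other
    validation, train = _per_relation_sample(remaining, val_fraction, seed)
    return SplitSpec(train, validation, test, [], seed=seed, mode="random")
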