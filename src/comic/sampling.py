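"""Negative triple generation and random-walk path sampling.

Walks traverse edges in both directions; a triple traversed head<-tail is
stored re-oriented with ``forward=False``. Paths are simple (no node
revisits) and capped at 5 relations, and a candidate is kept only when its
shared-edge fraction with every previously accepted path is below the
diversity threshold (default 50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .kg_core import KnowledgeGraph, Triple

DEFAULT_MAX_PATHS = 5
DEFAULT_MAX_LEN = 5
DEFAULT_DIVERSITY = 0.5
DEFAULT_MAX_ATTEMPTS = 200
DEFAULT_FALSE_PER_PATH = 5


class SamplingError(ValueError):
    pass


@dataclass(frozen=True)
class PathStep:
    """One traversed edge, oriented along the walk."""
    head: str
    relation: str
    tail: str
    forward: bool  # False when the underlying triple was traversed in reverse

    def triple(self) -> Triple:
        """The underlying directed triple as stored in the graph."""
        if self.forward:
            return Triple(self.head, self.relation, self.tail)
        return Triple(self.tail, self.relation, self.head)


@dataclass(frozen=True)
class Path:
    steps: tuple[PathStep, ...]

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.steps[0].head,) + tuple(s.tail for s in self.steps)

    @property
    def edge_keys(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(s.triple().key() for s in self.steps)

    def overlap_with(self, other: "Path") -> float:
        """Shared-edge fraction, normalized by this path's edge count."""
        return len(self.edge_keys & other.edge_keys) / len(self.edge_keys)

    def to_record(self) -> list[dict]:
        return [{"head": s.head, "relation": s.relation, "tail": s.tail,
                 "forward": s.forward} for s in self.steps]

    @classmethod
    def from_record(cls, rec: list[dict]) -> "Path":
        return cls(tuple(PathStep(r["head"], r["relation"], r["tail"],
                                  r["forward"]) for r in rec))


@dataclass
class NegativeBatch:
    triples: list[Triple]
    strategy: str  # "degree_hard" | "random_fixed_dest"
    seed: int
    epoch: int = 0


@dataclass
class SampledPathSet:
    head: str
    tail: str
    true_paths: list[Path]
    false_paths: list[list[Path]] = field(default_factory=list)  # per true path
    diversity_threshold: float = DEFAULT_DIVERSITY
    attempts: int = 0

    def all_false(self) -> list[Path]:
        return [p for group in self.false_paths for p in group]


# -- type-compatibility ----------------------------------------------------

def relation_type_pools(kg: KnowledgeGraph) -> dict[str, tuple[set[str], set[str]]]:
    """Observed (head-type set, tail-type set) per relation."""
    pools: dict[str, tuple[set[str], set[str]]] = {}
    for t in kg.triples:
        ht, tt = kg.entity_type(t.head), kg.entity_type(t.tail)
        h_set, t_set = pools.setdefault(t.relation, (set(), set()))
        h_set.add(ht)
        t_set.add(tt)
    return pools


def relation_slot_pools(kg: KnowledgeGraph) -> dict[str, tuple[list[str], list[str]]]:
    """Replacement candidates per relation: entities observed as head
    (resp. tail) of that relation in the graph, sorted.

    Corrupting within the observed role keeps negatives type-compatible and
    avoids branding entities that never carry the relation (e.g. an entire
    held-out disease area) as explicit negatives.
    """
    heads: dict[str, set[str]] = {}
    tails: dict[str, set[str]] = {}
    for t in kg.triples:
        heads.setdefault(t.relation, set()).add(t.head)
        tails.setdefault(t.relation, set()).add(t.tail)
    return {r: (sorted(heads[r]), sorted(tails[r])) for r in heads}


def _candidates(kg: KnowledgeGraph, types: set[str]) -> list[str]:
    out: list[str] = []
    for tp in sorted(types):
        out.extend(kg.entities_of_type(tp))
    return out


# -- negative sampling -----------------------------------------------------

def degree_hard_negatives(batch: Sequence[Triple], kg: KnowledgeGraph,
                          seed: int, epoch: int = 0,
                          positives: set | None = None) -> NegativeBatch:
    """One corrupted triple per positive, replacement entity drawn with
    probability proportional to its degree among type-compatible entities."""
    positives = positives if positives is not None else set(
        t.key() for t in kg.triples)
    pools = relation_slot_pools(kg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, epoch, 11]))
    out: list[Triple] = []
    for t in batch:
        h_cand, t_cand = pools.get(t.relation, ([t.head], [t.tail]))
        h_wide = t_wide = None
        for _attempt in range(100):
            corrupt_head = bool(rng.integers(2))
            if _attempt >= 50:
                # slot pool exhausted (rare relations): widen to all
                # entities of the observed endpoint types
                if h_wide is None:
                    h_wide = _candidates(kg, {kg.entity_type(e) for e in h_cand})
                    t_wide = _candidates(kg, {kg.entity_type(e) for e in t_cand})
                cand = h_wide if corrupt_head else t_wide
            else:
                cand = h_cand if corrupt_head else t_cand
            degs = np.array([kg.degrees[c] for c in cand], dtype=float)
            total = degs.sum()
            if total <= 0:
                raise SamplingError(
                    f"no type-compatible replacement with nonzero degree for {t}")
            repl = cand[int(rng.choice(len(cand), p=degs / total))]
            new = (Triple(repl, t.relation, t.tail) if corrupt_head
                   else Triple(t.head, t.relation, repl))
            if new.head == new.tail or new.key() in positives or new.key() == t.key():
                continue
            out.append(new)
            break
        else:
            raise SamplingError(f"could not corrupt {t} in 100 attempts")
    return NegativeBatch(out, "degree_hard", seed, epoch)


def random_fixed_dest_negatives(batch: Sequence[Triple], kg: KnowledgeGraph,
                                epoch: int, seed: int,
                                positives: set | None = None) -> NegativeBatch:
    """Tails preserved, heads drawn uniformly from type-compatible entities.

    The effective seed mixes (seed, epoch) so each epoch regenerates fresh
    negatives for the same positives.
    """
    positives = positives if positives is not None else set(
        t.key() for t in kg.triples)
    pools = relation_slot_pools(kg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, epoch, 13]))
    out: list[Triple] = []
    for t in batch:
        cand = pools.get(t.relation, ([t.head], [t.tail]))[0]
        if not cand:
            raise SamplingError(f"no type-compatible head replacement for {t}")
        wide = None
        for _attempt in range(100):
            if _attempt >= 50:
                if wide is None:
                    wide = _candidates(kg, {kg.entity_type(e) for e in cand})
                pool = wide
            else:
                pool = cand
            repl = pool[int(rng.integers(len(pool)))]
            new = Triple(repl, t.relation, t.tail)
            if new.head == new.tail or new.key() in positives or new.key() == t.key():
                continue
            out.append(new)
            break
        else:
            raise SamplingError(f"could not corrupt {t} in 100 attempts")
    return NegativeBatch(out, "random_fixed_dest", seed, epoch)


# -- path sampling ---------------------------------------------------------

def sample_paths(kg: KnowledgeGraph, head: str, tail: str,
                 max_paths: int = DEFAULT_MAX_PATHS,
                 max_len: int = DEFAULT_MAX_LEN,
                 diversity: float = DEFAULT_DIVERSITY,
                 max_attempts: int = DEFAULT_MAX_ATTEMPTS,
                 seed: int = 0,
                 exclude_edges: Iterable[tuple[str, str, str]] = ()) -> SampledPathSet:
    """Random walks from head over undirected adjacency, accepted when they
    reach tail within ``max_len`` relations and pass the diversity rule.

    Unreachable pairs return an empty set (no error): that feeds the
    "no explanation available" behavior downstream.
    """
    if head == tail:
        raise SamplingError("head and tail must differ")
    excluded = set(exclude_edges)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    accepted: list[Path] = []
    attempts = 0
    while len(accepted) < max_paths and attempts < max_attempts:
        attempts += 1
        current = head
        visited = {head}
        steps: list[PathStep] = []
        while len(steps) < max_len:
            nbrs = [(nid, tr, fwd) for nid, tr, fwd in kg.neighbors(current)
                    if nid not in visited and tr.key() not in excluded]
            if not nbrs:
                break
            nid, tr, fwd = nbrs[int(rng.integers(len(nbrs)))]
            steps.append(PathStep(current, tr.relation, nid, fwd))
            visited.add(nid)
            current = nid
            if current == tail:
                break
        if current != tail or not steps:
            continue
        candidate = Path(tuple(steps))
        if all(candidate.overlap_with(p) < diversity for p in accepted):
            accepted.append(candidate)
    return SampledPathSet(head, tail, accepted, [],
                          diversity_threshold=diversity, attempts=attempts)


def corrupt_paths(path: Path, kg: KnowledgeGraph,
                  n: int = DEFAULT_FALSE_PER_PATH, seed: int = 0,
                  active_filter: set[str] | None = None) -> list[Path]:
    """``n`` false paths replacing the last two nodes with random entities
    observed in the same relation slot; edges need not exist in the graph.
    A length-1 path has only its terminal node corrupted (documented
    degenerate case).

    ``active_filter`` optionally restricts replacements (e.g. to entities
    carrying therapeutic edges) so that entities absent from the positive
    class are not systematically branded as path negatives.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 19]))
    nodes = path.nodes
    corrupt_positions = [len(nodes) - 1] if len(path) == 1 else [len(nodes) - 2,
                                                                 len(nodes) - 1]
    slot_pools = relation_slot_pools(kg)

    def _pool(pos: int) -> list[str]:
        # replacement drawn from entities observed in the same role of the
        # incoming step's relation; falls back to the node's type
        step = path.steps[pos - 1]
        pools = slot_pools.get(step.relation)
        pool: list[str] = []
        if pools is not None:
            pool = pools[1] if step.forward else pools[0]
        if len(pool) < 2:
            pool = kg.entities_of_type(kg.entity_type(nodes[pos]))
        if active_filter is not None:
            filtered = [e for e in pool if e in active_filter]
            if len(filtered) >= 2:
                pool = filtered
        return pool

    out: list[Path] = []
    for _ in range(n):
        for _attempt in range(100):
            new_nodes = list(nodes)
            for pos in corrupt_positions:
                pool = _pool(pos)
                new_nodes[pos] = pool[int(rng.integers(len(pool)))]
            if tuple(new_nodes) == nodes:
                continue
            steps = []
            ok = True
            for i, s in enumerate(path.steps):
                h, t = new_nodes[i], new_nodes[i + 1]
                if h == t:
                    ok = False
                    break
                steps.append(PathStep(h, s.relation, t, s.forward))
            if not ok:
                continue
            out.append(Path(tuple(steps)))
            break
        else:
            raise SamplingError(f"could not corrupt path {path} in 100 attempts")
    return out
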