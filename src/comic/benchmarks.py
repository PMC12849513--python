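"""Canonical toy fixtures and end-to-end benchmark runners.

These are the configurations shared by the test suite and the acceptance
report: a mechanism-community fixture whose planted rule (drug and disease
share a mechanism community <=> indication) is recoverable from held-out
disease areas, a zero-noise fixture with unique drug->disease routes, and a
pathological fixture with congested drugs and sparse diseases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .interpret_eval import auprc, path_evidence, score_pairs
from .kg_core import KnowledgeGraph, SplitSpec, Triple, disease_area_split
from .synthetic_kg import PlantedTruth, SynthConfig, generate
from .training import ComicModel, TrainHistory, TrainingConfig, train


def toy_synth_config(seed: int, congestion: float = 0.0,
                     sparsity: float = 0.0) -> SynthConfig:
    """The standard noisy fixture: ~280 entities, 8 mechanism communities
    with two parallel pathways each, indication <=> shared community."""
    return SynthConfig(
        n_drugs=30, n_proteins=120, n_pathways=16, pathways_per_community=2,
        n_diseases=16, n_phenotypes=96, n_planted_indications=60,
        n_planted_contraindications=12, noise_edge_rate=0.3,
        communities_per_drug=1, intra_community_drug_drug=5,
        n_off_label=0, phenotypes_per_disease=5, extra_chains_per_drug=4,
        associate_all_diseases=True, congestion_drug_fraction=congestion,
        sparse_disease_fraction=sparsity, seed=seed)


def pathology_synth_config(seed: int) -> SynthConfig:
    """Fixture with the two structural pathologies injected: congested
    drugs (>=95% similarity edges) and sparse diseases (<=4 connections).

    Congestion needs enough drug partners, so the drug pool is enlarged and
    indications are planted on a sampled subset of community pairs.
    """
    return SynthConfig(
        n_drugs=60, n_proteins=96, n_pathways=16, pathways_per_community=2,
        n_diseases=16, n_phenotypes=64, n_planted_indications=60,
        n_planted_contraindications=12, noise_edge_rate=0.3,
        communities_per_drug=1, intra_community_drug_drug=4,
        n_off_label=0, phenotypes_per_disease=4, extra_chains_per_drug=3,
        associate_all_diseases=True, congestion_drug_fraction=0.1,
        sparse_disease_fraction=0.25, seed=seed)


def mechanism_synth_config(seed: int) -> SynthConfig:
    """Noisy fixture for mechanism-recovery checks: planted chains are the
    dominant explanatory routes (no extra scaffolding, similarity edges
    rare) and inert noise dilutes the global mechanism-edge fraction."""
    return SynthConfig(
        n_drugs=30, n_proteins=120, n_pathways=16, pathways_per_community=2,
        n_diseases=16, n_phenotypes=96, n_planted_indications=60,
        n_planted_contraindications=12, noise_edge_rate=1.5,
        communities_per_drug=1, intra_community_drug_drug=1,
        n_off_label=0, phenotypes_per_disease=2, extra_chains_per_drug=0,
        associate_all_diseases=False, seed=seed)


def zero_noise_synth_config(seed: int, n_pairs: int = 20) -> SynthConfig:
    """Bijective zero-noise fixture: one drug, protein, pathway and disease
    per community, so each planted pair has a unique indirect route — its
    mechanism chain."""
    return SynthConfig(
        n_drugs=n_pairs, n_proteins=n_pairs, n_pathways=n_pairs,
        pathways_per_community=1, n_diseases=n_pairs, n_phenotypes=4,
        n_planted_indications=n_pairs, n_planted_contraindications=0,
        noise_edge_rate=0.0, communities_per_drug=1,
        intra_community_drug_drug=0, n_off_label=0, phenotypes_per_disease=0,
        extra_chains_per_drug=0, associate_all_diseases=False, seed=seed)


def toy_training_config(seed: int, shuffle_labels: bool = False) -> TrainingConfig:
    """Optimization settings calibrated for the toy scale (the published
    recipe targets a 4M-edge graph; see README)."""
    return TrainingConfig(
        learning_rate=3e-3, batch_size=128, max_epochs=60,
        grad_clip_norm=5.0, patience_epochs=60, dim=64,
        max_paths=3, false_paths_per_path=2, seed=seed,
        checkpoint_selection="final", shuffle_labels=shuffle_labels)


def eval_config(cfg: TrainingConfig) -> TrainingConfig:
    """Evaluation-time path sampling: more accepted paths, deeper walk
    budget than during training."""
    return replace(cfg, max_paths=5, path_max_attempts=1000)


def toy_disease_area(kg: KnowledgeGraph, n_area: int = 4) -> set[str]:
    """Held-out disease area: the first ``n_area`` disease ids. Diseases
    are assigned to communities round-robin, so the area spans communities
    (a disease area shares mechanisms with trained areas, but all of its
    therapeutic edges leave the training data)."""
    return set(sorted(kg.entities_of_type("disease"))[:n_area])


def _reachable_within(graph: KnowledgeGraph, src: str, dst: str,
                      max_hops: int) -> bool:
    """Hop-limited BFS over undirected adjacency."""
    frontier = {src}
    seen = {src}
    for _ in range(max_hops):
        nxt = set()
        for node in frontier:
            for other, _, _ in graph.neighbors(node):
                if other == dst:
                    return True
                if other not in seen:
                    seen.add(other)
                    nxt.add(other)
        frontier = nxt
        if not frontier:
            return False
    return False


def held_out_pairs(kg: KnowledgeGraph, truth: PlantedTruth, split: SplitSpec,
                   seed: int,
                   train_graph: KnowledgeGraph | None = None
                   ) -> tuple[list[tuple[str, str]], list[int]]:
    """Test indications of the held-out area plus an equal number of
    non-indicated (drug, area disease) pairs.

    Negatives are connectivity-matched: a candidate is kept only when drug
    and disease are linked within 5 hops of the training graph, so class
    separation cannot come from mere reachability.
    """
    pos = [(t.head, t.tail) for t in split.test if t.relation == "indication"]
    area = {z for _, z in pos} | {t.tail for t in split.test}
    if train_graph is None:
        train_graph = kg.subgraph_with_triples(split.train)
    drugs = kg.entities_of_type("drug")
    adis = sorted(area)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    neg: list[tuple[str, str]] = []
    guard = 0
    while len(neg) < len(pos) and guard < 100000:
        guard += 1
        d = drugs[int(rng.integers(len(drugs)))]
        z = adis[int(rng.integers(len(adis)))]
        if ((d, z) in truth.indications or (d, z) in neg
                or not _reachable_within(train_graph, d, z, 5)):
            continue
        neg.append((d, z))
    pairs = pos + neg
    labels = [1] * len(pos) + [0] * len(neg)
    return pairs, labels


@dataclass
class ToyRun:
    seed: int
    kg: KnowledgeGraph
    truth: PlantedTruth
    split: SplitSpec
    train_graph: KnowledgeGraph
    model: ComicModel
    history: TrainHistory
    cfg: TrainingConfig
    pairs: list = field(default_factory=list)
    labels: list = field(default_factory=list)
    scores: np.ndarray | None = None
    test_auprc: float = float("nan")


def run_toy_benchmark(seed: int, shuffle_labels: bool = False,
                      synth: SynthConfig | None = None,
                      n_area: int = 4) -> ToyRun:
    """Generate -> split -> train -> score held-out pairs, fully seeded."""
    synth = synth if synth is not None else toy_synth_config(seed)
    kg, truth = generate(synth)
    area = toy_disease_area(kg, n_area)
    split = disease_area_split(kg, area, seed=seed)
    cfg = toy_training_config(seed, shuffle_labels=shuffle_labels)
    model, history = train(kg, split, cfg)
    train_graph = kg.subgraph_with_triples(split.train)
    pairs, labels = held_out_pairs(kg, truth, split, seed,
                                   train_graph=train_graph)
    scores = score_pairs(model, train_graph, pairs, eval_config(cfg), seed=seed)
    run = ToyRun(seed, kg, truth, split, train_graph, model, history, cfg,
                 pairs, labels, scores)
    run.test_auprc = auprc(scores, labels)
    return run
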