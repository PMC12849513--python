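"""Prediction metrics, percentile ranking, mask-derived edge importance,
and insertion/deletion faithfulness curves.

Pair scoring at evaluation time is graph-aware: the classifier probability
from the masked triple representation is combined with path evidence (the
best alignment of a sampled path with the positive label embedding), so
inserting or deleting graph edges moves the score without retraining.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score

from .kg_core import KnowledgeGraph, Triple
from .sampling import Path, corrupt_paths, sample_paths
from .training import ComicModel, TrainingConfig, _pair_seed

DEFAULT_PATH_WEIGHT = 0.5
INSERTION_K_GRID = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
DELETION_K_GRID = (0, 10, 20, 30, 40, 50, 60, 70, 80, 90)


# -- prediction metrics ----------------------------------------------------

def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (step-wise construction; equal
    scores collapse to one threshold)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("AUPRC needs at least one positive and one negative")
    return float(average_precision_score(labels, scores))


def accuracy(scores: Sequence[float], labels: Sequence[int],
             threshold: float = 0.5) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = (scores >= threshold).astype(int)
    return float(np.mean(pred == labels))


def rank_percentile(drug_score: float, candidate_scores: Sequence[float]) -> float:
    """Percentile of the drug among candidates: strictly-below count over
    |candidates| - 1, ties (other than the drug itself) counted as half."""
    scores = np.asarray(candidate_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 candidates")
    below = int(np.sum(scores < drug_score))
    ties = int(np.sum(scores == drug_score)) - 1  # exclude the drug itself
    return 100.0 * (below + 0.5 * ties) / (scores.size - 1)


# -- graph-aware pair scoring ---------------------------------------------

def path_evidence(model: ComicModel, kg: KnowledgeGraph, drug: str,
                  disease: str, cfg: TrainingConfig, seed: int = 0,
                  exclude_direct: bool = True, n_null: int = 4):
    """(evidence in [0, 1], scored paths); 0 when no path exists.

    Evidence contrasts the best positive-label critic logit over sampled
    paths against the same statistic over their corrupted variants:
    sigma(max_i b+(p_i) - max_i mean_j b+(corrupt_j(p_i))). The null term
    uses the same path count, so evidence is calibrated against both
    reachability and path-count artefacts: an uninformative path branch
    yields ~0.5 regardless of how many paths a pair has.
    """
    exclude = []
    if exclude_direct:
        from .kg_core import THERAPEUTIC_RELATIONS
        exclude = [(drug, r, disease) for r in THERAPEUTIC_RELATIONS]
        exclude += [(disease, r, drug) for r in THERAPEUTIC_RELATIONS]
    pseed = int(_pair_seed(seed, model.ent_index[drug],
                           model.ent_index[disease]).generate_state(1)[0])
    # two independent sampler runs improve coverage of the decisive route
    paths: list[Path] = []
    seen_keys: set[frozenset] = set()
    for s_off in (0, 1):
        pset = sample_paths(kg, drug, disease, max_paths=cfg.max_paths,
                            max_len=cfg.max_path_len,
                            diversity=cfg.path_diversity,
                            max_attempts=cfg.path_max_attempts,
                            seed=pseed + 7 * s_off, exclude_edges=exclude)
        for p in pset.true_paths:
            if p.edge_keys not in seen_keys:
                seen_keys.add(p.edge_keys)
                paths.append(p)
    if not paths:
        return 0.0, []
    align, mean_mask, _, _ = model.path_alignment(paths)
    scored = sorted(zip(paths, align, mean_mask), key=lambda x: -x[1])

    # pad the max to a fixed draw budget with corrupted-path alignments:
    # an uninformative branch then sees the same number of draws for every
    # reachable pair (no path-count artefact), while a trained branch
    # scores corruptions near zero so padding never wins the max
    draws = list(align)
    missing = 2 * cfg.max_paths - len(paths)
    if missing > 0:
        pad = corrupt_paths(paths[0], kg, n=missing, seed=pseed + 101)
        draws.extend(model.path_alignment(pad)[0])
    return float(np.max(draws)), scored


def _positive_logits(model: ComicModel, paths: Sequence[Path]) -> np.ndarray:
    """Critic logit of each path's masked representation against the
    positive-class label embedding."""
    X_p = model.encode_paths(paths)
    Z_p, _ = model.path_branch.mask(X_p, model.temperature)
    logits = model.path_branch.critic_zy.log_score_matrix(
        Z_p, model.path_branch.label_embeddings)
    return logits.data[:, 1]


def score_pairs(model: ComicModel, kg: KnowledgeGraph,
                pairs: Sequence[tuple[str, str]], cfg: TrainingConfig,
                relation: str = "indication", seed: int = 0,
                path_weight: float = DEFAULT_PATH_WEIGHT) -> np.ndarray:
    """Combined score per (drug, disease) pair:
    (1 - w) * classifier probability + w * path evidence."""
    triples = [Triple(d, relation, z) for d, z in pairs]
    probs = model.score_triples(triples)
    evidence = np.array([path_evidence(model, kg, d, z, cfg, seed=seed)[0]
                         for d, z in pairs])
    return (1.0 - path_weight) * probs + path_weight * evidence


# -- edge importance -------------------------------------------------------

@dataclass
class EdgeImportance:
    scores: dict[tuple[str, str, str], float]
    aggregator: str = "max"

    def ranked_edges(self) -> list[tuple[str, str, str]]:
        return [k for k, _ in sorted(self.scores.items(),
                                     key=lambda kv: (-kv[1], kv[0]))]


def edge_importance(model: ComicModel, kg: KnowledgeGraph,
                    pairs: Sequence[tuple[str, str]], cfg: TrainingConfig,
                    seed: int = 0, aggregator: str = "max") -> EdgeImportance:
    """Path score = mean mask magnitude * alignment with the positive label
    embedding; each edge takes the max (default) over scored paths that
    contain it. Edges on no sampled path score 0."""
    if aggregator not in ("max", "mean", "sum"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    acc: dict[tuple[str, str, str], list[float]] = {}
    for drug, disease in pairs:
        _, scored = path_evidence(model, kg, drug, disease, cfg, seed=seed)
        for path, align, mean_mask in scored:
            pscore = float(mean_mask * align)
            for key in path.edge_keys:
                acc.setdefault(key, []).append(pscore)
    agg = {"max": max, "mean": lambda v: sum(v) / len(v), "sum": sum}[aggregator]
    scores = {t.key(): 0.0 for t in kg.triples}
    for key, vals in acc.items():
        if key in scores:
            scores[key] = float(agg(vals))
    return EdgeImportance(scores, aggregator)


# -- faithfulness ----------------------------------------------------------

@dataclass
class FaithfulnessCurve:
    mode: str  # "insertion" | "deletion"
    K_values: list[float]
    auprc_values: list[float]

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("K,auprc\n")
            for k, a in zip(self.K_values, self.auprc_values):
                fh.write(f"{k},{a}\n")


def faithfulness_curve(model: ComicModel, kg: KnowledgeGraph,
                       test_pairs: Sequence[tuple[str, str]],
                       test_labels: Sequence[int],
                       importance: EdgeImportance, mode: str,
                       K_values: Iterable[float] | None = None,
                       cfg: TrainingConfig | None = None, seed: int = 0,
                       relation: str = "indication",
                       path_weight: float = DEFAULT_PATH_WEIGHT) -> FaithfulnessCurve:
    """Insert (from empty) or delete (from full) the top-K% ranked edges,
    re-sample paths against the modified graph, and record AUPRC at each K.
    Model parameters stay frozen."""
    if mode not in ("insertion", "deletion"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or TrainingConfig()
    Ks = list(K_values) if K_values is not None else list(
        INSERTION_K_GRID if mode == "insertion" else DELETION_K_GRID)
    if any(k < 0 or k > 100 for k in Ks):
        raise ValueError("K values must lie in [0, 100]")
    if sorted(Ks) != Ks or len(set(Ks)) != len(Ks):
        raise ValueError("K values must be strictly increasing")

    ranked = importance.ranked_edges()
    n_edges = len(ranked)
    key_to_triple = {t.key(): t for t in kg.triples}
    aup = []
    for K in Ks:
        top = {k for k in ranked[:int(round(K / 100.0 * n_edges))]}
        if mode == "insertion":
            keep = [key_to_triple[k] for k in key_to_triple if k in top]
        else:
            keep = [key_to_triple[k] for k in key_to_triple if k not in top]
        sub = kg.subgraph_with_triples(keep)
        scores = score_pairs(model, sub, test_pairs, cfg, relation=relation,
                             seed=seed, path_weight=path_weight)
        aup.append(auprc(scores, test_labels))
    return FaithfulnessCurve(mode, [float(k) for k in Ks], aup)


# -- explanations ----------------------------------------------------------

@dataclass
class Explanation:
    drug: str
    disease: str
    score: float
    paths: list[dict] = field(default_factory=list)  # ranked by path score
    features: list[dict] = field(default_factory=list)  # top mask dims

    def to_json(self) -> str:
        return json.dumps({"drug": self.drug, "disease": self.disease,
                           "score": self.score, "paths": self.paths,
                           "features": self.features}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Explanation":
        d = json.loads(text)
        return cls(d["drug"], d["disease"], d["score"], d["paths"],
                   d["features"])


def explain_pair(model: ComicModel, kg: KnowledgeGraph, drug: str,
                 disease: str, cfg: TrainingConfig | None = None,
                 seed: int = 0, relation: str = "indication",
                 top_k_features: int = 10) -> Explanation:
    """Classification score, ranked sampled paths, and the strongest triple-
    mask feature dimensions. Unreachable pairs get an empty path list."""
    for eid in (drug, disease):
        if eid not in model.ent_index:
            raise KeyError(f"unknown entity {eid!r}")
    cfg = cfg or TrainingConfig()
    triple = Triple(drug, relation, disease)
    X_t, Z_t, M_t, probs = model.forward_triples([triple])
    score = float(probs.data[0])
    _, scored = path_evidence(model, kg, drug, disease, cfg, seed=seed)
    paths = [{"steps": p.to_record(), "score": float(mm * al),
              "alignment": float(al), "mean_mask": float(mm)}
             for p, al, mm in sorted(scored, key=lambda x: -(x[2] * x[1]))]
    mask = M_t.data[0]
    top = np.argsort(-mask)[:top_k_features]
    features = [{"dimension": int(i), "magnitude": float(mask[i])} for i in top]
    return Explanation(drug, disease, score, paths, features)
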