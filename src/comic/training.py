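"""Classifier head, loss assembly, and the full optimization loop.

Defaults follow the published recipe: Adam at lr 5e-4, batch 1024, at most
30 epochs, temperature annealed linearly 1.0 -> 0.1, beta = 0.1,
beta2 = 0.2, gradient clipping at norm 1.0, early stopping with patience 2
on the validation loss.

Training positives are ALL train-split triples (every relation), each
contrasted with one corrupted negative; the path branch is computed for
therapeutic-relation (drug-disease) pairs in the batch. Prediction consumes
only the masked triple representation Z_t — the path branch influences
training solely through its contrastive loss.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .contrastive_masking import ContrastiveConfig, MaskingBranch
from .encoders import DEFAULT_DIM, PathEncoder, TripleEncoder, init_embeddings
from .kg_core import THERAPEUTIC_RELATIONS, KnowledgeGraph, SplitSpec, Triple
from .nn import Adam, ClassifierMLP, Module, Tensor, clip_grad_norm, concat, constant
from . import sampling as sp


@dataclass
class TrainingConfig:
    learning_rate: float = 0.0005
    batch_size: int = 1024
    max_epochs: int = 30
    temperature_start: float = 1.0
    temperature_min: float = 0.1
    beta: float = 0.1
    beta2: float = 0.2
    grad_clip_norm: float = 1.0
    patience_epochs: int = 2
    negative_strategy: str = "degree_hard"  # or "random_fixed_dest"
    negatives_per_positive: int = 1
    seed: int = 0
    dim: int = DEFAULT_DIM
    max_paths: int = sp.DEFAULT_MAX_PATHS
    max_path_len: int = sp.DEFAULT_MAX_LEN
    path_diversity: float = sp.DEFAULT_DIVERSITY
    path_max_attempts: int = sp.DEFAULT_MAX_ATTEMPTS
    false_paths_per_path: int = sp.DEFAULT_FALSE_PER_PATH
    shuffle_labels: bool = False  # control experiment: destroys supervision
    val_loss_edges: str = "all"  # "all" | "therapeutic": edges used for early stopping
    # "best_val": restore the min-validation-loss checkpoint (default);
    # "val_auprc": select/stop on validation AUPRC of the combined
    #   classifier + path-evidence score over therapeutic validation pairs;
    # "final": keep the last epoch's weights
    checkpoint_selection: str = "best_val"

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.temperature_start, self.temperature_min, self.grad_clip_norm,
               self.patience_epochs) <= 0:
            raise ValueError("config values must be positive")
        if self.temperature_min > self.temperature_start:
            raise ValueError("temperature_min must be <= temperature_start")
        if self.negative_strategy not in ("degree_hard", "random_fixed_dest"):
            raise ValueError(f"unknown negative strategy {self.negative_strategy!r}")


@dataclass
class EpochRecord:
    epoch: int
    l_bce: float
    l_triple: float
    l_path: float
    l_total: float
    val_loss: float
    temperature: float
    early_stop: bool = False
    val_auprc: float | None = None


@dataclass
class TrainHistory:
    epochs: list[EpochRecord] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)  # post-clip, per step
    best_epoch: int = -1
    stopped_early: bool = False

    def to_csv(self, path: str) -> None:
        cols = ["epoch", "l_bce", "l_triple", "l_path", "l_total", "val_loss",
                "temperature", "early_stop", "val_auprc"]
        with open(path, "w") as fh:
            fh.write(",".join(cols) + "\n")
            for rec in self.epochs:
                d = asdict(rec)
                fh.write(",".join(str(d[c]) for c in cols) + "\n")


def temperature_at(epoch: int, cfg: TrainingConfig) -> float:
    """Linear anneal from temperature_start (epoch 0) to temperature_min
    (epoch max_epochs - 1)."""
    if not 0 <= epoch < cfg.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.max_epochs})")
    if cfg.max_epochs == 1:
        return cfg.temperature_min
    frac = epoch / (cfg.max_epochs - 1)
    return cfg.temperature_start + frac * (cfg.temperature_min - cfg.temperature_start)


_EPS = 1e-7


def bce(labels, probs) -> Tensor:
    """Mean binary cross entropy; probabilities squeezed into
    [1e-7, 1 - 1e-7] (smooth clamp) to avoid log(0)."""
    y = constant(np.asarray(labels, dtype=np.float64))
    p = probs if isinstance(probs, Tensor) else constant(np.asarray(probs, float))
    p = p * (1.0 - 2.0 * _EPS) + _EPS
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()


def total_loss(l_bce, l_triple, l_path, beta2: float):
    """L_total = L_BCE + beta2 * (L_triple + L_path)."""
    return l_bce + beta2 * (l_triple + l_path)


class ComicModel(Module):
    """Dual-branch predictor over a frozen entity/relation vocabulary."""

    def __init__(self, kg: KnowledgeGraph, dim: int = DEFAULT_DIM, seed: int = 0):
        self.dim = dim
        self.entity_ids = sorted(kg.entities)
        self.relation_ids = list(kg.relations)
        self.ent_index = {e: i for i, e in enumerate(self.entity_ids)}
        self.rel_index = {r: i for i, r in enumerate(self.relation_ids)}
        self.tables = init_embeddings(len(self.entity_ids),
                                      len(self.relation_ids), seed=seed, dim=dim)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
        self.triple_encoder = TripleEncoder(rng, dim)
        self.path_encoder = PathEncoder(rng, dim)
        self.triple_branch = MaskingBranch(rng, dim)
        self.path_branch = MaskingBranch(rng, dim)
        self.classifier = ClassifierMLP(rng, dim)
        self.temperature = 1.0  # updated by the annealing schedule

    # -- parameters (embedding tables included) ---------------------------
    def parameters(self) -> list[tuple[str, Tensor]]:
        params = [("tables.entity", self.tables.entity_vectors),
                  ("tables.relation", self.tables.relation_vectors)]
        for name in ("triple_encoder", "path_encoder", "triple_branch",
                     "path_branch", "classifier"):
            mod: Module = getattr(self, name)
            params.extend((f"{name}.{n}", p) for n, p in mod.parameters())
        return params

    # -- encoding ----------------------------------------------------------
    def triple_tokens(self, triples: Sequence[Triple]) -> Tensor:
        h = np.array([self.ent_index[t.head] for t in triples])
        r = np.array([self.rel_index[t.relation] for t in triples])
        l = np.array([self.ent_index[t.tail] for t in triples])
        n = len(triples)
        eh = self.tables.entity_vectors.take_rows(h).reshape(n, 1, self.dim)
        er = self.tables.relation_vectors.take_rows(r).reshape(n, 1, self.dim)
        el = self.tables.entity_vectors.take_rows(l).reshape(n, 1, self.dim)
        return concat([eh, er, el], axis=1)

    def encode_triples(self, triples: Sequence[Triple]) -> Tensor:
        return self.triple_encoder(self.triple_tokens(triples))

    def encode_paths(self, paths: Sequence[sp.Path]) -> Tensor:
        """Encode a heterogeneous-length path batch (grouped internally by
        length, reassembled in input order)."""
        if not paths:
            raise ValueError("empty path batch")
        by_len: dict[int, list[int]] = {}
        for i, p in enumerate(paths):
            by_len.setdefault(len(p), []).append(i)
        pieces, order = [], []
        for plen in sorted(by_len):
            idxs = by_len[plen]
            hs, rs, ls = [], [], []
            for i in idxs:
                for s in paths[i].steps:
                    hs.append(self.ent_index[s.head])
                    rs.append(self.rel_index[s.relation])
                    ls.append(self.ent_index[s.tail])
            n = len(idxs)
            eh = self.tables.entity_vectors.take_rows(np.array(hs))
            er = self.tables.relation_vectors.take_rows(np.array(rs))
            el = self.tables.entity_vectors.take_rows(np.array(ls))
            tok = concat([eh, er, el], axis=-1).reshape(n, plen, 3 * self.dim)
            pieces.append(self.path_encoder(tok))
            order.extend(idxs)
        stacked = pieces[0] if len(pieces) == 1 else concat(pieces, axis=0)
        inv = np.empty(len(paths), dtype=np.intp)
        inv[np.array(order)] = np.arange(len(paths))
        return stacked.take_rows(inv)

    # -- prediction --------------------------------------------------------
    def classify(self, Z_t: Tensor) -> Tensor:
        """Probability in (0, 1) from the masked triple representation."""
        return self.classifier(Z_t).reshape(Z_t.shape[0])

    def forward_triples(self, triples: Sequence[Triple],
                        temperature: float | None = None):
        T = self.temperature if temperature is None else temperature
        X_t = self.encode_triples(triples)
        Z_t, M_t = self.triple_branch.mask(X_t, T)
        probs = self.classify(Z_t)
        return X_t, Z_t, M_t, probs

    def score_triples(self, triples: Sequence[Triple]) -> np.ndarray:
        return self.forward_triples(triples)[3].data

    def path_alignment(self, paths: Sequence[sp.Path],
                       temperature: float | None = None):
        """Per-path (alignment probability with the positive label embedding,
        mean mask magnitude)."""
        T = self.temperature if temperature is None else temperature
        X_p = self.encode_paths(paths)
        Z_p, M_p = self.path_branch.mask(X_p, T)
        logits = (Z_p @ self.path_branch.critic_zy.W) \
            @ self.path_branch.label_embeddings.swapaxes(0, 1)  # (N, 2)
        lg = logits.data
        align = 1.0 / (1.0 + np.exp(-(lg[:, 1] - lg[:, 0])))
        return align, M_p.data.mean(axis=1), Z_p, M_p

    # -- checkpointing -----------------------------------------------------
    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        arrays = {name: p.data for name, p in self.parameters()}
        np.savez(os.path.join(out_dir, "params.npz"), **arrays)
        meta = {"dim": self.dim, "temperature": self.temperature,
                "entity_ids": self.entity_ids, "relation_ids": self.relation_ids}
        with open(os.path.join(out_dir, "model.json"), "w") as fh:
            json.dump(meta, fh)

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for name, p in self.parameters():
            p.data = np.array(arrays[name])

    @classmethod
    def restore(cls, kg: KnowledgeGraph, in_dir: str) -> "ComicModel":
        with open(os.path.join(in_dir, "model.json")) as fh:
            meta = json.load(fh)
        model = cls(kg, dim=meta["dim"], seed=0)
        if model.entity_ids != meta["entity_ids"]:
            raise ValueError("checkpoint vocabulary does not match the graph")
        with np.load(os.path.join(in_dir, "params.npz")) as npz:
            model.load_arrays({k: npz[k] for k in npz.files})
        model.temperature = meta["temperature"]
        return model


class TrainingDiverged(RuntimeError):
    pass


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without improvement.

    ``update`` returns (improved, should_stop); should_stop flips exactly
    when the metric has failed to improve for ``patience`` epochs in a row.
    """

    def __init__(self, patience: int):
        if patience <= 0:
            raise ValueError("patience must be positive")
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0

    def update(self, metric: float) -> tuple[bool, bool]:
        if metric < self.best:
            self.best = metric
            self.bad_epochs = 0
            return True, False
        self.bad_epochs += 1
        return False, self.bad_epochs >= self.patience


def _pair_seed(seed: int, hi: int, ti: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, 31, hi, ti])


class PathCache:
    """Per-pair sampled paths + corruptions over a fixed training graph.

    The direct therapeutic edges between the query pair are excluded from
    walks so the path branch cannot read the label off the graph.
    """

    def __init__(self, graph: KnowledgeGraph, cfg: TrainingConfig,
                 ent_index: dict[str, int]):
        self.graph = graph
        self.cfg = cfg
        self.ent_index = ent_index
        self._cache: dict[tuple[str, str], sp.SampledPathSet] = {}
        # drugs/diseases qualify for path corruption only when they carry a
        # therapeutic edge in this graph; other types are unrestricted
        restricted = {"drug", "disease"}
        active = {e for e in graph.entities
                  if graph.entities[e].type not in restricted}
        for t in graph.triples:
            if t.relation in THERAPEUTIC_RELATIONS:
                active.add(t.head)
                active.add(t.tail)
        self.active_filter = active

    def get(self, head: str, tail: str,
            max_attempts: int | None = None) -> sp.SampledPathSet:
        key = (head, tail)
        if key in self._cache:
            return self._cache[key]
        cfg = self.cfg
        exclude = [(head, r, tail) for r in THERAPEUTIC_RELATIONS]
        exclude += [(tail, r, head) for r in THERAPEUTIC_RELATIONS]
        seed_seq = _pair_seed(cfg.seed, self.ent_index[head], self.ent_index[tail])
        seed = int(seed_seq.generate_state(1)[0])
        pset = sp.sample_paths(self.graph, head, tail,
                               max_paths=cfg.max_paths, max_len=cfg.max_path_len,
                               diversity=cfg.path_diversity,
                               max_attempts=max_attempts or cfg.path_max_attempts,
                               seed=seed, exclude_edges=exclude)
        pset.false_paths = [
            sp.corrupt_paths(p, self.graph, n=cfg.false_paths_per_path,
                             seed=seed + 1 + i,
                             active_filter=self.active_filter)
            for i, p in enumerate(pset.true_paths)
        ]
        self._cache[key] = pset
        return pset


def _batch_paths(cache: PathCache, triples: Sequence[Triple],
                 labels: np.ndarray) -> tuple[list[sp.Path], np.ndarray]:
    """Collect paths for therapeutic pairs in the batch with supervision
    labels: true paths inherit the pair's label, corrupted paths get 0."""
    paths: list[sp.Path] = []
    plabels: list[int] = []
    for t, lab in zip(triples, labels):
        if t.relation not in THERAPEUTIC_RELATIONS:
            continue
        # positive pairs are stable across epochs (cached once), so they can
        # afford a deeper walk budget than the per-epoch corrupted pairs
        pset = cache.get(t.head, t.tail,
                         max_attempts=None if lab < 0.5 else
                         3 * cache.cfg.path_max_attempts)
        for i, p in enumerate(pset.true_paths):
            paths.append(p)
            plabels.append(int(lab))
            for fp in pset.false_paths[i]:
                paths.append(fp)
                plabels.append(0)
    return paths, np.array(plabels, dtype=np.intp)


def _sample_negatives(positives: Sequence[Triple], graph: KnowledgeGraph,
                      cfg: TrainingConfig, epoch: int, batch_idx: int,
                      known: set) -> list[Triple]:
    reps = []
    for k in range(cfg.negatives_per_positive):
        seed = cfg.seed * 1000003 + batch_idx * 101 + k
        if cfg.negative_strategy == "degree_hard":
            nb = sp.degree_hard_negatives(positives, graph, seed=seed,
                                          epoch=epoch, positives=known)
        else:
            nb = sp.random_fixed_dest_negatives(positives, graph, epoch=epoch,
                                                seed=seed, positives=known)
        reps.extend(nb.triples)
    return reps


def train(kg: KnowledgeGraph, split: SplitSpec, cfg: TrainingConfig,
          model: ComicModel | None = None) -> tuple[ComicModel, TrainHistory]:
    """Run the optimization loop; returns the best-validation checkpoint."""
    cfg.validate()
    if not split.train or not split.validation:
        raise ValueError("train and validation sets must be nonempty")
    model = model or ComicModel(kg, dim=cfg.dim, seed=cfg.seed)
    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    ccfg = ContrastiveConfig(beta=cfg.beta)

    train_graph = kg.subgraph_with_triples(split.train)
    known = {t.key() for t in kg.triples}
    cache = PathCache(train_graph, cfg, model.ent_index)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 37]))

    # fixed validation contrast set (stable across epochs)
    val_pos = list(split.validation)
    if cfg.val_loss_edges == "therapeutic":
        ther = [t for t in val_pos if t.relation in THERAPEUTIC_RELATIONS]
        val_pos = ther or val_pos  # fall back when no therapeutic edge landed
    val_neg = sp.degree_hard_negatives(
        val_pos, train_graph, seed=cfg.seed ^ 0xBEEF, epoch=0,
        positives=known).triples
    val_triples = val_pos + val_neg
    val_labels = np.array([1.0] * len(val_pos) + [0.0] * len(val_neg))

    # therapeutic validation pairs for AUPRC-based checkpoint selection
    # selection negatives mirror evaluation-time negatives (uniform head
    # replacement, destination kept) rather than degree-hard ones
    vther = [t for t in split.validation if t.relation in THERAPEUTIC_RELATIONS]
    vther_neg = sp.random_fixed_dest_negatives(
        vther, train_graph, epoch=0, seed=cfg.seed ^ 0xACE5,
        positives=known).triples if vther else []
    sel_triples = vther + vther_neg
    sel_labels = np.array([1] * len(vther) + [0] * len(vther_neg))
    use_auprc_sel = (cfg.checkpoint_selection == "val_auprc" and len(vther) > 0)

    def _evidence(head: str, tail: str) -> float:
        pset = cache.get(head, tail)
        if not pset.true_paths:
            return 0.0
        align = model.path_alignment(pset.true_paths)[0]
        return float(np.max(align))

    history = TrainHistory()
    stopper = EarlyStopper(cfg.patience_epochs)
    best_arrays: dict[str, np.ndarray] | None = None

    for epoch in range(cfg.max_epochs):
        model.temperature = temperature_at(epoch, cfg)
        order = rng.permutation(len(split.train))
        ep_bce, ep_tri, ep_path, ep_tot, n_batches = 0.0, 0.0, 0.0, 0.0, 0

        for b0 in range(0, len(order), cfg.batch_size):
            batch_pos = [split.train[int(i)] for i in order[b0:b0 + cfg.batch_size]]
            batch_neg = _sample_negatives(batch_pos, train_graph, cfg, epoch,
                                          b0 // cfg.batch_size, known)
            triples = batch_pos + batch_neg
            labels = np.array([1.0] * len(batch_pos) + [0.0] * len(batch_neg))
            if cfg.shuffle_labels:
                labels = labels[rng.permutation(len(labels))]

            X_t, Z_t, M_t, probs = model.forward_triples(triples)
            l_bce = bce(labels, probs)
            l_triple = model.triple_branch.loss(X_t, Z_t,
                                                labels.astype(np.intp), ccfg)
            paths, plabels = _batch_paths(cache, triples, labels)
            if len(paths):
                X_p = model.encode_paths(paths)
                Z_p, M_p = model.path_branch.mask(X_p, model.temperature)
                l_path = model.path_branch.loss(X_p, Z_p, plabels, ccfg)
            else:
                l_path = constant(0.0)
            l_total = total_loss(l_bce, l_triple, l_path, cfg.beta2)
            if not np.isfinite(l_total.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}: bce={l_bce.data}, "
                    f"triple={l_triple.data}, path={l_path.data}")

            opt.zero_grad()
            l_total.backward()
            history.grad_norms.append(clip_grad_norm(params, cfg.grad_clip_norm))
            opt.step()

            ep_bce += float(l_bce.data)
            ep_tri += float(l_triple.data)
            ep_path += float(l_path.data)
            ep_tot += float(l_total.data)
            n_batches += 1

        val_probs = model.score_triples(val_triples)
        val_loss = float(bce(val_labels, val_probs).data)
        rec = EpochRecord(epoch, ep_bce / n_batches, ep_tri / n_batches,
                          ep_path / n_batches, ep_tot / n_batches,
                          val_loss, model.temperature)
        selection_metric = val_loss
        if use_auprc_sel:
            sel_probs = model.score_triples(sel_triples)
            sel_ev = np.array([_evidence(t.head, t.tail) for t in sel_triples])
            combined = 0.5 * sel_probs + 0.5 * sel_ev
            # stepwise AUPRC; sel set always has both classes by construction
            from sklearn.metrics import average_precision_score
            rec.val_auprc = float(average_precision_score(sel_labels, combined))
            selection_metric = -rec.val_auprc
        improved, should_stop = stopper.update(selection_metric)
        if improved:
            best_arrays = {n: p.data.copy() for n, p in params}
            history.best_epoch = epoch
        if should_stop:
            rec.early_stop = True
            history.stopped_early = True
            history.epochs.append(rec)
            break
        history.epochs.append(rec)

    if cfg.checkpoint_selection in ("best_val", "val_auprc") and best_arrays is not None:
        model.load_arrays(best_arrays)
    return model, history
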