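"""Toy knowledge-graph generator with planted mechanistic ground truth.

The generator emits a miniature multi-type graph shaped like a precision-
medicine KG: drugs, proteins, pathways, diseases and phenotypes, with an
8-relation vocabulary. Indications are planted together with an explicit
mechanism chain drug -targets-> protein -participates-> pathway
-associated-> disease, so downstream explanation tests have a ground truth.

Two structural pathologies can be injected on demand: "congested" drugs
whose connections are dominated (>=95%) by drug-drug similarity edges, and
"sparse" diseases pruned to at most 4 connections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .kg_core import Entity, KnowledgeGraph, Triple

RELATIONS = ("indication", "contraindication", "off_label", "drug_drug",
             "targets", "participates", "associated", "phenotype_of")

#: Allowed (head type, tail type) per relation — noise edges respect these.
RELATION_SCHEMA: dict[str, tuple[str, str]] = {
    "indication": ("drug", "disease"),
    "contraindication": ("drug", "disease"),
    "off_label": ("drug", "disease"),
    "drug_drug": ("drug", "drug"),
    "targets": ("drug", "protein"),
    "participates": ("protein", "pathway"),
    "associated": ("pathway", "disease"),
    "phenotype_of": ("phenotype", "disease"),
}

CONGESTION_DOMINANCE = 0.95
SPARSE_MAX_CONNECTIONS = 4


class SynthesisError(ValueError):
    pass


@dataclass
class SynthConfig:
    n_drugs: int = 40
    n_proteins: int = 30
    n_pathways: int = 5
    n_diseases: int = 30
    n_phenotypes: int = 20
    mechanism_length: int = 3
    n_planted_indications: int = 30
    n_planted_contraindications: int = 0
    noise_edge_rate: float = 0.0
    congestion_drug_fraction: float = 0.0
    sparse_disease_fraction: float = 0.0
    communities_per_drug: int = 2   # how many pathway communities each drug spans
    pathways_per_community: int = 1  # parallel pathways per mechanism community
    associate_all_diseases: bool = False  # scaffold pathway->disease for every disease
    intra_community_drug_drug: int = 0  # similarity edges per drug to same-pathway drugs
    n_off_label: int = 0            # off-label drug-disease hints within communities
    phenotypes_per_disease: int = 0  # community-correlated phenotype links
    extra_chains_per_drug: int = 0   # additional targets->participates scaffolding
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_drugs", "n_proteins", "n_pathways", "n_diseases",
                     "n_phenotypes"):
            if getattr(self, name) <= 0:
                raise SynthesisError(f"{name} must be positive")
        if self.mechanism_length != 3:
            raise SynthesisError("only 3-hop mechanism chains "
                                 "(drug->protein->pathway->disease) are supported")
        if self.noise_edge_rate < 0:
            raise SynthesisError("noise_edge_rate must be >= 0")
        for name in ("congestion_drug_fraction", "sparse_disease_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise SynthesisError(f"{name} must be in [0, 1]")
        if self.n_planted_indications > self.n_drugs * self.n_diseases:
            raise SynthesisError("more planted indications than drug-disease pairs")


@dataclass
class PlantedTruth:
    indications: set[tuple[str, str]]
    mechanism_edges: dict[tuple[str, str], list[Triple]]
    contraindications: set[tuple[str, str]]
    congested_drugs: list[str] = field(default_factory=list)
    sparse_diseases: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "indications": sorted(list(p) for p in self.indications),
            "contraindications": sorted(list(p) for p in self.contraindications),
            "mechanism_edges": {
                f"{d}||{z}": [list(t.key()) for t in chain]
                for (d, z), chain in sorted(self.mechanism_edges.items())
            },
            "congested_drugs": self.congested_drugs,
            "sparse_diseases": self.sparse_diseases,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        payload = json.loads(text)
        mech = {}
        for key, chain in payload["mechanism_edges"].items():
            d, z = key.split("||")
            mech[(d, z)] = [Triple(*t) for t in chain]
        return cls(indications={tuple(p) for p in payload["indications"]},
                   mechanism_edges=mech,
                   contraindications={tuple(p) for p in payload["contraindications"]},
                   congested_drugs=payload.get("congested_drugs", []),
                   sparse_diseases=payload.get("sparse_diseases", []))


def _round_robin(items: list[str], n_bins: int) -> dict[str, int]:
    return {item: i % n_bins for i, item in enumerate(items)}


def generate(config: SynthConfig) -> tuple[KnowledgeGraph, PlantedTruth]:
    """Build the toy graph deterministically for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    drugs = [f"DRUG{i:04d}" for i in range(config.n_drugs)]
    proteins = [f"PROT{i:04d}" for i in range(config.n_proteins)]
    pathways = [f"PATH{i:04d}" for i in range(config.n_pathways)]
    diseases = [f"DIS{i:04d}" for i in range(config.n_diseases)]
    phenotypes = [f"PHEN{i:04d}" for i in range(config.n_phenotypes)]

    entities = ([Entity(d, "drug") for d in drugs]
                + [Entity(p, "protein") for p in proteins]
                + [Entity(p, "pathway") for p in pathways]
                + [Entity(d, "disease") for d in diseases]
                + [Entity(p, "phenotype") for p in phenotypes])

    K = max(1, config.n_pathways // max(1, config.pathways_per_community))
    pathway_comm = _round_robin(pathways, K)
    protein_comm = _round_robin(proteins, K)
    disease_comm = _round_robin(diseases, K)
    if config.communities_per_drug <= 1:
        drug_comms = {d: [i % K] for i, d in enumerate(drugs)}
    else:
        drug_comms = {d: sorted({i % K, (i // K + i + 1) % K})
                      for i, d in enumerate(drugs)}
    comm_pathways = {k: [p for p in pathways if pathway_comm[p] == k] for k in range(K)}
    comm_proteins = {k: [p for p in proteins if protein_comm[p] == k] for k in range(K)}
    comm_diseases = {k: [z for z in diseases if disease_comm[z] == k] for k in range(K)}

    edges: dict[tuple[str, str, str], Triple] = {}

    def add(h: str, r: str, t: str) -> Triple:
        tr = Triple(h, r, t)
        edges.setdefault(tr.key(), tr)
        return edges[tr.key()]

    # congested drugs are fixed up front so planting can cap them at one
    # indication (keeps the >=95% similarity dominance reachable)
    n_congested = int(np.ceil(config.congestion_drug_fraction * config.n_drugs))
    congested = drugs[:n_congested]
    congested_set = set(congested)

    # ---- planted indications with mechanism chains -----------------------
    candidate_pairs = []
    for d in drugs:
        for k in drug_comms[d]:
            for z in comm_diseases[k]:
                candidate_pairs.append((d, z, k))
    if config.n_planted_indications > len(candidate_pairs):
        raise SynthesisError("not enough community-compatible drug-disease pairs "
                             "for the requested planted indications")
    order = rng.permutation(len(candidate_pairs))
    indications: set[tuple[str, str]] = set()
    mechanism: dict[tuple[str, str], list[Triple]] = {}
    drug_indication_count: dict[str, int] = {}
    for i in order:
        d, z, k = candidate_pairs[int(i)]
        if (d, z) in indications:
            continue
        if d in congested_set and drug_indication_count.get(d, 0) >= 1:
            continue
        if not comm_proteins[k] or not comm_pathways[k]:
            continue
        prot = comm_proteins[k][int(rng.integers(len(comm_proteins[k])))]
        pw = comm_pathways[k][int(rng.integers(len(comm_pathways[k])))]
        chain = [add(d, "targets", prot),
                 add(prot, "participates", pw),
                 add(pw, "associated", z)]
        add(d, "indication", z)
        indications.add((d, z))
        drug_indication_count[d] = drug_indication_count.get(d, 0) + 1
        mechanism[(d, z)] = chain
        if len(indications) >= config.n_planted_indications:
            break
    if len(indications) < config.n_planted_indications:
        raise SynthesisError("could not plant the requested number of indications")

    # ---- contraindications: drug targets a pathway negatively marked -----
    contraindications: set[tuple[str, str]] = set()
    if config.n_planted_contraindications:
        attempts = 0
        while (len(contraindications) < config.n_planted_contraindications
               and attempts < 50 * config.n_planted_contraindications):
            attempts += 1
            d = drugs[int(rng.integers(len(drugs)))]
            # negatively-marked community: one the drug does NOT belong to
            neg = [k for k in range(K) if k not in drug_comms[d]]
            if not neg:
                continue
            k = neg[int(rng.integers(len(neg)))]
            if not comm_diseases[k]:
                continue
            z = comm_diseases[k][int(rng.integers(len(comm_diseases[k])))]
            if (d, z) in indications or (d, z) in contraindications:
                continue
            add(d, "contraindication", z)
            contraindications.add((d, z))

    # ---- intra-community drug-drug similarity edges ----------------------
    if config.intra_community_drug_drug:
        comm_drugs = {k: [d for d in drugs if k in drug_comms[d]] for k in range(K)}
        for d in drugs:
            pool = sorted({o for k in drug_comms[d] for o in comm_drugs[k]} - {d})
            if not pool:
                continue
            n_pick = min(config.intra_community_drug_drug, len(pool))
            picks = rng.choice(len(pool), size=n_pick, replace=False)
            for i in picks:
                o = pool[int(i)]
                a, b = (d, o) if d < o else (o, d)
                add(a, "drug_drug", b)

    # ---- community-correlated auxiliary structure ------------------------
    if config.n_off_label:
        placed = 0
        for i in rng.permutation(len(candidate_pairs)):
            if placed >= config.n_off_label:
                break
            d, z, k = candidate_pairs[int(i)]
            if (d, z) in indications or (d, "off_label", z) in edges:
                continue
            add(d, "off_label", z)
            placed += 1

    if config.extra_chains_per_drug:
        for d in drugs:
            for _ in range(config.extra_chains_per_drug):
                k = drug_comms[d][int(rng.integers(len(drug_comms[d])))]
                if not comm_proteins[k] or not comm_pathways[k]:
                    continue
                prot = comm_proteins[k][int(rng.integers(len(comm_proteins[k])))]
                pw = comm_pathways[k][int(rng.integers(len(comm_pathways[k])))]
                add(d, "targets", prot)
                add(prot, "participates", pw)

    if config.associate_all_diseases:
        for z in diseases:
            for pw in comm_pathways[disease_comm[z]]:
                add(pw, "associated", z)

    if config.phenotypes_per_disease and config.n_phenotypes:
        phen_comm = _round_robin(phenotypes, K)
        for z in diseases:
            k = disease_comm[z]
            pool = [p for p in phenotypes if phen_comm[p] == k]
            for _ in range(config.phenotypes_per_disease):
                if pool:
                    add(pool[int(rng.integers(len(pool)))], "phenotype_of", z)

    # ---- type-respecting noise edges ------------------------------------
    by_type = {"drug": drugs, "protein": proteins, "pathway": pathways,
               "disease": diseases, "phenotype": phenotypes}
    if config.noise_edge_rate > 0:
        all_ids = drugs + proteins + pathways + diseases + phenotypes
        node_type = {e.id: e.type for e in entities}
        # therapeutic relations carry the supervision signal, and the
        # mechanism-chain relations (targets/participates/associated) stay
        # signal-only so noise cannot fabricate cross-community chains;
        # noise lives on similarity, off-label and phenotype edges
        noise_relations = ("drug_drug", "off_label", "phenotype_of")
        for node in all_ids:
            n_new = int(rng.poisson(config.noise_edge_rate))
            for _ in range(n_new):
                ntype = node_type[node]
                compat = [r for r in noise_relations
                          if RELATION_SCHEMA[r][0] == ntype
                          or RELATION_SCHEMA[r][1] == ntype]
                if not compat:
                    break
                rel = compat[int(rng.integers(len(compat)))]
                ht, tt = RELATION_SCHEMA[rel]
                if ht == ntype:
                    pool = by_type[tt]
                    other = pool[int(rng.integers(len(pool)))]
                    h, t = node, other
                else:
                    pool = by_type[ht]
                    other = pool[int(rng.integers(len(pool)))]
                    h, t = other, node
                if h == t:
                    continue
                if rel in ("indication", "contraindication") and (
                        (h, t) in indications or (h, t) in contraindications):
                    continue
                add(h, rel, t)

    protected = {t.key() for chain in mechanism.values() for t in chain}
    protected |= {(d, "indication", z) for d, z in indications}
    protected |= {(d, "contraindication", z) for d, z in contraindications}

    # ---- congestion pathology -------------------------------------------
    for d in congested:
        # drop the drug's non-protected, non-similarity edges (noise), then
        # add similarity edges until dominance is reached
        for key in [k for k in list(edges)
                    if d in (k[0], k[2]) and k[1] != "drug_drug"
                    and k not in protected]:
            edges.pop(key)
        incident = [t for t in edges.values() if d in (t.head, t.tail)]
        n_sim = sum(1 for t in incident if t.relation == "drug_drug")
        n_other = len(incident) - n_sim
        target = int(np.ceil(CONGESTION_DOMINANCE / (1 - CONGESTION_DOMINANCE)
                             * max(n_other, 1)))
        pool = [o for o in drugs if o != d]
        rng.shuffle(pool)
        for o in pool:
            if n_sim >= target:
                break
            a, b = (d, o) if d < o else (o, d)
            if (a, "drug_drug", b) not in edges:
                add(a, "drug_drug", b)
                n_sim += 1
        if n_sim < target:
            raise SynthesisError(
                f"cannot reach {CONGESTION_DOMINANCE:.0%} similarity dominance "
                f"for {d}: needs {target} partners, only {len(pool)} drugs exist")

    # ---- sparsity pathology ---------------------------------------------
    n_sparse = int(np.ceil(config.sparse_disease_fraction * config.n_diseases))
    # prefer non-planted diseases so mechanism chains stay intact
    planted_diseases = {z for _, z in indications} | {z for _, z in contraindications}
    spare_order = ([z for z in reversed(diseases) if z not in planted_diseases]
                   + [z for z in reversed(diseases) if z in planted_diseases])
    sparse = sorted(spare_order[:n_sparse])
    for z in sparse:
        incident = sorted(t.key() for t in edges.values() if z in (t.head, t.tail))
        removable = [k for k in incident if k not in protected]
        excess = len(incident) - SPARSE_MAX_CONNECTIONS
        if excess > 0:
            drop = rng.permutation(len(removable))[:excess]
            for i in drop:
                edges.pop(removable[int(i)], None)

    kg = KnowledgeGraph(entities, [edges[k] for k in sorted(edges)])
    truth = PlantedTruth(indications, mechanism, contraindications,
                         congested_drugs=list(congested),
                         sparse_diseases=list(sparse))
    return kg, truth


def negative_truth(truth: PlantedTruth, kg: KnowledgeGraph, n: int,
                   seed: int = 0) -> set[tuple[str, str]]:
    """Sample ``n`` (drug, disease) pairs disjoint from planted indications."""
    drugs = kg.entities_of_type("drug")
    diseases = kg.entities_of_type("disease")
    candidates = [(d, z) for d in drugs for z in diseases
                  if (d, z) not in truth.indications]
    if n > len(candidates):
        raise SynthesisError(f"requested {n} negatives but only "
                             f"{len(candidates)} non-positive pairs exist")
    if n == 0:
        return set()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    picks = rng.choice(len(candidates), size=n, replace=False)
    return {candidates[int(i)] for i in picks}
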