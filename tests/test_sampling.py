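import numpy as np
import pytest
from scipy import stats

from comic.benchmarks import zero_noise_synth_config
from comic.kg_core import Triple
from comic.sampling import (
    Path,
    PathStep,
    SamplingError,
    corrupt_paths,
    degree_hard_negatives,
    random_fixed_dest_negatives,
    relation_slot_pools,
    sample_paths,
)
from comic.synthetic_kg import generate

from conftest import make_kg


def chain_kg(n=4):
    """A single directed chain n0 -r-> n1 -r-> ... with distinct types."""
    types = ["drug", "protein", "pathway", "disease", "phenotype"]
    rows = []
    rels = ["targets", "participates", "associated", "phenotype_of"]
    for i in range(n):
        rows.append((f"n{i}", types[i], rels[i % len(rels)],
                     f"n{i+1}", types[i + 1]))
    return make_kg(rows)


@pytest.fixture
def degree_kg():
    """Indication heads {A: degree 3, B: 1, Q: 1}; degree boosted through
    similarity edges to drugs outside the head pool."""
    rows = [
        ("A", "drug", "indication", "X", "disease"),
        ("B", "drug", "indication", "X2", "disease"),
        ("Q", "drug", "indication", "Y", "disease"),
        ("A", "drug", "drug_drug", "C2", "drug"),
        ("A", "drug", "drug_drug", "C3", "drug"),
    ]
    return make_kg(rows)


class TestDegreeHardNegatives:
    def test_proportionality_10k_draws(self, degree_kg):
        """Empirical head-replacement frequency ~ degree proportional."""
        t = Triple("Q", "indication", "Y")
        batch = [t] * 10_000
        nb = degree_hard_negatives(batch, degree_kg, seed=0, positives=set())
        # head pool {A,B,Q} with degrees {3,1,1}; identity Q rejected ->
        # P(A)=0.75, P(B)=0.25 among head corruptions
        heads = [n.head for n in nb.triples if n.head in ("A", "B")]
        freq_a = heads.count("A") / len(heads)
        assert 0.73 <= freq_a <= 0.77

    def test_uniform_when_degrees_equal(self):
        rows = [(f"d{i}", "drug", "indication", f"z{i}", "disease")
                for i in range(4)]
        kg = make_kg(rows)
        t = Triple("d0", "indication", "z0")
        nb = degree_hard_negatives([t] * 4000, kg, seed=1, positives=set())
        tails = [n.tail for n in nb.triples if n.tail != "z0"]
        freqs = np.array([tails.count(f"z{i}") / len(tails)
                          for i in range(1, 4)])
        assert np.all(np.abs(freqs - 1 / 3) < 0.05)

    def test_chi_square_against_exact(self, degree_kg):
        """10^4 draws vs exact probabilities, p > 0.001 across 5 seeds."""
        t = Triple("Q", "indication", "Y")
        # per attempt: coin 0.5 head/tail, degree-proportional draw, retry
        # (with a fresh coin) when the identity entity comes up.
        # head pool degrees {A:3, B:1, Q:1}; tail pool {X:1, X2:1, Y:1}.
        per_attempt = np.array([0.5 * 3 / 5, 0.5 * 1 / 5,   # A, B
                                0.5 * 1 / 3, 0.5 * 1 / 3])  # X, X2
        outcomes = ["A", "B", "X", "X2"]
        exact = per_attempt / per_attempt.sum()
        for seed in range(5):
            nb = degree_hard_negatives([t] * 10_000, degree_kg, seed=seed,
                                       positives=set())
            counts = np.zeros(4)
            for n in nb.triples:
                repl = n.head if n.head != "Q" else n.tail
                counts[outcomes.index(repl)] += 1
            p = stats.chisquare(counts, exact * counts.sum()).pvalue
            assert p > 0.001

    def test_filters_known_positives(self, degree_kg):
        positives = {t.key() for t in degree_kg.triples}
        batch = [t for t in degree_kg.triples
                 if t.relation == "indication"] * 20
        nb = degree_hard_negatives(batch, degree_kg, seed=2,
                                   positives=positives)
        assert all(n.key() not in positives for n in nb.triples)

    def test_no_candidate_error(self):
        kg = make_kg([("A", "drug", "indication", "X", "disease")])
        # pool only holds the original entities -> identity always rejected
        with pytest.raises(SamplingError):
            degree_hard_negatives([Triple("A", "indication", "X")], kg,
                                  seed=0, positives=set())


class TestRandomFixedDestNegatives:
    def test_tails_preserved(self, degree_kg):
        batch = [t for t in degree_kg.triples if t.relation == "indication"]
        nb = random_fixed_dest_negatives(batch, degree_kg, epoch=0, seed=0,
                                         positives=set())
        assert [n.tail for n in nb.triples] == [t.tail for t in batch]

    def test_epochs_differ(self, degree_kg):
        batch = [Triple("B", "indication", "Y")] * 30
        a = random_fixed_dest_negatives(batch, degree_kg, epoch=1, seed=5,
                                        positives=set())
        b = random_fixed_dest_negatives(batch, degree_kg, epoch=2, seed=5,
                                        positives=set())
        assert [t.head for t in a.triples] != [t.head for t in b.triples]

    def test_disjoint_from_positives(self, degree_kg):
        positives = {t.key() for t in degree_kg.triples}
        batch = [t for t in degree_kg.triples if t.relation == "indication"]
        nb = random_fixed_dest_negatives(batch * 30, degree_kg, epoch=0,
                                         seed=1, positives=positives)
        assert all(n.key() not in positives for n in nb.triples)


class TestSamplePaths:
    def test_unique_route_graph_yields_one_path(self):
        kg = chain_kg(3)
        pset = sample_paths(kg, "n0", "n3", max_paths=5, max_attempts=100,
                            seed=0)
        assert len(pset.true_paths) == 1
        path = pset.true_paths[0]
        assert path.nodes == ("n0", "n1", "n2", "n3")
        assert all(s.forward for s in path.steps)

    def test_unreachable_pair_returns_empty(self):
        kg = make_kg([("a", "drug", "targets", "b", "protein"),
                      ("c", "drug", "targets", "d", "protein")])
        pset = sample_paths(kg, "a", "d", seed=0)
        assert pset.true_paths == []

    def test_same_head_tail_rejected(self, tiny_kg):
        with pytest.raises(SamplingError):
            sample_paths(tiny_kg, "d1", "d1")

    def test_paths_are_connected_chains(self, tiny_kg):
        pset = sample_paths(tiny_kg, "d2", "z1", seed=3, max_attempts=200)
        for p in pset.true_paths:
            for s1, s2 in zip(p.steps, p.steps[1:]):
                assert s1.tail == s2.head
            for s in p.steps:
                assert tiny_kg.has_triple(s.triple())

    def test_diversity_constraint_exhaustive(self):
        kg, truth = generate(zero_noise_synth_config(0, n_pairs=10))
        for d, z in sorted(truth.indications)[:5]:
            pset = sample_paths(kg, d, z, seed=7, max_attempts=300)
            paths = pset.true_paths
            for i, p in enumerate(paths):
                for q in paths[:i]:
                    assert p.overlap_with(q) < 0.5

    def test_excluded_edges_not_traversed(self, tiny_kg):
        pset = sample_paths(tiny_kg, "d1", "z1", seed=1, max_attempts=300,
                            exclude_edges=[("d1", "indication", "z1")])
        assert pset.true_paths
        for p in pset.true_paths:
            assert ("d1", "indication", "z1") not in p.edge_keys

    def test_deterministic(self, tiny_kg):
        a = sample_paths(tiny_kg, "d2", "z1", seed=9)
        b = sample_paths(tiny_kg, "d2", "z1", seed=9)
        assert [p.steps for p in a.true_paths] == [p.steps for p in b.true_paths]

    def test_zero_noise_chain_recovery_rate(self):
        """The planted chain is recovered in >=95% of 100 seeded trials."""
        kg, truth = generate(zero_noise_synth_config(1, n_pairs=8))
        (d, z) = sorted(truth.indications)[0]
        chain_keys = frozenset(t.key() for t in truth.mechanism_edges[(d, z)])
        hits = 0
        for seed in range(100):
            pset = sample_paths(kg, d, z, seed=seed, max_attempts=200)
            hits += any(p.edge_keys == chain_keys for p in pset.true_paths)
        assert hits >= 95


class TestPathOverlap:
    def _path_from_edges(self, edges):
        return Path(tuple(PathStep(h, r, t, True) for h, r, t in edges))

    def test_overlap_three_of_five_rejected_rule(self):
        base = [(f"a{i}", "targets", f"a{i+1}") for i in range(5)]
        cand = base[:3] + [("x", "targets", "y"), ("y", "targets", "z")]
        p = self._path_from_edges(cand)
        q = self._path_from_edges(base)
        assert p.overlap_with(q) == pytest.approx(0.6)
        assert not p.overlap_with(q) < 0.5

    def test_overlap_two_of_five_accepted_rule(self):
        base = [(f"a{i}", "targets", f"a{i+1}") for i in range(5)]
        cand = base[:2] + [(f"x{i}", "targets", f"x{i+1}") for i in range(3)]
        p = self._path_from_edges(cand)
        q = self._path_from_edges(base)
        assert p.overlap_with(q) == pytest.approx(0.4)
        assert p.overlap_with(q) < 0.5


def rich_kg():
    rows = [("d1", "drug", "targets", f"p{i}", "protein") for i in range(1, 5)]
    rows += [(f"p{i}", "protein", "participates", f"w{i}", "pathway")
             for i in range(1, 5)]
    rows += [("d2", "drug", "drug_drug", "d1", "drug")]
    return make_kg(rows)


class TestCorruptPaths:
    def test_emits_exactly_five_with_prefix(self):
        kg = rich_kg()
        path = Path((PathStep("d2", "drug_drug", "d1", True),
                     PathStep("d1", "targets", "p1", True),
                     PathStep("p1", "participates", "w1", True)))
        false = corrupt_paths(path, kg, n=5, seed=0)
        assert len(false) == 5
        for fp in false:
            assert fp.nodes[:-2] == path.nodes[:-2]
            assert fp.steps != path.steps
            assert [s.relation for s in fp.steps] == \
                [s.relation for s in path.steps]

    def test_single_step_path_corrupts_terminal_only(self):
        path = Path((PathStep("d1", "targets", "p1", True),))
        false = corrupt_paths(path, rich_kg(), n=5, seed=1)
        for fp in false:
            assert fp.steps[0].head == "d1"
            assert fp.steps != path.steps

    def test_deterministic(self):
        kg = rich_kg()
        path = Path((PathStep("d1", "targets", "p1", True),
                     PathStep("p1", "participates", "w1", True)))
        a = corrupt_paths(path, kg, n=5, seed=4)
        b = corrupt_paths(path, kg, n=5, seed=4)
        assert [p.steps for p in a] == [p.steps for p in b]


def test_relation_slot_pools(tiny_kg):
    pools = relation_slot_pools(tiny_kg)
    assert pools["indication"] == (["d1"], ["z1"])
    assert pools["targets"] == (["d1"], ["p1"])
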