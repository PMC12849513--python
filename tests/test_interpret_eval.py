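import numpy as np
import pytest

from comic.benchmarks import zero_noise_synth_config
from comic.interpret_eval import (
    EdgeImportance,
    Explanation,
    accuracy,
    auprc,
    edge_importance,
    explain_pair,
    faithfulness_curve,
    path_evidence,
    rank_percentile,
    score_pairs,
)
from comic.kg_core import Triple, random_split
from comic.synthetic_kg import generate
from comic.training import ComicModel, TrainingConfig

from conftest import make_kg


def stepwise_auprc_oracle(scores, labels):
    """Independent step-wise PR construction (ties = one threshold)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    ap, tp, fp = 0.0, 0, 0
    prev_recall = 0.0
    for s in sorted(set(scores), reverse=True):
        sel = scores == s
        tp += int(labels[sel].sum())
        fp += int((~labels[sel].astype(bool)).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestAUPRC:
    def test_perfect_separation(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        labels = [1, 0, 0, 0, 1]
        assert auprc([0.5] * 5, labels) == pytest.approx(2 / 5)

    def test_three_point_hand_construction(self):
        # ranked: 0.9 (pos), 0.8 (neg), 0.3 (pos)
        # AP = 0.5*1 + 0.5*(2/3) = 5/6
        assert auprc([0.9, 0.8, 0.3], [1, 0, 1]) == pytest.approx(5 / 6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auprc([0.1, 0.2], [1, 1])

    def test_agrees_with_stepwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            scores = rng.choice(np.round(rng.random(8), 3), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auprc(scores, labels) == pytest.approx(
                stepwise_auprc_oracle(scores, labels), abs=1e-9)


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy([0.9, 0.1], [1, 0]) == 1.0

    def test_all_wrong(self):
        assert accuracy([0.4, 0.6], [1, 0]) == 0.0

    def test_balanced_random_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, size=10_000)
        # binomial 3-sigma band around 0.5
        assert abs(accuracy(scores, labels) - 0.5) < 3 * 0.5 / 100

    def test_threshold(self):
        assert accuracy([0.4], [1], threshold=0.3) == 1.0


class TestRankPercentile:
    def test_highest_of_eleven(self):
        scores = np.linspace(0, 1, 11)
        assert rank_percentile(1.0, scores) == pytest.approx(100.0)

    def test_lowest(self):
        scores = np.linspace(0, 1, 11)
        assert rank_percentile(0.0, scores) == pytest.approx(0.0)

    def test_midpoint_of_21(self):
        scores = np.linspace(0, 1, 21)
        assert rank_percentile(scores[10], scores) == pytest.approx(50.0)

    def test_ties_count_half(self):
        assert rank_percentile(0.5, [0.5, 0.5, 0.1]) == pytest.approx(
            100 * (1 + 0.5) / 2)

    def test_too_few_candidates(self):
        with pytest.raises(ValueError):
            rank_percentile(0.5, [0.5])


@pytest.fixture(scope="module")
def zero_model():
    """Untrained model over the zero-noise fixture (scoring mechanics only)."""
    kg, truth = generate(zero_noise_synth_config(3, n_pairs=8))
    model = ComicModel(kg, dim=16, seed=3)
    cfg = TrainingConfig(dim=16, seed=3)
    return kg, truth, model, cfg


class TestEdgeImportance:
    def test_unscored_edges_zero(self, zero_model):
        kg, truth, model, cfg = zero_model
        (d, z) = sorted(truth.indications)[0]
        imp = edge_importance(model, kg, [(d, z)], cfg, seed=0)
        assert set(imp.scores) == {t.key() for t in kg.triples}
        chain = {t.key() for t in truth.mechanism_edges[(d, z)]}
        untouched = [k for k, v in imp.scores.items()
                     if k not in chain and k != (d, "indication", z)]
        assert all(imp.scores[k] == 0.0 for k in untouched)

    def test_single_path_edges_share_score(self, zero_model):
        kg, truth, model, cfg = zero_model
        (d, z) = sorted(truth.indications)[0]
        imp = edge_importance(model, kg, [(d, z)], cfg, seed=0)
        chain_scores = {imp.scores[t.key()]
                        for t in truth.mechanism_edges[(d, z)]}
        assert len(chain_scores) == 1
        assert chain_scores.pop() > 0

    def test_ranked_edges_sorted(self, zero_model):
        kg, truth, model, cfg = zero_model
        imp = edge_importance(model, kg, sorted(truth.indications)[:3],
                              cfg, seed=0)
        ranked = imp.ranked_edges()
        vals = [imp.scores[k] for k in ranked]
        assert vals == sorted(vals, reverse=True)

    def test_unknown_aggregator(self, zero_model):
        kg, truth, model, cfg = zero_model
        with pytest.raises(ValueError):
            edge_importance(model, kg, [], cfg, aggregator="median")


class TestFaithfulnessCurve:
    def _setup(self, zero_model):
        kg, truth, model, cfg = zero_model
        pos = sorted(truth.indications)[:4]
        neg = [(d, z2) for (d, _), (_, z2)
               in zip(pos, sorted(truth.indications)[4:8])]
        pairs = pos + neg
        labels = [1] * 4 + [0] * 4
        imp = edge_importance(model, kg, pos, cfg, seed=0)
        return kg, model, cfg, pairs, labels, imp

    def test_deletion_at_zero_equals_full_graph(self, zero_model):
        kg, model, cfg, pairs, labels, imp = self._setup(zero_model)
        full = auprc(score_pairs(model, kg, pairs, cfg, seed=0), labels)
        curve = faithfulness_curve(model, kg, pairs, labels, imp, "deletion",
                                   K_values=[0, 50], cfg=cfg, seed=0)
        assert curve.auprc_values[0] == pytest.approx(full, abs=1e-12)

    def test_insertion_at_hundred_equals_full_graph(self, zero_model):
        kg, model, cfg, pairs, labels, imp = self._setup(zero_model)
        full = auprc(score_pairs(model, kg, pairs, cfg, seed=0), labels)
        curve = faithfulness_curve(model, kg, pairs, labels, imp, "insertion",
                                   K_values=[50, 100], cfg=cfg, seed=0)
        assert curve.auprc_values[-1] == pytest.approx(full, abs=1e-12)

    def test_invalid_k_rejected(self, zero_model):
        kg, model, cfg, pairs, labels, imp = self._setup(zero_model)
        with pytest.raises(ValueError):
            faithfulness_curve(model, kg, pairs, labels, imp, "deletion",
                               K_values=[-5, 10], cfg=cfg)
        with pytest.raises(ValueError):
            faithfulness_curve(model, kg, pairs, labels, imp, "insertion",
                               K_values=[10, 120], cfg=cfg)
        with pytest.raises(ValueError):
            faithfulness_curve(model, kg, pairs, labels, imp, "sideways",
                               K_values=[10], cfg=cfg)

    def test_curve_csv(self, zero_model, tmp_path):
        kg, model, cfg, pairs, labels, imp = self._setup(zero_model)
        curve = faithfulness_curve(model, kg, pairs, labels, imp, "deletion",
                                   K_values=[0, 50], cfg=cfg, seed=0)
        out = tmp_path / "curve.csv"
        curve.to_csv(str(out))
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "K,auprc"
        assert len(lines) == 3


class TestExplainPair:
    def test_unreachable_pair_empty_paths(self):
        kg = make_kg([("d1", "drug", "targets", "p1", "protein"),
                      ("d2", "drug", "indication", "z1", "disease")])
        model = ComicModel(kg, dim=16, seed=0)
        exp = explain_pair(model, kg, "d1", "z1")
        assert exp.paths == []
        assert 0 < exp.score < 1
        assert len(exp.features) > 0

    def test_json_round_trip(self, zero_model):
        kg, truth, model, cfg = zero_model
        (d, z) = sorted(truth.indications)[0]
        exp = explain_pair(model, kg, d, z, cfg=cfg, seed=0)
        again = Explanation.from_json(exp.to_json())
        assert again == exp

    def test_unknown_entity(self, zero_model):
        kg, truth, model, cfg = zero_model
        with pytest.raises(KeyError):
            explain_pair(model, kg, "nope", "alsono")

    def test_paths_sorted_by_score(self, zero_model):
        kg, truth, model, cfg = zero_model
        (d, z) = sorted(truth.indications)[0]
        exp = explain_pair(model, kg, d, z, cfg=cfg, seed=0)
        scores = [p["score"] for p in exp.paths]
        assert scores == sorted(scores, reverse=True)


class TestPathEvidence:
    def test_no_paths_gives_zero(self):
        kg = make_kg([("d1", "drug", "targets", "p1", "protein"),
                      ("d2", "drug", "indication", "z1", "disease")])
        model = ComicModel(kg, dim=16, seed=0)
        ev, scored = path_evidence(model, kg, "d1", "z1", TrainingConfig(dim=16))
        assert ev == 0.0 and scored == []

    def test_direct_edge_excluded_by_default(self, zero_model):
        kg, truth, model, cfg = zero_model
        (d, z) = sorted(truth.indications)[0]
        _, scored = path_evidence(model, kg, d, z, cfg, seed=0)
        for path, _, _ in scored:
            assert (d, "indication", z) not in path.edge_keys
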