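# comic-kg

Interpretable drug-repurposing link prediction over typed biomedical
knowledge graphs. The predictor couples two branches:

* a **feature-masking branch** — a position-aware self-attention encoder
  over (head, relation, tail) embedding triples, filtered through a
  learnable contrastive mask (information-bottleneck style) and classified
  by a GELU MLP;
* a **path-masking branch** — diversity-constrained random-walk paths
  between drug and disease, encoded with self-attention, filtered through
  an independent contrastive mask, and trained with InfoNCE losses against
  corrupted ("false") paths.

Both branches are trained jointly:
`L_total = L_BCE + beta2 * (L_triple + L_path)` where each branch loss is
`-I_NCE(Z;Y) + beta * I_NCE(X;Z)`. The learned masks expose edge-level
importances that are validated with insertion/deletion faithfulness
curves, and per-pair explanations surface the ranked mechanistic paths.

The whole model stack (attention encoders, gates, bilinear critics, Adam,
gradient clipping) runs on a small reverse-mode autodiff engine over NumPy
(`comic.nn`) — no deep-learning framework is required.

## Layout

| module | role |
|---|---|
| `comic.kg_core` | typed edge-list I/O, graph model, disease-area/random splits, connection profiles |
| `comic.synthetic_kg` | toy KG generator with planted mechanism chains and structural pathologies |
| `comic.encoders` | embedding tables, triple encoder, path encoder |
| `comic.contrastive_masking` | mask gate, InfoNCE estimator, branch losses |
| `comic.sampling` | degree-hard / fixed-destination negatives, random-walk path sampling, path corruption |
| `comic.training` | classifier head, loss assembly, optimization loop |
| `comic.interpret_eval` | AUPRC/accuracy/percentiles, edge importance, faithfulness curves, explanations |
| `comic.benchmarks` | canonical toy fixtures and end-to-end benchmark runners |
| `comic.cli` | `comic` command-line entry point |

## CLI

All commands accept `--seed`; every run writes a `manifest.json` next to
its outputs.

```bash
comic simulate --config synth.yaml --seed 1 --out toy/
comic split --kg toy/edges.tsv --mode disease_area --area-file diseases.txt --seed 1 --out splits/
comic train --kg toy/edges.tsv --split splits/ --config train.yaml --seed 1 --out run1/
comic predict --kg toy/edges.tsv --model run1/ --pair DRUG0001:DIS0003
comic explain --kg toy/edges.tsv --model run1/ --pair DRUG0001:DIS0003
comic paths --kg toy/edges.tsv --pair DRUG0001:DIS0003 --seed 1
comic faithfulness --kg toy/edges.tsv --model run1/ --split splits/ --mode deletion --out curve.csv
comic profile --kg toy/edges.tsv --entity DRUG0001
```

Edge lists are 5-column TSV: `head_id  head_type  relation  tail_id
tail_type` with an optional `#` header. YAML configs mirror the
`SynthConfig` / `TrainingConfig` field names.

## Published vs. toy-scale settings

`TrainingConfig()` defaults follow the published recipe (Adam lr 5e-4,
batch 1024, ≤30 epochs, temperature annealed 1.0→0.1, beta 0.1, beta2 0.2,
clip 1.0, patience 2). The full-scale evaluation substrate (a 4M-edge
precision-medicine graph) is far outside a desk-scale CI budget, so the
test suite and benchmarks run on synthetic fixtures (~300 entities) with
optimization settings calibrated for that scale
(`comic.benchmarks.toy_training_config`). Headline numbers from the
original large-scale study are therefore not reproduced here; acceptance
is property-based (see `tests/test_acceptance.py`).

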