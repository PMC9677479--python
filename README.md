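# kgfuse

Ensembles of knowledge-graph-embedding (KGE) scores for drug–disease link
prediction.

## The problem

Knowledge-graph embedding models learn vector representations of the
entities (drugs, proteins, diseases) and relations of a biomedical knowledge
graph, and score the plausibility of unseen triples such as
*(drug, treats, disease)*. In a drug-discovery setting only a handful of
top-ranked predictions can ever be validated experimentally, so what matters
is **Precision@K** — the fraction of the top K predicted drug–disease pairs
that are genuinely positive — rather than global ranking metrics. Individual
KGE models disagree wildly: each interaction function (translational,
bilinear, complex-rotational, ...) produces its own score distribution on its
own scale, and two well-trained models can emit nearly disjoint top lists.
Empirically, though, what different models *do* agree on is far more often
correct than not: the cross-model overlap among true positives dwarfs the
overlap among false positives. kgfuse operationalizes that observation.

## The method

For each model *m* with raw scores `s_m` over the candidate drug × disease
space (all pairs not already present in the training or validation graph):

1. **Threshold** — keep only the top fraction of each model's predictions,
   e.g. the 99th percentile, retaining `k = ⌊N·0.01⌋` pairs.
2. **Normalize within the retained set** onto [0, 1]:
   min–max `x ↦ (x − min)/(max − min)`; sigmoid `x ↦ σ((x − μ)/σ_pop)`; or
   rank `r ↦ (k − r)/(k − 1)`. Normalizing only the retained tail keeps the
   fine distinctions among confident predictions instead of flattening them
   against the bulk of the distribution.
3. **Aggregate** across models. The baseline is *sum aggregation*:
   `S(d, z) = Σ_m ŝ_m(d, z)`, with a pair absent from model *m*'s retained
   top-K contributing 0 — pairs retained by several models accumulate score,
   which is exactly the consensus signal. Variants: averages (over all
   members, or over supporting members only), a product of experts
   (`Σ_m log softmax_m`) over the full candidate space, and a position
   (rank-sum) ensemble. Member sets: *ensemble-all* (every model) or
   *ensemble-top5* (the five best by validation Precision@100).
4. **Evaluate** with Precision@K against held-out test edges, pairwise
   top-K TP/FP agreement matrices, and score–degree correlation.

The package also ships lightweight trainable scorers for four classic
interaction functions (TransE, DistMult, ComplEx, RotatE; pure numpy with
analytic gradients), TSV/JSON knowledge-graph I/O with the 80/10/10
drug–disease split (validation/test are drug–disease-only), and a synthetic
generator for both toy knowledge graphs and multi-model score tables with
controllable per-model precision and cross-model agreement — so the whole
pipeline is testable at desk scale. External per-model score tables (e.g.
from PyKEEN-trained models) can be supplied as TSV; the ensemble layer is
agnostic to where scores come from.

## Worked example

`examples/02_ensemble_vs_individual.py` builds the default synthetic
committee — 10 models over 100,000 candidate pairs with 500 planted
positives, per-model Precision@100 targets spread over 0.10–0.60, and
agreement 0.5 on true positives vs 0.05 on false positives — then thresholds
each model's top 0.1%, min–max normalizes, and sum-aggregates:

```
Individual models (Precision@10 / Precision@100):
  model_00: 0.40 / 0.14
  ...
  model_09: 0.80 / 0.63

Best individual Precision@100: 0.63
ensemble-all : P@10 1.00, P@100 0.67
ensemble-top5 (model_09, model_08, model_07, model_06, model_05):
               P@10 1.00, P@100 0.74
```

The ensembles beat the best single model even though half their members are
poor, because summing normalized scores weights up the pairs that several
models retained — and those are disproportionately true positives.
`examples/03_model_agreement.py` prints the corresponding agreement
matrices (mean pairwise TP overlap ≈ 8.4 pairs at K=100 versus ≈ 0.2 for
FPs); `examples/01_normalize_scores.py` and `examples/04_toy_kg_pipeline.py`
cover normalization and the full train-from-a-KG pipeline.

A CLI mirrors the library stage by stage:

```bash
kgfuse pipeline --seed 7 --out runs/demo          # full synthetic run
kgfuse normalize --scores scores.tsv --percentile 99 --method minmax --out topk.tsv
kgfuse ensemble --topk topk.tsv --agg sum --percentile 99 --out ranking.tsv
kgfuse evaluate --ranking ranking.tsv --test test.tsv --k 1,5,10,100 --out report.json
```

Every stage writes a JSON manifest with its parameters and artifact content
hashes; identical inputs reproduce identical hashes.

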