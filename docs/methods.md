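# Methods

This note records the models, conventions and design choices behind kgfuse,
in the order the pipeline runs them.

## Knowledge-graph model and splitting

A knowledge graph is a set of directed `(head, relation, tail)` triples over
entities typed `drug`, `protein` or `disease`; types live in a separate
two-column TSV because common triple-file dialects do not encode them.
Identifiers are opaque case-sensitive strings — no CURIE or vocabulary
normalization is attempted. `reduce_schema` restricts a heterogeneous graph
to triples whose endpoints both carry a kept type, optionally whitelisting
relation labels (e.g. keeping only causal protein–protein relations); it is
idempotent and prunes the type map to surviving entities.

`split_drug_disease` partitions the drug→disease triples with a seeded
uniform permutation applied to the lexicographically sorted triple list, so
splits are platform-independent and byte-reproducible. Sizes follow a floor
rule: `|test| = ⌊N·f_test⌋`, `|validation| = ⌊N·f_valid⌋`, train takes the
remainder plus every non-drug–disease triple. (For 52,060 drug–disease
triples at 0.8/0.1/0.1 this gives 41,648/5,206/5,206; the floor convention
is ours — other roundings are equally defensible and will differ by ±1 on
sizes not divisible by the ratios.) Inverse triples are never added: the
treats relation is directed.

The candidate space defaults to `{test drugs} × {test diseases}` minus every
pair already asserted in train ∪ validation, ordered by (drug, disease);
`scope="all_entities"` widens it to all typed drugs and diseases. Candidate
purity (no overlap with seen pairs) holds by construction and is tested
exhaustively on fixtures.

## Lightweight embedding models

Four interaction functions span the two main modelling paradigms:

| interaction | score (higher = more plausible) | parameters |
|---|---|---|
| TransE | −‖h + r − t‖₂ | real vectors |
| DistMult | Σᵢ hᵢ rᵢ tᵢ | real vectors |
| ComplEx | Re(Σᵢ hᵢ rᵢ conj(tᵢ)) | complex vectors |
| RotatE | −‖h ∘ r − t‖₂ | complex entities, unit-modulus relations |

Distance-based scores are negated internally so *every* interaction is
oriented higher-is-better; downstream code never needs to know the family.
Training is minibatch SGD on the margin ranking loss
`max(0, γ − s_pos + s_neg)` with analytic gradients written in numpy. For
complex parameters the gradient is stored as `∂/∂Re + i·∂/∂Im`, so a plain
complex-array update moves both components; RotatE relations are
parametrized by phase, keeping the unit-modulus constraint exact throughout
training rather than re-projecting. All gradients are verified against
central finite differences in the test suite.

Negative sampling is type-aware: a corrupted head is drawn uniformly from
entities of the head's type and a corrupted tail from the tail's type
(resampled until distinct from the original), which keeps toy-scale training
meaningful — corrupting a drug into a protein would be trivially
distinguishable. Defaults (margin γ=2, 10 negatives per positive, learning
rate 1.0 with per-term mean reduction, batch 64, 150 epochs, dimension 64
for the toy benchmark) were selected by a small sweep on the blocked
synthetic graph below, targeting reliable learning for all four
interactions; RotatE in particular needed the larger dimension to clear the
random-rank baseline consistently. Per-model hyperparameter optimization is
deliberately out of scope — these scorers exist to exercise the ensemble
machinery end-to-end, not to reproduce tuned large-scale benchmarks, and
externally produced score tables can be substituted via TSV at the ensemble
boundary.

## Thresholding and normalization

`threshold_top_percentile` keeps exactly `k = ⌊N·(100 − p)/100⌋` pairs (a
tiny epsilon guards the float product against artifacts like
`(100 − 99.9)/100` rounding below the exact fraction; percentile 99 over
1,350,266 candidates retains 13,502). Ties at the boundary are broken by
(score desc, drug asc, disease asc) — deterministic across platforms. A
threshold that would retain zero pairs is an error rather than a silent
no-op.

Normalization happens strictly *within* the retained set, never over the
full distribution (the product-of-experts comparator is the one deliberate
exception). Three monotone maps are provided: min–max; sigmoid, concretized
as z-standardization with the population standard deviation followed by the
logistic (so the retained-set mean lands exactly on 0.5 — the "S-shaped"
family leaves the exact form open, and this is our choice); and rank, i.e.
min–max on ranks giving uniform spacing `1/(k−1)` with best ↦ 1. Degenerate
all-equal inputs map to 0.5 with a warning instead of erroring, so pipelines
survive pathological toy inputs.

## Ensemble aggregation

Members of an ensemble must share percentile and normalization method;
heterogeneous mixtures are rejected rather than silently coerced. The
baseline is sum aggregation with absence-as-zero. Two average variants
exist because "average" is genuinely ambiguous here: `avg_zero` divides the
sum by the number of member models (order-equivalent to the sum — asserted
as a regression test) while `avg_present` divides by the number of
supporting members, which removes the consensus weighting and can invert
orderings (a pair at {0.9, 0.2} averages 0.55 and loses to a lone 1.0 that
the sum would beat). Both are reported by the comparison harness; neither is
privileged.

The product of experts maps each model's *full* candidate-space scores to a
probability distribution by softmax and sums log-probabilities
(monotone-equivalent to the product); softmax-then-log is the standard PoE
reading and is our concretization. The position ensemble is sum aggregation
constrained to rank-normalized members. Ensemble ties break by
(score desc, supporting-model count desc, drug, disease).
`select_top_models` orders members by validation Precision@100, ties broken
by model id ascending.

## Evaluation

`precision_at_k` counts test-set membership in ranked prefix K, for K
defaulting to {1, 5, 10, 25, 50, 100, 250, 500}; a K exceeding the ranking
length is an error, not a truncation. No Hits@K is computed anywhere —
Precision@K over the candidate space is a different quantity and the two
must not be conflated. `pairwise_overlap` intersects two models' top-K lists
after partitioning by test membership; the matrices are symmetric with
diagonal equal to each model's own TP (resp. FP) count.
`degree_correlation` relates ensemble scores to `deg(drug) + deg(disease)`
counted on the training graph, Pearson by default with Spearman behind a
flag (the degree statistic and coefficient choice are both conventions, not
derivations); zero variance in either variable returns an undefined flag
rather than a number.

## Synthetic generators

`generate_kg` samples independent Bernoulli edges per relation layer
(drug–protein, protein–protein without self-loops, protein–disease,
drug–disease) over typed entity grids. With `n_blocks` set, drugs and
diseases are partitioned round-robin into communities and treats edges occur
only within a community — giving the embedding models a planted structure to
recover. The toy benchmark configuration used by the end-to-end tests and
the acceptance script is 60 drugs × 30 proteins × 60 diseases, 3 blocks,
treats density 0.25 and 0.08 for the protein layers (~600–700 triples,
~400–600 candidate pairs): large enough that a top-5% retained list and
Precision@10 are meaningful, small enough to train four models in seconds.

`generate_score_tables` emulates a committee of link predictors. Per model
with precision target `p_m`, the top-K true-positive count is
`Binomial(k_top, p_m)` — targets are means, individual committees vary with
sampling noise. Agreement uses a shared latent-easiness model: every
positive carries one global easiness value; model m ranks positives by
`α·easiness + (1−α)·private noise` and plants its n_tp highest. α=1 makes
all models choose the same (easiest) positives, α=0 makes them independent;
in between, consensus decays gracefully with easiness, spreading overlap
over a graded set of positives rather than one fully shared core — which is
what coexisting modest pairwise overlap and strong ensemble gains require.
False positives are drawn identically from the non-positive pool with rate
β. Note the selection quantile matters alongside the mixing weight: equal α
and β produce equal overlap *rates* only when the two pools are comparably
sized relative to the draws (the symmetry test constructs exactly that
situation).

Within a model's top-K, true-positive ranks are drawn without replacement
with linearly decaying weights (`k − r + 1` at rank r): committees of real
link predictors show near-perfect precision at tiny K that erodes as K
grows, so planted TPs must concentrate at the very top. Raw scores come
from per-model skew-normal distributions (default locations spread over
[−5, 5], scales over [0.5, 3], skews over [−8, 8]) so tables lie in
different intervals with different shapes; the K largest draws go to the
planted top-K in rank order and the rest scatter uniformly. Defaults — 10
models, k_top 100, 100,000 candidates, 500 positives, precision targets
linearly spaced over [0.10, 0.60], α = 0.5, β = 0.05 — constitute the
package's benchmark committee; under them, sum-aggregated ensemble-all
matches or beats the best member's Precision@100 in ≥ 90% of seeds and mean
pairwise TP overlap exceeds FP overlap in every seed (both are asserted by
the test suite and recomputed by `scripts/acceptance.py`).

What the generator does *not* emulate: the empirical score distributions of
any particular trained model family, miscalibration correlated with entity
degree, biologically meaningful identifiers, or train/test leakage
pathologies. Passing benchmarks on this committee therefore demonstrates
that the ensemble machinery exploits a TP-biased agreement structure when
present — not that any particular real model set has that structure to the
same degree.

## Numerical and degenerate-input conventions

Percentile → count uses floor with a 1e-9 epsilon; all sorting tie-breaks
are lexicographic on (drug, disease) after the primary keys; constant
retained scores normalize to 0.5 (warning); a single retained pair
rank-normalizes to 1.0 (warning); zero-variance degree correlation returns
None; zero-distance translational scores get zero gradient. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`; no
global state is touched.

## Known limitations

Only 4 of the common interaction functions are implemented, without
hyperparameter search, early stopping or GPU support — large-scale scores
should be produced externally and imported. The split floor rule will not
reproduce every published split size on totals where rounding conventions
differ (e.g. a 5,139-triple set printed as 4,108/516/515 implies a different
rule). The degree-correlation figures reported on real benchmark graphs
depend on full-scale trained models and are not reproducible at desk scale;
this package documents the statistic, not those values.
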