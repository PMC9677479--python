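import numpy as np
import pytest

from kgfuse.errors import ConfigError, EmbeddingLookupError, TrainingError
from kgfuse.kg_data import SplitBundle, Triple
from kgfuse.kgem import (
    INTERACTIONS,
    TrainConfig,
    _score_batch,
    _score_grads,
    init_model,
    score_candidates,
    score_triple,
    train,
)
from kgfuse.kg_data import CandidateSpace
from kgfuse.synthetic import SyntheticKGConfig, generate_kg
from kgfuse import enumerate_candidates, split_drug_disease

ENTITIES = [f"e{i}" for i in range(6)]
RELATIONS = ["r0", "r1"]


class TestInit:
    @pytest.mark.parametrize("interaction", INTERACTIONS)
    def test_seed_determinism(self, interaction):
        a = init_model(interaction, 8, ENTITIES, RELATIONS, seed=5)
        b = init_model(interaction, 8, ENTITIES, RELATIONS, seed=5)
        assert np.array_equal(a.entity_emb, b.entity_emb)
        assert np.array_equal(a.relation_emb, b.relation_emb)

    def test_zero_dim_rejected(self):
        with pytest.raises(ConfigError):
            init_model("transe", 0, ENTITIES, RELATIONS)

    def test_unknown_interaction_rejected(self):
        with pytest.raises(ConfigError):
            init_model("rescal", 4, ENTITIES, RELATIONS)

    def test_rotate_relations_unit_modulus(self):
        m = init_model("rotate", 16, ENTITIES, RELATIONS, seed=1)
        mods = np.abs(m.relation_vectors())
        assert np.allclose(mods, 1.0, atol=1e-12)


class TestScoreTriple:
    def test_transe_zero_distance_is_maximum(self):
        m = init_model("transe", 4, ENTITIES, RELATIONS, seed=0)
        # force t = h + r exactly
        m.entity_emb[1] = m.entity_emb[0] + m.relation_emb[0]
        s = score_triple(m, Triple("e0", "r0", "e1"))
        assert s == 0.0
        others = [
            score_triple(m, Triple("e0", "r0", e)) for e in ENTITIES[2:]
        ]
        assert all(o <= 0 for o in others)

    def test_distmult_hand_computation(self):
        m = init_model("distmult", 2, ENTITIES, RELATIONS, seed=0)
        m.entity_emb[0] = [1.0, 2.0]
        m.relation_emb[0] = [1.0, 1.0]
        m.entity_emb[1] = [2.0, 1.0]
        assert score_triple(m, Triple("e0", "r0", "e1")) == pytest.approx(4.0)

    def test_complex_brute_force_arithmetic(self, rng):
        m = init_model("complex", 3, ENTITIES, RELATIONS, seed=2)
        h, r, t = m.entity_emb[0], m.relation_emb[1], m.entity_emb[3]
        expected = sum(
            (h[i] * r[i] * np.conj(t[i])).real for i in range(3)
        )
        assert score_triple(m, Triple("e0", "r1", "e3")) == pytest.approx(expected)
        # the unit case: h = r = t = 1 + 0i
        m.entity_emb[0] = m.entity_emb[1] = np.array([1 + 0j, 0, 0])
        m.relation_emb[0] = np.array([1 + 0j, 0, 0])
        assert score_triple(m, Triple("e0", "r0", "e1")) == pytest.approx(1.0)

    def test_unknown_ids_rejected(self):
        m = init_model("transe", 4, ENTITIES, RELATIONS)
        with pytest.raises(EmbeddingLookupError):
            score_triple(m, Triple("nope", "r0", "e1"))
        with pytest.raises(EmbeddingLookupError):
            score_triple(m, Triple("e0", "r9", "e1"))

    @pytest.mark.parametrize("interaction", ["transe", "rotate"])
    def test_distance_scores_never_positive(self, interaction, rng):
        m = init_model(interaction, 8, ENTITIES, RELATIONS, seed=3)
        for h in ENTITIES[:3]:
            for t in ENTITIES[3:]:
                assert score_triple(m, Triple(h, "r0", t)) <= 0


@pytest.mark.parametrize("interaction", INTERACTIONS)
def test_analytic_gradients_match_finite_differences(interaction, rng):
    """Score gradients agree with central finite differences, including the
    complex-parameter convention and RotatE's phase parametrization."""
    dim = 5
    eps = 1e-6
    if interaction in ("complex", "rotate"):
        h = rng.normal(size=(1, dim)) + 1j * rng.normal(size=(1, dim))
        t = rng.normal(size=(1, dim)) + 1j * rng.normal(size=(1, dim))
    else:
        h = rng.normal(size=(1, dim))
        t = rng.normal(size=(1, dim))
    if interaction == "rotate":
        phase = rng.uniform(0, 2 * np.pi, size=(1, dim))
        r = np.exp(1j * phase)
    elif interaction == "complex":
        r = rng.normal(size=(1, dim)) + 1j * rng.normal(size=(1, dim))
    else:
        r = rng.normal(size=(1, dim))
    gh, gr, gt = _score_grads(interaction, h, r, t)

    def fd(x, build):
        grad = np.zeros_like(x)
        for i in range(dim):
            for part in ([1, 1j] if np.iscomplexobj(x) else [1]):
                xp, xm = x.copy(), x.copy()
                xp[0, i] += eps * part
                xm[0, i] -= eps * part
                delta = (build(xp) - build(xm)) / (2 * eps)
                grad[0, i] += part * float(np.asarray(delta).item())
        return grad

    assert np.allclose(
        gh, fd(h, lambda x: _score_batch(interaction, x, r, t)), atol=1e-5
    )
    assert np.allclose(
        gt, fd(t, lambda x: _score_batch(interaction, h, r, x)), atol=1e-5
    )
    if interaction == "rotate":
        num = np.zeros_like(phase)
        for i in range(dim):
            pp, pm = phase.copy(), phase.copy()
            pp[0, i] += eps
            pm[0, i] -= eps
            num[0, i] = (
                (_score_batch("rotate", h, np.exp(1j * pp), t)
                 - _score_batch("rotate", h, np.exp(1j * pm), t)) / (2 * eps)
            ).item()
        assert np.allclose(gr, num, atol=1e-5)
    else:
        assert np.allclose(
            gr, fd(r, lambda x: _score_batch(interaction, h, x, t)), atol=1e-5
        )


def _toy_split(seed=0):
    kg = generate_kg(
        SyntheticKGConfig(
            n_drugs=20, n_proteins=10, n_diseases=20, n_blocks=2,
            density_drug_disease=0.5, density_drug_protein=0.2,
            density_protein_disease=0.2, seed=seed,
        )
    )
    return split_drug_disease(kg, (0.8, 0.1, 0.1), seed)


class TestTrain:
    def test_zero_epochs_is_identity(self):
        split = _toy_split()
        m = init_model("transe", 8, sorted(split.entity_types), ["treats",
                       "targets", "activates", "associated_with"], seed=0)
        out = train(m, split, TrainConfig(epochs=0))
        assert np.array_equal(out.entity_emb, m.entity_emb)
        assert np.array_equal(out.relation_emb, m.relation_emb)

    @pytest.mark.parametrize("interaction", INTERACTIONS)
    def test_loss_decreases_on_fixture(self, interaction):
        split = _toy_split(1)
        m = init_model(interaction, 16, sorted(split.entity_types),
                       sorted({t.relation for t in split.train}), seed=1)
        out = train(m, split, TrainConfig(epochs=50, seed=1))
        assert out.loss_history[-1] < out.loss_history[0]

    def test_single_entity_of_type_rejected(self):
        triples = {Triple("d1", "treats", "z1"), Triple("d2", "treats", "z1")}
        types = {"d1": "drug", "d2": "drug", "z1": "disease"}
        split = SplitBundle(triples, set(), set(), (1, 0, 0), 0, types)
        m = init_model("transe", 4, ["d1", "d2", "z1"], ["treats"], seed=0)
        with pytest.raises(TrainingError):
            train(m, split, TrainConfig(epochs=1))

    def test_rotate_constraint_survives_training(self):
        split = _toy_split(2)
        m = init_model("rotate", 8, sorted(split.entity_types),
                       sorted({t.relation for t in split.train}), seed=2)
        out = train(m, split, TrainConfig(epochs=20, seed=2))
        assert np.allclose(np.abs(out.relation_vectors()), 1.0, atol=1e-12)

    def test_block_structure_learned_across_seeds(self):
        """Within-community held-out pairs outscore cross-community pairs in
        at least 4 of 5 seeds, for a translational and a semantic model."""
        hits = 0
        for seed in range(5):
            split = _toy_split(seed)
            space = enumerate_candidates(split)
            m = init_model("rotate", 16, sorted(split.entity_types),
                           sorted({t.relation for t in split.train}), seed=seed)
            fit = train(m, split, TrainConfig(epochs=100, seed=seed))
            table = score_candidates(fit, space, "treats")
            within, cross = [], []
            for (d, z), s in zip(
                zip(table.frame["drug"], table.frame["disease"]),
                table.frame["score"],
            ):
                same = int(d.split("_")[1]) % 2 == int(z.split("_")[1]) % 2
                (within if same else cross).append(s)
            hits += np.mean(within) > np.mean(cross)
        assert hits >= 4


class TestScoreCandidates:
    def test_single_pair_matches_score_triple(self):
        m = init_model("distmult", 8, ENTITIES, RELATIONS, seed=4)
        space = CandidateSpace(pairs=[("e0", "e5")], scope="test_entities")
        table = score_candidates(m, space, "r0")
        assert table.frame["score"].iloc[0] == pytest.approx(
            score_triple(m, Triple("e0", "r0", "e5"))
        )

    @pytest.mark.parametrize("interaction", INTERACTIONS)
    def test_elementwise_oracle(self, interaction):
        m = init_model(interaction, 8, ENTITIES, RELATIONS, seed=5)
        pairs = [(h, t) for h in ENTITIES[:4] for t in ENTITIES[2:5] if h != t]
        space = CandidateSpace(pairs=pairs, scope="test_entities")
        table = score_candidates(m, space, "r1")
        for (d, z), s in zip(
            zip(table.frame["drug"], table.frame["disease"]), table.frame["score"]
        ):
            assert s == pytest.approx(score_triple(m, Triple(d, "r1", z)))

    def test_repeated_calls_identical(self):
        m = init_model("complex", 8, ENTITIES, RELATIONS, seed=6)
        space = CandidateSpace(pairs=[("e0", "e1"), ("e2", "e3")],
                               scope="test_entities")
        a = score_candidates(m, space, "r0").frame
        b = score_candidates(m, space, "r0").frame
        assert a.equals(b)

    def test_unknown_entity_listed(self):
        m = init_model("transe", 4, ENTITIES, RELATIONS)
        space = CandidateSpace(pairs=[("ghost", "e1")], scope="test_entities")
        with pytest.raises(EmbeddingLookupError, match="ghost"):
            score_candidates(m, space, "r0")
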