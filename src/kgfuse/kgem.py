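"""Lightweight knowledge-graph embedding models.

Implements four classic interaction functions spanning the two main modelling
paradigms — translational (TransE, RotatE) and semantic matching (DistMult,
ComplEx) — with minibatch SGD on the margin ranking loss and type-aware
negative sampling. Scores are always oriented higher-is-more-plausible;
distance-based interactions are negated internally:

* ``transe``:   s(h, r, t) = -|| h + r - t ||_2
* ``distmult``: s(h, r, t) = sum_i h_i r_i t_i
* ``complex``:  s(h, r, t) = Re( sum_i h_i r_i conj(t_i) )   (complex vectors)
* ``rotate``:   s(h, r, t) = -|| h o r - t ||_2 with relation entries e^{i phi}
                (complex Hadamard product; unit-modulus relations)

Gradients are derived analytically in numpy (for complex parameters the
gradient is stored as d/dRe + i d/dIm, so a plain complex SGD update moves
both components correctly); RotatE relations are parametrized by their phases
so the unit-modulus constraint holds exactly throughout training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigError,
    DataError,
    EmbeddingLookupError,
    TrainingError,
)
from .kg_data import CandidateSpace, SplitBundle, Triple
from .scores import ScoreTable

INTERACTIONS = ("transe", "distmult", "complex", "rotate")


@dataclass
class TrainConfig:
    """Hyperparameters for margin-ranking training."""

    epochs: int = 150
    learning_rate: float = 1.0
    negatives_per_positive: int = 10
    margin: float = 2.0
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if self.negatives_per_positive < 1:
            raise ConfigError("negatives_per_positive must be >= 1")


@dataclass
class EmbeddingModelLite:
    """Entity and relation embeddings under one interaction function.

    ``entity_emb`` has one row per entity (complex dtype for complex/rotate).
    For rotate, relations are stored as phases in ``relation_phase`` and the
    complex unit vectors are derived on demand.
    """

    interaction: str
    dim: int
    entities: list[str]
    relations: list[str]
    entity_emb: np.ndarray
    relation_emb: np.ndarray  # for rotate this holds phases (real)
    seed: int
    entity_index: dict[str, int] = field(default_factory=dict)
    relation_index: dict[str, int] = field(default_factory=dict)
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entity_index:
            self.entity_index = {e: i for i, e in enumerate(self.entities)}
        if not self.relation_index:
            self.relation_index = {r: i for i, r in enumerate(self.relations)}

    def relation_vectors(self) -> np.ndarray:
        """Relation embeddings in the form the interaction consumes."""
        if self.interaction == "rotate":
            return np.exp(1j * self.relation_emb)
        return self.relation_emb

    def copy(self) -> "EmbeddingModelLite":
        return EmbeddingModelLite(
            interaction=self.interaction,
            dim=self.dim,
            entities=list(self.entities),
            relations=list(self.relations),
            entity_emb=self.entity_emb.copy(),
            relation_emb=self.relation_emb.copy(),
            seed=self.seed,
            loss_history=list(self.loss_history),
        )


def init_model(
    interaction: str,
    dim: int,
    entities: list[str],
    relations: list[str],
    seed: int = 0,
) -> EmbeddingModelLite:
    """Reproducibly initialize an embedding model.

    Real embeddings are drawn from N(0, 1/sqrt(dim)); complex ones get
    independent real and imaginary parts on the same scale. RotatE relation
    phases are uniform on [0, 2*pi), giving exactly unit-modulus entries.
    """
    if interaction not in INTERACTIONS:
        raise ConfigError(
            f"unknown interaction {interaction!r}; choose from {INTERACTIONS}"
        )
    if dim < 1:
        raise ConfigError("embedding dimension must be >= 1")
    if not entities or not relations:
        raise ConfigError("entity and relation lists must be non-empty")
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(dim)
    n_e, n_r = len(entities), len(relations)
    if interaction in ("complex", "rotate"):
        entity_emb = (
            rng.normal(0, scale, (n_e, dim)) + 1j * rng.normal(0, scale, (n_e, dim))
        )
        if interaction == "rotate":
            relation_emb = rng.uniform(0, 2 * np.pi, (n_r, dim))
        else:
            relation_emb = (
                rng.normal(0, scale, (n_r, dim))
                + 1j * rng.normal(0, scale, (n_r, dim))
            )
    else:
        entity_emb = rng.normal(0, scale, (n_e, dim))
        relation_emb = rng.normal(0, scale, (n_r, dim))
    return EmbeddingModelLite(
        interaction=interaction,
        dim=dim,
        entities=list(entities),
        relations=list(relations),
        entity_emb=entity_emb,
        relation_emb=relation_emb,
        seed=seed,
    )


def _score_batch(
    interaction: str, h: np.ndarray, r: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Vectorized interaction scores for (B, dim) embedding blocks."""
    if interaction == "transe":
        return -np.linalg.norm(h + r - t, axis=-1)
    if interaction == "distmult":
        return np.sum(h * r * t, axis=-1)
    if interaction == "complex":
        return np.real(np.sum(h * r * np.conj(t), axis=-1))
    if interaction == "rotate":
        return -np.linalg.norm(h * r - t, axis=-1)
    raise ConfigError(f"unknown interaction {interaction!r}")


def _score_grads(
    interaction: str, h: np.ndarray, r: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the score w.r.t. (h, r, t).

    Complex gradients use the d/dRe + i d/dIm convention; for rotate, the
    relation gradient is returned w.r.t. the phase (r must already be on the
    unit circle). Zero-distance translational cases get zero gradient.
    """
    if interaction == "transe":
        d = h + r - t
        n = np.linalg.norm(d, axis=-1, keepdims=True)
        u = np.divide(d, n, out=np.zeros_like(d), where=n > 0)
        return -u, -u, u
    if interaction == "distmult":
        return r * t, h * t, h * r
    if interaction == "complex":
        return np.conj(r) * t, np.conj(h) * t, h * r
    if interaction == "rotate":
        d = h * r - t
        n = np.linalg.norm(d, axis=-1, keepdims=True)
        dn = np.divide(d, n, out=np.zeros_like(d), where=n > 0)
        gh = -dn * np.conj(r)
        gt = dn
        # phase gradient: ds/dphi_k = Im(conj(d_k) h_k r_k) / ||d||
        gphi = np.divide(
            np.imag(np.conj(d) * h * r),
            n,
            out=np.zeros(d.shape),
            where=n > 0,
        )
        return gh, gphi, gt
    raise ConfigError(f"unknown interaction {interaction!r}")


def score_triple(model: EmbeddingModelLite, triple: Triple) -> float:
    """Plausibility score of one triple (higher = more plausible)."""
    try:
        hi = model.entity_index[triple.head]
        ti = model.entity_index[triple.tail]
    except KeyError as exc:
        raise EmbeddingLookupError(f"unknown entity: {exc.args[0]!r}") from exc
    try:
        ri = model.relation_index[triple.relation]
    except KeyError as exc:
        raise EmbeddingLookupError(f"unknown relation: {exc.args[0]!r}") from exc
    rvec = model.relation_vectors()[ri]
    return float(
        _score_batch(
            model.interaction, model.entity_emb[hi], rvec, model.entity_emb[ti]
        )
    )


def score_candidates(
    model: EmbeddingModelLite,
    space: CandidateSpace,
    relation: str,
    *,
    model_id: str | None = None,
    chunk_size: int = 100_000,
) -> ScoreTable:
    """Score every candidate pair under one relation, returning a ScoreTable.

    Deterministic given the model; evaluation happens in chunks so large
    candidate spaces stay memory-bounded.
    """
    if len(space) == 0:
        raise DataError("candidate space is empty")
    if relation not in model.relation_index:
        raise EmbeddingLookupError(f"unknown relation: {relation!r}")
    unknown = sorted(
        {e for p in space.pairs for e in p if e not in model.entity_index}
    )
    if unknown:
        raise EmbeddingLookupError(
            f"{len(unknown)} candidate entities unknown to model: {unknown[:10]}"
        )
    idx = model.entity_index
    heads = np.fromiter((idx[d] for d, _ in space.pairs), dtype=np.int64)
    tails = np.fromiter((idx[z] for _, z in space.pairs), dtype=np.int64)
    rvec = model.relation_vectors()[model.relation_index[relation]]
    out = np.empty(len(space), dtype=float)
    for start in range(0, len(space), chunk_size):
        sl = slice(start, start + chunk_size)
        out[sl] = _score_batch(
            model.interaction,
            model.entity_emb[heads[sl]],
            rvec[None, :],
            model.entity_emb[tails[sl]],
        )
    return ScoreTable.from_pairs(model_id or model.interaction, space.pairs, out)


def _corruption_pools(
    split: SplitBundle, model: EmbeddingModelLite
) -> dict[str, np.ndarray]:
    """Index arrays of model entities grouped by type, for negative sampling."""
    pools: dict[str, list[int]] = {}
    for e in model.entities:
        ty = split.entity_types.get(e)
        if ty is not None:
            pools.setdefault(ty, []).append(model.entity_index[e])
    return {ty: np.asarray(ixs, dtype=np.int64) for ty, ixs in pools.items()}


def train(
    model: EmbeddingModelLite,
    split: SplitBundle,
    cfg: TrainConfig,
) -> EmbeddingModelLite:
    """Train by minibatch SGD on the margin ranking loss.

    For each positive triple, ``negatives_per_positive`` corruptions replace
    the head or the tail (chosen uniformly) with a uniformly drawn entity of
    the *same type*, so a drug is always corrupted into another drug and a
    disease into another disease. The hinge ``max(0, margin - s_pos + s_neg)``
    is averaged per epoch and logged into ``loss_history``. ``epochs=0``
    returns a copy with embeddings bit-identical to the input.
    """
    if not split.train:
        raise TrainingError("train split is empty")
    out = model.copy()
    if cfg.epochs == 0:
        return out
    triples = sorted(
        t
        for t in split.train
        if t.head in model.entity_index
        and t.tail in model.entity_index
        and t.relation in model.relation_index
    )
    if not triples:
        raise TrainingError("no training triples reference known entities/relations")
    pools = _corruption_pools(split, model)
    for t in triples:
        for e in (t.head, t.tail):
            ty = split.entity_types.get(e)
            if ty is None or len(pools.get(ty, ())) < 2:
                raise TrainingError(
                    f"cannot corrupt entity {e!r}: fewer than two entities of "
                    f"its type ({ty!r}) are known"
                )
    idx = model.entity_index
    heads = np.asarray([idx[t.head] for t in triples], dtype=np.int64)
    tails = np.asarray([idx[t.tail] for t in triples], dtype=np.int64)
    rels = np.asarray([model.relation_index[t.relation] for t in triples], dtype=np.int64)
    type_names = sorted(pools)
    type_id = {ty: i for i, ty in enumerate(type_names)}
    pool_list = [pools[ty] for ty in type_names]
    head_ty = np.asarray([type_id[split.entity_types[t.head]] for t in triples])
    tail_ty = np.asarray([type_id[split.entity_types[t.tail]] for t in triples])

    rng = np.random.default_rng(cfg.seed)
    n = len(triples)
    k = cfg.negatives_per_positive
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_terms = 0
        for start in range(0, n, cfg.batch_size):
            b = order[start : start + cfg.batch_size]
            rows = np.repeat(b, k)  # each positive replicated k times
            hb_r, tb_r, rb_r = heads[rows], tails[rows], rels[rows]
            corrupt_head = rng.random(len(rows)) < 0.5
            orig = np.where(corrupt_head, hb_r, tb_r)
            ctypes = np.where(corrupt_head, head_ty[rows], tail_ty[rows])
            cand = _sample_negatives(rng, pool_list, ctypes, orig)
            neg_h = np.where(corrupt_head, cand, hb_r)
            neg_t = np.where(corrupt_head, tb_r, cand)
            loss, nt = _sgd_step(out, hb_r, rb_r, tb_r, neg_h, neg_t, cfg)
            epoch_loss += loss
            n_terms += nt
        out.loss_history.append(epoch_loss / max(n_terms, 1))
    return out


def _sample_negatives(
    rng: np.random.Generator,
    pool_list: list[np.ndarray],
    ctypes: np.ndarray,
    orig: np.ndarray,
) -> np.ndarray:
    """Uniform same-type replacements, resampled until distinct from orig."""
    cand = np.empty_like(orig)
    todo = np.ones(len(orig), dtype=bool)
    while todo.any():
        for ty, pool in enumerate(pool_list):
            mask = todo & (ctypes == ty)
            m = int(mask.sum())
            if m:
                cand[mask] = pool[rng.integers(len(pool), size=m)]
        todo = cand == orig
    return cand


def _sgd_step(
    model: EmbeddingModelLite,
    pos_h: np.ndarray,
    rel: np.ndarray,
    pos_t: np.ndarray,
    neg_h: np.ndarray,
    neg_t: np.ndarray,
    cfg: TrainConfig,
) -> tuple[float, int]:
    """One SGD update on hinge terms max(0, margin - s_pos + s_neg)."""
    E = model.entity_emb
    rvecs = model.relation_vectors()
    h_p, r_v, t_p = E[pos_h], rvecs[rel], E[pos_t]
    h_n, t_n = E[neg_h], E[neg_t]
    s_pos = _score_batch(model.interaction, h_p, r_v, t_p)
    s_neg = _score_batch(model.interaction, h_n, r_v, t_n)
    hinge = cfg.margin - s_pos + s_neg
    active = hinge > 0
    total_loss = float(np.sum(hinge[active]))
    n_terms = len(hinge)
    if not active.any():
        return total_loss, n_terms
    scale = cfg.learning_rate / n_terms
    gh_p, gr_p, gt_p = _score_grads(model.interaction, h_p[active], r_v[active], t_p[active])
    gh_n, gr_n, gt_n = _score_grads(model.interaction, h_n[active], r_v[active], t_n[active])
    # dL/ds_pos = -1, dL/ds_neg = +1 on active terms
    np.add.at(E, pos_h[active], scale * gh_p)
    np.add.at(E, pos_t[active], scale * gt_p)
    np.subtract.at(E, neg_h[active], scale * gh_n)
    np.subtract.at(E, neg_t[active], scale * gt_n)
    # for rotate the relation gradient is w.r.t. the stored phase
    R = model.relation_emb
    np.add.at(R, rel[active], scale * gr_p)
    np.subtract.at(R, rel[active], scale * gr_n)
    return total_loss, n_terms
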