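"""Synthetic inputs: toy knowledge graphs and multi-model score tables.

Two generators back the test and benchmark harnesses:

* :func:`generate_kg` samples a typed drug/protein/disease graph with
  independent Bernoulli edges per relation type (drug-protein ``targets``,
  protein-protein ``activates``, protein-disease ``associated_with``,
  drug-disease ``treats``), optionally with community (block) structure on
  the drug-disease layer so embedding models have signal to learn.

* :func:`generate_score_tables` emulates the statistical structure of a
  committee of link-prediction models scoring a shared candidate space: each
  model has its own raw-score distribution (different location, scale and
  skew), plants a controllable number of true positives in its top-K with a
  controllable concentration toward the very top, and reuses positives from a
  shared pool so models agree on true positives with rate ``tp_agreement``
  and on false positives with rate ``fp_agreement``. With tp_agreement >
  fp_agreement the generated committee reproduces the empirical signature
  that cross-model consensus concentrates on correct predictions.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError
from .kg_data import DISEASE, DRUG, PROTEIN, KnowledgeGraph, Triple
from .scores import ScoreTable

REL_TARGETS = "targets"
REL_ACTIVATES = "activates"
REL_ASSOCIATED = "associated_with"
REL_TREATS = "treats"


@dataclass
class SyntheticKGConfig:
    """Parameters of the toy KG sampler.

    Densities are Bernoulli edge probabilities per relation type. With
    ``n_blocks`` set, drugs and diseases are partitioned into that many
    communities and ``treats`` edges occur only within a community.
    """

    n_drugs: int = 20
    n_proteins: int = 30
    n_diseases: int = 20
    density_drug_protein: float = 0.1
    density_protein_protein: float = 0.05
    density_protein_disease: float = 0.1
    density_drug_disease: float = 0.15
    n_blocks: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_proteins, self.n_diseases) < 1:
            raise ConfigError("entity counts must be >= 1")
        for name in (
            "density_drug_protein",
            "density_protein_protein",
            "density_protein_disease",
            "density_drug_disease",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.n_blocks is not None and self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")


def _bernoulli_edges(
    rng: np.random.Generator,
    heads: list[str],
    tails: list[str],
    relation: str,
    density: float,
    *,
    mask: Optional[np.ndarray] = None,
    no_self: bool = False,
) -> set[Triple]:
    draw = rng.random((len(heads), len(tails))) < density
    if mask is not None:
        draw &= mask
    if no_self:
        np.fill_diagonal(draw, False)
    hi, ti = np.nonzero(draw)
    return {Triple(heads[i], relation, tails[j]) for i, j in zip(hi, ti)}


def generate_kg(cfg: SyntheticKGConfig) -> KnowledgeGraph:
    """Sample a typed drug/protein/disease KG per the configured densities."""
    rng = np.random.default_rng(cfg.seed)
    drugs = [f"drug_{i:04d}" for i in range(cfg.n_drugs)]
    proteins = [f"protein_{i:04d}" for i in range(cfg.n_proteins)]
    diseases = [f"disease_{i:04d}" for i in range(cfg.n_diseases)]

    dd_mask = None
    if cfg.n_blocks is not None:
        drug_block = np.arange(cfg.n_drugs) % cfg.n_blocks
        disease_block = np.arange(cfg.n_diseases) % cfg.n_blocks
        dd_mask = drug_block[:, None] == disease_block[None, :]

    triples: set[Triple] = set()
    triples |= _bernoulli_edges(
        rng, drugs, proteins, REL_TARGETS, cfg.density_drug_protein
    )
    triples |= _bernoulli_edges(
        rng, proteins, proteins, REL_ACTIVATES, cfg.density_protein_protein,
        no_self=True,
    )
    triples |= _bernoulli_edges(
        rng, proteins, diseases, REL_ASSOCIATED, cfg.density_protein_disease
    )
    dd = _bernoulli_edges(
        rng, drugs, diseases, REL_TREATS, cfg.density_drug_disease, mask=dd_mask
    )
    if not dd:
        raise DataError(
            "sampled zero drug-disease edges; raise density_drug_disease or sizes"
        )
    triples |= dd
    entity_types = (
        {d: DRUG for d in drugs}
        | {p: PROTEIN for p in proteins}
        | {z: DISEASE for z in diseases}
    )
    return KnowledgeGraph(triples, entity_types)


@dataclass
class SyntheticScoreConfig:
    """Parameters of the multi-model score-table generator.

    Defaults describe the benchmark committee used throughout the package's
    own evaluation: 10 models whose top-100 precision targets are spread
    evenly over [0.10, 0.60] on a candidate space of 100,000 pairs holding
    500 planted positives, with true-positive agreement 0.5 and
    false-positive agreement 0.05 across models.

    ``tp_position_bias`` controls how strongly each model's true positives
    concentrate at the very top of its top-K (rank r gets sampling weight
    ``(k_top - r + 1) ** bias``); the default linear decay mirrors the way
    real committees show near-perfect precision at tiny K that erodes as K
    grows. ``locs``/``scales``/``skews`` give each model its own skew-normal
    raw-score distribution so tables lie in different intervals with
    different shapes.
    """

    n_models: int = 10
    k_top: int = 100
    n_candidates: int = 100_000
    n_positives: int = 500
    precision_targets: Optional[Sequence[float]] = None
    tp_agreement: float = 0.5
    fp_agreement: float = 0.05
    tp_position_bias: float = 1.0
    locs: Optional[Sequence[float]] = None
    scales: Optional[Sequence[float]] = None
    skews: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ConfigError("n_models must be >= 1")
        if self.n_positives > self.n_candidates:
            raise ConfigError("n_positives cannot exceed n_candidates")
        if self.k_top > self.n_candidates:
            raise ConfigError("k_top cannot exceed n_candidates")
        for name in ("tp_agreement", "fp_agreement"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.precision_targets is None:
            self.precision_targets = tuple(
                np.linspace(0.10, 0.60, self.n_models).round(6)
            )
        self.precision_targets = tuple(float(p) for p in self.precision_targets)
        if len(self.precision_targets) != self.n_models:
            raise ConfigError("need one precision target per model")
        for p in self.precision_targets:
            if not 0 <= p <= 1:
                raise ConfigError(f"precision target {p} outside [0, 1]")
            if p * self.k_top > self.n_positives:
                raise ConfigError(
                    f"precision target {p} needs {p * self.k_top:.0f} positives "
                    f"in the top-{self.k_top} but only {self.n_positives} exist"
                )
        if self.locs is None:
            self.locs = tuple(np.linspace(-5.0, 5.0, self.n_models))
        if self.scales is None:
            self.scales = tuple(np.linspace(0.5, 3.0, self.n_models))
        if self.skews is None:
            alternating = np.linspace(-8.0, 8.0, self.n_models)
            self.skews = tuple(alternating)
        for name in ("locs", "scales", "skews"):
            if len(getattr(self, name)) != self.n_models:
                raise ConfigError(f"{name} must have one entry per model")

    def model_ids(self) -> list[str]:
        return [f"model_{i:02d}" for i in range(self.n_models)]


def _candidate_pairs(n: int) -> list[tuple[str, str]]:
    """A deterministic drug x disease grid truncated to exactly n pairs."""
    n_dis = int(np.ceil(np.sqrt(n)))
    n_drug = int(np.ceil(n / n_dis))
    pairs = [
        (f"D{i:05d}", f"Z{j:05d}")
        for i in range(n_drug)
        for j in range(n_dis)
    ]
    return pairs[:n]


def _weighted_ranks_without_replacement(
    rng: np.random.Generator, k: int, n_pick: int, bias: float
) -> np.ndarray:
    """Pick n_pick ranks from 0..k-1, weight (k - r) ** bias, no replacement.

    Uses the Gumbel-top-k trick, which is exactly equivalent to sequential
    weighted sampling without replacement.
    """
    if n_pick == 0:
        return np.empty(0, dtype=np.int64)
    w = (k - np.arange(k)).astype(float) ** bias
    keys = np.log(w) + rng.gumbel(size=k)
    return np.sort(np.argpartition(-keys, n_pick - 1)[:n_pick])


def generate_score_tables(
    cfg: SyntheticScoreConfig,
) -> tuple[list[ScoreTable], set[tuple[str, str]]]:
    """Generate one full score table per model plus the planted positive set.

    Mechanism per model m with precision target p_m:

    1. The number of true positives in its top-K is Binomial(k_top, p_m).
    2. Every positive carries one global latent "easiness" value shared by
       all models; model m ranks the positive pool by the mixture key
       ``tp_agreement * easiness + (1 - tp_agreement) * private noise`` and
       plants its n_tp highest-keyed positives. With agreement 1 all models
       plant the same (easiest) positives, with agreement 0 they choose
       independently; in between, consensus degrades gracefully with
       easiness, so the overlap is spread over a graded set of positives
       rather than one fully shared core. False positives are selected the
       same way from the non-positive pool using ``fp_agreement``.
    3. Ranks inside the top-K are assigned to true positives by weighted
       sampling without replacement with linearly decaying weights (see
       ``tp_position_bias``), so TPs sit preferentially near the top.
    4. Raw scores for the whole candidate space are drawn from the model's
       skew-normal distribution and assigned so that the planted top-K
       receives the K largest draws in rank order; the remaining draws are
       scattered uniformly over the rest of the space.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs = _candidate_pairs(cfg.n_candidates)
    n = cfg.n_candidates
    pos_idx = rng.choice(n, size=cfg.n_positives, replace=False)
    positives = {pairs[i] for i in pos_idx}
    neg_idx = np.setdiff1d(np.arange(n), pos_idx)
    ease_tp = rng.random(len(pos_idx))  # shared latent easiness per positive
    ease_fp = rng.random(len(neg_idx))

    tables: list[ScoreTable] = []
    for m, model_id in enumerate(cfg.model_ids()):
        p_m = cfg.precision_targets[m]
        n_tp = int(
            min(rng.binomial(cfg.k_top, p_m), cfg.n_positives, cfg.k_top)
        )
        n_fp = cfg.k_top - n_tp

        key_tp = cfg.tp_agreement * ease_tp + (1 - cfg.tp_agreement) * rng.random(
            len(pos_idx)
        )
        tp_chosen = (
            pos_idx[np.argpartition(-key_tp, n_tp - 1)[:n_tp]]
            if n_tp
            else np.empty(0, dtype=np.int64)
        )
        key_fp = cfg.fp_agreement * ease_fp + (1 - cfg.fp_agreement) * rng.random(
            len(neg_idx)
        )
        fp_chosen = (
            neg_idx[np.argpartition(-key_fp, n_fp - 1)[:n_fp]]
            if n_fp
            else np.empty(0, dtype=np.int64)
        )

        tp_ranks = _weighted_ranks_without_replacement(
            rng, cfg.k_top, n_tp, cfg.tp_position_bias
        )
        top_slots = np.empty(cfg.k_top, dtype=np.int64)
        fp_ranks = np.setdiff1d(np.arange(cfg.k_top), tp_ranks)
        top_slots[tp_ranks] = rng.permutation(tp_chosen)
        top_slots[fp_ranks] = rng.permutation(fp_chosen)

        raw = stats.skewnorm.rvs(
            cfg.skews[m],
            loc=cfg.locs[m],
            scale=cfg.scales[m],
            size=n,
            random_state=rng,
        )
        raw.sort()
        raw = raw[::-1]  # descending
        scores = np.empty(n, dtype=float)
        scores[top_slots] = raw[: cfg.k_top]
        rest = np.setdiff1d(np.arange(n), top_slots)
        scores[rng.permutation(rest)] = raw[cfg.k_top :]
        tables.append(ScoreTable.from_pairs(model_id, pairs, scores))
    return tables, positives
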