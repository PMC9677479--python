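"""Ranking evaluation: Precision@K, pairwise top-K agreement, degree bias.

Precision@K is the fraction of a ranking's top K drug-disease pairs that are
present in the held-out test set. It evaluates the usable top of the ranked
list directly — the quantity that matters when only a handful of predictions
can be validated experimentally — and is invariant to any strictly monotone
rescaling of the scores. (This is not Hits@K, which ranks each test triple
against corrupted alternatives; no Hits@K is computed here.)

``pairwise_overlap`` measures how much the top-K lists of different models
intersect, split into true positives (pairs in the test set) and false
positives, the diagnostic showing that models agree far more on correct
predictions. ``degree_correlation`` checks whether a ranking simply tracks
node degree in the training graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import EnsembleRanking
from .errors import ConfigError, DataError, EvaluationError
from .kg_data import KnowledgeGraph
from .scores import ScoreTable, TopKScores

DEFAULT_K_VALUES = (1, 5, 10, 25, 50, 100, 250, 500)

RankingLike = Union[EnsembleRanking, TopKScores, ScoreTable, Sequence[tuple[str, str]]]


@dataclass
class EvalReport:
    """Precision@K results for one model or ensemble."""

    subject_id: str
    k_values: tuple[int, ...]
    precision_at_k: dict[int, float]
    tp_counts: dict[int, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subject": self.subject_id,
            "k": list(self.k_values),
            "precision": {str(k): v for k, v in self.precision_at_k.items()},
            "tp_count": {str(k): v for k, v in self.tp_counts.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class AgreementMatrix:
    """Pairwise top-K intersection counts, split into TP and FP parts.

    Both matrices are symmetric; the diagonal of ``tp_overlap`` is each
    model's own TP count at K and the diagonal of ``fp_overlap`` is K minus
    that count.
    """

    k: int
    models: list[str]
    tp_overlap: pd.DataFrame
    fp_overlap: pd.DataFrame

    def mean_offdiagonal(self) -> tuple[float, float]:
        """Mean pairwise (i != j) TP and FP overlap counts."""
        n = len(self.models)
        if n < 2:
            raise DataError("need >= 2 models for off-diagonal means")
        mask = ~np.eye(n, dtype=bool)
        return (
            float(self.tp_overlap.to_numpy()[mask].mean()),
            float(self.fp_overlap.to_numpy()[mask].mean()),
        )

    def save(self, tp_path: str | Path, fp_path: str | Path) -> None:
        self.tp_overlap.to_csv(tp_path, sep="\t")
        self.fp_overlap.to_csv(fp_path, sep="\t")


def ranked_pairs(ranking: RankingLike) -> list[tuple[str, str]]:
    """Extract the ordered (drug, disease) list from any ranking-like object.

    Score tables are ordered by (score desc, drug, disease); top-K tables by
    their stored rank; ensembles by their own deterministic order.
    """
    if isinstance(ranking, EnsembleRanking):
        return ranking.ranked_pairs()
    if isinstance(ranking, TopKScores):
        f = ranking.frame.sort_values("rank", kind="mergesort")
        return list(zip(f["drug"], f["disease"]))
    if isinstance(ranking, ScoreTable):
        f = ranking.frame.sort_values(
            ["score", "drug", "disease"], ascending=[False, True, True],
            kind="mergesort",
        )
        return list(zip(f["drug"], f["disease"]))
    return list(ranking)


def precision_at_k(
    ranking: RankingLike,
    test: set[tuple[str, str]],
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    *,
    subject_id: str = "ranking",
) -> EvalReport:
    """Precision@K = |top-K intersect test| / K, for each requested K."""
    if not test:
        raise DataError("test set is empty")
    if not k_values:
        raise ConfigError("k_values must be non-empty")
    pairs = ranked_pairs(ranking)
    bad = [k for k in k_values if k < 1 or k > len(pairs)]
    if bad:
        raise EvaluationError(
            f"K values {bad} outside [1, {len(pairs)}] for this ranking"
        )
    is_tp = np.fromiter((p in test for p in pairs), dtype=bool, count=len(pairs))
    cum_tp = np.cumsum(is_tp)
    precision = {int(k): float(cum_tp[k - 1] / k) for k in k_values}
    tp_counts = {int(k): int(cum_tp[k - 1]) for k in k_values}
    return EvalReport(
        subject_id=subject_id,
        k_values=tuple(int(k) for k in k_values),
        precision_at_k=precision,
        tp_counts=tp_counts,
    )


def pairwise_overlap(
    rankings: Mapping[str, RankingLike],
    test: set[tuple[str, str]],
    k: int,
) -> AgreementMatrix:
    """Intersection of each pair of models' top-K lists, split by TP/FP."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    models = sorted(rankings)
    tops: dict[str, list[tuple[str, str]]] = {}
    for m in models:
        pairs = ranked_pairs(rankings[m])
        if len(pairs) < k:
            raise EvaluationError(
                f"ranking for {m!r} has only {len(pairs)} entries, need {k}"
            )
        tops[m] = pairs[:k]
    tp_sets = {m: {p for p in tops[m] if p in test} for m in models}
    fp_sets = {m: {p for p in tops[m] if p not in test} for m in models}
    n = len(models)
    tp = np.zeros((n, n), dtype=int)
    fp = np.zeros((n, n), dtype=int)
    for i, mi in enumerate(models):
        for j, mj in enumerate(models):
            tp[i, j] = len(tp_sets[mi] & tp_sets[mj])
            fp[i, j] = len(fp_sets[mi] & fp_sets[mj])
    return AgreementMatrix(
        k=k,
        models=models,
        tp_overlap=pd.DataFrame(tp, index=models, columns=models),
        fp_overlap=pd.DataFrame(fp, index=models, columns=models),
    )


def degree_correlation(
    ranking: EnsembleRanking,
    kg: KnowledgeGraph,
    *,
    method: str = "pearson",
) -> tuple[float | None, int]:
    """Correlation between a pair's ensemble score and deg(drug)+deg(disease).

    Degrees are counted on the supplied (training) graph. Returns
    ``(coefficient, n)``; the coefficient is None when either variable has
    zero variance (correlation undefined). ``method`` may be ``pearson``
    (default) or ``spearman``.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigError(f"unknown correlation method {method!r}")
    deg = kg.degree()
    f = ranking.frame
    missing = sorted(
        {e for e in pd.concat([f["drug"], f["disease"]]) if e not in deg}
    )
    if missing:
        raise DataError(f"ranked entities absent from graph: {missing[:10]}")
    scores = f["score"].to_numpy(dtype=float)
    degsum = np.array([deg[d] + deg[z] for d, z in zip(f["drug"], f["disease"])],
                      dtype=float)
    if np.ptp(scores) == 0 or np.ptp(degsum) == 0:
        return None, len(f)
    if method == "pearson":
        r = stats.pearsonr(scores, degsum).statistic
    else:
        r = stats.spearmanr(scores, degsum).statistic
    return float(r), len(f)
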