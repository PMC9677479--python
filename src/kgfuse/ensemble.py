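"""Ensemble aggregation of normalized per-model score tables.

The core operation is unweighted *sum aggregation*: a pair's ensemble score
is the sum of its normalized scores over all member models, with absence from
a model's retained top-K counted as 0. Pairs retained by several models
therefore accumulate score — the mechanism that exploits models agreeing more
on true positives than on false positives. Average variants, a
product-of-experts combiner over full score tables, and a position (rank)
based ensemble are provided for comparison, along with selection of the
best members by validation Precision@100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_softmax

from .errors import ConfigError, DataError
from .scores import ScoreTable, TopKScores

if TYPE_CHECKING:  # pragma: no cover
    from .evaluate import EvalReport

AGGREGATIONS = ("sum", "avg_zero", "avg_present", "poe")


@dataclass
class EnsembleRanking:
    """Aggregated pair scores sorted descending.

    ``frame`` columns: ``drug, disease, score, n_models`` where ``n_models``
    counts the member models whose retained top-K contained the pair.
    Ordering is deterministic: (score desc, n_models desc, drug asc,
    disease asc).
    """

    frame: pd.DataFrame
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = (
            self.frame.sort_values(
                ["score", "n_models", "drug", "disease"],
                ascending=[False, False, True, True],
                kind="mergesort",
            ).reset_index(drop=True)
        )

    def ranked_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.frame["drug"], self.frame["disease"]))

    def __len__(self) -> int:
        return len(self.frame)


def _check_members(tables: Sequence[TopKScores]) -> None:
    if not tables:
        raise ConfigError("ensemble needs at least one member table")
    methods = {t.method for t in tables}
    if len(methods) > 1:
        raise ConfigError(f"mixed normalization methods in ensemble: {sorted(methods)}")
    percentiles = {t.percentile for t in tables}
    if len(percentiles) > 1:
        raise ConfigError(f"mixed percentiles in ensemble: {sorted(percentiles)}")
    ids = [t.model_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"duplicate member model ids: {ids}")


def _combined(tables: Sequence[TopKScores]) -> pd.DataFrame:
    frames = [
        t.frame[["drug", "disease", "normalized"]] for t in tables
    ]
    cat = pd.concat(frames, ignore_index=True)
    return (
        cat.groupby(["drug", "disease"], sort=False)["normalized"]
        .agg(total="sum", n_models="count")
        .reset_index()
    )


def aggregate_sum(tables: Sequence[TopKScores]) -> EnsembleRanking:
    """Sum of normalized scores; absence from a member's top-K contributes 0.

    Pairs outside every member's top-K are excluded entirely. Frequently
    retained pairs accumulate score across members, which weights cross-model
    consensus up.
    """
    _check_members(tables)
    g = _combined(tables)
    frame = g.rename(columns={"total": "score"})[
        ["drug", "disease", "score", "n_models"]
    ]
    return EnsembleRanking(
        frame,
        config={
            "aggregation": "sum",
            "members": sorted(t.model_id for t in tables),
            "percentile": tables[0].percentile,
            "method": tables[0].method,
        },
    )


def aggregate_avg(
    tables: Sequence[TopKScores], mode: str = "avg_zero"
) -> EnsembleRanking:
    """Average variants of sum aggregation.

    ``avg_zero`` divides the summed normalized score by the number of member
    models M (a pair missing from a member contributes 0 to the numerator) —
    order-equivalent to the plain sum. ``avg_present`` divides by the number
    of members that actually retained the pair, which removes the consensus
    weighting and produces genuinely different rankings.
    """
    if mode not in ("avg_zero", "avg_present"):
        raise ConfigError(f"unknown average mode {mode!r}")
    _check_members(tables)
    g = _combined(tables)
    denom = len(tables) if mode == "avg_zero" else g["n_models"]
    frame = pd.DataFrame(
        {
            "drug": g["drug"],
            "disease": g["disease"],
            "score": g["total"] / denom,
            "n_models": g["n_models"],
        }
    )
    return EnsembleRanking(
        frame,
        config={
            "aggregation": mode,
            "members": sorted(t.model_id for t in tables),
            "percentile": tables[0].percentile,
            "method": tables[0].method,
        },
    )


def product_of_experts(full_tables: Sequence[ScoreTable]) -> EnsembleRanking:
    """Product-of-experts over *full* (unthresholded) score tables.

    Each model's scores over the whole candidate space are turned into a
    probability distribution by softmax, and the ensemble score of a pair is
    the sum of log-probabilities across models (monotone-equivalent to the
    product of probabilities). All tables must cover exactly the same
    candidate space.
    """
    if not full_tables:
        raise ConfigError("product_of_experts needs at least one table")
    ref = full_tables[0].frame[["drug", "disease"]].sort_values(
        ["drug", "disease"], kind="mergesort"
    ).reset_index(drop=True)
    total = np.zeros(len(ref))
    for t in full_tables:
        if len(t) != len(ref):
            sym = abs(len(t) - len(ref))
            raise ConfigError(
                f"candidate space mismatch for model {t.model_id!r}: "
                f"size difference {sym}"
            )
        f = t.frame.sort_values(["drug", "disease"], kind="mergesort").reset_index(
            drop=True
        )
        if not (
            f["drug"].equals(ref["drug"]) and f["disease"].equals(ref["disease"])
        ):
            diff = len(
                set(zip(f["drug"], f["disease"]))
                ^ set(zip(ref["drug"], ref["disease"]))
            )
            raise ConfigError(
                f"candidate space mismatch for model {t.model_id!r}: "
                f"symmetric difference of {diff} pairs"
            )
        total += log_softmax(f["score"].to_numpy(dtype=float))
    frame = pd.DataFrame(
        {
            "drug": ref["drug"],
            "disease": ref["disease"],
            "score": total,
            "n_models": len(full_tables),
        }
    )
    return EnsembleRanking(
        frame,
        config={
            "aggregation": "poe",
            "members": sorted(t.model_id for t in full_tables),
        },
    )


def position_ensemble(tables: Sequence[TopKScores]) -> EnsembleRanking:
    """Sum aggregation over rank-normalized tables (the position ensemble).

    Prioritizes pairs by their ranked positions instead of score magnitudes;
    requires every member to use rank normalization.
    """
    non_rank = [t.model_id for t in tables if t.method != "rank"]
    if non_rank:
        raise ConfigError(
            f"position ensemble requires rank normalization; offending "
            f"members: {non_rank}"
        )
    ranking = aggregate_sum(tables)
    ranking.config["aggregation"] = "position"
    return ranking


def select_top_models(
    reports: Mapping[str, "EvalReport"], n: int = 5
) -> list[str]:
    """Pick the n members with the best validation Precision@100.

    Ties are broken by model id ascending, so selection is deterministic.
    """
    if n > len(reports):
        raise ConfigError(f"cannot select {n} models from {len(reports)} reports")
    missing = sorted(
        m for m, rep in reports.items() if 100 not in rep.precision_at_k
    )
    if missing:
        raise DataError(f"Precision@100 missing for models: {missing}")
    ordered = sorted(
        reports, key=lambda m: (-reports[m].precision_at_k[100], m)
    )
    return ordered[:n]


def save_ranking(ranking: EnsembleRanking, path: str | Path) -> None:
    """Write rank \\t drug \\t disease \\t score \\t n_models TSV."""
    f = ranking.frame.copy()
    f.insert(0, "rank", np.arange(1, len(f) + 1))
    f.to_csv(path, sep="\t", index=False)


def load_ranking(path: str | Path) -> EnsembleRanking:
    df = pd.read_csv(path, sep="\t", dtype={"drug": str, "disease": str})
    return EnsembleRanking(df.drop(columns=["rank"], errors="ignore"))
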