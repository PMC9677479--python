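"""Containers for per-model plausibility scores.

A :class:`ScoreTable` holds one model's raw scores over a set of candidate
drug-disease pairs (higher = more plausible). A :class:`TopKScores` is the
thresholded, normalized top slice of one table, the unit the ensemble layer
aggregates. Both round-trip to plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

SCORE_COLUMNS = ["model", "drug", "disease", "score"]
TOPK_COLUMNS = ["model", "drug", "disease", "raw_score", "normalized", "rank"]


@dataclass
class ScoreTable:
    """Raw plausibility scores of one model over candidate drug-disease pairs.

    ``frame`` has columns ``drug, disease, score``; pairs are unique and
    scores are finite. Higher scores mean more plausible triples.
    """

    model_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = {"drug", "disease", "score"} - set(f.columns)
        if missing:
            raise DataError(f"ScoreTable frame missing columns: {sorted(missing)}")
        if len(f) == 0:
            raise DataError(f"ScoreTable for {self.model_id!r} is empty")
        if not np.isfinite(f["score"].to_numpy()).all():
            raise DataError(f"ScoreTable for {self.model_id!r} has NaN/inf scores")
        if f.duplicated(["drug", "disease"]).any():
            raise DataError(f"ScoreTable for {self.model_id!r} has duplicate pairs")

    @classmethod
    def from_pairs(
        cls,
        model_id: str,
        pairs: Sequence[tuple[str, str]],
        scores: Iterable[float],
    ) -> "ScoreTable":
        arr = np.asarray(list(scores), dtype=float)
        frame = pd.DataFrame(
            {
                "drug": [p[0] for p in pairs],
                "disease": [p[1] for p in pairs],
                "score": arr,
            }
        )
        return cls(model_id, frame)

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.frame["drug"], self.frame["disease"]))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TopKScores:
    """The retained, normalized top fraction of one model's score table.

    ``frame`` columns: ``drug, disease, raw_score, normalized, rank`` with
    rank 1 = best raw score and every normalized value in [0, 1]. The
    normalizers are monotone, so the normalized ordering matches the raw one.
    """

    model_id: str
    percentile: float
    method: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        norm = self.frame["normalized"].to_numpy()
        if len(norm) == 0:
            raise DataError("TopKScores cannot be empty")
        if norm.min() < -1e-12 or norm.max() > 1 + 1e-12:
            raise DataError("normalized scores outside [0, 1]")

    @property
    def k_kept(self) -> int:
        return len(self.frame)

    def normalized_map(self) -> dict[tuple[str, str], float]:
        f = self.frame
        return dict(zip(zip(f["drug"], f["disease"]), f["normalized"]))

    def __len__(self) -> int:
        return len(self.frame)


def write_score_tables(tables: Iterable[ScoreTable], path: str | Path) -> None:
    """Write one or more score tables as long-format TSV (model column)."""
    frames = []
    for t in tables:
        f = t.frame.copy()
        f.insert(0, "model", t.model_id)
        frames.append(f[SCORE_COLUMNS])
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_score_tables(path: str | Path) -> list[ScoreTable]:
    """Read long-format score TSV back into one ScoreTable per model."""
    df = pd.read_csv(path, sep="\t", dtype={"model": str, "drug": str, "disease": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"score TSV {path} missing columns: {sorted(missing)}")
    return [
        ScoreTable(model_id, grp.drop(columns="model").reset_index(drop=True))
        for model_id, grp in df.groupby("model", sort=True)
    ]


def write_topk(tables: Iterable[TopKScores], path: str | Path) -> None:
    frames = []
    for t in tables:
        f = t.frame.copy()
        f.insert(0, "model", t.model_id)
        frames.append(f[TOPK_COLUMNS])
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_topk(path: str | Path, percentile: float, method: str) -> list[TopKScores]:
    df = pd.read_csv(path, sep="\t", dtype={"model": str, "drug": str, "disease": str})
    return [
        TopKScores(model_id, percentile, method, grp.drop(columns="model").reset_index(drop=True))
        for model_id, grp in df.groupby("model", sort=True)
    ]
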