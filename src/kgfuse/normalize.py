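"""Percentile thresholding and score normalization.

Different embedding models emit scores on different scales and with
differently shaped distributions, so raw scores cannot be aggregated across
models. The approach implemented here first keeps only each model's top
fraction of predictions (e.g. the 99th percentile = top 1%) and then
normalizes *within that retained set* onto [0, 1], which preserves the fine
distinctions among the confident predictions that matter in a prioritization
setting instead of flattening them against the bulk of the distribution.

Three monotone normalizers are provided:

* ``minmax`` — affine map of the retained raw scores; preserves relative
  distances.
* ``sigmoid`` — z-standardize the retained scores (population sd) and pass
  through the logistic, compressing both tails.
* ``rank`` — min-max on the rank rather than the score, yielding uniformly
  spaced values: best -> 1.0, worst -> 0.0, step 1/(k-1).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, ThresholdError
from .scores import ScoreTable, TopKScores

METHODS = ("minmax", "sigmoid", "rank")


def threshold_top_percentile(table: ScoreTable, percentile: float) -> ScoreTable:
    """Retain the top ``floor(N * (100 - percentile) / 100)`` scored pairs.

    ``percentile=99`` keeps the top 1%. Ties at the boundary are broken
    deterministically by (score desc, drug asc, disease asc). Raises
    :class:`ThresholdError` when the floor would retain zero pairs.
    """
    if not 0 < percentile < 100:
        raise ConfigError(f"percentile must be in (0, 100), got {percentile}")
    n = len(table)
    # epsilon guards against float artifacts like (100 - 99.9)/100 rounding
    # just below the exact fraction, which would floor one entry too few
    k = math.floor(n * (100.0 - percentile) / 100.0 + 1e-9)
    if k < 1:
        raise ThresholdError(
            f"percentile {percentile} retains 0 of {n} pairs; lower the percentile"
        )
    f = table.frame.sort_values(
        ["score", "drug", "disease"], ascending=[False, True, True], kind="mergesort"
    ).head(k)
    return ScoreTable(table.model_id, f.reset_index(drop=True))


def minmax_normalize(retained: ScoreTable, percentile: float = 99.0) -> TopKScores:
    """Affine map x -> (x - min) / (max - min) of the retained raw scores.

    A degenerate all-equal input maps every score to 0.5 (with a warning)
    rather than failing, so pipelines survive pathological toy inputs.
    """
    f = retained.frame.sort_values(
        ["score", "drug", "disease"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    x = f["score"].to_numpy(dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn(
            "all retained scores equal; min-max normalization maps them to 0.5",
            stacklevel=2,
        )
        norm = np.full_like(x, 0.5)
    else:
        norm = (x - lo) / (hi - lo)
    return _finish(retained.model_id, f, norm, percentile, "minmax")


def sigmoid_normalize(retained: ScoreTable, percentile: float = 99.0) -> TopKScores:
    """Z-standardize the retained scores, then apply the logistic function.

    Standardization uses the population standard deviation of the retained
    set, so the retained-set mean maps to exactly 0.5. Zero spread degrades
    to a constant 0.5 with a warning.
    """
    f = retained.frame.sort_values(
        ["score", "drug", "disease"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    x = f["score"].to_numpy(dtype=float)
    sd = x.std()  # population sd (ddof=0)
    if sd == 0:
        warnings.warn(
            "zero spread in retained scores; sigmoid normalization maps to 0.5",
            stacklevel=2,
        )
        norm = np.full_like(x, 0.5)
    else:
        z = (x - x.mean()) / sd
        norm = 1.0 / (1.0 + np.exp(-z))
    return _finish(retained.model_id, f, norm, percentile, "sigmoid")


def rank_normalize(retained: ScoreTable, percentile: float = 99.0) -> TopKScores:
    """Min-max on ranks: best pair -> 1.0, worst -> 0.0, uniform spacing.

    With rank r in 1..k (1 = highest raw score, ties broken by the standard
    deterministic order), the normalized value is (k - r) / (k - 1). A
    single retained pair maps to 1.0 with a warning.
    """
    f = retained.frame.sort_values(
        ["score", "drug", "disease"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    k = len(f)
    if k == 1:
        warnings.warn("single retained pair; rank normalization maps it to 1.0",
                      stacklevel=2)
        norm = np.array([1.0])
    else:
        ranks = np.arange(1, k + 1, dtype=float)
        norm = (k - ranks) / (k - 1)
    return _finish(retained.model_id, f, norm, percentile, "rank")


def _finish(
    model_id: str, sorted_frame: pd.DataFrame, norm: np.ndarray,
    percentile: float, method: str
) -> TopKScores:
    frame = pd.DataFrame(
        {
            "drug": sorted_frame["drug"],
            "disease": sorted_frame["disease"],
            "raw_score": sorted_frame["score"],
            "normalized": norm,
            "rank": np.arange(1, len(sorted_frame) + 1),
        }
    )
    return TopKScores(model_id, percentile, method, frame)


_NORMALIZERS = {
    "minmax": minmax_normalize,
    "sigmoid": sigmoid_normalize,
    "rank": rank_normalize,
}


def normalize_table(
    table: ScoreTable, percentile: float, method: str
) -> TopKScores:
    """Threshold to the top percentile, then normalize with ``method``."""
    if method not in _NORMALIZERS:
        raise ConfigError(f"unknown normalization method {method!r}; choose from {METHODS}")
    retained = threshold_top_percentile(table, percentile)
    return _NORMALIZERS[method](retained, percentile)
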