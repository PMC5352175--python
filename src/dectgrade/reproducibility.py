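"""Test-retest feature stability filtering.

Features extracted twice from repeated segmentations/acquisitions are
screened with Lin's concordance correlation coefficient (CCC); features
with CCC below 0.8 are considered non-reproducible and excluded from
modeling.  ICC(2,1) is provided for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionMismatchError, UndefinedConcordanceError

DEFAULT_CCC_THRESHOLD = 0.8


@dataclass
class RetestPair:
    """Paired per-tumor values of one feature from two runs."""

    feature: str
    values_run1: np.ndarray
    values_run2: np.ndarray

    def __post_init__(self) -> None:
        self.values_run1 = np.asarray(self.values_run1, dtype=float)
        self.values_run2 = np.asarray(self.values_run2, dtype=float)
        if self.values_run1.shape != self.values_run2.shape:
            raise DimensionMismatchError(
                f"run lengths differ for {self.feature}: "
                f"{self.values_run1.shape} vs {self.values_run2.shape}"
            )


def ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    Uses population (1/n) moments: ``2 s_xy / (s_x^2 + s_y^2 + (mx - my)^2)``.
    Measures how tightly paired values cluster around the identity line,
    penalizing both imprecision and location/scale shift.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DimensionMismatchError("x and y must have equal length")
    if x.size < 2:
        raise UndefinedConcordanceError("need at least 2 paired observations")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    if sx2 == 0.0 or sy2 == 0.0:
        raise UndefinedConcordanceError("concordance undefined for constant input")
    sxy = float(np.mean((x - mx) * (y - my)))
    return 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def icc21(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``x``/``y`` are the two measurement occasions of the same targets.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise UndefinedConcordanceError("need >= 3 paired observations")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedConcordanceError("degenerate data for ICC")
    return float((msr - mse) / denom)


def filter_by_ccc(
    pairs: list[RetestPair],
    threshold: float = DEFAULT_CCC_THRESHOLD,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Partition features into reproducible and excluded by CCC >= threshold.

    Returns ``(retained, excluded, report)`` where the report lists every
    feature's CCC (NaN when undefined, with the reason).
    """
    if not pairs:
        raise UndefinedConcordanceError("no retest pairs supplied")
    rows = []
    retained, excluded = [], []
    for pair in pairs:
        reason = ""
        try:
            value = ccc(pair.values_run1, pair.values_run2)
        except UndefinedConcordanceError as exc:
            value, reason = float("nan"), str(exc)
        keep = (not np.isnan(value)) and value >= threshold
        (retained if keep else excluded).append(pair.feature)
        rows.append({"feature": pair.feature, "ccc": value,
                     "retained": keep, "reason": reason})
    report = pd.DataFrame(rows)
    return retained, excluded, report


def pairs_from_frames(
    run1: pd.DataFrame, run2: pd.DataFrame, id_column: str = "tumor_id"
) -> list[RetestPair]:
    """Build retest pairs from two feature tables aligned on an id column."""
    merged = run1.merge(run2, on=id_column, suffixes=("_1", "_2"))
    features = [
        c for c in run1.columns
        if c != id_column and np.issubdtype(run1[c].dtype, np.number)
        and c in run2.columns
    ]
    return [
        RetestPair(
            feature=f,
            values_run1=merged[f + "_1"].to_numpy(),
            values_run2=merged[f + "_2"].to_numpy(),
        )
        for f in features
    ]
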